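"""Maximum-likelihood Gaussian linear mixed models with structured residuals.

Small, direct ML fitter for the two designs used here:

* random intercept per cluster (kitten), optional nested random intercept
  per subcluster (week within kitten);
* residual variance that may differ by an observation-level group (diet)
  and/or be scaled by known weights (variance proportional to 1/weight).

The marginal covariance is block-diagonal by cluster, so the profile
log-likelihood (beta profiled out by GLS) is accumulated cluster by
cluster with Cholesky factorisations of small blocks. Variance parameters
are optimised on the log scale with Nelder-Mead. ML (not REML) is used
throughout so that likelihood-ratio tests between nested models are valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass
class LMMFit:
    beta: np.ndarray
    beta_names: list[str]
    cov_beta: np.ndarray
    loglik: float
    tau2_cluster: float
    tau2_subcluster: float | None
    sigma2: dict
    converged: bool
    singular: bool
    n_obs: int

    def wald_p(self, idx: list[int]) -> float:
        """Joint Wald chi-square p-value for the listed coefficients."""
        from scipy.stats import chi2

        b = self.beta[idx]
        V = self.cov_beta[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        return float(chi2.sf(stat, len(idx)))


def _cluster_blocks(cluster: np.ndarray):
    order = np.argsort(cluster, kind="stable")
    sorted_c = cluster[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_c[1:] != sorted_c[:-1], True])
    return order, [(boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)]


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    cluster: np.ndarray,
    beta_names: list[str] | None = None,
    subcluster: np.ndarray | None = None,
    resid_group: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    reml: bool = False,
    maxiter: int = 2000,
) -> LMMFit:
    """Fit y = X beta + b_cluster (+ b_subcluster) + eps by ML or REML.

    eps_i ~ N(0, sigma2_{g(i)} / w_i). ``resid_group`` labels choose which
    sigma2 applies to each observation (one shared sigma2 when None);
    ``weights`` are known precision weights (None = 1). REML likelihoods
    are comparable between models with identical fixed effects, which is
    how the variance-heterogeneity test uses them.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    cluster = np.asarray(cluster)
    if beta_names is None:
        beta_names = [f"x{i}" for i in range(p)]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    groups = (
        np.zeros(n, dtype=int)
        if resid_group is None
        else np.unique(np.asarray(resid_group), return_inverse=True)[1]
    )
    group_labels = (
        ["sigma2"]
        if resid_group is None
        else [str(g) for g in np.unique(np.asarray(resid_group))]
    )
    n_sigma = len(group_labels)

    order, blocks = _cluster_blocks(cluster)
    ys, Xs, ws, gs = y[order], X[order], w[order], groups[order]
    subs = None if subcluster is None else np.asarray(subcluster)[order]

    use_sub = subcluster is not None

    # Fast path: equal-sized compound-symmetric blocks with one residual
    # variance per block (the kitten x week diversity design). The block
    # covariance sigma2 I_m + tau2 J_m has closed-form inverse and
    # determinant, and all blocks vectorise.
    sizes = {hi - lo for lo, hi in blocks}
    fast = (
        not use_sub
        and weights is None
        and len(sizes) == 1
        and all(len(np.unique(gs[lo:hi])) == 1 for lo, hi in blocks)
    )
    if fast:
        m = sizes.pop()
        B = len(blocks)
        Yb = ys.reshape(B, m)
        Xb = Xs.reshape(B, m, p)
        g_b = np.array([gs[lo] for lo, _ in blocks])
        XX = np.einsum("bmi,bmj->bij", Xb, Xb)
        X1 = Xb.sum(axis=1)  # (B, p)
        Xy = np.einsum("bmi,bm->bi", Xb, Yb)
        ysum = Yb.sum(axis=1)
        yy = (Yb**2).sum(axis=1)

        def profile_negll_fast(params):
            tau2 = np.exp(params[0])
            sig = np.exp(params[1 : 1 + n_sigma])
            s2 = sig[g_b]
            c = tau2 / (s2 * (s2 + m * tau2))
            XtViX = (
                XX / s2[:, None, None] - c[:, None, None] * X1[:, :, None] * X1[:, None, :]
            ).sum(axis=0)
            XtViy = (Xy / s2[:, None] - (c * ysum)[:, None] * X1).sum(axis=0)
            try:
                beta = np.linalg.solve(XtViX, XtViy)
            except np.linalg.LinAlgError:
                return 1e300, None, None, None
            rr = yy - 2 * Xy @ beta + np.einsum("i,bij,j->b", beta, XX, beta)
            rsum = ysum - X1 @ beta
            quad = (rr / s2 - c * rsum**2).sum()
            logdet = ((m - 1) * np.log(s2) + np.log(s2 + m * tau2)).sum()
            if reml:
                logdet += np.linalg.slogdet(XtViX)[1]
                ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + quad)
            else:
                ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
            return -ll, beta, XtViX, ll

    def build_V(block, params):
        lo, hi = block
        m = hi - lo
        tau2_c = np.exp(params[0])
        k = 1
        V = np.full((m, m), tau2_c)
        if use_sub:
            tau2_s = np.exp(params[1])
            k = 2
            sub_b = subs[lo:hi]
            same = sub_b[:, None] == sub_b[None, :]
            V = V + tau2_s * same
        sig = np.exp(params[k : k + n_sigma])
        resvar = sig[gs[lo:hi]] / ws[lo:hi]
        V[np.diag_indices(m)] += resvar
        return V

    def profile_negll(params):
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        logdet = 0.0
        chols = []
        try:
            for blk in blocks:
                lo, hi = blk
                V = build_V(blk, params)
                L = np.linalg.cholesky(V)
                chols.append((blk, L))
                logdet += 2.0 * np.log(np.diag(L)).sum()
                Lx = np.linalg.solve(L, Xs[lo:hi])
                Ly = np.linalg.solve(L, ys[lo:hi])
                XtViX += Lx.T @ Lx
                XtViy += Lx.T @ Ly
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError:
            # large finite penalty keeps Nelder-Mead's termination test happy
            return 1e300, None, None, None
        quad = 0.0
        for blk, L in chols:
            lo, hi = blk
            r = ys[lo:hi] - Xs[lo:hi] @ beta
            Lr = np.linalg.solve(L, r)
            quad += Lr @ Lr
        if reml:
            logdet += np.linalg.slogdet(XtViX)[1]
            ll = -0.5 * ((n - p) * np.log(2 * np.pi) + logdet + quad)
        else:
            ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
        return -ll, beta, XtViX, ll

    if fast:
        profile_negll = profile_negll_fast

    def objective(params):
        return profile_negll(params)[0]

    # Start values from the OLS residual variance, split half random / half
    # residual; log-scale parameters keep everything positive.
    beta_ols, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta_ols
    s2 = max(float(resid @ resid) / max(n - p, 1), 1e-10)
    x0 = [np.log(s2 / 2)]
    if use_sub:
        x0.append(np.log(s2 / 4))
    x0 += [np.log(s2 / 2)] * n_sigma
    x0 = np.array(x0)

    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-8, "fatol": 1e-10},
    )
    negll, beta, XtViX, ll = profile_negll(res.x)
    if beta is None:
        raise np.linalg.LinAlgError("mixed model covariance not positive definite")
    cov_beta = np.linalg.inv(XtViX)

    k = 2 if use_sub else 1
    tau2_c = float(np.exp(res.x[0]))
    tau2_s = float(np.exp(res.x[1])) if use_sub else None
    sig = {lab: float(np.exp(v)) for lab, v in zip(group_labels, res.x[k:])}
    scale = max(s2, 1e-12)
    singular = tau2_c / scale < 1e-8 or any(v / scale < 1e-8 for v in sig.values())
    return LMMFit(
        beta=beta,
        beta_names=list(beta_names),
        cov_beta=cov_beta,
        loglik=float(ll),
        tau2_cluster=tau2_c,
        tau2_subcluster=tau2_s,
        sigma2=sig,
        converged=bool(res.success),
        singular=singular,
        n_obs=n,
    )
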