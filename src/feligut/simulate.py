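"""Synthetic longitudinal metagenome count data with known ground truth.

Emulates the structure of a two-diet kitten feeding trial: 6 kittens per
diet (HPLC = high-protein low-carbohydrate, MPMC = moderate-protein
moderate-carbohydrate) sampled at weeks 8, 12 and 16, with a skewed feature
abundance profile (few dominant, many rare taxa), within-kitten correlation
across weeks, diet effects on the log-odds scale for a subset of features,
and pathway membership in which some pathways are enriched for
diet-affected ortholog groups.

Counts are drawn Dirichlet-multinomial: per sample, expected proportions
follow a multinomial-logit model (log baseline weight + per-kitten effect +
diet effect on affected features), a Dirichlet draw around those
proportions adds between-sample overdispersion, and a multinomial draw at
the realised library size produces integer counts. Because the model is
multinomial-logit, a shift ``delta`` on a single feature's log-weight is
exactly a ``delta`` shift of that feature's marginal log-odds — planted
effects are interpretable as the log odds ratios the differential-abundance
model estimates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import CountTable, PathwayMembership, TaxonomyMap

DIETS = ("HPLC", "MPMC")


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design: 6 kittens per diet, weeks {8, 12, 16},
    a log-normal baseline profile skewed enough that the 19 most abundant
    features carry more than half the reads, and library sizes of 1e5
    reads/sample (desk scale; the study's ~1e8 is configurable).
    """

    n_kittens_per_diet: int = 6
    weeks: tuple[int, ...] = (8, 12, 16)
    n_litters_per_diet: int = 2
    n_features: int = 150
    n_pathways: int = 25
    library_size_mean: float = 1e5
    library_size_cv: float = 0.2
    base_abundance_logmu: float = 0.0
    base_abundance_logsigma: float = 2.0
    kitten_effect_sd: float = 0.3
    diet_effect_log_or: float = 1.5
    prop_features_affected: float = 0.1
    prop_pathways_enriched: float = 0.2
    overdispersion: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_kittens_per_diet < 1:
            raise ConfigurationError("need at least one kitten per diet")
        if len(self.weeks) == 0:
            raise ConfigurationError("weeks must be non-empty")
        if self.n_litters_per_diet < 1:
            raise ConfigurationError("need at least one litter per diet")
        if self.n_features < 1 or self.n_pathways < 1:
            raise ConfigurationError("n_features and n_pathways must be >= 1")
        for name in ("prop_features_affected", "prop_pathways_enriched"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in (
            "library_size_mean",
            "library_size_cv",
            "kitten_effect_sd",
            "diet_effect_log_or",
            "overdispersion",
            "base_abundance_logsigma",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")
        if self.library_size_mean <= 0 or self.overdispersion <= 0:
            raise ConfigurationError("library_size_mean and overdispersion must be > 0")


@dataclass
class SyntheticTruth:
    """Generator ledger: what was planted, for recovery testing."""

    diet_log_or: pd.Series  # per-feature planted log odds ratio (MPMC vs HPLC)
    affected_features: list[str]
    enriched_pathways: list[str] = field(default_factory=list)
    library_sizes: pd.Series | None = None
    seed: int = 0


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Named substream so stages are independently reproducible."""
    key = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence(config.seed, spawn_key=(key,))
    return np.random.default_rng(ss)


def generate_design(config: SimulationConfig) -> pd.DataFrame:
    """Balanced two-diet longitudinal design, litters nested within diet.

    Returns one record per kitten x week with columns kitten, litter, diet,
    week, indexed by sample_id.
    """
    rows = []
    for d_idx, diet in enumerate(DIETS):
        for k in range(config.n_kittens_per_diet):
            kitten = f"K{d_idx * config.n_kittens_per_diet + k + 1:02d}"
            litter = f"L{d_idx * config.n_litters_per_diet + (k % config.n_litters_per_diet) + 1}"
            for week in config.weeks:
                rows.append(
                    {
                        "sample_id": f"{kitten}_w{week}",
                        "kitten": kitten,
                        "litter": litter,
                        "diet": diet,
                        "week": int(week),
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def _baseline_weights(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    logw = rng.normal(config.base_abundance_logmu, config.base_abundance_logsigma, config.n_features)
    return np.exp(logw)


def generate_counts(
    config: SimulationConfig,
    design: pd.DataFrame,
    level: str = "species",
    feature_prefix: str = "S",
) -> tuple[CountTable, SyntheticTruth]:
    """Draw a Dirichlet-multinomial count table over the given design.

    Planted diet effects carry a random sign (half the affected features up
    with MPMC, half up with HPLC) so the normalisation of the compositional
    model stays near 1 and the planted per-feature log odds ratio is the
    marginal effect the differential-abundance model targets.
    """
    feats = [f"{feature_prefix}{i + 1:04d}" for i in range(config.n_features)]
    rng_base = _rng(config, f"baseline:{feature_prefix}")
    base_w = _baseline_weights(config, rng_base)

    rng_fx = _rng(config, f"effects:{feature_prefix}")
    n_aff = int(round(config.prop_features_affected * config.n_features))
    affected = sorted(rng_fx.choice(config.n_features, size=n_aff, replace=False).tolist())
    signs = rng_fx.choice([-1.0, 1.0], size=n_aff)
    delta = np.zeros(config.n_features)
    delta[affected] = signs * config.diet_effect_log_or

    rng_kit = _rng(config, f"kitten:{feature_prefix}")
    kittens = sorted(design["kitten"].unique())
    kit_fx = {
        k: rng_kit.normal(0.0, config.kitten_effect_sd, config.n_features) for k in kittens
    }

    rng_counts = _rng(config, f"counts:{feature_prefix}")
    n_samples = len(design)
    if config.library_size_cv > 0:
        # Gamma with the requested mean and CV, rounded to integer reads.
        shape = 1.0 / config.library_size_cv**2
        scale = config.library_size_mean / shape
        lib = np.maximum(1, np.round(rng_counts.gamma(shape, scale, n_samples))).astype(np.int64)
    else:
        lib = np.full(n_samples, int(round(config.library_size_mean)), dtype=np.int64)

    counts = np.zeros((config.n_features, n_samples), dtype=np.int64)
    log_base = np.log(base_w)
    for j, (sample_id, row) in enumerate(design.iterrows()):
        eta = log_base + kit_fx[row["kitten"]]
        if row["diet"] == "MPMC":
            eta = eta + delta
        w = np.exp(eta - eta.max())
        p = w / w.sum()
        if np.isfinite(config.overdispersion) and config.overdispersion > 0:
            p = rng_counts.dirichlet(config.overdispersion * p)
            # Dirichlet can return exact zeros for tiny concentrations.
            p = np.maximum(p, 1e-300)
            p = p / p.sum()
        counts[:, j] = rng_counts.multinomial(lib[j], p)

    table = CountTable(
        counts=pd.DataFrame(counts, index=feats, columns=design.index),
        level=level,
    )
    truth = SyntheticTruth(
        diet_log_or=pd.Series(delta, index=feats),
        affected_features=[feats[i] for i in affected],
        library_sizes=pd.Series(lib, index=design.index),
        seed=config.seed,
    )
    return table, truth


def generate_taxonomy(
    config: SimulationConfig,
    species_ids: Sequence[str],
    mean_species_per_genus: float = 3.0,
) -> TaxonomyMap:
    """Random nested hierarchy above the species level.

    Genera group species; each higher rank groups the rank below it by a
    factor of ~3, keeping the mapping functional (one parent per rank).
    """
    rng = _rng(config, "taxonomy")
    n_sp = len(species_ids)
    n_gen = max(1, int(round(n_sp / mean_species_per_genus)))
    genus_of = rng.integers(0, n_gen, n_sp)
    levels = {"genus": [f"g{g + 1:03d}" for g in genus_of]}
    prev_n, prev_assign = n_gen, genus_of
    for rank, tag in (("family", "f"), ("order", "o"), ("class", "c"), ("phylum", "p")):
        n_up = max(1, prev_n // 3)
        up_of_prev = rng.integers(0, n_up, prev_n)
        assign = up_of_prev[prev_assign]
        levels[rank] = [f"{tag}{a + 1:03d}" for a in assign]
        prev_n, prev_assign = n_up, assign
    levels["superkingdom"] = ["Bacteria"] * n_sp
    df = pd.DataFrame(levels, index=pd.Index(species_ids, name="species"))
    return TaxonomyMap(table=df)


def generate_pathway_membership(
    config: SimulationConfig,
    og_ids: Sequence[str],
    truth: SyntheticTruth | None = None,
    mean_pathway_size: float = 12.0,
    enrichment_boost: float = 5.0,
) -> tuple[PathwayMembership, list[str]]:
    """Many-to-many pathway membership with planted enrichment.

    Each pathway samples members from the ortholog-group pool; enriched
    pathways (a ``prop_pathways_enriched`` fraction) sample diet-affected
    groups with ``enrichment_boost``-fold higher probability. Database sizes
    exceed realised memberships by a Poisson-distributed margin, mimicking
    reference pathways only partially observed in the metagenome. Some
    groups land in more than one pathway by construction.
    """
    if len(og_ids) == 0:
        raise ConfigurationError("og_ids must be non-empty")
    rng = _rng(config, "membership")
    og_ids = list(og_ids)
    n = len(og_ids)
    affected_mask = np.zeros(n, dtype=bool)
    if truth is not None:
        aff = set(truth.affected_features)
        affected_mask = np.array([og in aff for og in og_ids])

    n_enriched = int(round(config.prop_pathways_enriched * config.n_pathways))
    enriched_idx = set(rng.choice(config.n_pathways, size=n_enriched, replace=False).tolist())

    pairs = []
    sizes: dict[str, int] = {}
    enriched_names = []
    for p in range(config.n_pathways):
        name = f"pw{p + 1:03d}"
        size = max(2, rng.poisson(mean_pathway_size))
        size = min(size, n)
        w = np.ones(n)
        if p in enriched_idx and affected_mask.any():
            w[affected_mask] = enrichment_boost
            enriched_names.append(name)
        w = w / w.sum()
        members = rng.choice(n, size=size, replace=False, p=w)
        for m in members:
            pairs.append((og_ids[m], name))
        sizes[name] = size + int(rng.poisson(0.4 * mean_pathway_size))
    if truth is not None:
        truth.enriched_pathways = enriched_names
    membership = PathwayMembership(
        pairs=pd.DataFrame(pairs, columns=["ortholog_group", "pathway"]),
        database_size=sizes,
    )
    return membership, enriched_names


def simulate_study(config: SimulationConfig) -> dict:
    """Full synthetic study: design, species and OG tables, taxonomy, pathways.

    Returns a dict with keys design, species_table, og_table, taxonomy,
    membership, truth_species, truth_og.
    """
    design = generate_design(config)
    sp_table, truth_sp = generate_counts(config, design, level="species", feature_prefix="S")
    og_table, truth_og = generate_counts(
        config, design, level="ortholog_group", feature_prefix="K"
    )
    taxonomy = generate_taxonomy(config, sp_table.feature_ids)
    membership, _ = generate_pathway_membership(config, og_table.feature_ids, truth_og)
    return {
        "design": design,
        "species_table": sp_table,
        "og_table": og_table,
        "taxonomy": taxonomy,
        "membership": membership,
        "truth_species": truth_sp,
        "truth_og": truth_og,
        "config": asdict(config),
    }
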