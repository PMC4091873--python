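import numpy as np
import pandas as pd
import pytest

from feligut.simulate import SimulationConfig, generate_counts, generate_design


@pytest.fixture(scope="session")
def study_design():
    """The 12-kitten x 3-week two-diet design."""
    return generate_design(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study reused by read-only tests."""
    cfg = SimulationConfig(
        n_features=60,
        n_pathways=12,
        library_size_mean=30000,
        seed=42,
    )
    design = generate_design(cfg)
    table, truth = generate_counts(cfg, design)
    return cfg, design, table, truth


@pytest.fixture()
def tiny_counts():
    """3 features x 2 samples with column sums (12, 7)."""
    df = pd.DataFrame(
        {"s1": [3, 4, 5], "s2": [1, 2, 4]},
        index=["fA", "fB", "fC"],
    )
    from feligut.tables import CountTable

    return CountTable(counts=df, level="genus")


def balanced_metadata(n_per_diet=6, weeks=(8, 12, 16)):
    rows = []
    for d_idx, diet in enumerate(("HPLC", "MPMC")):
        for k in range(n_per_diet):
            kitten = f"K{d_idx * n_per_diet + k + 1:02d}"
            for w in weeks:
                rows.append(
                    {
                        "sample_id": f"{kitten}_w{w}",
                        "kitten": kitten,
                        "litter": f"L{d_idx + 1}",
                        "diet": diet,
                        "week": w,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")
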