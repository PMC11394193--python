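import numpy as np
import pandas as pd
import pytest

from refstab import (CqTable, SampleMeta, collapse_technical_replicates,
                     relative_quantity, simulate_musc_panel)


def make_cq_table(values: dict[str, list[float]], groups: list[str],
                  bio_reps: list[int] | None = None,
                  tech_reps: list[int] | None = None,
                  sample_ids: list[str] | None = None) -> CqTable:
    """Small-panel constructor used throughout the suite."""
    n = len(next(iter(values.values())))
    bio_reps = bio_reps or list(range(1, n + 1))
    tech_reps = tech_reps or [1] * n
    if sample_ids is None:
        sample_ids = [f"{g}_{b}" if t == 1 else f"{g}_{b}_t{t}"
                      for g, b, t in zip(groups, bio_reps, tech_reps)]
    samples = [SampleMeta(s, g, b, t)
               for s, g, b, t in zip(sample_ids, groups, bio_reps, tech_reps)]
    frame = pd.DataFrame(values, index=sample_ids).T
    return CqTable(frame, samples)


@pytest.fixture
def three_gene_table() -> CqTable:
    """Hand panel whose log2 Q vectors are A=(0,0,0), B=(0,-1,-2),
    C=(0,-2,-4): pairwise variations V_AB=1, V_AC=2, V_BC=1."""
    return make_cq_table(
        {"A": [20.0, 20.0, 20.0], "B": [20.0, 21.0, 22.0],
         "C": [20.0, 22.0, 24.0]},
        groups=["GM", "GM", "GM"],
    )


@pytest.fixture(scope="session")
def musc_panel():
    return simulate_musc_panel(7)


@pytest.fixture(scope="session")
def musc_collapsed(musc_panel):
    table, _ = musc_panel
    collapsed, _ = collapse_technical_replicates(table)
    return collapsed


@pytest.fixture(scope="session")
def musc_q(musc_collapsed):
    return relative_quantity(musc_collapsed)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240826)


def random_rel_quant(rng: np.random.Generator, n_genes: int = 5,
                     n_samples: int = 6):
    """Random valid relative-quantity matrix via a random Cq panel."""
    cq = rng.uniform(15, 30, size=(n_genes, n_samples))
    genes = [f"G{i}" for i in range(n_genes)]
    groups = ["X"] * (n_samples // 2) + ["Y"] * (n_samples - n_samples // 2)
    table = make_cq_table(
        {g: list(cq[i]) for i, g in enumerate(genes)},
        groups=groups,
        bio_reps=[i % (n_samples // 2) + 1 if n_samples >= 4 else i + 1
                  for i in range(n_samples)],
    )
    return relative_quantity(table)
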