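"""Synthetic Cq panels, FPKM matrices, and dilution series with known truth.

The generative model for a Cq panel is

    Cq[g, well] = base_g + effect_g(group) + loading_b + eps,
    eps ~ N(0, noise_sd),  loading_b ~ N(0, loading_sd),

where ``loading_b`` is drawn once per biological sample and shared by all
genes (and all technical replicates) of that sample — exactly the
template-input variation that reference-gene normalization is designed to
remove — and ``eps`` is independent per well.  Group effects are additive on
the Cq scale, i.e. multiplicative on transcript abundance.  All random draws
happen before effects are applied, so re-running with the same seed but
different effect sizes reuses identical noise (useful for monotonicity
checks).

Defaults emulate a three-phase cell-culture design (proliferation GM,
differentiation days DM1/DM5) with 3 biological × 3 technical replicates and
0.15-cycle technical noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_model import CqTable, ExpressionMatrix, SampleMeta

__all__ = [
    "SimTruth",
    "DilutionSeries",
    "simulate_cq_panel",
    "simulate_musc_panel",
    "musc_panel_truth",
    "simulate_fpkm_matrix",
    "simulate_dilution_series",
    "DEFAULT_GROUPS",
]

DEFAULT_GROUPS = ("GM", "DM1", "DM5")

#: Default per-well technical noise SD, cycles.
DEFAULT_NOISE_SD = 0.15


@dataclass
class SimTruth:
    """Ground truth behind one simulated Cq panel."""

    base_cq: dict[str, float]
    group_effects: dict[str, dict[str, float]]
    loading_sd: float
    noise_sd: float
    seed: int
    stable_genes: tuple[str, ...] = ()
    unstable_genes: tuple[str, ...] = ()
    loadings: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.loading_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        for g in self.stable_genes:
            effs = self.group_effects.get(g, {})
            if any(v != 0 for v in effs.values()):
                raise ValueError(f"gene {g!r} labeled stable but has group effects")

    def effect(self, gene: str, group: str) -> float:
        return float(self.group_effects.get(gene, {}).get(group, 0.0))


@dataclass
class DilutionSeries:
    """Standard-curve data: Cq at each relative template input."""

    rel_inputs: np.ndarray          # relative concentration per level, descending
    cq: pd.DataFrame                # rows = dilution levels, cols = replicates
    e_true: float

    def __post_init__(self) -> None:
        self.rel_inputs = np.asarray(self.rel_inputs, dtype=float)
        if len(self.rel_inputs) < 3:
            raise ValueError("need >= 3 dilution points")
        if not np.all(np.diff(self.rel_inputs) < 0):
            raise ValueError("relative inputs must be strictly decreasing")
        if not 0 < self.e_true <= 1.2:
            raise ValueError("true efficiency must lie in (0, 1.2]")

    def long_form(self) -> pd.DataFrame:
        rows = []
        for i, rel in enumerate(self.rel_inputs):
            for rep, val in enumerate(self.cq.iloc[i], start=1):
                rows.append({"rel_input": rel, "replicate": rep, "cq": val})
        return pd.DataFrame(rows)


def simulate_cq_panel(
    truth: SimTruth,
    n_groups: int = 3,
    n_bio: int = 3,
    n_tech: int = 3,
    group_names: tuple[str, ...] | None = None,
) -> tuple[CqTable, SimTruth]:
    """Draw one Cq panel from the generative model; the returned truth copy
    records the drawn per-sample loadings."""
    if min(n_groups, n_bio, n_tech) < 1:
        raise ValueError("counts must be >= 1")
    if group_names is None:
        group_names = (DEFAULT_GROUPS[:n_groups] if n_groups <= 3 else
                       tuple(f"G{i+1}" for i in range(n_groups)))
    if len(group_names) != n_groups:
        raise ValueError("group_names length must equal n_groups")

    rng = np.random.default_rng(truth.seed)
    genes = list(truth.base_cq)
    bio_keys = [(g, b) for g in group_names for b in range(1, n_bio + 1)]
    loadings = {f"{g}_{b}": rng.normal(0.0, truth.loading_sd)
                for g, b in bio_keys}
    n_wells = n_groups * n_bio * n_tech
    noise = rng.normal(0.0, truth.noise_sd, size=(len(genes), n_wells))

    samples, columns = [], {}
    w = 0
    for group, bio in bio_keys:
        for tech in range(1, n_tech + 1):
            sid = f"{group}_{bio}_t{tech}" if n_tech > 1 else f"{group}_{bio}"
            samples.append(SampleMeta(sid, group, bio, tech))
            col = np.array([
                truth.base_cq[g] + truth.effect(g, group)
                + loadings[f"{group}_{bio}"] + noise[i, w]
                for i, g in enumerate(genes)
            ])
            columns[sid] = col
            w += 1

    values = pd.DataFrame(columns, index=genes)
    table = CqTable(values, samples)
    return table, replace(truth, loadings=loadings)


def musc_panel_truth(seed: int,
                     noise_sd: float = DEFAULT_NOISE_SD,
                     loading_sd: float = 0.3) -> SimTruth:
    """Truth for a ten-gene panel shaped like the goat MuSC candidate set:
    eight screened genes with no differentiation response (stable), one
    GAPDH-like gene with a moderate response, one ACTB-like gene whose Cq
    shifts by >= 1 cycle between proliferation and late differentiation."""
    base = {
        "RPL14": 15.6, "RPL5": 16.2, "RPS15A": 16.5, "YBX1": 17.0,
        "CAPNS1": 18.0, "HSPA9": 18.5, "DDOST": 19.2, "EEF1G": 19.8,
        "GAPDH": 17.5, "ACTB": 16.0,
    }
    effects = {
        "GAPDH": {"GM": 0.0, "DM1": 0.25, "DM5": 0.5},
        "ACTB": {"GM": 0.0, "DM1": 0.7, "DM5": 1.4},
    }
    stable = tuple(g for g in base if g not in effects)
    return SimTruth(base, effects, loading_sd, noise_sd, seed,
                    stable_genes=stable, unstable_genes=("GAPDH", "ACTB"))


def simulate_musc_panel(
    seed: int,
    noise_sd: float = DEFAULT_NOISE_SD,
    loading_sd: float = 0.3,
) -> tuple[CqTable, SimTruth]:
    """10 genes × (3 groups × 3 biological × 3 technical) wells with the
    designed stable/GAPDH-like/ACTB-like structure; base Cq within the
    plausible 15–21 band for abundant transcripts."""
    truth = musc_panel_truth(seed, noise_sd=noise_sd, loading_sd=loading_sd)
    return simulate_cq_panel(truth, n_groups=3, n_bio=3, n_tech=3)


def simulate_fpkm_matrix(
    n_genes: int = 50,
    n_samples: int = 9,
    n_candidates: int = 8,
    seed: int = 0,
    fpkm_min: float = 100.0,
    cv_max: float = 10.0,
) -> tuple[ExpressionMatrix, list[str]]:
    """FPKM matrix in which exactly ``n_candidates`` genes satisfy
    mean FPKM > ``fpkm_min`` and CV < ``cv_max`` %; every other gene violates
    at least one criterion.  Returns the matrix and the candidate gene names.

    Non-candidates alternate between low-expression genes (mean well below
    the FPKM floor) and noisy high-expression genes (CV well above the cap);
    each gene is redrawn until its realised sample statistics respect its
    designed class, so the truth labels are exact by construction.
    """
    if n_candidates >= n_genes:
        raise ValueError("n_candidates must be < n_genes")
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    rng = np.random.default_rng(seed)

    def _draw(mean: float, cv_pct: float) -> np.ndarray:
        sigma = np.sqrt(np.log1p((cv_pct / 100.0) ** 2))
        vals = mean * rng.lognormal(-sigma**2 / 2, sigma, size=n_samples)
        return vals

    def _stats(x: np.ndarray) -> tuple[float, float]:
        m = x.mean()
        return m, 100.0 * x.std(ddof=1) / m

    rows, candidates = {}, []
    for i in range(n_genes):
        if i < n_candidates:
            name = f"CAND{i+1:02d}"
            ok = lambda m, cv: m > fpkm_min and cv < cv_max and m < 10 * fpkm_min
            draw = lambda: _draw(rng.uniform(1.5, 8) * fpkm_min,
                                 rng.uniform(2, 0.7 * cv_max))
            candidates.append(name)
        elif i % 2 == 0:
            name = f"LOW{i+1:03d}"   # fails the expression floor
            ok = lambda m, cv: m <= fpkm_min
            draw = lambda: _draw(rng.uniform(0.02, 0.6) * fpkm_min,
                                 rng.uniform(5, 40))
        else:
            name = f"VAR{i+1:03d}"   # abundant but noisy: fails the CV cap
            ok = lambda m, cv: m > fpkm_min and cv >= cv_max
            draw = lambda: _draw(rng.uniform(1.5, 8) * fpkm_min,
                                 rng.uniform(2.5 * cv_max, 6 * cv_max))
        for _ in range(1000):
            vals = draw()
            if ok(*_stats(vals)):
                break
        else:  # pragma: no cover - parameters make this unreachable
            raise RuntimeError(f"could not realise design for gene {name}")
        rows[name] = vals

    return ExpressionMatrix(pd.DataFrame(rows).T), candidates


def simulate_dilution_series(
    e_true: float = 1.0,
    intercept: float = 20.0,
    n_points: int = 5,
    n_reps: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    dilution_step: float = 10.0,
) -> DilutionSeries:
    """Gradient-diluted standard curve:
    Cq = intercept − log10(rel_input) / log10(1 + e_true) + noise."""
    if not 0 < e_true <= 1.2:
        raise ValueError("e_true must lie in (0, 1.2]")
    if n_points < 3:
        raise ValueError("need >= 3 dilution points")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rel = dilution_step ** (-np.arange(n_points, dtype=float))
    slope = -1.0 / np.log10(1.0 + e_true)
    clean = intercept + slope * np.log10(rel)
    cq = clean[:, None] + rng.normal(0.0, noise_sd, size=(n_points, n_reps))
    frame = pd.DataFrame(cq, columns=[f"rep{r+1}" for r in range(n_reps)])
    return DilutionSeries(rel, frame, e_true)
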