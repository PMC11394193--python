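"""geNorm stability analysis.

For genes j, k with relative quantities Q, the pairwise variation
V_jk = SD_s[ log2(Q_j(s)/Q_k(s)) ] measures how far the two genes are from
a constant ratio; a gene's expression stability M_j is the average of its
V_jk over all partners.  Ranking proceeds by stepwise exclusion of the
gene with the largest M.  The pairwise-variation curve V_{n/n+1} between
normalization factors built from the n and n+1 most stable genes decides
how many references are needed: the smallest n with V_{n/n+1} below a
threshold (conventionally 0.15).

All SDs use the n−1 denominator and all ratios are log base 2.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import RelQuantMatrix, StabilityResult

__all__ = [
    "GenormResult",
    "pairwise_variation_matrix",
    "m_values",
    "genorm_ranking",
    "v_curve",
    "genorm_full",
    "normalization_factor",
]

V_THRESHOLD = 0.15


@dataclass
class GenormResult:
    m_full: pd.Series                 # full-panel M per gene
    rank: pd.Series                   # 1 = most stable
    trace: list[dict] = field(default_factory=list)
    v_values: pd.Series | None = None # index n, value V_{n/n+1}
    optimal_n: int | None = None
    v_threshold: float = V_THRESHOLD
    v_warning: str | None = None

    def ordered_genes(self) -> list[str]:
        return list(self.rank.sort_values().index)

    def to_stability(self) -> StabilityResult:
        extras = {"trace": self.trace, "v_values": self.v_values,
                  "optimal_n": self.optimal_n}
        return StabilityResult("genorm", self.m_full, self.rank, extras)


def _log_q(q: RelQuantMatrix) -> np.ndarray:
    v = q.values.to_numpy(dtype=float)
    if (v <= 0).any():
        raise ValueError("all relative quantities must be > 0")
    return np.log2(v)


def pairwise_variation_matrix(q: RelQuantMatrix) -> pd.DataFrame:
    """Symmetric gene × gene matrix of V_jk = SD over samples of the pairwise
    log2 quantity ratio (zero diagonal)."""
    a = _log_q(q)
    k, n = a.shape
    if k < 2 or n < 2:
        raise ValueError("need >= 2 genes and >= 2 samples")
    diff = a[:, None, :] - a[None, :, :]
    v = diff.std(axis=2, ddof=1)
    np.fill_diagonal(v, 0.0)
    return pd.DataFrame(v, index=q.genes, columns=q.genes)


def m_values(q: RelQuantMatrix) -> pd.Series:
    """M_j = mean over partners k≠j of V_jk; lower = more stable."""
    if len(q.genes) < 2:
        raise ValueError("M values need >= 2 genes")
    v = pairwise_variation_matrix(q)
    k = v.shape[0]
    return (v.sum(axis=1) / (k - 1)).rename("M")


def genorm_ranking(q: RelQuantMatrix) -> GenormResult:
    """Stepwise-exclusion ranking.

    Repeatedly removes the gene with the largest M on the surviving set
    (ties broken lexicographically and recorded in the trace) until two
    genes remain; geNorm cannot separate the final pair, so their ranks 1–2
    are ordered by full-panel M, ties again lexicographic.
    """
    genes = list(q.genes)
    if len(genes) < 3:
        raise ValueError("stepwise ranking needs >= 3 genes")
    m_full = m_values(q)

    rank = pd.Series(0, index=genes, dtype=int)
    trace: list[dict] = []
    current = list(genes)
    while len(current) > 2:
        m = m_values(q.subset_genes(current))
        worst_val = m.max()
        at_max = sorted(m.index[m == worst_val])
        removed = at_max[0]
        trace.append({
            "set_size": len(current),
            "m": m.copy(),
            "removed": removed,
            "tie": at_max if len(at_max) > 1 else None,
        })
        rank[removed] = len(current)
        current.remove(removed)

    # final pair: order by full-panel M, tie -> lexicographic
    a, b = sorted(current, key=lambda g: (m_full[g], g))
    rank[a], rank[b] = 1, 2
    trace.append({"set_size": 2, "m": m_values(q.subset_genes(current)),
                  "removed": None,
                  "final_pair_order": [a, b]})
    return GenormResult(m_full, rank, trace)


def normalization_factor(q: RelQuantMatrix, genes: list[str]) -> pd.Series:
    """Per-sample geometric mean of the chosen genes' quantities."""
    sub = np.log2(q.values.loc[genes].to_numpy())
    return pd.Series(np.power(2.0, sub.mean(axis=0)), index=q.sample_ids)


def v_curve(
    q: RelQuantMatrix,
    ranking: list[str] | None = None,
    threshold: float = V_THRESHOLD,
) -> tuple[pd.Series, int, str | None]:
    """Pairwise variation V_{n/n+1} for n = 2..k−1 along a stability ranking.

    V_{n/n+1} = SD over samples of log2(NF_n/NF_{n+1}) where NF_n is the
    geometric-mean normalization factor of the n most stable genes.  The
    optimal number of references is the smallest n with V_{n/n+1} below the
    threshold; if no V clears it, k is reported with a warning.
    """
    k = len(q.genes)
    if k < 3:
        raise ValueError("V curve needs >= 3 genes")
    if ranking is None:
        ranking = genorm_ranking(q).ordered_genes()
    if sorted(ranking) != sorted(q.genes):
        raise ValueError("ranking must be a permutation of the panel's genes")

    values = {}
    for n in range(2, k):
        nf_n = np.log2(normalization_factor(q, ranking[:n]).to_numpy())
        nf_n1 = np.log2(normalization_factor(q, ranking[: n + 1]).to_numpy())
        values[n] = float(np.std(nf_n - nf_n1, ddof=1))
    v = pd.Series(values, name="V")

    below = [n for n, val in values.items() if val < threshold]
    if below:
        return v, min(below), None
    msg = (f"no V_n/n+1 below {threshold}; all {k} genes may be needed")
    warnings.warn(msg, stacklevel=2)
    return v, k, msg


def genorm_full(q: RelQuantMatrix,
                threshold: float = V_THRESHOLD) -> GenormResult:
    """Ranking plus V curve in one result."""
    res = genorm_ranking(q)
    v, n_opt, warn = v_curve(q, res.ordered_genes(), threshold)
    res.v_values, res.optimal_n = v, n_opt
    res.v_threshold, res.v_warning = threshold, warn
    return res
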