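r"""Model-based (NormFinder-style) stability estimation.

Work on y_igj = log2 Q for gene i, group g, sample j.  The model is

    y_igj = alpha_ig + beta_gj + e_igj,   Var(e_igj) = sigma2_ig,

where beta_gj is a sample (loading) effect common to all genes and alpha_ig
splits into a gene level plus a gene-by-group interaction d_ig.  An unstable
gene is one with a large intragroup variance sigma2_ig or a large systematic
group difference d_ig.

Estimation, with k genes, G groups, n_g samples in group g:

1. sample-centering removes beta:  z_igj = y_igj − mean_i y_igj
2. naive within-group variances s2_ig = Var_j(z_igj) (n−1 denominator) are
   biased by the centering: E[s2_ig] = sigma2_ig (1 − 2/k) + sbar2_g / k
   with sbar2_g the group's gene-averaged variance.  Setting
   sbar2_g = (k/(k−1)) · mean_i s2_ig and inverting gives the unbiased
   sigma2_ig = max(0, (s2_ig − sbar2_g/k) / (1 − 2/k))      (needs k ≥ 3)
3. group differences d_ig = zbar_ig − mean_g zbar_ig (sum to 0 per gene)
4. intergroup variance by moments:
   gamma2_i = max(0, sum_g d_ig^2/(G−1) − mean_g sigma2_ig/n_g)
5. shrinkage of the observed differences toward 0:
   dtilde_ig = d_ig · gamma2_i / (gamma2_i + sigma2_ig/n_g)
6. stability value (lower = more stable):
   rho_i = mean_g [ |dtilde_ig|
                    + sqrt( (gamma2_i · sigma2_ig/n_g)
                            / (gamma2_i + sigma2_ig/n_g) ) ]
   with both shrinkage terms defined as 0 when their denominator is 0.

With a single group the interaction vanishes and the stability value
reduces to the pooled intragroup SD sqrt(sigma2_i).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import RelQuantMatrix, StabilityResult

__all__ = ["NormfinderResult", "normfinder_stability", "normfinder_ungrouped"]


@dataclass
class NormfinderResult:
    stability: pd.Series            # rho per gene (lower = more stable)
    rank: pd.Series
    sigma2: pd.DataFrame            # genes × groups intragroup variances
    d: pd.DataFrame                 # genes × groups differences (sum 0/row)
    d_shrunk: pd.DataFrame
    gamma2: pd.Series               # intergroup variance per gene
    grouped: bool

    def ordered_genes(self) -> list[str]:
        return list(self.rank.sort_values().index)

    def to_stability(self) -> StabilityResult:
        return StabilityResult(
            "normfinder", self.stability, self.rank,
            {"sigma2": self.sigma2, "d": self.d, "d_shrunk": self.d_shrunk,
             "gamma2": self.gamma2, "grouped": self.grouped},
        )


def _rank_ascending(stat: pd.Series) -> pd.Series:
    order = sorted(stat.index, key=lambda g: (stat[g], g))
    return pd.Series({g: i + 1 for i, g in enumerate(order)},
                     name="rank").loc[stat.index]


def _decompose(y: np.ndarray, group_cols: list[np.ndarray]):
    """Per-group centering and variance deconvolution; returns per-group
    unbiased sigma2 (clamped), group means of centered data, and counts."""
    k = y.shape[0]
    if k <= 2:
        raise ValueError("variance decomposition needs >= 3 genes")
    sigma2, zbar, n_g = [], [], []
    for cols in group_cols:
        z = y[:, cols] - y[:, cols].mean(axis=0, keepdims=True)
        s2 = z.var(axis=1, ddof=1)
        sbar2 = (k / (k - 1)) * s2.mean()
        sig = (s2 - sbar2 / k) / (1.0 - 2.0 / k)
        sigma2.append(np.maximum(sig, 0.0))
        zbar.append(z.mean(axis=1))
        n_g.append(len(cols))
    return (np.column_stack(sigma2), np.column_stack(zbar),
            np.asarray(n_g, dtype=float))


def normfinder_stability(q: RelQuantMatrix,
                         groups: pd.Series | None = None) -> NormfinderResult:
    """Grouped stability values; falls back to the ungrouped estimator (with
    a warning) when fewer than two groups are present.

    ``groups`` maps sample_id → group label; defaults to the metadata
    carried by ``q``.  Every group must contain at least two samples.
    """
    if groups is None:
        groups = q.groups
    groups = groups.loc[q.sample_ids]
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        warnings.warn("fewer than 2 groups; using ungrouped stability",
                      stacklevel=2)
        return normfinder_ungrouped(q)
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has < 2 samples")

    y = np.log2(q.values.to_numpy(dtype=float))
    cols = [np.flatnonzero((groups == lab).to_numpy()) for lab in labels]
    sigma2, zbar, n_g = _decompose(y, cols)
    G = len(labels)

    d = zbar - zbar.mean(axis=1, keepdims=True)
    gamma2 = np.maximum(
        (d ** 2).sum(axis=1) / (G - 1) - (sigma2 / n_g).mean(axis=1), 0.0
    )
    denom = gamma2[:, None] + sigma2 / n_g
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(denom > 0, gamma2[:, None] / denom, 0.0)
        var_term = np.where(denom > 0,
                            (gamma2[:, None] * sigma2 / n_g) / denom, 0.0)
    d_shrunk = d * shrink
    rho = (np.abs(d_shrunk) + np.sqrt(var_term)).mean(axis=1)

    genes = q.genes
    stability = pd.Series(rho, index=genes, name="stability")
    return NormfinderResult(
        stability, _rank_ascending(stability),
        pd.DataFrame(sigma2, index=genes, columns=labels),
        pd.DataFrame(d, index=genes, columns=labels),
        pd.DataFrame(d_shrunk, index=genes, columns=labels),
        pd.Series(gamma2, index=genes, name="gamma2"),
        grouped=True,
    )


def normfinder_ungrouped(q: RelQuantMatrix) -> NormfinderResult:
    """All samples as one group; stability = pooled intragroup SD."""
    y = np.log2(q.values.to_numpy(dtype=float))
    cols = [np.arange(y.shape[1])]
    sigma2, _, _ = _decompose(y, cols)
    genes = q.genes
    stability = pd.Series(np.sqrt(sigma2[:, 0]), index=genes, name="stability")
    zeros = pd.DataFrame(0.0, index=genes, columns=["all"])
    return NormfinderResult(
        stability, _rank_ascending(stability),
        pd.DataFrame(sigma2, index=genes, columns=["all"]),
        zeros, zeros.copy(),
        pd.Series(0.0, index=genes, name="gamma2"),
        grouped=False,
    )
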