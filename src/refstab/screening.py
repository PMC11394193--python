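"""Candidate reference-gene screening from an RNA-seq expression matrix.

A good reference candidate is abundant and flat across conditions: the
screen keeps genes with aggregate FPKM strictly above a floor (default 100)
and coefficient of variation strictly below a cap (default 10%), ranked
ascending by CV, and returns at most ``top_k`` of them.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix

__all__ = ["ScreeningResult", "gene_cv", "screen_candidates"]


@dataclass
class ScreeningResult:
    table: pd.DataFrame            # gene, agg_fpkm, cv_pct, pass_fpkm, pass_cv, excluded_reason
    candidates: list[str]          # ascending CV, ties lexicographic
    fpkm_min: float
    cv_max: float
    top_k: int
    warning: str | None = None

    def candidate_frame(self) -> pd.DataFrame:
        """candidates.csv payload: gene, mean_fpkm, cv_pct, rank."""
        sub = self.table.loc[self.candidates, ["agg_fpkm", "cv_pct"]].copy()
        sub.insert(0, "gene", sub.index)
        sub["rank"] = np.arange(1, len(sub) + 1)
        return sub.reset_index(drop=True)


def gene_cv(x: ExpressionMatrix) -> pd.Series:
    """Per-gene CV% = 100·SD/mean (SD with n−1 denominator).

    Genes with zero mean have no defined CV and are returned as NaN; the
    screen records them as excluded-with-reason rather than propagating NaN.
    """
    if x.values.shape[1] < 2:
        raise ValueError("CV needs >= 2 samples")
    mean = x.values.mean(axis=1)
    sd = x.values.std(axis=1, ddof=1)
    cv = pd.Series(np.full(len(mean), np.nan), index=mean.index, name="cv_pct")
    ok = mean > 0
    cv[ok] = 100.0 * sd[ok] / mean[ok]
    return cv


def screen_candidates(
    x: ExpressionMatrix,
    fpkm_min: float = 100.0,
    cv_max: float = 10.0,
    top_k: int = 8,
    fpkm_agg: str = "mean",
) -> ScreeningResult:
    """Apply the strict two-criterion screen (agg FPKM > fpkm_min AND
    CV < cv_max) and rank passers ascending by CV, ties broken by gene
    symbol.  If fewer than ``top_k`` genes pass, all passers are returned
    with a warning."""
    if fpkm_min <= 0 or cv_max <= 0 or top_k < 1:
        raise ValueError("thresholds must be strictly positive")
    if fpkm_agg not in ("mean", "min", "median"):
        raise ValueError("fpkm_agg must be mean, min or median")

    agg = getattr(x.values, fpkm_agg)(axis=1)
    cv = gene_cv(x)
    pass_fpkm = agg > fpkm_min
    pass_cv = cv < cv_max            # NaN compares False: zero-mean genes fail

    reason = pd.Series("", index=x.values.index, dtype=object)
    reason[cv.isna()] = "zero_mean_expression"
    table = pd.DataFrame({
        "agg_fpkm": agg, "cv_pct": cv,
        "pass_fpkm": pass_fpkm, "pass_cv": pass_cv,
        "excluded_reason": reason,
    })

    passers = table[pass_fpkm & pass_cv]
    # CV ascending; exact CV ties in lexicographic gene order
    passers = passers.loc[
        sorted(passers.index, key=lambda g: (passers.loc[g, "cv_pct"], g))
    ]
    warning = None
    if len(passers) < top_k:
        warning = (f"only {len(passers)} genes pass the screen "
                   f"(requested top_k={top_k})")
        warnings.warn(warning, stacklevel=2)
    candidates = list(passers.index[:top_k])
    return ScreeningResult(table, candidates, fpkm_min, cv_max, top_k, warning)
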