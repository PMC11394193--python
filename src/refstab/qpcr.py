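"""qPCR numerics: amplification efficiency, relative quantities, ΔΔCt.

Efficiency comes from the standard-curve slope: an assay that doubles
template every cycle has slope −1/log10(2) ≈ −3.32 cycles per 10-fold
dilution, i.e. E = 100·(10^(−1/slope) − 1) = 100%.  Relative quantities use
the base-2 convention Q = 2^(−ΔCq) anchored at each gene's minimum Cq;
measured efficiencies are not folded into Q by default (an efficiency-aware
mode uses (1+E)^(−ΔCq) instead).  Target-gene fold changes follow the
2^(−ΔΔCt) scheme against one reference gene or the per-sample mean Cq of a
reference combination.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CqTable, RelQuantMatrix

__all__ = [
    "EfficiencyFit",
    "FoldChangeTable",
    "fit_efficiency",
    "relative_quantity",
    "ddct_fold_change",
]

#: Flag-only acceptance band for amplification efficiency, percent.
EFFICIENCY_BAND = (90.0, 110.0)


@dataclass
class EfficiencyFit:
    slope: float            # Cq per log10(relative input)
    intercept: float        # Cq at relative input 1
    efficiency_pct: float   # E = 100·(10^(−1/slope) − 1)
    r_squared: float
    n_points: int
    valid: bool             # slope < 0
    within_band: bool       # efficiency inside EFFICIENCY_BAND


@dataclass
class FoldChangeTable:
    target: str
    references: tuple[str, ...]
    calibrator: str
    per_sample: pd.DataFrame   # sample_id, group, bio_rep, delta_ct, ddct, fold

    def group_means(self) -> pd.DataFrame:
        g = self.per_sample.groupby("group", sort=False)["fold"]
        return pd.DataFrame({
            "mean_fold": g.mean(),
            "sem": g.sem(ddof=1),
            "n": g.size(),
        })


def fit_efficiency(series) -> EfficiencyFit:
    """Ordinary least squares of Cq on log10(relative input); replicates
    enter as individual points.

    Raises if fewer than 3 distinct dilution levels are present.  A
    non-negative slope yields ``valid=False`` (efficiency is reported from
    the magnitude-less formula only when the slope is negative).
    """
    long = series.long_form()
    if long["rel_input"].nunique() < 3:
        raise ValueError("need >= 3 distinct dilution levels")
    x = np.log10(long["rel_input"].to_numpy())
    y = long["cq"].to_numpy()
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    valid = slope < 0
    eff = 100.0 * (10.0 ** (-1.0 / slope) - 1.0) if valid else float("nan")
    r2 = float(fit.rvalue ** 2)
    within = valid and EFFICIENCY_BAND[0] <= eff <= EFFICIENCY_BAND[1]
    return EfficiencyFit(slope, intercept, eff, r2, len(y), valid, within)


def relative_quantity(table: CqTable,
                      efficiency_pct: pd.Series | None = None) -> RelQuantMatrix:
    """Q = 2^(−ΔCq) with ΔCq = Cq − min over samples, per gene.

    Expects a collapsed (one column per biological sample) complete table.
    If ``efficiency_pct`` gives per-gene measured efficiencies, uses
    (1 + E)^(−ΔCq) instead of base 2.
    """
    if max(s.tech_rep for s in table.samples) > 1:
        raise ValueError("collapse technical replicates before computing Q")
    if table.values.isna().any().any():
        raise ValueError(
            "missing Cq entries; resolve them first (drop_incomplete_samples "
            "or read with missing='drop')"
        )
    dcq = table.values.sub(table.values.min(axis=1), axis=0)
    if efficiency_pct is None:
        q = np.power(2.0, -dcq)
    else:
        base = 1.0 + efficiency_pct.loc[table.genes] / 100.0
        q = np.power(base.to_numpy()[:, None], -dcq)
        q = pd.DataFrame(q, index=dcq.index, columns=dcq.columns)
    return RelQuantMatrix(q, list(table.samples), delta_cq=dcq)


def ddct_fold_change(
    table: CqTable,
    target: str,
    references: list[str] | tuple[str, ...],
    calibrator: str,
) -> FoldChangeTable:
    """2^(−ΔΔCt) fold change of ``target`` against one or more reference
    genes, relative to the ``calibrator`` group.

    ΔCt_s = Cq_target,s − mean(Cq over references, sample s);
    ΔΔCt_s = ΔCt_s − mean(ΔCt over calibrator samples);
    fold_s = 2^(−ΔΔCt_s).  Multi-reference normalization averages reference
    Cq arithmetically per sample (geometric mean on the quantity scale).
    The calibrator group's geometric-mean fold is 1 by construction.
    """
    references = tuple(references)
    if not references:
        raise ValueError("empty reference set")
    for g in (target, *references):
        if g not in table.values.index:
            raise KeyError(f"gene {g!r} not in table")
    groups = table.groups
    cal_ids = groups.index[groups == calibrator]
    if len(cal_ids) == 0:
        raise ValueError(f"calibrator group {calibrator!r} has no samples")

    ref_mean = table.values.loc[list(references)].mean(axis=0)
    delta_ct = table.values.loc[target] - ref_mean
    ddct = delta_ct - delta_ct.loc[cal_ids].mean()
    fold = np.power(2.0, -ddct)

    meta = table.meta_frame()
    per_sample = pd.DataFrame({
        "sample_id": table.sample_ids,
        "group": [meta.loc[s, "group"] for s in table.sample_ids],
        "bio_rep": [meta.loc[s, "bio_rep"] for s in table.sample_ids],
        "delta_ct": delta_ct.to_numpy(),
        "ddct": ddct.to_numpy(),
        "fold": fold.to_numpy(),
    })
    return FoldChangeTable(target, references, calibrator, per_sample)
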