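"""BestKeeper descriptive stability and the comparative ΔCt method.

BestKeeper works on raw Cq (not relative quantities): per gene it reports
the arithmetic mean Cq, a dispersion (sample SD by default, mean absolute
deviation optionally), CV as a percentage of the mean Cq, and the Pearson
correlation with the BestKeeper index — the per-sample geometric mean Cq
over all candidates.  Genes are ranked ascending by the dispersion, ties by
CV then gene symbol; the correlation is reported but does not enter the
default ranking key.

The comparative ΔCt method ranks gene j by the mean over partners k of the
SD over samples of the raw difference Cq_j − Cq_k — the same pairwise
algebra as the geNorm M value but on unanchored Cq.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import CqTable, StabilityResult

__all__ = ["BestkeeperResult", "DeltaCtResult", "bestkeeper",
           "delta_ct_method", "rank_by_dispersion"]


@dataclass
class BestkeeperResult:
    table: pd.DataFrame        # gene, mean_cq, sd, cv_pct, r, rank
    index: pd.Series           # per-sample geometric mean Cq
    dispersion: str            # "sd" or "mad"

    def ordered_genes(self) -> list[str]:
        return list(self.table.sort_values("rank").index)

    def to_stability(self) -> StabilityResult:
        return StabilityResult(
            "bestkeeper", self.table["sd"], self.table["rank"],
            {"cv_pct": self.table["cv_pct"], "r": self.table["r"],
             "index": self.index, "dispersion": self.dispersion},
        )


@dataclass
class DeltaCtResult:
    mean_pair_sd: pd.Series
    rank: pd.Series

    def ordered_genes(self) -> list[str]:
        return list(self.rank.sort_values().index)

    def to_stability(self) -> StabilityResult:
        return StabilityResult("delta_ct", self.mean_pair_sd, self.rank, {})


def rank_by_dispersion(sd: pd.Series, cv: pd.Series) -> pd.Series:
    """BestKeeper ranking key: dispersion ascending, ties by CV then gene
    symbol.  Exposed separately so published SD/CV tables can be re-ranked
    with the exact production key."""
    order = sorted(sd.index, key=lambda g: (sd[g], cv[g], g))
    return pd.Series({g: i + 1 for i, g in enumerate(order)},
                     name="rank").loc[sd.index].astype(int)


def _check_complete(table: CqTable) -> np.ndarray:
    vals = table.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing Cq values; resolve them before analysis")
    return vals


def bestkeeper(table: CqTable, dispersion: str = "sd") -> BestkeeperResult:
    """Descriptive stability on a collapsed Cq table.

    ``dispersion="sd"`` uses the sample SD (n−1); ``"mad"`` uses the mean
    absolute deviation from the mean, the dispersion the original
    BestKeeper spreadsheet reported.  CV is always 100·dispersion/mean.
    """
    if dispersion not in ("sd", "mad"):
        raise ValueError("dispersion must be 'sd' or 'mad'")
    vals = _check_complete(table)
    if vals.shape[1] < 2:
        raise ValueError("need >= 2 samples")

    mean = vals.mean(axis=1)
    if dispersion == "sd":
        disp = vals.std(axis=1, ddof=1)
    else:
        disp = np.abs(vals - mean[:, None]).mean(axis=1)
    cv = 100.0 * disp / mean

    index = np.exp(np.log(vals).mean(axis=0))   # per-sample geometric mean Cq
    r = np.array([
        stats.pearsonr(vals[i], index).statistic if np.ptp(vals[i]) > 0 else np.nan
        for i in range(vals.shape[0])
    ])

    genes = table.genes
    sd_s = pd.Series(disp, index=genes, name="sd")
    cv_s = pd.Series(cv, index=genes, name="cv_pct")
    out = pd.DataFrame({
        "mean_cq": pd.Series(mean, index=genes),
        "sd": sd_s, "cv_pct": cv_s,
        "r": pd.Series(r, index=genes),
        "rank": rank_by_dispersion(sd_s, cv_s),
    })
    return BestkeeperResult(out, pd.Series(index, index=table.sample_ids,
                                           name="bestkeeper_index"), dispersion)


def delta_ct_method(table: CqTable) -> DeltaCtResult:
    """Mean pairwise-difference SD per gene, ranked ascending."""
    vals = _check_complete(table)
    k = vals.shape[0]
    if k < 3:
        raise ValueError("comparative ΔCt needs >= 3 genes")
    diff = vals[:, None, :] - vals[None, :, :]
    sd = diff.std(axis=2, ddof=1)
    np.fill_diagonal(sd, 0.0)
    mean_sd = pd.Series(sd.sum(axis=1) / (k - 1), index=table.genes,
                        name="mean_pair_sd")
    order = sorted(mean_sd.index, key=lambda g: (mean_sd[g], g))
    rank = pd.Series({g: i + 1 for i, g in enumerate(order)},
                     name="rank").loc[mean_sd.index].astype(int)
    return DeltaCtResult(mean_sd, rank)
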