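"""Consensus ranking across stability algorithms, normalization comparison,
and the end-to-end pipeline driver.

The comprehensive ranking aggregates each algorithm's ranks by geometric
mean — the RefFinder-style "Mean Rank" — and orders genes ascending by it;
ties fall back to the gene's best single-method rank, then to the gene
symbol.  Normalization choices are compared by one-way ANOVA of target-gene
fold changes across groups with Tukey-HSD pairwise labels.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .bestkeeper import bestkeeper, delta_ct_method
from .genorm import genorm_full
from .io_model import (CqTable, ExpressionMatrix, PipelineConfig,
                       StabilityResult, collapse_technical_replicates)
from .normfinder import normfinder_stability, normfinder_ungrouped
from .qpcr import ddct_fold_change, relative_quantity

__all__ = [
    "ConsensusResult",
    "GroupComparison",
    "ReportBundle",
    "geometric_mean_rank",
    "comprehensive_ranking",
    "compare_normalizations",
    "run_pipeline",
]

logger = logging.getLogger("refstab")


@dataclass
class ConsensusResult:
    ranks: pd.DataFrame          # genes × methods, integer ranks
    mean_rank: pd.Series         # aggregated rank, full precision
    final_rank: pd.Series        # 1..k
    methods: tuple[str, ...]
    aggregation: str = "geometric"

    def ordered_genes(self) -> list[str]:
        return list(self.final_rank.sort_values().index)

    def table(self) -> pd.DataFrame:
        """consensus.csv payload: per-method ranks, 2-decimal mean rank,
        comprehensive rank, ordered most → least stable."""
        out = self.ranks.copy()
        out.columns = [f"rank_{m}" for m in self.methods]
        out["mean_rank"] = self.mean_rank.round(2)
        out["comprehensive_rank"] = self.final_rank
        out.insert(0, "gene", out.index)
        return out.sort_values("comprehensive_rank").reset_index(drop=True)


@dataclass
class GroupComparison:
    normalizer: str
    group_stats: pd.DataFrame    # group, mean_fold, sem, n
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame       # group_a, group_b, p, label (** / * / ns)


@dataclass
class ReportBundle:
    config: PipelineConfig
    collapsed: CqTable
    tech_flags: pd.DataFrame
    genorm: object
    normfinder: object
    bestkeeper: object
    delta_ct: object
    consensus: ConsensusResult
    screening: object | None = None
    outputs: dict[str, Path] = field(default_factory=dict)


def geometric_mean_rank(ranks: pd.DataFrame,
                        aggregation: str = "geometric") -> pd.Series:
    """Aggregate a genes × methods rank table into one mean rank per gene.

    Geometric mean (default) is (prod ranks)^(1/m); an arithmetic mode is
    available.  Every gene must carry a rank >= 1 from every method.
    """
    if ranks.isna().any().any():
        gene = ranks.index[ranks.isna().any(axis=1)][0]
        method = ranks.columns[ranks.loc[gene].isna()][0]
        raise ValueError(f"gene {gene!r} has no rank from method {method!r}")
    vals = ranks.to_numpy(dtype=float)
    if (vals < 1).any():
        raise ValueError("ranks must be >= 1")
    if aggregation == "geometric":
        agg = np.exp(np.log(vals).mean(axis=1))
    elif aggregation == "arithmetic":
        agg = vals.mean(axis=1)
    else:
        raise ValueError("aggregation must be geometric or arithmetic")
    return pd.Series(agg, index=ranks.index, name="mean_rank")


def comprehensive_ranking(results: list[StabilityResult],
                          aggregation: str = "geometric") -> ConsensusResult:
    """Aggregate >= 2 per-method rankings into the comprehensive ranking."""
    if len(results) < 2:
        raise ValueError("consensus needs >= 2 methods")
    gene_sets = [set(r.genes) for r in results]
    if any(s != gene_sets[0] for s in gene_sets[1:]):
        raise ValueError("methods rank inconsistent gene sets")
    genes = results[0].genes
    methods = tuple(r.method for r in results)
    if len(set(methods)) != len(methods):
        raise ValueError("duplicate method names in consensus input")

    ranks = pd.DataFrame({r.method: r.rank.loc[genes] for r in results})
    mean_rank = geometric_mean_rank(ranks, aggregation)
    best = ranks.min(axis=1)
    order = sorted(genes, key=lambda g: (mean_rank[g], best[g], g))
    final = pd.Series({g: i + 1 for i, g in enumerate(order)},
                      name="comprehensive_rank").loc[genes].astype(int)
    return ConsensusResult(ranks, mean_rank, final, methods, aggregation)


def _sig_label(p: float, alpha: float = 0.05, alpha_strong: float = 0.01) -> str:
    if p < alpha_strong:
        return "**"
    if p < alpha:
        return "*"
    return "ns"


def compare_normalizations(fold_tables: dict[str, "FoldChangeTable"],
                           ) -> dict[str, GroupComparison]:
    """One-way ANOVA of fold changes across groups, per normalizer, with
    Tukey-HSD pairwise significance labels (α = 0.05 / 0.01).

    Keys of ``fold_tables`` name the normalizer (e.g. "RPL14" or
    "RPL14+RPS15A"); each table must carry >= 2 groups with >= 2 biological
    replicates each.
    """
    out = {}
    for name, tab in fold_tables.items():
        per = tab.per_sample
        labels = list(dict.fromkeys(per["group"]))
        arrays = [per.loc[per["group"] == g, "fold"].to_numpy() for g in labels]
        if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
            raise ValueError(
                f"normalizer {name!r}: need >= 2 groups with >= 2 replicates"
            )
        if all(np.ptp(a) == 0 for a in arrays) and np.ptp(per["fold"]) == 0:
            f_stat, p = 0.0, 1.0    # fully degenerate: no variation anywhere
        else:
            f_stat, p = stats.f_oneway(*arrays)
        tk = stats.tukey_hsd(*arrays)
        rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                pij = float(tk.pvalue[i, j])
                rows.append({"group_a": labels[i], "group_b": labels[j],
                             "p": pij, "label": _sig_label(pij)})
        gstats = tab.group_means().reset_index().rename(
            columns={"index": "group"})
        out[name] = GroupComparison(name, gstats, float(f_stat), float(p),
                                    pd.DataFrame(rows))
    return out


def run_pipeline(
    config: PipelineConfig,
    cq: CqTable,
    fpkm: ExpressionMatrix | None = None,
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Full analysis: collapse technical replicates → relative quantities →
    geNorm / NormFinder / BestKeeper / comparative ΔCt → consensus; plus the
    RNA-seq screen when an FPKM matrix is given.  Writes the standard CSVs
    and a run log when ``out_dir`` is set.  Deterministic: identical inputs
    and config yield byte-identical outputs.
    """
    stage = "collapse"
    try:
        collapsed, flags = collapse_technical_replicates(cq, config.tech_sd_flag)
        stage = "relative_quantity"
        q = relative_quantity(collapsed)
        stage = "genorm"
        gn = genorm_full(q, config.v_threshold)
        stage = "normfinder"
        n_groups = len(set(s.group for s in collapsed.samples))
        if n_groups >= 2:
            nf = normfinder_stability(q)
        else:
            logger.warning("single group: NormFinder falls back to ungrouped")
            nf = normfinder_ungrouped(q)
        stage = "bestkeeper"
        bk = bestkeeper(collapsed, config.bestkeeper_dispersion)
        stage = "delta_ct"
        dc = delta_ct_method(collapsed)
        stage = "consensus"
        cons = comprehensive_ranking(
            [gn.to_stability(), nf.to_stability(), bk.to_stability(),
             dc.to_stability()],
            config.rank_aggregation,
        )
        screening_result = None
        if fpkm is not None:
            stage = "screening"
            from .screening import screen_candidates
            screening_result = screen_candidates(
                fpkm, config.fpkm_min, config.cv_max, config.top_k,
                config.fpkm_agg)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    bundle = ReportBundle(config, collapsed, flags, gn, nf, bk, dc, cons,
                          screening_result)
    if out_dir is not None:
        bundle.outputs = _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(b: ReportBundle, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _csv(name: str, frame: pd.DataFrame) -> None:
        p = out_dir / name
        frame.to_csv(p, index=False, float_format="%.6g")
        paths[name] = p

    gn = b.genorm
    _csv("genorm.csv", pd.DataFrame({
        "gene": gn.m_full.index, "M": gn.m_full.round(6).to_numpy(),
        "rank": gn.rank.to_numpy()}).sort_values("rank"))
    _csv("genorm_v.csv", pd.DataFrame({
        "n": gn.v_values.index,
        "V": gn.v_values.round(6).to_numpy(),
        "below_threshold": (gn.v_values < gn.v_threshold).to_numpy()}))
    nf = b.normfinder
    _csv("normfinder.csv", pd.DataFrame({
        "gene": nf.stability.index,
        "stability": nf.stability.round(6).to_numpy(),
        "gamma2": nf.gamma2.round(6).to_numpy(),
        "rank": nf.rank.to_numpy()}).sort_values("rank"))
    bk = b.bestkeeper
    bk_out = bk.table.round(6).copy()
    bk_out.insert(0, "gene", bk_out.index)
    _csv("bestkeeper.csv", bk_out.sort_values("rank").reset_index(drop=True))
    dc = b.delta_ct
    _csv("deltact.csv", pd.DataFrame({
        "gene": dc.mean_pair_sd.index,
        "mean_pair_sd": dc.mean_pair_sd.round(6).to_numpy(),
        "rank": dc.rank.to_numpy()}).sort_values("rank"))
    _csv("consensus.csv", b.consensus.table())
    _csv("tech_flags.csv", b.tech_flags)
    if b.screening is not None:
        _csv("candidates.csv", b.screening.candidate_frame().round(6))

    log = out_dir / "report.log"
    with open(log, "w", encoding="utf-8") as fh:
        fh.write("refstab pipeline run\n")
        for key, val in vars(b.config).items():
            fh.write(f"config.{key} = {val}\n")
        fh.write(f"genes = {len(b.collapsed.genes)}\n")
        fh.write(f"samples (collapsed) = {len(b.collapsed.samples)}\n")
        fh.write(f"technical flags = {len(b.tech_flags)}\n")
        fh.write(f"genorm optimal n = {gn.optimal_n}\n")
        fh.write("consensus order = "
                 + ",".join(b.consensus.ordered_genes()) + "\n")
    paths["report.log"] = log
    return paths
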