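"""Core containers, table I/O, and configuration for the RT-qPCR stability pipeline.

The central object is the :class:`CqTable`: a genes × samples matrix of
quantification-cycle (Cq) values plus per-sample metadata (experimental group,
biological replicate, technical replicate).  Raw tables carry one column per
well; :func:`collapse_technical_replicates` averages wells down to one column
per biological sample, which is the shape every stability algorithm consumes.

All downstream modules treat these containers as validated: construction
raises on duplicate gene symbols, unknown samples, non-finite or out-of-range
Cq values, and shape mismatches.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SampleMeta",
    "CqTable",
    "RelQuantMatrix",
    "ExpressionMatrix",
    "StabilityResult",
    "PipelineConfig",
    "read_cq_table",
    "write_cq_table",
    "read_expression_matrix",
    "collapse_technical_replicates",
]

#: Default upper bound on plausible Cq values (cycles).
CQ_CEILING = 45.0


@dataclass(frozen=True, order=True)
class SampleMeta:
    """Identity and design position of one sample (one well, or one
    biological sample once technical replicates are collapsed)."""

    sample_id: str
    group: str
    bio_rep: int
    tech_rep: int = 1

    def __post_init__(self) -> None:
        if self.bio_rep < 1 or self.tech_rep < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: bio_rep and tech_rep must be >= 1"
            )


def _check_samples(samples: Sequence[SampleMeta]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dup}")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")


def _check_genes(genes: Iterable[str]) -> None:
    genes = list(genes)
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise ValueError(f"duplicate gene symbol: {g!r}")
        seen.add(g)


@dataclass
class CqTable:
    """Genes × samples matrix of Cq values with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol with one column per ``sample_id``,
        in the same order as ``samples``.
    samples
        Per-column metadata.
    allow_missing
        If False (default) any NaN entry is rejected; if True NaN marks an
        explicitly missing well (stability algorithms still refuse it — use
        :meth:`drop_incomplete_samples` first).
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    allow_missing: bool = False
    cq_ceiling: float = CQ_CEILING

    def __post_init__(self) -> None:
        _check_genes(self.values.index)
        _check_samples(self.samples)
        ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != ids:
            raise ValueError("matrix columns do not match sample metadata order")
        vals = self.values.to_numpy(dtype=float)
        nan = np.isnan(vals)
        if nan.any() and not self.allow_missing:
            g, s = np.argwhere(nan)[0]
            raise ValueError(
                f"missing Cq at gene {self.values.index[g]!r}, sample "
                f"{ids[s]!r}; enable allow_missing or drop the sample"
            )
        ok = nan | ((vals > 0) & (vals <= self.cq_ceiling) & np.isfinite(vals))
        if not ok.all():
            g, s = np.argwhere(~ok)[0]
            raise ValueError(
                f"Cq out of range (0, {self.cq_ceiling}] at gene "
                f"{self.values.index[g]!r}, sample {ids[s]!r}: {vals[g, s]}"
            )
        self.values = self.values.astype(float)

    # -- convenience accessors -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def groups(self) -> pd.Series:
        """sample_id → group label, in column order."""
        return pd.Series(
            {s.sample_id: s.group for s in self.samples}, name="group"
        ).loc[self.sample_ids]

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(s) for s in self.samples]
        ).set_index("sample_id", drop=False)

    def subset_genes(self, genes: Sequence[str]) -> "CqTable":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in table: {missing}")
        return CqTable(self.values.loc[list(genes)], list(self.samples),
                       self.allow_missing, self.cq_ceiling)

    def drop_incomplete_samples(self) -> "CqTable":
        """Complete-case filtering: drop every sample column containing any
        missing Cq.  Never imputes."""
        keep = [sid for sid in self.sample_ids
                if not self.values[sid].isna().any()]
        samples = [s for s in self.samples if s.sample_id in set(keep)]
        return CqTable(self.values[keep], samples, False, self.cq_ceiling)


@dataclass
class RelQuantMatrix:
    """Per-gene relative quantities Q = 2^(−ΔCq), ΔCq = Cq − min over samples.

    Technical replicates are already collapsed; each gene's most abundant
    (lowest-Cq) sample has Q = 1 exactly.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    delta_cq: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_genes(self.values.index)
        _check_samples(self.samples)
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("matrix columns do not match sample metadata order")
        v = self.values.to_numpy(dtype=float)
        if not np.isfinite(v).all() or (v <= 0).any() or (v > 1 + 1e-12).any():
            raise ValueError("relative quantities must satisfy 0 < Q <= 1")
        if not np.allclose(v.max(axis=1), 1.0, atol=1e-12):
            raise ValueError("each gene must have max Q == 1 (min-Cq anchoring)")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def groups(self) -> pd.Series:
        return pd.Series({s.sample_id: s.group for s in self.samples}).loc[
            self.sample_ids
        ]

    def subset_genes(self, genes: Sequence[str]) -> "RelQuantMatrix":
        # Q anchoring is per gene over samples, so row subsetting is exact.
        sub = self.values.loc[list(genes)]
        dcq = None if self.delta_cq is None else self.delta_cq.loc[list(genes)]
        return RelQuantMatrix(sub, list(self.samples), dcq)


@dataclass
class ExpressionMatrix:
    """RNA-seq expression matrix in FPKM (genes × samples), all entries >= 0."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_genes(self.values.index)
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 samples")
        v = self.values.to_numpy(dtype=float)
        if not np.isfinite(v).all() or (v < 0).any():
            raise ValueError("FPKM values must be finite and non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


@dataclass
class StabilityResult:
    """One algorithm's verdict: a per-gene statistic (lower = more stable)
    and the ranks 1..k it induces (1 = most stable)."""

    method: str
    statistic: pd.Series
    rank: pd.Series
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.statistic.index) != set(self.rank.index):
            raise ValueError("statistic and rank cover different gene sets")
        k = len(self.rank)
        if sorted(self.rank) != list(range(1, k + 1)):
            raise ValueError("ranks must be a permutation of 1..k")
        self.rank = self.rank.astype(int)

    @property
    def genes(self) -> list[str]:
        return list(self.statistic.index)

    def ordered_genes(self) -> list[str]:
        return list(self.rank.sort_values().index)


@dataclass
class PipelineConfig:
    """Tunable knobs for the full pipeline, serialisable to/from YAML."""

    log_base: float = 2.0
    cq_ceiling: float = CQ_CEILING
    tech_sd_flag: float = 0.5          # cycles; technical-replicate QC flag
    v_threshold: float = 0.15          # geNorm pairwise-variation cutoff
    fpkm_min: float = 100.0
    cv_max: float = 10.0               # percent
    top_k: int = 8
    fpkm_agg: str = "mean"             # mean | min | median
    bestkeeper_dispersion: str = "sd"  # sd | mad
    rank_aggregation: str = "geometric"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")
        for name in ("cq_ceiling", "tech_sd_flag", "v_threshold",
                     "fpkm_min", "cv_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.fpkm_agg not in ("mean", "min", "median"):
            raise ValueError("fpkm_agg must be mean, min or median")
        if self.bestkeeper_dispersion not in ("sd", "mad"):
            raise ValueError("bestkeeper_dispersion must be 'sd' or 'mad'")
        if self.rank_aggregation not in ("geometric", "arithmetic"):
            raise ValueError("rank_aggregation must be geometric or arithmetic")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# File I/O — UTF-8 CSV/TSV, delimiter inferred from extension, decimal point.
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cq_table(
    path: str | Path,
    meta_path: str | Path,
    *,
    gene_column: str = "gene",
    missing: str = "error",
    cq_ceiling: float = CQ_CEILING,
) -> CqTable:
    """Read a wide Cq matrix (``gene`` column + one column per sample) and its
    sample-metadata table (``sample_id,group,bio_rep,tech_rep``).

    ``missing`` controls NaN policy: ``"error"`` (default) rejects them,
    ``"drop"`` removes every sample column containing a missing value.
    """
    if missing not in ("error", "drop"):
        raise ValueError("missing must be 'error' or 'drop'")
    raw = pd.read_csv(path, sep=_sep_for(path))
    if gene_column not in raw.columns:
        raise ValueError(f"no {gene_column!r} column in {path}")
    dup = raw[gene_column][raw[gene_column].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate gene symbol: {dup.iloc[0]!r}")
    matrix = raw.set_index(gene_column)

    meta = pd.read_csv(meta_path, sep=_sep_for(meta_path))
    required = {"sample_id", "group", "bio_rep", "tech_rep"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must provide columns {sorted(required)}")
    meta = meta.set_index("sample_id", drop=False)
    absent = [c for c in matrix.columns if c not in meta.index]
    if absent:
        raise ValueError(f"samples missing from metadata: {absent}")

    for col in matrix.columns:
        coerced = pd.to_numeric(matrix[col], errors="coerce")
        bad = coerced.isna() & matrix[col].notna()
        if bad.any():
            gene = bad.idxmax()
            raise ValueError(
                f"non-numeric Cq at gene {gene!r}, sample {col!r}: "
                f"{matrix.loc[gene, col]!r}"
            )
        matrix[col] = coerced

    samples = [
        SampleMeta(str(sid), str(meta.loc[sid, "group"]),
                   int(meta.loc[sid, "bio_rep"]), int(meta.loc[sid, "tech_rep"]))
        for sid in matrix.columns
    ]
    table = CqTable(matrix, samples, allow_missing=(missing == "drop"),
                    cq_ceiling=cq_ceiling)
    if missing == "drop":
        table = table.drop_incomplete_samples()
    return table


def write_cq_table(table: CqTable, path: str | Path, meta_path: str | Path,
                   *, float_format: str = "%.10g") -> None:
    """Write a CqTable back to the wide-CSV + metadata-CSV pair that
    :func:`read_cq_table` consumes (lossless round trip at 10 significant
    digits)."""
    out = table.values.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep=_sep_for(path), index=False, float_format=float_format)
    meta = pd.DataFrame([dataclasses.asdict(s) for s in table.samples])
    meta.to_csv(meta_path, sep=_sep_for(meta_path), index=False)


def read_expression_matrix(path: str | Path,
                           *, gene_column: str = "gene") -> ExpressionMatrix:
    raw = pd.read_csv(path, sep=_sep_for(path))
    if gene_column not in raw.columns:
        raise ValueError(f"no {gene_column!r} column in {path}")
    dup = raw[gene_column][raw[gene_column].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate gene symbol: {dup.iloc[0]!r}")
    return ExpressionMatrix(raw.set_index(gene_column).astype(float))


# ---------------------------------------------------------------------------
# Technical-replicate handling
# ---------------------------------------------------------------------------

def collapse_technical_replicates(
    table: CqTable, sd_flag: float = 0.5
) -> tuple[CqTable, pd.DataFrame]:
    """Average technical replicates on the Cq scale.

    Returns one column per (group, bio_rep) — id ``"{group}_{bio_rep}"`` —
    holding the arithmetic mean Cq of that biological sample's wells, plus a
    QC report listing every (gene, biological sample) whose technical-replicate
    SD (n−1 denominator) exceeds ``sd_flag`` cycles.  Collapsing an
    already-collapsed table is the identity (up to sample ids).
    """
    if sd_flag <= 0:
        raise ValueError("sd_flag must be > 0")
    meta = table.meta_frame()
    order: list[tuple[str, int]] = []
    for s in table.samples:
        key = (s.group, s.bio_rep)
        if key not in order:
            order.append(key)

    cols, samples, flags = {}, [], []
    for group, bio in order:
        ids = meta.index[(meta["group"] == group) & (meta["bio_rep"] == bio)]
        block = table.values[list(ids)]
        usable = block.notna().sum(axis=1)
        if (usable == 0).any():
            gene = usable.index[usable == 0][0]
            raise ValueError(
                f"no usable wells for gene {gene!r} in sample "
                f"({group}, bio_rep {bio})"
            )
        new_id = f"{group}_{bio}"
        cols[new_id] = block.mean(axis=1)
        samples.append(SampleMeta(new_id, group, bio, 1))
        if block.shape[1] > 1:
            sd = block.std(axis=1, ddof=1)
            for gene in sd.index[sd > sd_flag]:
                flags.append({"gene": gene, "sample_id": new_id,
                              "group": group, "bio_rep": bio,
                              "tech_sd": float(sd[gene])})

    collapsed = CqTable(pd.DataFrame(cols, index=table.values.index),
                        samples, table.allow_missing, table.cq_ceiling)
    report = pd.DataFrame(
        flags, columns=["gene", "sample_id", "group", "bio_rep", "tech_sd"]
    )
    return collapsed, report
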