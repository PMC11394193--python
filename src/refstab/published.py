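"""Published stability statistics for the ten-gene goat muscle satellite
cell candidate panel (HSPA9, DDOST, RPL5, CAPNS1, YBX1, EEF1G, RPS15A,
RPL14, GAPDH, ACTB across proliferation GM and differentiation DM1/DM5).

These printed per-method ranks and BestKeeper dispersion statistics serve
as fixed inputs for checking the rank-aggregation and ranking-key code
paths: the raw per-well Cq data behind them are not publicly available, so
the printed summaries are the only exact anchor.
"""
from __future__ import annotations

import pandas as pd

__all__ = [
    "published_method_ranks",
    "published_mean_ranks",
    "published_comprehensive_order",
    "published_bestkeeper_stats",
    "published_bestkeeper_ranks",
]

# gene -> (geNorm rank, NormFinder rank, BestKeeper rank)
_METHOD_RANKS = {
    "RPL14": (1, 1, 4),
    "RPS15A": (2, 3, 1),
    "YBX1": (3, 6, 2),
    "RPL5": (5, 4, 3),
    "HSPA9": (6, 2, 8),
    "CAPNS1": (4, 5, 6),
    "GAPDH": (8, 8, 5),
    "DDOST": (7, 7, 9),
    "EEF1G": (9, 9, 7),
    "ACTB": (10, 10, 10),
}

# gene -> published (mean rank, comprehensive rank)
_MEAN_RANKS = {
    "RPL14": (1.59, 1), "RPS15A": (1.82, 2), "YBX1": (3.30, 3),
    "RPL5": (3.91, 4), "HSPA9": (4.58, 5), "CAPNS1": (4.93, 6),
    "GAPDH": (6.84, 7), "DDOST": (7.61, 8), "EEF1G": (8.28, 9),
    "ACTB": (10.00, 10),
}

# gene -> (CV %, SD in cycles, published BestKeeper rank)
_BESTKEEPER = {
    "RPS15A": (1.58, 0.26, 1),
    "YBX1": (1.66, 0.27, 2),
    "RPL5": (1.76, 0.28, 3),
    "RPL14": (1.98, 0.31, 4),
    "GAPDH": (1.79, 0.33, 5),
    "CAPNS1": (1.82, 0.36, 6),
    "EEF1G": (2.22, 0.45, 7),
    "HSPA9": (2.60, 0.47, 8),
    "DDOST": (2.30, 0.48, 9),
    "ACTB": (5.39, 0.94, 10),
}


def published_method_ranks() -> pd.DataFrame:
    """Genes × (genorm, normfinder, bestkeeper) published rank table."""
    return pd.DataFrame.from_dict(
        _METHOD_RANKS, orient="index",
        columns=["genorm", "normfinder", "bestkeeper"],
    )


def published_mean_ranks() -> pd.Series:
    return pd.Series({g: v[0] for g, v in _MEAN_RANKS.items()},
                     name="mean_rank")


def published_comprehensive_order() -> list[str]:
    """Genes ordered most → least stable by the published comprehensive
    rank."""
    return sorted(_MEAN_RANKS, key=lambda g: _MEAN_RANKS[g][1])


def published_bestkeeper_stats() -> pd.DataFrame:
    return pd.DataFrame.from_dict(
        _BESTKEEPER, orient="index", columns=["cv_pct", "sd", "rank"],
    )


def published_bestkeeper_ranks() -> pd.Series:
    return published_bestkeeper_stats()["rank"]
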