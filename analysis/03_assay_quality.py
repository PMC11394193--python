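"""Fit amplification efficiencies from the simulated standard curves.

A usable assay needs a slope near -1/log10(2) = -3.32 (E near 100%) and an
R^2 near 1; fits outside the 90-110% band are flagged.  Writes
results/efficiency.csv.
"""
from pathlib import Path

import pandas as pd

from refstab import fit_efficiency
from refstab.synthetic import DilutionSeries

ROOT = Path(__file__).resolve().parent.parent / "results"


def load_series(path: Path) -> DilutionSeries:
    long = pd.read_csv(path)
    levels = sorted(long["rel_input"].unique(), reverse=True)
    wide = pd.DataFrame([
        long.loc[long["rel_input"] == lv, "cq"].to_numpy() for lv in levels])
    return DilutionSeries(pd.Series(levels).to_numpy(), wide, e_true=1.0)


def main() -> None:
    rows = []
    for path in sorted((ROOT / "data").glob("dilution_*.csv")):
        fit = fit_efficiency(load_series(path))
        rows.append({
            "series": path.stem, "slope": round(fit.slope, 5),
            "intercept": round(fit.intercept, 4),
            "efficiency_pct": round(fit.efficiency_pct, 3),
            "r_squared": round(fit.r_squared, 6),
            "within_90_110": fit.within_band,
        })
        print(f"{path.stem}: slope {fit.slope:+.4f}  "
              f"E {fit.efficiency_pct:6.2f}%  R2 {fit.r_squared:.5f}  "
              f"{'ok' if fit.within_band else 'FLAGGED'}")
    pd.DataFrame(rows).to_csv(ROOT / "efficiency.csv", index=False)
    print(f"-> {ROOT / 'efficiency.csv'}")


if __name__ == "__main__":
    main()
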