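"""Validate the chosen references by normalizing a regulated target gene.

Builds a panel containing a PCNA-like target with a genuine differentiation
response, normalizes it by the most stable reference, by the two-reference
combination, and by the unstable ACTB-like gene, then compares the group
patterns by one-way ANOVA with Tukey-HSD pairwise labels.  The unstable
normalizer shares the target's response and masks it.  Writes
results/validation/.
"""
from pathlib import Path

from refstab import (SimTruth, collapse_technical_replicates,
                     compare_normalizations, ddct_fold_change,
                     simulate_cq_panel)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240826


def main() -> None:
    base = {"RPL14": 15.6, "RPS15A": 16.5, "ACTB": 16.0, "PCNA": 22.0}
    effects = {
        # PCNA falls during differentiation (Cq rises); the ACTB-like gene
        # drifts the same way, which is exactly what makes it a bad reference
        "PCNA": {"GM": 0.0, "DM1": 0.6, "DM5": 1.2},
        "ACTB": {"GM": 0.0, "DM1": 0.6, "DM5": 1.2},
    }
    truth = SimTruth(base, effects, 0.3, 0.15, seed=SEED)
    table, _ = simulate_cq_panel(truth, 3, 3, 3)
    collapsed, _ = collapse_technical_replicates(table)

    tables = {
        "RPL14": ddct_fold_change(collapsed, "PCNA", ["RPL14"], "GM"),
        "RPS15A": ddct_fold_change(collapsed, "PCNA", ["RPS15A"], "GM"),
        "RPL14+RPS15A": ddct_fold_change(collapsed, "PCNA",
                                         ["RPL14", "RPS15A"], "GM"),
        "ACTB": ddct_fold_change(collapsed, "PCNA", ["ACTB"], "GM"),
    }
    comps = compare_normalizations(tables)

    out = ROOT / "validation"
    out.mkdir(parents=True, exist_ok=True)
    for name, fc in tables.items():
        safe = name.replace("+", "_")
        fc.per_sample.to_csv(out / f"fold_{safe}.csv", index=False,
                             float_format="%.6g")
    for name, cmp in comps.items():
        print(f"PCNA normalized by {name}:")
        for _, row in cmp.group_stats.iterrows():
            print(f"    {row['group']:4s} fold {row['mean_fold']:.3f} "
                  f"± {row['sem']:.3f}")
        print(f"    ANOVA F = {cmp.f_statistic:.2f}, p = {cmp.p_value:.2e}")
        for _, row in cmp.pairwise.iterrows():
            print(f"    {row['group_a']} vs {row['group_b']}: "
                  f"{row['label']} (p = {row['p']:.3g})")
        cmp.pairwise.to_csv(out / f"anova_{name.replace('+', '_')}.csv",
                            index=False, float_format="%.6g")
    print(f"-> {out}")


if __name__ == "__main__":
    main()
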