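"""Generate the study's synthetic inputs with recorded ground truth.

Produces, under results/data/:
  - a ten-gene Cq panel (GM/DM1/DM5, 3 biological x 3 technical replicates)
    with eight designed-stable genes, a moderately regulated GAPDH-like gene
    and a strongly regulated ACTB-like gene, plus truth.json;
  - an RNA-seq FPKM matrix with exactly eight designed screening candidates;
  - noiseless and noisy standard-curve dilution series.
"""
import dataclasses
import json
from pathlib import Path

from refstab import (simulate_dilution_series, simulate_fpkm_matrix,
                     simulate_musc_panel, write_cq_table)

SEED = 20240826
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    table, truth = simulate_musc_panel(SEED)
    write_cq_table(table, OUT / "cq.csv", OUT / "meta.csv")
    with open(OUT / "cq_truth.json", "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2, default=list)
    print(f"Cq panel: {len(table.genes)} genes x {len(table.samples)} wells "
          f"-> {OUT / 'cq.csv'}")

    x, candidates = simulate_fpkm_matrix(50, 9, 8, seed=SEED + 1)
    frame = x.values.copy()
    frame.insert(0, "gene", frame.index)
    frame.to_csv(OUT / "fpkm.tsv", sep="\t", index=False, float_format="%.6g")
    with open(OUT / "fpkm_truth.json", "w") as fh:
        json.dump({"candidates": candidates}, fh, indent=2)
    print(f"FPKM matrix: {x.values.shape[0]} genes x {x.values.shape[1]} "
          f"samples, {len(candidates)} designed candidates -> "
          f"{OUT / 'fpkm.tsv'}")

    for name, e_true, noise in (("dilution_perfect", 1.0, 0.0),
                                ("dilution_e95_noisy", 0.95, 0.1)):
        s = simulate_dilution_series(e_true=e_true, noise_sd=noise,
                                     seed=SEED + 2)
        s.long_form().to_csv(OUT / f"{name}.csv", index=False,
                             float_format="%.8g")
        print(f"dilution series (E={100*e_true:.0f}%, noise {noise} cycles) "
              f"-> {OUT / f'{name}.csv'}")


if __name__ == "__main__":
    main()
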