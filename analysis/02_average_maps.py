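#!/usr/bin/env python
"""Average-method probability maps, border-zone ratios and certainty index.

Reads the cohort written by 01_simulate_cohort.py, mirrors right-hemisphere
masks to the left, and computes the lesion-frequency map per territory, the
MCA/ACA and MCA/PCA border-zone ratio maps, and per-ROI mean certainty
indices against the phantom's true territory labels.
"""

from pathlib import Path

import numpy as np

from arterial_atlas import (
    average_prob_maps,
    border_ratio,
    certainty_index,
    mean_ci_by_roi,
    read_cohort,
    read_volume,
    territory_scheme,
    write_prob_maps_4d,
    write_scalar,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main():
    cohort = read_cohort(RESULTS / "phantom" / "cohort").flipped_to_left()
    maps = average_prob_maps(cohort)
    write_prob_maps_4d(maps, RESULTS / "phantom" / "ProbAtlas_average.nii")

    for a, b in (("MCA", "ACA"), ("MCA", "PCA")):
        rm = border_ratio(maps, a, b)
        n_sup = rm.support_mask.n_voxels
        vals = rm.values[rm.support_mask.data > 0]
        write_scalar(rm.grid, np.nan_to_num(rm.values, nan=0.0),
                     RESULTS / "phantom" / f"BorderZone_{a}_{b}.nii")
        if n_sup:
            frac_a = float(np.mean(vals > 1))
            print(f"border zone {a}/{b}: {n_sup} shared voxels, "
                  f"{100 * frac_a:.1f}% more often lesioned in {a} strokes")
        else:
            print(f"border zone {a}/{b}: no shared support")

    ci = certainty_index(maps)
    labels = read_volume(RESULTS / "phantom" / "true_labels.nii", kind="label",
                         scheme=territory_scheme())
    table = mean_ci_by_roi(ci, labels)
    table.to_csv(RESULTS / "tables" / "certainty_index_by_roi.tsv", sep="\t", index=False)
    print("\nmean certainty index (%) per true territory sector:")
    pivot = table.pivot(index="roi", columns="territory", values="mean_ci_pct")
    print(pivot.round(1).to_string())


if __name__ == "__main__":
    main()
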