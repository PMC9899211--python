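#!/usr/bin/env python
"""Registration-QC strip metrics on misaligned phantom B0 volumes.

Builds the OSBM/ISBM/OSLV strips from the phantom brain and ventricle masks
and evaluates the three gamma misregistration ratios for translations of
0..4 voxels (with mild intensity noise), demonstrating that the metrics are
zero for perfect alignment and increase with misalignment.
"""

from pathlib import Path

import pandas as pd

from arterial_atlas import make_phantom, make_phantom_b0, qc_report

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 7


def main():
    template = make_phantom((32, 32, 32), 4, (1, 2, 2, 3), seed=SEED)
    volumes = {
        f"shift_{s}vox": make_phantom_b0(template, (s, 0, 0), noise_sd=2.0, seed=SEED + s)
        for s in range(5)
    }
    table = qc_report(template.brain_mask, template.ventricle_mask, volumes,
                      bandwidth=3)
    (RESULTS / "tables").mkdir(parents=True, exist_ok=True)
    table.to_csv(RESULTS / "tables" / "registration_qc.tsv", sep="\t", index=False)
    print(table.round(4).to_string(index=False))
    print("\ngamma_osbm/gamma_isbm are 0 at perfect alignment and grow with shift;"
          "\ngamma_oslv tracks bright CSF-like voxels escaping the template ventricles.")


if __name__ == "__main__":
    main()
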