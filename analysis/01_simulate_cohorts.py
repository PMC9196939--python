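#!/usr/bin/env python
"""Simulate one example subject per cohort layout and archive the raw data.

Writes multi-contrast image stacks (NIfTI + JSON sidecars), label maps and
ground-truth CSVs for the tumor / rn / mixed / control layouts, plus a 2H
FID series per spectroscopy cohort and the standard-addition titration
series.  Bulky image data goes under scratch/sim; small tables under
results/sim.
"""
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results" / "sim"

from qmrpipe import io as qio
from qmrpipe.acquisition import DEFAULT_FACTORIES
from qmrpipe.phantom import (
    LAYOUTS,
    build_label_map,
    ground_truth_table,
    simulate_fid_series,
    simulate_stack,
    simulate_titration,
)
from qmrpipe.presets import cohort_kinetics

SEED = 2026


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    for layout in LAYOUTS:
        phantom = build_label_map(lesion_layout=layout, seed=SEED)
        qio.save_labels(phantom.label_map, phantom.voxel_size, SCRATCH / f"labels_{layout}.nii")
        qio.write_ground_truth(ground_truth_table(phantom), RESULTS / f"truth_{layout}.csv")
        for seq in ("vfa", "mems", "dwi", "mt", "dce"):
            stack = simulate_stack(phantom, DEFAULT_FACTORIES[seq]())
            qio.save_stack(stack, SCRATCH / f"{seq}_{layout}.nii")
        print(f"simulated {layout}: 5 contrasts at 64x64x21")

    for cohort in ("control", "tumor", "rn"):
        fids = simulate_fid_series(
            cohort_kinetics(cohort), DEFAULT_FACTORIES["dmrs"](), n_blocks=11, seed=SEED
        )
        qio.save_fids(fids, SCRATCH / f"dmrs_{cohort}.h5")
        print(f"simulated dmrs {cohort}: 11 blocks x 1024 complex points")

    titration = simulate_titration(seed=SEED)
    pd.DataFrame(
        {"delta_mM": titration.deltas, "amplitude": titration.amplitudes}
    ).to_csv(RESULTS / "titration.csv", index=False)
    print(f"wrote raw data under {SCRATCH} and tables under {RESULTS}")


if __name__ == "__main__":
    sys.exit(main())
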