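#!/usr/bin/env python
"""Run the full imaging study with noise and tabulate cohort statistics.

Simulates n = 9 subjects for each pure-lesion cohort and n = 9 for the
mixed model at SNR 50 (Rician), fits all parametric maps per subject,
aggregates conservative lesion ROIs, and writes the cohort summary
(mean +/- across-subject SD per parameter) and the Holm-adjusted contrast
table.  Tables land in results/cohort_stats.
"""
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "cohort_stats"

from qmrpipe.pipeline import RunConfig, run_pipeline

SEED = 2026


def main() -> None:
    cfg = RunConfig(
        seed=SEED,
        out_dir=str(OUT),
        cohorts={"tumor": 9, "rn": 9, "mixed": 9},
        dmrs_cohorts={},  # spectroscopy handled by 04_dmrs_quantification.py
        matrix=(64, 64),
        n_slices=11,
        noise="rician",
        noise_sd=0.02,
        make_plots=False,
        log_level="WARNING",
    )
    res = run_pipeline(cfg)
    summary = res["parameter_summary"]
    lesions = summary[summary["roi"].isin(["tumor", "rn"])]
    print("cohort parameter summary (lesion ROIs):")
    print(lesions.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print("\nHolm-adjusted contrasts:")
    print(res["parameter_contrasts"].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    print(f"\ntables under {OUT}")


if __name__ == "__main__":
    sys.exit(main())
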