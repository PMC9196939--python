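#!/usr/bin/env python
"""Quantify the deuterated-glucose study: timecourses and cohort contrasts.

Simulates n = 4 subjects per cohort (control, tumor, rn) over eleven
10-minute blocks (two pre-infusion), fits each FID series jointly, scales
amplitudes to mM via the natural-abundance HOD reference, and reports the
Lac and Glx:Lac timecourses with the pooled terminal-block tests.  Also
runs the 100-replicate terminal-block lactate separation study.  Tables
and the timecourse figure land in results/dmrs.
"""
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "dmrs"

from qmrpipe.pipeline import (
    RunConfig,
    plot_timecourses,
    replicate_lac_separation,
    run_dmrs_arm,
    terminal_block_tests,
)

SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(
        seed=SEED,
        out_dir=str(OUT),
        cohorts={},
        dmrs_cohorts={"control": 4, "tumor": 4, "rn": 4},
        dmrs_n_blocks=11,
        log_level="WARNING",
    )
    df = run_dmrs_arm(cfg, OUT)
    tests = terminal_block_tests(df)
    tests.to_csv(OUT / "terminal_block_tests.csv", index=False)
    plot_timecourses(df, OUT)

    last = df[df["block"] == df["block"].max()]
    print("terminal-block cohort means:")
    print(
        last.groupby("cohort")[["Lac_mM", "Glx_mM", "glx_lac"]]
        .mean()
        .to_string(float_format=lambda v: f"{v:.3f}")
    )
    print("\npooled terminal-block tests (Holm-adjusted):")
    print(tests.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

    print("\nreplicating the terminal-block Lac separation 100x (n=4/cohort) ...")
    study = replicate_lac_separation(n_replicates=100, seed=SEED)
    study.to_csv(OUT / "lac_separation_replicates.csv", index=False)
    frac = (study["p_lac"] < 1e-4).mean()
    print(
        f"fraction of replicates with tumor-vs-rn Lac p < 1e-4: {frac:.2f} "
        f"(median p = {study['p_lac'].median():.2e})"
    )
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    sys.exit(main())
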