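"""ROI aggregation and the study's statistical comparisons.

Parametric maps are summarised over ROI masks (mean/SD over fitted voxels
only), cohorts are compared with two-tailed t-tests — Welch by default,
pooled-variance optionally — pairs within the mixed-lesion model with a
paired t-test, and each parameter's family of contrasts is adjusted by the
Holm step-down Bonferroni procedure.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ParametricMap


@dataclass
class RoiSummary:
    """Mean/SD of one parameter over one subject's ROI."""

    subject: str
    cohort: str
    roi: str
    param: str
    mean: float
    sd: float
    n_voxels: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.n_voxels <= 0:
            raise ValueError("ROI summary needs at least one voxel")
        if self.sd < 0:
            raise ValueError("SD cannot be negative")


@dataclass
class ComparisonResult:
    """One statistical contrast: statistic, df, raw and adjusted p."""

    contrast: str
    statistic: float
    df: float
    p_value: float
    p_adjusted: float | None = None
    n_per_group: tuple[int, int] = (0, 0)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")
        if self.p_adjusted is not None:
            if not (self.p_value <= self.p_adjusted + 1e-12 and self.p_adjusted <= 1.0):
                raise ValueError("adjusted p must lie in [raw p, 1]")


def summarize_roi(
    pmap: ParametricMap, mask: np.ndarray, subject: str, cohort: str, roi: str
) -> RoiSummary:
    """Mean/SD (n-1 denominator) over fitted, unmasked ROI voxels.

    Voxels the fit flagged out are excluded and counted, never imputed.
    """
    roi_mask = np.asarray(mask, dtype=bool)
    sel = roi_mask & pmap.mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"ROI {roi!r} has no overlap with the fitted region of {pmap.param}")
    vals = pmap.values[sel]
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return RoiSummary(
        subject=subject,
        cohort=cohort,
        roi=roi,
        param=pmap.param,
        mean=float(vals.mean()),
        sd=sd,
        n_voxels=n,
        n_excluded=int((roi_mask & ~pmap.mask).sum()),
    )


def _degenerate(a: np.ndarray, b: np.ndarray, paired: bool) -> ComparisonResult | None:
    """Handle zero-variance corner cases with explicit conventions."""
    if paired:
        d = a - b
        if np.all(d == d[0]):
            if d[0] == 0:
                return ComparisonResult(
                    "paired", 0.0, len(d) - 1, 1.0, None, (len(a), len(b)),
                    ["zero-variance-differences"],
                )
            return ComparisonResult(
                "paired", np.inf if d[0] > 0 else -np.inf, len(d) - 1, 0.0, None,
                (len(a), len(b)), ["degenerate-variance"],
            )
        return None
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return ComparisonResult(
                "two-sample", 0.0, len(a) + len(b) - 2, 1.0, None, (len(a), len(b)),
                ["zero-variance-equal-means"],
            )
        sign = 1.0 if a.mean() > b.mean() else -1.0
        return ComparisonResult(
            "two-sample", sign * np.inf, len(a) + len(b) - 2, 0.0, None, (len(a), len(b)),
            ["degenerate-variance"],
        )
    return None


def two_sample_ttest(
    a: Sequence[float], b: Sequence[float], equal_var: bool = False, contrast: str = "two-sample"
) -> ComparisonResult:
    """Two-tailed two-sample t-test (Welch by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    deg = _degenerate(a, b, paired=False)
    if deg is not None:
        deg.contrast = contrast
        return deg
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(
        contrast=contrast,
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        n_per_group=(len(a), len(b)),
    )


def paired_ttest(
    a: Sequence[float], b: Sequence[float], contrast: str = "paired"
) -> ComparisonResult:
    """Two-tailed paired t-test on subject-matched differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired test needs equal-length, subject-matched samples")
    if len(a) < 2:
        raise ValueError("paired test needs at least 2 pairs")
    deg = _degenerate(a, b, paired=True)
    if deg is not None:
        deg.contrast = contrast
        return deg
    res = stats.ttest_rel(a, b)
    return ComparisonResult(
        contrast=contrast,
        statistic=float(res.statistic),
        df=float(len(a) - 1),
        p_value=float(res.pvalue),
        n_per_group=(len(a), len(b)),
    )


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm (1979) step-down Bonferroni adjustment, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def adjust_family(results: Sequence[ComparisonResult]) -> list[ComparisonResult]:
    """Apply Holm adjustment across one family of contrasts, in place."""
    adj = holm_adjust([r.p_value for r in results])
    for r, pa in zip(results, adj):
        r.p_adjusted = float(pa)
    return list(results)


# ---------------------------------------------------------------------------
# study-level tables
# ---------------------------------------------------------------------------


def summary_table(summaries: Sequence[RoiSummary]) -> pd.DataFrame:
    """Across-subject mean (SD of ROI means) per cohort/roi/parameter.

    The SD is the across-subject SD of per-subject ROI means, not the
    pooled voxel SD.
    """
    df = pd.DataFrame([vars(s) for s in summaries])
    grouped = (
        df.groupby(["cohort", "roi", "param"])["mean"]
        .agg(group_mean="mean", group_sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
             n_subjects="count")
        .reset_index()
    )
    return grouped


def contrast_table(
    summaries: Sequence[RoiSummary],
    contrasts: Sequence[tuple[str, tuple[str, str], tuple[str, str], bool]],
    params: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Cohort contrasts per parameter with Holm adjustment per parameter.

    Each contrast is (name, (cohort_a, roi_a), (cohort_b, roi_b), paired).
    The adjustment family is one parameter across its set of contrasts.
    """
    df = pd.DataFrame([vars(s) for s in summaries])
    params = list(params or sorted(df["param"].unique()))
    rows = []
    for param in params:
        sub = df[df["param"] == param]
        fam: list[ComparisonResult] = []
        for name, (ca, ra), (cb, rb), paired in contrasts:
            ga = sub[(sub["cohort"] == ca) & (sub["roi"] == ra)].sort_values("subject")
            gb = sub[(sub["cohort"] == cb) & (sub["roi"] == rb)].sort_values("subject")
            if len(ga) < 2 or len(gb) < 2:
                continue
            if paired:
                res = paired_ttest(ga["mean"].to_numpy(), gb["mean"].to_numpy(), contrast=name)
            else:
                res = two_sample_ttest(ga["mean"].to_numpy(), gb["mean"].to_numpy(), contrast=name)
            fam.append(res)
        adjust_family(fam)
        for r in fam:
            rows.append(
                {
                    "param": param,
                    "contrast": r.contrast,
                    "statistic": r.statistic,
                    "df": r.df,
                    "p_raw": r.p_value,
                    "p_holm": r.p_adjusted,
                    "n_a": r.n_per_group[0],
                    "n_b": r.n_per_group[1],
                    "flags": ";".join(r.flags),
                }
            )
    return pd.DataFrame(rows)


#: the study's four cohort contrasts per parameter
DEFAULT_CONTRASTS: list[tuple[str, tuple[str, str], tuple[str, str], bool]] = [
    ("tumor_vs_tumor_in_mixed", ("tumor", "tumor"), ("mixed", "tumor"), False),
    ("rn_vs_rn_in_mixed", ("rn", "rn"), ("mixed", "rn"), False),
    ("tumor_vs_rn", ("tumor", "tumor"), ("rn", "rn"), False),
    ("tumor_in_mixed_vs_rn_in_mixed", ("mixed", "tumor"), ("mixed", "rn"), True),
]
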