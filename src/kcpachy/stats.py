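"""Zone-level cohort statistics of the thickness profiles.

Each mirrored 40-point profile is divided equally into 20 zones (zone j
averages samples 2j-1 and 2j, 1-based; zone 1 is the most temporal /
inferior).  Per zone and group the module computes means with t-based 95%
confidence intervals, a one-way ANOVA across the five stage groups, Welch
two-sample t-tests between group pairs, and an ordinary-least-squares trend
of thickness on the stage ordinal (0 = normal ... 4 = scarring).

No multiple-testing correction is applied; p-values are reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.stats

from .errors import DegenerateDataError, InsufficientDataError
from .geometry import StageLabel
from .pachymetry import SAMPLE_SPACING_MM, N_SAMPLES, ThicknessProfile

N_ZONES = 20


@dataclass(frozen=True)
class ZoneValue:
    """Mean thickness of one zone of one profile."""

    eye_id: str
    stage: StageLabel | None
    meridian: str
    tissue: str
    zone: int  # 1-based, 1..20
    value: float  # um


@dataclass(frozen=True)
class ZoneGroupSummary:
    """Group mean and 95% CI of one zone."""

    zone: int
    group: StageLabel
    n: int
    mean: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of zone thickness against the stage ordinal."""

    zone: int
    tissue: str
    meridian: str
    slope: float  # um per stage step
    intercept: float  # um
    p_value: float


def assign_zones(profile: ThicknessProfile) -> list[ZoneValue]:
    """Average consecutive sample pairs into the 20 zone values.

    Expects a profile already mirrored to the common orientation, so zone 1
    is most temporal (H) / most inferior (V).
    """
    if profile.values.shape != (N_SAMPLES,):
        raise ValueError(f"profile must have exactly {N_SAMPLES} values")
    means = profile.values.reshape(N_ZONES, 2).mean(axis=1)
    return [
        ZoneValue(
            eye_id=profile.eye_id,
            stage=profile.stage,
            meridian=profile.meridian,
            tissue=profile.tissue,
            zone=j + 1,
            value=float(means[j]),
        )
        for j in range(N_ZONES)
    ]


def zone_positions_mm(zone: int) -> tuple[float, float]:
    """The two sample positions (mm) a zone aggregates."""
    if not 1 <= zone <= N_ZONES:
        raise ValueError("zone must be in 1..20")
    first = (2 * (zone - 1) - (N_SAMPLES - 1) / 2.0) * SAMPLE_SPACING_MM
    return first, first + SAMPLE_SPACING_MM


def zone_group_summary(
    values: Iterable[float],
    confidence: float = 0.95,
    zone: int = 0,
    group: StageLabel = StageLabel.normal,
) -> ZoneGroupSummary:
    """Mean and t-based confidence interval of one group's zone values."""
    v = np.asarray(list(values), dtype=float)
    n = v.size
    if n < 2:
        raise InsufficientDataError("need at least 2 values for a CI")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(n))
    tcrit = float(scipy.stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    half = tcrit * sem
    return ZoneGroupSummary(
        zone=zone, group=group, n=n, mean=mean, ci_low=mean - half, ci_high=mean + half
    )


def anova_by_zone(groups: Sequence[Iterable[float]]) -> tuple[float, float]:
    """One-way ANOVA F and p across the stage groups of one zone."""
    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    arrs = [a for a in arrs if a.size > 0]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise InsufficientDataError("ANOVA needs >=2 groups with n >= 2")
    within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrs)
    means = [a.mean() for a in arrs]
    if within == 0 and max(means) == min(means):
        raise DegenerateDataError("all values identical; ANOVA undefined")
    if within == 0:
        return float("inf"), 0.0
    f, p = scipy.stats.f_oneway(*arrs)
    return float(f), float(p)


def pairwise_ttest(a: Iterable[float], b: Iterable[float]) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances), two-sided."""
    av = np.asarray(list(a), dtype=float)
    bv = np.asarray(list(b), dtype=float)
    if av.size < 2 or bv.size < 2:
        raise InsufficientDataError("t-test needs n >= 2 per group")
    if av.std(ddof=1) == 0 and bv.std(ddof=1) == 0:
        if av.mean() == bv.mean():
            return 0.0, 1.0
        raise DegenerateDataError("zero variance in both groups with unequal means")
    t, p = scipy.stats.ttest_ind(av, bv, equal_var=False)
    return float(t), float(p)


def zone_trend(
    values: Iterable[float],
    ordinals: Iterable[int],
    zone: int = 0,
    tissue: str = "",
    meridian: str = "",
) -> TrendFit:
    """OLS regression of thickness on the stage ordinal for one zone."""
    v = np.asarray(list(values), dtype=float)
    o = np.asarray(list(ordinals), dtype=float)
    if v.shape != o.shape:
        raise ValueError("values and ordinals must align")
    if np.unique(o).size < 2:
        raise InsufficientDataError("trend needs >=2 distinct stage ordinals")
    res = scipy.stats.linregress(o, v)
    return TrendFit(
        zone=zone,
        tissue=tissue,
        meridian=meridian,
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
    )
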