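"""Normal-line pachymetry: reference point, ROI sampling and thickness.

The measurement follows the clinical protocol: the pupil centre on the
anterior surface is the reference point (scans are pupil-fixated, so it sits
at the central image column); a 6 mm region of interest extends 3 mm to
either side; 40 sample points are placed every 0.15 mm along the anterior
surface; and at each sample the epithelial and corneal thickness are the
distances from the anterior surface to the epithelium--stroma interface and
the posterior surface along the local *inward surface normal*.

Sample positions are measured as arc length along the anterior trace.  The
40 points are the centres of 40 contiguous 0.15 mm bins spanning [-3, +3] mm,
i.e. -2.925, -2.775, ..., +2.925 mm; zone 9 of the 20-zone division then sits
at -0.45 mm, matching where keratoconic thinning concentrates (slightly
temporal / inferior of the pupil centre).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .boundaries import BoundarySet, BoundaryTrace, smooth_trace, validate_boundaries
from .errors import (
    CoverageError,
    InsufficientDataError,
    NoIntersectionError,
)
from .geometry import StageLabel

ROI_HALFWIDTH_MM = 3.0
SAMPLE_SPACING_MM = 0.15
N_SAMPLES = 40

# Normal estimation and ray-marching defaults.
NORMAL_FIT_HALFWIDTH_UM = 300.0
MARCH_STEP_UM = 0.5
MARCH_CAP_UM = 2000.0
BISECT_TOL_UM = 0.1

Tissue = Literal["epithelium", "cornea"]


@dataclass(frozen=True)
class ReferencePoint:
    """The pupil-centre reference on the anterior surface (um)."""

    x: float
    y: float


@dataclass
class ThicknessProfile:
    """40-point thickness profile of one tissue along one meridian.

    Positions are signed mm from the reference point; by convention negative
    is temporal for horizontal scans (in the common left-eye orientation) and
    inferior for vertical scans.
    """

    meridian: str
    tissue: Tissue
    positions: np.ndarray  # mm
    values: np.ndarray  # um
    eye_id: str = ""
    stage: StageLabel | None = None
    laterality: str = "OS"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != (N_SAMPLES,) or self.values.shape != (N_SAMPLES,):
            raise ValueError(f"profile must have exactly {N_SAMPLES} samples")
        d = np.diff(self.positions)
        if not np.allclose(d, SAMPLE_SPACING_MM, atol=1e-9):
            raise ValueError("positions must be spaced 0.15 mm")
        if abs(self.positions.sum()) > 1e-9:
            raise ValueError("positions must be symmetric about 0")
        if np.any(self.values <= 0):
            raise ValueError("thickness values must be positive")


def sample_positions(bset: BoundarySet | None = None) -> np.ndarray:
    """The 40 signed sample positions in mm: -2.925, -2.775, ..., +2.925.

    If a boundary set is given, verify that its anterior trace covers the
    3 mm arc on each side of the reference point.
    """
    pos = (np.arange(N_SAMPLES) - (N_SAMPLES - 1) / 2.0) * SAMPLE_SPACING_MM
    if bset is not None:
        ref = locate_reference(bset)
        s = _arc_position_mm(bset.anterior, ref.x)
        if s[0] > -ROI_HALFWIDTH_MM or s[-1] < ROI_HALFWIDTH_MM:
            raise CoverageError(
                f"anterior trace spans [{s[0]:.2f}, {s[-1]:.2f}] mm of arc; "
                f"ROI needs +-{ROI_HALFWIDTH_MM} mm"
            )
    return pos


def locate_reference(bset: BoundarySet) -> ReferencePoint:
    """Anterior-surface point at the central image column (pupil centre)."""
    cx = bset.geometry.center_x_um
    y = float(np.asarray(bset.anterior.y_at(cx)))
    if np.isnan(y):
        raise CoverageError("anterior trace does not span the central column")
    return ReferencePoint(x=cx, y=y)


def _arc_position_mm(trace: BoundaryTrace, ref_x: float) -> np.ndarray:
    """Signed arc length (mm) of every trace point, zero at ref_x."""
    dx = np.diff(trace.x)
    dy = np.diff(trace.y)
    seg = np.hypot(dx, dy)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s0 = np.interp(ref_x, trace.x, s)
    return (s - s0) / 1000.0


def surface_normal(
    trace: BoundaryTrace,
    x0: float,
    fit_halfwidth: float = NORMAL_FIT_HALFWIDTH_UM,
) -> tuple[float, float]:
    """Inward (toward +y) unit normal of a local quadratic fit at x0 (um)."""
    sel = np.abs(trace.x - x0) <= fit_halfwidth
    if sel.sum() < 5:
        raise InsufficientDataError(
            f"only {int(sel.sum())} trace points within +-{fit_halfwidth} um of x0"
        )
    # Centre x for conditioning.
    xs = trace.x[sel] - x0
    coef = np.polyfit(xs, trace.y[sel], 2)
    slope = coef[1]  # derivative at xs=0
    norm = float(np.hypot(slope, 1.0))
    return (-slope / norm, 1.0 / norm)


def thickness_along_normal(
    point: tuple[float, float],
    normal: tuple[float, float],
    target: BoundaryTrace,
    step_um: float = MARCH_STEP_UM,
    cap_um: float = MARCH_CAP_UM,
) -> float:
    """Distance (um) from a surface point to the target trace along a ray.

    Marches ``point + t * normal`` in fixed steps, detects the first sign
    change of the depth relative to the (linearly interpolated) target trace,
    then refines by bisection to below 0.1 um.
    """
    px, py = point
    nx, ny = normal
    if ny <= 0:
        raise ValueError("normal must point into tissue (+y component)")
    t = np.arange(0.0, cap_um + step_um, step_um)
    g = (py + t * ny) - np.asarray(target.y_at(px + t * nx))
    valid = ~np.isnan(g)
    crossing = valid[:-1] & valid[1:] & (g[:-1] < 0) & (g[1:] >= 0)
    idx = np.flatnonzero(crossing)
    if idx.size == 0:
        raise NoIntersectionError(
            f"no intersection with {target.surface} within {cap_um} um"
        )
    lo, hi = t[idx[0]], t[idx[0] + 1]

    def depth(tt: float) -> float:
        return (py + tt * ny) - float(np.asarray(target.y_at(px + tt * nx)))

    while hi - lo > BISECT_TOL_UM:
        mid = 0.5 * (lo + hi)
        if depth(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def measure_profile(
    bset: BoundarySet,
    eye_id: str = "",
    stage: StageLabel | None = None,
    smooth_window: int = 31,
) -> tuple[ThicknessProfile, ThicknessProfile]:
    """Measure the epithelial and corneal 40-point profiles of one scan.

    Traces are lightly moving-average smoothed first (default 31 columns,
    ~90 um): mask-path boundaries are pixel-edge quantized, and unsmoothed
    stair-stepping would inflate arc-length positions and tilt the fitted
    normals.  The window is short enough that the induced flattening of a
    corneal-scale circle is <0.1 um.

    Returns ``(epithelium, cornea)`` profiles in scan orientation (not yet
    mirrored).  Raises on boundary-ordering violations, insufficient ROI
    coverage, or a sample whose normal ray misses a target boundary (the
    failing position is named in the error).
    """
    report = validate_boundaries(bset, roi_halfwidth_um=0.0)
    if report.ordering_violations.size:
        raise CoverageError(
            f"boundary ordering violated at {report.ordering_violations.size} columns"
        )
    positions = sample_positions(bset)
    ant = smooth_trace(bset.anterior, smooth_window)
    interface = smooth_trace(bset.epithelial_interface, smooth_window)
    posterior = smooth_trace(bset.posterior, smooth_window)
    ref = locate_reference(bset)
    s = _arc_position_mm(ant, ref.x)

    epi = np.empty(N_SAMPLES)
    cor = np.empty(N_SAMPLES)
    for i, p in enumerate(positions):
        x0 = float(np.interp(p, s, ant.x))
        y0 = float(np.asarray(ant.y_at(x0)))
        n = surface_normal(ant, x0)
        try:
            epi[i] = thickness_along_normal((x0, y0), n, interface)
            cor[i] = thickness_along_normal((x0, y0), n, posterior)
        except NoIntersectionError as err:
            raise NoIntersectionError(f"at position {p:+.3f} mm: {err}") from None

    common = dict(
        meridian=bset.meridian,
        positions=positions,
        eye_id=eye_id,
        stage=stage,
        laterality=bset.laterality,
    )
    return (
        ThicknessProfile(tissue="epithelium", values=epi, **common),
        ThicknessProfile(tissue="cornea", values=cor, **common),
    )


def mirror_to_common_orientation(
    profile: ThicknessProfile, laterality: str | None = None
) -> ThicknessProfile:
    """Mirror right-eye horizontal profiles to the left-eye orientation.

    For OD horizontal scans the temporal side sits at positive positions;
    negating positions (equivalently, reversing the value sequence on the
    fixed symmetric grid) unifies all profiles to temporal-negative.  OS and
    vertical profiles pass through unchanged.  Applying the operation twice
    is the identity.
    """
    lat = laterality if laterality is not None else profile.laterality
    if lat == "OD" and profile.meridian == "H":
        return replace(profile, values=profile.values[::-1].copy())
    return replace(
        profile, positions=profile.positions.copy(), values=profile.values.copy()
    )
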