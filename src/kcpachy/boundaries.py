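"""Subpixel boundary traces from label masks or grayscale B-scans.

Two extraction paths produce the same contract, a :class:`BoundarySet` with
anterior, epithelium--stroma interface and posterior traces:

* the *mask path* reads edges directly off a 3-class label mask (exact up to
  rasterization: boundaries sit on pixel edges, half-integer rows);
* the *image path* finds axial-gradient extrema per column in a grayscale
  render, with parabolic subpixel refinement and cross-column median
  filtering — a classical stand-in for a learned segmenter, which could be
  slotted in behind the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter

from .errors import (
    EmptyMaskError,
    ExtractionFailureError,
    MalformedMaskError,
)
from .geometry import ImageGeometry
from .phantom import BACKGROUND, EPITHELIUM, STROMA, BoundaryTruth, LabelMask

Surface = Literal["anterior", "epithelial_interface", "posterior"]


@dataclass
class BoundaryTrace:
    """One boundary as a single-valued curve y(x), both in um."""

    surface: Surface
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if self.x.size >= 2 and not np.all(np.diff(self.x) > 0):
            raise ValueError("trace x must be strictly increasing")

    def y_at(self, x_query: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation of y at the query x (um); NaN outside range."""
        return np.interp(x_query, self.x, self.y, left=np.nan, right=np.nan)

    def __len__(self) -> int:
        return self.x.size


@dataclass
class BoundarySet:
    """The three boundary traces of one scan plus its acquisition metadata."""

    anterior: BoundaryTrace
    epithelial_interface: BoundaryTrace
    posterior: BoundaryTrace
    geometry: ImageGeometry
    laterality: str = "OS"
    meridian: str = "H"

    @property
    def traces(self) -> tuple[BoundaryTrace, BoundaryTrace, BoundaryTrace]:
        return self.anterior, self.epithelial_interface, self.posterior

    def shared_x_range(self) -> tuple[float, float]:
        lo = max(t.x[0] for t in self.traces)
        hi = min(t.x[-1] for t in self.traces)
        return lo, hi


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_boundaries`."""

    passed: bool
    ordering_violations: np.ndarray  # x positions (um) violating the ordering
    x_overlap: tuple[float, float]
    roi_covered: bool
    messages: list[str]


def _fill_interior_gaps(cols: np.ndarray, vals: np.ndarray, ok: np.ndarray):
    """Interpolate interior missing columns; truncate leading/trailing gaps."""
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return None
    lo, hi = idx[0], idx[-1]
    sel = slice(lo, hi + 1)
    vals = vals[sel].copy()
    ok_in = ok[sel]
    if not ok_in.all():
        pos = np.arange(vals.size)
        vals[~ok_in] = np.interp(pos[~ok_in], pos[ok_in], vals[ok_in])
    return cols[sel], vals


def trace_from_mask(mask: LabelMask) -> BoundarySet:
    """Extract the three boundaries from a label mask.

    Per column: anterior = top edge of the first tissue pixel, interface =
    edge between the last epithelium and first stroma pixel, posterior =
    bottom edge of the last tissue pixel.  Edges are placed on pixel borders
    (row index +- 0.5) then scaled to um.  Interior columns lacking one of the
    classes are linearly interpolated; leading/trailing ones are truncated.

    Raises :class:`MalformedMaskError` if any column violates the
    background -> epithelium -> stroma -> background ordering and
    :class:`EmptyMaskError` if no tissue exists at all.
    """
    lab = mask.labels
    g = mask.geometry
    h, w = lab.shape
    rows = np.arange(h)[:, None]

    is_epi = lab == EPITHELIUM
    is_str = lab == STROMA
    is_tis = is_epi | is_str
    if not is_tis.any():
        raise EmptyMaskError("mask contains no tissue pixels")

    n_epi = is_epi.sum(axis=0)
    n_str = is_str.sum(axis=0)
    big = h + 1
    first_epi = np.where(n_epi > 0, np.argmax(is_epi, axis=0), big)
    last_epi = np.where(n_epi > 0, h - 1 - np.argmax(is_epi[::-1], axis=0), -1)
    first_str = np.where(n_str > 0, np.argmax(is_str, axis=0), big)
    last_str = np.where(n_str > 0, h - 1 - np.argmax(is_str[::-1], axis=0), -1)

    has_both = (n_epi > 0) & (n_str > 0)
    # Ordering violations: non-contiguous bands or stroma above epithelium.
    bad = np.zeros(w, dtype=bool)
    bad |= (n_epi > 0) & (last_epi - first_epi + 1 != n_epi)
    bad |= (n_str > 0) & (last_str - first_str + 1 != n_str)
    bad |= has_both & (first_str <= last_epi)
    if bad.any():
        raise MalformedMaskError(
            f"column ordering violated in {int(bad.sum())} columns "
            f"(first at column {int(np.flatnonzero(bad)[0])})"
        )

    ok = has_both
    cols = np.arange(w)
    ant = first_epi.astype(float) - 0.5
    inter = last_epi.astype(float) + 0.5
    post = last_str.astype(float) + 0.5

    filled = [
        _fill_interior_gaps(cols, v, ok) for v in (ant, inter, post)
    ]
    if any(f is None for f in filled):
        raise EmptyMaskError("no column contains both epithelium and stroma")

    traces = []
    for (c, v), name in zip(
        filled, ("anterior", "epithelial_interface", "posterior")
    ):
        traces.append(BoundaryTrace(name, c * g.pitch_h, v * g.pitch_v))
    return BoundarySet(*traces, geometry=g)


@dataclass(frozen=True)
class ImageTraceParams:
    """Tuning of the gradient-based image path."""

    smooth_sigma_px: float = 2.0  # axial pre-smoothing
    lateral_sigma_px: float = 4.0  # cross-column pre-smoothing (speckle is
    # uncorrelated between columns, so lateral averaging suppresses it)
    median_window: int = 15  # cross-column median filter (columns)
    min_gradient: float = 4.0  # intensity units per pixel


def _parabolic_refine(grad_col: np.ndarray, idx: int) -> float:
    """Subpixel peak position via a parabola through the peak and neighbours."""
    if idx <= 0 or idx >= grad_col.size - 1:
        return float(idx)
    a, b, c = grad_col[idx - 1], grad_col[idx], grad_col[idx + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(idx)
    delta = 0.5 * (a - c) / denom
    return float(idx + np.clip(delta, -0.5, 0.5))


def trace_from_image(
    image: np.ndarray,
    geometry: ImageGeometry,
    params: ImageTraceParams | None = None,
) -> BoundarySet:
    """Extract boundaries from a grayscale B-scan by axial gradient extrema.

    Per column the anterior is the strongest dark-to-bright gradient, the
    posterior the strongest bright-to-dark gradient below it, and the
    epithelium--stroma interface the strongest dark-to-bright gradient between
    the two (epithelium renders darker than stroma).  Columns whose best
    gradient falls below ``min_gradient`` are interpolated from neighbours;
    if more than half the columns fail, extraction fails.
    """
    p = params or ImageTraceParams()
    img = np.asarray(image, dtype=float)
    if img.shape != (geometry.height_px, geometry.width_px):
        raise ValueError("image shape does not match geometry")

    sm = gaussian_filter1d(img, p.smooth_sigma_px, axis=0)
    if p.lateral_sigma_px > 0:
        sm = gaussian_filter1d(sm, p.lateral_sigma_px, axis=1)
    grad = np.gradient(sm, axis=0)
    h, w = img.shape

    ant = np.full(w, np.nan)
    inter = np.full(w, np.nan)
    post = np.full(w, np.nan)
    for c in range(w):
        gcol = grad[:, c]
        gmax = float(gcol.max())
        if gmax < p.min_gradient:
            continue
        # Anterior: the first strong dark->bright peak from the top (the
        # epithelium--stroma interface is a comparably strong rise further
        # down, so a global argmax would sometimes land there).
        strong = np.flatnonzero(gcol > max(p.min_gradient, 0.4 * gmax))
        breaks = np.flatnonzero(np.diff(strong) > 1)
        run_end = strong[breaks[0]] if breaks.size else strong[-1]
        first_run = strong[strong <= run_end]
        ia = int(first_run[np.argmax(gcol[first_run])])
        # Posterior: most negative gradient well below the anterior.
        below = gcol[ia + 10 :]
        if below.size == 0:
            continue
        ip = ia + 10 + int(np.argmin(below))
        if -gcol[ip] < p.min_gradient:
            continue
        # Interface: strongest dark->bright rise within the plausible
        # epithelium band (>=6 px thick), clear of both gradient tails.
        mid = gcol[ia + 6 : min(ia + 30, ip - 4)]
        if mid.size == 0:
            continue
        ii = ia + 6 + int(np.argmax(mid))
        ant[c] = _parabolic_refine(gcol, ia)
        post[c] = _parabolic_refine(gcol, ip)
        inter[c] = _parabolic_refine(gcol, ii)

    ok = ~np.isnan(ant) & ~np.isnan(inter) & ~np.isnan(post)
    if ok.sum() < 0.5 * w:
        raise ExtractionFailureError(
            f"boundary gradients found in only {int(ok.sum())}/{w} columns"
        )

    cols = np.arange(w)
    traces = []
    for v, name in zip(
        (ant, inter, post), ("anterior", "epithelial_interface", "posterior")
    ):
        c, vv = _fill_interior_gaps(cols, np.where(ok, v, 0.0), ok)
        vv = median_filter(vv, size=p.median_window, mode="nearest")
        traces.append(BoundaryTrace(name, c * geometry.pitch_h, vv * geometry.pitch_v))
    bset = BoundarySet(*traces, geometry=geometry)
    _enforce_ordering(bset)
    return bset


def _enforce_ordering(bset: BoundarySet) -> None:
    """Clip interface strictly between anterior and posterior where crossed."""
    lo, hi = bset.shared_x_range()
    x = bset.epithelial_interface.x
    sel = (x >= lo) & (x <= hi)
    ya = np.interp(x[sel], bset.anterior.x, bset.anterior.y)
    yp = np.interp(x[sel], bset.posterior.x, bset.posterior.y)
    yi = bset.epithelial_interface.y[sel]
    eps = 1e-6
    bset.epithelial_interface.y[sel] = np.clip(yi, ya + eps, yp - eps)


def smooth_trace(trace: BoundaryTrace, window: int) -> BoundaryTrace:
    """Moving-average smoothing of y over an odd window of columns.

    ``window=1`` is the identity; edges use shrinking symmetric windows so a
    straight line is exactly invariant.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window == 1:
        return BoundaryTrace(trace.surface, trace.x.copy(), trace.y.copy())
    half = window // 2
    n = len(trace)
    y = trace.y
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(y)])
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = (csum[i + k + 1] - csum[i - k]) / (2 * k + 1)
    return BoundaryTrace(trace.surface, trace.x.copy(), out)


def validate_boundaries(
    bset: BoundarySet,
    roi_halfwidth_um: float = 3000.0,
) -> ValidationReport:
    """Check anterior < interface < posterior ordering and ROI coverage.

    Coverage requires the shared x-range of the three traces to span the
    requested half-width on each side of the central column.
    """
    lo, hi = bset.shared_x_range()
    msgs: list[str] = []
    if hi <= lo:
        return ValidationReport(
            False, np.empty(0), (lo, hi), False, ["traces share no x range"]
        )
    xq = bset.anterior.x[(bset.anterior.x >= lo) & (bset.anterior.x <= hi)]
    ya = np.asarray(bset.anterior.y_at(xq))
    yi = np.asarray(bset.epithelial_interface.y_at(xq))
    yp = np.asarray(bset.posterior.y_at(xq))
    viol = xq[(ya >= yi) | (yi >= yp)]
    if viol.size:
        msgs.append(f"ordering violated at {viol.size} columns")

    cx = bset.geometry.center_x_um
    covered = (lo <= cx - roi_halfwidth_um) and (hi >= cx + roi_halfwidth_um)
    if not covered:
        msgs.append(
            f"shared x range [{lo:.0f}, {hi:.0f}] um does not cover "
            f"+-{roi_halfwidth_um:.0f} um around the centre {cx:.0f}"
        )
    return ValidationReport(
        passed=viol.size == 0 and covered,
        ordering_violations=viol,
        x_overlap=(lo, hi),
        roi_covered=covered,
        messages=msgs,
    )


def boundary_set_from_truth(
    truth: BoundaryTruth, geometry: ImageGeometry | None = None
) -> BoundarySet:
    """Sample the analytic curves at column centres (discretization-free path).

    Useful for isolating measurement error from rasterization error.
    """
    g = geometry or truth.geometry
    _, (ax, ay), (ix, iy), (px, py) = truth.curve_samples()
    xcols = np.arange(g.width_px) * g.pitch_h
    out = []
    for (xc, yc), name in zip(
        ((ax, ay), (ix, iy), (px, py)),
        ("anterior", "epithelial_interface", "posterior"),
    ):
        y = np.interp(xcols, xc, yc, left=np.nan, right=np.nan)
        okc = ~np.isnan(y)
        out.append(BoundaryTrace(name, xcols[okc], y[okc]))
    return BoundarySet(
        *out,
        geometry=g,
        laterality=truth.spec.laterality,
        meridian=truth.spec.meridian,
    )


def mask_from_boundaries(bset: BoundarySet) -> LabelMask:
    """Rasterize a BoundarySet back into a 3-class label mask.

    Inverse of :func:`trace_from_mask` up to pixel quantization; used to score
    image-path extractions with overlap metrics against reference masks.
    """
    g = bset.geometry
    xcols = np.arange(g.width_px) * g.pitch_h
    ya = np.asarray(bset.anterior.y_at(xcols))
    yi = np.asarray(bset.epithelial_interface.y_at(xcols))
    yp = np.asarray(bset.posterior.y_at(xcols))
    valid = ~(np.isnan(ya) | np.isnan(yi) | np.isnan(yp))
    ycent = (np.arange(g.height_px) * g.pitch_v)[:, None]
    labels = np.zeros((g.height_px, g.width_px), dtype=np.uint8)
    with np.errstate(invalid="ignore"):
        epi = (ycent >= ya[None, :]) & (ycent < yi[None, :])
        stro = (ycent >= yi[None, :]) & (ycent < yp[None, :])
    labels[epi & valid[None, :]] = EPITHELIUM
    labels[stro & valid[None, :]] = STROMA
    return LabelMask(labels, g)
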