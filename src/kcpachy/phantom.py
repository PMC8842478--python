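"""Synthetic corneal cross-section phantoms with analytic ground truth.

The study population this generator emulates is five stage groups — normal,
mild, moderate and severe keratoconus (KC), plus scarring KC — each eye scanned
along the horizontal and vertical meridians through the pupil centre.  A
phantom cornea is built from

* a circular anterior surface (radius ~7.8 mm, apex near the top of the grid),
* a corneal thickness profile ``T(s)`` and epithelial thickness profile
  ``E(s)`` along the anterior arc position ``s`` (mm from the scan centre),
  each a peripheral baseline minus a Gaussian cone of central thinning,
* for the scarring stage, a smooth seeded zero-mean fluctuation added to
  ``E(s)`` (irregular epithelium over a grossly thinned stroma).

The epithelium--stroma interface and posterior surface are constructed by
stepping ``E(s)`` and ``T(s)`` along the *inward anterior normal*, so
normal-line pachymetry recovers ``T`` and ``E`` exactly: the analytic profiles
are the ground truth the measurement pipeline is judged against.

Stage-group central thickness values are calibrated to the clinical cohort's
reported group means; cone width and peripheral values are generator choices
(see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .errors import KcpachyError
from .geometry import ImageGeometry, StageLabel

Laterality = Literal["OD", "OS"]
Meridian = Literal["H", "V"]

# Background / epithelium / stroma label codes used in masks.
BACKGROUND, EPITHELIUM, STROMA = 0, 1, 2

# Stage-group central (apex) thickness in um: Table-derived group means.
APEX_CORNEAL_UM: dict[StageLabel, float] = {
    StageLabel.normal: 504.5,
    StageLabel.mild: 496.0,
    StageLabel.moderate: 475.7,
    StageLabel.severe: 455.3,
    StageLabel.scarring: 376.1,
}
APEX_EPITHELIAL_UM: dict[StageLabel, float] = {
    StageLabel.normal: 48.9,
    StageLabel.mild: 48.2,
    StageLabel.moderate: 43.7,
    StageLabel.severe: 40.3,
    StageLabel.scarring: 46.9,
}
# Between-eye s.d. of the apex draws, set so that simulated 95% CIs at the
# clinical group sizes match the reported CI widths.
APEX_CORNEAL_SD_UM: dict[StageLabel, float] = {
    StageLabel.normal: 39.5,
    StageLabel.mild: 34.0,
    StageLabel.moderate: 37.2,
    StageLabel.severe: 49.6,
    StageLabel.scarring: 55.0,
}
APEX_EPITHELIAL_SD_UM: dict[StageLabel, float] = {
    StageLabel.normal: 5.7,
    StageLabel.mild: 6.1,
    StageLabel.moderate: 6.6,
    StageLabel.severe: 7.1,
    StageLabel.scarring: 15.0,
}
# Gaussian cone width (mm): broad natural thinning for normal eyes, narrowing
# with KC severity so the thinnest zone and steepest trend sit ~0.45 mm off
# centre.
CONE_SIGMA_MM: dict[StageLabel, float] = {
    StageLabel.normal: 1.5,
    StageLabel.mild: 1.2,
    StageLabel.moderate: 1.0,
    StageLabel.severe: 0.8,
    StageLabel.scarring: 0.8,
}

# Peripheral corneal baseline (um) declines with stage: keratoconic corneas
# are thinner across the whole profile, not only at the cone, and the chosen
# values keep the group ordering monotone at every zone distance even though
# the cone narrows with severity.
PERIPHERAL_CORNEAL_UM: dict[StageLabel, float] = {
    StageLabel.normal: 620.0,
    StageLabel.mild: 586.0,
    StageLabel.moderate: 570.0,
    StageLabel.severe: 552.0,
    StageLabel.scarring: 525.0,
}
PERIPHERAL_EPITHELIAL_UM = 52.0
ANTERIOR_RADIUS_UM = 7800.0
CONE_OFFSET_MM = -0.45  # negative = temporal (H) / inferior (V)
SCAR_FLUCTUATION_AMP_UM = 6.0
SCAR_FLUCTUATION_CORR_MM = 0.5

# Clinical cohort group sizes (eyes per stage, normal..scarring).
DEFAULT_EYES_PER_STAGE: tuple[int, ...] = (118, 134, 239, 153, 71)

_LAT_CODE = {"OD": 1, "OS": 2}
_MER_CODE = {"H": 1, "V": 2}


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one synthetic B-scan."""

    stage: StageLabel
    anterior_radius: float  # um
    apex_corneal_thickness: float  # um
    peripheral_corneal_thickness: float  # um
    apex_epithelial_thickness: float  # um
    peripheral_epithelial_thickness: float  # um
    cone_center_offset: float  # mm, signed
    cone_sigma: float  # mm
    epithelial_fluctuation_amp: float  # um
    scar: bool
    laterality: Laterality
    meridian: Meridian
    seed: int

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")
        if self.meridian not in ("H", "V"):
            raise ValueError(f"meridian must be H or V, got {self.meridian!r}")
        if self.cone_sigma <= 0:
            raise ValueError("cone_sigma must be positive")
        if self.apex_corneal_thickness <= 0:
            raise ValueError("apex corneal thickness must be positive")
        if not self.scar and self.apex_corneal_thickness > self.peripheral_corneal_thickness:
            raise ValueError(
                "apex corneal thickness must not exceed the peripheral value "
                "for non-scarring stages"
            )
        if self.apex_epithelial_thickness >= self.peripheral_corneal_thickness:
            raise ValueError("epithelium cannot be thicker than the cornea")
        if self.epithelial_fluctuation_amp < 0:
            raise ValueError("fluctuation amplitude must be non-negative")
        if self.anterior_radius <= 0:
            raise ValueError("anterior radius must be positive")


def make_phantom_spec(
    stage: StageLabel | str,
    laterality: Laterality = "OS",
    meridian: Meridian = "H",
    seed: int = 0,
) -> PhantomSpec:
    """Draw one stage-typical spec, deterministic in all four arguments.

    Central thickness values are drawn around the stage-group means.  The two
    meridians of the same (stage, laterality, seed) share the eye-level draws
    (apex thickness, anterior radius) and differ only in cone placement, so an
    eye is internally coherent while its meridians keep independent cones.

    For right-eye (OD) horizontal scans the cone offset sign is flipped: in OD
    scan coordinates the temporal side is at positive x, and mirroring to the
    common left-eye orientation then lands the cone temporally.
    """
    stage = StageLabel.from_name(stage)
    if laterality not in _LAT_CODE:
        raise ValueError(f"laterality must be OD or OS, got {laterality!r}")
    if meridian not in _MER_CODE:
        raise ValueError(f"meridian must be H or V, got {meridian!r}")
    seed = int(seed)

    # Eye-level stream: shared between meridians of one eye.
    rng_eye = np.random.default_rng(
        [seed % (2**31), int(stage), _LAT_CODE[laterality], 11]
    )
    peripheral_ct = PERIPHERAL_CORNEAL_UM[stage]
    apex_ct = float(
        np.clip(
            rng_eye.normal(APEX_CORNEAL_UM[stage], APEX_CORNEAL_SD_UM[stage]),
            250.0,
            peripheral_ct - 5.0,
        )
    )
    apex_et = float(
        np.clip(
            rng_eye.normal(APEX_EPITHELIAL_UM[stage], APEX_EPITHELIAL_SD_UM[stage]),
            25.0,
            72.0,
        )
    )
    radius = float(np.clip(rng_eye.normal(ANTERIOR_RADIUS_UM, 120.0), 7300.0, 8300.0))

    # Meridian-level stream: cone geometry specific to this scan.
    rng_mer = np.random.default_rng(
        [seed % (2**31), int(stage), _LAT_CODE[laterality], _MER_CODE[meridian], 13]
    )
    offset = float(np.clip(rng_mer.normal(CONE_OFFSET_MM, 0.10), -0.80, -0.10))
    if laterality == "OD" and meridian == "H":
        offset = -offset
    sigma = float(CONE_SIGMA_MM[stage] * np.exp(rng_mer.normal(0.0, 0.08)))

    scar = stage == StageLabel.scarring
    fluct = 0.0
    if scar:
        fluct = float(np.clip(rng_mer.normal(SCAR_FLUCTUATION_AMP_UM, 1.0), 3.0, 9.0))

    return PhantomSpec(
        stage=stage,
        anterior_radius=radius,
        apex_corneal_thickness=apex_ct,
        peripheral_corneal_thickness=peripheral_ct,
        apex_epithelial_thickness=apex_et,
        peripheral_epithelial_thickness=PERIPHERAL_EPITHELIAL_UM,
        cone_center_offset=offset,
        cone_sigma=sigma,
        epithelial_fluctuation_amp=fluct,
        scar=scar,
        laterality=laterality,
        meridian=meridian,
        seed=seed,
    )


class BoundaryTruth:
    """Analytic boundary curves and exact thickness functions of a phantom.

    Arc position ``s`` is in mm along the anterior surface, signed, with 0 at
    the scan centre (the apex of the anterior circle, placed at the central
    column of the target geometry).  All point coordinates are in um, with y
    increasing downward into tissue.
    """

    #: depth of the anterior apex below the top image edge, um
    APEX_DEPTH_UM = 150.0

    def __init__(self, spec: PhantomSpec, geometry: ImageGeometry | None = None):
        self.spec = spec
        self.geometry = geometry or ImageGeometry()
        g = self.geometry
        self.radius = spec.anterior_radius
        self.center_x = g.center_x_um
        self.center_y = self.APEX_DEPTH_UM + self.radius
        # Lateral half-extent limited by the grid; one pixel margin each side.
        half_w = g.width_um / 2.0 - g.pitch_h
        half_w = min(half_w, 0.98 * self.radius)
        self.s_max_mm = self.radius * np.arcsin(half_w / self.radius) / 1000.0
        self._fluct = self._build_fluctuation()

    # -- thickness profiles ------------------------------------------------

    def corneal_thickness(self, s_mm: np.ndarray | float) -> np.ndarray | float:
        """Exact corneal thickness T(s) in um."""
        s = self._check_s(s_mm)
        sp = self.spec
        out = sp.peripheral_corneal_thickness - (
            sp.peripheral_corneal_thickness - sp.apex_corneal_thickness
        ) * np.exp(-((s - sp.cone_center_offset) ** 2) / (2.0 * sp.cone_sigma**2))
        return out if np.ndim(s_mm) else float(out)

    def epithelial_thickness(self, s_mm: np.ndarray | float) -> np.ndarray | float:
        """Exact epithelial thickness E(s) in um (incl. scar fluctuation)."""
        s = self._check_s(s_mm)
        sp = self.spec
        out = sp.peripheral_epithelial_thickness - (
            sp.peripheral_epithelial_thickness - sp.apex_epithelial_thickness
        ) * np.exp(-((s - sp.cone_center_offset) ** 2) / (2.0 * sp.cone_sigma**2))
        if self._fluct is not None:
            grid_s, grid_f = self._fluct
            out = out + np.interp(s, grid_s, grid_f)
        return out if np.ndim(s_mm) else float(out)

    # -- curves ------------------------------------------------------------

    def anterior_point(self, s_mm: np.ndarray | float):
        """Point (x, y) in um on the anterior surface at arc position s."""
        theta = self._theta(s_mm)
        return (
            self.center_x + self.radius * np.sin(theta),
            self.center_y - self.radius * np.cos(theta),
        )

    def inward_normal(self, s_mm: np.ndarray | float):
        """Unit normal at s pointing into tissue (+y direction component)."""
        theta = self._theta(s_mm)
        return -np.sin(theta), np.cos(theta)

    def interface_point(self, s_mm: np.ndarray | float):
        return self._offset_point(s_mm, self.epithelial_thickness(s_mm))

    def posterior_point(self, s_mm: np.ndarray | float):
        return self._offset_point(s_mm, self.corneal_thickness(s_mm))

    def curve_samples(self, n: int = 4001):
        """Dense (s, anterior, interface, posterior) samples over the extent."""
        s = np.linspace(-self.s_max_mm, self.s_max_mm, n)
        return s, self.anterior_point(s), self.interface_point(s), self.posterior_point(s)

    # -- helpers -----------------------------------------------------------

    def _offset_point(self, s_mm, dist_um):
        ax, ay = self.anterior_point(s_mm)
        nx, ny = self.inward_normal(s_mm)
        return ax + np.asarray(dist_um) * nx, ay + np.asarray(dist_um) * ny

    def _theta(self, s_mm):
        s = self._check_s(s_mm)
        return s * 1000.0 / self.radius

    def _check_s(self, s_mm):
        s = np.asarray(s_mm, dtype=float)
        if np.any(np.abs(s) > self.s_max_mm + 1e-9):
            raise ValueError(
                f"arc position out of modeled extent +-{self.s_max_mm:.3f} mm"
            )
        return s

    def _build_fluctuation(self):
        sp = self.spec
        if not sp.scar or sp.epithelial_fluctuation_amp <= 0:
            return None
        step = 0.05  # mm
        pad = 4 * SCAR_FLUCTUATION_CORR_MM
        grid = np.arange(-self.s_max_mm - pad, self.s_max_mm + pad + step, step)
        rng = np.random.default_rng(
            [sp.seed % (2**31), int(sp.stage), _MER_CODE[sp.meridian], 977]
        )
        white = rng.standard_normal(grid.size)
        smooth = gaussian_filter1d(white, SCAR_FLUCTUATION_CORR_MM / step, mode="wrap")
        smooth -= smooth.mean()
        sd = smooth.std()
        if sd > 0:
            smooth *= sp.epithelial_fluctuation_amp / sd
        return grid, smooth


def boundaries_from_spec(
    spec: PhantomSpec, geometry: ImageGeometry | None = None
) -> BoundaryTruth:
    """Construct the analytic boundary curves realizing a spec."""
    return BoundaryTruth(spec, geometry)


def analytic_thickness(
    truth: BoundaryTruth,
    s_mm: np.ndarray | float,
    tissue: Literal["epithelium", "cornea"],
) -> np.ndarray | float:
    """Ground-truth thickness at arc position s (mm), in um."""
    if tissue == "cornea":
        return truth.corneal_thickness(s_mm)
    if tissue == "epithelium":
        return truth.epithelial_thickness(s_mm)
    raise ValueError(f"tissue must be 'epithelium' or 'cornea', got {tissue!r}")


@dataclass
class LabelMask:
    """Per-pixel labels (0=background, 1=epithelium, 2=stroma) on a grid."""

    labels: np.ndarray
    geometry: ImageGeometry

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.geometry.height_px, self.geometry.width_px):
            raise ValueError(
                f"label grid {self.labels.shape} does not match geometry "
                f"({self.geometry.height_px}, {self.geometry.width_px})"
            )


def rasterize_masks(truth: BoundaryTruth, geometry: ImageGeometry | None = None) -> LabelMask:
    """Label every pixel by which tissue region its centre falls in.

    Raises if the curves run off the bottom of the grid.
    """
    g = geometry or truth.geometry
    _, (ax, ay), (ix, iy), (px, py) = truth.curve_samples()
    if py.max() > g.height_um or ay.min() < 0:
        raise KcpachyError("phantom curves exceed the image grid extent")

    xcols = np.arange(g.width_px) * g.pitch_h
    y_ant = np.interp(xcols, ax, ay, left=np.nan, right=np.nan)
    y_int = np.interp(xcols, ix, iy, left=np.nan, right=np.nan)
    y_post = np.interp(xcols, px, py, left=np.nan, right=np.nan)
    valid = ~(np.isnan(y_ant) | np.isnan(y_int) | np.isnan(y_post))

    ycent = (np.arange(g.height_px) * g.pitch_v)[:, None]
    labels = np.zeros((g.height_px, g.width_px), dtype=np.uint8)
    with np.errstate(invalid="ignore"):
        epi = (ycent >= y_ant[None, :]) & (ycent < y_int[None, :])
        stro = (ycent >= y_int[None, :]) & (ycent < y_post[None, :])
    labels[epi & valid[None, :]] = EPITHELIUM
    labels[stro & valid[None, :]] = STROMA
    return LabelMask(labels, g)


@dataclass(frozen=True)
class RenderParams:
    """Intensity model for grayscale B-scan rendering (8-bit scale)."""

    background: float = 15.0
    epithelium: float = 90.0
    stroma: float = 150.0
    blur_px: float = 1.2
    speckle_sd: float = 0.2
    scar_boost: float = 60.0
    scar_sigma_um: float = 500.0


def render_bscan(
    truth: BoundaryTruth,
    geometry: ImageGeometry | None = None,
    noise_params: RenderParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Render a grayscale B-scan (float array, 0-255 scale) of a phantom.

    Tissue classes get distinct mean intensities, a scar adds a hyperintense
    stromal patch near the cone, and multiplicative speckle is applied.
    Deterministic given the seed.
    """
    g = geometry or truth.geometry
    p = noise_params or RenderParams()
    mask = rasterize_masks(truth, g)
    img = np.full(mask.labels.shape, p.background, dtype=float)
    img[mask.labels == EPITHELIUM] = p.epithelium
    img[mask.labels == STROMA] = p.stroma

    if truth.spec.scar:
        # Hyperintense blob around the mid-stroma point at the cone centre.
        s0 = float(np.clip(truth.spec.cone_center_offset, -truth.s_max_mm, truth.s_max_mm))
        cx, cy = truth._offset_point(s0, 0.55 * truth.corneal_thickness(s0))
        xs = np.arange(g.width_px) * g.pitch_h
        ys = np.arange(g.height_px) * g.pitch_v
        blob = np.exp(
            -((xs[None, :] - cx) ** 2) / (2 * p.scar_sigma_um**2)
            - ((ys[:, None] - cy) ** 2) / (2 * (0.35 * truth.corneal_thickness(s0)) ** 2)
        )
        img += p.scar_boost * blob * (mask.labels == STROMA)

    if p.blur_px > 0:
        img = gaussian_filter(img, p.blur_px)
    if p.speckle_sd > 0:
        rng = np.random.default_rng([int(seed) % (2**31), 313])
        k = 1.0 / p.speckle_sd**2
        img = img * rng.gamma(k, 1.0 / k, size=img.shape)
    return np.clip(img, 0.0, 255.0)


@dataclass
class EyeRecord:
    """One synthetic eye: stage, laterality and its two meridian scans."""

    eye_id: str
    stage: StageLabel
    laterality: Laterality
    spec_h: PhantomSpec
    spec_v: PhantomSpec
    geometry: ImageGeometry = field(default_factory=ImageGeometry)

    def spec(self, meridian: Meridian) -> PhantomSpec:
        return self.spec_h if meridian == "H" else self.spec_v

    def truth(self, meridian: Meridian) -> BoundaryTruth:
        return boundaries_from_spec(self.spec(meridian), self.geometry)

    def mask(self, meridian: Meridian) -> LabelMask:
        return rasterize_masks(self.truth(meridian), self.geometry)


def generate_cohort(
    n_per_stage: Sequence[int] | Mapping[StageLabel | str, int] | None = None,
    seed: int = 0,
    geometry: ImageGeometry | None = None,
) -> list[EyeRecord]:
    """Generate a cohort of synthetic eyes, two meridian scans each.

    ``n_per_stage`` may be a 5-sequence (normal..scarring order) or a mapping;
    the default reproduces the clinical group sizes 118/134/239/153/71.
    Laterality alternates ~1:1 within each stage group.  Deterministic given
    the seed; masks and truths are materialized lazily per eye.
    """
    geometry = geometry or ImageGeometry()
    if n_per_stage is None:
        counts = dict(zip(StageLabel, DEFAULT_EYES_PER_STAGE))
    elif isinstance(n_per_stage, Mapping):
        counts = {StageLabel.from_name(k): int(v) for k, v in n_per_stage.items()}
    else:
        if len(n_per_stage) != len(StageLabel):
            raise ValueError("n_per_stage sequence must have 5 entries")
        counts = dict(zip(StageLabel, (int(n) for n in n_per_stage)))
    if any(v < 0 for v in counts.values()):
        raise ValueError("group sizes must be non-negative")

    rng = np.random.default_rng([int(seed) % (2**31), 101])
    eyes: list[EyeRecord] = []
    for stage, n in counts.items():
        lats = np.array((["OD", "OS"] * (n // 2 + 1))[:n])
        rng.shuffle(lats)
        eye_seeds = rng.integers(0, 2**31, size=n)
        for i in range(n):
            lat: Laterality = str(lats[i])  # type: ignore[assignment]
            es = int(eye_seeds[i])
            eyes.append(
                EyeRecord(
                    eye_id=f"{stage.name}-{i:03d}",
                    stage=stage,
                    laterality=lat,
                    spec_h=make_phantom_spec(stage, lat, "H", es),
                    spec_v=make_phantom_spec(stage, lat, "V", es),
                    geometry=geometry,
                )
            )
    return eyes
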