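import numpy as np
import pytest

import kcpachy as kp


@pytest.fixture(scope="session")
def severe_truth():
    """One severe-stage phantom with its analytic ground truth."""
    spec = kp.make_phantom_spec("severe", "OS", "H", seed=3)
    return kp.boundaries_from_spec(spec)


@pytest.fixture(scope="session")
def severe_mask(severe_truth):
    return kp.rasterize_masks(severe_truth)


@pytest.fixture(scope="session")
def severe_bset(severe_mask):
    return kp.trace_from_mask(severe_mask)


@pytest.fixture(scope="session")
def uniform_truth():
    """Degenerate phantom: constant 520 um cornea / 50 um epithelium."""
    spec = kp.PhantomSpec(
        stage=kp.StageLabel.normal,
        anterior_radius=7800.0,
        apex_corneal_thickness=520.0,
        peripheral_corneal_thickness=520.0,
        apex_epithelial_thickness=50.0,
        peripheral_epithelial_thickness=50.0,
        cone_center_offset=-0.45,
        cone_sigma=1.0,
        epithelial_fluctuation_amp=0.0,
        scar=False,
        laterality="OS",
        meridian="H",
        seed=0,
    )
    return kp.boundaries_from_spec(spec)


@pytest.fixture(scope="session")
def mini_cohort():
    """Five eyes per stage; small but exercises every stage group."""
    return kp.generate_cohort(n_per_stage=(5, 5, 5, 5, 5), seed=11)


def circle_trace(radius_um=7800.0, cx=4000.0, cy=7950.0, n=801, jitter=0.0, seed=0):
    """An anterior-like circular arc trace, optionally with axial jitter."""
    theta = np.linspace(-0.45, 0.45, n)
    x = cx + radius_um * np.sin(theta)
    y = cy - radius_um * np.cos(theta)
    if jitter:
        rng = np.random.default_rng(seed)
        y = y + rng.uniform(-jitter, jitter, size=n)
    return kp.BoundaryTrace("anterior", x, y)
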