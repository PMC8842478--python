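"""Generator determinism, stage calibration and rasterization fidelity."""

import numpy as np
import pytest

import kcpachy as kp
from kcpachy.phantom import (
    APEX_CORNEAL_UM,
    EPITHELIUM,
    STROMA,
    DEFAULT_EYES_PER_STAGE,
)


def mask_column_ordering_ok(labels):
    """Every tissue column reads background->epithelium->stroma->background."""
    for c in np.flatnonzero((labels > 0).any(axis=0)):
        col = labels[:, c]
        runs = col[np.concatenate([[True], col[1:] != col[:-1]])]
        nz = runs[runs > 0]
        if not (len(nz) <= 2 and list(nz) == sorted(nz)):
            return False
    return True


class TestSpecDrawing:
    def test_same_arguments_give_identical_specs(self):
        a = kp.make_phantom_spec("normal", "OS", "H", seed=1)
        b = kp.make_phantom_spec("normal", "OS", "H", seed=1)
        assert a == b

    def test_different_seeds_differ(self):
        a = kp.make_phantom_spec("normal", "OS", "H", seed=1)
        b = kp.make_phantom_spec("normal", "OS", "H", seed=2)
        assert a.apex_corneal_thickness != b.apex_corneal_thickness

    def test_severe_group_mean_matches_reported_interval(self):
        # Reported 95% CI for the severe-group central corneal thickness.
        apexes = [
            kp.make_phantom_spec("severe", "OS", "H", seed=s).apex_corneal_thickness
            for s in range(200)
        ]
        assert 447.38 <= np.mean(apexes) <= 463.22

    def test_scarring_stage_sets_scar_and_fluctuation(self):
        spec = kp.make_phantom_spec("scarring", "OD", "V", seed=5)
        assert spec.scar and spec.epithelial_fluctuation_amp > 0

    def test_non_scarring_stages_have_no_fluctuation(self):
        spec = kp.make_phantom_spec("moderate", "OD", "V", seed=5)
        assert not spec.scar and spec.epithelial_fluctuation_amp == 0

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            kp.make_phantom_spec("keratoglobus", "OS", "H", seed=0)

    def test_mean_apex_thickness_strictly_decreases_with_stage(self):
        means = []
        for stage in kp.StageLabel:
            vals = [
                kp.make_phantom_spec(stage, "OS", "H", s).apex_corneal_thickness
                for s in range(120)
            ]
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_od_horizontal_cone_sits_nasal_in_scan_coords(self):
        # so that mirroring to the common orientation lands it temporally
        od = kp.make_phantom_spec("severe", "OD", "H", seed=7)
        os_ = kp.make_phantom_spec("severe", "OS", "H", seed=7)
        assert od.cone_center_offset > 0 > os_.cone_center_offset


class TestBoundaryTruth:
    def test_uniform_spec_gives_constant_thickness(self, uniform_truth):
        s = np.linspace(-2.9, 2.9, 41)
        assert np.allclose(uniform_truth.corneal_thickness(s), 520.0)
        assert np.allclose(uniform_truth.epithelial_thickness(s), 50.0)

    def test_thickness_at_cone_center_equals_apex(self):
        spec = kp.make_phantom_spec("severe", "OS", "H", seed=2)
        truth = kp.boundaries_from_spec(spec)
        assert kp.analytic_thickness(
            truth, spec.cone_center_offset, "cornea"
        ) == pytest.approx(spec.apex_corneal_thickness)

    def test_thickness_recovers_peripheral_four_sigma_out(self):
        spec = kp.make_phantom_spec("severe", "OS", "H", seed=2)
        truth = kp.boundaries_from_spec(spec)
        for s in (
            spec.cone_center_offset + 4 * spec.cone_sigma,
            spec.cone_center_offset - 4 * spec.cone_sigma,
        ):
            t = truth.corneal_thickness(s)
            assert (
                abs(t - spec.peripheral_corneal_thickness)
                < 1e-3 * spec.peripheral_corneal_thickness
            )

    def test_epithelium_thinner_than_cornea_everywhere(self):
        for stage in kp.StageLabel:
            truth = kp.boundaries_from_spec(kp.make_phantom_spec(stage, "OS", "V", 9))
            s = np.linspace(-3, 3, 201)
            assert np.all(
                truth.epithelial_thickness(s) < truth.corneal_thickness(s)
            )

    def test_out_of_extent_arc_position_rejected(self, severe_truth):
        with pytest.raises(ValueError):
            severe_truth.corneal_thickness(severe_truth.s_max_mm + 0.1)

    def test_scarring_fluctuation_is_zero_mean_and_seeded(self):
        spec = kp.make_phantom_spec("scarring", "OS", "H", seed=4)
        t1 = kp.boundaries_from_spec(spec)
        t2 = kp.boundaries_from_spec(spec)
        s = np.linspace(-3, 3, 301)
        assert np.allclose(t1.epithelial_thickness(s), t2.epithelial_thickness(s))
        # fluctuation visibly departs from the smooth Gaussian-cone baseline
        smooth_spec = kp.PhantomSpec(
            **{**spec.__dict__, "epithelial_fluctuation_amp": 0.0}
        )
        baseline = kp.boundaries_from_spec(smooth_spec).epithelial_thickness(s)
        resid = np.asarray(t1.epithelial_thickness(s)) - np.asarray(baseline)
        assert resid.std() > 1.0
        assert abs(resid.mean()) < 2.0


class TestRasterization:
    def test_near_flat_truth_gives_rectangular_bands(self):
        # A huge anterior radius makes the layers effectively horizontal.
        spec = kp.PhantomSpec(
            stage=kp.StageLabel.normal,
            anterior_radius=5e6,
            apex_corneal_thickness=500.0,
            peripheral_corneal_thickness=500.0,
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
        g = kp.ImageGeometry()
        mask = kp.rasterize_masks(kp.boundaries_from_spec(spec, g), g)
        c = mask.labels.shape[1] // 2
        mid = mask.labels[:, c - 200 : c + 200]
        # each row is uniform across columns
        assert (mid == mid[:, :1]).all()
        n_epi_rows = (mid[:, 0] == EPITHELIUM).sum()
        n_str_rows = (mid[:, 0] == STROMA).sum()
        assert n_epi_rows == pytest.approx(50.0 / g.pitch_v, abs=1)
        assert (n_epi_rows + n_str_rows) == pytest.approx(500.0 / g.pitch_v, abs=1)

    def test_column_ordering_invariant(self, severe_mask):
        assert mask_column_ordering_ok(severe_mask.labels)

    def test_traced_boundaries_within_one_pixel_of_truth(self, severe_truth, severe_mask):
        bset = kp.trace_from_mask(severe_mask)
        g = severe_mask.geometry
        s, (ax, ay), (ix, iy), (px, py) = severe_truth.curve_samples()
        for trace, (xc, yc) in (
            (bset.anterior, (ax, ay)),
            (bset.epithelial_interface, (ix, iy)),
            (bset.posterior, (px, py)),
        ):
            y_true = np.interp(trace.x, xc, yc)
            assert np.abs(trace.y - y_true).max() <= g.pitch_v + 1e-9

    def test_curves_exceeding_grid_rejected(self, severe_truth):
        tiny = kp.ImageGeometry(width_px=2648, height_px=100)
        with pytest.raises(kp.errors.KcpachyError):
            kp.rasterize_masks(severe_truth, tiny)


class TestRender:
    def test_render_is_deterministic(self, severe_truth):
        a = kp.render_bscan(severe_truth, seed=5)
        b = kp.render_bscan(severe_truth, seed=5)
        assert np.array_equal(a, b)

    def test_tissue_brighter_than_background(self, severe_truth, severe_mask):
        img = kp.render_bscan(severe_truth, seed=5)
        lab = severe_mask.labels
        assert img[lab == STROMA].mean() > img[lab == 0].mean()
        assert img[lab == EPITHELIUM].mean() > img[lab == 0].mean()

    def test_scar_patch_hyperintense(self):
        spec = kp.make_phantom_spec("scarring", "OS", "H", seed=6)
        truth = kp.boundaries_from_spec(spec)
        img = kp.render_bscan(truth, seed=6)
        mask = kp.rasterize_masks(truth)
        g = mask.geometry
        s0 = spec.cone_center_offset
        cx, cy = truth.anterior_point(s0)
        xs = np.arange(g.width_px) * g.pitch_h
        near = np.abs(xs - cx) < 400.0
        stroma = mask.labels == STROMA
        inside = stroma & near[None, :]
        outside = stroma & ~near[None, :]
        assert img[inside].mean() > img[outside].mean() + 10


class TestCohort:
    def test_requested_group_sizes_and_two_scans_per_eye(self, mini_cohort):
        assert len(mini_cohort) == 25
        scans = [(e.eye_id, m) for e in mini_cohort for m in ("H", "V")]
        assert len(scans) == 50
        for eye in mini_cohort:
            assert eye.spec("H").meridian == "H"
            assert eye.spec("V").meridian == "V"

    def test_same_seed_reproduces_cohort(self):
        a = kp.generate_cohort((2, 2, 2, 2, 2), seed=3)
        b = kp.generate_cohort((2, 2, 2, 2, 2), seed=3)
        assert [(e.eye_id, e.laterality, e.spec_h, e.spec_v) for e in a] == [
            (e.eye_id, e.laterality, e.spec_h, e.spec_v) for e in b
        ]

    def test_default_cohort_matches_clinical_group_sizes(self):
        eyes = kp.generate_cohort(seed=1)
        counts = {s: 0 for s in kp.StageLabel}
        for e in eyes:
            counts[e.stage] += 1
        assert tuple(counts[s] for s in kp.StageLabel) == DEFAULT_EYES_PER_STAGE

    def test_laterality_roughly_balanced(self):
        eyes = kp.generate_cohort((40, 0, 0, 0, 0), seed=2)
        n_od = sum(e.laterality == "OD" for e in eyes)
        assert n_od == 20

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            kp.generate_cohort((-1, 2, 2, 2, 2), seed=0)
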