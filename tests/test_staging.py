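"""Ectasia indices, Fisher LDA and ROC/AUC."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import kcpachy as kp
from kcpachy.errors import DegenerateModelError, KcpachyError


def eye_profiles(cor_h=None, cor_v=None, epi_h=None, epi_v=None, base=500.0):
    pos = kp.sample_positions()
    default_c = np.full(40, base)
    default_e = np.full(40, 50.0)
    out = []
    for tissue, meridian, vals, fallback in (
        ("cornea", "H", cor_h, default_c),
        ("cornea", "V", cor_v, default_c),
        ("epithelium", "H", epi_h, default_e),
        ("epithelium", "V", epi_v, default_e),
    ):
        out.append(
            kp.ThicknessProfile(
                meridian=meridian,
                tissue=tissue,
                positions=pos,
                values=np.asarray(vals if vals is not None else fallback, float),
            )
        )
    return out


class TestEctasiaIndices:
    def test_constant_profiles_give_unit_indices(self):
        idx = kp.ectasia_indices(eye_profiles())
        assert idx.EEI_H == idx.EEI_V == idx.CEI_H == idx.CEI_V == 1.0

    def test_max_over_min_definition(self):
        vals = np.linspace(496.0, 620.0, 40)
        idx = kp.ectasia_indices(eye_profiles(cor_h=vals))
        assert idx.CEI_H == pytest.approx(620.0 / 496.0)
        assert idx.CEI_H == pytest.approx(1.25)

    def test_deeper_cone_raises_index_of_affected_meridian(self):
        spec = kp.make_phantom_spec("moderate", "OS", "H", seed=3)
        deeper = kp.PhantomSpec(
            **{**spec.__dict__, "apex_corneal_thickness": spec.apex_corneal_thickness - 40}
        )
        def cei_h(sp):
            truth = kp.boundaries_from_spec(sp)
            s = kp.sample_positions()
            t = np.asarray(kp.analytic_thickness(truth, s, "cornea"))
            return t.max() / t.min()
        assert cei_h(deeper) > cei_h(spec)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        vals = 500 + rng.uniform(-30, 30, 40)
        a = kp.ectasia_indices(eye_profiles(cor_h=vals))
        b = kp.ectasia_indices(eye_profiles(cor_h=3.7 * vals))
        assert a.CEI_H == pytest.approx(b.CEI_H)

    def test_missing_meridian_rejected(self):
        profiles = eye_profiles()[:3]
        with pytest.raises(KcpachyError):
            kp.ectasia_indices(profiles)

    def test_indices_at_least_one(self, mini_cohort):
        eye = mini_cohort[0]
        profs = []
        for mer in ("H", "V"):
            bset = kp.trace_from_mask(eye.mask(mer))
            bset.meridian, bset.laterality = mer, eye.laterality
            profs += list(kp.measure_profile(bset))
        idx = kp.ectasia_indices(profs)
        assert min(idx.as_array()) >= 1.0


class TestFisherLda:
    def test_one_dimensional_hand_example(self):
        # classes {-1,0,1} and {5,6,7}: pooled var = 1, mean gap = 6
        a = np.array([[-1.0], [0.0], [1.0], [-1.0], [0.0]])
        b = np.array([[5.0], [6.0], [7.0], [5.0], [6.0]])
        model = kp.fit_lda(a, b, ridge=0.0)
        # weight proportional to gap / pooled variance
        mu_a, mu_b = a.mean(), b.mean()
        pooled = (
            ((a - mu_a) ** 2).sum() + ((b - mu_b) ** 2).sum()
        ) / (len(a) + len(b) - 2)
        assert model.weights[0] == pytest.approx((mu_b - mu_a) / pooled)
        scores_a = a @ model.weights + model.offset
        scores_b = b @ model.weights + model.offset
        assert scores_a.max() < 0 < scores_b.min()  # fully separated

    def test_identical_classes_rejected(self):
        pts = np.tile([[1.0, 2.0, 3.0, 4.0]], (6, 1)) + np.arange(6)[:, None]
        with pytest.raises(DegenerateModelError):
            kp.fit_lda(pts, pts.copy())

    def test_swapping_classes_negates_scores(self):
        rng = np.random.default_rng(4)
        a = rng.normal(1.0, 0.1, (30, 4))
        b = rng.normal(1.3, 0.15, (30, 4))
        m1 = kp.fit_lda(a, b)
        m2 = kp.fit_lda(b, a)
        x = rng.normal(1.15, 0.2, 4)
        assert kp.discriminant_score(m1, x) == pytest.approx(
            -kp.discriminant_score(m2, x)
        )

    def test_small_class_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(DegenerateModelError):
            kp.fit_lda(rng.normal(0, 1, (3, 4)), rng.normal(1, 1, (30, 4)))

    def test_direction_matches_sklearn(self):
        # independent oracle: sklearn's lsqr solver fits the same Fisher rule
        rng = np.random.default_rng(8)
        a = rng.multivariate_normal([1.0, 1.1, 1.2, 1.05], 0.01 * np.eye(4), 200)
        b = a[:100] * 1.08 + rng.normal(0, 0.02, (100, 4))
        model = kp.fit_lda(a, b, ridge=0.0)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(
            np.vstack([a, b]), np.r_[np.zeros(200), np.ones(100)]
        )
        w_sk = sk.coef_.ravel()
        cos = w_sk @ model.weights / (
            np.linalg.norm(w_sk) * np.linalg.norm(model.weights)
        )
        assert cos == pytest.approx(1.0, abs=1e-6)


class TestScores:
    def _model(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 0.05, (40, 4))
        b = rng.normal(1.2, 0.08, (40, 4))
        return kp.fit_lda(a, b), a, b

    def test_class_means_fall_on_either_side(self):
        model, a, b = self._model()
        assert kp.discriminant_score(model, a.mean(axis=0)) < 0
        assert kp.discriminant_score(model, b.mean(axis=0)) > 0

    def test_score_is_affine(self):
        model, _, _ = self._model()
        f1 = np.array([1.0, 1.1, 1.2, 1.3])
        f2 = np.array([1.2, 1.0, 1.4, 1.1])
        lhs = kp.discriminant_score(model, (f1 + f2) / 2)
        rhs = (kp.discriminant_score(model, f1) + kp.discriminant_score(model, f2)) / 2
        assert lhs == pytest.approx(rhs)

    def test_nonfinite_features_rejected(self):
        model, _, _ = self._model()
        with pytest.raises(ValueError):
            kp.discriminant_score(model, np.array([1.0, np.nan, 1.0, 1.0]))


class TestRoc:
    def test_four_point_worked_example(self):
        r = kp.roc_auc([0.1, 0.35, 0.4, 0.8], [0, 1, 0, 1])
        assert r.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        r = kp.roc_auc([0, 0, 1, 1], [0, 0, 1, 1])
        assert r.auc == pytest.approx(1.0)

    def test_all_tied_scores(self):
        r = kp.roc_auc([0.3, 0.3, 0.3, 0.3], [0, 1, 0, 1])
        assert r.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(KcpachyError):
            kp.roc_auc([0.1, 0.2], [1, 1])

    def test_curve_runs_from_origin_to_corner(self):
        rng = np.random.default_rng(6)
        r = kp.roc_auc(rng.normal(0, 1, 50), rng.integers(0, 2, 50))
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_matches_pair_counting_oracle(self):
        # AUC = P(score_pos > score_neg) + 0.5 P(tie), counted exhaustively
        rng = np.random.default_rng(9)
        for _ in range(20):
            scores = np.round(rng.normal(0, 1, 30), 1)  # rounding forces ties
            labels = rng.integers(0, 2, 30)
            if labels.min() == labels.max():
                continue
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert kp.roc_auc(scores, labels).auc == pytest.approx(expected)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        a1 = kp.roc_auc(scores, labels).auc
        a2 = kp.roc_auc(np.exp(3 * scores) - 7, labels).auc
        assert a1 == pytest.approx(a2)


class TestScreen:
    def _features(self, rng, center, n=100):
        return rng.normal(center, 0.05, (n, 4))

    def test_normal_only_cohort_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(KcpachyError):
            kp.stage_vs_normal_screen(
                {kp.StageLabel.normal: self._features(rng, 1.05)}
            )

    def test_missing_normal_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(KcpachyError):
            kp.stage_vs_normal_screen({kp.StageLabel.mild: self._features(rng, 1.1)})

    def test_auc_grows_with_separation(self):
        rng = np.random.default_rng(12)
        feats = {
            kp.StageLabel.normal: self._features(rng, 1.05),
            kp.StageLabel.mild: self._features(rng, 1.07),
            kp.StageLabel.moderate: self._features(rng, 1.12),
            kp.StageLabel.severe: self._features(rng, 1.20),
        }
        res = kp.stage_vs_normal_screen(feats)
        aucs = [res[s][1].auc for s in sorted(res)]
        assert aucs[0] < aucs[1] < aucs[2]

    def test_shuffled_labels_give_chance_auc(self):
        # in-sample fitting inflates the null slightly; the mean over a few
        # permutations stays within 0.1 of chance at n=100/group
        rng = np.random.default_rng(13)
        pool = self._features(rng, 1.1, n=200)
        aucs = []
        for _ in range(20):
            perm = rng.permutation(200)
            feats = {
                kp.StageLabel.normal: pool[perm[:100]],
                kp.StageLabel.severe: pool[perm[100:]],
            }
            res = kp.stage_vs_normal_screen(feats)
            aucs.append(res[kp.StageLabel.severe][1].auc)
        assert abs(np.mean(aucs) - 0.5) <= 0.1
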