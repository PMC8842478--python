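"""Ectasia indices and LDA-based discrimination of KC stages from normal.

A thickness *ectasia index* is the ratio of the maximum to the minimum
thickness over a profile's 40 ROI samples: localized thinning inflates it,
and it is 1 exactly for a constant profile.  Four indices summarise one eye —
epithelial and corneal, horizontal and vertical meridian (EEI_H, EEI_V,
CEI_H, CEI_V).  A two-class Fisher linear discriminant over the four indices
separates each KC stage group from the normal group; diagnostic performance
is read off in-sample ROC curves and their AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .errors import DegenerateModelError, KcpachyError
from .geometry import StageLabel
from .pachymetry import ThicknessProfile

FEATURE_NAMES = ("EEI_H", "EEI_V", "CEI_H", "CEI_V")


@dataclass(frozen=True)
class EctasiaIndices:
    """The four max/min thickness ratios of one eye."""

    EEI_H: float
    EEI_V: float
    CEI_H: float
    CEI_V: float

    def as_array(self) -> np.ndarray:
        return np.array([self.EEI_H, self.EEI_V, self.CEI_H, self.CEI_V])


@dataclass(frozen=True)
class DiscriminantModel:
    """Two-class Fisher LDA over the four ectasia indices.

    ``score = weights . features + offset``; the offset centres the score at
    the midpoint of the projected class means, so normal-like eyes score
    below 0 and stage-like eyes above.
    """

    weights: np.ndarray
    offset: float
    positive_class: StageLabel

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.weights.ndim != 1:
            raise ValueError("weights must be a 1-D coefficient vector")


@dataclass(frozen=True)
class RocResult:
    """ROC curve points and trapezoidal AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def ectasia_indices(
    profiles: Sequence[ThicknessProfile] | Mapping[tuple[str, str], ThicknessProfile],
) -> EctasiaIndices:
    """Compute the four max/min indices from one eye's four profiles.

    Accepts the four profiles (epithelium/cornea x H/V) in any order.
    """
    if isinstance(profiles, Mapping):
        lookup = dict(profiles)
    else:
        lookup = {(p.tissue, p.meridian): p for p in profiles}
    vals = {}
    for tissue, meridian, name in (
        ("epithelium", "H", "EEI_H"),
        ("epithelium", "V", "EEI_V"),
        ("cornea", "H", "CEI_H"),
        ("cornea", "V", "CEI_V"),
    ):
        p = lookup.get((tissue, meridian))
        if p is None:
            raise KcpachyError(f"missing {tissue}/{meridian} profile")
        v = np.asarray(p.values, dtype=float)
        if np.any(v <= 0):
            raise ValueError("thickness values must be positive")
        vals[name] = float(v.max() / v.min())
    return EctasiaIndices(**vals)


def fit_lda(
    normal_features: np.ndarray,
    stage_features: np.ndarray,
    positive_class: StageLabel = StageLabel.mild,
    ridge: float = 1e-6,
) -> DiscriminantModel:
    """Fit a two-class Fisher discriminant: normal vs one KC stage.

    Weights are ``pooled_cov^-1 (mu_stage - mu_normal)``; a small ridge
    (``ridge * trace(cov)/d`` on the diagonal) guards against the near-singular
    pooled covariance of four correlated ratio features.
    """
    a = np.atleast_2d(np.asarray(normal_features, dtype=float))
    b = np.atleast_2d(np.asarray(stage_features, dtype=float))
    if a.shape[0] < 5 or b.shape[0] < 5:
        raise DegenerateModelError("each class needs n >= 5")
    d = a.shape[1]
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    diff = mu_b - mu_a
    if np.allclose(diff, 0):
        raise DegenerateModelError("identical class means; no discriminant direction")
    cov = (
        (a - mu_a).T @ (a - mu_a) + (b - mu_b).T @ (b - mu_b)
    ) / (a.shape[0] + b.shape[0] - 2)
    cov = cov + ridge * np.trace(cov) / d * np.eye(d)
    try:
        w = np.linalg.solve(cov, diff)
    except np.linalg.LinAlgError:
        raise DegenerateModelError("pooled covariance singular after ridge") from None
    offset = -float(w @ (mu_a + mu_b) / 2.0)
    return DiscriminantModel(weights=w, offset=offset, positive_class=positive_class)


def discriminant_score(
    model: DiscriminantModel, features: EctasiaIndices | np.ndarray
) -> float:
    """Affine discriminant score of one feature vector."""
    f = features.as_array() if isinstance(features, EctasiaIndices) else np.asarray(features, dtype=float)
    if f.shape != model.weights.shape or not np.all(np.isfinite(f)):
        raise ValueError("features must match the model dimension and be finite")
    return float(model.weights @ f + model.offset)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve by threshold sweep and trapezoidal AUC.

    AUC equals the Mann-Whitney concordance probability with ties counted
    half.  Raises if only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise KcpachyError("ROC needs both classes present")
    fpr, tpr, _ = _roc_curve(y, s)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def stage_vs_normal_screen(
    features_by_stage: Mapping[StageLabel, np.ndarray],
) -> dict[StageLabel, tuple[DiscriminantModel, RocResult]]:
    """Fit one discriminant + in-sample ROC per KC stage against normal.

    ``features_by_stage`` maps each stage to an (n, 4) array of ectasia
    indices.  Returns results for every non-normal stage present.
    """
    feats = {StageLabel.from_name(k): np.atleast_2d(v) for k, v in features_by_stage.items()}
    if StageLabel.normal not in feats:
        raise KcpachyError("cohort must contain a normal group")
    normal = feats[StageLabel.normal]
    kc_stages = [s for s in feats if s != StageLabel.normal]
    if not kc_stages:
        raise KcpachyError("cohort contains only normal eyes")
    out: dict[StageLabel, tuple[DiscriminantModel, RocResult]] = {}
    for stage in sorted(kc_stages):
        model = fit_lda(normal, feats[stage], positive_class=stage)
        X = np.vstack([normal, feats[stage]])
        y = np.concatenate([np.zeros(len(normal)), np.ones(len(feats[stage]))])
        scores = X @ model.weights + model.offset
        out[stage] = (model, roc_auc(scores, y))
    return out
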