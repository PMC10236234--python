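"""SPARE indices: machine-learned atrophy-pattern scores.

SPARE-BA (brain age) is a linear epsilon-insensitive support-vector
regression predicting chronological age from standardized ROI volumes of
healthy controls; values above chronological age indicate advanced
age-related atrophy.  SPARE-AD is a linear soft-margin support-vector
classifier trained on amyloid-negative controls (coded -1) vs
amyloid-positive AD cases (+1); the signed decision value is the score, so
positive and higher values point to more AD-like atrophy.

Both models freeze their feature standardization constants and their
weight vector at training time; scoring is a deterministic linear map.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import balanced_accuracy_score, mean_absolute_error
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold, cross_val_predict
from sklearn.svm import LinearSVC, LinearSVR

from .containers import CONTROL, CovariatePanel, REFERENCE_AD, REFERENCE_CONTROL, ROITable
from .errors import BrainageError, ConfigurationError, RosterMismatchError

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1
DEFAULT_C_GRID = tuple(10.0 ** k for k in range(-3, 4))
CONTROL_LABELS = (CONTROL, REFERENCE_CONTROL)


@dataclass
class SpareModel:
    """A trained SPARE index: linear weights in standardized-feature space."""

    kind: str                    # "BA" or "AD"
    roi_names: list[str]
    weights: np.ndarray          # (V,)
    intercept: float
    feature_means: np.ndarray    # (V,)
    feature_sds: np.ndarray      # (V,)
    training_meta: dict = field(default_factory=dict)
    hyperparameters: dict = field(default_factory=dict)
    #: optional age-bias correction (slope, intercept) of prediction on age
    bias_correction: tuple[float, float] | None = None
    schema_version: int = MODEL_SCHEMA_VERSION

    def to_json(self, path: str | Path) -> None:
        d = {
            "schema_version": self.schema_version,
            "kind": self.kind,
            "roi_names": self.roi_names,
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "training_meta": self.training_meta,
            "hyperparameters": self.hyperparameters,
            "bias_correction": list(self.bias_correction) if self.bias_correction else None,
        }
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpareModel":
        d = json.loads(Path(path).read_text())
        if d.pop("schema_version") != MODEL_SCHEMA_VERSION:
            raise BrainageError("unsupported SPARE model schema version")
        for key in ("weights", "feature_means", "feature_sds"):
            d[key] = np.asarray(d[key], dtype=float)
        if d["bias_correction"] is not None:
            d["bias_correction"] = tuple(d["bias_correction"])
        return cls(**d)


def _standardize(X: np.ndarray):
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    return (X - means) / sds, means, sds


def train_spare_ba(roi: ROITable, covars: CovariatePanel, *,
                   c_grid=DEFAULT_C_GRID, epsilon: float = 0.1,
                   kernel: str = "linear", seed: int = 0,
                   bias_correction: bool = False) -> SpareModel:
    """Train the brain-age index on healthy controls.

    Linear epsilon-SVR predicting age from standardized ROI volumes; the
    regularization constant is selected by inner 5-fold cross-validation
    over ``c_grid`` and held-out MAE / age-prediction correlation from an
    outer 5-fold CV are recorded in ``training_meta``.
    """
    if kernel != "linear":
        raise ConfigurationError(f"only the linear kernel is implemented, got '{kernel}'")
    bad = set(roi.label.unique()) - set(CONTROL_LABELS)
    if bad:
        raise BrainageError(
            f"SPARE-BA training requires controls only; found labels {sorted(bad)}")
    n = len(roi)
    if n < 50:
        raise BrainageError(f"need at least 50 training subjects, got {n}")
    age = covars.frame["age"].reindex(roi.subjects)
    if age.isna().any():
        raise BrainageError("age missing for some training subjects")

    X, means, sds = _standardize(roi.volumes.to_numpy(dtype=float))
    y = age.to_numpy(dtype=float)
    inner = KFold(n_splits=5, shuffle=True, random_state=seed)
    base = LinearSVR(epsilon=epsilon, loss="epsilon_insensitive",
                     max_iter=3000, random_state=seed)
    search = GridSearchCV(base, {"C": list(c_grid)}, cv=inner,
                          scoring="neg_mean_absolute_error")
    outer = KFold(n_splits=5, shuffle=True, random_state=seed + 1)
    with warnings.catch_warnings():
        # large-C grid points may hit the liblinear iteration cap; they lose
        # the CV selection and are harmless
        warnings.simplefilter("ignore", ConvergenceWarning)
        pred = cross_val_predict(search, X, y, cv=outer)
        mae = float(mean_absolute_error(y, pred))
        corr = float(np.corrcoef(y, pred)[0, 1]) if np.std(pred) > 0 else 0.0
        search.fit(X, y)
    est = search.best_estimator_
    model = SpareModel(
        kind="BA", roi_names=roi.roi_names,
        weights=est.coef_.ravel().astype(float), intercept=float(est.intercept_[0]),
        feature_means=means, feature_sds=sds,
        training_meta={"n": n, "cv_mae_years": mae, "cv_age_corr": corr,
                       "C": float(search.best_params_["C"]), "seed": seed},
        hyperparameters={"C_grid": list(c_grid), "epsilon": epsilon, "kernel": kernel},
    )
    if bias_correction:
        # regress CV predictions on age; invert at scoring time
        slope, icept = np.polyfit(y, pred, 1)
        model.bias_correction = (float(slope), float(icept))
    return model


def train_spare_ad(reference_roi: ROITable, reference_covars: CovariatePanel, *,
                   c_grid=DEFAULT_C_GRID, kernel: str = "linear",
                   seed: int = 0) -> SpareModel:
    """Train the AD-signature classifier on the reference cohort.

    Linear soft-margin SVM, AD coded +1 and controls -1; regularization
    chosen by inner 5-fold CV on balanced accuracy; held-out balanced
    accuracy from an outer 5-fold CV is recorded in ``training_meta``.
    """
    if kernel != "linear":
        raise ConfigurationError(f"only the linear kernel is implemented, got '{kernel}'")
    labels = reference_roi.label
    is_ad = (labels == REFERENCE_AD).to_numpy()
    is_ctrl = labels.isin(CONTROL_LABELS).to_numpy()
    if not is_ad.any() or not is_ctrl.any():
        raise BrainageError("SPARE-AD training needs both AD cases and controls")
    keep = is_ad | is_ctrl
    if keep.sum() != len(labels):
        logger.warning("dropping %d subject(s) with other labels", int((~keep).sum()))
    n_ad, n_ctrl = int(is_ad.sum()), int(is_ctrl.sum())
    if min(n_ad, n_ctrl) < 20:
        raise BrainageError(
            f"need at least 20 subjects per class, got AD={n_ad}, controls={n_ctrl}")

    sub = reference_roi.subset(keep)
    X, means, sds = _standardize(sub.volumes.to_numpy(dtype=float))
    y = np.where((sub.label == REFERENCE_AD).to_numpy(), 1, -1)
    inner = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    # hinge-loss liblinear solver: the linear soft-margin SVM objective
    base = LinearSVC(loss="hinge", max_iter=5000, random_state=seed)
    search = GridSearchCV(base, {"C": list(c_grid)}, cv=inner,
                          scoring="balanced_accuracy")
    outer = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pred = cross_val_predict(search, X, y, cv=outer)
        bacc = float(balanced_accuracy_score(y, pred))
        search.fit(X, y)
    est = search.best_estimator_
    return SpareModel(
        kind="AD", roi_names=sub.roi_names,
        weights=est.coef_.ravel().astype(float), intercept=float(est.intercept_[0]),
        feature_means=means, feature_sds=sds,
        training_meta={"n_ad": n_ad, "n_controls": n_ctrl,
                       "cv_balanced_accuracy": bacc,
                       "C": float(search.best_params_["C"]), "seed": seed},
        hyperparameters={"C_grid": list(c_grid), "kernel": kernel},
    )


def score_spare(model: SpareModel, roi: ROITable) -> pd.Series:
    """Score a table with a trained SPARE model (deterministic linear map).

    BA scores are predicted ages in years; AD scores are signed decision
    values.  Output is keyed by subject_id.
    """
    if roi.roi_names != model.roi_names:
        missing = sorted(set(model.roi_names) - set(roi.roi_names))
        extra = sorted(set(roi.roi_names) - set(model.roi_names))
        raise RosterMismatchError(
            f"ROI roster mismatch (missing {missing}, extra {extra})")
    Z = (roi.volumes.to_numpy(dtype=float) - model.feature_means) / model.feature_sds
    scores = Z @ model.weights + model.intercept
    if model.kind == "BA" and model.bias_correction is not None:
        slope, icept = model.bias_correction
        scores = (scores - icept) / slope
    return pd.Series(scores, index=roi.subjects, name=f"SPARE_{model.kind}")
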