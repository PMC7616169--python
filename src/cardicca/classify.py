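"""Fusion of the two canonical projections and RBF-SVM response classification.

The aligned projections V1, V2 of a trained deep CCA are combined by a fixed
weighted sum, ``F = alpha * V1 + beta * V2`` (default alpha = beta = 0.5, an
even blend), and a radial-basis-function support vector machine classifies
the fused feature into responder / non-responder.  Because the canonical
projections are trained to agree across views, the fitted SVM can also be
applied to a single view's projection at test time — the clinically relevant
mode in which only the cheap modality is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .dcca import DeepCCA
from .exceptions import ConfigurationError, ValidationError
from .preprocessing import View

__all__ = ["GAMMA_GRID", "COST_GRID", "FusionWeights", "SVMConfig", "fuse",
           "train_response_classifier", "predict_response",
           "MultimodalResponseClassifier"]

#: SVM hyperparameter grids searched in grid-search mode
GAMMA_GRID = (0.1, 0.01, 0.001, 0.0001)
COST_GRID = (1.0, 10.0, 100.0, 1000.0)

#: prediction modes
MODES = ("fused", "view1_only", "view2_only")


@dataclass(frozen=True)
class FusionWeights:
    """Weights of the fusion layer F = alpha * V1 + beta * V2."""

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ConfigurationError(
                f"fusion weights must be nonnegative with alpha + beta > 0, "
                f"got alpha={self.alpha}, beta={self.beta}")


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters; ``class_weighting='balanced'`` compensates prevalence."""

    gamma: float = 0.01
    cost: float = 10.0
    class_weighting: str = "balanced"
    grid_mode: bool = False

    def __post_init__(self):
        if self.class_weighting not in ("none", "balanced"):
            raise ConfigurationError(
                f"class_weighting must be 'none' or 'balanced', got {self.class_weighting!r}")
        if self.grid_mode:
            if self.gamma not in GAMMA_GRID:
                raise ConfigurationError(
                    f"grid mode: gamma must be one of {GAMMA_GRID}, got {self.gamma}")
            if self.cost not in COST_GRID:
                raise ConfigurationError(
                    f"grid mode: cost must be one of {COST_GRID}, got {self.cost}")
        if self.gamma <= 0 or self.cost <= 0:
            raise ConfigurationError("gamma and cost must be positive")


def fuse(v1: np.ndarray, v2: np.ndarray,
         weights: FusionWeights = FusionWeights()) -> np.ndarray:
    """Exact weighted sum of paired projection vectors (or row-stacked matrices)."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValidationError(f"shape mismatch: {v1.shape} vs {v2.shape}")
    return weights.alpha * v1 + weights.beta * v2


def train_response_classifier(fused_features: np.ndarray, labels,
                              config: SVMConfig = SVMConfig()) -> SVC:
    """Fit the RBF-SVM on fused training features; labels in {0, 1}."""
    x = np.asarray(fused_features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValidationError(
            f"features {x.shape} and labels {y.shape} are inconsistent")
    if not np.all(np.isfinite(x)):
        raise ValidationError("features contain non-finite values")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present in the training labels")
    clf = SVC(kernel="rbf", gamma=config.gamma, C=config.cost,
              class_weight=None if config.class_weighting == "none" else "balanced")
    clf.fit(x, y)
    return clf


def _single_view_feature(v: np.ndarray, view: View, weights: FusionWeights,
                         single_view_scale: str) -> np.ndarray:
    if single_view_scale == "raw":
        return v
    if single_view_scale == "fusion-weighted":
        w = weights.alpha if view is View.view1 else weights.beta
        return w * v
    raise ConfigurationError(
        f"single_view_scale must be 'raw' or 'fusion-weighted', got {single_view_scale!r}")


def predict_response(model: DeepCCA, classifier: SVC, inputs, mode: str = "fused",
                     weights: FusionWeights = FusionWeights(),
                     single_view_scale: str = "raw") -> np.ndarray:
    """Classify one or more subjects in fused or single-view mode.

    ``inputs`` is ``(X1, X2)`` for fused mode, or a single view's matrices for
    the single-view modes.  In single-view mode the projected vector V_view is
    fed in place of the fused feature; ``single_view_scale`` selects whether
    it is passed as-is ('raw', the default literal reading of applying the
    model to one view) or rescaled by its fusion weight ('fusion-weighted').
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}, got {mode!r}")
    if mode == "fused":
        v1, v2 = model.transform(inputs)
        features = fuse(v1, v2, weights)
    else:
        view = View.view1 if mode == "view1_only" else View.view2
        if isinstance(inputs, tuple) and len(inputs) == 2:
            raise ValidationError(
                f"mode {mode!r} takes a single view's matrices, got a view pair")
        v = model.transform_view(inputs, view)
        features = _single_view_feature(v, view, weights, single_view_scale)
    return classifier.predict(np.atleast_2d(features))


class MultimodalResponseClassifier(BaseEstimator, ClassifierMixin):
    """End-to-end estimator: deep CCA alignment + fusion + RBF-SVM.

    ``fit`` takes ``X = (X1, X2)`` with each view an ``(n, d_view, T)`` array
    of canonical latent matrices and binary labels ``y``.  ``predict``
    accepts the same pair (fused mode) or one view with
    ``mode='view1_only' | 'view2_only'``.
    """

    def __init__(self, k_dcca: int = 25, learning_rate: float = 0.01,
                 epochs: int = 500, batch_size: int = 10, cov_reg: float = 1e-4,
                 gamma: float = 0.01, cost: float = 10.0,
                 class_weighting: str = "balanced",
                 alpha: float = 0.5, beta: float = 0.5,
                 single_view_scale: str = "raw",
                 linear_probe: bool = False, seed: int = 0):
        self.k_dcca = k_dcca
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.cov_reg = cov_reg
        self.gamma = gamma
        self.cost = cost
        self.class_weighting = class_weighting
        self.alpha = alpha
        self.beta = beta
        self.single_view_scale = single_view_scale
        self.linear_probe = linear_probe
        self.seed = seed

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        self.dcca_ = DeepCCA(k_dcca=self.k_dcca, learning_rate=self.learning_rate,
                             epochs=self.epochs, batch_size=self.batch_size,
                             cov_reg=self.cov_reg, linear_probe=self.linear_probe,
                             seed=self.seed).fit(X)
        v1, v2 = self.dcca_.transform(X)
        weights = FusionWeights(self.alpha, self.beta)
        features = fuse(v1, v2, weights)
        self.svm_ = train_response_classifier(
            features, y, SVMConfig(gamma=self.gamma, cost=self.cost,
                                   class_weighting=self.class_weighting))
        self.classes_ = np.unique(y)
        return self

    def fit_from_projections(self, v1: np.ndarray, v2: np.ndarray, y,
                             dcca: DeepCCA):
        """Attach a pre-trained DCCA and fit only the SVM head (CV efficiency path)."""
        self.dcca_ = dcca
        features = fuse(v1, v2, FusionWeights(self.alpha, self.beta))
        self.svm_ = train_response_classifier(
            features, np.asarray(y, dtype=int),
            SVMConfig(gamma=self.gamma, cost=self.cost,
                      class_weighting=self.class_weighting))
        self.classes_ = np.unique(np.asarray(y, dtype=int))
        return self

    def predict(self, X, mode: str = "fused") -> np.ndarray:
        check_is_fitted(self, "svm_")
        return predict_response(self.dcca_, self.svm_, X, mode=mode,
                                weights=FusionWeights(self.alpha, self.beta),
                                single_view_scale=self.single_view_scale)
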