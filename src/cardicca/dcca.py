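"""Deep canonical correlation analysis with convolutional view branches.

Each view's canonical d x T latent matrix passes through its own small CNN
branch (see :func:`cardicca.nn.build_branch`); the two branch parameter sets
are trained jointly by gradient ascent on the total-correlation objective

    (theta1*, theta2*) = argmax corr(f1(X1; theta1), f2(X2; theta2))

realized as the sum of the top canonical correlations of the branch output
blocks (:func:`cardicca.cca.total_correlation_with_grad`).  After training, a
closed-form linear CCA is fitted on the final-epoch branch outputs of the full
training set; its projections V1, V2 are the model's aligned per-view
representations, usable from either view alone at test time.

By default every optimization step evaluates the objective on the full
training set (cohorts here are small, and the whitened cross-covariance of a
10-sample mini-batch is rank deficient for k >= 10); a literal mini-batch
loss mode is available behind ``minibatch_loss=True`` with k capped at
``batch_size - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .cca import (DEFAULT_REG, linear_cca, total_correlation,
                  total_correlation_with_grad)
from .exceptions import ConfigurationError, DivergenceError, ValidationError
from .preprocessing import LatentMatrix, View

__all__ = ["K_DCCA_GRID", "LEARNING_RATE_GRID", "DCCAHyperparams", "DeepCCA",
           "train_dcca", "branch_forward", "project"]

#: hyperparameter grids searched in grid-search mode
K_DCCA_GRID = (5, 10, 15, 20, 25, 30, 35)
LEARNING_RATE_GRID = (0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class DCCAHyperparams:
    """Training hyperparameters of the deep CCA model."""

    k_dcca: int = 25
    learning_rate: float = 0.01
    epochs: int = 500
    batch_size: int = 10
    cov_reg: float = DEFAULT_REG
    seed: int = 0
    grid_mode: bool = False

    def __post_init__(self):
        if self.grid_mode:
            if self.k_dcca not in K_DCCA_GRID:
                raise ConfigurationError(
                    f"grid mode: k_dcca must be one of {K_DCCA_GRID}, got {self.k_dcca}")
            if self.learning_rate not in LEARNING_RATE_GRID:
                raise ConfigurationError(
                    f"grid mode: learning_rate must be one of {LEARNING_RATE_GRID}, "
                    f"got {self.learning_rate}")
        if self.k_dcca < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("k_dcca, epochs and batch_size must be >= 1")
        if self.cov_reg < 0:
            raise ConfigurationError(f"cov_reg must be >= 0, got {self.cov_reg}")

    def to_dict(self) -> dict:
        return asdict(self)


def _stack_views(X):
    """Accept (X1, X2) as arrays (n, d, T) or lists of LatentMatrix; return arrays."""
    if not (isinstance(X, (tuple, list)) and len(X) == 2):
        raise ValidationError("X must be a pair (view1, view2)")
    out = []
    for xv in X:
        if isinstance(xv, np.ndarray):
            arr = np.asarray(xv, dtype=float)
        else:
            arr = np.stack([m.values if isinstance(m, LatentMatrix) else np.asarray(m, float)
                            for m in xv])
        if arr.ndim != 3:
            raise ValidationError(
                f"each view must be (n_subjects, d, T); got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("view data contain non-finite values")
        out.append(arr)
    if out[0].shape[0] != out[1].shape[0]:
        raise ValidationError(
            f"views have different subject counts: {out[0].shape[0]} vs {out[1].shape[0]}")
    return out[0], out[1]


def _as_images(arr: np.ndarray, linear_probe: bool) -> np.ndarray:
    """Lay out (n, d, T) matrices as branch input images.

    Standard mode: single-channel d x T images.  Linear-probe mode: latent
    dimensions become input channels of a 1 x T image, so the 1x1-conv branch
    is an affine map of the per-dimension temporal means.
    """
    if linear_probe:
        return arr[:, :, None, :]
    return arr[:, None, :, :]


class DeepCCA(BaseEstimator, TransformerMixin):
    """CNN-branched deep CCA transformer (scikit-learn style).

    Parameters
    ----------
    k_dcca : int
        Output dimension of each branch and of the canonical projections.
    learning_rate : float
        Adam step size.
    epochs : int
        Number of full-batch optimization steps.
    batch_size : int
        Mini-batch size, used only when ``minibatch_loss=True``.
    cov_reg : float
        Ridge on the auto-covariance blocks of the correlation objective.
    k_corr : int or None
        Number of retained canonical correlations in the objective
        (default: all ``k_dcca``).
    linear_probe : bool
        Degenerate linear branch configuration (tests/diagnostics only).
    minibatch_loss : bool
        Evaluate the correlation loss per mini-batch of ``batch_size``
        instead of on the full training set.
    seed : int
        Seeds weight initialization and mini-batch shuffling.

    Attributes
    ----------
    branch1_, branch2_ : Sequential
        Trained view branches.
    post_cca_ : CCAResult
        Linear CCA fitted on final-epoch branch outputs.
    training_curve_ : ndarray
        Per-epoch total-correlation objective (before each step).
    objective_ : float
        Final objective on the training set after the last step.
    """

    def __init__(self, k_dcca: int = 25, learning_rate: float = 0.01,
                 epochs: int = 500, batch_size: int = 10,
                 cov_reg: float = DEFAULT_REG, k_corr: int | None = None,
                 linear_probe: bool = False, minibatch_loss: bool = False,
                 seed: int = 0):
        self.k_dcca = k_dcca
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.cov_reg = cov_reg
        self.k_corr = k_corr
        self.linear_probe = linear_probe
        self.minibatch_loss = minibatch_loss
        self.seed = seed

    # -- helpers -----------------------------------------------------------
    def _branch_input(self, arr):
        return _as_images(arr, self.linear_probe)

    def fit(self, X, y=None):
        x1, x2 = _stack_views(X)
        n = x1.shape[0]
        if n < 3:
            raise ValidationError(f"need at least 3 training pairs, got {n}")
        k_corr = self.k_corr if self.k_corr is not None else self.k_dcca
        if self.minibatch_loss and k_corr > self.batch_size - 1:
            raise ConfigurationError(
                f"mini-batch loss with batch_size={self.batch_size} supports at "
                f"most k_corr={self.batch_size - 1} (rank of the batch covariance); "
                f"got {k_corr}")

        rng = np.random.default_rng(self.seed)
        in1 = 1 if not self.linear_probe else x1.shape[1]
        in2 = 1 if not self.linear_probe else x2.shape[1]
        b1 = nn.build_branch(self.k_dcca, rng, self.linear_probe, in1)
        b2 = nn.build_branch(self.k_dcca, rng, self.linear_probe, in2)
        opt = nn.Adam(b1.params + b2.params, lr=self.learning_rate)
        im1 = self._branch_input(x1)
        im2 = self._branch_input(x2)

        curve = []
        for epoch in range(self.epochs):
            if self.minibatch_loss:
                order = rng.permutation(n)
                epoch_vals = []
                for start in range(0, n, self.batch_size):
                    idx = order[start:start + self.batch_size]
                    if idx.size < 3:
                        continue
                    val = self._step(b1, b2, opt, im1[idx], im2[idx], k_corr)
                    epoch_vals.append(val)
                val = float(np.mean(epoch_vals))
            else:
                val = self._step(b1, b2, opt, im1, im2, k_corr)
            if not np.isfinite(val):
                raise DivergenceError(
                    f"non-finite objective at epoch {epoch} "
                    f"(learning_rate={self.learning_rate})")
            curve.append(val)

        h1 = b1.forward(im1)
        h2 = b2.forward(im2)
        self.objective_ = total_correlation(h1, h2, k_corr=k_corr, reg=self.cov_reg)
        self.post_cca_ = linear_cca(h1, h2, k=self.k_dcca, reg=self.cov_reg)
        self.branch1_, self.branch2_ = b1, b2
        self.training_curve_ = np.asarray(curve)
        self.k_corr_ = k_corr
        self.n_features_in_ = x1.shape[1] * x1.shape[2]
        return self

    def _step(self, b1, b2, opt, im1, im2, k_corr):
        h1 = b1.forward(im1)
        h2 = b2.forward(im2)
        val, g1, g2 = total_correlation_with_grad(h1, h2, k_corr=k_corr,
                                                  reg=self.cov_reg)
        b1.backward(-g1)  # ascent on the objective = descent on its negative
        b2.backward(-g2)
        opt.step(b1.grads + b2.grads)
        return val

    def transform_view(self, matrices, view: View | str) -> np.ndarray:
        """Project matrices of one view: branch forward then post-hoc CCA."""
        check_is_fitted(self, "post_cca_")
        view = View(view)
        arr = matrices if isinstance(matrices, np.ndarray) else np.stack(
            [m.values if isinstance(m, LatentMatrix) else np.asarray(m, float)
             for m in matrices])
        if arr.ndim == 2:
            arr = arr[None]
        branch = self.branch1_ if view is View.view1 else self.branch2_
        h = branch.forward(self._branch_input(arr))
        return self.post_cca_.project(h, 1 if view is View.view1 else 2)

    def transform(self, X):
        """Project a paired dataset; returns ``(V1, V2)``."""
        x1, x2 = _stack_views(X)
        return (self.transform_view(x1, View.view1),
                self.transform_view(x2, View.view2))


# ---------------------------------------------------------------------------
# thin functional surface over the estimator
# ---------------------------------------------------------------------------

def train_dcca(training_pairs, hyper: DCCAHyperparams, **kwargs) -> DeepCCA:
    """Train a :class:`DeepCCA` on a list of ``(LatentMatrix, LatentMatrix)`` pairs."""
    if len(training_pairs) < 3:
        raise ValidationError(
            f"need at least 3 training pairs, got {len(training_pairs)}")
    v1 = [p[0] for p in training_pairs]
    v2 = [p[1] for p in training_pairs]
    est = DeepCCA(k_dcca=hyper.k_dcca, learning_rate=hyper.learning_rate,
                  epochs=hyper.epochs, batch_size=hyper.batch_size,
                  cov_reg=hyper.cov_reg, seed=hyper.seed, **kwargs)
    return est.fit((v1, v2))


def branch_forward(model: DeepCCA, matrix, view: View | str) -> np.ndarray:
    """Raw branch output L for one latent matrix (no CCA projection)."""
    check_is_fitted(model, "post_cca_")
    view = View(view)
    values = matrix.values if isinstance(matrix, LatentMatrix) else np.asarray(matrix, float)
    branch = model.branch1_ if view is View.view1 else model.branch2_
    return branch.forward(model._branch_input(values[None]))[0]


def project(model: DeepCCA, matrix, view: View | str) -> np.ndarray:
    """Canonical projection V of one latent matrix from the stated view."""
    view = View(view)
    if isinstance(matrix, LatentMatrix) and matrix.view_tag is not view:
        raise ValidationError(
            f"matrix is tagged {matrix.view_tag.value}, requested {view.value}")
    values = matrix.values if isinstance(matrix, LatentMatrix) else np.asarray(matrix, float)
    return model.transform_view(values[None], view)[0]
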