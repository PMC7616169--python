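"""Closed-form regularized linear CCA and the differentiable total-correlation objective.

Canonical correlation analysis (CCA) finds paired linear projections of two
views that maximize the correlation between the projected variables.  Two
pieces live here:

* :func:`linear_cca` — the closed-form solution via the singular value
  decomposition of the whitened cross-covariance.  It serves both as the
  post-hoc projection layer fitted on deep-branch outputs and as the exact
  oracle the deep model is tested against in its linear regime.

* :func:`total_correlation` / :func:`total_correlation_with_grad` — the sum of
  the top canonical correlations of two output blocks, with its analytic
  gradient with respect to both blocks.  This is the training objective of the
  deep CCA model: maximize corr(f1(X1; theta1), f2(X2; theta2)) over the branch
  parameters.

Conventions (fixed so tests are exact): samples are rows; covariances are
normalized by n - 1; ridge regularization ``reg`` is added to both
auto-covariance blocks; canonical correlations are reported in descending
order, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import SingularityError, ValidationError

__all__ = ["CCAResult", "linear_cca", "total_correlation", "total_correlation_with_grad",
           "canonical_correlations_from_cov"]

#: default ridge added to the auto-covariance blocks (standard deep-CCA practice)
DEFAULT_REG = 1e-4

_RANK_TOL = 1e-10


@dataclass
class CCAResult:
    """Fitted linear canonical projections for two views.

    Attributes
    ----------
    projection_1, projection_2 : ndarray of shape (d_view, k)
        Projection maps; columns are canonical directions in the whitened
        (regularized) metric, so projected training data have unit variance
        per canonical dimension.
    mean_1, mean_2 : ndarray of shape (d_view,)
        Training means subtracted before projection.
    correlations : ndarray of shape (k,)
        Canonical correlations, descending, each in [0, 1].
    reg : float
        Ridge added to the auto-covariance blocks at fit time.
    """

    projection_1: np.ndarray
    projection_2: np.ndarray
    mean_1: np.ndarray
    mean_2: np.ndarray
    correlations: np.ndarray
    reg: float = field(default=DEFAULT_REG)

    @property
    def k(self) -> int:
        return self.correlations.shape[0]

    def project(self, samples: np.ndarray, view: int) -> np.ndarray:
        """Project ``samples`` (n x d or d-vector) of view 1 or 2 onto the canonical space."""
        if view not in (1, 2):
            raise ValidationError(f"view must be 1 or 2, got {view!r}")
        mean = self.mean_1 if view == 1 else self.mean_2
        w = self.projection_1 if view == 1 else self.projection_2
        samples = np.asarray(samples, dtype=float)
        single = samples.ndim == 1
        if single:
            samples = samples[None, :]
        if samples.shape[1] != w.shape[0]:
            raise ValidationError(
                f"view {view} samples have dimension {samples.shape[1]}, "
                f"expected {w.shape[0]}")
        out = (samples - mean) @ w
        return out[0] if single else out


def _as_2d(x, name):
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValidationError(f"{name} must be a 2-D array, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{name} contains non-finite values")
    return x


def _inv_sqrt_psd(cov: np.ndarray, reg: float, name: str) -> np.ndarray:
    """Inverse symmetric square root of ``cov + reg*I``; raises if singular at reg=0."""
    k = cov.shape[0]
    cov = cov + reg * np.eye(k)
    vals, vecs = np.linalg.eigh(cov)
    tol = _RANK_TOL * max(1.0, float(vals[-1]))
    if vals[0] <= tol:
        raise SingularityError(
            f"{name} auto-covariance is rank deficient (min eigenvalue "
            f"{vals[0]:.3e}); supply reg > 0")
    return (vecs * (1.0 / np.sqrt(vals))) @ vecs.T


def _whitened_cross_cov(h1, h2, reg):
    """Center both blocks and return (T, S1is, S2is, h1c, h2c, n)."""
    n = h1.shape[0]
    h1c = h1 - h1.mean(axis=0)
    h2c = h2 - h2.mean(axis=0)
    s11 = h1c.T @ h1c / (n - 1)
    s22 = h2c.T @ h2c / (n - 1)
    s12 = h1c.T @ h2c / (n - 1)
    s1is = _inv_sqrt_psd(s11, reg, "view1")
    s2is = _inv_sqrt_psd(s22, reg, "view2")
    t = s1is @ s12 @ s2is
    return t, s1is, s2is, h1c, h2c, n


def linear_cca(samples_1: np.ndarray, samples_2: np.ndarray, k: int,
               reg: float = DEFAULT_REG) -> CCAResult:
    """Fit linear CCA between two sample blocks.

    Parameters
    ----------
    samples_1, samples_2 : ndarray of shape (n, d1) and (n, d2)
        Paired observations, one row per sample.
    k : int
        Number of canonical pairs to keep; ``k <= min(d1, d2)``.
    reg : float
        Ridge added to both auto-covariance blocks.  ``reg = 0`` demands full
        rank and raises :class:`SingularityError` otherwise.

    Returns
    -------
    CCAResult

    Notes
    -----
    Correlations are the top-k singular values of the whitened cross-covariance
    ``S11^{-1/2} S12 S22^{-1/2}``.  Signs are fixed deterministically: each
    view-1 direction is scaled so its largest-magnitude loading is positive and
    the paired view-2 direction is flipped together with it, preserving a
    nonnegative canonical covariance.
    """
    h1 = _as_2d(samples_1, "samples_1")
    h2 = _as_2d(samples_2, "samples_2")
    if h1.shape[0] != h2.shape[0]:
        raise ValidationError(
            f"sample counts differ: {h1.shape[0]} vs {h2.shape[0]}")
    n, d1 = h1.shape
    d2 = h2.shape[1]
    if n < 3:
        raise ValidationError(f"need at least 3 samples, got {n}")
    if not 1 <= k <= min(d1, d2):
        raise ValidationError(f"k={k} must be in [1, min(d1, d2)={min(d1, d2)}]")
    if reg < 0:
        raise ValidationError(f"reg must be nonnegative, got {reg}")

    t, s1is, s2is, h1c, h2c, _ = _whitened_cross_cov(h1, h2, reg)
    u, s, vt = np.linalg.svd(t)
    corr = np.clip(s[:k], 0.0, 1.0)
    w1 = s1is @ u[:, :k]
    w2 = s2is @ vt[:k].T
    # sign convention: largest-|loading| of the view-1 direction positive;
    # view-2 flipped jointly so the canonical covariance stays nonnegative
    for j in range(k):
        i = int(np.argmax(np.abs(w1[:, j])))
        if w1[i, j] < 0:
            w1[:, j] = -w1[:, j]
            w2[:, j] = -w2[:, j]
    return CCAResult(projection_1=w1, projection_2=w2,
                     mean_1=h1.mean(axis=0), mean_2=h2.mean(axis=0),
                     correlations=corr, reg=reg)


def _pinv_sqrt_psd(cov: np.ndarray) -> np.ndarray:
    """Pseudo-inverse symmetric square root, restricting to the support of ``cov``."""
    vals, vecs = np.linalg.eigh(cov)
    tol = _RANK_TOL * max(1.0, float(vals[-1]))
    inv = np.where(vals > tol, 1.0 / np.sqrt(np.clip(vals, tol, None)), 0.0)
    return (vecs * inv) @ vecs.T


def canonical_correlations_from_cov(s11: np.ndarray, s12: np.ndarray,
                                    s22: np.ndarray) -> np.ndarray:
    """Population canonical correlations from covariance blocks, descending in [0, 1].

    Rank-deficient auto-covariances (e.g. a noiseless linear observation of a
    lower-dimensional signal) are handled by restricting to their support.
    """
    s1is = _pinv_sqrt_psd(np.asarray(s11, dtype=float))
    s2is = _pinv_sqrt_psd(np.asarray(s22, dtype=float))
    s = np.linalg.svd(s1is @ np.asarray(s12, dtype=float) @ s2is, compute_uv=False)
    return np.clip(np.sort(s)[::-1], 0.0, 1.0)


def _validate_tc(outputs_1, outputs_2, k_corr, reg):
    h1 = _as_2d(outputs_1, "outputs_1")
    h2 = _as_2d(outputs_2, "outputs_2")
    if h1.shape[0] != h2.shape[0]:
        raise ValidationError(
            f"sample counts differ: {h1.shape[0]} vs {h2.shape[0]}")
    n = h1.shape[0]
    if n < 2:
        raise ValidationError(f"need at least 2 samples, got {n}")
    if reg < 0:
        raise ValidationError(f"reg must be nonnegative, got {reg}")
    kmax = min(h1.shape[1], h2.shape[1])
    if k_corr is None:
        k_corr = kmax
    if not 1 <= k_corr <= kmax:
        raise ValidationError(f"k_corr={k_corr} must be in [1, {kmax}]")
    return h1, h2, int(k_corr)


def total_correlation(outputs_1: np.ndarray, outputs_2: np.ndarray,
                      k_corr: int | None = None, reg: float = DEFAULT_REG) -> float:
    """Sum of the top ``k_corr`` canonical correlations of two output blocks.

    This is the deep-CCA training objective: a value in ``[0, k_corr]``,
    reaching ``k_corr`` only when the two blocks are perfectly correlated in
    ``k_corr`` dimensions (up to the regularized metric).
    """
    h1, h2, k_corr = _validate_tc(outputs_1, outputs_2, k_corr, reg)
    t, *_ = _whitened_cross_cov(h1, h2, reg)
    s = np.linalg.svd(t, compute_uv=False)
    return float(np.sum(np.clip(s[:k_corr], 0.0, 1.0)))


def total_correlation_with_grad(outputs_1: np.ndarray, outputs_2: np.ndarray,
                                k_corr: int | None = None,
                                reg: float = DEFAULT_REG):
    """Total-correlation objective and its gradient w.r.t. both output blocks.

    Returns ``(value, grad_1, grad_2)`` where ``grad_v`` has the shape of
    ``outputs_v``.  The gradient follows the standard deep-CCA derivation:
    with ``T = S11^{-1/2} S12 S22^{-1/2} = U diag(s) V'`` and the retained
    top-r triple ``(U_r, s_r, V_r)``,

        d f / d H1 = (1/(n-1)) (H1c · 2∇11 + H2c · ∇12') ,
        ∇12 = S11^{-1/2} U_r V_r' S22^{-1/2} ,
        ∇11 = -(1/2) S11^{-1/2} U_r diag(s_r) U_r' S11^{-1/2} ,

    and symmetrically for the second block.  Valid wherever the retained
    singular values are simple (away from ties), which is where gradient
    correctness is asserted.
    """
    h1, h2, k_corr = _validate_tc(outputs_1, outputs_2, k_corr, reg)
    t, s1is, s2is, h1c, h2c, n = _whitened_cross_cov(h1, h2, reg)
    u, s, vt = np.linalg.svd(t)
    value = float(np.sum(np.clip(s[:k_corr], 0.0, 1.0)))
    ur = u[:, :k_corr]
    vr = vt[:k_corr].T
    sr = s[:k_corr]
    nabla12 = s1is @ ur @ vr.T @ s2is
    nabla11 = -0.5 * s1is @ (ur * sr) @ ur.T @ s1is
    nabla22 = -0.5 * s2is @ (vr * sr) @ vr.T @ s2is
    g1 = (h1c @ (2.0 * nabla11) + h2c @ nabla12.T) / (n - 1)
    g2 = (h2c @ (2.0 * nabla22) + h1c @ nabla12) / (n - 1)
    return value, g1, g2
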