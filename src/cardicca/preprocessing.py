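"""Temporal normalisation of per-frame latent sequences.

Different acquisitions sample the cardiac cycle at different native frame
counts, so per-subject latent sequences must be warped onto a canonical
temporal grid before they can be compared or fed to a convolutional model.
A two-segment piecewise-linear time map anchored at end diastole (ED, cycle
start) and end systole (ES) sends every native sequence to exactly ``T``
canonical frames (default 25), with the ES anchor landing at a configurable
canonical position.  Each latent dimension is interpolated linearly and
independently; no smoothing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ValidationError

__all__ = ["View", "CycleTimings", "LatentMatrix", "piecewise_linear_resample",
           "assemble_latent_matrix", "CycleResampler", "CANONICAL_T",
           "CANONICAL_ES_FRACTION"]

#: canonical number of frames per cardiac cycle after resampling
CANONICAL_T = 25
#: canonical cycle fraction at which the ES anchor is placed (typical systole)
CANONICAL_ES_FRACTION = 0.35


class View(str, Enum):
    """Tag for the two imaging views (e.g. CMR la4Ch and echo apical 4Ch)."""

    view1 = "view1"
    view2 = "view2"


@dataclass(frozen=True)
class CycleTimings:
    """Cardiac-cycle anchors of a native frame sequence.

    ``ed_index`` is the cycle start (by convention 0), ``es_index`` the
    end-systolic frame, ``n_frames`` the native sequence length; the
    invariant ``0 = ed_index < es_index < n_frames - 1`` must hold so both
    warp segments are non-degenerate.
    """

    ed_index: int
    es_index: int
    n_frames: int

    def __post_init__(self):
        if self.ed_index != 0:
            raise ValidationError(f"ed_index must be 0, got {self.ed_index}")
        if not (0 < self.es_index < self.n_frames - 1):
            raise ValidationError(
                f"es_index={self.es_index} must lie strictly between ED (0) "
                f"and the last frame ({self.n_frames - 1})")


@dataclass
class LatentMatrix:
    """A d x T latent matrix: rows are latent variables, columns temporal frames."""

    values: np.ndarray
    view_tag: View
    subject_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError(
                f"latent matrix must be 2-D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("latent matrix contains non-finite values")
        self.view_tag = View(self.view_tag)

    @property
    def d(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


def _frames_to_array(frames, name="frames"):
    try:
        arr = np.asarray(frames, dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{name} is ragged: {exc}") from None
    if arr.ndim == 1 and arr.dtype == object or arr.ndim != 2:
        raise ValidationError(
            f"{name} must be a sequence of equal-length vectors")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contain non-finite values")
    return arr  # (n_frames, d)


def canonical_es_index(T: int, canonical_es_fraction: float) -> int:
    """Canonical column index of the ES anchor: round(fraction * (T - 1))."""
    return int(round(canonical_es_fraction * (T - 1)))


def piecewise_linear_resample(frames, timings: CycleTimings, T: int = CANONICAL_T,
                              canonical_es_fraction: float = CANONICAL_ES_FRACTION,
                              view_tag: View = View.view1,
                              subject_id: str = "") -> LatentMatrix:
    """Warp a native latent sequence onto the canonical ``T``-frame grid.

    The two-segment piecewise-linear map sends native ED (frame 0) to
    canonical column 0, the native ES frame to canonical column
    ``round(canonical_es_fraction * (T - 1))`` and the native last frame to
    column ``T - 1``.  Every canonical column is the linear interpolation of
    its two bracketing native frames under the inverse map, per latent
    dimension independently.
    """
    arr = _frames_to_array(frames)
    if arr.shape[0] != timings.n_frames:
        raise ValidationError(
            f"got {arr.shape[0]} frames but timings declare {timings.n_frames}")
    if arr.shape[0] < 3:
        raise ValidationError(f"need at least 3 frames, got {arr.shape[0]}")
    if T < 3:
        raise ValidationError(f"T must be at least 3, got {T}")
    if not 0.0 < canonical_es_fraction < 1.0:
        raise ValidationError(
            f"canonical_es_fraction must be in (0, 1), got {canonical_es_fraction}")
    es_c = canonical_es_index(T, canonical_es_fraction)
    if not 0 < es_c < T - 1:
        raise ValidationError(
            f"canonical ES column {es_c} degenerate for T={T}, "
            f"fraction={canonical_es_fraction}")
    es, last = timings.es_index, timings.n_frames - 1
    cols = np.arange(T, dtype=float)
    native = np.where(
        cols <= es_c,
        cols * (es / es_c),
        es + (cols - es_c) * ((last - es) / (T - 1 - es_c)),
    )
    out = np.empty((arr.shape[1], T))
    grid = np.arange(timings.n_frames, dtype=float)
    for i in range(arr.shape[1]):
        out[i] = np.interp(native, grid, arr[:, i])
    return LatentMatrix(values=out, view_tag=view_tag, subject_id=subject_id)


def assemble_latent_matrix(per_frame_vectors, view_tag: View = View.view1,
                           subject_id: str = "") -> LatentMatrix:
    """Stack per-frame latent vectors into a d x n_frames matrix (column j = frame j)."""
    arr = _frames_to_array(per_frame_vectors, "per_frame_vectors")
    if arr.shape[0] == 0:
        raise ValidationError("per_frame_vectors is empty")
    return LatentMatrix(values=arr.T, view_tag=view_tag, subject_id=subject_id)


class CycleResampler(BaseEstimator, TransformerMixin):
    """Stateless transformer applying the piecewise-linear cycle warp.

    ``transform`` takes a list of ``(frames, CycleTimings)`` pairs — frames as
    an ``(n_frames, d)`` array — and returns an ``(n_subjects, d, T)`` array of
    canonical latent matrices.  Kept as an estimator so it composes with
    scikit-learn pipelines; ``fit`` is a no-op.
    """

    def __init__(self, T: int = CANONICAL_T,
                 canonical_es_fraction: float = CANONICAL_ES_FRACTION):
        self.T = T
        self.canonical_es_fraction = canonical_es_fraction

    def fit(self, X, y=None):
        self.n_features_in_ = None  # sequences are ragged by design
        return self

    def transform(self, X):
        mats = [
            piecewise_linear_resample(frames, timings, T=self.T,
                                      canonical_es_fraction=self.canonical_es_fraction).values
            for frames, timings in X
        ]
        return np.stack(mats, axis=0)
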