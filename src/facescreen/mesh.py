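"""Face-mesh normalization and PCA reduction of per-frame landmark vectors.

Each frame carries 478 3-D landmarks (plus an optional visibility flag).
Normalization recenters every frame on a designated face-center landmark
and isotropically rescales it so the largest absolute coordinate is 1,
removing camera placement and distance as nuisance factors.  Normalized
frames (1434 = 478 x 3 features after the visibility channel is dropped)
are then reduced by PCA fit on pooled training frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_N_LANDMARKS",
    "DEFAULT_CENTER_INDEX",
    "MeshFrame",
    "MeshSequence",
    "PCAModel",
    "center_frame",
    "rescale_frame",
    "normalize_sequence",
    "fit_pca",
    "transform_pca",
    "explained_variance_table",
]

DEFAULT_N_LANDMARKS = 478
#: Nose-tip landmark of the 478-point face-mesh topology; a stable,
#: near-centroid choice for the recentering origin.
DEFAULT_CENTER_INDEX = 1
#: Normalized coordinates are rounded to this many decimals.  The rounding
#: canonicalizes the output so that sub-microscale arithmetic noise from a
#: session's camera transform (values differ by ~1e-14 after the analytic
#: nuisance cancels) does not leak into downstream results.
_CANONICAL_DECIMALS = 9


@dataclass(frozen=True)
class MeshFrame:
    """One frame of face-mesh landmarks: ``coords`` of shape (n, 3),
    optional per-landmark ``visibility`` of shape (n,)."""

    coords: np.ndarray
    visibility: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must have shape (n_landmarks, 3), got {coords.shape}")
        object.__setattr__(self, "coords", coords)
        if self.visibility is not None:
            vis = np.asarray(self.visibility, dtype=float)
            if vis.shape != (coords.shape[0],):
                raise ValueError("visibility must have one entry per landmark")
            object.__setattr__(self, "visibility", vis)

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class MeshSequence:
    """Time-ordered landmark frames of one session.

    ``coords`` has shape (n_frames, n_landmarks, 3); ``visibility``,
    if present, (n_frames, n_landmarks).
    """

    coords: np.ndarray
    visibility: np.ndarray | None = None
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_landmarks, 3), got {coords.shape}"
            )
        if coords.shape[0] == 0:
            raise ValueError("mesh sequence must contain at least one frame")
        object.__setattr__(self, "coords", coords)
        if self.visibility is not None:
            vis = np.asarray(self.visibility, dtype=float)
            if vis.shape != coords.shape[:2]:
                raise ValueError("visibility must have shape (n_frames, n_landmarks)")
            object.__setattr__(self, "visibility", vis)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def frame(self, t: int) -> MeshFrame:
        vis = None if self.visibility is None else self.visibility[t]
        return MeshFrame(self.coords[t], vis)


def center_frame(frame: MeshFrame, center_index: int = DEFAULT_CENTER_INDEX) -> MeshFrame:
    """Translate a frame so the designated center landmark sits at the origin."""
    if not 0 <= center_index < frame.n_landmarks:
        raise IndexError(
            f"center_index {center_index} out of range for {frame.n_landmarks} landmarks"
        )
    return MeshFrame(frame.coords - frame.coords[center_index], frame.visibility)


def rescale_frame(frame: MeshFrame) -> MeshFrame:
    """Apply one isotropic scale so the largest absolute coordinate is 1.

    Requires a centered frame with at least one nonzero coordinate; shape
    is preserved because a single scalar multiplies every axis.
    """
    scale = np.abs(frame.coords).max()
    if scale == 0.0:
        raise ValueError("cannot rescale an all-zero frame: scale is undefined")
    return MeshFrame(frame.coords / scale, frame.visibility)


def normalize_sequence(
    seq: MeshSequence, center_index: int = DEFAULT_CENTER_INDEX
) -> np.ndarray:
    """Center and rescale every frame; return (n_frames, n_landmarks*3).

    Each frame is processed independently and flattened landmark-major
    (x, y, z per landmark); the visibility channel is dropped.  Output is
    invariant to any global translation plus positive isotropic scaling of
    the input session.
    """
    out = np.empty((seq.n_frames, seq.n_landmarks * 3))
    for t in range(seq.n_frames):
        try:
            frame = rescale_frame(center_frame(seq.frame(t), center_index))
        except (ValueError, IndexError) as exc:
            raise type(exc)(f"frame {t}: {exc}") from exc
        out[t] = frame.coords.ravel()
    return np.round(out, _CANONICAL_DECIMALS)


@dataclass(frozen=True)
class PCAModel:
    """PCA basis fit on pooled training frames.

    ``mean`` is the training-frame mean, ``components`` a (k, n_features)
    matrix with orthonormal rows, ``explained_variance_ratio`` the share of
    total variance captured per component (nonincreasing).
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        components = np.asarray(self.components, dtype=float)
        ratios = np.asarray(self.explained_variance_ratio, dtype=float)
        if components.ndim != 2 or components.shape[1] != mean.shape[0]:
            raise ValueError("components must be (k, n_features) matching the mean length")
        if ratios.shape != (components.shape[0],):
            raise ValueError("one explained-variance ratio per component required")
        gram = components @ components.T
        if not np.allclose(gram, np.eye(components.shape[0]), atol=1e-8):
            raise ValueError("component rows must be orthonormal")
        if np.any(np.diff(ratios) > 1e-12) or np.any(ratios < -1e-12):
            raise ValueError("explained-variance ratios must be nonnegative and nonincreasing")
        if ratios.sum() > 1 + 1e-8:
            raise ValueError("explained-variance ratios must sum to at most 1")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "components", components)
        object.__setattr__(self, "explained_variance_ratio", ratios)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def save(self, path: str | Path, config: dict | None = None) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "config": config or {},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            np.asarray(payload["mean"]),
            np.asarray(payload["components"]),
            np.asarray(payload["explained_variance_ratio"]),
        )


def fit_pca(training_frames: np.ndarray, k: int) -> PCAModel:
    """Fit a k-component PCA on a pooled (n_frames, n_features) matrix.

    Components are the top-k right singular directions of the mean-centered
    matrix.  Sign is fixed by forcing the largest-magnitude entry of each
    component nonnegative, making the fit deterministic.
    """
    X = np.asarray(training_frames, dtype=float)
    if X.ndim != 2:
        raise ValueError("training frames must form a 2-D matrix")
    n, d = X.shape
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k >= n:
        raise ValueError(f"k={k} requires more than k training frames, got {n}")
    if k > d:
        raise ValueError(f"k={k} exceeds the feature dimension {d}")
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    components = vt[:k].copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    total = float(np.sum(s**2))
    ratios = (s[:k] ** 2 / total) if total > 0 else np.zeros(k)
    return PCAModel(mean, components, ratios)


def transform_pca(model: PCAModel, frames: np.ndarray) -> np.ndarray:
    """Project mean-centered frames onto the model's components."""
    X = np.atleast_2d(np.asarray(frames, dtype=float))
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"frame width {X.shape[1]} does not match model width {model.mean.shape[0]}"
        )
    return (X - model.mean) @ model.components.T


def explained_variance_table(model: PCAModel) -> pd.DataFrame:
    """Cumulative explained variance per component count, as a table."""
    cumulative = np.cumsum(model.explained_variance_ratio)
    return pd.DataFrame(
        {
            "n_components": np.arange(1, model.n_components + 1),
            "cumulative_explained_variance": cumulative,
        }
    )
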