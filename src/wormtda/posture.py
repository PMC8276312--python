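"""Midline <-> tangent-angle conversion, posture PCA, occlusion fill.

A worm midline is 101 evenly spaced planar points; its posture is the vector
of 100 tangent angles of consecutive segments, mean-centered so that rigid
rotation (overall heading) is removed along with position.  This is the
"worm-centric" eigenworm-style parameterization: the angles are absolute
tangent angles, not adjacent-segment turning angles (both conventions exist
in the literature; centered-absolute is the default here).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .series import TimeSeries

N_MIDLINE_POINTS = 101
N_ANGLES = N_MIDLINE_POINTS - 1


@dataclass
class Midline:
    """101 ordered planar points with distinct consecutive points."""

    points: np.ndarray  # (101, 2)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_MIDLINE_POINTS, 2):
            raise ValueError(f"midline must be ({N_MIDLINE_POINTS}, 2)")

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.points, columns=["x", "y"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Midline":
        import pandas as pd

        return cls(pd.read_csv(path)[["x", "y"]].to_numpy(dtype=float))


@dataclass
class PostureBasis:
    """PCA basis over posture vectors: mean, orthonormal components,
    explained variances sorted descending."""

    mean: np.ndarray
    components: np.ndarray  # (d, d) rows = components
    explained_variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("mean", data=self.mean)
            f.create_dataset("components", data=self.components)
            f.create_dataset("explained_variance", data=self.explained_variance)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "PostureBasis":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(f["mean"][()], f["components"][()], f["explained_variance"][()])


def midline_to_angles(m: Midline) -> np.ndarray:
    """Mean-centered tangent angles of the 100 midline segments."""
    diff = np.diff(m.points, axis=0)
    if np.any(np.all(diff == 0, axis=1)):
        raise ValueError("degenerate segment: repeated consecutive midline points")
    ang = np.arctan2(diff[:, 1], diff[:, 0])
    # unwrap so nearly-straight midlines crossing the +-pi seam stay smooth
    ang = np.unwrap(ang)
    return ang - ang.mean()


def angles_to_midline(theta: np.ndarray, segment_length: float = 1.0) -> Midline:
    """Midline realizing the tangent angles, centroid at the origin.

    Heading of segment ``i`` is ``theta[i]``; the inverse of
    :func:`midline_to_angles` up to mean-centering of the angles.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1 or len(theta) != N_ANGLES:
        raise ValueError(f"expected {N_ANGLES} angles")
    if not np.all(np.isfinite(theta)):
        raise ValueError("angles must be finite")
    steps = segment_length * np.c_[np.cos(theta), np.sin(theta)]
    pts = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return Midline(pts - pts.mean(axis=0))


def fit_posture_pca(series: TimeSeries) -> PostureBasis:
    """Full PCA of the posture frames (mean-centered, unscaled).

    The full orthonormal basis is retained by default: projecting onto it is
    an isometry, so downstream persistence is unchanged; truncation is a
    separate, explicit step (:func:`truncate_projection`).
    """
    X = series.frames
    if len(X) < 2:
        raise ValueError("need at least 2 frames for PCA")
    mean = X.mean(axis=0)
    _, s, Vt = np.linalg.svd(X - mean, full_matrices=True)
    var = np.zeros(X.shape[1])
    var[: len(s)] = s**2 / (len(X) - 1)
    return PostureBasis(mean=mean, components=Vt, explained_variance=var)


def truncate_projection(series: TimeSeries, basis: PostureBasis, k: int) -> TimeSeries:
    """Project each frame onto the first ``k`` principal components."""
    d = series.dim
    if not 1 <= k <= d:
        raise ValueError(f"k={k} out of range 1..{d}")
    proj = (series.frames - basis.mean) @ basis.components[:k].T
    return TimeSeries(proj, fps=series.fps)


def reconstruct_from_projection(
    proj: TimeSeries, basis: PostureBasis
) -> TimeSeries:
    """Back-project truncated PCA coordinates to posture space."""
    k = proj.dim
    X = proj.frames @ basis.components[:k] + basis.mean
    return TimeSeries(X, fps=proj.fps)


def occlusion_fill(series: TimeSeries, valid_mask) -> TimeSeries:
    """Replace invalid frames with the most recent valid frame.

    Emulates the handling of self-occluded frames in midline tracking: an
    occluded frame carries the last well-segmented posture forward.  The
    first frame must be valid.  Idempotent.
    """
    mask = np.asarray(valid_mask, dtype=bool)
    if mask.shape != (series.n_frames,):
        raise ValueError("mask length must equal series length")
    if not mask[0]:
        raise ValueError("first frame invalid: no predecessor to copy")
    # index of most recent valid frame at each position
    idx = np.where(mask, np.arange(len(mask)), 0)
    idx = np.maximum.accumulate(idx)
    return TimeSeries(series.frames[idx], fps=series.fps)
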