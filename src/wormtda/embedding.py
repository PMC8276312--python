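"""Sliding-window (delay) embeddings, patches, and the null model.

The sliding-window embedding of window length ``l`` maps a time series
``(x_t)`` of ``N`` frames in ``R^d`` to the ``N - l + 1`` concatenations
``[x_t x_{t+1} ... x_{t+l-1}]`` in ``R^{l*d}`` (delay 1, no subsampling).
Periodic dynamics unroll into loops in the embedded space, and - unlike a
moving-average filter, which stays in ``R^d`` - the embedding retains the
arrow of time: a series and its reversal can have distinct embedded clouds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import TimeSeries


@dataclass
class WindowedSeries:
    """Sliding-window embedding of a time series.

    ``frames[j]`` is the concatenation of source frames ``j .. j+l-1``;
    ``start_index(j) == j`` maps an embedded point to its first source frame.
    """

    frames: np.ndarray  # (N - l + 1, l * d)
    window_len: int
    source_len: int
    source_dim: int
    fps: float = 30.0

    def __len__(self) -> int:
        return len(self.frames)

    def start_index(self, j: int) -> int:
        if not 0 <= j < len(self.frames):
            raise IndexError(j)
        return j

    def as_series(self) -> TimeSeries:
        return TimeSeries(self.frames, fps=self.fps)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("embedded", data=self.frames)
            ds.attrs["window_len"] = self.window_len
            ds.attrs["source_len"] = self.source_len
            ds.attrs["source_dim"] = self.source_dim
            ds.attrs["fps"] = self.fps

    @classmethod
    def from_hdf5(cls, path) -> "WindowedSeries":
        import h5py

        with h5py.File(path, "r") as f:
            ds = f["embedded"]
            return cls(
                frames=ds[()],
                window_len=int(ds.attrs["window_len"]),
                source_len=int(ds.attrs["source_len"]),
                source_dim=int(ds.attrs["source_dim"]),
                fps=float(ds.attrs["fps"]),
            )


@dataclass
class PatchSet:
    """Contiguous, typically half-overlapping slices of a series."""

    patches: list[TimeSeries]
    offsets: list[int]
    patch_len: int
    stride: int

    def __len__(self) -> int:
        return len(self.patches)


def sliding_window(series: TimeSeries, l: int) -> WindowedSeries:
    """Sliding-window embedding of window length ``l`` (delay 1).

    Raises if ``l`` is not in ``1..N``; the output has ``N - l + 1`` points
    of dimension ``l * d``.
    """
    N, d = series.frames.shape
    if not 1 <= l <= N:
        raise ValueError(f"window length {l} not in 1..{N}")
    idx = np.arange(N - l + 1)[:, None] + np.arange(l)[None, :]
    emb = series.frames[idx].reshape(N - l + 1, l * d)
    return WindowedSeries(
        frames=emb, window_len=l, source_len=N, source_dim=d, fps=series.fps
    )


def moving_average(series: TimeSeries, l: int) -> TimeSeries:
    """Window-mean smoothing; same length as the sliding-window embedding.

    Frame ``j`` of the output is the mean of source frames ``j .. j+l-1``;
    the output stays in the source dimension ``d`` and is therefore blind to
    the direction of time.
    """
    N, d = series.frames.shape
    if not 1 <= l <= N:
        raise ValueError(f"window length {l} not in 1..{N}")
    # block mean of the window view: exactly the linear image of the
    # sliding-window embedding under averaging of the l blocks
    idx = np.arange(N - l + 1)[:, None] + np.arange(l)[None, :]
    out = series.frames[idx].mean(axis=1)
    return TimeSeries(out, fps=series.fps)


def make_patches(series: TimeSeries, P: int, stride: int | None = None) -> PatchSet:
    """Split a series into contiguous patches of ``P`` frames.

    Patches start at ``0, stride, 2*stride, ...``; the default stride is
    ``P // 2`` (adjacent patches overlap by half the patch length).  A final
    partial patch is dropped, so the count is ``floor((N - P)/stride) + 1``.
    """
    N = series.n_frames
    if P > N:
        raise ValueError(f"patch length {P} exceeds series length {N}")
    if stride is None:
        stride = P // 2
    if not 1 <= stride <= P:
        raise ValueError(f"stride {stride} not in 1..{P}")
    starts = range(0, N - P + 1, stride)
    patches = [TimeSeries(series.frames[s : s + P], fps=series.fps) for s in starts]
    return PatchSet(patches=patches, offsets=list(starts), patch_len=P, stride=stride)


def permute_frames(series: TimeSeries, seed: int) -> TimeSeries:
    """Null model: uniformly random permutation of the frame order.

    Destroys all temporal structure while preserving the multiset of poses;
    deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(series.n_frames)
    return TimeSeries(series.frames[perm], fps=series.fps)


def reverse_series(series: TimeSeries) -> TimeSeries:
    """Frames in reversed chronological order (same point set)."""
    return TimeSeries(series.frames[::-1].copy(), fps=series.fps)
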