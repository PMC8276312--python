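"""Time-series container shared by every pipeline stage.

A posture recording is an ordered sequence of fixed-dimension real vectors
(for *C. elegans*, 100 tangent angles per frame at 30 fps).  The container is
a thin, immutable-by-convention wrapper around a ``(N, d)`` float array plus
the frame rate, with CSV and HDF5 round-trip I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class TimeSeries:
    """Ordered frames of fixed-dimension real vectors.

    Parameters
    ----------
    frames : ndarray, shape (N, d)
        One row per frame.  N >= 1.
    fps : float
        Frames per second (metadata only; does not affect geometry).
    """

    frames: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 1:
            self.frames = self.frames[:, None]
        if self.frames.ndim != 2 or len(self.frames) < 1:
            raise ValueError("frames must be a nonempty (N, d) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def dim(self) -> int:
        return self.frames.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        d = self.frames.shape[1]
        pd.DataFrame(self.frames, columns=[f"a{i}" for i in range(d)]).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, fps: float = 30.0) -> "TimeSeries":
        return cls(pd.read_csv(path).to_numpy(dtype=float), fps=fps)

    def to_hdf5(self, path: str | Path, seed: int | None = None) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("angles", data=self.frames)
            ds.attrs["fps"] = self.fps
            if seed is not None:
                ds.attrs["seed"] = seed

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "TimeSeries":
        import h5py

        with h5py.File(path, "r") as f:
            ds = f["angles"]
            return cls(ds[()], fps=float(ds.attrs.get("fps", 30.0)))


@dataclass
class BehaviorLabelTrack:
    """Per-frame behavior label, one of {forward, backward, pause, turn}."""

    labels: list[str] = field(default_factory=list)

    VALID = ("forward", "backward", "pause", "turn")

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        bad = set(self.labels) - set(self.VALID)
        if bad:
            raise ValueError(f"unknown behavior labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    def segments(self) -> list[tuple[str, int, int]]:
        """Contiguous runs as (label, start, stop) with stop exclusive."""
        out = []
        start = 0
        for i in range(1, len(self.labels) + 1):
            if i == len(self.labels) or self.labels[i] != self.labels[start]:
                out.append((self.labels[start], start, i))
                start = i
        return out

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"behavior": self.labels}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BehaviorLabelTrack":
        return cls(pd.read_csv(path)["behavior"].tolist())
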