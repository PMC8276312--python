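"""Persistence landscapes: construction, discretization, averaging, distances.

For a diagram point ``(a, b)`` the tent function is

    f_{a,b}(t) = t - a   on [a, (a+b)/2]
               = b - t   on [(a+b)/2, b]
               = 0       elsewhere

and the depth-``k`` landscape ``lambda_k(t)`` is the k-th largest tent value
at ``t`` over all diagram points.  Landscapes are nested (``lambda_k >=
lambda_{k+1} >= 0``), piecewise linear with slopes in ``[-1, 1]`` (so a grid
of step ``h`` bounds the discretization error by ``h``), and live in a
vector space: averages and Euclidean distances between their discretized
vectors are well defined.  The grid step defaults to 0.1 filtration-scale
units and the grid must cover every bar it discretizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .persistence import PersistenceDiagram

DEFAULT_STEP = 0.1


@dataclass(frozen=True)
class LandscapeGrid:
    """Uniform scale grid ``start + step * (0 .. n_points-1)``."""

    start: float
    step: float
    n_points: int

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.n_points < 2:
            raise ValueError("need at least 2 grid points")

    @property
    def values(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    @property
    def stop(self) -> float:
        return self.start + self.step * (self.n_points - 1)

    def covers(self, diagram: PersistenceDiagram) -> bool:
        if len(diagram) == 0:
            return True
        return self.start <= diagram.points.min() and diagram.points.max() <= self.stop


def grid_for_diagrams(
    diagrams, step: float = DEFAULT_STEP, start: float = 0.0
) -> LandscapeGrid:
    """Shared grid ``[start, max death + step]`` covering every diagram."""
    top = start + step
    for dgm in diagrams:
        if len(dgm):
            top = max(top, float(dgm.points.max()))
    n = int(np.ceil((top + step - start) / step)) + 1
    return LandscapeGrid(start=start, step=step, n_points=n)


@dataclass
class PersistenceLandscape:
    """Discretized landscape: ``values[k, i] = lambda_{k+1}(grid[i])``."""

    grid: LandscapeGrid
    values: np.ndarray  # (K, n_points), nonnegative, nested in k

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.grid.n_points:
            raise ValueError("values do not match the grid")

    @property
    def depth(self) -> int:
        return self.values.shape[0]

    def to_vector(self) -> np.ndarray:
        """Concatenation of the sampled depths, length ``K * n_points``."""
        return self.values.ravel().copy()

    @classmethod
    def from_vector(cls, vec: np.ndarray, grid: LandscapeGrid) -> "PersistenceLandscape":
        vec = np.asarray(vec, dtype=float)
        if vec.size % grid.n_points:
            raise ValueError("vector length not a multiple of grid size")
        return cls(grid=grid, values=vec.reshape(-1, grid.n_points))

    def pad_to_depth(self, K: int) -> "PersistenceLandscape":
        """Zero-pad (or keep) the depth axis to exactly ``K`` functions."""
        if K < self.depth:
            raise ValueError("cannot truncate nonzero depths")
        out = np.zeros((K, self.grid.n_points))
        out[: self.depth] = self.values
        return PersistenceLandscape(grid=self.grid, values=out)

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path: str | Path) -> None:
        """Long format: one row per (depth, t, value)."""
        import pandas as pd

        t = self.grid.values
        rows = [
            (k + 1, t[i], self.values[k, i])
            for k in range(self.depth)
            for i in range(self.grid.n_points)
        ]
        pd.DataFrame(rows, columns=["depth", "t", "value"]).to_csv(path, index=False)

    def to_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values)
            f.attrs["grid_start"] = self.grid.start
            f.attrs["grid_step"] = self.grid.step

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "PersistenceLandscape":
        import h5py

        with h5py.File(path, "r") as f:
            values = f["values"][()]
            grid = LandscapeGrid(
                start=float(f.attrs["grid_start"]),
                step=float(f.attrs["grid_step"]),
                n_points=values.shape[1],
            )
        return cls(grid=grid, values=values)


def tent(a: float, b: float, t) -> np.ndarray | float:
    """Tent function ``f_{a,b}`` evaluated at ``t`` (scalar or array)."""
    if a >= b:
        raise ValueError("tent requires birth < death")
    t = np.asarray(t, dtype=float)
    val = np.maximum(0.0, np.minimum(t - a, b - t))
    return float(val) if val.ndim == 0 else val


def diagram_to_landscape(
    diagram: PersistenceDiagram,
    grid: LandscapeGrid,
    max_depth: int | None = None,
) -> PersistenceLandscape:
    """Exact landscape values on the grid knots.

    ``max_depth=None`` keeps every nonzero depth (one per diagram point).
    """
    if not grid.covers(diagram):
        raise ValueError("grid does not cover the diagram")
    t = grid.values
    if len(diagram) == 0:
        K = max_depth or 1
        return PersistenceLandscape(grid=grid, values=np.zeros((K, grid.n_points)))
    a = diagram.points[:, 0][:, None]
    b = diagram.points[:, 1][:, None]
    tents = np.maximum(0.0, np.minimum(t[None, :] - a, b - t[None, :]))
    tents = -np.sort(-tents, axis=0)  # descending per grid point
    K = len(diagram) if max_depth is None else max_depth
    values = np.zeros((K, grid.n_points))
    take = min(K, len(diagram))
    values[:take] = tents[:take]
    return PersistenceLandscape(grid=grid, values=values)


def average_landscapes(landscapes) -> PersistenceLandscape:
    """Pointwise mean; depths are zero-padded to the common maximum."""
    landscapes = list(landscapes)
    if not landscapes:
        raise ValueError("empty landscape list")
    grid = landscapes[0].grid
    if any(L.grid != grid for L in landscapes):
        raise ValueError("landscapes live on different grids")
    K = max(L.depth for L in landscapes)
    stack = np.stack([L.pad_to_depth(K).values for L in landscapes])
    return PersistenceLandscape(grid=grid, values=stack.mean(axis=0))


def landscape_distance(A: PersistenceLandscape, B: PersistenceLandscape) -> float:
    """Euclidean distance between discretized vectors (depths zero-padded)."""
    if A.grid != B.grid:
        raise ValueError("landscapes live on different grids")
    K = max(A.depth, B.depth)
    return float(
        np.linalg.norm(A.pad_to_depth(K).values - B.pad_to_depth(K).values)
    )


def normalize_class_distances(D: np.ndarray, origin_index: int = -1) -> np.ndarray:
    """Scale a class distance matrix so the mean class-origin distance is 1.

    ``D`` is the symmetric distance matrix over the classes plus the zero
    landscape (the origin), whose row/column is ``origin_index``.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T):
        raise ValueError("D must be symmetric")
    to_origin = np.delete(D[:, origin_index], origin_index % D.shape[0])
    mean = to_origin.mean()
    if mean == 0:
        raise ValueError("all class-to-origin distances are zero")
    return D / mean
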