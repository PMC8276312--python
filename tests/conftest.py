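"""Shared fixtures and the independent brute-force persistence oracle."""

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import pdist


def brute_force_vr(points, max_degree=1):
    """Full boundary-matrix reduction over GF(2), written independently of
    the package: enumerate every simplex up to dimension ``max_degree + 1``,
    sort by (diameter, dimension), reduce left-to-right with dense column
    bitsets, and read the pairs off the pivots.  Only feasible for tiny
    clouds; used as the oracle for the package's reduction.

    Returns {degree: sorted list of (birth, death)} with zero-persistence
    pairs dropped and one infinite degree-0 bar.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    D = np.zeros((n, n))
    if n > 1:
        from scipy.spatial.distance import squareform

        D = squareform(pdist(points))

    simplices = []  # (diameter, dim, vertex tuple)
    for dim in range(0, max_degree + 2):
        for verts in combinations(range(n), dim + 1):
            diam = max(
                (D[a][b] for a, b in combinations(verts, 2)), default=0.0
            )
            simplices.append((diam, dim, verts))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index_of = {s[2]: i for i, s in enumerate(simplices)}

    columns = []
    for _, dim, verts in simplices:
        col = 0
        if dim > 0:
            for face in combinations(verts, dim):
                col |= 1 << index_of[face]
        columns.append(col)

    low_of = {}
    pairs = {}
    for j, col in enumerate(columns):
        while col:
            p = col.bit_length() - 1
            if p not in low_of:
                low_of[p] = j
                pairs[p] = j
                break
            col ^= columns[low_of[p]]
        columns[j] = col

    bars = {d: [] for d in range(max_degree + 1)}
    paired = set(pairs) | set(pairs.values())
    for i, j in pairs.items():
        birth_diam, birth_dim, _ = simplices[i]
        death_diam, _, _ = simplices[j]
        if birth_dim <= max_degree and death_diam > birth_diam:
            bars[birth_dim].append((birth_diam, death_diam))
    for i, (diam, dim, _) in enumerate(simplices):
        if i not in paired and dim <= max_degree and columns[i] == 0:
            bars[dim].append((diam, np.inf))
    return {d: sorted(v) for d, v in bars.items()}


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture(scope="session")
def case_study():
    import wormtda as w

    return w.generate_case_study(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """4-class, 3-per-class cohort with shortened recordings (unit tests)."""
    from dataclasses import replace

    import wormtda as w
    from wormtda.synthdata import DEFAULT_CLASS_PRESETS

    presets = {
        k: replace(p, n_frames=600) for k, p in DEFAULT_CLASS_PRESETS.items()
    }
    return w.generate_class_cohort(presets, 3, seed=7)
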