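"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: brute-force grids,
closed-form geometry and exhaustive enumeration, kept simple enough to be
audited by eye.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.transform import Rotation


def grid_search_min_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Brute-force minimum RMSD over rotations via an Euler-angle grid.

    Hierarchical: a 6° global zyx grid, refined ±6° at 1° and ±2° at 0.5°
    around the running best, with centroid-matching translation at every
    rotation. The terminal resolution is 0.5° (the refinement window is
    wide enough to contain the coarser level's discretization error); since
    the search never solves the algebraic problem it upper-bounds the true
    minimum.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)

    def eval_mats(mats):
        moved = np.einsum("rij,nj->rni", mats, ac)
        msd = np.mean(np.sum((moved - bc) ** 2, axis=2), axis=1)
        k = int(np.argmin(msd))
        return mats[k], float(np.sqrt(msd[k]))

    z = np.arange(-180.0, 180.0, 6.0)
    y = np.arange(-90.0, 90.1, 6.0)
    x = np.arange(-180.0, 180.0, 6.0)
    angles = np.array(list(itertools.product(z, y, x)))
    best_mat, best = eval_mats(Rotation.from_euler("zyx", angles, degrees=True).as_matrix())
    # local refinement in rotation-vector coordinates around the running best
    # (no gimbal degeneracy, unlike refining Euler angles directly)
    for half, step in ((6.0, 1.0), (2.0, 0.5)):
        offs = np.radians(np.arange(-half, half + step / 2, step))
        deltas = np.array(list(itertools.product(offs, offs, offs)))
        mats = Rotation.from_rotvec(deltas).as_matrix() @ best_mat
        mat, val = eval_mats(mats)
        if val < best:
            best_mat, best = mat, val
    return best


def spherical_cap_sasa(r_expanded: float, d: float) -> float:
    """Accessible area of one of two equal spheres (radius already
    probe-expanded) whose centres are ``d`` apart: 4πR² − 2πRh with cap
    height h = R − d/2. Valid for 0 < d < 2R."""
    h = r_expanded - d / 2.0
    return 4.0 * np.pi * r_expanded**2 - 2.0 * np.pi * r_expanded * h


def exact_permutation_p(x, y, stat) -> float:
    """One-sided exact permutation p-value by full enumeration."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    import math

    obs = stat(x, y)
    hits = sum(
        1
        for perm in itertools.permutations(range(x.size))
        if stat(x, y[list(perm)]) >= obs - 1e-12
    )
    return hits / math.factorial(x.size)
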