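"""Registration quality metrics.

Dice similarity over anatomical label masks, per-voxel Jacobian
determinants of the deformation ``phi = id + u``, the folding ratio (the
percentage of voxels with non-positive determinant, i.e. locally
orientation-reversing deformations), and the hierarchical Dice summary
(per-pair mean over structures, then group mean +/- sd over pairs).

Jacobian gradients use central differences on interior voxels; boundary
voxels are excluded from the evaluated set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice coefficient 2|X∩Y| / (|X|+|Y|) of two binary masks.

    Defined as 1.0 when both masks are empty (and 0.0 when exactly one is).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    for name, m in (("X", x), ("Y", y)):
        vals = np.unique(m)
        if not np.isin(vals, (0, 1, False, True)).all():
            raise ValueError(f"mask {name} is not binary (values {vals[:5]}...)")
    nx = int(np.count_nonzero(x))
    ny = int(np.count_nonzero(y))
    if nx + ny == 0:
        return 1.0
    inter = int(np.count_nonzero(np.logical_and(x, y)))
    return 2.0 * inter / (nx + ny)


def jacobian_determinant(u: np.ndarray) -> np.ndarray:
    """Determinant of d(phi)/dp, phi = id + u, at interior voxels.

    `u` is (3,H,W,D); the result has shape (H-2, W-2, D-2).  A zero field
    gives determinant 1 everywhere.
    """
    u = np.asarray(u, dtype=np.float64)
    if u.ndim != 4 or u.shape[0] != 3:
        raise ValueError(f"expected (3,H,W,D) field, got {u.shape}")
    # J[c, d] = d(u_c)/d(x_d) by central differences, interior only
    jac = np.empty((3, 3) + tuple(s - 2 for s in u.shape[1:]), dtype=np.float64)
    for d in range(3):
        hi = [slice(1, -1)] * 3
        lo = [slice(1, -1)] * 3
        hi[d] = slice(2, None)
        lo[d] = slice(None, -2)
        jac[:, d] = (u[(slice(None),) + tuple(hi)] - u[(slice(None),) + tuple(lo)]) / 2.0
    jac[0, 0] += 1.0
    jac[1, 1] += 1.0
    jac[2, 2] += 1.0
    det = (jac[0, 0] * (jac[1, 1] * jac[2, 2] - jac[1, 2] * jac[2, 1])
           - jac[0, 1] * (jac[1, 0] * jac[2, 2] - jac[1, 2] * jac[2, 0])
           + jac[0, 2] * (jac[1, 0] * jac[2, 1] - jac[1, 1] * jac[2, 0]))
    return det


def folding_ratio(u: np.ndarray) -> float:
    """Percentage of interior voxels whose Jacobian determinant is <= 0."""
    det = jacobian_determinant(u)
    return float(np.count_nonzero(det <= 0) / det.size * 100.0)


def dice_per_structure(labels_a: np.ndarray, labels_b: np.ndarray,
                       structures=None) -> dict[int, float]:
    """Dice per non-background label value present in either map."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if structures is None:
        structures = sorted(set(np.unique(a).tolist()) | set(np.unique(b).tolist()))
        structures = [int(s) for s in structures if s != 0]
    return {int(s): dice(a == s, b == s) for s in structures}


def summarize_dice(table: pd.DataFrame) -> tuple[float, float]:
    """Hierarchical summary: per-pair mean over structures, then group
    mean and standard deviation over pairs.

    `table` must have columns ``pair``, ``structure``, ``dice``.
    """
    if len(table) == 0:
        raise ValueError("empty Dice table")
    for col in ("pair", "structure", "dice"):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    per_pair = table.groupby("pair")["dice"].mean()
    return float(per_pair.mean()), float(per_pair.std(ddof=0))
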