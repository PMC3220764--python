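"""Independent oracles used by the test suite.

These deliberately avoid the package's analytic code paths: elementary
rotation matrices are written out long-hand, and the tilt decomposition is
checked against an exhaustive grid search over in-plane tilt hypotheses.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation as ScipyRotation


def rz(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def ry(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def zyz_matrix(phi: float, theta: float, psi: float) -> np.ndarray:
    """Reference ZYZ composition, built only from the elementary matrices."""
    return rz(phi) @ ry(theta) @ rz(psi)


def in_plane_rotation(azimuth_deg: float, tilt_deg: float) -> np.ndarray:
    """Tilt by tilt_deg in direction azimuth_deg: axis in the xy-plane at
    azimuth - 90 degrees."""
    a = np.radians(azimuth_deg - 90.0)
    axis = np.array([np.cos(a), np.sin(a), 0.0])
    return ScipyRotation.from_rotvec(axis * np.radians(tilt_deg)).as_matrix()


def _grid_rotations(az_step: float, tilt_max: float, tilt_step: float):
    az = np.arange(0.0, 360.0, az_step)
    tilts = np.arange(tilt_step, tilt_max + tilt_step / 2.0, tilt_step)
    a = np.radians(az - 90.0)
    axes = np.column_stack([np.cos(a), np.sin(a), np.zeros_like(a)])
    rotvec = (axes[:, None, :] * np.radians(tilts)[None, :, None]).reshape(-1, 3)
    mats = ScipyRotation.from_rotvec(rotvec).as_matrix()
    az_grid = np.repeat(az, len(tilts))
    tilt_grid = np.tile(tilts, len(az))
    return mats, az_grid, tilt_grid


_GRID_CACHE: dict[tuple, tuple] = {}


def grid_search_tilt(
    mu: np.ndarray,
    mt: np.ndarray,
    operators: np.ndarray,
    az_step: float = 1.0,
    tilt_max: float = 60.0,
    tilt_step: float = 0.1,
) -> tuple[float, float, float]:
    """Brute-force tilt recovery.

    Scans every in-plane tilt hypothesis T(azimuth, tilt) on a regular grid
    and returns the (azimuth, tilt, residual_deg) minimizing the
    symmetry-aware angular distance between the predicted tilted
    orientation mu @ T^T (up to a symmetry operator on the left) and the
    observed one.
    """
    key = (az_step, tilt_max, tilt_step)
    if key not in _GRID_CACHE:
        _GRID_CACHE[key] = _grid_rotations(*key)
    grid, az_grid, tilt_grid = _GRID_CACHE[key]

    best = (np.inf, 0.0, 0.0)
    for s in operators:
        # residual for operator s at hypothesis T: angle(mt^T s mu T^T);
        # tr(A T^T) = sum_ij A_ij T_ij with A = mt^T s mu
        a = mt.T @ s @ mu
        tr = np.einsum("ij,nij->n", a, grid)
        cosang = np.clip((tr - 1.0) / 2.0, -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
        i = int(np.argmin(ang))
        if ang[i] < best[0]:
            best = (float(ang[i]), float(az_grid[i]), float(tilt_grid[i]))
    residual, az, tilt = best
    return az, tilt, residual
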