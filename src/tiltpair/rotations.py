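"""Rotation algebra for tilt-pair analysis.

Everything downstream — point-group generation, tilt-axis/angle recovery,
the synthetic-data generator — works in terms of 3x3 proper rotation
matrices.  Euler angles follow the ZYZ convention used by projection
matching: the matrix for a triplet (phi, theta, psi) in degrees is

    M = Rz(phi) @ Ry(theta) @ Rz(psi)

with Rz(a) rotating x toward y and Ry(a) rotating z toward x.  Angles are
degrees at every public boundary; radians appear only internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

#: absolute tolerance for orthonormality / determinant validation
ORTHONORMAL_TOL = 1e-10

#: below this rotation angle (degrees) a rotation is treated as the identity
#: for axis conventions
_ANGLE_EPS_DEG = 1e-9


@dataclass(frozen=True)
class EulerTriplet:
    """ZYZ Euler angles in degrees, stored in canonical ranges.

    theta is canonicalized to [0, 180]; phi and psi to [0, 360).  A triplet
    with theta outside [0, 180] is folded using the identity
    Ry(-t) = Rz(180) Ry(t) Rz(180), so construction never raises for finite
    input.
    """

    phi: float
    theta: float
    psi: float

    def __post_init__(self) -> None:
        phi, theta, psi = float(self.phi), float(self.theta), float(self.psi)
        if not (np.isfinite(phi) and np.isfinite(theta) and np.isfinite(psi)):
            raise ValueError("Euler angles must be finite")
        theta = theta % 360.0
        if theta > 180.0:
            theta = 360.0 - theta
            phi += 180.0
            psi += 180.0
        object.__setattr__(self, "phi", phi % 360.0)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "psi", psi % 360.0)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.phi, self.theta, self.psi)


@dataclass(frozen=True)
class AxisAngle:
    """Axis-angle form: unit axis in the lab frame (beam along +z), angle in
    degrees in [0, 180].  The zero rotation is reported with axis (0, 0, 1)."""

    axis: tuple[float, float, float]
    angle: float

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        if ax.shape != (3,) or not np.all(np.isfinite(ax)):
            raise ValueError("axis must be a finite 3-vector")
        n = float(np.linalg.norm(ax))
        if abs(n - 1.0) > 1e-8:
            raise ValueError(f"axis must be a unit vector (|axis| = {n})")
        if not (0.0 <= self.angle <= 180.0 + 1e-9):
            raise ValueError("angle must lie in [0, 180] degrees")
        object.__setattr__(self, "axis", (float(ax[0]), float(ax[1]), float(ax[2])))
        object.__setattr__(self, "angle", float(self.angle))


def check_rotation(m: np.ndarray, tol: float = ORTHONORMAL_TOL) -> np.ndarray:
    """Validate that *m* is a proper rotation matrix and return it as float64.

    Raises ValueError if columns are not orthonormal within *tol* or the
    determinant is not +1 within *tol*.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3) or not np.all(np.isfinite(m)):
        raise ValueError("rotation must be a finite 3x3 matrix")
    if np.max(np.abs(m.T @ m - np.eye(3))) > tol:
        raise ValueError("matrix columns are not orthonormal")
    if abs(np.linalg.det(m) - 1.0) > tol:
        raise ValueError("matrix determinant is not +1 (improper rotation?)")
    return m


def euler_to_matrix(e: EulerTriplet) -> np.ndarray:
    """Rotation matrix Rz(phi) @ Ry(theta) @ Rz(psi) for a ZYZ triplet."""
    return _ScipyRotation.from_euler(
        "ZYZ", [e.phi, e.theta, e.psi], degrees=True
    ).as_matrix()


def matrix_to_euler(r: np.ndarray) -> EulerTriplet:
    """ZYZ Euler triplet of a rotation matrix.

    At gimbal lock (theta = 0 or 180, where phi and psi are degenerate) the
    convention psi = 0 is used, so results are deterministic.  Outside the
    lock the closed-form extraction is exact:

        m[0,2] = cos(phi) sin(theta)   m[1,2] = sin(phi) sin(theta)
        m[2,0] = -sin(theta) cos(psi)  m[2,1] = sin(theta) sin(psi)
    """
    m = check_rotation(r)
    sin_theta = float(np.hypot(m[0, 2], m[1, 2]))
    theta = np.degrees(np.arctan2(sin_theta, m[2, 2]))
    if sin_theta < 1e-13:
        # lock branch: the two z-rotations merge; residual error O(theta*psi)
        # is below 1e-12 here
        if m[2, 2] > 0.0:
            return EulerTriplet(np.degrees(np.arctan2(m[1, 0], m[0, 0])), 0.0, 0.0)
        return EulerTriplet(np.degrees(np.arctan2(-m[1, 0], -m[0, 0])), 180.0, 0.0)
    phi = np.degrees(np.arctan2(m[1, 2], m[0, 2]))
    psi = np.degrees(np.arctan2(m[2, 1], -m[2, 0]))
    return EulerTriplet(phi, theta, psi)


def axis_angle_to_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation by *angle_deg* about *axis* (normalized internally)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0 or not np.all(np.isfinite(axis)):
        raise ValueError("axis must be a nonzero finite vector")
    return _ScipyRotation.from_rotvec(
        axis / n * np.radians(float(angle_deg))
    ).as_matrix()


def matrix_to_axis_angle(r: np.ndarray) -> AxisAngle:
    """Axis-angle decomposition with a deterministic axis sign.

    The rotation vector fixes the axis uniquely for angles in (0, 180); the
    conventions only matter at the degenerate points: the identity reports
    axis (0, 0, 1), and at 180 deg (where both signs represent the same
    rotation) the sign is chosen so that z >= 0, breaking ties by y >= 0,
    then x > 0.
    """
    m = check_rotation(r)
    rotvec = _ScipyRotation.from_matrix(m).as_rotvec()
    angle_rad = float(np.linalg.norm(rotvec))
    angle = np.degrees(angle_rad)
    if angle < _ANGLE_EPS_DEG:
        return AxisAngle((0.0, 0.0, 1.0), 0.0)
    axis = rotvec / angle_rad
    if angle > 180.0 - 1e-9:
        # R(n, 180) == R(-n, 180): canonicalize the sign
        for i in (2, 1, 0):
            if abs(axis[i]) > 1e-12:
                if axis[i] < 0:
                    axis = -axis
                break
        angle = min(angle, 180.0)
    return AxisAngle(tuple(axis), angle)


def rotation_angle(r: np.ndarray) -> float:
    """Geodesic rotation angle of a single rotation matrix, in degrees."""
    return float(np.degrees(_ScipyRotation.from_matrix(r).magnitude()))


def _batch_angles_deg(mats: np.ndarray) -> np.ndarray:
    """Rotation angles (degrees) of a stack of matrices, quaternion-accurate."""
    return np.degrees(_ScipyRotation.from_matrix(mats).magnitude())


def rotation_distance(
    r1: np.ndarray, r2: np.ndarray, group: "PointGroup | None" = None
) -> float:
    """Symmetry-aware angular distance between two orientations, degrees.

    Computes min over symmetry operators s of the rotation angle of
    r1 @ s @ r2.T; with the trivial group (or ``group=None``) this is the
    ordinary geodesic angle on SO(3).  Symmetric in its arguments and zero
    exactly when the orientations are symmetry-equivalent.
    """
    r1 = check_rotation(r1)
    r2 = check_rotation(r2)
    if group is None:
        return rotation_angle(r1 @ r2.T)
    prods = np.einsum("ij,njk,lk->nil", r1, group.operators, r2)
    return float(np.min(_batch_angles_deg(prods)))


def haar_random_rotation(
    rng: np.random.Generator, n: int | None = None
) -> np.ndarray:
    """Uniform (Haar) random rotation(s) via normalized Gaussian quaternions.

    Returns a (3, 3) matrix for ``n=None``, else an (n, 3, 3) stack.  The
    sampling is reproducible from the supplied numpy Generator.
    """
    size = 1 if n is None else int(n)
    q = rng.normal(size=(size, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    mats = _ScipyRotation.from_quat(q).as_matrix()
    return mats[0] if n is None else mats


def small_random_rotation(
    sigma_rms: float, rng: np.random.Generator, n: int | None = None
) -> np.ndarray:
    """Random small rotation(s) with RMS total rotation angle *sigma_rms* deg.

    The rotation vector has independent zero-mean normal components with
    standard deviation sigma_rms/sqrt(3) each, so E[angle^2] = sigma_rms^2
    exactly (the rotation-vector norm IS the rotation angle).
    """
    if sigma_rms < 0:
        raise ValueError("sigma_rms must be >= 0")
    size = 1 if n is None else int(n)
    if sigma_rms == 0.0:
        mats = np.broadcast_to(np.eye(3), (size, 3, 3)).copy()
    else:
        scale = np.radians(sigma_rms) / np.sqrt(3.0)
        rotvec = rng.normal(scale=scale, size=(size, 3))
        mats = _ScipyRotation.from_rotvec(rotvec).as_matrix()
    return mats[0] if n is None else mats


# imported late to avoid a cycle in type checking only; PointGroup is used
# purely duck-typed above
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .symmetry import PointGroup
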