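"""Tilt-axis/angle recovery between two views of the same particle.

Given ZYZ Euler orientations determined independently for the untilted and
tilted images of a particle, the relating rotation in the lab frame is

    S = M(t)^T  s  M(u)

where M maps view-frame to map-frame coordinates, s runs over the particle's
point-group operators (orientation assignment is only defined up to s), u/t
are the untilted/tilted triplets.  A physical goniometer tilt — plus any
beam-induced ice tilt — rotates the specimen about an axis lying in the
specimen (xy) plane, so the correct symmetry operator is the one whose S is
best fitted by a rotation about an in-plane axis.  The reported residual is
the out-of-plane error |arcsin(axis_z)|: the angle between the recovered
axis and the specimen plane.

A tilt-pair parameter plot reports the *direction of tilt* (perpendicular
to the tilt axis, matching the goniometer arrow on the plots) as azimuth
and the tilt angle as radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

from .rotations import EulerTriplet, euler_to_matrix
from .symmetry import PointGroup

#: below this relating angle (deg) the tilt is degenerate: azimuth and
#: out-of-plane error are reported as 0 by convention
DEGENERATE_TILT_DEG = 1e-9


@dataclass(frozen=True)
class TiltPairRecord:
    """One particle's candidate orientations in the two views.

    Candidate lists hold one triplet per independent orientation-search run;
    a single-run experiment has lists of length one.
    """

    particle_id: str
    pair_id: str
    untilted_candidates: tuple[EulerTriplet, ...]
    tilted_candidates: tuple[EulerTriplet, ...]
    residual: float | None = None
    defocus: float | None = None
    relative_magnification: float | None = None

    def __post_init__(self) -> None:
        if not str(self.particle_id) or not str(self.pair_id):
            raise ValueError("particle_id and pair_id must be non-empty")
        u = tuple(self.untilted_candidates)
        t = tuple(self.tilted_candidates)
        if not u or not t:
            raise ValueError("candidate lists must be non-empty")
        object.__setattr__(self, "untilted_candidates", u)
        object.__setattr__(self, "tilted_candidates", t)


@dataclass(frozen=True)
class TiltResult:
    """Recovered relative tilt for one particle."""

    particle_id: str
    pair_id: str
    tilt_azimuth: float  # degrees in [0, 360): direction of tilt
    tilt_angle: float  # degrees >= 0
    out_of_plane_error: float  # degrees in [0, 90]
    in_plane_misfit: float = 0.0  # degrees: residual of the best in-plane fit
    sym_operator_index: int = 0
    untilted_choice: int = 0
    tilted_choice: int = 0
    flagged: bool = False
    relating: np.ndarray | None = field(default=None, compare=False, repr=False)


def _decompose_stack(
    mats: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(azimuth, angle, out-of-plane error, in-plane misfit) in degrees for
    a stack of relating rotations.

    The in-plane misfit is the geodesic distance from the rotation to the
    nearest rotation about an axis in the specimen plane,
    2 arcsin(sin(angle/2) |sin(oop)|) — the residual of the best in-plane
    fit.  For small angles it reduces to the out-of-plane component of the
    rotation vector; operator selection uses it because it, unlike the bare
    axis inclination, is not small by chance for large wrong-operator
    rotations.
    """
    rotvec = _ScipyRotation.from_matrix(mats).as_rotvec()
    angle_rad = np.linalg.norm(rotvec, axis=1)
    angle = np.degrees(angle_rad)
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = rotvec / angle_rad[:, None]
    degenerate = angle < DEGENERATE_TILT_DEG
    axis[degenerate] = (0.0, 0.0, 1.0)
    z = np.clip(axis[:, 2], -1.0, 1.0)
    oop = np.degrees(np.abs(np.arcsin(z)))
    oop[degenerate] = 0.0
    misfit = np.degrees(
        2.0 * np.arcsin(np.clip(np.sin(angle_rad / 2.0) * np.abs(z), -1.0, 1.0))
    )
    misfit[degenerate] = 0.0
    # direction of tilt = in-plane axis direction rotated +90 deg about z
    azimuth = (np.degrees(np.arctan2(axis[:, 1], axis[:, 0])) + 90.0) % 360.0
    azimuth[degenerate] = 0.0
    # pure beam-axis rotation: in-plane direction undefined, report 0
    in_plane_norm = np.hypot(axis[:, 0], axis[:, 1])
    azimuth[(in_plane_norm < 1e-12) & ~degenerate] = 0.0
    return azimuth, angle, oop, misfit


def _relating_stack(mu: np.ndarray, mt: np.ndarray, group: PointGroup) -> np.ndarray:
    return np.einsum("ji,njk,kl->nil", mt, group.operators, mu)


def relative_tilt(
    u: EulerTriplet,
    t: EulerTriplet,
    group: PointGroup,
    *,
    particle_id: str = "particle",
    pair_id: str = "pair",
) -> TiltResult:
    """Recover the tilt relating a single untilted/tilted orientation pair.

    Every symmetry operator is tried; the one whose relating rotation is
    closest to a rotation about an in-plane axis (smallest in-plane misfit)
    wins, with ties broken by smaller tilt angle, then lower operator
    index.
    """
    mu = euler_to_matrix(u)
    mt = euler_to_matrix(t)
    s_stack = _relating_stack(mu, mt, group)
    azimuth, angle, oop, misfit = _decompose_stack(s_stack)
    best = min(range(len(oop)), key=lambda i: (misfit[i], angle[i], i))
    return TiltResult(
        particle_id=particle_id,
        pair_id=pair_id,
        tilt_azimuth=float(azimuth[best]),
        tilt_angle=float(angle[best]),
        out_of_plane_error=float(oop[best]),
        in_plane_misfit=float(misfit[best]),
        sym_operator_index=best,
        relating=s_stack[best],
    )


def tiltdiffmulti(rec: TiltPairRecord, group: PointGroup) -> TiltResult:
    """Recover the tilt from multi-candidate lists (Tiltdiffmulti).

    All untilted x tilted candidate pairs and all symmetry operators are
    scored; the globally smallest in-plane misfit wins, exploiting the
    prior that the tilt axis must lie in the specimen plane.  With
    single-candidate lists this reduces exactly to ``relative_tilt``.
    """
    mus = [euler_to_matrix(e) for e in rec.untilted_candidates]
    mts = [euler_to_matrix(e) for e in rec.tilted_candidates]
    best_key: tuple | None = None
    best_result: TiltResult | None = None
    for iu, mu in enumerate(mus):
        for it, mt in enumerate(mts):
            s_stack = _relating_stack(mu, mt, group)
            azimuth, angle, oop, misfit = _decompose_stack(s_stack)
            k = min(range(len(oop)), key=lambda i: (misfit[i], angle[i], i))
            key = (misfit[k], angle[k], k, iu, it)
            if best_key is None or key < best_key:
                best_key = key
                best_result = TiltResult(
                    particle_id=rec.particle_id,
                    pair_id=rec.pair_id,
                    tilt_azimuth=float(azimuth[k]),
                    tilt_angle=float(angle[k]),
                    out_of_plane_error=float(oop[k]),
                    in_plane_misfit=float(misfit[k]),
                    sym_operator_index=k,
                    untilted_choice=iu,
                    tilted_choice=it,
                    relating=s_stack[k],
                )
    assert best_result is not None
    return best_result


def tiltdiff(rec: TiltPairRecord, group: PointGroup) -> TiltResult:
    """Single-candidate analysis (Tiltdiff): uses only the first candidate
    from each view."""
    return replace(
        relative_tilt(
            rec.untilted_candidates[0],
            rec.tilted_candidates[0],
            group,
            particle_id=rec.particle_id,
            pair_id=rec.pair_id,
        )
    )


def flag_outliers(
    results: list[TiltResult], factor: float = 1.5
) -> list[TiltResult]:
    """Flag particles whose out-of-plane error exceeds *factor* times the
    mean out-of-plane error of the full input list.

    The mean is computed once over all particles (no re-iteration after
    flagging).  ``factor=inf`` flags nothing.
    """
    if not results:
        raise ValueError("results must be non-empty")
    if not factor > 0:
        raise ValueError("factor must be positive")
    errors = np.array([r.out_of_plane_error for r in results])
    threshold = factor * float(errors.mean())
    if math.isnan(threshold):  # inf * 0
        threshold = math.inf
    return [replace(r, flagged=bool(e > threshold)) for r, e in zip(results, errors)]


def analyze_records(
    records: list[TiltPairRecord],
    group: PointGroup,
    *,
    multi: bool = True,
    outlier_factor: float = 1.5,
) -> list[TiltResult]:
    """Run Tiltdiff(multi) over a dataset and flag outliers in one pass."""
    run = tiltdiffmulti if multi else tiltdiff
    return flag_outliers([run(r, group) for r in records], outlier_factor)
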