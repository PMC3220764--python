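"""Finite rotation point groups used to resolve orientation degeneracy.

Supported groups: cyclic Cn (n >= 1), dihedral Dn (n >= 2), and the proper
icosahedral group in its two axis conventions:

* ``I1`` — fivefold along (0, 1, t), the setting of the International
  Tables;
* ``I2`` — fivefold along (1, 0, t), the Crowther convention common in
  virus crystallography;

where t = (1 + sqrt(5))/2 is the golden ratio.  Both contain 60 proper
rotations and share twofold axes along x, y and z; they are conjugate by a
90 degree rotation about z.

Only proper rotations are generated.  Tilt-pair analysis is sensitive to
hand, and admitting mirror operators would silently erase exactly the
handedness signal the method exists to detect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .rotations import axis_angle_to_matrix, rotation_angle

#: matching tolerance when deduplicating / verifying closure
CLOSURE_TOL = 1e-8

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class PointGroup:
    """A named finite set of proper rotations, identity first."""

    name: str
    operators: np.ndarray = field(repr=False)  # (order, 3, 3)

    @property
    def order(self) -> int:
        return self.operators.shape[0]

    def __post_init__(self) -> None:
        ops = np.asarray(self.operators, dtype=float)
        if ops.ndim != 3 or ops.shape[1:] != (3, 3):
            raise ValueError("operators must be an (n, 3, 3) array")
        ops.setflags(write=False)
        object.__setattr__(self, "operators", ops)


def _project_so3(m: np.ndarray) -> np.ndarray:
    """Nearest proper rotation (polar decomposition via SVD)."""
    u, _, vt = np.linalg.svd(m)
    r = u @ vt
    if np.linalg.det(r) < 0:
        r = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    return r


def _saturate(generators: list[np.ndarray], max_order: int = 200) -> np.ndarray:
    """Close a generator set under composition.

    Products are re-projected onto SO(3) after every multiplication so
    floating-point drift cannot accumulate; new elements are recognized with
    an absolute tolerance of CLOSURE_TOL.
    """
    ops: list[np.ndarray] = [np.eye(3)]

    def _find(m: np.ndarray) -> bool:
        return any(np.max(np.abs(m - o)) < CLOSURE_TOL for o in ops)

    frontier = [g for g in generators]
    while frontier:
        new: list[np.ndarray] = []
        for g in frontier:
            if not _find(g):
                ops.append(g)
                new.append(g)
        if len(ops) > max_order:
            raise RuntimeError("group saturation exceeded the supported order")
        frontier = [
            _project_so3(a @ b) for a in new for b in ops
        ] + [_project_so3(b @ a) for a in new for b in ops]
        frontier = [m for m in frontier if not _find(m)]
    return np.array(ops)


def _sort_canonical(ops: np.ndarray) -> np.ndarray:
    """Deterministic operator order: identity first, then by rotation angle
    and rounded matrix entries."""
    keys = []
    for i, m in enumerate(ops):
        keys.append((round(rotation_angle(m), 6),) + tuple(np.round(m.ravel(), 9)))
    order = sorted(range(len(ops)), key=lambda i: keys[i])
    return ops[order]


_NAME_RE = re.compile(r"^([CcDd])(\d+)$|^([Ii])([12])$")


def make_group(name: str) -> PointGroup:
    """Build a point group from its Schoenflies-style name.

    ``C1``..``Cn`` are rotations by 360 k/n about z; ``Dn`` adds n twofold
    axes perpendicular to z (one along x); ``I1``/``I2`` are the 60 proper
    icosahedral rotations generated from a fivefold about (0,1,t) /
    (1,0,t) plus a twofold about z and closed by saturation.
    """
    m = _NAME_RE.match(str(name).strip())
    if not m:
        raise ValueError(f"unknown point group name: {name!r}")
    if m.group(3):  # icosahedral
        t = GOLDEN_RATIO
        five_axis = (0.0, 1.0, t) if m.group(4) == "1" else (1.0, 0.0, t)
        gens = [
            axis_angle_to_matrix(np.array(five_axis), 72.0),
            axis_angle_to_matrix(np.array([0.0, 0.0, 1.0]), 180.0),
        ]
        ops = _saturate(gens)
        if ops.shape[0] != 60:
            raise RuntimeError(
                f"icosahedral saturation produced {ops.shape[0]} operators"
            )
        return PointGroup(f"I{m.group(4)}", _sort_canonical(ops))

    kind, n = m.group(1).upper(), int(m.group(2))
    if n < 1 or (kind == "D" and n < 2):
        raise ValueError(f"invalid point group name: {name!r}")
    z = np.array([0.0, 0.0, 1.0])
    cyclic = [axis_angle_to_matrix(z, 360.0 * k / n) for k in range(n)]
    if kind == "C":
        return PointGroup(f"C{n}", np.array(cyclic))
    two_x = axis_angle_to_matrix(np.array([1.0, 0.0, 0.0]), 180.0)
    ops = np.array(cyclic + [_project_so3(two_x @ c) for c in cyclic])
    return PointGroup(f"D{n}", ops)


def is_closed(group: PointGroup, tol: float = CLOSURE_TOL) -> bool:
    """Numerically verify closure: every pairwise product matches an operator."""
    ops = group.operators
    for a in ops:
        prods = np.einsum("ij,njk->nik", a, ops)
        for p in prods:
            if not np.any(np.max(np.abs(ops - p), axis=(1, 2)) < tol):
                return False
    return True


def group_equivalent(r1: np.ndarray, r2: np.ndarray, group: PointGroup) -> bool:
    """True iff r1 and r2 differ by a symmetry operator (within 1e-6 deg)."""
    from .rotations import rotation_distance

    return rotation_distance(r1, r2, group) < 1e-6
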