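"""Synthetic tilt-pair generator with known ground truth.

The generative model mirrors the statistical structure a tilt-pair
experiment is assumed to produce:

* per micrograph pair: a nominal goniometer tilt (azimuth alpha*, angle
  tau*) composed with a coherent beam-induced perturbation of the ice film
  — an extra tilt about a random in-plane axis with magnitude uniform in
  [0, beam_tilt_max] (ice films tilt by up to ~2 degrees under a typical
  20 e/A^2 exposure, in directions with no detectable pattern);
* per particle: a Haar-random untilted orientation; the tilted-view truth
  is the effective pair tilt applied in the lab frame;
* per view and candidate: an independent small random rotation with RMS
  total angle sigma (orientation noise of one projection-matching run), or
  — for the tilted view, with probability p per candidate — a Haar-random
  misassignment.  Misassignment is applied to the tilted view because the
  second, more radiation-damaged exposure is the one whose orientation
  search fails more often;
* orientations are then reduced to a canonical symmetry representative, so
  downstream code must genuinely resolve the point-group degeneracy.

With candidates_per_view = K > 1, each candidate emulates one independent
orientation-search run (independently noisy, independently misassigned),
the regime in which multi-candidate selection outperforms a single run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rotations import (
    axis_angle_to_matrix,
    haar_random_rotation,
    matrix_to_axis_angle,
    matrix_to_euler,
    small_random_rotation,
)
from .symmetry import PointGroup, make_group
from .tiltcore import TiltPairRecord


def in_plane_tilt_matrix(azimuth: float, angle: float) -> np.ndarray:
    """Lab-frame rotation tilting the specimen by *angle* degrees in the
    direction *azimuth*: the rotation axis lies in the specimen plane at
    azimuth - 90 degrees."""
    ax = np.radians(azimuth - 90.0)
    return axis_angle_to_matrix(
        np.array([np.cos(ax), np.sin(ax), 0.0]), angle
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth geometry and noise structure of a simulated experiment.

    true_tilt / true_azimuth may be scalars (shared by all pairs) or
    per-pair sequences.  noise_rms is the RMS total rotation angle of the
    per-image orientation error, degrees.  misassignment_fraction is the
    per-candidate probability that the tilted-view orientation search
    returned junk.  beam_tilt_max caps the per-pair coherent ice tilt.
    """

    n_particles: int = 100
    n_pairs: int = 1
    true_tilt: float | tuple[float, ...] = 10.0
    true_azimuth: float | tuple[float, ...] = 90.0
    noise_rms: float = 2.0
    misassignment_fraction: float = 0.0
    beam_tilt_max: float = 0.0
    bend_gradient: float = 0.0
    candidates_per_view: int = 1
    symmetry: str = "C1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_pairs < 1:
            raise ValueError("n_particles and n_pairs must be >= 1")
        if self.candidates_per_view < 1:
            raise ValueError("candidates_per_view must be >= 1")
        if not 0.0 <= self.misassignment_fraction <= 1.0:
            raise ValueError("misassignment_fraction must be in [0, 1]")
        if self.noise_rms < 0 or self.beam_tilt_max < 0 or self.bend_gradient < 0:
            raise ValueError(
                "noise_rms, beam_tilt_max and bend_gradient must be >= 0"
            )
        for v in np.atleast_1d(np.asarray(self.true_tilt, dtype=float)):
            if v < 0:
                raise ValueError("true_tilt must be >= 0")

    def per_pair(self, value) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            return np.full(self.n_pairs, float(arr[0]))
        if arr.size != self.n_pairs:
            raise ValueError("per-pair values must match n_pairs")
        return arr.astype(float)


@dataclass(frozen=True)
class GroundTruth:
    """Every latent variable of one simulated dataset."""

    pair_ids: tuple[str, ...]
    nominal_azimuth: np.ndarray  # (n_pairs,)
    nominal_tilt: np.ndarray  # (n_pairs,)
    effective_azimuth: np.ndarray  # (n_pairs,) after beam-induced motion
    effective_tilt: np.ndarray  # (n_pairs,)
    effective_matrix: np.ndarray  # (n_pairs, 3, 3)
    particle_pair: np.ndarray  # (n,) pair index per particle
    untilted_true: np.ndarray  # (n, 3, 3)
    tilted_true: np.ndarray  # (n, 3, 3)
    misassigned: np.ndarray  # (n, K) bool, tilted-view candidates
    flexed: np.ndarray = field(default=None)  # (n,) bool or None
    bend_positions: np.ndarray = field(default=None)  # (n,) in [-1/2, 1/2] or None


def _canonical_representative(m: np.ndarray, group: PointGroup) -> np.ndarray:
    """Deterministic fundamental-domain representative of the coset
    {s @ m}: the lexicographically smallest rounded matrix."""
    if group.order == 1:
        return m
    stack = np.einsum("nij,jk->nik", group.operators, m)
    keys = np.round(stack.reshape(group.order, 9), 9)
    idx = np.lexsort(keys.T[::-1])[0]
    return stack[idx]


def simulate(
    config: SimulationConfig, domain_split_angle: float = 0.0
) -> tuple[list[TiltPairRecord], GroundTruth]:
    """Generate a reproducible synthetic tilt-pair dataset.

    ``domain_split_angle > 0`` emulates a flexible particle: with
    probability 1/2 per particle the tilted-view truth is composed with an
    extra map-frame rotation of that magnitude (random axis) before noise —
    the orientation "locks onto" a shifted domain in one of the two images,
    broadening the TPPP scatter.

    Returns the particle records and the full latent-state ground truth.
    Identical configs (and split angles) give bit-identical output.
    """
    if domain_split_angle < 0:
        raise ValueError("domain_split_angle must be >= 0")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    group = make_group(cfg.symmetry)

    nominal_az = cfg.per_pair(cfg.true_azimuth)
    nominal_tilt = cfg.per_pair(cfg.true_tilt)
    pair_ids = tuple(f"MP{i + 1:02d}" for i in range(cfg.n_pairs))

    eff_mats = np.empty((cfg.n_pairs, 3, 3))
    eff_az = np.empty(cfg.n_pairs)
    eff_tilt = np.empty(cfg.n_pairs)
    beam_azimuths = np.empty(cfg.n_pairs)
    for p in range(cfg.n_pairs):
        tilt_mat = in_plane_tilt_matrix(nominal_az[p], nominal_tilt[p])
        beam_azimuths[p] = rng.uniform(0.0, 360.0)
        beam_angle = rng.uniform(0.0, cfg.beam_tilt_max) if cfg.beam_tilt_max else 0.0
        beam = in_plane_tilt_matrix(beam_azimuths[p], beam_angle)
        eff = beam @ tilt_mat
        eff_mats[p] = eff
        aa = matrix_to_axis_angle(eff)
        eff_tilt[p] = aa.angle
        eff_az[p] = (
            np.degrees(np.arctan2(aa.axis[1], aa.axis[0])) + 90.0
        ) % 360.0 if aa.angle > 0 else 0.0

    n, K = cfg.n_particles, cfg.candidates_per_view
    particle_pair = np.arange(n) % cfg.n_pairs
    untilted_true = haar_random_rotation(rng, n)
    particle_tilt = eff_mats[particle_pair]
    bend_positions = None
    if cfg.bend_gradient > 0.0:
        # ice bending: the extra tilt varies linearly with the particle's
        # position across the field of view, about the beam-motion azimuth
        bend_positions = rng.uniform(-0.5, 0.5, size=n)
        particle_tilt = particle_tilt.copy()
        for i in range(n):
            bend = in_plane_tilt_matrix(
                beam_azimuths[particle_pair[i]],
                cfg.bend_gradient * bend_positions[i],
            )
            particle_tilt[i] = bend @ particle_tilt[i]
    tilted_true = np.einsum("nij,nkj->nik", untilted_true, particle_tilt)

    flexed = np.zeros(n, dtype=bool)
    tilted_basis = tilted_true.copy()
    if domain_split_angle > 0.0:
        flexed = rng.random(n) < 0.5
        axes = haar_random_rotation(rng, n)  # random axes via random frames
        for i in np.flatnonzero(flexed):
            q = axis_angle_to_matrix(axes[i][:, 2], domain_split_angle)
            tilted_basis[i] = q @ tilted_basis[i]

    misassigned = np.zeros((n, K), dtype=bool)
    if cfg.misassignment_fraction > 0.0:
        misassigned = rng.random((n, K)) < cfg.misassignment_fraction

    records: list[TiltPairRecord] = []
    for i in range(n):
        u_cands = []
        t_cands = []
        for k in range(K):
            nu = small_random_rotation(cfg.noise_rms, rng)
            u_obs = _canonical_representative(nu @ untilted_true[i], group)
            u_cands.append(matrix_to_euler(u_obs))
            if misassigned[i, k]:
                t_obs = haar_random_rotation(rng)
            else:
                nt = small_random_rotation(cfg.noise_rms, rng)
                t_obs = nt @ tilted_basis[i]
            t_cands.append(matrix_to_euler(_canonical_representative(t_obs, group)))
        records.append(
            TiltPairRecord(
                particle_id=f"P{i + 1:05d}",
                pair_id=pair_ids[particle_pair[i]],
                untilted_candidates=tuple(u_cands),
                tilted_candidates=tuple(t_cands),
            )
        )

    truth = GroundTruth(
        pair_ids=pair_ids,
        nominal_azimuth=nominal_az,
        nominal_tilt=nominal_tilt,
        effective_azimuth=eff_az,
        effective_tilt=eff_tilt,
        effective_matrix=eff_mats,
        particle_pair=particle_pair,
        untilted_true=untilted_true,
        tilted_true=tilted_true,
        misassigned=misassigned,
        flexed=flexed,
        bend_positions=bend_positions,
    )
    return records, truth


def flexibility_mode(
    config: SimulationConfig, domain_split_angle: float
) -> tuple[list[TiltPairRecord], GroundTruth]:
    """Dataset from a conformationally flexible particle (see ``simulate``)."""
    return simulate(config, domain_split_angle=domain_split_angle)
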