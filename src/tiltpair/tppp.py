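"""Tilt-pair parameter plot (TPPP) construction and clustering statistics.

A TPPP is a polar scatter plot: each particle contributes one point at
(azimuth = direction of tilt, radius = tilt angle, both degrees).  A
validated map/orientation set produces a tight cluster at the goniometer
setting; misassigned orientations scatter across the plot and carry large
out-of-plane errors.

All distances, centers and spreads are computed in the 2-D plot plane
(points embedded as (r cos a, r sin a)) — the plane in which the plot's
circles are actually drawn.  This is a tangent-plane (small-angle)
approximation, adequate for the <= 50 degree plot radii in practical use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tiltcore import TiltResult


@dataclass(frozen=True)
class TPPPoint:
    """One plotted particle; glyph '+' marks flagged (excess out-of-plane
    error) particles, '*' the rest."""

    particle_id: str
    pair_id: str
    azimuth: float
    radius: float
    flagged: bool

    @property
    def glyph(self) -> str:
        return "+" if self.flagged else "*"


@dataclass(frozen=True)
class TPPPSummary:
    """Clustering statistics for one dataset (or one micrograph pair)."""

    n_particles: int
    expected_azimuth: float
    expected_tilt: float
    circle_radius: float
    frac_in_circle: float
    frac_in_plane: float
    mean_angular_error: float
    tilt_angle_sd: float
    cluster_center: tuple[float, float]  # (azimuth, tilt) degrees


def tppp_points(
    results: list[TiltResult], include_flagged: bool = True
) -> list[TPPPoint]:
    """Convert tilt results to plot points, optionally omitting flagged
    particles."""
    if not results:
        raise ValueError("results must be non-empty")
    return [
        TPPPoint(r.particle_id, r.pair_id, r.tilt_azimuth, r.tilt_angle, r.flagged)
        for r in results
        if include_flagged or not r.flagged
    ]


def _embed(points: list[TPPPoint]) -> np.ndarray:
    az = np.radians([p.azimuth for p in points])
    r = np.array([p.radius for p in points])
    return np.column_stack([r * np.cos(az), r * np.sin(az)])


def _embed_center(center: tuple[float, float]) -> np.ndarray:
    az, r = np.radians(center[0]), center[1]
    return np.array([r * np.cos(az), r * np.sin(az)])


def _center_distances(
    points: list[TPPPoint], center: tuple[float, float]
) -> np.ndarray:
    return np.linalg.norm(_embed(points) - _embed_center(center), axis=1)


def cluster_fraction(
    points: list[TPPPoint], center: tuple[float, float], radius: float
) -> float:
    """Fraction of points within *radius* degrees of *center* (azimuth,
    tilt), measured in the plot plane."""
    if not points:
        raise ValueError("points must be non-empty")
    if not radius > 0:
        raise ValueError("radius must be positive")
    return float(np.mean(_center_distances(points, center) <= radius))


def radius_for_fraction(
    points: list[TPPPoint], center: tuple[float, float], target_fraction: float
) -> float:
    """Smallest radius containing at least *target_fraction* of the points
    (an order statistic of the center distances)."""
    if not points:
        raise ValueError("points must be non-empty")
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    d = np.sort(_center_distances(points, center))
    k = int(np.ceil(target_fraction * len(d)))
    return float(d[max(k - 1, 0)])


def in_plane_fraction(results: list[TiltResult], max_error: float) -> float:
    """Fraction of particles whose recovered tilt axis lies within
    *max_error* degrees of the specimen plane."""
    if not results:
        raise ValueError("results must be non-empty")
    if not max_error > 0:
        raise ValueError("max_error must be positive")
    errs = np.array([r.out_of_plane_error for r in results])
    return float(np.mean(errs <= max_error))


def cluster_center_and_spread(
    points: list[TPPPoint],
) -> tuple[tuple[float, float], float, float]:
    """Cluster center and spread in the plot plane.

    Returns ``((azimuth, tilt), mean_angular_error, tilt_angle_sd)`` where
    the center is the arithmetic mean of the embedded points mapped back to
    polar form, mean_angular_error is the mean distance to that center, and
    tilt_angle_sd is the sample SD of the radius coordinate.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    xy = _embed(points)
    cx, cy = xy.mean(axis=0)
    tilt = float(np.hypot(cx, cy))
    azimuth = float(np.degrees(np.arctan2(cy, cx)) % 360.0)
    mean_err = float(np.mean(np.linalg.norm(xy - [cx, cy], axis=1)))
    tilt_sd = float(np.std([p.radius for p in points], ddof=1))
    return (azimuth, tilt), mean_err, tilt_sd


def summarize(
    results: list[TiltResult],
    expected_tilt: float,
    expected_azimuth: float,
    circle_radius: float | None = None,
    target_fraction: float = 0.5,
    include_flagged: bool = True,
) -> TPPPSummary:
    """Dataset-level clustering summary.

    If *circle_radius* is given it is honored; otherwise the radius is
    chosen so that ``target_fraction`` (default one half, the 40-60% design
    band) of the particles fall inside the circle centered at the expected
    goniometer setting.  The in-plane fraction uses the same angular
    tolerance as the circle, mirroring the convention of tilt-pair
    statistics tables.
    """
    points = tppp_points(results, include_flagged=include_flagged)
    if not points:
        raise ValueError("no points retained")
    center = (expected_azimuth, expected_tilt)
    if circle_radius is None:
        circle_radius = radius_for_fraction(points, center, target_fraction)
        if circle_radius <= 0.0:
            circle_radius = 1e-6  # all points exactly at center
    retained_ids = {(p.particle_id, p.pair_id) for p in points}
    retained_results = [
        r for r in results if (r.particle_id, r.pair_id) in retained_ids
    ]
    # center and spread are derived from the clustered points: a lone
    # surviving misassignment 100+ degrees out would otherwise dominate
    # the mean error and SD
    dist = _center_distances(points, center)
    clustered = [p for p, d in zip(points, dist) if d <= circle_radius]
    basis = clustered if len(clustered) >= 2 else points
    (c_az, c_tilt), mean_err, tilt_sd = (
        cluster_center_and_spread(basis)
        if len(basis) >= 2
        else ((basis[0].azimuth, basis[0].radius), 0.0, 0.0)
    )
    return TPPPSummary(
        n_particles=len(points),
        expected_azimuth=float(expected_azimuth),
        expected_tilt=float(expected_tilt),
        circle_radius=float(circle_radius),
        frac_in_circle=cluster_fraction(points, center, circle_radius),
        frac_in_plane=in_plane_fraction(retained_results, circle_radius),
        mean_angular_error=mean_err,
        tilt_angle_sd=tilt_sd,
        cluster_center=(c_az, c_tilt),
    )


def summarize_by_pair(
    results: list[TiltResult],
    expected_tilt: float,
    expected_azimuth: float,
    circle_radius: float | None = None,
    target_fraction: float = 0.5,
    include_flagged: bool = True,
) -> dict[str, TPPPSummary]:
    """Per-micrograph-pair summaries (resolves per-pair cluster shifts from
    beam-induced specimen motion)."""
    pairs: dict[str, list[TiltResult]] = {}
    for r in results:
        pairs.setdefault(r.pair_id, []).append(r)
    return {
        pid: summarize(
            rs,
            expected_tilt,
            expected_azimuth,
            circle_radius=circle_radius,
            target_fraction=target_fraction,
            include_flagged=include_flagged,
        )
        for pid, rs in pairs.items()
    }
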