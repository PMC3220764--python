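"""Readers/writers for orientation tables, tilt results and TPPP rendering.

Two input dialects are supported:

* ``table`` — a delimited text table with a header row.  Required columns
  (case-insensitive): ``particle_id`` (or ``particle``), ``phi``,
  ``theta``, ``psi``; optional: ``pair_id`` (or ``film``), ``candidate``,
  ``residual``, ``defocus``, ``magnification``.
* ``par`` — FREALIGN-style fixed-column files: whitespace-separated numeric
  rows, comment lines beginning with ``C`` skipped, fields selected by
  0-based column index via ``column_map`` (default: particle number in
  column 0, then psi, theta, phi in columns 1-3, film in column 7 when
  present).

Angles are degrees everywhere at the I/O boundary.  phi/psi are normalized
to [0, 360); theta must already lie in [0, 180] — anything else is treated
as a sign the file uses a foreign convention and is rejected rather than
silently folded.  A per-dialect convention switch (matrix transpose and/or
in-plane angle sign flip) maps foreign ZYZ variants onto the internal
convention; the shipped presets ``generic-zyz`` and ``frealign`` are both
the identity, since the internal convention is chosen to match projection
matching.
"""

from __future__ import annotations

import io as _io
import logging
import warnings
from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd

from .rotations import EulerTriplet, euler_to_matrix, matrix_to_euler
from .tiltcore import TiltPairRecord, TiltResult
from .tppp import TPPPoint, TPPPSummary

logger = logging.getLogger("tiltpair")

#: default FREALIGN-style .par column layout (0-based indices)
PAR_COLUMNS = {"particle": 0, "psi": 1, "theta": 2, "phi": 3, "film": 7}

_TABLE_ALIASES = {
    "particle_id": ("particle_id", "particle", "id"),
    "pair_id": ("pair_id", "film", "micrograph", "pair"),
    "phi": ("phi",),
    "theta": ("theta",),
    "psi": ("psi",),
    "candidate": ("candidate", "run"),
    "residual": ("residual", "presa", "phase_residual"),
    "defocus": ("defocus", "df1"),
    "magnification": ("magnification", "mag", "relative_magnification"),
}


@dataclass(frozen=True)
class ConventionSpec:
    """Maps a foreign ZYZ dialect onto the internal convention.

    ``invert`` replaces each orientation matrix by its transpose (inverse);
    ``flip_in_plane`` negates phi and psi (in-plane angle sign flip).
    """

    invert: bool = False
    flip_in_plane: bool = False

    def apply(self, e: EulerTriplet) -> EulerTriplet:
        if self.flip_in_plane:
            e = EulerTriplet(-e.phi, e.theta, -e.psi)
        if self.invert:
            e = matrix_to_euler(euler_to_matrix(e).T)
        return e


CONVENTIONS: dict[str, ConventionSpec] = {
    "generic-zyz": ConventionSpec(),
    "frealign": ConventionSpec(),
}


class ParseError(ValueError):
    """A descriptive orientation-table parse failure (includes line numbers)."""


def _normalize_angles(df: pd.DataFrame, source: str) -> pd.DataFrame:
    for col in ("phi", "theta", "psi"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()].tolist()
        if bad:
            lines = ", ".join(str(df.loc[i, "_line"]) for i in bad[:5])
            raise ParseError(
                f"{source}: non-numeric {col} value(s) at line(s) {lines}"
            )
        df[col] = vals.astype(float)
    out_of_range = df.index[(df["theta"] < 0.0) | (df["theta"] > 180.0)].tolist()
    if out_of_range:
        lines = ", ".join(str(df.loc[i, "_line"]) for i in out_of_range[:5])
        raise ParseError(
            f"{source}: theta outside [0, 180] at line(s) {lines}; "
            "convert the file's Euler convention first"
        )
    df["phi"] = df["phi"] % 360.0
    df["psi"] = df["psi"] % 360.0
    return df


def _finalize(df: pd.DataFrame, source: str, convention: str) -> pd.DataFrame:
    df = _normalize_angles(df, source)
    spec = CONVENTIONS.get(convention)
    if spec is None:
        raise ValueError(f"unknown convention preset: {convention!r}")
    if spec.invert or spec.flip_in_plane:
        triplets = [
            spec.apply(EulerTriplet(p, t, s)).as_tuple()
            for p, t, s in zip(df["phi"], df["theta"], df["psi"])
        ]
        df[["phi", "theta", "psi"]] = np.array(triplets)
    if "candidate" not in df.columns:
        df["candidate"] = df.groupby("particle_id").cumcount()
    dup = df.duplicated(subset=["particle_id", "candidate"])
    if dup.any():
        lines = ", ".join(str(v) for v in df.loc[dup, "_line"].head(5))
        raise ParseError(
            f"{source}: duplicate (particle, candidate) key(s) at line(s) {lines}"
        )
    if "pair_id" not in df.columns:
        df["pair_id"] = "pair"
    df["particle_id"] = df["particle_id"].astype(str)
    df["pair_id"] = df["pair_id"].astype(str)
    cols = ["particle_id", "pair_id", "candidate", "phi", "theta", "psi"]
    for opt in ("residual", "defocus", "magnification"):
        if opt in df.columns:
            cols.append(opt)
    return df[cols].reset_index(drop=True)


def _read_table(path, convention: str) -> pd.DataFrame:
    raw = pd.read_csv(path, sep=None, engine="python", comment="#")
    rename = {}
    lower = {c.lower().strip(): c for c in raw.columns}
    for canonical, aliases in _TABLE_ALIASES.items():
        for a in aliases:
            if a in lower:
                rename[lower[a]] = canonical
                break
    raw = raw.rename(columns=rename)
    missing = [c for c in ("particle_id", "phi", "theta", "psi") if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    raw["_line"] = raw.index + 2  # header is line 1
    return _finalize(raw, str(path), convention)


def _read_par(path, column_map: dict | None, convention: str) -> pd.DataFrame:
    cmap = dict(PAR_COLUMNS)
    if column_map:
        cmap.update(column_map)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped[0].upper() == "C":
                continue
            fields = stripped.split()
            row = {"_line": lineno}
            for name, idx in cmap.items():
                if idx >= len(fields):
                    if name in ("particle", "phi", "theta", "psi"):
                        raise ParseError(
                            f"{path}: line {lineno}: missing column {idx} ({name})"
                        )
                    continue
                row[name] = fields[idx]
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no data rows found")
    df = pd.DataFrame(rows).rename(columns={"particle": "particle_id", "film": "pair_id"})
    return _finalize(df, str(path), convention)


def read_orientations(
    path,
    dialect: str = "table",
    column_map: dict | None = None,
    convention: str = "generic-zyz",
) -> pd.DataFrame:
    """Read an orientation table into a canonical DataFrame.

    Returns columns particle_id, pair_id, candidate, phi, theta, psi plus
    any optional metadata present.  Raises ParseError with line numbers on
    malformed input.
    """
    if dialect == "table":
        return _read_table(path, convention)
    if dialect == "par":
        return _read_par(path, column_map, convention)
    raise ValueError(f"unknown dialect: {dialect!r} (expected 'table' or 'par')")


def merge_runs(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate orientation tables from independent search runs,
    renumbering candidates so each run appends to the per-particle list."""
    if not tables:
        raise ValueError("no tables to merge")
    out = []
    offset: dict[str, int] = {}
    for df in tables:
        df = df.copy()
        shift = df["particle_id"].map(lambda p: offset.get(p, 0))
        df["candidate"] = df["candidate"] + shift
        for pid, grp in df.groupby("particle_id"):
            offset[pid] = offset.get(pid, 0) + len(grp)
        out.append(df)
    return pd.concat(out, ignore_index=True)


def pair_views(
    untilted: pd.DataFrame,
    tilted: pd.DataFrame,
    matching: str = "particle_id",
) -> list[TiltPairRecord]:
    """Join untilted and tilted orientation tables into tilt-pair records.

    ``matching='particle_id'`` performs an inner join on particle id (the
    pair id is taken from the untilted table); orphan ids on either side
    are reported as a warning.  ``matching='order'`` pairs the i-th
    particle of each table regardless of id.
    """

    def _group(df: pd.DataFrame) -> dict[str, pd.DataFrame]:
        return {
            pid: grp.sort_values("candidate")
            for pid, grp in df.groupby("particle_id", sort=False)
        }

    gu, gt = _group(untilted), _group(tilted)
    if matching == "order":
        keys = list(zip(gu.keys(), gt.keys()))
    elif matching == "particle_id":
        common = [k for k in gu if k in gt]
        orphans = [k for k in gu if k not in gt] + [k for k in gt if k not in gu]
        if orphans:
            msg = f"{len(orphans)} unmatched particle id(s): {sorted(orphans)[:10]}"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        keys = [(k, k) for k in common]
    else:
        raise ValueError("matching must be 'particle_id' or 'order'")
    if not keys:
        raise ValueError("no matching particles between the two views")

    records = []
    for ku, kt in keys:
        du, dt = gu[ku], gt[kt]
        records.append(
            TiltPairRecord(
                particle_id=str(ku),
                pair_id=str(du["pair_id"].iloc[0]),
                untilted_candidates=tuple(
                    EulerTriplet(r.phi, r.theta, r.psi) for r in du.itertuples()
                ),
                tilted_candidates=tuple(
                    EulerTriplet(r.phi, r.theta, r.psi) for r in dt.itertuples()
                ),
                residual=float(du["residual"].iloc[0]) if "residual" in du else None,
                defocus=float(du["defocus"].iloc[0]) if "defocus" in du else None,
            )
        )
    return records


def records_to_frames(
    records: list[TiltPairRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten records back into (untilted, tilted) orientation tables."""
    rows_u, rows_t = [], []
    for rec in records:
        for rows, cands in (
            (rows_u, rec.untilted_candidates),
            (rows_t, rec.tilted_candidates),
        ):
            for k, e in enumerate(cands):
                rows.append(
                    {
                        "particle_id": rec.particle_id,
                        "pair_id": rec.pair_id,
                        "candidate": k,
                        "phi": e.phi,
                        "theta": e.theta,
                        "psi": e.psi,
                    }
                )
    return pd.DataFrame(rows_u), pd.DataFrame(rows_t)


def write_orientations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def results_to_frame(results: list[TiltResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "particle_id": [r.particle_id for r in results],
            "pair_id": [r.pair_id for r in results],
            "tilt_azimuth": [r.tilt_azimuth for r in results],
            "tilt_angle": [r.tilt_angle for r in results],
            "out_of_plane_error": [r.out_of_plane_error for r in results],
            "in_plane_misfit": [r.in_plane_misfit for r in results],
            "sym_operator": [r.sym_operator_index for r in results],
            "untilted_choice": [r.untilted_choice for r in results],
            "tilted_choice": [r.tilted_choice for r in results],
            "flagged": [int(r.flagged) for r in results],
        }
    )


def frame_to_results(df: pd.DataFrame) -> list[TiltResult]:
    return [
        TiltResult(
            particle_id=str(r.particle_id),
            pair_id=str(r.pair_id),
            tilt_azimuth=float(r.tilt_azimuth),
            tilt_angle=float(r.tilt_angle),
            out_of_plane_error=float(r.out_of_plane_error),
            in_plane_misfit=float(getattr(r, "in_plane_misfit", 0.0)),
            sym_operator_index=int(r.sym_operator),
            untilted_choice=int(r.untilted_choice),
            tilted_choice=int(r.tilted_choice),
            flagged=bool(r.flagged),
        )
        for r in df.itertuples()
    ]


def _summary_lines(summary: TPPPSummary) -> list[str]:
    return [
        f"# n_particles\t{summary.n_particles}",
        f"# expected_azimuth\t{summary.expected_azimuth:.3f}",
        f"# expected_tilt\t{summary.expected_tilt:.3f}",
        f"# circle_radius\t{summary.circle_radius:.3f}",
        f"# frac_in_circle\t{summary.frac_in_circle:.4f}",
        f"# frac_in_plane\t{summary.frac_in_plane:.4f}",
        f"# mean_angular_error\t{summary.mean_angular_error:.4f}",
        f"# tilt_angle_sd\t{summary.tilt_angle_sd:.4f}",
        f"# cluster_center\t{summary.cluster_center[0]:.3f}\t"
        f"{summary.cluster_center[1]:.3f}",
    ]


def write_tppp(
    results: list[TiltResult], summary: TPPPSummary | None, path
) -> None:
    """Write a tilt-result table, with the summary as a '#'-prefixed header
    block, to *path* (or any file-like object)."""
    if not results:
        raise ValueError("results must be non-empty")
    buf = _io.StringIO()
    if summary is not None:
        buf.write("\n".join(_summary_lines(summary)) + "\n")
    results_to_frame(results).to_csv(buf, sep="\t", index=False)
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_tppp(path) -> list[TiltResult]:
    """Read back a tilt-result table written by ``write_tppp``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return frame_to_results(df)


def render_plot(
    points: list[TPPPoint],
    expected: tuple[float, float] | None = None,
    circle_radius: float | None = None,
    path=None,
    outer_radius: float = 30.0,
    per_pair_colors: bool = True,
):
    """Render a TPPP: polar scatter with '*'/'+' glyphs, optional red
    expected-tilt circle and red tilt-direction line.

    *path* may be a single filename or a list (e.g. SVG and PNG); format
    follows the extension.  Returns the matplotlib figure.
    """
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if not points:
        raise ValueError("points must be non-empty")
    fig = plt.figure(figsize=(6, 6))
    ax = fig.add_subplot(111, projection="polar")
    ax.set_rmax(outer_radius)
    pair_ids = sorted({p.pair_id for p in points})
    cmap = plt.get_cmap("tab10")
    colors = {pid: cmap(i % 10) for i, pid in enumerate(pair_ids)}
    for flagged, marker in ((False, "*"), (True, "+")):
        sel = [p for p in points if p.flagged == flagged]
        if not sel:
            continue
        ax.scatter(
            [np.radians(p.azimuth) for p in sel],
            [p.radius for p in sel],
            c=[colors[p.pair_id] if per_pair_colors else "black" for p in sel],
            marker=marker,
            s=60,
            linewidths=1.2,
        )
    if expected is not None:
        az_e, r_e = np.radians(expected[0]), expected[1]
        ax.plot([az_e, az_e], [0, outer_radius], color="red", lw=1.0)
        if circle_radius is not None:
            u = np.linspace(0, 2 * np.pi, 256)
            cx = r_e * np.cos(az_e) + circle_radius * np.cos(u)
            cy = r_e * np.sin(az_e) + circle_radius * np.sin(u)
            ax.plot(np.arctan2(cy, cx), np.hypot(cx, cy), color="red", lw=1.2)
    ax.set_rlabel_position(0)
    if path is not None:
        for p in [path] if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__") else list(path):
            fig.savefig(p, bbox_inches="tight")
    return fig
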