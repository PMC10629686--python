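"""CSV readers and writers for tracking-software exports.

Three plain-text dialects are supported, modelled on the exports of
marker-based X-ray motion-analysis software:

* **3D points**: header ``<name>_X,<name>_Y,<name>_Z`` per point, one row per
  frame, blank (or NaN-token) cells meaning the point was untracked in that
  frame.
* **Rigid-body transforms**: 16 columns per body named ``<body>_00`` ..
  ``<body>_15``, the row-major flattening of a 4x4 homogeneous transform,
  one row per frame.
* **Marker map** sidecar: ``marker_id,series,series_rank`` assigning each
  intramuscular marker to a longitudinal series.

All positions are converted to centimetres on read via ``units_scale``
(e.g. 0.1 for data exported in millimetres).
"""

from __future__ import annotations

import re
import tomllib
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (AnalysisConfig, CenterlinePositions,
                        MarkerTrajectorySet, RigidBodyPoseSeries,
                        ValidationError)


class FormatError(ValueError):
    """The file's structure does not match the expected dialect."""


@dataclass(frozen=True)
class PointsDialect:
    """Tolerated variations of the 3D-points CSV export."""

    suffixes: tuple[str, str, str] = ("_X", "_Y", "_Z")
    na_tokens: tuple[str, ...] = ("", "NaN", "nan", "NA")


DEFAULT_DIALECT = PointsDialect()


def _read_numeric_csv(path, na_tokens) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=list(na_tokens), keep_default_na=True)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            raise FormatError(
                f"{path}: non-numeric cell(s) in column '{col}': "
                f"{bad.head(3).tolist()}")
    return df


def _point_names(columns, dialect: PointsDialect) -> list[str]:
    sx, sy, sz = dialect.suffixes
    names = [c[: -len(sx)] for c in columns if c.endswith(sx)]
    for name in names:
        for suf in dialect.suffixes:
            if name + suf not in columns:
                raise FormatError(
                    f"point '{name}' is missing coordinate column "
                    f"'{name + suf}'")
    if not names:
        raise FormatError(
            f"no point columns found (expected suffixes {dialect.suffixes})")
    return names


def read_marker_map(path) -> pd.DataFrame:
    """Read the sidecar table assigning markers to series and ranks."""
    df = pd.read_csv(path, dtype={"marker_id": str, "series": str})
    required = {"marker_id", "series", "series_rank"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"marker map {path} must have columns {sorted(required)}")
    df["series_rank"] = df["series_rank"].astype(int)
    return df


def read_points_csv(path, units_scale: float = 1.0, *,
                    marker_map=None, frame_rate: float = 500.0,
                    dialect: PointsDialect = DEFAULT_DIALECT):
    """Read a 3D-points CSV.

    With ``marker_map`` (path or DataFrame) the points are intramuscular
    markers and a :class:`MarkerTrajectorySet` is returned; without it the
    point names are treated as vertebral centra (any digits in the name give
    the vertebra index) and a :class:`CenterlinePositions` is returned.
    Untracked cells become NaN positions with ``valid`` False.
    """
    df = _read_numeric_csv(path, dialect.na_tokens)
    names = _point_names(df.columns, dialect)
    pos = np.stack(
        [df[[n + s for s in dialect.suffixes]].to_numpy(float) for n in names]
    ) * units_scale  # (n_points, n_frames, 3)
    valid = np.isfinite(pos).all(axis=2)

    if marker_map is None:
        idx = []
        for i, n in enumerate(names):
            m = re.search(r"(\d+)", n)
            idx.append(int(m.group(1)) if m else i + 1)
        order = np.argsort(idx)
        return CenterlinePositions(
            vertebra_index=np.asarray(idx)[order], positions=pos[order])

    mapping = (marker_map if isinstance(marker_map, pd.DataFrame)
               else read_marker_map(marker_map))
    mapped = set(mapping["marker_id"])
    missing = mapped - set(names)
    if missing:
        raise FormatError(f"marker map names absent from CSV: {sorted(missing)}")
    keep = [n for n in names if n in mapped]
    sel = [names.index(n) for n in keep]
    series = dict(zip(mapping["marker_id"], mapping["series"]))
    rank = dict(zip(mapping["marker_id"], mapping["series_rank"]))
    return MarkerTrajectorySet(
        marker_ids=keep, series=series, series_rank=rank,
        positions=pos[sel], valid=valid[sel], frame_rate=frame_rate)


def write_points_csv(obj, path, units_scale: float = 1.0,
                     dialect: PointsDialect = DEFAULT_DIALECT) -> None:
    """Write a MarkerTrajectorySet or CenterlinePositions as a points CSV.

    ``units_scale`` is the factor the *reader* will apply; positions are
    divided by it so that write -> read round-trips.
    """
    if isinstance(obj, MarkerTrajectorySet):
        names, pos = obj.marker_ids, np.array(obj.positions)
        pos[~obj.valid] = np.nan
    elif isinstance(obj, CenterlinePositions):
        names = [f"v{int(i):02d}" for i in obj.vertebra_index]
        pos = np.asarray(obj.positions)
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as points CSV")
    cols = {}
    for i, n in enumerate(names):
        for j, suf in enumerate(dialect.suffixes):
            cols[n + suf] = pos[i, :, j] / units_scale
    pd.DataFrame(cols).to_csv(path, index=False, na_rep="NaN")


def read_pose_csv(path, units_scale: float = 1.0, *,
                  body: str | None = None, det_tol: float = 1e-3):
    """Read rigid-body transforms (16 row-major columns per body).

    Returns a dict ``body -> RigidBodyPoseSeries``, or a single series when
    ``body`` is given or the file holds exactly one body.  Rotation blocks
    are validated (|det - 1| <= ``det_tol``); translations are scaled to cm.
    """
    df = _read_numeric_csv(path, ("", "NaN", "nan"))
    prefixes: dict[str, list[str]] = {}
    for c in df.columns:
        m = re.fullmatch(r"(.+)_(\d{2})", c)
        if m:
            prefixes.setdefault(m.group(1), []).append(c)
    out = {}
    for name, cols in prefixes.items():
        if len(cols) != 16:
            raise FormatError(
                f"body '{name}' has {len(cols)} transform columns, expected 16")
        cols = sorted(cols, key=lambda c: int(c[-2:]))
        T = df[cols].to_numpy(float).reshape(-1, 4, 4)
        T[:, :3, 3] *= units_scale
        dets = np.linalg.det(T[:, :3, :3])
        bad = np.nonzero(np.abs(dets - 1.0) > det_tol)[0]
        if bad.size:
            raise ValidationError(
                f"body '{name}': rotation determinant {dets[bad[0]]:.6f} at "
                f"frame {bad[0]} (|det-1| > {det_tol})")
        out[name] = RigidBodyPoseSeries(body=name, transforms=T)
    if body is not None:
        return out[body]
    if len(out) == 1:
        return next(iter(out.values()))
    return out


def write_pose_csv(poses, path, units_scale: float = 1.0) -> None:
    """Write one or more pose series as 16 row-major columns per body."""
    if isinstance(poses, RigidBodyPoseSeries):
        poses = {poses.body: poses}
    cols = {}
    for name, series in poses.items():
        T = np.array(series.transforms)
        T[:, :3, 3] /= units_scale
        flat = T.reshape(len(T), 16)
        for k in range(16):
            cols[f"{name}_{k:02d}"] = flat[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_marker_map(markers: MarkerTrajectorySet, path) -> None:
    pd.DataFrame({
        "marker_id": markers.marker_ids,
        "series": [markers.series[m] for m in markers.marker_ids],
        "series_rank": [markers.series_rank[m] for m in markers.marker_ids],
    }).to_csv(path, index=False)


_CONFIG_FIELDS = {f.name for f in fields(AnalysisConfig)}


def read_config(path) -> AnalysisConfig:
    """Read a flat key=value (TOML) config file into an AnalysisConfig."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    unknown = set(data) - _CONFIG_FIELDS
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)


def write_config(config: AnalysisConfig, path) -> None:
    lines = []
    for f in fields(AnalysisConfig):
        v = getattr(config, f.name)
        lines.append(f'{f.name} = "{v}"' if isinstance(v, str)
                     else f"{f.name} = {str(v).lower()}" if isinstance(v, bool)
                     else f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")
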