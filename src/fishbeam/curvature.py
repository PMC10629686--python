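"""Vertebral curvature from per-frame splines of centrum positions.

For every frame, transverse centrum position (dorsoventral y, mediolateral z)
is fitted against longitudinal position x with a penalized cubic smoothing
spline, and curvature is the second derivative of that spline evaluated on a
dense grid and at the muscle-subregion positions.  The convention follows the
projected-plane definition used throughout: kappa = d2(transverse)/dx2 in
cm^-1, positive dorsoventral curvature meaning concave-dorsal (dorsiflexion)
and positive mediolateral curvature meaning concave-left.  The
differential-geometric curvature y''/(1+y'^2)^(3/2) is available as an
off-by-default option; at the slopes seen in these data the two differ by
less than a few percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .datatypes import AnalysisConfig, CenterlinePositions, ValidationError

PLANES = ("dv", "ml")  # sagittal (dorsoventral), frontal (mediolateral)


@dataclass
class CurvatureField:
    """Curvature per frame at a set of longitudinal query positions.

    ``kappa_dv`` and ``kappa_ml`` have shape (n_frames, n_query), in cm^-1.
    ``baseline_corrected`` records, per plane, whether the resting curvature
    has been subtracted.
    """

    query_x: np.ndarray
    kappa_dv: np.ndarray
    kappa_ml: np.ndarray
    baseline_corrected: dict = field(
        default_factory=lambda: {"dv": False, "ml": False})
    reference_frame: int | None = None

    def __post_init__(self):
        for name in ("kappa_dv", "kappa_ml"):
            k = getattr(self, name)
            if k.shape != (k.shape[0], len(self.query_x)):
                raise ValidationError(f"{name} shape {k.shape} inconsistent "
                                      f"with {len(self.query_x)} query positions")
            if not np.isfinite(k).all():
                raise ValidationError(f"non-finite values in {name}")

    @property
    def n_frames(self) -> int:
        return self.kappa_dv.shape[0]

    def at(self, x: float) -> tuple[np.ndarray, np.ndarray]:
        """Curvature time series at longitudinal position ``x`` (linear
        interpolation between query columns)."""
        q = self.query_x
        if not (q.min() - 1e-9 <= x <= q.max() + 1e-9):
            raise ValidationError(
                f"x={x:.3f} cm outside evaluated span [{q.min():.3f}, "
                f"{q.max():.3f}]")
        if len(q) == 1:
            return self.kappa_dv[:, 0], self.kappa_ml[:, 0]
        j = int(np.clip(np.searchsorted(q, x), 1, len(q) - 1))
        w = (x - q[j - 1]) / (q[j] - q[j - 1])
        return ((1 - w) * self.kappa_dv[:, j - 1] + w * self.kappa_dv[:, j],
                (1 - w) * self.kappa_ml[:, j - 1] + w * self.kappa_ml[:, j])


def fit_plane_spline(x: np.ndarray, y: np.ndarray, smoothing):
    """Fit one frame's transverse-vs-longitudinal profile.

    ``smoothing``: 0 gives the exact cubic interpolant (not-a-knot, which
    reproduces polynomials up to cubic exactly); a positive float is the
    roughness penalty of a smoothing spline; ``"gcv"`` chooses the penalty by
    generalized cross-validation.  Knots sit at the centrum positions; the
    dense evaluation grid is independent of the knots.
    """
    if len(x) < 6:
        raise ValidationError(f"need >= 6 centra to fit curvature, got {len(x)}")
    if smoothing == "gcv":
        return make_smoothing_spline(x, y, lam=None)
    lam = float(smoothing)
    if lam < 0:
        raise ValidationError("spline smoothing penalty must be >= 0")
    if lam == 0.0:
        return CubicSpline(x, y)
    return make_smoothing_spline(x, y, lam=lam)


def _second_derivative(spl, xq, exact: bool) -> np.ndarray:
    d2 = spl.derivative(2)(xq) if hasattr(spl, "derivative") else spl(xq, 2)
    if not exact:
        return d2
    d1 = spl.derivative(1)(xq) if hasattr(spl, "derivative") else spl(xq, 1)
    return d2 / (1.0 + d1 ** 2) ** 1.5


def _frame_profile(centerline: CenterlinePositions, frame: int):
    """Sorted (x, y, z) centrum profile for one frame."""
    p = centerline.positions[:, frame, :]
    order = np.argsort(p[:, 0])
    return p[order, 0], p[order, 1], p[order, 2]


def fit_centerline_splines(centerline: CenterlinePositions, frame: int,
                           smoothing=0.0):
    """Positional splines y(x) and z(x) of the column at one frame.

    Used for the resting neutral axis when measuring subregion offsets.
    """
    x, y, z = _frame_profile(centerline, frame)
    return fit_plane_spline(x, y, smoothing), fit_plane_spline(x, z, smoothing)


def fit_and_evaluate_curvature(centerline: CenterlinePositions,
                               config: AnalysisConfig,
                               query_x: np.ndarray | None = None,
                               ) -> CurvatureField:
    """Fit per-frame splines in both planes and evaluate curvature.

    Curvature is evaluated at ``query_x`` (default: a ``spline_segments``-
    segment uniform grid over the longitudinal span common to all frames).
    Queries outside a frame's fitted span raise: curvature is only defined on
    the fitted column, never extrapolated.
    """
    n_frames = centerline.n_frames
    x0 = max(centerline.positions[:, f, 0].min() for f in range(n_frames))
    x1 = min(centerline.positions[:, f, 0].max() for f in range(n_frames))
    if query_x is None:
        query_x = np.linspace(x0, x1, config.spline_segments + 1)
    else:
        query_x = np.asarray(query_x, dtype=float)
        if query_x.min() < x0 - 1e-9 or query_x.max() > x1 + 1e-9:
            raise ValidationError(
                f"query positions [{query_x.min():.3f}, {query_x.max():.3f}] "
                f"extend beyond the fitted span [{x0:.3f}, {x1:.3f}] cm")

    kdv = np.empty((n_frames, len(query_x)))
    kml = np.empty_like(kdv)
    for f in range(n_frames):
        x, y, z = _frame_profile(centerline, f)
        kdv[f] = _second_derivative(
            fit_plane_spline(x, y, config.spline_smoothing), query_x,
            config.exact_curvature)
        kml[f] = _second_derivative(
            fit_plane_spline(x, z, config.spline_smoothing), query_x,
            config.exact_curvature)
    return CurvatureField(query_x=query_x, kappa_dv=kdv, kappa_ml=kml)


def baseline_correct_sagittal(field_: CurvatureField, reference_frame: int,
                              mode: str = "reference",
                              correct_frontal: bool = False) -> CurvatureField:
    """Remove the resting sagittal curvature of the vertebral column.

    The column is slightly curved dorsoventrally at rest; without correction
    this resting curvature would read as permanent muscle strain.  In
    ``"reference"`` mode (default) the curvature profile at the resting-
    length reference frame is subtracted from every frame, making predicted
    strain commensurate with strain referenced to the resting length.  The
    ``"first_difference"`` mode differences consecutive frames instead
    (yielding strain increments, not strain — kept for comparison only).
    The frontal plane is left uncorrected by default since the column is
    relatively straight in that plane.
    """
    if field_.baseline_corrected["dv"]:
        raise ValidationError("sagittal plane already baseline-corrected")
    if not 0 <= reference_frame < field_.n_frames:
        raise ValidationError(f"reference frame {reference_frame} outside field")

    def _correct(k):
        if mode == "reference":
            return k - k[reference_frame]
        if mode == "first_difference":
            return np.diff(k, axis=0, prepend=k[:1])
        raise ValidationError(f"unknown baseline mode '{mode}'")

    corrected = dict(field_.baseline_corrected, dv=True)
    kml = field_.kappa_ml
    if correct_frontal:
        kml = _correct(kml)
        corrected["ml"] = True
    return replace(field_, kappa_dv=_correct(field_.kappa_dv), kappa_ml=kml,
                   baseline_corrected=corrected,
                   reference_frame=reference_frame)


def combined_max_curvature(field_: CurvatureField, x_bar: float,
                           frames: slice | np.ndarray | None = None) -> float:
    """Sum of the maximum absolute curvatures in the two planes at ``x_bar``.

    This is the per-strike, per-subregion magnitude used to exclude
    low-curvature records (threshold 0.05 cm^-1 by default).
    """
    kdv, kml = field_.at(x_bar)
    if frames is not None:
        kdv, kml = kdv[frames], kml[frames]
    return float(np.abs(kml).max() + np.abs(kdv).max())


def segment_summary(field_: CurvatureField, n_segments: int = 7):
    """Peak absolute curvature in equidistant longitudinal segments.

    Mirrors the common summary layout of curvature along the column: one row
    per (segment, plane) with the segment's central x and the maximum
    absolute curvature across frames and positions within the segment.
    """
    import pandas as pd
    q = field_.query_x
    edges = np.linspace(q.min(), q.max(), n_segments + 1)
    rows = []
    for i in range(n_segments):
        sel = (q >= edges[i] - 1e-12) & (q <= edges[i + 1] + 1e-12)
        for plane, k in (("dv", field_.kappa_dv), ("ml", field_.kappa_ml)):
            rows.append({
                "segment": i + 1,
                "x_center_cm": 0.5 * (edges[i] + edges[i + 1]),
                "plane": plane,
                "max_abs_kappa_cm1": float(np.abs(k[:, sel]).max()),
            })
    return pd.DataFrame(rows)
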