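"""Muscle subregions, resting geometry, and fluoromicrometry strain.

A *subregion* is an adjacent pair of markers within one longitudinal marker
series; its strain is the fractional change of the 3D inter-marker distance
relative to the resting length L_i taken at the least-curved pre-strike
reference frame.  Its position for beam-theory prediction is the mean of the
two resting marker positions: x_bar longitudinally, and signed transverse
offsets gamma_dv (+ dorsal) and gamma_ml (+ left) measured from the fitted
resting centerline, which is taken as the neutral axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import MarkerTrajectorySet, StrikeRecording, ValidationError


@dataclass(frozen=True)
class SubregionPair:
    """An adjacent marker pair within one series."""

    series: str
    rank: int          # rank of the cranial marker; pair is (rank, rank+1)
    marker_a: str
    marker_b: str

    @property
    def label(self) -> str:
        return f"{self.series}_{self.rank}"


@dataclass
class SubregionGeometry:
    """Resting-frame geometry of a subregion (all in cm)."""

    pair: SubregionPair
    x_bar: float       # mean longitudinal position
    gamma_dv: float    # dorsoventral offset from the neutral axis, + dorsal
    gamma_ml: float    # mediolateral offset, + left
    L_i: float         # resting 3D inter-marker length

    def __post_init__(self):
        if self.L_i <= 0:
            raise ValidationError(
                f"subregion {self.pair.label}: resting length must be "
                f"positive, got {self.L_i}")


@dataclass
class StrainSeries:
    """Longitudinal strain over one strike; negative = shortening."""

    epsilon: np.ndarray
    kind: str  # measured | predicted_dv | predicted_ml | predicted_total
    pair: SubregionPair | None = None

    def __post_init__(self):
        kinds = ("measured", "predicted_dv", "predicted_ml", "predicted_total")
        if self.kind not in kinds:
            raise ValidationError(f"unknown strain kind '{self.kind}'")


def define_subregions(markers: MarkerTrajectorySet) -> list[SubregionPair]:
    """Enumerate subregions as adjacent in-series marker pairs.

    With ``n`` markers spread over ``k`` series the count is ``n - k``:
    e.g. 18 markers in four series give 14 subregions.
    """
    by_series: dict[str, list[tuple[int, str]]] = {}
    for m in markers.marker_ids:
        by_series.setdefault(markers.series[m], []).append(
            (markers.series_rank[m], m))
    pairs = []
    for series, members in by_series.items():
        ranks = [r for r, _ in members]
        if len(ranks) != len(set(ranks)):
            raise ValidationError(f"duplicate series_rank in series '{series}'")
        members.sort()
        for (r0, m0), (r1, m1) in zip(members, members[1:]):
            if r1 != r0 + 1:
                warnings.warn(
                    f"series '{series}': ranks {r0} and {r1} are not "
                    f"consecutive; pairing them as adjacent")
            pairs.append(SubregionPair(series=series, rank=r0,
                                       marker_a=m0, marker_b=m1))
    pairs.sort(key=lambda p: (p.series, p.rank))
    return pairs


def resting_geometry(pair: SubregionPair, rec: StrikeRecording,
                     centerline_splines) -> SubregionGeometry:
    """Measure a subregion's resting position, offsets and length.

    ``centerline_splines`` is the (y(x), z(x)) pair fitted to the centerline
    at the reference frame (see
    :func:`fishbeam.curvature.fit_centerline_splines`); the offsets are taken
    from this fitted neutral axis, not from the straight ACS x-axis, because
    the column itself is slightly curved at rest.
    """
    f = rec.reference_frame
    ia, ib = rec.markers.index_of(pair.marker_a), rec.markers.index_of(pair.marker_b)
    if not (rec.markers.valid[ia, f] and rec.markers.valid[ib, f]):
        raise ValidationError(
            f"subregion {pair.label}: marker untracked at reference frame {f}")
    a, b = rec.markers.positions[ia, f], rec.markers.positions[ib, f]
    mean = 0.5 * (a + b)
    spl_y, spl_z = centerline_splines
    xs = spl_y.t[3:-3] if hasattr(spl_y, "t") else spl_y.x
    if not (xs.min() - 1e-9 <= mean[0] <= xs.max() + 1e-9):
        raise ValidationError(
            f"subregion {pair.label}: x_bar {mean[0]:.3f} cm outside the "
            f"centerline span [{xs.min():.3f}, {xs.max():.3f}] — refusing to "
            f"extrapolate the neutral axis")
    return SubregionGeometry(
        pair=pair,
        x_bar=float(mean[0]),
        gamma_dv=float(mean[1] - spl_y(mean[0])),
        gamma_ml=float(mean[2] - spl_z(mean[0])),
        L_i=float(np.linalg.norm(a - b)),
    )


def _max_gap_run(valid: np.ndarray) -> int:
    """Length of the longest run of invalid frames."""
    if valid.all():
        return 0
    runs, run = [], 0
    for v in valid:
        run = 0 if v else run + 1
        runs.append(run)
    return max(runs)


def measured_strain(pair: SubregionPair, rec: StrikeRecording,
                    L_i: float, max_gap_frames: int = 3,
                    ) -> StrainSeries | None:
    """Fluoromicrometry strain: epsilon(t) = (d(t) - L_i) / L_i.

    ``d(t)`` is the 3D inter-marker distance.  Dropout gaps up to
    ``max_gap_frames`` are assumed to have been interpolated upstream; a
    longer gap excludes the subregion for this strike (returns None with a
    warning), since interpolating long gaps would fabricate strain.
    """
    if L_i <= 0:
        raise ValidationError(f"L_i must be positive, got {L_i}")
    ia, ib = rec.markers.index_of(pair.marker_a), rec.markers.index_of(pair.marker_b)
    both_valid = rec.markers.valid[ia] & rec.markers.valid[ib]
    gap = _max_gap_run(both_valid)
    if gap > max_gap_frames:
        warnings.warn(
            f"strike {rec.strike_id}, subregion {pair.label}: dropout gap of "
            f"{gap} frames exceeds {max_gap_frames}; subregion excluded")
        return None
    d = np.linalg.norm(rec.markers.positions[ia] - rec.markers.positions[ib],
                       axis=1)
    return StrainSeries(epsilon=(d - L_i) / L_i, kind="measured", pair=pair)
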