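"""Core domain types for the axial-bending analysis pipeline.

All lengths are stored in centimetres and curvatures in cm^-1.  The working
frame is the anatomical coordinate system (ACS) of the caudal-most animated
vertebra: +x craniocaudal (toward the head), +y dorsal, +z left, right-handed.
Strain is dimensionless with negative values meaning shortening.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Longitudinal marker series implanted in the epaxial musculature.
SERIES_NAMES = ("dorsal", "deep", "left_lateral", "right_lateral")

#: Rigid bodies tracked alongside the muscle markers.
BODY_NAMES = ("neurocranium", "body_plane", "caudal_vertebra_acs")

_ROT_TOL = 1e-6


class ValidationError(ValueError):
    """An input violated a structural invariant of a domain type."""


@dataclass
class MarkerTrajectorySet:
    """3D trajectories of intramuscular markers.

    Parameters
    ----------
    marker_ids : list of str
        One label per marker.
    series : dict
        marker_id -> series name (one of :data:`SERIES_NAMES`).
    series_rank : dict
        marker_id -> integer order within its series (1 = cranial-most).
    positions : ndarray, shape (n_markers, n_frames, 3)
        Marker positions in cm, in the caudal-vertebra ACS.
    valid : ndarray of bool, shape (n_markers, n_frames)
        False where the marker was untracked.
    frame_rate : float
        Sampling rate in Hz.
    """

    marker_ids: list[str]
    series: dict[str, str]
    series_rank: dict[str, int]
    positions: np.ndarray
    valid: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[0]

    def index_of(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)

    def trajectory(self, marker_id: str) -> np.ndarray:
        """Return the (n_frames, 3) trajectory of one marker."""
        return self.positions[self.index_of(marker_id)]

    def violations(self) -> list[str]:
        out = []
        if self.positions.shape[0] != len(self.marker_ids):
            out.append("positions first axis does not match marker count")
        if self.valid.shape != self.positions.shape[:2]:
            out.append("valid mask shape does not match positions")
        for name in SERIES_NAMES:
            ranks = [r for m, r in self.series_rank.items()
                     if self.series.get(m) == name]
            if len(ranks) != len(set(ranks)):
                out.append(f"duplicate series_rank in series '{name}'")
        for m in self.marker_ids:
            if m not in self.series:
                out.append(f"marker '{m}' missing series assignment")
        i = np.arange(self.n_markers)[:, None]
        bad = ~np.isfinite(self.positions).all(axis=2) & self.valid
        if bad.any():
            out.append("non-finite position at frames flagged valid")
        del i
        return out


@dataclass
class RigidBodyPoseSeries:
    """Per-frame 4x4 homogeneous transforms of one rigid body.

    Rotation blocks must be proper rotations (orthonormal, det +1);
    translations are in cm.
    """

    body: str
    transforms: np.ndarray  # (n_frames, 4, 4)

    def __post_init__(self) -> None:
        self.transforms = np.asarray(self.transforms, dtype=float)
        if self.transforms.ndim != 3 or self.transforms.shape[1:] != (4, 4):
            raise ValidationError(
                f"pose series '{self.body}': expected (n, 4, 4) transforms, "
                f"got {self.transforms.shape}")

    @property
    def n_frames(self) -> int:
        return self.transforms.shape[0]

    @property
    def rotations(self) -> np.ndarray:
        return self.transforms[:, :3, :3]

    @property
    def translations(self) -> np.ndarray:
        return self.transforms[:, :3, 3]

    def violations(self, tol: float = 1e-3) -> list[str]:
        out = []
        R = self.rotations
        dets = np.linalg.det(R)
        bad_det = np.nonzero(np.abs(dets - 1.0) > tol)[0]
        if bad_det.size:
            out.append(
                f"body '{self.body}': rotation determinant off unity at "
                f"frame(s) {bad_det[:5].tolist()}")
        rtr = np.einsum("nij,nik->njk", R, R)
        err = np.abs(rtr - np.eye(3)).max(axis=(1, 2))
        bad_orth = np.nonzero(err > tol)[0]
        if bad_orth.size:
            out.append(
                f"body '{self.body}': rotation not orthonormal at frame(s) "
                f"{bad_orth[:5].tolist()}")
        return out


@dataclass
class CenterlinePositions:
    """Vertebral centrum centres along the column, per frame.

    positions[i, t] is centrum ``vertebra_index[i]`` at frame ``t`` in the
    caudal-vertebra ACS (cm).  x must increase strictly with vertebra index
    at every frame (the column is traversed caudal -> cranial in +x).
    """

    vertebra_index: np.ndarray  # (n_vert,) int, cranial -> caudal order
    positions: np.ndarray       # (n_vert, n_frames, 3)

    def __post_init__(self) -> None:
        self.vertebra_index = np.asarray(self.vertebra_index, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)

    @property
    def n_vertebrae(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def x_span(self, frame: int) -> tuple[float, float]:
        x = self.positions[:, frame, 0]
        return float(x.min()), float(x.max())

    def violations(self) -> list[str]:
        out = []
        if self.n_vertebrae < 10:
            out.append(f"only {self.n_vertebrae} centra; need >= 10")
        x = self.positions[:, :, 0]
        dx = np.diff(x, axis=0)
        if not ((dx > 0).all() or (dx < 0).all()):
            frames = np.nonzero(~((dx > 0).all(axis=0) | (dx < 0).all(axis=0)))[0]
            out.append(
                "centerline x not strictly monotone along vertebra_index at "
                f"frame(s) {frames[:5].tolist()}")
        if not np.isfinite(self.positions).all():
            out.append("non-finite centerline positions")
        return out


@dataclass
class StrikeRecording:
    """Everything recorded for one feeding strike."""

    strike_id: str
    individual_id: str
    markers: MarkerTrajectorySet
    centerline: CenterlinePositions
    poses: dict[str, RigidBodyPoseSeries]
    frame_rate: float
    reference_frame: int  # least-curved pre-strike frame; L_i is taken here

    @property
    def n_frames(self) -> int:
        return self.markers.n_frames


@dataclass
class AnalysisConfig:
    """Thresholds and tunables for every pipeline stage.

    Defaults reproduce the study conditions: 5 deg minimum cranial elevation
    for strike inclusion, zero-phase 60 Hz Butterworth smoothing, penalized
    cubic splines evaluated on a 1000-segment grid, a 0.05 cm^-1 combined
    curvature exclusion threshold, and equivalence margins of +/-0.2 on the
    regression slope and +/-0.05 on the intercept.
    """

    elevation_min: float = 5.0          # deg
    butter_cutoff: float = 60.0         # Hz
    butter_order: int = 2               # applied forward-backward
    spline_segments: int = 1000         # evaluation grid, not knot count
    spline_smoothing: float | str = "gcv"   # penalty, 0 = interpolate
    curvature_exclusion: float = 0.05   # cm^-1
    equivalence_slope_margin: float = 0.2
    equivalence_intercept_margin: float = 0.05
    units_scale: float = 1.0            # input units -> cm
    baseline_fraction: float = 0.1      # leading fraction used as elevation baseline
    max_gap_frames: int = 3             # linear interpolation limit for dropouts
    sagittal_baseline_mode: str = "reference"  # or "first_difference"
    correct_frontal_baseline: bool = False
    exact_curvature: bool = False       # full differential-geometric kappa
    rng_seed: int = 0

    def violations(self) -> list[str]:
        out = []
        for name in ("elevation_min", "butter_cutoff", "curvature_exclusion",
                     "equivalence_slope_margin", "equivalence_intercept_margin",
                     "units_scale"):
            if getattr(self, name) <= 0:
                out.append(f"config field '{name}' must be > 0")
        if self.spline_smoothing != "gcv" and float(self.spline_smoothing) < 0:
            out.append("spline_smoothing must be >= 0 or 'gcv'")
        return out

    def replace(self, **kw) -> "AnalysisConfig":
        return dataclasses.replace(self, **kw)


def validate_recording(rec: StrikeRecording,
                       peak_frame: int | None = None) -> list[str]:
    """Structural validation of a strike recording.

    Returns a list of human-readable violations; an empty list means the
    recording is runnable.  If ``peak_frame`` is given, also checks that the
    resting-length reference frame precedes peak cranial elevation.
    """
    out: list[str] = []
    out += rec.markers.violations()
    out += rec.centerline.violations()
    for pose in rec.poses.values():
        out += pose.violations()

    counts = {"markers": rec.markers.n_frames,
              "centerline": rec.centerline.n_frames}
    counts.update({f"pose:{k}": v.n_frames for k, v in rec.poses.items()})
    if len(set(counts.values())) > 1:
        out.append(f"frame-count mismatch across components: {counts}")
    if not (0 <= rec.reference_frame < rec.markers.n_frames):
        out.append(f"reference_frame {rec.reference_frame} outside recording")
    if peak_frame is not None and rec.reference_frame >= peak_frame:
        out.append(
            f"reference_frame {rec.reference_frame} does not precede peak "
            f"elevation frame {peak_frame}")
    if rec.frame_rate <= 0:
        out.append("frame_rate must be positive")
    return out
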