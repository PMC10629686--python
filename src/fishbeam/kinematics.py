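"""Time-series filtering and joint-coordinate-system cranial elevation.

Cranial elevation is the dorsal rotation of the neurocranium relative to the
body plane, measured as the z rotation of a joint coordinate system (JCS)
decomposed in zyx order with the right-hand rule, and re-zeroed to its
pre-strike baseline.  The frame of peak elevation defines "time zero" for
aligning strikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation

from .datatypes import RigidBodyPoseSeries, StrikeRecording


class ParameterError(ValueError):
    pass


@dataclass
class ElevationSeries:
    """Cranial elevation over one strike, re-zeroed to the baseline window."""

    angle: np.ndarray      # deg per frame
    peak: float            # deg
    peak_frame: int        # "time zero"
    gimbal_frames: np.ndarray  # frames with |y rotation| within 1 deg of +/-90


def lowpass_filter(series: np.ndarray, cutoff: float, rate: float,
                   order: int = 2) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter along the first axis.

    The filter is applied forward and backward (``filtfilt``), doubling the
    effective order and cancelling phase delay so that peak timings are
    preserved.  Works on scalar series or (n_frames, ...) vector series.
    """
    series = np.asarray(series, dtype=float)
    nyquist = rate / 2.0
    if cutoff >= nyquist:
        raise ParameterError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {nyquist} Hz")
    if series.shape[0] <= 3 * order:
        raise ParameterError(
            f"series length {series.shape[0]} too short for order {order}")
    b, a = butter(order, cutoff / nyquist)
    return filtfilt(b, a, series, axis=0)


def filter_recording(rec: StrikeRecording, cutoff: float,
                     order: int = 2) -> StrikeRecording:
    """Low-pass filter marker and centerline trajectories of a recording.

    Invalid marker frames are linearly interpolated before filtering and
    remain flagged invalid afterwards.  Pose series are left untouched
    (rotations do not filter component-wise; elevation is filtered as an
    angle series instead).
    """
    markers = rec.markers
    pos = np.array(markers.positions)
    for i in range(pos.shape[0]):
        v = markers.valid[i]
        if not v.all() and v.sum() >= 2:
            t = np.arange(pos.shape[1])
            for j in range(3):
                pos[i, :, j] = np.interp(t, t[v], pos[i, v, j])
    pos = np.moveaxis(
        lowpass_filter(np.moveaxis(pos, 1, 0), cutoff, rec.frame_rate, order),
        0, 1)
    cl = np.moveaxis(
        lowpass_filter(np.moveaxis(rec.centerline.positions, 1, 0),
                       cutoff, rec.frame_rate, order), 0, 1)
    from dataclasses import replace
    return replace(
        rec,
        markers=replace(markers, positions=pos),
        centerline=replace(rec.centerline, positions=cl))


def _zyx_angles(R: np.ndarray) -> np.ndarray:
    """Decompose rotation matrices as R = Rz(a) @ Ry(b) @ Rx(c), degrees."""
    return Rotation.from_matrix(R).as_euler("ZYX", degrees=True)


def compose_zyx(z: float, y: float, x: float) -> np.ndarray:
    """Compose a rotation matrix from zyx Euler angles in degrees."""
    return Rotation.from_euler("ZYX", [z, y, x], degrees=True).as_matrix()


def cranial_elevation(neuro: RigidBodyPoseSeries,
                      body_plane: RigidBodyPoseSeries,
                      baseline_window: tuple[int, int] | None = None,
                      ) -> ElevationSeries:
    """Measure cranial elevation from neurocranium and body-plane poses.

    The relative transform body_plane^-1 o neurocranium is decomposed in zyx
    order; the z rotation, minus its mean over ``baseline_window`` (default:
    the first 10% of frames), is the elevation.
    """
    if neuro.n_frames != body_plane.n_frames:
        raise ParameterError("pose series lengths differ")
    n = neuro.n_frames
    if baseline_window is None:
        baseline_window = (0, max(1, n // 10))
    rel = np.linalg.solve(body_plane.transforms, neuro.transforms)
    angles = _zyx_angles(rel[:, :3, :3])
    z, y = angles[:, 0], angles[:, 1]
    gimbal = np.nonzero(np.abs(np.abs(y) - 90.0) < 1.0)[0]
    b0, b1 = baseline_window
    angle = z - z[b0:b1].mean()
    peak_frame = int(np.argmax(angle))
    return ElevationSeries(angle=angle, peak=float(angle[peak_frame]),
                           peak_frame=peak_frame, gimbal_frames=gimbal)


def include_and_align(elev: ElevationSeries, rec: StrikeRecording,
                      min_deg: float = 5.0) -> tuple[bool, np.ndarray]:
    """Apply the minimum-elevation inclusion rule and build the time axis.

    Returns ``(included, t)`` where ``included`` is True iff peak elevation
    reaches ``min_deg`` and ``t`` is time in seconds relative to peak
    elevation (t = 0 at the peak frame).
    """
    t = (np.arange(rec.n_frames) - elev.peak_frame) / rec.frame_rate
    return bool(elev.peak >= min_deg), t
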