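"""Subregion definition, resting geometry, and fluoromicrometry strain."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fishbeam.curvature import fit_centerline_splines
from fishbeam.datatypes import (CenterlinePositions, MarkerTrajectorySet,
                                StrikeRecording, ValidationError)
from fishbeam.phantom import BeamPhantomSpec, generate_strike
from fishbeam.strain import (define_subregions, measured_strain,
                             resting_geometry)


def _markers_from_sizes(sizes):
    names, series, rank = [], {}, {}
    series_names = ["dorsal", "deep", "left_lateral", "right_lateral"]
    for sname, n in zip(series_names, sizes):
        for k in range(1, n + 1):
            m = f"{sname}{k}"
            names.append(m)
            series[m] = sname
            rank[m] = k
    n_total = len(names)
    return MarkerTrajectorySet(
        marker_ids=names, series=series, series_rank=rank,
        positions=np.zeros((n_total, 2, 3)),
        valid=np.ones((n_total, 2), bool), frame_rate=500.0)


@pytest.mark.parametrize("sizes, expected", [
    ((5, 5, 4, 4), 14),   # the study's 18 markers in four series
    ((6, 4, 4, 4), 14),   # different split, same total
    ((2,), 1),
])
def test_subregion_count_is_markers_minus_series(sizes, expected):
    markers = _markers_from_sizes(sizes)
    pairs = define_subregions(markers)
    assert len(pairs) == expected
    # brute-force oracle: adjacent pairs within each series
    assert len(pairs) == sum(n - 1 for n in sizes)


def test_duplicate_rank_rejected():
    markers = _markers_from_sizes((3, 2, 2, 2))
    markers.series_rank["dorsal2"] = 1
    with pytest.raises(ValidationError, match="duplicate"):
        define_subregions(markers)


def _toy_recording(marker_pos):
    """Two markers on a straight centerline along y = z = 0."""
    n_frames = marker_pos.shape[1]
    markers = MarkerTrajectorySet(
        marker_ids=["dorsal1", "dorsal2"],
        series={"dorsal1": "dorsal", "dorsal2": "dorsal"},
        series_rank={"dorsal1": 1, "dorsal2": 2},
        positions=marker_pos,
        valid=np.ones((2, n_frames), bool), frame_rate=500.0)
    x = np.linspace(0, 20, 15)
    cl_pos = np.zeros((15, n_frames, 3))
    cl_pos[:, :, 0] = x[:, None]
    centerline = CenterlinePositions(np.arange(1, 16), cl_pos)
    return StrikeRecording("toy", "toy", markers, centerline, {},
                           500.0, reference_frame=0)


def test_resting_geometry_arithmetic():
    pos = np.zeros((2, 2, 3))
    pos[0, :, :] = [12.0, 1.0, 0.0]   # cranial marker (rank 1, larger x)
    pos[1, :, :] = [10.0, 1.0, 0.0]
    rec = _toy_recording(pos)
    pair = define_subregions(rec.markers)[0]
    splines = fit_centerline_splines(rec.centerline, 0)
    geo = resting_geometry(pair, rec, splines)
    assert geo.x_bar == pytest.approx(11.0)
    assert geo.gamma_dv == pytest.approx(1.0)
    assert geo.gamma_ml == pytest.approx(0.0, abs=1e-12)
    assert geo.L_i == pytest.approx(2.0)


def test_x_bar_outside_centerline_span_rejected():
    pos = np.zeros((2, 2, 3))
    pos[0, :, :] = [25.0, 1.0, 0.0]
    pos[1, :, :] = [23.0, 1.0, 0.0]
    rec = _toy_recording(pos)
    pair = define_subregions(rec.markers)[0]
    splines = fit_centerline_splines(rec.centerline, 0)
    with pytest.raises(ValidationError, match="span"):
        resting_geometry(pair, rec, splines)


def test_phantom_geometry_recovered_exactly_when_straight_at_rest():
    # no resting curvature, no noise: offsets and positions are exact
    spec = BeamPhantomSpec(noise_sd=0.0, resting_curvature=0.0, seed=3)
    rec, gt = generate_strike(spec)
    splines = fit_centerline_splines(rec.centerline, rec.reference_frame)
    for pair in define_subregions(rec.markers):
        geo = resting_geometry(pair, rec, splines)
        truth = gt.geometry[pair.label]
        assert geo.x_bar == pytest.approx(truth["s_bar"], abs=1e-6)
        assert geo.gamma_dv == pytest.approx(truth["gamma_dv"], abs=1e-6)
        assert geo.gamma_ml == pytest.approx(truth["gamma_ml"], abs=1e-6)


def test_mirrored_lateral_offsets(noiseless_strike):
    _, rec, _ = noiseless_strike
    splines = fit_centerline_splines(rec.centerline, rec.reference_frame)
    geos = {p.label: resting_geometry(p, rec, splines)
            for p in define_subregions(rec.markers)}
    for rank in (1, 2, 3):
        left = geos[f"left_lateral_{rank}"]
        right = geos[f"right_lateral_{rank}"]
        assert left.gamma_ml == pytest.approx(-right.gamma_ml, abs=1e-9)
        assert left.gamma_ml > 0


def test_measured_strain_values_and_reference_zero():
    pos = np.zeros((2, 3, 3))
    pos[0, :, 0] = [11.0, 11.0, 10.9]   # d: 1.0, 1.0, 0.9
    pos[1, :, 0] = 10.0
    rec = _toy_recording(pos)
    pair = define_subregions(rec.markers)[0]
    s = measured_strain(pair, rec, L_i=1.0)
    np.testing.assert_allclose(s.epsilon, [0.0, 0.0, -0.10], atol=1e-12)
    assert s.epsilon[rec.reference_frame] == 0.0
    assert (s.epsilon >= -1.0).all()


def test_measured_strain_invariant_under_rigid_motion(noiseless_strike):
    _, rec, _ = noiseless_strike
    pair = define_subregions(rec.markers)[0]
    base = measured_strain(pair, rec, L_i=1.5)
    R = Rotation.random(rng=np.random.default_rng(13)).as_matrix()
    t = np.array([3.0, -2.0, 7.0])
    moved = dataclasses.replace(
        rec, markers=dataclasses.replace(
            rec.markers, positions=rec.markers.positions @ R.T + t))
    out = measured_strain(pair, moved, L_i=1.5)
    np.testing.assert_allclose(out.epsilon, base.epsilon, atol=1e-9)


def test_long_dropout_gap_excludes_subregion(noiseless_strike):
    _, rec, _ = noiseless_strike
    pair = define_subregions(rec.markers)[0]
    valid = rec.markers.valid.copy()
    i = rec.markers.index_of(pair.marker_a)
    valid[i, 100:110] = False
    gappy = dataclasses.replace(
        rec, markers=dataclasses.replace(rec.markers, valid=valid))
    with pytest.warns(UserWarning, match="excluded"):
        assert measured_strain(pair, gappy, 1.5, max_gap_frames=3) is None
    # short gaps are tolerated
    valid2 = rec.markers.valid.copy()
    valid2[i, 100:102] = False
    ok = dataclasses.replace(
        rec, markers=dataclasses.replace(rec.markers, valid=valid2))
    assert measured_strain(pair, ok, 1.5, max_gap_frames=3) is not None


def test_measured_strain_tracks_fiber_oracle(noiseless_strike):
    """Chord-based marker distance tracks the fibre arc-length truth to
    within the chord-versus-arc error, well below strain magnitudes."""
    from fishbeam.phantom import strain_oracles
    _, rec, gt = noiseless_strike
    splines = fit_centerline_splines(rec.centerline, rec.reference_frame)
    for pair in define_subregions(rec.markers):
        geo = resting_geometry(pair, rec, splines)
        meas = measured_strain(pair, rec, geo.L_i)
        _, fib = strain_oracles(gt, pair.label)
        # chord-vs-arc bound: (kappa * L)^2 / 24 on ~2 cm subregions at
        # combined curvature up to ~0.17 cm^-1
        assert np.abs(meas.epsilon - fib).max() < 5e-3


def test_dorsal_shortens_and_laterals_anticorrelate():
    # pure dorsiflexion: every dorsal-series subregion shortens at peak
    spec = BeamPhantomSpec(noise_sd=0.0, ml_amplitude=0.0,
                           resting_curvature=0.0, seed=4)
    rec, gt = generate_strike(spec)
    peak = spec.peak_frame
    for label, eps in gt.epsilon_true.items():
        if label.startswith("dorsal"):
            assert eps[peak] < 0
    # pure lateral bending: mirrored subregions strain in opposite directions
    spec = BeamPhantomSpec(noise_sd=0.0, dv_amplitude=0.0,
                           resting_curvature=0.0, elevation_peak=6.0, seed=5)
    rec, gt = generate_strike(spec)
    for rank in (1, 2, 3):
        left = gt.epsilon_true[f"left_lateral_{rank}"]
        right = gt.epsilon_true[f"right_lateral_{rank}"]
        assert np.corrcoef(left, right)[0, 1] < -0.99
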