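"""End-to-end orchestration: strike analysis, study pooling, manifests.

Stage order follows the measurement chain: low-pass filtering ->
cranial elevation and strike inclusion -> per-frame curvature splines ->
sagittal baseline correction -> subregion geometry and measured strain ->
beam-theory prediction -> regression, exclusion and equivalence.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .beam import predicted_strain
from .curvature import (baseline_correct_sagittal, combined_max_curvature,
                        fit_and_evaluate_curvature, fit_centerline_splines,
                        CurvatureField)
from .datatypes import AnalysisConfig, StrikeRecording, validate_recording
from .kinematics import (cranial_elevation, filter_recording,
                         include_and_align, lowpass_filter, ElevationSeries)
from .stats import (apply_curvature_exclusion, fit_strain_regression,
                    regression_diagnostics, tost_equivalence,
                    EquivalenceResult, RegressionResult)
from .strain import define_subregions, measured_strain, resting_geometry


@dataclass
class StrikeResult:
    """All per-strike outputs in tidy form."""

    strike_id: str
    individual_id: str
    included: bool
    elevation: ElevationSeries
    time_s: np.ndarray
    field: CurvatureField
    geometry: pd.DataFrame     # one row per subregion
    strain: pd.DataFrame       # long format, one row per subregion-frame

    def elevation_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "strike_id": self.strike_id,
            "frame": np.arange(len(self.elevation.angle)),
            "t_s": self.time_s,
            "elevation_deg": self.elevation.angle,
        })

    def curvature_table(self) -> pd.DataFrame:
        rows = []
        for j, x in enumerate(self.field.query_x):
            rows.append(pd.DataFrame({
                "strike_id": self.strike_id,
                "frame": np.arange(self.field.n_frames),
                "x_cm": x,
                "kappa_dv_cm1": self.field.kappa_dv[:, j],
                "kappa_ml_cm1": self.field.kappa_ml[:, j],
            }))
        return pd.concat(rows, ignore_index=True)


def analyze_strike(rec: StrikeRecording,
                   config: AnalysisConfig | None = None) -> StrikeResult:
    """Run the full measurement chain on one strike recording."""
    config = config or AnalysisConfig()
    problems = validate_recording(rec)
    if problems:
        raise ValueError(
            f"strike {rec.strike_id}: invalid recording: {problems}")

    # elevation from raw poses, then zero-phase filtered as an angle series
    elev = cranial_elevation(
        rec.poses["neurocranium"], rec.poses["body_plane"],
        baseline_window=(0, max(1, int(config.baseline_fraction
                                       * rec.n_frames))))
    angle = lowpass_filter(elev.angle, config.butter_cutoff, rec.frame_rate,
                           config.butter_order)
    peak_frame = int(np.argmax(angle))
    elev = ElevationSeries(angle=angle, peak=float(angle[peak_frame]),
                           peak_frame=peak_frame,
                           gimbal_frames=elev.gimbal_frames)
    included, t_s = include_and_align(elev, rec, config.elevation_min)

    filtered = filter_recording(rec, config.butter_cutoff, config.butter_order)

    splines = fit_centerline_splines(filtered.centerline, rec.reference_frame,
                                     config.spline_smoothing)
    pairs = define_subregions(filtered.markers)
    geoms = []
    for p in pairs:
        try:
            geoms.append(resting_geometry(p, filtered, splines))
        except ValueError as exc:
            warnings.warn(f"strike {rec.strike_id}: skipping {p.label}: {exc}")
    if not geoms:
        raise ValueError(f"strike {rec.strike_id}: no usable subregions")

    query_x = np.unique([g.x_bar for g in geoms])
    field = fit_and_evaluate_curvature(filtered.centerline, config, query_x)
    field = baseline_correct_sagittal(
        field, rec.reference_frame, mode=config.sagittal_baseline_mode,
        correct_frontal=config.correct_frontal_baseline)

    geo_rows, strain_rows = [], []
    frames = np.arange(rec.n_frames)
    for g in geoms:
        meas = measured_strain(g.pair, filtered, g.L_i, config.max_gap_frames)
        if meas is None:
            continue
        pred = predicted_strain(field, g)
        combined = combined_max_curvature(field, g.x_bar)
        geo_rows.append({
            "strike_id": rec.strike_id, "series": g.pair.series,
            "rank": g.pair.rank, "x_bar": g.x_bar, "gamma_dv": g.gamma_dv,
            "gamma_ml": g.gamma_ml, "L_i": g.L_i,
            "combined_max_curvature": combined})
        strain_rows.append(pd.DataFrame({
            "strike_id": rec.strike_id, "series": g.pair.series,
            "rank": g.pair.rank, "frame": frames, "t_s": t_s,
            "strain_measured": meas.epsilon,
            "strain_pred_dv": pred["predicted_dv"].epsilon,
            "strain_pred_ml": pred["predicted_ml"].epsilon,
            "strain_predicted": pred["predicted_total"].epsilon,
            "combined_max_curvature": combined, "x_bar": g.x_bar}))
    return StrikeResult(
        strike_id=rec.strike_id, individual_id=rec.individual_id,
        included=included, elevation=elev, time_s=t_s, field=field,
        geometry=pd.DataFrame(geo_rows),
        strain=pd.concat(strain_rows, ignore_index=True))


@dataclass
class StudyResult:
    """Pooled and per-subregion validation of beam theory on many strikes."""

    strikes: list[StrikeResult]
    table: pd.DataFrame                 # pooled frames of included strikes
    accuracy: pd.DataFrame              # one row per (strike, subregion)
    pooled: RegressionResult
    pooled_excluded: RegressionResult
    exclusion_report: dict
    equivalence: EquivalenceResult
    diagnostics: dict

    @property
    def n_included(self) -> int:
        return sum(s.included for s in self.strikes)

    def summary(self) -> dict:
        e = self.equivalence
        return {
            "n_strikes": len(self.strikes),
            "n_included": self.n_included,
            "n_records": int(len(self.accuracy)),
            "pooled": {"slope": self.pooled.slope,
                       "intercept": self.pooled.intercept,
                       "r2": self.pooled.r_squared,
                       "p": self.pooled.p_value, "n": self.pooled.n},
            "pooled_after_exclusion": {
                "slope": self.pooled_excluded.slope,
                "intercept": self.pooled_excluded.intercept,
                "r2": self.pooled_excluded.r_squared,
                "n": self.pooled_excluded.n},
            "exclusion": self.exclusion_report,
            "equivalence": {
                "slope_ci90": list(e.slope_ci90),
                "intercept_ci90": list(e.intercept_ci90),
                "slope_margin": e.slope_margin,
                "intercept_margin": e.intercept_margin,
                "slope_pass": e.slope_pass,
                "intercept_pass": e.intercept_pass,
                "overall_pass": e.overall_pass},
        }


def analyze_study(recordings, config: AnalysisConfig | None = None,
                  ) -> StudyResult:
    """Analyze many strikes and pool included ones for validation.

    Only strikes passing the cranial-elevation inclusion rule enter the
    regressions; every strike is still analyzed and reported.
    """
    config = config or AnalysisConfig()
    results = [analyze_strike(rec, config) for rec in recordings]
    included = [r for r in results if r.included]
    if not included:
        raise ValueError("no strikes pass the inclusion threshold")
    table = pd.concat([r.strain for r in included], ignore_index=True)

    pooled = fit_strain_regression(table, "pooled")
    accuracy = fit_strain_regression(table, "per_strike_subregion")
    kept, report = apply_curvature_exclusion(table,
                                             config.curvature_exclusion)
    pooled_excl = fit_strain_regression(kept, "pooled")
    equivalence = tost_equivalence(
        pooled, slope_margin=config.equivalence_slope_margin,
        intercept_margin=config.equivalence_intercept_margin)
    diagnostics = regression_diagnostics(table)
    return StudyResult(strikes=results, table=table, accuracy=accuracy,
                       pooled=pooled, pooled_excluded=pooled_excl,
                       exclusion_report=report, equivalence=equivalence,
                       diagnostics=diagnostics)


@dataclass
class RunManifest:
    """Provenance record: config, seed, inputs and per-stage outputs."""

    config: dict
    seed: int
    version: str = __version__
    stages: list = field(default_factory=list)

    def add_stage(self, name: str, n_rows: int, outputs: dict) -> None:
        self.stages.append({"stage": name, "rows": int(n_rows),
                            "outputs": outputs})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
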