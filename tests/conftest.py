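"""Shared phantom fixtures.

Expensive phantom studies are generated once per session; individual tests
treat them as read-only.
"""

import numpy as np
import pytest

from fishbeam import (AnalysisConfig, BeamPhantomSpec, StudySpec,
                      analyze_strike, analyze_study, generate_strike,
                      generate_study)
from fishbeam.stats import fit_strain_regression


@pytest.fixture(scope="session")
def noiseless_strike():
    """One noiseless phantom strike at the default study conditions
    (A_dv = 0.05, A_ml = 0.125 cm^-1) plus its ground truth."""
    spec = BeamPhantomSpec(noise_sd=0.0, seed=11)
    rec, gt = generate_strike(spec)
    return spec, rec, gt


@pytest.fixture(scope="session")
def noiseless_result(noiseless_strike):
    """Full pipeline output on the noiseless strike (interpolating splines:
    there is no noise to smooth)."""
    _, rec, _ = noiseless_strike
    res = analyze_strike(rec, AnalysisConfig(spline_smoothing=0.0))
    reg = fit_strain_regression(res.strain, "pooled")
    return res, reg


@pytest.fixture(scope="session")
def noisy_strike():
    """One strike with the default 0.01 cm marker noise."""
    spec = BeamPhantomSpec(seed=12)
    rec, gt = generate_strike(spec)
    return spec, rec, gt


@pytest.fixture(scope="session")
def phantom_study():
    """The default three-individual study: 30 strikes, 20 above the 5 deg
    inclusion threshold, shortened to 120 frames per strike."""
    study = StudySpec(seed=7, base=BeamPhantomSpec(n_frames=120))
    return generate_study(study)


@pytest.fixture(scope="session")
def study_result(phantom_study):
    """Study-level analysis with the phantom smoothing calibration."""
    recs = [rec for rec, _ in phantom_study]
    return analyze_study(recs, AnalysisConfig(spline_smoothing=0.2))
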