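"""Shared fixtures: a reference instrument and a study-scale noisy dataset.

The study-scale dataset (three Cerulean/Venus constructs, 26/25/27 cells,
two decades of expression, shot noise) is expensive enough to build once
per session; several validation tests share it.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import quantifret as qf
from quantifret.calibration import corrected_fret_image
from quantifret.pipeline import analyze_study, preprocess_simulated_study

# reproducible property tests: derandomised example generation
settings.register_profile(
    "reproducible", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("reproducible")

# reference instrument constants used as synthetic ground truth
REF_FACTORS = {"alpha_BT": 0.421, "delta_DE": 0.110,
               "gamma_M": 2.10, "beta_X": 1.167}
CONSTRUCT_E = {"C5V": 0.503, "C17V": 0.417, "C32V": 0.351}


@pytest.fixture(scope="session")
def ref_instrument():
    return qf.instrument_from_factors(**REF_FACTORS)


@pytest.fixture(scope="session")
def study_scale():
    """Full synthetic calibration study: (study, prepared, analysis)."""
    study = qf.simulate_calibration_study(rng=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prepared = preprocess_simulated_study(study, rng=1000)
        analysis = analyze_study(prepared, rng=2000)
    return study, prepared, analysis


@pytest.fixture(scope="session")
def construct_pixels(study_scale):
    """Per-construct (I_DD, I_DA_corr, I_AA) pixel arrays of the study."""
    _, prepared, analysis = study_scale
    f = analysis.factors
    pops = {}
    for name, trips in prepared.constructs.items():
        dd, c, aa = [], [], []
        for t in trips:
            corr = corrected_fret_image(t, f.alpha_BT, f.delta_DE)
            sel = t.mask & np.isfinite(corr)
            dd.append(t.I_DD[sel])
            c.append(corr[sel])
            aa.append(t.I_AA[sel])
        pops[name] = tuple(np.concatenate(x) for x in (dd, c, aa))
    return pops


def noise_free_populations(
    instrument, construct_e=CONSTRUCT_E, n_per=400, s=0.5, seed=123,
    span=(2e4, 2e6),
):
    """Exact-intensity pixel populations for equivalence oracles."""
    rng = np.random.default_rng(seed)
    truth = qf.true_correction_factors(instrument)
    pops = {}
    for name, e0 in construct_e.items():
        n_tot = 10 ** rng.uniform(np.log10(span[0]), np.log10(span[1]), n_per)
        e = np.clip(rng.normal(e0, 0.02, n_per), 0, 1)
        exp = qf.expected_intensities(s * n_tot, (1 - s) * n_tot, e,
                                      instrument)
        c = exp.I_DA - truth.alpha_BT * exp.I_DD - truth.delta_DE * exp.I_AA
        pops[name] = (exp.I_DD, c, exp.I_AA)
    return pops
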