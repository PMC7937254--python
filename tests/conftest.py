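import numpy as np
import pytest

from dibh_margin import SimulationSpec, fit_reml, simulate_errors

#: Ground truth at the study's fitted values (mm).
TRUTH = {"mean_m": 0.30, "sigma_pt": 0.82, "sigma_fr": 1.19, "sigma_intra": 1.63}


@pytest.fixture(scope="session")
def study_scale_trace():
    """One seeded draw at the study design: 25 patients x 16 fractions,
    200 frames per fraction (100 per tangential field)."""
    spec = SimulationSpec(n_patients=25, n_fractions=16, n_fields=2,
                          frames_per_field=100, seed=20170101, **TRUTH)
    return simulate_errors(spec)


@pytest.fixture(scope="session")
def study_scale_fit(study_scale_trace):
    return fit_reml(study_scale_trace)


def balanced_trace(n_patients=4, n_fractions=3, frames=5, seed=0, **truth):
    params = dict(TRUTH)
    params.update(truth)
    spec = SimulationSpec(n_patients=n_patients, n_fractions=n_fractions,
                          n_fields=1, frames_per_field=frames, seed=seed, **params)
    return simulate_errors(spec)


def recovery_se_bands(n_patients, n_fractions, frames_per_fraction, truth=TRUTH):
    """3x Monte-Carlo standard errors of the SD estimates at a balanced design.

    Large-sample normal-theory SEs from the mean-square distributions:
    Var(MS) = 2 E[MS]^2 / df at each stratum, delta-method to the SD scale.
    """
    va, vb, ve = (truth["sigma_pt"] ** 2, truth["sigma_fr"] ** 2,
                  truth["sigma_intra"] ** 2)
    p, f, k = n_patients, n_fractions, frames_per_fraction
    ems_a = ve + k * vb + f * k * va
    ems_b = ve + k * vb
    se_va = np.sqrt(2 * ems_a**2 / (p - 1) + 2 * ems_b**2 / (p * (f - 1))) / (f * k)
    se_vb = np.sqrt(2 * ems_b**2 / (p * (f - 1)) + 2 * ve**2 / (p * f * (k - 1))) / k
    se_ve = np.sqrt(2 * ve**2 / (p * f * (k - 1)))
    return {
        "sigma_pt": 3 * se_va / (2 * np.sqrt(va)),
        "sigma_fr": 3 * se_vb / (2 * np.sqrt(vb)),
        "sigma_intra": 3 * se_ve / (2 * np.sqrt(ve)),
    }
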