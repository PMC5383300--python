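import numpy as np
import pytest

import plaquefit as pf

# Lesion-prevalence reference parameter set (solid lines of the prevalence
# study): Nnu0=3, alpha=12, gamma=0.2, nu1=1, nu2=1e-7 per year.
FIG2_RATES = pf.RateSet(nu0N=3.0, alpha=12.0, gamma=0.2, nu1=1.0,
                        nu2=1e-7, t_lag=10.0)

# Best-fit biological parameters of the age-independent cohort analysis:
# Nnu0=4.5, gamma=0.12, nu1=1.3 per year (alpha, nu2, t_lag fixed).
BESTFIT_RATES = pf.RateSet(nu0N=4.5, alpha=12.0, gamma=0.12, nu1=1.3,
                           nu2=1e-7, t_lag=10.0)


@pytest.fixture(scope="session")
def fig2_rates():
    return FIG2_RATES


@pytest.fixture(scope="session")
def bestfit_rates():
    return BESTFIT_RATES


@pytest.fixture(scope="session")
def bestfit_truth():
    return pf.MechanisticTruth(rates=BESTFIT_RATES)


@pytest.fixture(scope="session")
def small_cohort(bestfit_truth):
    """A modest synthetic cohort at the best-fit truth (fast fixture)."""
    design = pf.CohortDesign(n_workers=800, truth=bestfit_truth, seed=5)
    return pf.generate_cohort(design).cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
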