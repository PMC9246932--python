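import warnings

import numpy as np
import pandas as pd
import pytest

from bisensory.cohort import (CohortConfig, SubjectParams,
                              generate_subject_trials, generate_cohort,
                              sample_trial_sequence)
from bisensory.preprocess import clean_rts
from bisensory.cdf import condition_subsets


@pytest.fixture(scope="session")
def base_params():
    """Adult-like LATER channels, no coupling, no sequential effects."""
    return SubjectParams(mu_a=3.2, sigma_a=0.7, mu_v=3.0, sigma_v=0.65,
                        rho=0.0, eta=0.0, switch_cost=0.0, miss_rate=0.0,
                        double_press_rate=0.0)


@pytest.fixture(scope="session")
def subject_trials(base_params):
    """One synthetic subject with sequential switch costs and misses."""
    p = SubjectParams(mu_a=3.2, sigma_a=0.7, mu_v=3.0, sigma_v=0.65,
                      rho=-0.3, eta=0.15, switch_cost=0.3, miss_rate=0.04,
                      double_press_rate=0.01)
    seq = sample_trial_sequence(900, CohortConfig(), seed=101)
    return generate_subject_trials(p, seq, seed=102)


@pytest.fixture(scope="session")
def cleaned_subject(subject_trials):
    cleaned, report = clean_rts(subject_trials)
    return cleaned, report


@pytest.fixture(scope="session")
def subject_cdfset(cleaned_subject):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return condition_subsets(cleaned_subject[0])


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CohortConfig(n_subjects_per_group={"NT": 6, "ASD": 6},
                       trials_per_subject=400, seed=7)
    return generate_cohort(cfg)


def random_cdf_pair(rng, n_q=20):
    """Two random monotone CDF vectors on a shared grid (for invariants)."""
    from bisensory.cdf import QuantileCDF
    t = np.linspace(200.0, 1500.0, n_q)
    out = []
    for _ in range(2):
        p = np.sort(rng.uniform(0, 1, n_q))
        out.append(QuantileCDF(p, t, t[0], t[-1], 100))
    return out
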