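"""Raab race, bounds, benefit/gain AUCs, and violation tests."""

import numpy as np
import pytest

from bisensory.cdf import QuantileCDF, empirical_cdf
from bisensory.race import (benefits, bounds, conditioned_race,
                            multisensory_gain, raab_race, race_outcome,
                            race_violation_test)

from conftest import random_cdf_pair


def cdf_from(probs, t0=200.0, t1=900.0):
    probs = np.asarray(probs, dtype=float)
    t = np.linspace(t0, t1, len(probs))
    return QuantileCDF(probs, t, t0, t1, 100)


class TestRaab:
    def test_symmetric_input(self):
        f = cdf_from(np.linspace(0, 1, 20))
        out = raab_race(f, f)
        np.testing.assert_allclose(out.probs, 2 * f.probs - f.probs ** 2)

    def test_direct_arithmetic(self):
        f_a = cdf_from([0.2, 0.5])
        f_v = cdf_from([0.1, 0.4])
        np.testing.assert_allclose(raab_race(f_a, f_v).probs, [0.28, 0.70])

    def test_mismatched_times_rejected(self):
        f_a = cdf_from(np.linspace(0, 1, 20))
        f_v = cdf_from(np.linspace(0, 1, 20), t0=100.0)
        with pytest.raises(ValueError):
            raab_race(f_a, f_v)

    def test_against_min_latency_simulation_oracle(self):
        """Probability summation on empirical CDFs equals the CDF of the
        min of independently resampled unisensory RT pairs."""
        rng = np.random.default_rng(0)
        rts_a = rng.gamma(5, 60, 800) + 150
        rts_v = rng.gamma(4, 80, 700) + 180
        lims = (150.0, 1000.0)
        f_a, f_v = empirical_cdf(rts_a, lims), empirical_cdf(rts_v, lims)
        race = raab_race(f_a, f_v)
        n = 1_000_000
        mins = np.minimum(rng.choice(rts_a, n), rng.choice(rts_v, n))
        mc = empirical_cdf(mins, lims)
        assert np.abs(race.probs - mc.probs).max() < 0.005


class TestBounds:
    def test_symmetric_and_clipping(self):
        f = cdf_from(np.linspace(0, 1, 20))
        grice, miller = bounds(f, f)
        np.testing.assert_allclose(grice.probs, f.probs)
        np.testing.assert_allclose(miller.probs, np.minimum(2 * f.probs, 1))
        g2, m2 = bounds(cdf_from([0.7]), cdf_from([0.6]))
        assert m2.probs[0] == 1.0

    def test_ordering_grice_raab_miller(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            f_a, f_v = random_cdf_pair(rng)
            grice, miller = bounds(f_a, f_v)
            raab = raab_race(f_a, f_v)
            assert (grice.probs <= raab.probs + 1e-15).all()
            assert (raab.probs <= miller.probs + 1e-15).all()


class TestBenefitsAndGain:
    def test_trivial_identities(self):
        race = cdf_from(np.linspace(0.1, 1, 20))
        grice = cdf_from(np.linspace(0.1, 1, 20) - 0.1)
        b_pred, b_emp = benefits(grice, race, grice)
        assert b_emp == 0.0
        assert b_pred == pytest.approx(0.1)

    def test_gain_decomposition_and_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            f_av, race = random_cdf_pair(rng)
            grice, _ = random_cdf_pair(rng)
            gain, diff, a_pos, a_neg = multisensory_gain(f_av, race)
            assert gain == pytest.approx(a_pos + a_neg, abs=1e-15)
            b_pred, b_emp = benefits(f_av, race, grice)
            assert gain == pytest.approx(b_emp - b_pred, abs=1e-12)

    def test_rectangle_vs_trapezoid_quadrature(self):
        """The rectangle-rule AUC differs from trapezoidal quadrature by at
        most 1/40 of the range on monotone 20-point differences."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = np.sort(rng.uniform(-0.2, 0.4, 20))
            rect = d.mean()
            trap = np.trapezoid(d, dx=1 / 19)
            assert abs(rect - trap) <= (d.max() - d.min()) / 40 + 1e-12

    def test_negative_rate_correlation_boosts_gain(self):
        """Generator with rho = -0.8: the max of anticorrelated channel
        rates is faster than the independent race predicts, so gain is
        positive across subjects."""
        import warnings
        from bisensory.cohort import (CohortConfig, SubjectParams,
                                      generate_subject_trials,
                                      sample_trial_sequence)
        from bisensory.cdf import condition_subsets

        rng = np.random.default_rng(4)
        gains = []
        for i in range(30):
            p = SubjectParams(mu_a=3.2, sigma_a=0.7, mu_v=3.0, sigma_v=0.65,
                              rho=-0.8, eta=0.0, switch_cost=0.0,
                              miss_rate=0.0)
            seq = sample_trial_sequence(900, CohortConfig(),
                                        seed=rng.integers(2 ** 31))
            tr = generate_subject_trials(p, seq, seed=rng.integers(2 ** 31))
            tr = tr[tr.rt_ms.notna()]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gains.append(race_outcome(condition_subsets(tr)).gain)
        assert np.mean(gains) > 0
        assert np.mean(np.asarray(gains) > 0) > 0.8


class TestConditionedRace:
    def test_identical_strata_collapse(self, subject_cdfset):
        """If every preceding-modality stratum equals the unconditioned CDF,
        the conditioned race equals the unconditioned one."""
        import copy
        s = copy.deepcopy(subject_cdfset)
        for c in ("A", "V"):
            for m in ("A", "V", "AV"):
                s.by_prev[(c, m)] = s.full[c]
        cond = conditioned_race(s)
        uncond = raab_race(s.full["A"], s.full["V"])
        np.testing.assert_allclose(cond.probs, uncond.probs, atol=1e-15)

    def test_empty_stratum_fallback_definition(self, subject_cdfset):
        import copy
        s = copy.deepcopy(subject_cdfset)
        for c in ("A", "V"):
            for m in ("A", "V", "AV"):
                s.by_prev[(c, m)] = s.full[c]
        del s.by_prev[("A", "AV")], s.by_prev[("V", "AV")]
        cond = conditioned_race(s)
        uncond = raab_race(s.full["A"], s.full["V"])
        np.testing.assert_allclose(cond.probs, uncond.probs, atol=1e-15)

    def test_all_strata_missing_rejected(self, subject_cdfset):
        import copy
        s = copy.deepcopy(subject_cdfset)
        s.by_prev = {}
        with pytest.raises(ValueError):
            conditioned_race(s)

    def test_switch_cost_makes_conditioned_less_conservative(self):
        """With slowed switch trials, conditioning on the preceding modality
        captures channel dependency. Within each stratum the fast-channel
        and slow-channel CDFs are anticorrelated, so the average of the
        per-stratum races exceeds the race of the pooled CDFs: the
        conditioned model predicts more facilitation (a less conservative
        estimate of statistical facilitation)."""
        import warnings
        from bisensory.cohort import (CohortConfig, SubjectParams,
                                      generate_subject_trials,
                                      sample_trial_sequence)
        from bisensory.cdf import condition_subsets

        rng = np.random.default_rng(5)
        signed = []
        for i in range(20):
            p = SubjectParams(mu_a=3.2, sigma_a=0.7, mu_v=3.0, sigma_v=0.65,
                              rho=0.0, eta=0.0, switch_cost=0.5,
                              miss_rate=0.0)
            seq = sample_trial_sequence(1200, CohortConfig(),
                                        seed=rng.integers(2 ** 31))
            tr = generate_subject_trials(p, seq, seed=rng.integers(2 ** 31))
            tr = tr[tr.rt_ms.notna()]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = condition_subsets(tr)
            diff = conditioned_race(s).probs - raab_race(s.full["A"],
                                                         s.full["V"]).probs
            signed.append(diff.mean())
        assert np.mean(signed) > 0


class TestViolationTest:
    def test_zero_difference_functions_not_significant(self):
        diffs = np.zeros((10, 20))
        res = race_violation_test(diffs, n_perm=200, seed=0)
        assert not res.significant.any()

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            race_violation_test(np.zeros((1, 20)))

    def test_localised_facilitation_detected(self):
        """Facilitation injected at quantiles 1-3 only is flagged exactly
        there at n=50 subjects."""
        rng = np.random.default_rng(6)
        diffs = rng.normal(0, 0.02, (50, 20))
        diffs[:, :3] += 0.05
        res = race_violation_test(diffs, tail="right", n_perm=2000, seed=1)
        assert res.significant[:3].all()
        assert not res.significant[3:].any()
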