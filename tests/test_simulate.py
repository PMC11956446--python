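"""Trial data generation, single-trial runs, operating characteristics."""

import numpy as np
import pytest

from splinetrial import (BetaPrior, DesignConfig, Scenario, SplinePrior,
                         beta_from_summary, default_priors,
                         generate_trial_data, operating_characteristics,
                         run_trial, sample_size_search,
                         uninformative_priors)


def null_scenario(n=100, pi=0.3, pi_disc=0.2, **kw):
    return Scenario(pi_t=pi, pi_c=pi, pi_disc=pi_disc, n_per_arm=n, **kw)


class TestDefaultPriors:
    @pytest.mark.parametrize("family,cls", [("parametric", BetaPrior),
                                            ("semiparametric", SplinePrior)])
    @pytest.mark.parametrize("level", ["informative", "low_informative",
                                       "uninformative"])
    def test_six_prior_scenarios_constructible(self, family, cls, level):
        priors = default_priors(family, level)
        assert set(priors) == {"pi_t", "pi_c", "pi_disc"}
        for p in priors.values():
            assert isinstance(p, cls)
            assert p.informativeness == level

    def test_informative_centres_treatment_above_control(self):
        priors = default_priors("parametric", "informative")
        assert priors["pi_t"].mean > priors["pi_c"].mean

    def test_uninformative_is_flat(self):
        priors = default_priors("semiparametric", "uninformative")
        x = np.linspace(0, 1, 101)
        assert np.allclose(priors["pi_t"].pdf(x), 1.0)


class TestGenerateTrialData:
    def test_zero_rate_yields_zero_events(self):
        sc = Scenario(pi_t=0.0, pi_c=0.5, pi_disc=0.1, n_per_arm=50)
        for seed in range(20):
            data = generate_trial_data(sc, seed)
            assert data.final.events_t == 0

    def test_fixed_seed_reproducible(self):
        sc = null_scenario()
        assert generate_trial_data(sc, 11) == generate_trial_data(sc, 11)

    def test_interim_counts_nested_in_final(self):
        sc = null_scenario()
        for seed in range(30):
            d = generate_trial_data(sc, seed)
            assert d.interim.events_t <= d.final.events_t
            assert d.interim.events_c <= d.final.events_c
            assert d.interim.disc_t <= d.final.disc_t
            assert d.interim.n_t == 50 and d.final.n_t == 100

    def test_event_rate_unbiased(self):
        # binomial moment check across replicates
        sc = Scenario(pi_t=0.3, pi_c=0.3, pi_disc=0.1, n_per_arm=200)
        reps = 2000
        counts = [generate_trial_data(sc, s).final.events_t
                  for s in range(reps)]
        mean_rate = np.mean(counts) / 200
        se = np.sqrt(0.3 * 0.7 / (200 * reps))
        assert abs(mean_rate - 0.3) < 3 * se


class TestRunTrial:
    def test_extreme_separation_stops_for_efficacy_at_interim(self):
        sc = Scenario(pi_t=0.01, pi_c=0.6, pi_disc=0.01, n_per_arm=400)
        cfg = DesignConfig(n_total=400)
        priors = uninformative_priors()
        stops = sum(
            run_trial(sc, cfg, priors, s).interim_decision.action
            == "stop_efficacy" for s in range(200))
        assert stops > 198

    def test_null_scenario_hdi_rules_mostly_no_effect(self):
        sc = null_scenario(rule_family="hdi", pi_disc=0.1)
        cfg = DesignConfig(n_total=100, rule_family="hdi")
        priors = uninformative_priors()
        outcomes = [run_trial(sc, cfg, priors, s) for s in range(200)]
        declared = sum(r.declared_effect for r in outcomes)
        assert declared < 20  # large majority without an effect claim

    def test_final_decision_present_iff_continued(self):
        sc = null_scenario()
        cfg = DesignConfig(n_total=100)
        priors = uninformative_priors()
        for s in range(50):
            r = run_trial(sc, cfg, priors, s)
            assert (r.interim_decision.action == "continue") \
                == (r.final_decision is not None)

    def test_golden_trace_byte_stable(self):
        """A fully worked trial trace is identical across runs at a seed."""
        sc = Scenario(pi_t=0.2, pi_c=0.4, pi_disc=0.1, n_per_arm=60,
                      label="golden")
        cfg = DesignConfig(n_total=60)
        priors = uninformative_priors()
        a = run_trial(sc, cfg, priors, 123)
        b = run_trial(sc, cfg, priors, 123)
        assert a.data == b.data
        assert a.interim_decision == b.interim_decision
        assert a.final_decision == b.final_decision

    def test_inference_errors_carry_trial_context(self):
        sc = null_scenario()
        cfg = DesignConfig(n_total=100)
        bad_priors = {"pi_t": BetaPrior(1, 1), "pi_c": BetaPrior(1, 1)}
        with pytest.raises((RuntimeError, KeyError)):
            run_trial(sc, cfg, bad_priors, 0)


class TestOperatingCharacteristics:
    def test_reproducible_for_identical_inputs(self):
        sc = null_scenario()
        cfg = DesignConfig(n_total=100)
        a = operating_characteristics(sc, cfg, 100, 5)
        b = operating_characteristics(sc, cfg, 100, 5)
        assert a.as_row() == b.as_row()

    def test_null_interim_efficacy_bounded_by_boundary_crossing(self):
        """Under the null the interim-efficacy rate cannot exceed the
        one-sided crossing probability 1 - phi(c1) (the secondary-endpoint
        conjunction only removes stops)."""
        sc = null_scenario(pi_disc=0.1)
        cfg = DesignConfig(n_total=100)
        n_sims = 1000
        ss = np.random.SeedSequence(21)
        priors = uninformative_priors()
        stops = sum(
            run_trial(sc, cfg, priors, child).interim_decision.action
            == "stop_efficacy" for child in ss.spawn(n_sims))
        p = stops / n_sims
        bound = 1.0 - cfg.efficacy_prob
        mc = 3 * np.sqrt(bound * (1 - bound) / n_sims)
        assert p <= bound + mc

    def test_effect_scenario_beats_matched_null(self):
        eff = Scenario(pi_t=0.15, pi_c=0.4, pi_disc=0.1, n_per_arm=100)
        nul = null_scenario(pi=0.4, pi_disc=0.1)
        cfg = DesignConfig(n_total=100)
        oc_eff = operating_characteristics(eff, cfg, 300, 9)
        oc_nul = operating_characteristics(nul, cfg, 300, 9)
        assert oc_eff.p_declare_effect > oc_nul.fdr

    def test_truth_classification_of_futility(self):
        cfg = DesignConfig(n_total=100)
        # no effect: futility stops are "true"
        oc = operating_characteristics(null_scenario(), cfg, 100, 3)
        assert oc.p_false_futility == 0.0
        # real effect, acceptable discontinuation: futility stops are "false"
        sc = Scenario(pi_t=0.15, pi_c=0.45, pi_disc=0.1, n_per_arm=100)
        oc = operating_characteristics(sc, cfg, 100, 3)
        assert oc.p_true_futility == 0.0

    def test_futility_calibration_matches_exact_enumeration(self):
        """The interim futility probability under the calibration scenario
        (pi_T = pi_C, pi_disc = m) factorises into two independent pieces:
        P(p_eff < 0.5) is exactly 1/2 by arm exchangeability, and
        P(p_disc < 0.5) is a finite binomial sum over interim
        discontinuation counts.  The simulated proportion must agree with
        this exactly enumerated product."""
        from scipy.stats import beta as beta_dist, binom

        n_int = 50
        d_futility = [d for d in range(n_int + 1)
                      if beta_dist.cdf(0.2, 1 + d, n_int + 1 - d) < 0.5]
        p_disc_side = float(sum(binom.pmf(d, n_int, 0.2)
                                for d in d_futility))
        exact = 0.5 * p_disc_side
        sc = null_scenario()
        cfg = DesignConfig(n_total=100)
        n_sims = 2000
        oc = operating_characteristics(sc, cfg, n_sims, 88,
                                       priors=uninformative_priors())
        band = 3 * np.sqrt(exact * (1 - exact) / n_sims)
        assert abs(oc.p_true_futility - exact) < band

    def test_mc_se_formula(self):
        oc = operating_characteristics(null_scenario(), DesignConfig(
            n_total=100), 200, 1)
        p = oc.p_declare_effect
        assert oc.mc_se["p_declare_effect"] == pytest.approx(
            np.sqrt(p * (1 - p) / 200))

    def test_rejects_too_few_sims(self):
        with pytest.raises(ValueError):
            operating_characteristics(null_scenario(),
                                      DesignConfig(n_total=100), 50, 1)


class TestPriorDataConflict:
    def test_conflicting_informative_prior_reduces_power(self):
        """Informative priors centred on harm (pi_T > pi_C) slow down the
        declaration of a real benefit: more data are needed to overcome the
        prior, so power at fixed n drops below the uninformative case."""
        sc = Scenario(pi_t=0.2, pi_c=0.4, pi_disc=0.1, n_per_arm=80)
        cfg = DesignConfig(n_total=80)
        conflicted = {
            "pi_t": beta_from_summary(0.5, 40),   # expects harm
            "pi_c": beta_from_summary(0.3, 40),
            "pi_disc": BetaPrior(1, 1),
        }
        oc_conf = operating_characteristics(sc, cfg, 400, 31,
                                            priors=conflicted)
        oc_flat = operating_characteristics(sc, cfg, 400, 31,
                                            priors=uninformative_priors())
        assert oc_conf.p_declare_effect < oc_flat.p_declare_effect


class TestSampleSizeSearch:
    def test_huge_effect_takes_smallest_size(self):
        sc = Scenario(pi_t=0.05, pi_c=0.6, pi_disc=0.05, n_per_arm=20)
        cfg = DesignConfig(n_total=20)
        res = sample_size_search(sc, cfg, 0.8, [20, 40, 60], 150, 2)
        assert res.achieved and res.n_required == 20

    def test_null_effect_never_achieves_target(self):
        sc = null_scenario(pi_disc=0.1)
        cfg = DesignConfig(n_total=100)
        res = sample_size_search(sc, cfg, 0.8, [50, 100], 150, 2)
        assert not res.achieved and res.n_required is None

    def test_isotonic_power_curve_nondecreasing(self):
        sc = Scenario(pi_t=0.2, pi_c=0.45, pi_disc=0.1, n_per_arm=30)
        cfg = DesignConfig(n_total=30)
        res = sample_size_search(sc, cfg, 0.9, [30, 60, 90, 120, 150],
                                 200, 4)
        assert np.all(np.diff(res.curve["power_isotonic"]) >= 0.0)

    def test_rejects_unsorted_grid(self):
        sc = null_scenario()
        with pytest.raises(ValueError):
            sample_size_search(sc, DesignConfig(n_total=100), 0.8,
                               [100, 50], 150, 1)
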