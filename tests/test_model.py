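import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import passagefit as pf
from passagefit.design import CovariateSetting
from passagefit.errors import (
    InvalidInputError,
    RecursionOverflowError,
    UndefinedFrequencyError,
)
from passagefit.model import (
    CompetitionDataset,
    FitnessDecision,
    ModelSpec,
    ParameterSummary,
    PosteriorSummary,
    Replicate,
    interval_decision,
)


class TestEffectiveFitness:
    def test_no_covariates_returns_baseline(self):
        assert pf.effective_fitness(0.998, {}, CovariateSetting()) == 0.998

    def test_additive_mat_and_cocl2_offsets(self):
        # sum of the posterior medians for the exponential-phase fit
        w = pf.effective_fitness(
            0.9981,
            {"mat": 0.001, "cocl2": 0.001},
            CovariateSetting(mat=1, cocl2=1),
        )
        assert w == pytest.approx(1.0001, abs=1e-9)

    def test_glucose_offset_applies_above_two_percent(self):
        w = pf.effective_fitness(
            0.9981, {"glucose": 1.6e-4}, CovariateSetting(glucose_pct=4.0)
        )
        assert w == pytest.approx(0.9981 + 2 * 1.6e-4, abs=1e-12)

    def test_nonpositive_fitness_rejected(self):
        with pytest.raises(InvalidInputError):
            pf.effective_fitness(0.5, {"mat": -0.6}, CovariateSetting(mat=1))


class TestPropagateFrequency:
    def test_neutral_fitness_is_identity_for_both_variants(self):
        for variant in ("as_printed", "normalized"):
            assert pf.propagate_frequency(0.37, 1.0, 12.5, variant) == pytest.approx(0.37)

    def test_as_printed_power_law(self):
        assert pf.propagate_frequency(0.5, 0.99, 10) == pytest.approx(
            0.5 * 0.99**10, rel=1e-12
        )
        assert pf.propagate_frequency(0.5, 0.99, 10) == pytest.approx(0.452191, abs=1e-6)

    def test_normalized_variant(self):
        grown = 0.5 * 0.99**10
        expected = grown / (grown + 0.5)
        assert pf.propagate_frequency(0.5, 0.99, 10, "normalized") == pytest.approx(
            expected, rel=1e-12
        )
        assert pf.propagate_frequency(0.5, 0.99, 10, "normalized") == pytest.approx(
            0.474896, abs=1e-6
        )

    def test_as_printed_overflow_names_the_variant(self):
        with pytest.raises(RecursionOverflowError, match="normalized"):
            pf.propagate_frequency(0.9, 1.5, 10)

    @given(
        w=st.floats(0.995, 1.005),
        dg=st.floats(0.1, 10.0),
        p=st.floats(0.2, 0.8),
    )
    @settings(max_examples=200, deadline=None)
    def test_variant_discrepancy_matches_closed_form(self, w, dg, p):
        # exact error term of the un-normalized update:
        # a - b = p*w^g * p*(w^g - 1) / (p*w^g + 1 - p)
        a = pf.propagate_frequency(p, w, dg, "as_printed")
        b = pf.propagate_frequency(p, w, dg, "normalized")
        g = w**dg
        expected = p * g * p * (g - 1) / (p * g + 1 - p)
        assert a - b == pytest.approx(expected, abs=1e-12)

    @given(
        w=st.floats(1 - 1e-5, 1 + 1e-5),
        dg=st.floats(0.1, 10.0),
        p=st.floats(0.2, 0.8),
    )
    @settings(max_examples=200, deadline=None)
    def test_variants_agree_when_selection_per_interval_is_weak(self, w, dg, p):
        a = pf.propagate_frequency(p, w, dg, "as_printed")
        b = pf.propagate_frequency(p, w, dg, "normalized")
        assert abs(a - b) < 1e-4

    @given(p=st.floats(0.05, 0.95), dg=st.floats(0.5, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_fitness(self, p, dg):
        ws = [0.97, 0.99, 1.0, 1.01]
        vals = [pf.propagate_frequency(p, w, dg, "normalized") for w in ws]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestSelectionCoefficients:
    def test_reported_fitness_arithmetic(self):
        s_total, s_per = pf.selection_coefficients(0.9981, 13)
        assert s_total == pytest.approx(-1.9e-3, abs=1.1e-4)
        assert s_per == pytest.approx(-1.5e-4, abs=5e-6)

    @pytest.mark.parametrize(
        "w,n,expected",
        [(1.0, 13, (0.0, 0.0)), (1.013, 13, (0.013, 1.0e-3))],
    )
    def test_arithmetic(self, w, n, expected):
        s_total, s_per = pf.selection_coefficients(w, n)
        assert s_total == pytest.approx(expected[0], abs=1e-9)
        assert s_per == pytest.approx(expected[1], abs=1e-6)

    def test_zero_insertions_rejected(self):
        with pytest.raises(InvalidInputError):
            pf.selection_coefficients(0.99, 0)


def brute_force_hpdi(draws, prob):
    """Independent oracle: exhaustive search over contiguous windows."""
    x = np.sort(np.asarray(draws, float))
    n = len(x)
    m = max(int(math.ceil(prob * n)), 1)
    if m >= n:
        return float(x[0]), float(x[-1])
    best = None
    for i in range(n - m + 1):
        width = x[i + m - 1] - x[i]
        if best is None or width < best[0]:
            best = (width, i)
    i = best[1]
    return float(x[i]), float(x[i + m - 1])


class TestHpdi:
    def test_constant_draws_give_degenerate_interval(self):
        assert pf.hpdi([3.0] * 20) == (3.0, 3.0)

    def test_uniform_grid_example(self):
        draws = np.arange(0.01, 1.005, 0.01)
        assert pf.hpdi(draws, 0.89) == pytest.approx((0.01, 0.89))

    def test_standard_normal_interval(self):
        # symmetric density: HPDI is the central interval +/- z(0.945) = 1.5982;
        # the width converges faster than the endpoints, whose position
        # jitters along the flat part of the window objective
        draws = np.random.default_rng(0).standard_normal(100_000)
        lo, hi = pf.hpdi(draws, 0.89)
        assert hi - lo == pytest.approx(2 * 1.5982, abs=0.03)
        assert lo == pytest.approx(-1.598, abs=0.05)
        assert hi == pytest.approx(1.598, abs=0.05)

    @given(
        draws=st.lists(st.floats(-50, 50), min_size=2, max_size=200),
        prob=st.floats(0.1, 0.99),
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, draws, prob):
        assert pf.hpdi(draws, prob) == brute_force_hpdi(draws, prob)

    def test_width_nondecreasing_in_prob(self):
        draws = np.random.default_rng(3).standard_normal(5000)
        widths = [np.diff(pf.hpdi(draws, p))[0] for p in (0.5, 0.7, 0.89, 0.95)]
        assert all(b >= a for a, b in zip(widths, widths[1:]))

    def test_empty_draws_rejected(self):
        with pytest.raises(InvalidInputError):
            pf.hpdi([])


def _summary_with(name, lo, hi, median=None):
    if median is None:
        median = (lo + hi) / 2
    p = ParameterSummary(
        name=name,
        draws=np.array([[median]]),
        median=median,
        hpdi_low=lo,
        hpdi_high=hi,
        rhat=1.0,
        ess=1000.0,
    )
    return PosteriorSummary(parameters={name: p}, hpdi_prob=0.89)


class TestDecideNeutrality:
    def test_reported_intervals_reproduce_verdicts(self):
        # exponential-phase fitness: clearly below 1
        s = _summary_with("w_base", 0.9980, 0.9983, 0.9981)
        assert pf.decide_neutrality(s, "w_base").verdict == "non_null"
        # saturation fitness: interval spans 1
        s = _summary_with("w_base", 0.9994, 1.0004, 0.9999)
        assert pf.decide_neutrality(s, "w_base").verdict == "consistent_with_null"
        # effect of lacking the insertions: clearly below 0
        s = _summary_with("beta_tf_null", -0.0041, -0.0037, -0.0039)
        assert pf.decide_neutrality(s, "beta_tf_null").verdict == "non_null"

    def test_boundary_is_inclusive(self):
        s = _summary_with("w_base", 0.999, 1.000)
        assert pf.decide_neutrality(s, "w_base").verdict == "consistent_with_null"

    def test_interval_decision_helper(self):
        assert interval_decision((0.0008, 0.0012), 0.0) == "non_null"
        assert interval_decision((-0.001, 0.002), 0.0) == "consistent_with_null"

    def test_explicit_null_value(self):
        s = _summary_with("w_base", 0.9980, 0.9983)
        d = pf.decide_neutrality(s, "w_base", null_value=0.9981)
        assert isinstance(d, FitnessDecision)
        assert d.verdict == "consistent_with_null"


def _one_obs_dataset(tf0, wt):
    return CompetitionDataset(
        [
            Replicate(
                rep_id="r1",
                covariates=CovariateSetting(),
                delta_g=np.array([0.0]),
                count_tf0=np.array([tf0]),
                count_wt=np.array([wt]),
            )
        ]
    )


class TestLogLikelihood:
    def test_single_timepoint_closed_form_binomial(self):
        ds = _one_obs_dataset(5, 5)
        ll = pf.log_likelihood(ds, {"w_base": 1.0, "p0": 0.5}, ModelSpec(active_betas=()))
        assert ll == pytest.approx(math.log(math.comb(10, 5)) + 10 * math.log(0.5))

    def test_empty_dataset_loglik_is_zero(self):
        assert pf.log_likelihood(
            CompetitionDataset([]), {"w_base": 1.0, "p0": 0.5}, ModelSpec()
        ) == 0.0

    def test_boundary_frequency_with_discordant_counts_is_minus_inf(self):
        ds = _one_obs_dataset(3, 7)
        ll = pf.log_likelihood(ds, {"w_base": 1.0, "p0": 0.0}, ModelSpec(active_betas=()))
        assert ll == -np.inf

    def test_likelihood_peaks_at_true_fitness_on_clean_data(self):
        # drift-free, high-depth simulation; profile over w on a grid
        design = pf.exponential_design(
            n_replicates=3,
            conditions=(CovariateSetting(),),
            read_depth=10**6,
            bottleneck_cells=math.inf,
            seed=17,
        )
        ds = pf.simulate_experiment(design, pf.TrueParameters(w_base=0.998, p0=0.5))
        dataset = CompetitionDataset.from_table(ds.counts)
        spec = ModelSpec(active_betas=())
        grid = np.arange(0.9972, 0.9988, 2e-5)
        lls = [
            pf.log_likelihood(dataset, {"w_base": w, "p0": 0.5}, spec) for w in grid
        ]
        w_hat = grid[int(np.argmax(lls))]
        assert abs(w_hat - 0.998) < 2e-4

    def test_truth_beats_perturbed_fitness(self):
        design = pf.exponential_design(
            n_replicates=1,
            conditions=(CovariateSetting(),),
            read_depth=10**5,
            bottleneck_cells=math.inf,
            seed=23,
        )
        ds = pf.simulate_experiment(design, pf.TrueParameters(w_base=0.998, p0=0.5))
        dataset = CompetitionDataset.from_table(ds.counts)
        spec = ModelSpec(active_betas=())
        at = lambda w: pf.log_likelihood(dataset, {"w_base": w, "p0": 0.5}, spec)
        assert at(0.998) > at(0.998 + 0.01)
        assert at(0.998) > at(0.998 - 0.01)


class TestDatasetValidation:
    def test_missing_generation_column_named_in_error(self):
        import pandas as pd

        table = pd.DataFrame(
            {"replicate": [1], "timepoint": [0], "count_tf0": [5], "count_wt": [5]}
        )
        with pytest.raises(InvalidInputError, match="cum_generations"):
            CompetitionDataset.from_table(table)

    def test_zero_informative_reads_rejected(self):
        with pytest.raises(UndefinedFrequencyError):
            _one_obs_dataset(0, 0)
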