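import math

import numpy as np
import pytest

from icefalcon.core import (
    IceFalconResult,
    bidirectional,
    bootstrap_changes,
    derive_direction_seeds,
    fit_three_models,
    information_metric,
    interpret,
)
from icefalcon.oracle import population_coefficients
from icefalcon.simulate import calibrate, implied_covariance, simulate_pairs
from icefalcon.twin_data import TwinPairDataset


class TestFitThreeModels:
    def test_causal_data_matches_oracle(self, example_like_spec):
        spec = example_like_spec.with_(n_pairs=50_000, seed=61)
        data = simulate_pairs(spec)
        pop = population_coefficients(implied_covariance(spec), "x", "y")
        m1, m2, m3 = fit_three_models(data, "x", "y")
        assert m3.coefficients.iloc[2] == pytest.approx(0.0, abs=0.015)
        assert m1.coefficients.iloc[1] == pytest.approx(pop.beta_self, abs=0.015)
        assert m2.coefficients.iloc[1] == pytest.approx(pop.beta_cotwin, abs=0.015)

    def test_reverse_causal_data_nulls_model2(self):
        spec = calibrate(0.79, 0.37, 0.30, "c", n_pairs=50_000, seed=62)
        data = simulate_pairs(spec)
        m1, m2, m3 = fit_three_models(data, "x", "y")
        assert m2.coefficients.iloc[1] == pytest.approx(0.0, abs=0.015)

    def test_independent_traits_all_null(self):
        spec = calibrate(0.0, 0.0, 0.0, "b", n_pairs=20_000, seed=63)
        data = simulate_pairs(spec)
        for m in fit_three_models(data, "x", "y"):
            assert np.all(np.abs(m.coefficients.iloc[1:]) < 0.03)

    def test_invalid_direction_rejected(self, diagram_b_data):
        with pytest.raises(ValueError):
            fit_three_models(diagram_b_data, "x", "x")


class TestBootstrapChanges:
    def test_same_seed_is_bit_identical(self, diagram_b_data):
        r1 = bootstrap_changes(diagram_b_data, "x", "y", n_boot=150, seed=5)
        r2 = bootstrap_changes(diagram_b_data, "x", "y", n_boot=150, seed=5)
        assert r1.to_dict() == r2.to_dict()
        np.testing.assert_array_equal(r1.boot_delta_cotwin, r2.boot_delta_cotwin)

    def test_deltas_recompute_from_models(self, diagram_b_data):
        res = bootstrap_changes(diagram_b_data, "x", "y", n_boot=150, seed=6)
        assert res.delta_self == res.beta_self_prime - res.beta_self
        assert res.delta_cotwin == res.beta_cotwin_prime - res.beta_cotwin
        # attenuation identity on stored values
        assert res.attenuation_cotwin == pytest.approx(
            100 * (res.beta_cotwin - res.beta_cotwin_prime) / res.beta_cotwin)

    def test_p_values_and_ses_valid(self, diagram_b_data):
        res = bootstrap_changes(diagram_b_data, "x", "y", n_boot=200, seed=7)
        assert 0 <= res.p_delta_self <= 1
        assert 0 <= res.p_delta_cotwin <= 1
        assert res.se_delta_self > 0 and res.se_delta_cotwin > 0
        lo, hi = res.percentile_interval("cotwin")
        assert lo < res.delta_cotwin < hi

    def test_causal_data_attenuates_cotwin_not_self(self, diagram_b_data):
        res = bootstrap_changes(diagram_b_data, "x", "y", n_boot=400, seed=8)
        assert res.p_delta_cotwin < 0.01          # strong attenuation signal
        assert res.p_delta_self > 0.05            # self slope unchanged
        assert res.attenuation_cotwin > 80        # attenuated to near-null

    def test_minimum_boot_enforced(self, diagram_b_data):
        with pytest.raises(ValueError, match="100"):
            bootstrap_changes(diagram_b_data, n_boot=50, seed=1)


class TestBidirectional:
    def test_relabeling_contract(self, example_like_spec):
        """Swapping the trait labels in the input swaps the two directions'
        results exactly, given swapped seeds."""
        data = simulate_pairs(example_like_spec.with_(n_pairs=200))
        s_fwd, s_rev = derive_direction_seeds(42)
        fwd, rev = bidirectional(data, n_boot=150, seed=42)
        swapped = TwinPairDataset(data.frame.rename(columns={
            "x_1": "y_1", "y_1": "x_1", "x_2": "y_2", "y_2": "x_2"}))
        fwd_s = bootstrap_changes(swapped, "x", "y", n_boot=150, seed=s_rev)
        assert fwd_s.beta_self == rev.beta_self
        assert fwd_s.delta_cotwin == rev.delta_cotwin
        np.testing.assert_array_equal(fwd_s.boot_delta_cotwin, rev.boot_delta_cotwin)

    def test_symmetric_confounding_gives_matching_patterns(self, confounding_spec):
        data = simulate_pairs(confounding_spec.with_(n_pairs=2000))
        fwd, rev = bidirectional(data, n_boot=150, seed=3)
        assert fwd.beta_self == pytest.approx(rev.beta_self, abs=0.05)
        assert fwd.beta_cotwin == pytest.approx(rev.beta_cotwin, abs=0.05)

    def test_causal_data_reversal_shows_emergence(self, diagram_b_data):
        fwd, rev = bidirectional(diagram_b_data, n_boot=300, seed=4)
        # forward: cross-pair slope attenuates to null
        assert fwd.p_delta_cotwin < 0.01
        # reverse: marginally null cross-pair slope becomes nonzero
        assert float(rev.model2.pvalues.iloc[1]) > 0.05
        assert abs(rev.beta_cotwin_prime) > abs(rev.beta_cotwin)


class TestInterpret:
    def test_causal_verdict(self, diagram_b_data):
        results = bidirectional(diagram_b_data, n_boot=300, seed=9)
        call = interpret(results)
        assert call.verdict == "X causes Y"

    def test_reverse_causal_verdict(self):
        spec = calibrate(0.79, 0.37, 0.30, "c", n_pairs=500, seed=91)
        results = bidirectional(simulate_pairs(spec), n_boot=300, seed=10)
        call = interpret(results)
        assert call.verdict == "Y causes X"

    def test_confounding_verdict(self, confounding_spec):
        data = simulate_pairs(confounding_spec.with_(n_pairs=3000, seed=92))
        results = bidirectional(data, n_boot=300, seed=11)
        call = interpret(results)
        assert call.verdict == "familial confounding"

    def test_null_data_is_indeterminate(self):
        spec = calibrate(0.5, 0.5, 0.0, "b", n_pairs=300, seed=93)
        results = bidirectional(simulate_pairs(spec), n_boot=150, seed=12)
        call = interpret(results)
        assert call.verdict == "indeterminate"

    def test_verdict_is_deterministic_function_of_results(self, diagram_b_data):
        results = bidirectional(diagram_b_data, n_boot=150, seed=13)
        assert interpret(results).verdict == interpret(results).verdict


class TestInformationMetric:
    @pytest.mark.parametrize(
        "z, n, expected",
        [
            (1.75, 130, 0.153),   # co-twin change statistic, 65 pairs
            (4.00, 4034, 0.063),  # large instrumental-variable study
            (2.69, 2170, 0.058),  # second instrumental-variable study
            (0.0, 50, 0.0),
        ],
    )
    def test_reference_values(self, z, n, expected):
        assert information_metric(z, n) == pytest.approx(expected, abs=5e-4)

    def test_positive_n_required(self):
        with pytest.raises(ValueError):
            information_metric(1.0, 0)
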