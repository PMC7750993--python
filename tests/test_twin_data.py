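import numpy as np
import pandas as pd
import pytest

from icefalcon.simulate import calibrate, simulate_pairs
from icefalcon.twin_data import (
    ConfigurationError,
    TwinPairDataset,
    ValidationError,
    double_enter,
    read_pairs,
    residualize,
    within_pair_correlation,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadPairs:
    def test_long_complete(self, tmp_path):
        p = _write(tmp_path, "twins.csv",
                   "pair_id,twin_id,x,y\n1,1,0.1,0.2\n1,2,0.3,0.4\n2,1,0.5,0.6\n2,2,0.7,0.8\n")
        data = read_pairs(p, layout="long")
        assert data.n_pairs == 2
        assert data.n_dropped == 0

    def test_long_incomplete_pair_dropped(self, tmp_path):
        p = _write(tmp_path, "twins.csv",
                   "pair_id,twin_id,x,y\n1,1,0.1,0.2\n1,2,0.3,0.4\n"
                   "2,1,0.5,0.6\n2,2,0.7,0.8\n3,1,0.9,1.0\n")
        data = read_pairs(p, layout="long")
        assert data.n_pairs == 2
        assert data.n_dropped == 1

    def test_long_triplet_is_error(self, tmp_path):
        p = _write(tmp_path, "twins.csv",
                   "pair_id,twin_id,x,y\n1,1,0.1,0.2\n1,2,0.3,0.4\n1,3,0.5,0.6\n")
        with pytest.raises(ValidationError, match="1"):
            read_pairs(p, layout="long")

    def test_missing_column_is_configuration_error(self, tmp_path):
        p = _write(tmp_path, "twins.csv", "pair_id,x_1,y_1,x_2\n1,0.1,0.2,0.3\n")
        with pytest.raises(ConfigurationError):
            read_pairs(p, layout="wide")

    def test_column_map(self, tmp_path):
        p = _write(tmp_path, "twins.csv",
                   "fam,bmi_1,meth_1,bmi_2,meth_2\n1,1,2,3,4\n2,5,6,7,8\n3,1,1,1,1\n")
        data = read_pairs(p, layout="wide", column_map={
            "pair_id": "fam", "x_1": "bmi_1", "y_1": "meth_1",
            "x_2": "bmi_2", "y_2": "meth_2"})
        assert data.n_pairs == 3

    def test_wide_missing_trait_drops_pair(self, tmp_path):
        p = _write(tmp_path, "twins.csv",
                   "pair_id,x_1,y_1,x_2,y_2\n1,1,2,3,4\n2,5,,7,8\n3,1,1,1,1\n")
        data = read_pairs(p)
        assert data.n_pairs == 2
        assert data.n_dropped == 1

    def test_simulated_wide_roundtrip(self, tmp_path, example_like_spec):
        data = simulate_pairs(example_like_spec.with_(n_pairs=250))
        path = tmp_path / "sim.csv"
        data.to_file(path)
        back = read_pairs(path)
        assert back.n_pairs == 250
        assert back.n_individuals == 500
        np.testing.assert_allclose(back.trait("x"), data.trait("x"))

    def test_dropped_plus_retained_equals_input(self, tmp_path):
        rows = ["pair_id,x_1,y_1,x_2,y_2"]
        rng = np.random.default_rng(0)
        n_missing = 0
        for i in range(30):
            vals = rng.normal(size=4).round(3).astype(object)
            if rng.random() < 0.3:
                vals[rng.integers(0, 4)] = ""
                n_missing += 1
            rows.append(",".join([str(i)] + [str(v) for v in vals]))
        p = _write(tmp_path, "t.csv", "\n".join(rows) + "\n")
        data = read_pairs(p)
        assert data.n_pairs + data.n_dropped == 30
        assert data.n_dropped == n_missing


class TestDoubleEnter:
    def test_definition_single_pair(self):
        data = TwinPairDataset(pd.DataFrame(
            {"pair_id": [1], "x_1": [1.0], "y_1": [2.0], "x_2": [3.0], "y_2": [4.0]}))
        de = double_enter(data)
        assert de.n_obs == 2
        r1, r2 = de.frame.iloc[0], de.frame.iloc[1]
        assert (r1.y_self, r1.x_self, r1.x_cotwin, r1.y_cotwin) == (2.0, 1.0, 3.0, 4.0)
        assert (r2.y_self, r2.x_self, r2.x_cotwin, r2.y_cotwin) == (4.0, 3.0, 1.0, 2.0)

    def test_twin_label_swap_symmetry(self, diagram_b_data):
        swapped = TwinPairDataset(diagram_b_data.frame.rename(columns={
            "x_1": "x_2", "x_2": "x_1", "y_1": "y_2", "y_2": "y_1"}))
        a = double_enter(diagram_b_data).frame
        b = double_enter(swapped).frame
        key = ["pair_id", "x_self", "y_self"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True)[a.columns.drop("twin")],
            b.sort_values(key).reset_index(drop=True)[a.columns.drop("twin")],
        )

    def test_row_count_doubles_pairs(self, example_like_spec):
        data = simulate_pairs(example_like_spec.with_(n_pairs=65))
        assert double_enter(data).n_obs == 130


class TestResidualize:
    def test_empty_covariates_centres(self, diagram_b_data):
        out = residualize(diagram_b_data, "x", [])
        assert abs(out.trait("x").mean()) < 1e-12
        # centring only: within-pair differences unchanged
        np.testing.assert_allclose(
            np.diff(out.trait("x")), np.diff(diagram_b_data.trait("x")))

    def test_residual_orthogonal_to_covariate(self, example_like_spec):
        data = simulate_pairs(example_like_spec.with_(n_pairs=300))
        rng = np.random.default_rng(5)
        age = rng.uniform(40, 70, (300, 2))
        x = data.trait("x") + 0.5 * age
        data = data.with_trait("x", x)
        frame = data.frame.copy()
        frame["age_1"], frame["age_2"] = age[:, 0], age[:, 1]
        data = TwinPairDataset(frame)
        out = residualize(data, "x", ["age"])
        resid = out.trait("x").reshape(-1)
        assert abs(np.corrcoef(resid, age.reshape(-1))[0, 1]) < 1e-10
        assert abs(resid.mean()) < 1e-10

    def test_idempotent(self, example_like_spec):
        data = simulate_pairs(example_like_spec.with_(n_pairs=200))
        once = residualize(data, "y", [])
        twice = residualize(once, "y", [])
        np.testing.assert_allclose(twice.trait("y"), once.trait("y"), atol=1e-10)

    def test_within_pair_correlation_preserved(self, example_like_spec):
        # adding and removing an age effect should leave rho_x near target
        spec = example_like_spec.with_(n_pairs=500)
        data = simulate_pairs(spec)
        rng = np.random.default_rng(6)
        age = rng.uniform(40, 70, (500, 2))
        frame = data.frame.copy()
        frame["x_1"] += 0.5 * age[:, 0]
        frame["x_2"] += 0.5 * age[:, 1]
        frame["age_1"], frame["age_2"] = age[:, 0], age[:, 1]
        out = residualize(TwinPairDataset(frame), "x", ["age"])
        rho = within_pair_correlation(out, "x").estimate
        assert rho == pytest.approx(0.79, abs=0.06)

    def test_constant_covariate_warns_and_drops(self, diagram_b_data):
        frame = diagram_b_data.frame.copy()
        frame["c_1"] = 1.0
        frame["c_2"] = 1.0
        data = TwinPairDataset(frame)
        with pytest.warns(UserWarning, match="constant"):
            out = residualize(data, "x", ["c"])
        assert abs(out.trait("x").mean()) < 1e-12


class TestWithinPairCorrelation:
    def test_identical_twins_give_one(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=20)
        data = TwinPairDataset(pd.DataFrame(
            {"pair_id": range(20), "x_1": v, "x_2": v, "y_1": v, "y_2": v}))
        assert within_pair_correlation(data, "x").estimate == pytest.approx(1.0)

    def test_independent_twins_near_zero(self):
        rng = np.random.default_rng(2)
        data = TwinPairDataset(pd.DataFrame({
            "pair_id": range(10000),
            "x_1": rng.normal(size=10000), "x_2": rng.normal(size=10000),
            "y_1": rng.normal(size=10000), "y_2": rng.normal(size=10000)}))
        est = within_pair_correlation(data, "x")
        assert abs(est.estimate) < 0.03
        assert est.ci_low < est.estimate < est.ci_high

    def test_matches_simulator_target(self):
        spec = calibrate(0.79, 0.37, 0.30, "b", n_pairs=5000, seed=9)
        data = simulate_pairs(spec)
        assert within_pair_correlation(data, "x").estimate == pytest.approx(0.79, abs=0.02)
        assert within_pair_correlation(data, "y").estimate == pytest.approx(0.37, abs=0.03)

    def test_label_swap_invariance(self, diagram_b_data):
        swapped = TwinPairDataset(diagram_b_data.frame.rename(columns={
            "x_1": "x_2", "x_2": "x_1", "y_1": "y_2", "y_2": "y_1"}))
        assert (within_pair_correlation(diagram_b_data, "x").estimate
                == within_pair_correlation(swapped, "x").estimate)

    def test_zero_variance_errors(self):
        data = TwinPairDataset(pd.DataFrame(
            {"pair_id": range(5), "x_1": 1.0, "x_2": 1.0,
             "y_1": np.arange(5.0), "y_2": np.arange(5.0)}))
        with pytest.raises(ValidationError, match="variance"):
            within_pair_correlation(data, "x")

    def test_too_few_pairs_errors(self):
        data = TwinPairDataset(pd.DataFrame(
            {"pair_id": [1, 2], "x_1": [1.0, 2.0], "x_2": [1.5, 2.5],
             "y_1": [0.0, 1.0], "y_2": [0.0, 1.0]}))
        with pytest.raises(ValidationError):
            within_pair_correlation(data, "x")
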