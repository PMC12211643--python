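import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smartmiss import (
    MIConfig,
    MissingnessSpec,
    apply_missingness,
    calibrate_spec,
    complete_case,
    default_m,
    mice_impute,
    pool_rubin,
    simulate_trial,
    table1_preset,
)
from smartmiss.handling import IMPUTATION_DESIGNS


@pytest.fixture(scope="module")
def masked_s3a():
    params = table1_preset(2).params
    spec = calibrate_spec(MissingnessSpec("S3a", "strong", 0.2), params, seed=60)
    data = simulate_trial(params, 500, 61)
    masked, _ = apply_missingness(data, spec, 62)
    return masked


class TestCompleteCase:
    def test_identity_on_complete_table(self):
        data = simulate_trial(table1_preset(1).params, 100, 1)
        pd.testing.assert_frame_equal(complete_case(data), data)

    def test_drops_exactly_incomplete_records(self):
        data = simulate_trial(table1_preset(1).params, 100, 2)
        data.loc[[3, 10, 20], "Y"] = np.nan
        data.loc[[10, 40], "O2"] = np.nan
        out = complete_case(data)
        assert len(out) == 100 - 4
        assert list(out.index) == [i for i in range(100) if i not in (3, 10, 20, 40)]

    def test_all_missing_is_error(self):
        data = simulate_trial(table1_preset(1).params, 5, 3)
        data["Y"] = np.nan
        with pytest.raises(ValueError, match="infeasible"):
            complete_case(data)

    def test_expected_size_under_calibrated_missingness(self):
        params = table1_preset(1).params
        spec = calibrate_spec(MissingnessSpec("S3a", "strong", 0.2), params, seed=70)
        sizes = []
        for rep in range(40):
            data = simulate_trial(params, 500, 400 + rep)
            masked, _ = apply_missingness(data, spec, 500 + rep)
            sizes.append(len(complete_case(masked)))
        assert np.mean(sizes) == pytest.approx(400, abs=5)


class TestMice:
    def test_complete_input_returns_identical_copies(self):
        data = simulate_trial(table1_preset(2).params, 80, 5)
        out = mice_impute(data, MIConfig(m=3, seed=1))
        assert len(out) == 3
        for c in out:
            pd.testing.assert_frame_equal(c, data)

    def test_observed_cells_never_altered_and_binaries_valid(self, masked_s3a):
        completed = mice_impute(masked_s3a, MIConfig(m=4, seed=9))
        observed = masked_s3a.notna()
        for c in completed:
            assert not c.isna().any().any()
            for col in masked_s3a.columns:
                obs = observed[col]
                assert (c.loc[obs, col] == masked_s3a.loc[obs, col]).all()
            assert c.loc[~observed["O2"], "O2"].isin([-1.0, 1.0]).all()
            assert c.loc[~observed["A2"], "A2"].isin([-1.0, 1.0]).all()

    def test_monotone_block_fully_imputed(self, masked_s3a):
        # records missing O2 are missing A2 and Y too; all three get values
        block = masked_s3a["O2"].isna()
        assert block.any()
        completed = mice_impute(masked_s3a, MIConfig(m=2, seed=11))
        for c in completed:
            assert c.loc[block, ["O2", "A2", "Y"]].notna().all().all()

    def test_imputation_model_designs_are_the_stated_sets(self):
        """The univariate models are exactly compatible with the two-stage
        analysis model: stated main effects plus the quoted interactions."""
        assert IMPUTATION_DESIGNS["Y"] == ("O1", "A1", "O2", "A2", "O1*A1", "O2*A2", "A1*A2")
        assert IMPUTATION_DESIGNS["O2"] == ("O1", "A1", "A2", "Y", "O1*A1", "A1*A2", "Y*A2")
        assert IMPUTATION_DESIGNS["A2"] == ("O1", "A1", "O2", "Y", "O1*A1", "Y*O2", "Y*A1")

    def test_all_missing_variable_is_error(self):
        data = simulate_trial(table1_preset(1).params, 30, 7)
        data["Y"] = np.nan
        with pytest.raises(ValueError, match="no observed values"):
            mice_impute(data, MIConfig(m=2, seed=1))

    def test_reproducible_given_seed(self, masked_s3a):
        a = mice_impute(masked_s3a, MIConfig(m=2, seed=13))
        b = mice_impute(masked_s3a, MIConfig(m=2, seed=13))
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MIConfig(m=1)
        with pytest.raises(ValueError):
            MIConfig(m=5, n_cycles=0)

    def test_default_m_rule(self):
        assert default_m(0.2) == 20
        assert default_m(0.4) == 40


class TestPoolRubin:
    def test_identical_points(self):
        pooled = pool_rubin([1.7, 1.7], [0.04, 0.04])
        assert pooled.point == pytest.approx(1.7)
        assert pooled.between_var == 0.0
        assert pooled.total_var == pytest.approx(0.04)
        # normal-limit interval when between-variance vanishes
        assert pooled.ci_high - pooled.point == pytest.approx(1.959964 * 0.2, rel=1e-4)

    def test_hand_arithmetic(self):
        pooled = pool_rubin([0.0, 1.0], [1.0, 1.0])
        assert pooled.point == pytest.approx(0.5)
        assert pooled.within_var == pytest.approx(1.0)
        assert pooled.between_var == pytest.approx(0.5)
        assert pooled.total_var == pytest.approx(1.0 + 1.5 * 0.5)  # 1.75
        assert pooled.df == pytest.approx((1 + 1 / 0.75) ** 2)

    def test_large_m_limit(self, rng):
        points = rng.normal(size=5000)
        pooled = pool_rubin(points, np.full(5000, 2.0))
        assert pooled.total_var == pytest.approx(2.0 + points.var(ddof=1), rel=1e-3)

    def test_m_below_two_is_error(self):
        with pytest.raises(ValueError):
            pool_rubin([1.0], [1.0])

    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=30),
        st.floats(0.01, 5.0),
    )
    def test_invariants(self, points, v):
        pooled = pool_rubin(points, [v] * len(points))
        m = len(points)
        assert pooled.total_var == pytest.approx(
            pooled.within_var + (1 + 1 / m) * pooled.between_var
        )
        assert pooled.between_var >= 0
        assert pooled.ci_low <= pooled.point <= pooled.ci_high
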