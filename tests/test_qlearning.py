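import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import linalg

from smartmiss import (
    conditional_outcome_mean,
    derive_truth,
    fit_stage1,
    fit_stage2,
    optimal_rule,
    pseudo_outcome,
    qlearn,
    simulate_trial,
    table1_preset,
)
from smartmiss.qlearning import Stage2Fit, _stage2_matrix


def normal_equations_oracle(X, y):
    """Brute-force OLS via the normal equations (independent of the QR path)."""
    return linalg.solve(X.T @ X, X.T @ y)


def true_stage2_fit(setting):
    g = table1_preset(setting).params.gamma
    return Stage2Fit(
        beta2=np.array(g[:4]), psi2=np.array(g[4:]), residual_sd=1.0, cov=np.zeros((7, 7))
    )


class TestFitStage2:
    def test_zero_outcome_gives_zero_coefficients(self, balanced_table):
        fit = fit_stage2(balanced_table)
        assert np.allclose(fit.beta2, 0) and np.allclose(fit.psi2, 0)

    def test_exact_recovery_on_balanced_design(self, balanced_table):
        # Y set to the noiseless conditional mean of setting 3: the
        # saturated orthogonal design recovers the coefficients exactly
        p = table1_preset(3).params
        data = balanced_table.copy()
        data["Y"] = conditional_outcome_mean(
            p, data.O1.to_numpy(), data.A1.to_numpy(), data.O2.to_numpy(), data.A2.to_numpy()
        )
        fit = fit_stage2(data)
        assert np.allclose(fit.beta2, [0, 0, -0.5, 0], atol=1e-12)
        assert np.allclose(fit.psi2, [0.5, 0, 0.5], atol=1e-12)
        oracle = normal_equations_oracle(_stage2_matrix(data), data.Y.to_numpy())
        assert np.allclose(np.concatenate([fit.beta2, fit.psi2]), oracle, atol=1e-12)

    def test_large_n_consistency_of_psi2(self):
        data = simulate_trial(table1_preset(2).params, 100_000, 3)
        fit = fit_stage2(data)
        ses = np.sqrt(np.diag(fit.cov))[4:]
        for est, se, true in zip(fit.psi2, ses, (0.0, 0.0, 1.0)):
            assert abs(est - true) < 3 * se

    def test_rank_deficiency_names_columns(self, balanced_table):
        degenerate = balanced_table.copy()
        degenerate["O2"] = degenerate["A2"]  # O2A2 column becomes constant
        with pytest.raises(ValueError, match="rank deficient"):
            fit_stage2(degenerate)

    def test_missing_cells_rejected(self, balanced_table):
        data = balanced_table.copy()
        data.loc[0, "Y"] = np.nan
        with pytest.raises(ValueError, match="observed"):
            fit_stage2(data)


class TestPseudoOutcome:
    def test_zero_fit_gives_zero(self, balanced_table):
        fit = fit_stage2(balanced_table)
        assert np.allclose(pseudo_outcome(fit, balanced_table), 0)

    def test_true_coefficients_preset5(self):
        # with A1 = -1 the stage-2 effect |1 + 0*O2 - 1| vanishes and the
        # pseudo-outcome is the pure history part -g3 = 0.5
        fit = true_stage2_fit(5)
        rec = pd.DataFrame({"O1": [1.0], "A1": [-1.0], "O2": [1.0], "A2": [1.0], "Y": [0.0]})
        assert pseudo_outcome(fit, rec)[0] == pytest.approx(0.5)

    def test_true_coefficients_preset4(self):
        # A1 = +1: history -0.5 plus |0.5 + 0.49| = 0.99 -> 0.49
        fit = true_stage2_fit(4)
        rec = pd.DataFrame({"O1": [1.0], "A1": [1.0], "O2": [-1.0], "A2": [1.0], "Y": [0.0]})
        assert pseudo_outcome(fit, rec)[0] == pytest.approx(0.49)

    def test_dominates_fitted_q2_at_observed_action(self):
        data = simulate_trial(table1_preset(4).params, 500, 9)
        fit = fit_stage2(data)
        pseudo = pseudo_outcome(fit, data)
        X = _stage2_matrix(data)
        fitted = X @ np.concatenate([fit.beta2, fit.psi2])
        assert (pseudo >= fitted - 1e-12).all()

    def test_missing_o2_rejected(self, balanced_table):
        fit = fit_stage2(balanced_table)
        data = balanced_table.copy()
        data.loc[0, "O2"] = np.nan
        with pytest.raises(ValueError, match="O2"):
            pseudo_outcome(fit, data)


class TestFitStage1:
    def test_constant_pseudo(self, balanced_table):
        fit = fit_stage1(np.full(len(balanced_table), 2.5), balanced_table)
        assert fit.beta1[0] == pytest.approx(2.5)
        assert np.allclose([fit.beta1[1], *fit.psi1], 0, atol=1e-12)

    def test_matches_normal_equations(self, rng, balanced_table):
        pseudo = rng.normal(size=len(balanced_table))
        fit = fit_stage1(pseudo, balanced_table)
        X = np.column_stack(
            [
                np.ones(len(balanced_table)),
                balanced_table.O1,
                balanced_table.A1,
                balanced_table.O1 * balanced_table.A1,
            ]
        )
        oracle = normal_equations_oracle(X, pseudo)
        assert np.allclose(np.concatenate([fit.beta1, fit.psi1]), oracle, atol=1e-10)


class TestOptimalRule:
    def test_examples(self):
        assert optimal_rule((0.5, 0, 0.5), (1, 1, 1)) == (1, False)
        assert optimal_rule((0.5, 0, 0.5), (1, -1, -1)) == (1, True)
        assert optimal_rule((0, 0, 0), (1, 1, 1)) == (1, True)
        assert optimal_rule((-0.2, 0, 0), (1, 1, 1)) == (-1, False)

    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=3))
    def test_sign_flip_antisymmetry(self, psi):
        h = (1.0, 1.0, -1.0)
        d = optimal_rule(psi, h)
        d_neg = optimal_rule([-p for p in psi], h)
        if not d.tie:
            assert d_neg.action == -d.action
        else:
            assert d_neg.tie


class TestQlearn:
    @pytest.mark.parametrize("setting", [1, 2, 3, 4, 5])
    def test_large_n_consistency_of_psi10(self, setting):
        p = table1_preset(setting).params
        fit = qlearn(simulate_trial(p, 100_000, 100 + setting))
        truth = derive_truth(p)
        assert abs(fit.psi10 - truth.psi10) < 3 * fit.psi10_se
        assert fit.psi10_se < 0.01

    def test_a2_relabelling_invariance(self):
        """Flipping the A2 labels flips the stage-2 treatment coefficients
        but leaves the pseudo-outcome and stage-1 estimates unchanged."""
        data = simulate_trial(table1_preset(4).params, 2000, 15)
        flipped = data.copy()
        flipped["A2"] = -flipped["A2"]
        fit, fit_f = qlearn(data), qlearn(flipped)
        assert np.allclose(fit_f.stage2.psi2, -fit.stage2.psi2, atol=1e-10)
        assert np.allclose(fit_f.stage2.beta2, fit.stage2.beta2, atol=1e-10)
        assert np.allclose(fit_f.pseudo, fit.pseudo, atol=1e-10)
        assert fit_f.psi10 == pytest.approx(fit.psi10, abs=1e-12)

    def test_pure_noise_has_no_stage1_effect(self):
        # mean psi10 over replicates of a no-signal trial is ~0
        p = table1_preset(1).params
        vals = [qlearn(simulate_trial(p, 500, 300 + r)).psi10 for r in range(50)]
        assert abs(np.mean(vals)) < 3 * np.std(vals, ddof=1) / np.sqrt(len(vals))


class TestOracleEquivalence:
    def test_random_small_tables_match_normal_equations(self, rng):
        """QR solve equals the brute-force normal-equations oracle to 1e-10
        relative on random full-rank tables of <= 50 records."""
        checked = 0
        while checked < 100:
            n = int(rng.integers(12, 51))
            data = pd.DataFrame(
                {
                    "O1": rng.choice([-1.0, 1.0], n),
                    "A1": rng.choice([-1.0, 1.0], n),
                    "O2": rng.choice([-1.0, 1.0], n),
                    "A2": rng.choice([-1.0, 1.0], n),
                    "Y": rng.normal(size=n),
                }
            )
            X = _stage2_matrix(data)
            if np.linalg.matrix_rank(X) < 7:
                continue
            fit = fit_stage2(data)
            oracle = normal_equations_oracle(X, data.Y.to_numpy())
            est = np.concatenate([fit.beta2, fit.psi2])
            assert np.allclose(est, oracle, rtol=1e-10, atol=1e-10)
            checked += 1
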