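"""Regularized t-test, BUM/PPDE mixture, calls and step-wise contrasts."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import anoxmeta as am
from anoxmeta.diffexpr import BumModel, regularized_variance


def _two_group_study(A: np.ndarray, B: np.ndarray, genes=None) -> am.ExpressionStudy:
    n = A.shape[0]
    genes = genes or [f"g{i}" for i in range(n)]
    samples = [f"a{j}" for j in range(A.shape[1])] + [f"b{j}" for j in range(B.shape[1])]
    values = pd.DataFrame(np.hstack([A, B]), index=genes, columns=samples)
    design = pd.DataFrame(
        {
            "sample": samples,
            "condition": ["ctrl"] * A.shape[1] + ["anoxia"] * B.shape[1],
            "replicate": list(range(1, A.shape[1] + 1)) + list(range(1, B.shape[1] + 1)),
        }
    ).set_index("sample")
    return am.ExpressionStudy("s", values, design)


def _spec(study: am.ExpressionStudy, orientation: int = 1) -> am.ContrastSpec:
    return am.ContrastSpec(
        "s", "anoxia v ctrl",
        tuple(study.samples_for("ctrl")), tuple(study.samples_for("anoxia")),
        orientation=orientation,
    )


class TestBackgroundSd:
    def test_constant_sd_field_is_unchanged(self):
        means = np.arange(20.0)
        sds = np.full(20, 0.5)
        for w in (1, 5, 19):
            assert np.allclose(am.background_sd(means, sds, w), 0.5)

    def test_window_one_returns_own_sd(self):
        rng = np.random.default_rng(3)
        means, sds = rng.normal(8, 2, 50), rng.uniform(0.1, 1, 50)
        assert np.allclose(am.background_sd(means, sds, 1), sds)

    def test_five_gene_hand_window(self):
        # genes already ordered by mean; middle gene pools sds (0.2, 0.3, 0.4)
        means = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        sds = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        got = am.background_sd(means, sds, 3)
        assert got[2] == pytest.approx(np.sqrt((0.04 + 0.09 + 0.16) / 3), abs=1e-12)
        # edges truncate: first gene pools (0.1, 0.2)
        assert got[0] == pytest.approx(np.sqrt((0.01 + 0.04) / 2), abs=1e-12)

    def test_oversized_window_is_clipped(self):
        means, sds = np.arange(4.0), np.array([0.1, 0.2, 0.3, 0.4])
        got = am.background_sd(means, sds, 101)
        assert got[1] == pytest.approx(np.sqrt(np.mean(sds[:3] ** 2)))

    def test_fewer_than_two_genes_is_an_error(self):
        with pytest.raises(am.ValidationError, match="2 genes"):
            am.background_sd(np.array([1.0]), np.array([0.1]), 1)


class TestCyberT:
    def test_v0_zero_reduces_to_classical_welch_t(self):
        rng = np.random.default_rng(5)
        A = rng.normal(8, 1, size=(1000, 3))
        B = rng.normal(8, 1, size=(1000, 3))
        study = _two_group_study(A, B)
        res = am.cybert_contrast(
            study, _spec(study), am.CyberTParams(prior_df=0.0, variance_floor=1e-300)
        )
        welch = stats.ttest_ind(B, A, axis=1, equal_var=False)
        assert np.max(np.abs(res.t_stat.to_numpy() - welch.statistic)) < 1e-10

    def test_identical_groups_give_null_statistics(self):
        rng = np.random.default_rng(6)
        A = rng.normal(8, 1, size=(30, 3))
        study = _two_group_study(A, A.copy())
        res = am.cybert_contrast(study, _spec(study))
        assert np.allclose(res.log2fc, 0) and np.allclose(res.t_stat, 0)
        assert np.allclose(res.p_value, 1)

    def test_single_gene_hand_arithmetic(self):
        """t and p recomputed by direct arithmetic from the documented
        formula (shrinkage weights v0 and n-1; df = n_a+n_b-2+2*v0)."""
        a, b = np.array([7.0, 7.2]), np.array([9.1, 8.9])
        v0, sigma0 = 2.0, 0.3
        na = nb = 2
        sa2, sb2 = np.var(a, ddof=1), np.var(b, ddof=1)
        reg_a = (v0 * sigma0 ** 2 + (na - 1) * sa2) / (v0 + na - 1)
        reg_b = (v0 * sigma0 ** 2 + (nb - 1) * sb2) / (v0 + nb - 1)
        t_expected = (b.mean() - a.mean()) / np.sqrt(reg_a / na + reg_b / nb)
        p_expected = 2 * stats.t.sf(abs(t_expected), na + nb - 2 + 2 * v0)
        got_reg_a = regularized_variance(sa2, sigma0 ** 2, na, v0)
        got_reg_b = regularized_variance(sb2, sigma0 ** 2, nb, v0)
        t_got = (b.mean() - a.mean()) / np.sqrt(got_reg_a / na + got_reg_b / nb)
        assert t_got == pytest.approx(t_expected, abs=1e-12)
        assert 2 * stats.t.sf(abs(t_got), 6.0) == pytest.approx(p_expected, abs=1e-12)

    def test_orientation_flips_reported_log2fc(self):
        rng = np.random.default_rng(7)
        study = _two_group_study(rng.normal(8, 1, (20, 3)), rng.normal(9, 1, (20, 3)))
        plus = am.cybert_contrast(study, _spec(study, orientation=1))
        minus = am.cybert_contrast(study, _spec(study, orientation=-1))
        assert np.allclose(plus.log2fc, -minus.log2fc)
        assert np.allclose(plus.p_value, minus.p_value)

    @given(st.integers(0, 10_000))
    def test_antisymmetry_under_group_swap(self, seed):
        rng = np.random.default_rng(seed)
        study = _two_group_study(rng.normal(8, 1, (12, 3)), rng.normal(8, 1.5, (12, 3)))
        spec = _spec(study)
        fwd = am.cybert_contrast(study, spec)
        rev = am.cybert_contrast(study, spec.swapped())
        assert np.allclose(fwd.log2fc.to_numpy(), -rev.log2fc.to_numpy())
        assert np.allclose(fwd.t_stat.to_numpy(), -rev.t_stat.to_numpy())
        assert np.allclose(fwd.p_value.to_numpy(), rev.p_value.to_numpy())

    @given(
        st.floats(0.01, 2.0), st.floats(0.01, 2.0),
        st.floats(0.0, 50.0), st.integers(2, 10),
    )
    def test_shrinkage_stays_between_observed_and_background(self, s2, bg2, v0, n):
        reg = regularized_variance(s2, bg2, n, v0)
        assert min(s2, bg2) - 1e-12 <= reg <= max(s2, bg2) + 1e-12

    def test_all_zero_variance_with_no_prior_is_an_error(self):
        A = np.tile([[7.0], [5.0]], (1, 3))
        study = _two_group_study(A, A + 1.0)
        with pytest.raises(am.ValidationError, match="variance floor"):
            am.cybert_contrast(study, _spec(study), am.CyberTParams(prior_df=0.0))

    def test_unknown_sample_in_spec_is_an_error(self, toy_study):
        spec = am.ContrastSpec("toy", "bad", ("c_r1", "c_r2"), ("nope1", "nope2"))
        with pytest.raises(am.ValidationError, match="nope1"):
            am.CyberT(toy_study, spec)


class TestCallRule:
    @staticmethod
    def _results_with(log2fc, p, ppde):
        table = pd.DataFrame(
            {"log2fc": [log2fc], "t": [0.0], "p": [p], "ppde": [ppde],
             "call": pd.array([None], dtype=object)},
            index=["g"],
        )
        spec = am.ContrastSpec("s", "c", ("a1", "a2"), ("b1", "b2"))
        return am.ContrastResults(spec, am.CyberTParams(), table)

    @pytest.mark.parametrize(
        "log2fc,p,ppde,expected",
        [
            (1.1, 0.01, 0.99, "up"),       # all three thresholds met
            (0.9, 0.001, 0.99, "ns"),      # fold 1.87 fails "greater than 2-fold"
            (-3.0, 0.2, 0.5, "ns"),        # fails p and PPDE
            (-1.2, 0.01, 0.99, "down"),
            (1.0, 0.001, 0.99, "ns"),      # exactly 2-fold is not > 2-fold
        ],
    )
    def test_three_part_rule(self, log2fc, p, ppde, expected):
        res = am.call_de(self._results_with(log2fc, p, ppde))
        assert res.call.iloc[0] == expected

    def test_call_without_ppde_is_an_error(self):
        res = self._results_with(1.0, 0.01, np.nan)
        with pytest.raises(am.ValidationError, match="PPDE"):
            res.with_calls()


class TestStepwiseContrasts:
    @staticmethod
    def _timecourse(timepoints, reps=2):
        rng = np.random.default_rng(0)
        conds = [f"{t}h" for t in timepoints]
        samples, cond_col = [], []
        for c in conds:
            for r in range(1, reps + 1):
                samples.append(f"{c}_r{r}")
                cond_col.append(c)
        values = pd.DataFrame(
            rng.normal(8, 1, (5, len(samples))),
            index=[f"g{i}" for i in range(5)], columns=samples,
        )
        design = pd.DataFrame(
            {"sample": samples, "condition": cond_col,
             "timepoint": [conds.index(c) for c in cond_col],
             "replicate": [int(s[-1]) for s in samples]}
        ).set_index("sample")
        return am.ExpressionStudy("tc", values, design), conds

    def test_four_timepoints_give_three_stepwise_specs(self):
        study, conds = self._timecourse([0, 3, 12, 24])
        specs = am.stepwise_contrasts(study, conds)
        assert [s.name for s in specs] == ["3h v 0h", "12h v 3h", "24h v 12h"]
        assert all(s.orientation == 1 for s in specs)

    def test_single_timepoint_gives_empty_list(self):
        study, conds = self._timecourse([0])
        assert am.stepwise_contrasts(study, conds) == []

    def test_two_timepoints_give_one_spec_with_earlier_reference(self):
        study, conds = self._timecourse([0, 24])
        (spec,) = am.stepwise_contrasts(study, conds)
        assert set(spec.group_a) == set(study.samples_for("0h"))
        assert set(spec.group_b) == set(study.samples_for("24h"))

    def test_timepoint_with_single_replicate_is_an_error(self):
        study, conds = self._timecourse([0, 3], reps=1)
        with pytest.raises(am.ValidationError, match="replicate"):
            am.stepwise_contrasts(study, conds)


class TestBum:
    def test_uniform_null_fits_mostly_uniform(self):
        rng = np.random.default_rng(0)
        fit, ppde = am.fit_bum_ppde(rng.random(10_000), seed=0)
        assert fit.lambda_ >= 0.95
        assert np.median(ppde) <= 0.1

    def test_parameter_recovery_from_known_mixture(self):
        rng = np.random.default_rng(1)
        n, lam, a = 20_000, 0.7, 0.3
        p = np.where(rng.random(n) < lam, rng.random(n), rng.random(n) ** (1 / a))
        fit, _ = am.fit_bum_ppde(p, seed=0)
        assert abs(fit.lambda_ - lam) <= 0.05
        assert abs(fit.a - a) <= 0.05

    def test_ppde_tends_to_one_as_p_tends_to_zero(self):
        fit = am.BumResults(lambda_=0.7, a=0.3, loglik=0.0, n_obs=100, n_iter=1, converged=True)
        assert fit.ppde(1e-12) > 0.999999
        assert fit.ppde(1.0) < fit.ppde(1e-6)

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.99))
    def test_ppde_is_non_increasing_in_p_for_a_below_one(self, lam, a):
        fit = am.BumResults(lambda_=lam, a=a, loglik=0.0, n_obs=100, n_iter=1, converged=True)
        grid = np.logspace(-10, 0, 200)
        vals = np.asarray(fit.ppde(grid))
        assert np.all(np.diff(vals) <= 1e-12)

    def test_density_integrates_to_one(self):
        from scipy.integrate import quad
        fit = am.BumResults(lambda_=0.6, a=0.4, loglik=0.0, n_obs=1, n_iter=1, converged=True)
        integral, _ = quad(lambda x: float(fit.density(x)), 1e-12, 1.0)
        assert integral == pytest.approx(1.0, abs=1e-6)

    def test_out_of_range_pvalues_are_an_error(self):
        with pytest.raises(am.ValidationError):
            BumModel([0.5, 1.5])

    def test_results_summary_mentions_the_mixture(self):
        rng = np.random.default_rng(2)
        fit, _ = am.fit_bum_ppde(rng.random(500), seed=0)
        assert "lambda" in fit.summary()
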