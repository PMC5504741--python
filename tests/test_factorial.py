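"""Factorial model estimation, FDR, significance calls and group taxonomy."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import digamma, polygamma

import stressfactor as sf
from conftest import make_matrix

# Frozen expected labels for the full 27-point call space, transcribed from
# the taxonomy rules: rows additive/enhanced/reduced/specific by the
# interaction call, columns drought-only/shared/heat-only by the single-
# stress calls, opposite-sign single-stress patterns to side classes.
TRUTH_TABLE = {
    ("ns", "ns", "ns"): "null",
    ("ns", "ns", "up"): "4", ("ns", "ns", "down"): "4",
    ("up", "ns", "ns"): "2.1", ("down", "ns", "ns"): "2.1",
    ("up", "ns", "up"): "3.1", ("down", "ns", "down"): "3.1",
    ("up", "ns", "down"): "1.1", ("down", "ns", "up"): "1.1",
    ("ns", "up", "ns"): "2.3", ("ns", "down", "ns"): "2.3",
    ("ns", "up", "up"): "3.3", ("ns", "down", "down"): "3.3",
    ("ns", "up", "down"): "1.3", ("ns", "down", "up"): "1.3",
    ("up", "up", "ns"): "2.2", ("down", "down", "ns"): "2.2",
    ("up", "up", "up"): "3.2", ("down", "down", "down"): "3.2",
    ("up", "up", "down"): "1.2", ("down", "down", "up"): "1.2",
    ("up", "down", "ns"): "opp_additive", ("down", "up", "ns"): "opp_additive",
    ("up", "down", "up"): "opp_interaction",
    ("up", "down", "down"): "opp_interaction",
    ("down", "up", "up"): "opp_interaction",
    ("down", "up", "down"): "opp_interaction",
}


def _cell_means_matrix(means, design, noise_sd=0.0, seed=0):
    """One-variable matrix whose condition means are as given."""
    rng = np.random.default_rng(seed)
    cond = design["condition"].to_numpy()
    values = np.array([[means[c] for c in cond]], dtype=float)
    values += noise_sd * rng.standard_normal(values.shape)
    return sf.OmicsMatrix(values, ["g0"], design["sample_id"].tolist(),
                          scale="log2")


class TestFitFactorialModel:
    def test_noise_free_main_effect(self, balanced_design):
        m = _cell_means_matrix(
            {"control": 10, "D": 12, "H_LrH": 10, "DH_LrH": 12},
            balanced_design)
        fit = sf.fit_factorial_model(m, balanced_design, moderation=False)
        np.testing.assert_allclose(
            fit.coefficients.loc["g0"], [10, 2, 0, 0], atol=1e-10)

    def test_interaction_contrast_identity(self, balanced_design):
        m = _cell_means_matrix(
            {"control": 10, "D": 12, "H_LrH": 11, "DH_LrH": 15},
            balanced_design)
        fit = sf.fit_factorial_model(m, balanced_design, moderation=False)
        # beta_DH = DH - D - H + control
        assert fit.coefficients.loc["g0", "D:H"] == pytest.approx(2.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, balanced_design):
        rng = np.random.default_rng(7)
        n = len(balanced_design)
        values = rng.normal(size=(100, n))
        m = sf.OmicsMatrix(values, [f"g{i}" for i in range(100)],
                           balanced_design["sample_id"].tolist(), scale="log2")
        fit = sf.fit_factorial_model(m, balanced_design, moderation=False)
        D = balanced_design["drought"].to_numpy(float)
        H = balanced_design["heat"].to_numpy(float)
        X = np.column_stack([np.ones(n), D, H, D * H])
        oracle = np.linalg.inv(X.T @ X) @ X.T @ values.T
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), oracle.T, atol=1e-10)

    def test_cell_mean_contrast_identities(self, balanced_design):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(50, len(balanced_design)))
        m = sf.OmicsMatrix(values, [f"g{i}" for i in range(50)],
                           balanced_design["sample_id"].tolist(), scale="log2")
        fit = sf.fit_factorial_model(m, balanced_design, moderation=False)
        cond = balanced_design["condition"].to_numpy()
        mean = {c: values[:, cond == c].mean(axis=1)
                for c in ("control", "D", "H_LrH", "DH_LrH")}
        np.testing.assert_allclose(
            fit.coefficients["intercept"], mean["control"], atol=1e-10)
        np.testing.assert_allclose(
            fit.coefficients["D"], mean["D"] - mean["control"], atol=1e-10)
        np.testing.assert_allclose(
            fit.coefficients["H"], mean["H_LrH"] - mean["control"], atol=1e-10)
        np.testing.assert_allclose(
            fit.coefficients["D:H"],
            mean["DH_LrH"] - mean["D"] - mean["H_LrH"] + mean["control"],
            atol=1e-10)

    def test_high_humidity_cells_excluded(self, planted_study):
        fit = sf.fit_factorial_model(
            planted_study["transcriptome"], planted_study["design"],
            moderation=False)
        n_lrh = planted_study["design"]["condition"].isin(
            ["control", "D", "H_LrH", "DH_LrH"]).sum()
        assert fit.residual_df == n_lrh - 4

    def test_too_few_replicates_rejected(self, balanced_design):
        design = balanced_design[balanced_design["condition"] != "D"]
        m = make_matrix(np.ones((2, len(design))))
        m.sample_ids = design["sample_id"].tolist()
        with pytest.raises(ValueError, match="replicates"):
            sf.fit_factorial_model(m, design)


class TestVarianceModeration:
    def test_recovers_known_prior(self):
        # residual variances drawn from a scaled inverse chi-square prior:
        # d0*s0^2 / chi^2_{d0}, observed through chi^2_d sampling noise
        rng = np.random.default_rng(42)
        d0, s0_sq, d = 8.0, 2.0, 10.0
        n = 20_000
        true_var = d0 * s0_sq / rng.chisquare(d0, size=n)
        s2 = true_var * rng.chisquare(d, size=n) / d
        s2_tilde, s0_hat, d0_hat = sf.moderate_variances(s2, d)
        assert s0_hat == pytest.approx(s0_sq, rel=0.1)
        assert d0_hat == pytest.approx(d0, rel=0.2)
        # shrinkage: moderated values lie between observation and prior
        between = ((s2_tilde >= np.minimum(s2, s0_hat) - 1e-12)
                   & (s2_tilde <= np.maximum(s2, s0_hat) + 1e-12))
        assert between.all()

    def test_moment_equations_hold_at_estimate(self):
        rng = np.random.default_rng(1)
        d = 8.0
        s2 = 1.5 * rng.chisquare(d, size=5000) / d
        _, s0_hat, d0_hat = sf.moderate_variances(s2, d)
        e = np.log(s2) - digamma(d / 2) + np.log(d / 2)
        # mean equation: E[e] = log s0^2 - (digamma(d0/2) - log(d0/2)),
        # since log s^2 = log s0^2 + log(chi2_d/d) - log(chi2_d0/d0)
        lhs = np.mean(e)
        rhs = np.log(s0_hat) - digamma(d0_hat / 2) + np.log(d0_hat / 2)
        assert lhs == pytest.approx(rhs, abs=1e-8)
        if d0_hat < 1e6:  # variance equation only binds off the cap
            assert np.var(e, ddof=1) == pytest.approx(
                polygamma(1, d / 2) + polygamma(1, d0_hat / 2), abs=1e-8)

    def test_moderation_off_equals_plain_ols_t(self, balanced_design):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(60, len(balanced_design)))
        m = sf.OmicsMatrix(values, [f"g{i}" for i in range(60)],
                           balanced_design["sample_id"].tolist(), scale="log2")
        plain = sf.fit_factorial_model(m, balanced_design, moderation=False)
        t = plain.t_statistics().to_numpy()
        se_manual = np.sqrt(plain.residual_variance)
        assert np.all(np.isfinite(t))
        assert plain.total_df == plain.residual_df
        assert np.all(se_manual >= 0)


class TestAdjustFdr:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            sf.adjust_fdr(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_edge_cases(self):
        np.testing.assert_allclose(sf.adjust_fdr(np.ones(5)), np.ones(5))
        np.testing.assert_allclose(sf.adjust_fdr(np.array([0.2])), [0.2])
        with pytest.raises(ValueError):
            sf.adjust_fdr(np.array([1.5]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_step_up_definition(self, p_list):
        p = np.array(p_list)
        adj = sf.adjust_fdr(p)
        # independent oracle: direct transcription of the step-up definition
        m = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(m)
        running_min = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running_min = min(running_min, m * p[i] / rank)
            expected[i] = running_min
        np.testing.assert_allclose(adj, np.minimum(expected, 1.0), atol=1e-12)
        assert np.all(adj >= p - 1e-12)


class TestCallSignificance:
    @pytest.mark.parametrize("beta,p_adj,expected", [
        (1.5, 0.001, "up"),
        (1.5, 0.2, "ns"),
        (0.9, 1e-9, "ns"),
        (-1.5, 0.001, "down"),
    ])
    def test_joint_fold_change_and_fdr_rule(self, balanced_design, beta,
                                            p_adj, expected, monkeypatch):
        m = _cell_means_matrix(
            {"control": 10, "D": 10 + beta, "H_LrH": 10, "DH_LrH": 10 + beta},
            balanced_design, noise_sd=0.01, seed=0)
        fit = sf.fit_factorial_model(m, balanced_design, moderation=False)
        # pin estimate and adjusted p to the example values
        fit.coefficients.loc["g0", "D"] = beta
        monkeypatch.setattr(
            sf.factorial, "adjust_fdr", lambda p: np.full_like(p, p_adj))
        calls = sf.call_significance(fit)
        assert calls.loc["g0", "D"] == expected


class TestClassification:
    def test_exhaustive_truth_table(self):
        seen = {}
        for triple in itertools.product(["up", "down", "ns"], repeat=3):
            label, direction = sf.classify_calls(*triple)
            assert label == TRUTH_TABLE[triple], triple
            seen[triple] = label
        assert len(seen) == 27

    def test_direction_labels(self):
        assert sf.classify_calls("up", "ns", "ns") == ("2.1", "up")
        assert sf.classify_calls("down", "down", "up") == ("1.2", "down")
        assert sf.classify_calls("ns", "ns", "down") == ("4", "down")
        assert sf.classify_calls("up", "down", "ns")[1] == "mixed"
        assert sf.classify_calls("ns", "ns", "ns")[1] == "none"

    def test_scale_free(self, balanced_design):
        rng = np.random.default_rng(10)
        values = rng.normal(0, 2, size=(80, len(balanced_design)))
        ids = [f"g{i}" for i in range(80)]
        sids = balanced_design["sample_id"].tolist()
        for c in (1.0, 3.7):
            m = sf.OmicsMatrix(values * c, ids, sids, scale="log2")
            fit = sf.fit_factorial_model(m, balanced_design, moderation=False)
            th = sf.Thresholds(lfc=1.0 * c)
            calls = sf.call_significance(fit, th)
            groups = sf.classify_response_groups(calls)
            if c == 1.0:
                reference = groups["group"]
            else:
                pd.testing.assert_series_equal(groups["group"], reference)


class TestSummaries:
    def test_counts_partition_variables(self, planted_study):
        t = sf.correct_batch(planted_study["transcriptome"],
                             planted_study["design"])
        fit = sf.fit_factorial_model(t, planted_study["design"])
        groups = sf.classify_response_groups(sf.call_significance(fit))
        summary = sf.summarize_groups(groups)
        assert summary["count"].sum() == len(groups)
        assert summary["fraction"].sum() == pytest.approx(1.0)

    def test_all_null_table(self):
        calls = pd.DataFrame(
            "ns", index=[f"g{i}" for i in range(10)],
            columns=["D", "H", "D:H"])
        groups = sf.classify_response_groups(calls)
        assert (groups["group"] == "null").all()
        summary = sf.summarize_groups(groups)
        assert summary["count"].tolist() == [10]
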