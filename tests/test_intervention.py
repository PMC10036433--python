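"""Intervention stage: paired tests, ddCt quantification, correlation screen."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import imatnet as im
from imatnet.errors import (InfiniteStatisticError, InvalidParameterError,
                            UndefinedChangeError)
from imatnet.intervention import (ScreenConfig, baseline_matrix,
                                  change_test_table, correlation_screen,
                                  delta_matrix, differential_expression_anova,
                                  differential_expression_table,
                                  paired_change_test, relative_change,
                                  relative_expression)


class TestRelativeChange:
    @pytest.mark.parametrize("pre,post,expected", [
        (100.0, 90.0, -10.0),
        (3.5, 5.4, 100 * (5.4 - 3.5) / 3.5),  # +54.2857...
        (7.0, 7.0, 0.0),
    ])
    def test_values(self, pre, post, expected):
        assert relative_change(pre, post) == pytest.approx(expected, abs=1e-10)

    def test_zero_baseline_rejected(self):
        with pytest.raises(UndefinedChangeError):
            relative_change(0.0, 1.0)


class TestPairedChangeTest:
    def test_hand_computed_t(self):
        pre = np.zeros(3)
        post = np.array([1.0, 2.0, 3.0])
        t, p, mean_diff = paired_change_test(pre, post)
        # oracle: mean/ (sd/sqrt(n)) = 2 / (1/sqrt(3)) = 2*sqrt(3)
        assert t == pytest.approx(2 * math.sqrt(3), abs=1e-10)
        assert mean_diff == pytest.approx(2.0)
        assert p == pytest.approx(2 * stats.t.sf(2 * math.sqrt(3), df=2), abs=1e-12)

    def test_identical_pairs(self):
        v = np.array([1.0, 2.0, 3.0])
        assert paired_change_test(v, v) == (0.0, 1.0, 0.0)

    def test_constant_shift_is_infinite_statistic(self):
        v = np.array([1.0, 2.0, 3.0])
        with pytest.raises(InfiniteStatisticError):
            paired_change_test(v, v + 1.0)

    def test_planted_gir_improvement_rejected_reliably(self):
        """Monte-Carlo power on the calibrated longitudinal cohort."""
        rejections = 0
        reps = 200
        for seed in range(reps):
            clin, _, _ = im.generate_intervention_cohort(
                im.InterventionSpec(seed=seed))
            pre = clin.frame.query("group == 'pre'").set_index("participant_id")
            post = clin.frame.query("group == 'post'").set_index("participant_id")
            _, p, _ = paired_change_test(pre["GIR"], post.loc[pre.index, "GIR"])
            rejections += p < 0.05
        assert rejections / reps >= 0.95

    def test_power_consistent_with_noncentral_t_oracle(self, rng):
        """Simulated paired-t power matches the closed-form noncentral-t
        power within Monte-Carlo error (independent oracle)."""
        n, delta, sd = 17, 0.8, 1.0
        reps = 1500
        hits = 0
        for _ in range(reps):
            diff = rng.normal(delta, sd, n)
            t = diff.mean() / (diff.std(ddof=1) / math.sqrt(n))
            hits += abs(t) > stats.t.ppf(0.975, n - 1)
        observed = hits / reps
        nc = delta / (sd / math.sqrt(n))
        crit = stats.t.ppf(0.975, n - 1)
        power = stats.nct.sf(crit, n - 1, nc) + stats.nct.cdf(-crit, n - 1, nc)
        mc_se = math.sqrt(power * (1 - power) / reps)
        assert abs(observed - power) < 3 * mc_se + 1e-9

    def test_change_table_covers_variables(self):
        clin, _, _ = im.generate_intervention_cohort(im.InterventionSpec(seed=3))
        table = change_test_table(clin)
        assert {"GIR", "FG", "BW"} <= set(table["variable"])
        gir = table.set_index("variable").loc["GIR"]
        assert gir["mean_difference"] > 0 and gir["n"] == 17


def make_ct(rows):
    return pd.DataFrame(rows, columns=["participant_id", "timepoint", "gene", "Ct"])


class TestRelativeExpression:
    def test_calibrator_cancels_to_zero(self):
        ct = make_ct([("P1", "pre", "PDK4", 25.0), ("P1", "pre", "TBP", 20.0)])
        rel = relative_expression(ct)
        assert rel["dCt"].iloc[0] == 5.0
        assert rel["ddCt"].iloc[0] == 0.0
        assert rel["log2_level"].iloc[0] == 0.0

    def test_one_cycle_drop_doubles_level(self):
        ct = make_ct([("P1", "pre", "PDK4", 25.0), ("P1", "pre", "TBP", 20.0),
                      ("P2", "pre", "PDK4", 24.0), ("P2", "pre", "TBP", 20.0)])
        rel = relative_expression(ct, calibrator="named-sample",
                                  calibrator_sample="P1")
        levels = rel.set_index("participant_id")["log2_level"]
        assert levels["P1"] == 0.0
        assert levels["P2"] == 1.0  # one fewer cycle = doubled expression

    def test_identical_samples_all_zero(self):
        ct = make_ct([(f"P{i}", tp, g, 25.0 if g == "PDK4" else 20.0)
                      for i in range(4) for tp in ("pre", "post")
                      for g in ("PDK4", "TBP")])
        rel = relative_expression(ct)
        assert (rel["log2_level"] == 0.0).all()

    def test_per_participant_ct_shift_invariance(self):
        """Adding a constant to every Ct of one participant (target and
        reference) leaves log2 levels unchanged."""
        _, ct, _ = im.generate_intervention_cohort(im.InterventionSpec(seed=9))
        rel_a = relative_expression(ct)
        shifted = ct.copy()
        mask = shifted["participant_id"] == "Pi003"
        shifted.loc[mask, "Ct"] += 1.7
        rel_b = relative_expression(shifted)
        merged = rel_a.merge(rel_b, on=["participant_id", "timepoint", "gene"],
                             suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["log2_level_a"], merged["log2_level_b"],
                                   atol=1e-10)

    def test_missing_reference_drops_row(self, caplog):
        ct = make_ct([("P1", "pre", "PDK4", 25.0), ("P1", "pre", "TBP", 20.0),
                      ("P2", "pre", "PDK4", 24.0)])  # P2 lacks TBP
        with caplog.at_level("WARNING", logger="imatnet.intervention"):
            rel = relative_expression(ct)
        assert list(rel["participant_id"]) == ["P1"]
        assert "dropped 1" in caplog.text


class TestDifferentialExpression:
    def test_identical_groups(self):
        assert differential_expression_anova([1.0, 1.0], [1.0, 1.0]) == (0.0, 1.0)

    def test_f_equals_t_squared_on_toy(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        f, p_f = differential_expression_anova(a, b)
        t, p_t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2, abs=1e-10)
        assert p_f == pytest.approx(p_t, abs=1e-12)

    def test_f_equals_t_squared_random(self, rng):
        for _ in range(100):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(size=rng.integers(3, 12))
            f, _ = differential_expression_anova(a, b)
            t, _ = stats.ttest_ind(a, b)
            assert f == pytest.approx(t ** 2, abs=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            differential_expression_anova([1.0], [1.0, 2.0])

    def test_paired_mode_matches_paired_t(self):
        _, ct, _ = im.generate_intervention_cohort(im.InterventionSpec(seed=8))
        rel = relative_expression(ct)
        de = differential_expression_table(rel, paired=True).set_index("gene")
        sub = rel[rel["gene"] == "PDK4"]
        pre = sub[sub["timepoint"] == "pre"].set_index("participant_id")["log2_level"]
        post = sub[sub["timepoint"] == "post"].set_index("participant_id")["log2_level"]
        t, p, _ = paired_change_test(pre, post.loc[pre.index])
        assert de.loc["PDK4", "F"] == pytest.approx(t ** 2, abs=1e-10)
        assert de.loc["PDK4", "p"] == pytest.approx(p, abs=1e-12)

    def test_planted_shift_detected(self):
        """A gene with a planted pre-to-post log2 shift reaches p<0.05 in
        nearly all replicates at the default within-gene noise."""
        hits = 0
        reps = 100
        for seed in range(reps):
            spec = im.InterventionSpec(seed=seed, planted_de={"ARF1": -1.0})
            _, ct, _ = im.generate_intervention_cohort(spec)
            rel = relative_expression(ct)
            de = differential_expression_table(rel).set_index("gene")
            hits += de.loc["ARF1", "p"] < 0.05
        assert hits / reps >= 0.95


class TestCorrelationScreen:
    def test_perfectly_linear_gene(self):
        delta = pd.DataFrame({"FG": np.linspace(-20, 5, 10)},
                             index=[f"P{i}" for i in range(10)])
        expr = pd.DataFrame([2.0 + 0.1 * delta["FG"].to_numpy()],
                            index=["SIN3A"], columns=delta.index)
        out = correlation_screen(expr, delta)
        row = out.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-6 and row["significant"]

    def test_too_few_pairs_reported_missing(self):
        delta = pd.DataFrame({"FG": [1.0, 2.0, np.nan, np.nan]},
                             index=[f"P{i}" for i in range(4)])
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"],
                            columns=delta.index)
        out = correlation_screen(expr, delta)
        assert out["n"].iloc[0] == 2
        assert np.isnan(out["r"].iloc[0]) and not out["significant"].iloc[0]

    def test_q_values_monotone_in_p(self, rng):
        delta = pd.DataFrame(rng.normal(size=(17, 3)),
                             index=[f"P{i}" for i in range(17)],
                             columns=["FG", "BW", "GIR"])
        expr = pd.DataFrame(rng.normal(size=(6, 17)),
                            index=[f"g{i}" for i in range(6)],
                            columns=delta.index)
        out = correlation_screen(expr, delta).sort_values("p")
        assert (out["q"].to_numpy()[1:] >= out["q"].to_numpy()[:-1] - 1e-12).all()
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_spearman_option_rank_invariant(self, rng):
        delta = pd.DataFrame({"FG": rng.normal(size=12)},
                             index=[f"P{i}" for i in range(12)])
        expr = pd.DataFrame([np.exp(delta["FG"].to_numpy())], index=["g"],
                            columns=delta.index)
        out = correlation_screen(expr, delta, ScreenConfig(method="spearman"))
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_planted_gene_flagged_in_default_simulation(self):
        clin, ct, truth = im.generate_intervention_cohort(
            im.InterventionSpec(seed=17))
        rel = relative_expression(ct)
        out = correlation_screen(baseline_matrix(rel), delta_matrix(clin))
        hit = out.query("gene == 'ST3GAL2' and variable == 'FG'").iloc[0]
        assert hit["significant"] and hit["r"] < -0.5

    def test_type_one_error_calibrated(self, rng):
        """Null screen flags ~5% at alpha=0.05 (quick check; the full
        1000-replicate calibration runs in the acceptance suite)."""
        hits = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=17)
            y = rng.normal(size=17)
            hits += stats.pearsonr(x, y)[1] < 0.05
        assert 0.02 < hits / reps < 0.08
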