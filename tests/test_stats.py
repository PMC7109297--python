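"""Assumption gate, gated comparisons, Dunn post hocs, summary ANOVA."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from mnephys.stats import (GateResult, VariableSeries, anova_from_summary,
                           assess_assumptions, build_results_table,
                           compare_groups, dunn_test)


def _series(arrays, names=("sham", "u", "m", "sev"), ref="sham"):
    values = np.concatenate(arrays)
    labels = np.concatenate([[n] * len(a) for n, a in zip(names, arrays)])
    return VariableSeries("v", values, labels, reference=ref)


class TestGate:
    def test_normal_equal_variance_passes(self):
        """Under its own null the gate passes at the expected rate: two
        independent tests at alpha 0.05 pass jointly ~(0.95)^2 ~ 90% of the
        time; assert within the binomial band around that."""
        passed = 0
        reps = 150
        for i in range(reps):
            rng = np.random.default_rng(1000 + i)
            s = _series([rng.normal(0, 1, 50) for _ in range(4)])
            passed += assess_assumptions(s).parametric
        rate = passed / reps
        half = 1.96 * np.sqrt(0.9025 * 0.0975 / reps)
        assert 0.9025 - half <= rate <= 0.9025 + half

    def test_strong_skew_fails_normality(self):
        failed = 0
        reps = 40
        for i in range(reps):
            rng = np.random.default_rng(2000 + i)
            s = _series([np.exp(rng.normal(0, 1, 50)) for _ in range(4)])
            failed += not assess_assumptions(s).normal
        assert failed / reps >= 0.9

    def test_constant_group_routes_nonparametric(self):
        s = _series([np.zeros(5), np.zeros(5), np.zeros(5), np.zeros(5)])
        with pytest.warns(UserWarning, match="constant"):
            gate = assess_assumptions(s)
        assert gate.degenerate and not gate.parametric


class TestCompareGroups:
    def test_identical_groups_f_zero_p_one(self):
        a = np.arange(10, dtype=float)
        s = _series([a, a, a, a])
        comp = compare_groups(s, GateResult(True, True, 1.0, 1.0))
        assert comp.statistic == pytest.approx(0.0, abs=1e-12)
        assert all(p == pytest.approx(1.0, abs=1e-9)
                   for p in comp.posthoc_p.values())

    def test_two_group_tukey_equals_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        s = _series([a, b], names=("sham", "sev"))
        comp = compare_groups(s, GateResult(True, True, 1.0, 1.0))
        t_p = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert comp.posthoc_p["sev"] == pytest.approx(t_p, abs=1e-9)

    def test_two_group_kruskal_equals_ranksum(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 15), rng.normal(0.3, 1, 11)
        s = _series([a, b], names=("sham", "sev"))
        comp = compare_groups(s, GateResult(False, True, 0.0, 1.0))
        rs_p = sps.ranksums(a, b).pvalue
        assert comp.p_omnibus == pytest.approx(rs_p, abs=1e-9)
        assert comp.posthoc_p["sev"] == pytest.approx(rs_p, abs=1e-9)

    def test_null_omnibus_calibrated_posthoc_conservative(self):
        """On 4-group null data the omnibus rejects at ~alpha while the
        adjusted severe-vs-sham contrast rejects well below alpha."""
        rej_om = rej_ph = 0
        reps = 400
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(reps):
                rng = np.random.default_rng(5000 + i)
                s = _series([rng.normal(0, 1, n) for n in (9, 12, 10, 8)])
                c = compare_groups(s)
                rej_om += c.p_omnibus <= 0.05
                rej_ph += c.posthoc_p["sev"] <= 0.05
        assert 0.028 <= rej_om / reps <= 0.075
        assert rej_ph / reps <= 0.05


class TestDunn:
    def test_adjusted_not_below_unadjusted(self):
        rng = np.random.default_rng(6)
        groups = {g: rng.normal(i * 0.3, 1, 10)
                  for i, g in enumerate("abcd")}
        raw = dunn_test(groups, adjust="none")
        holm = dunn_test(groups, adjust="holm")
        for pair in raw:
            assert holm[pair] >= raw[pair] - 1e-12

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_kruskal_route_monotone_transform_invariant(self, seed):
        rng = np.random.default_rng(seed)
        arrays = [rng.normal(i * 0.4, 1, 8) for i in range(3)]
        s1 = _series(arrays, names=("sham", "b", "c"))
        s2 = _series([np.exp(a) for a in arrays], names=("sham", "b", "c"))
        gate = GateResult(False, False, 0.0, 0.0)
        c1, c2 = compare_groups(s1, gate), compare_groups(s2, gate)
        assert c1.p_omnibus == pytest.approx(c2.p_omnibus, abs=1e-12)
        assert c1.posthoc_p == pytest.approx(c2.posthoc_p)


class TestSummaryANOVA:
    def test_equal_means_f_zero(self):
        F, p, ph = anova_from_summary([5, 5, 5], [1, 2, 1], [6, 7, 8])
        assert F == pytest.approx(0.0) and p == pytest.approx(1.0)

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_raw_data_anova(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        arrays = [rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2),
                             int(rng.integers(3, 15))) for _ in range(k)]
        F_raw, p_raw = sps.f_oneway(*arrays)
        F_sum, p_sum, _ = anova_from_summary(
            [a.mean() for a in arrays], [a.std(ddof=1) for a in arrays],
            [len(a) for a in arrays])
        assert F_sum == pytest.approx(F_raw, abs=1e-8)
        assert p_sum == pytest.approx(p_raw, abs=1e-8)

    def test_published_summary_row(self):
        """Printed per-group summaries of peak instantaneous firing: the
        reconstructed omnibus is near-significant and the Tukey-Kramer
        severe-vs-sham contrast is ~0.16 (computed independently with the
        studentized-range distribution)."""
        F, p, ph = anova_from_summary([98, 106, 129, 129],
                                      [28, 32, 33, 23], [9, 12, 10, 8])
        assert F == pytest.approx(2.668, abs=0.01)
        assert p == pytest.approx(0.0627, abs=0.002)
        assert ph[3] == pytest.approx(0.160, abs=0.005)

    def test_invalid_summaries_rejected(self):
        with pytest.raises(ValueError):
            anova_from_summary([1, 2], [1, 1], [1, 5])
        with pytest.raises(ValueError):
            anova_from_summary([1, 2], [-1, 1], [5, 5])


class TestResultsTable:
    @pytest.fixture(scope="class")
    def table(self):
        rng = np.random.default_rng(8)
        rows = []
        for g, n, shift in (("sham", 9, 0.0), ("HI_unaffected", 12, 0.0),
                            ("HI_mild", 10, 0.0), ("HI_severe", 8, 3.0)):
            for i in range(n):
                rows.append({"cell_id": f"{g}_{i}", "group": g,
                             "qc": "included",
                             "rmp_mV": rng.normal(-60 + shift, 1.5),
                             "delta_I_pA": rng.normal(200 - 60 * shift, 30)})
        return pd.DataFrame(rows)

    def test_layout_and_significance(self, table):
        out, comps = build_results_table(table)
        assert list(out.columns) == ["Variable", "Condition", "Mean", "SD",
                                     "N", "p", "significant", "test"]
        assert set(out.Variable) == {"rmp_mV", "delta_I_pA"}
        sev = out[(out.Variable == "rmp_mV") &
                  (out.Condition == "HI_severe")].iloc[0]
        assert sev.p <= 0.05 and sev.significant

    def test_deterministic_rendering(self, table):
        a, _ = build_results_table(table)
        b, _ = build_results_table(table)
        assert a.to_csv() == b.to_csv()

    def test_shuffled_labels_near_alpha(self):
        """Permutation null of the full table builder: severe-vs-sham
        significance appears at a rate no greater than alpha."""
        rng = np.random.default_rng(9)
        hits = trials = 0
        for rep in range(150):
            labels = np.repeat(["sham", "HI_unaffected", "HI_mild",
                                "HI_severe"], [9, 12, 10, 8])
            rng.shuffle(labels)
            df = pd.DataFrame({"group": labels, "qc": "included",
                               "x": rng.normal(0, 1, len(labels))})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out, _ = build_results_table(df)
            row = out[(out.Condition == "HI_severe")].iloc[0]
            hits += bool(row.significant)
            trials += 1
        assert hits / trials <= 0.05
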