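"""Validation statistics: ANOVA, pairwise t with Bonferroni, direction
classification, diagnosis contrasts, TCI explanatory power, confounders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcgroups.atlas import TCI_DIMENSIONS
from fcgroups.stats import (
    anova_oneway,
    bonferroni,
    classify_directions,
    confounder_tests,
    diagnosis_within_group,
    effect_size_r,
    pairwise_t_bonferroni,
    tci_explanatory_power,
    welch_t,
)


class TestAnova:
    def test_two_groups_f_equals_pooled_t_squared(self, rng):
        x = rng.standard_normal(14)
        y = rng.standard_normal(11) + 0.5
        f, p = anova_oneway([x, y])
        # pooled two-sample t
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        assert f == pytest.approx(t * t, rel=1e-8)

    def test_identical_distributions_give_zero_f(self):
        g = np.array([1.0, 2.0, 3.0])
        f, p = anova_oneway([g, g, g])
        assert f == 0.0
        assert p == 1.0

    def test_degenerate_constant_groups(self):
        f, p = anova_oneway([np.ones(3), np.full(3, 2.0)])
        assert np.isinf(f) and p == 0.0
        f, p = anova_oneway([np.ones(3), np.ones(3)])
        assert f == 0.0 and p == 1.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([np.ones(1), np.ones(3)])


class TestBonferroni:
    def test_definition_and_cap(self):
        assert bonferroni(0.01, 10) == pytest.approx(0.10)
        assert bonferroni(0.4, 5) == 1.0

    @given(st.floats(0, 1), st.floats(0, 1), st.integers(1, 50))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_raw_p(self, p1, p2, m):
        lo, hi = sorted([p1, p2])
        assert bonferroni(lo, m) <= bonferroni(hi, m) <= 1.0

    def test_requires_positive_family(self):
        with pytest.raises(ValueError):
            bonferroni(0.1, 0)


def test_effect_size_formula():
    assert effect_size_r(2.0, 16.0) == pytest.approx(np.sqrt(4 / 20))
    assert effect_size_r(float("inf"), 10) == 1.0


class TestPairwise:
    def test_adjustment_and_effect_columns(self, rng):
        groups = {
            "members": rng.standard_normal(10) + 1,
            "others": rng.standard_normal(12),
            "controls": rng.standard_normal(8),
        }
        table = pairwise_t_bonferroni(groups, m_tests=5)
        assert len(table) == 3
        assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()
        assert (table["p_adj"] <= 1.0).all()
        for _, row in table.iterrows():
            assert row["effect_r"] == pytest.approx(
                effect_size_r(row["t"], row["df"])
            )

    def test_small_group_skipped(self, rng, caplog):
        groups = {"a": rng.standard_normal(5), "b": np.array([1.0])}
        table = pairwise_t_bonferroni(groups, m_tests=1)
        assert table.empty


class TestDirections:
    def _table(self, member_mean, p_adj):
        return pd.DataFrame(
            {
                "network": ["DMN"], "member_mean": [member_mean],
                "other_mean": [0.0], "control_mean": [0.0],
                "p_adj_vs_control": [p_adj],
            }
        )

    def test_positive_bold(self):
        out = classify_directions(self._table(0.5, 0.0005))
        assert out.loc[0, "direction"] == "Positive"
        assert bool(out.loc[0, "bold"])

    def test_negative_not_bold(self):
        out = classify_directions(self._table(-0.5, 0.01))
        assert out.loc[0, "direction"] == "Negative"
        assert not bool(out.loc[0, "bold"])

    def test_nonsignificant_dashes(self):
        out = classify_directions(self._table(0.5, 0.2))
        assert out.loc[0, "direction"] == "--"

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            classify_directions(self._table(0.5, 0.5), p_sig=0.001, p_bold=0.05)

    def test_planted_group4_pattern_recovered(self, pipeline_runs):
        # ground-truth oracle: members of the planted Fragile-Avolitional
        # group show reduced DMN/CON and raised FPN vs controls. DAN is
        # planted positive but many members also belong to the
        # Explosive-Inattentive group, whose strongly negative DAN dilutes
        # the contrast — so for DAN we only require that it is never
        # classified in the wrong direction.
        from fcgroups.pipeline import network_block_values
        from fcgroups.stats import network_test_table

        hits = {"DMN": 0, "CON": 0, "FPN": 0, "DAN": 0}
        runs = list(pipeline_runs.values())
        for res in runs:
            co = res.cohort
            blocks = network_block_values(res.stack, co.control_ids)
            members = co.memberships["Fragile-Avolitional"]
            table = network_test_table(
                blocks, members, co.control_ids, co.patient_ids
            )
            out = classify_directions(table).set_index("network")
            if out.loc["DMN", "direction"] == "Negative":
                hits["DMN"] += 1
            if out.loc["CON", "direction"] == "Negative":
                hits["CON"] += 1
            if out.loc["FPN", "direction"] == "Positive":
                hits["FPN"] += 1
            if out.loc["DAN", "direction"] in ("Positive", "--"):
                hits["DAN"] += 1
        n = len(runs)
        for net, count in hits.items():
            assert count >= 0.9 * n, f"{net}: {count}/{n}"


class TestDiagnosisContrast:
    def test_null_band_rate_matches_uniform_p(self, rng):
        # same distribution for SZ and BP: ~4% of p-values in (0.01, 0.05)
        x = rng.standard_normal((30, 1000))
        res = diagnosis_within_group(x, np.arange(30) < 15)
        assert res["applicable"]
        assert 0.01 < res["weak"] / res["n_features"] < 0.08

    def test_identical_values_nothing_significant(self):
        x = np.ones((10, 50))
        res = diagnosis_within_group(x, np.arange(10) < 5)
        assert res["weak"] == 0 and res["strong"] == 0

    def test_strong_shift_mostly_below_001(self, rng):
        x = rng.standard_normal((30, 200))
        x[:15] += 2.0
        res = diagnosis_within_group(x, np.arange(30) < 15)
        assert res["strong"] / res["n_features"] > 0.5

    def test_single_diagnosis_not_applicable(self, rng):
        res = diagnosis_within_group(rng.standard_normal((6, 4)), np.ones(6, bool))
        assert not res["applicable"]


class TestTCIPower:
    def _null_r2(self, seed):
        rng = np.random.default_rng(seed)
        tci = pd.DataFrame(rng.standard_normal((62, 7)), columns=TCI_DIMENSIONS)
        y = np.zeros(62)
        y[rng.choice(62, 12, replace=False)] = 1
        return tci_explanatory_power(tci, y).r2_percent

    def _planted_r2(self, seed, effect=1.5, n_mem=11):
        rng = np.random.default_rng(seed)
        tci = pd.DataFrame(rng.standard_normal((62, 7)), columns=TCI_DIMENSIONS)
        y = np.zeros(62)
        y[:n_mem] = 1
        tci.loc[: n_mem - 1, "HA"] += effect
        tci.loc[: n_mem - 1, "SD"] -= effect
        return tci_explanatory_power(tci, y).r2_percent

    def test_null_membership_has_little_explanatory_power(self):
        r2s = [self._null_r2(s) for s in range(100)]
        assert np.median(r2s) < 10.0

    def test_planted_profile_lands_in_reported_band(self):
        r2s = [self._planted_r2(s) for s in range(1, 11)]
        assert 30.0 <= np.median(r2s) <= 70.0

    def test_near_separable_membership_explains_most_variance(self):
        rng = np.random.default_rng(0)
        tci = pd.DataFrame(rng.standard_normal((62, 7)), columns=TCI_DIMENSIONS)
        y = (tci["HA"] > 0.2).astype(float)
        tci.loc[y == 1, "HA"] += 3.0  # wide margin
        res = tci_explanatory_power(tci, y)
        assert res.r2_percent > 90

    def test_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(3)
        tci = pd.DataFrame(rng.standard_normal((62, 7)), columns=TCI_DIMENSIONS)
        y = np.zeros(62)
        y[:15] = 1
        tci.loc[:14, "NS"] += 1.5
        base = tci_explanatory_power(tci, y)
        scaled = tci.copy()
        scaled["NS"] = scaled["NS"] * 7.3 - 2.0
        scaled["HA"] = scaled["HA"] * 0.1 + 100.0
        res = tci_explanatory_power(scaled, y)
        assert res.r2_percent == pytest.approx(base.r2_percent, abs=1.0)
        assert res.predictors == base.predictors

    def test_minimum_group_size_enforced(self):
        tci = pd.DataFrame(np.zeros((20, 7)), columns=TCI_DIMENSIONS)
        with pytest.raises(ValueError):
            tci_explanatory_power(tci, np.r_[np.ones(2), np.zeros(18)])


class TestConfounders:
    def _cohort(self, rng, n=60):
        status = ["control"] * 15 + ["SZ"] * 20 + ["BP"] * 25
        return pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "status": status,
                "age": rng.normal(35, 10, n),
                "illness_duration": rng.gamma(2, 40, n),
                "sex": rng.choice(["F", "M"], n),
                "ethnicity": rng.choice(["A", "B", "C"], n),
                "handedness": rng.choice(["R", "L"], n, p=[0.9, 0.1]),
                "antipsychotic": rng.random(n) < 0.7,
                "mood_stabilizer": rng.random(n) < 0.4,
            }
        )

    def test_balanced_design_is_mostly_null(self, rng):
        ps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            cohort = self._cohort(r)
            patients = cohort[cohort["status"] != "control"]["subject_id"]
            members = list(r.choice(patients, 15, replace=False))
            table = confounder_tests(cohort, {"G1": members})
            ps.extend(table["p"].dropna().tolist())
        assert np.mean(np.asarray(ps) > 0.05) >= 0.85

    def test_constant_category_gives_p_one(self, rng):
        cohort = self._cohort(rng)
        cohort["sex"] = "F"
        patients = list(cohort[cohort["status"] != "control"]["subject_id"])
        table = confounder_tests(cohort, {"G1": patients[:15]})
        row = table[(table["variable"] == "sex")].iloc[0]
        assert row["p"] == 1.0

    def test_age_shift_detected(self, rng):
        cohort = self._cohort(rng)
        patients = list(cohort[cohort["status"] != "control"]["subject_id"])
        members = patients[:15]
        cohort.loc[cohort["subject_id"].isin(members), "age"] += 10
        table = confounder_tests(cohort, {"G1": members})
        row = table[(table["variable"] == "age") & (table["test"] == "t")].iloc[0]
        assert row["p"] < 0.01

    def test_requires_groups(self, rng):
        with pytest.raises(ValueError):
            confounder_tests(self._cohort(rng), {})


def test_welch_t_matches_scipy(rng):
    from scipy import stats as sps

    x, y = rng.standard_normal(12), rng.standard_normal(15) + 1
    t, df, p = welch_t(x, y)
    ref = sps.ttest_ind(x, y, equal_var=False)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
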