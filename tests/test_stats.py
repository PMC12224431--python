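"""Group-level statistics: paired tests, FDR, baseline map, behavior, confounds."""

import numpy as np
import pandas as pd
import pytest

from brainentropy import (
    baseline_map,
    behavior_change,
    behavioral_change_tests,
    build_entropy_table,
    confound_screen,
    correlate_entropy_behavior,
    entropy_change,
    paired_node_tests,
)
from conftest import entropy_table_from_values


def paired_table(pre_by_node: dict[int, list[float]], post_by_node: dict[int, list[float]],
                 condition: str = "dlPFC") -> pd.DataFrame:
    values = {}
    n_sub = len(next(iter(pre_by_node.values())))
    for s in range(n_sub):
        sid = f"s{s}"
        values[(sid, condition, "pre")] = {nid: v[s] for nid, v in pre_by_node.items()}
        values[(sid, condition, "post")] = {nid: v[s] for nid, v in post_by_node.items()}
    return entropy_table_from_values(values)


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Independent step-up adjustment used to cross-check the pipeline's FDR."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestPairedNodeTests:
    def test_closed_form_three_subjects(self):
        table = paired_table({1: [1.0, 2.0, 3.0]}, {1: [0.9, 1.8, 2.9]})
        res = paired_node_tests(table, "dlPFC").iloc[0]
        # diffs -0.1, -0.2, -0.1: |t| = 0.1333/(0.0577/sqrt(3)) = 4
        assert res["t_stat"] == pytest.approx(-4.0, abs=1e-10)
        assert res["df"] == 2
        assert res["cohen_d"] == pytest.approx(-0.13333333 / 0.05773503, rel=1e-6)
        assert res["direction"] == "decrease"

    def test_identical_sessions_give_null_result(self):
        table = paired_table({1: [1.0, 1.5, 2.0]}, {1: [1.0, 1.5, 2.0]})
        res = paired_node_tests(table, "dlPFC").iloc[0]
        assert res["t_stat"] == 0.0 and res["p_raw"] == 1.0
        assert res["direction"] == "none" and not res["significant"]

    def test_fdr_matches_independent_stepup(self, small_entropy_table):
        res = paired_node_tests(small_entropy_table, "dlPFC")
        tested = res[res["tested"]]
        np.testing.assert_allclose(tested["p_fdr"].to_numpy(),
                                   bh_stepup(tested["p_raw"].to_numpy()), atol=1e-12)

    def test_fdr_monotone_in_raw_p(self, small_entropy_table):
        res = paired_node_tests(small_entropy_table, "dlPFC")
        tested = res[res["tested"]].sort_values("p_raw")
        assert tested["p_fdr"].is_monotonic_increasing
        assert (tested["p_fdr"] >= tested["p_raw"] - 1e-15).all()

    def test_uniform_small_p_all_rejected_by_stepup(self):
        # the textbook step-up case: p = (0.01, 0.02, 0.03, 0.04), q = 0.05
        # -> p_(i) <= i*q/4 for all i, so every node is rejected
        rng = np.random.default_rng(0)
        pre, post = {}, {}
        targets = [0.01, 0.02, 0.03, 0.04]
        from scipy import stats as sps
        n = 10
        for nid, p_target in enumerate(targets, start=1):
            t_target = sps.t.ppf(1 - p_target / 2, n - 1)
            base = rng.standard_normal(n)
            diff = (base - base.mean()) / base.std(ddof=1)  # mean 0, sd 1
            diff = diff + t_target / np.sqrt(n)  # paired t == t_target
            pre[nid] = list(np.zeros(n))
            post[nid] = list(diff)
        res = paired_node_tests(paired_table(pre, post), "dlPFC")
        np.testing.assert_allclose(np.sort(res["p_raw"]), targets, atol=1e-9)
        assert res["significant"].all()
        np.testing.assert_allclose(res["p_fdr"], 0.04, atol=1e-9)

    def test_underpowered_node_listed_not_tested(self):
        table = paired_table({1: [1.0, 2.0, 3.0, 4.0], 2: [1.0, 2.0, 3.0, 4.0]},
                             {1: [0.5, 1.5, 2.4, 3.6], 2: [0.8, 1.9, 2.7, 3.9]})
        # remove node 2 for all but two subjects
        table = table[~((table["node_id"] == 2) & (table["subject_id"].isin(["s2", "s3"])))]
        res = paired_node_tests(table, "dlPFC").set_index("node_id")
        assert res.loc[1, "tested"]
        assert not res.loc[2, "tested"]
        assert "pairs" in res.loc[2, "note"]

    def test_unknown_condition_rejected(self, small_entropy_table):
        with pytest.raises(ValueError, match="condition"):
            paired_node_tests(small_entropy_table, "sham")


class TestBaselineMap:
    def test_flat_subjects_flag_nothing(self):
        values = {(f"s{i}", "dlPFC", "pre"): {1: 1.5, 2: 1.5, 3: 1.5} for i in range(5)}
        res = baseline_map(entropy_table_from_values(values))
        assert (res["t_vs_global"] == 0).all()
        assert (res["relation"] == "none").all()

    def test_constructed_offset_flagged_above(self):
        rng = np.random.default_rng(1)
        values = {}
        for i in range(10):
            base = 1.5 + 0.01 * rng.standard_normal()
            nodes = {nid: base + 0.005 * rng.standard_normal() for nid in range(2, 8)}
            nodes[1] = float(np.mean(list(nodes.values()))) + 0.5 + 0.02 * rng.standard_normal()
            values[(f"s{i}", "dlPFC", "pre")] = nodes
        res = baseline_map(entropy_table_from_values(values)).set_index("node_id")
        assert res.loc[1, "relation"] == "above"

    def test_two_node_atlas_antisymmetric(self):
        rng = np.random.default_rng(2)
        values = {(f"s{i}", "v5", "pre"): {1: 1.0 + 0.3 * rng.standard_normal(),
                                           2: 2.0 + 0.3 * rng.standard_normal()}
                  for i in range(6)}
        res = baseline_map(entropy_table_from_values(values)).set_index("node_id")
        # node - global = +/- half the node difference: exactly opposite t
        assert res.loc[1, "t_vs_global"] == pytest.approx(-res.loc[2, "t_vs_global"], rel=1e-9)

    def test_insufficient_subjects_rejected(self):
        values = {("s0", "dlPFC", "pre"): {1: 1.0, 2: 2.0}}
        with pytest.raises(ValueError, match="subjects"):
            baseline_map(entropy_table_from_values(values))


def behavior_frame(condition, pre, post):
    rows = []
    measures = ("sjws_total", "sjws_craving_total", "sjws_craving_average", "uts_score")
    for s, (p_pre, p_post) in enumerate(zip(pre, post)):
        for session, val in (("pre", p_pre), ("post", p_post)):
            rows.append({"subject_id": f"s{s}", "condition": condition, "session": session,
                         **{m: val for m in measures}})
    return pd.DataFrame(rows)


class TestBehavior:
    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(3)
        pre = rng.normal(22, 8, 20)
        post = pre - rng.normal(1.0, 2.0, 20)
        res = behavioral_change_tests(behavior_frame("dlPFC", pre, post), "dlPFC",
                                      measures=("sjws_total", "uts_score"))
        assert (res["family"] == 2).all()
        for _, row in res.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, row["p_raw"] * 2))

    def test_no_change_gives_zero_t(self):
        pre = [20.0, 22.0, 25.0, 30.0]
        res = behavioral_change_tests(behavior_frame("v5", pre, pre), "v5")
        assert (res["t_stat"] == 0).all()

    def test_recovers_constructed_craving_effect(self):
        # build diffs with exact mean 1.55 and SD 4.05 at n = 38, so the
        # paired t equals 1.55 / (4.05 / sqrt(38)) by the closed form
        rng = np.random.default_rng(4)
        z = rng.standard_normal(38)
        drop = (z - z.mean()) / z.std(ddof=1) * 4.05 + 1.55
        pre = rng.normal(22, 8.25, 38)
        res = behavioral_change_tests(behavior_frame("dlPFC", pre, pre - drop), "dlPFC")
        expected_t = -1.55 / (4.05 / np.sqrt(38))
        assert res.set_index("measure").loc["sjws_craving_total", "t_stat"] == pytest.approx(
            expected_t, abs=1e-9)

    def test_unpaired_subjects_dropped_and_counted(self):
        frame = behavior_frame("dlPFC", [20.0, 21.0, 22.0, 23.0], [19.0, 20.0, 21.0, 22.0])
        frame = frame[~((frame["subject_id"] == "s3") & (frame["session"] == "post"))]
        res = behavioral_change_tests(frame, "dlPFC")
        assert (res["n_pairs"] == 3).all()
        assert (res["n_dropped"] == 1).all()


class TestCorrelations:
    def test_exact_linear_relation_retained(self):
        ent = pd.DataFrame({"subject_id": [f"s{i}" for i in range(5)],
                            "node_id": 1, "delta": [0.1, 0.2, 0.3, 0.4, 0.5]})
        beh = pd.DataFrame({"subject_id": [f"s{i}" for i in range(5)],
                            "measure": "sjws_craving_total",
                            "delta": [0.2, 0.4, 0.6, 0.8, 1.0]})
        res = correlate_entropy_behavior(ent, beh)
        assert len(res) == 1
        assert res.iloc[0]["r"] == pytest.approx(1.0)

    def test_independent_deltas_screened_out(self):
        rng = np.random.default_rng(6)
        n_sub, n_node = 200, 30
        ent = pd.DataFrame({
            "subject_id": np.repeat([f"s{i}" for i in range(n_sub)], n_node),
            "node_id": np.tile(np.arange(1, n_node + 1), n_sub),
            "delta": rng.standard_normal(n_sub * n_node),
        })
        beh = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n_sub)],
                            "measure": "uts_score", "delta": rng.standard_normal(n_sub)})
        screened = correlate_entropy_behavior(ent, beh, screen_r=0.2)
        full = correlate_entropy_behavior(ent, beh, screen_r=0.2, full=True)
        assert len(full) == n_node
        assert len(screened) <= 0.1 * n_node

    def test_zero_variance_flagged_in_full_output(self):
        ent = pd.DataFrame({"subject_id": [f"s{i}" for i in range(4)],
                            "node_id": 1, "delta": [0.3, 0.3, 0.3, 0.3]})
        beh = pd.DataFrame({"subject_id": [f"s{i}" for i in range(4)],
                            "measure": "uts_score", "delta": [1.0, 2.0, 3.0, 4.0]})
        full = correlate_entropy_behavior(ent, beh, full=True)
        assert np.isnan(full.iloc[0]["r"]) and "zero-variance" in full.iloc[0]["note"]
        assert correlate_entropy_behavior(ent, beh).empty

    def test_change_helpers_are_post_minus_pre(self, small_cohort, small_entropy_table):
        deltas = entropy_change(small_entropy_table, "dlPFC")
        wide = small_entropy_table[small_entropy_table["condition"] == "dlPFC"].pivot_table(
            index=["subject_id", "node_id"], columns="session", values="sampen")
        expected = (wide["post"] - wide["pre"]).dropna()
        merged = deltas.set_index(["subject_id", "node_id"])["delta"]
        np.testing.assert_allclose(merged.sort_index(), expected.sort_index())
        beh = behavior_change(small_cohort.behavior, "dlPFC")
        assert set(beh["measure"]) == {"sjws_total", "sjws_craving_total",
                                       "sjws_craving_average", "uts_score"}


class TestConfounds:
    @staticmethod
    def covariates(n=10):
        rng = np.random.default_rng(8)
        return pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "sex": ["F" if i < n // 2 else "M" for i in range(n)],
            "ethnicity": ["a"] * n,
            "age": rng.integers(18, 45, n).astype(float),
            "years_smoking": rng.integers(1, 20, n).astype(float),
            "education": rng.integers(10, 20, n).astype(float),
        })

    @staticmethod
    def baseline_entropy(values_by_subject):
        return entropy_table_from_values(
            {(sid, "dlPFC", "pre"): nodes for sid, nodes in values_by_subject.items()})

    def test_identical_sex_distributions_give_zero_t(self):
        # females s0..s4 and males s5..s9 hold literally the same values
        vals = {f"s{i}": {35: [1.0, 1.1, 1.2, 1.3, 1.4][i % 5]} for i in range(10)}
        report = confound_screen(self.baseline_entropy(vals), self.covariates())
        assert report.sex_tests["t_stat"].abs().max() == pytest.approx(0.0, abs=1e-12)

    def test_single_ethnicity_group_skipped(self):
        vals = {f"s{i}": {35: 1.0 + 0.1 * i} for i in range(10)}
        report = confound_screen(self.baseline_entropy(vals), self.covariates())
        assert report.ethnicity_anova["f_stat"].isna().all()
        assert report.ethnicity_anova["note"].str.contains("group").all()

    def test_exact_linear_covariate_gives_unit_correlation(self):
        cov = self.covariates()
        vals = {row.subject_id: {35: 20.0 + 2.0 * row.age} for row in cov.itertuples()}
        report = confound_screen(self.baseline_entropy(vals), cov)
        corr = report.covariate_correlations
        r_age = corr[(corr["covariate"] == "age") & (corr["node_id"] == 35)]["r"].iloc[0]
        assert r_age == pytest.approx(1.0)

    def test_long_table_collects_all_screens(self):
        vals = {f"s{i}": {35: 1.0 + 0.05 * i, 98: 1.2 - 0.03 * i} for i in range(10)}
        report = confound_screen(self.baseline_entropy(vals), self.covariates())
        long = report.as_long_table()
        assert set(long["screen"]) == {"sex_t", "ethnicity_anova", "pearson"}
        assert report.notes  # uncorrected-screen note always present
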