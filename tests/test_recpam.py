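"""Split enumeration, permutation selection, tree growth, amalgamation,
class profiles and reporting."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from gemtree.recpam import (
    Stopping,
    amalgamate,
    candidate_splits,
    class_profiles,
    evaluate_split,
    fisher_exact_rxc,
    grow_tree,
    report_tree,
    select_split_variable,
    tree_to_dict,
)
from gemtree.synthetic_cohort import default_config, make_cohort
from tests.conftest import exp_cohort


def two_group_records(rng, n, hr, censor_max=1e6, hazard0=0.5):
    x = (np.arange(n) % 2).astype(float)
    lam = hazard0 * np.where(x == 1, hr, 1.0)
    t_event = rng.exponential(1.0 / lam)
    censor = (1.0 - rng.random(n)) * censor_max
    t = np.minimum(t_event, censor)
    e = (t_event <= censor).astype(int)
    return pd.DataFrame({"time": t, "event": e, "x": x})


class TestCandidateSplits:
    def test_constant_covariate_gives_none(self):
        assert candidate_splits(np.ones(8), np.ones(8, int)) == []

    def test_six_value_example_single_admissible_cut(self):
        values = np.array([0.1, 0.2, 0.4, 0.8, 1.0, 1.2])
        events = np.ones(6, dtype=int)
        cands = candidate_splits(values, events, Stopping(1, 3))
        assert len(cands) == 1
        assert cands[0].threshold == pytest.approx(0.6)
        assert (cands[0].left_n, cands[0].right_n) == (3, 3)

    def test_binary_covariate_at_most_one(self):
        values = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        events = np.ones(8, dtype=int)
        cands = candidate_splits(values, events, Stopping(1, 3))
        assert len(cands) == 1

    def test_categorical_enumerates_proper_subsets(self):
        values = np.array(list("aabbccdd"))
        events = np.ones(8, dtype=int)
        cands = candidate_splits(
            values, events, Stopping(1, 3), categorical=True
        )
        # 4 levels -> 2^3 - 1 = 7 complement-deduplicated subsets; only the
        # three 2-level-vs-2-level splits keep >= 3 subjects on both sides
        assert all(isinstance(c.threshold, frozenset) for c in cands)
        assert len(cands) == 3


class TestEvaluateSplit:
    def test_identical_groups_statistic_zero(self):
        t = np.tile([1.0, 2, 3, 4], 2)
        e = np.tile([1, 1, 0, 1], 2)
        v = np.repeat([0.0, 1.0], 4)
        cand = candidate_splits(v, e, Stopping(1, 3))[0]
        out = evaluate_split(t, e, v, cand)
        assert out.statistic == pytest.approx(0.0, abs=1e-8)
        assert out.hr == pytest.approx(1.0, abs=1e-6)

    def test_null_statistic_is_chi2_1(self, rng):
        # independent indicator: LR statistic should average ~1 (chi2, 1 df)
        stats = []
        for _ in range(1000):
            df = two_group_records(rng, 40, 1.0)
            cand = candidate_splits(df["x"].to_numpy(), df["event"].to_numpy())[0]
            out = evaluate_split(
                df["time"].to_numpy(), df["event"].to_numpy(), df["x"].to_numpy(), cand
            )
            stats.append(out.statistic)
        assert 0.85 <= np.mean(stats) <= 1.15

    def test_planted_hr5_exceeds_chi2_999_quantile(self, rng):
        df = two_group_records(rng, 200, 5.0)
        cand = candidate_splits(df["x"].to_numpy(), df["event"].to_numpy())[0]
        out = evaluate_split(
            df["time"].to_numpy(), df["event"].to_numpy(), df["x"].to_numpy(), cand
        )
        assert out.statistic > ss.chi2.ppf(0.999, 1)
        assert out.hr > 1.0


class TestSelectSplitVariable:
    def test_single_candidate_covariate_returned(self, rng):
        df = two_group_records(rng, 60, 4.0)
        sel = select_split_variable(df, ["x"], n_permutations=99, seed=1)
        assert sel is not None
        assert sel.covariate == "x"
        assert sel.candidate.threshold == pytest.approx(0.5)

    def test_no_admissible_split_returns_none(self, rng):
        df = two_group_records(rng, 4, 1.0)  # too small for 3+3
        assert select_split_variable(df, ["x"], seed=1) is None

    def test_planted_covariate_beats_noise(self, rng):
        # scaled down from a 200-replicate power study to keep runtime low
        hits = 0
        for _ in range(20):
            df = two_group_records(rng, 200, 5.0)
            for j in range(3):
                df[f"noise{j}"] = rng.normal(size=len(df))
            sel = select_split_variable(
                df, ["x", "noise0", "noise1", "noise2"], n_permutations=199, seed=7
            )
            hits += sel is not None and sel.covariate == "x"
        assert hits >= 19

    def test_deterministic_given_seed(self, rng):
        df = two_group_records(rng, 80, 3.0)
        df["noise0"] = rng.normal(size=len(df))
        a = select_split_variable(df, ["x", "noise0"], n_permutations=99, seed=5)
        b = select_split_variable(df, ["x", "noise0"], n_permutations=99, seed=5)
        assert (a.covariate, a.permutation_p, a.gate_p) == (
            b.covariate,
            b.permutation_p,
            b.gate_p,
        )


class TestGrowTree:
    def test_alpha_zero_keeps_root_leaf(self, cohort26):
        tree = grow_tree(cohort26, "os", ["DCK_fc", "CHOP_fc"], alpha=0.0, seed=1)
        assert tree.root.is_leaf
        assert len(tree.nodes) == 1

    def test_five_subjects_cannot_split(self, rng):
        t, e = exp_cohort(5, 1.0, 1e6, rng)
        e[:] = 0
        e[0] = 1
        coh = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(5)],
                "os_time": t,
                "os_event": e,
                "g_fc": rng.normal(size=5),
            }
        )
        tree = grow_tree(coh, "os", ["g_fc"], seed=1)
        assert tree.root.is_leaf

    def test_zero_events_rejected(self, rng):
        coh = pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "os_time": [1.0, 2.0, 3.0],
                "os_event": [0, 0, 0],
                "g_fc": [0.1, 0.2, 0.3],
            }
        )
        with pytest.raises(ValueError, match="no events"):
            grow_tree(coh, "os", ["g_fc"], seed=1)

    def test_partition_and_stopping_invariants(self):
        cfg = default_config(n_patients=120, seed=21)
        coh = make_cohort(cfg)
        tree = grow_tree(
            coh, "os", ["DCK_fc", "CHOP_fc", "hENT1_fc", "MRP1_fc"], seed=21
        )
        for node in tree.nodes.values():
            assert node.n_events + node.n_nonevents == len(node.member_ids)
            if node.children:
                left, right = (tree.nodes[c] for c in node.children)
                assert set(left.member_ids) | set(right.member_ids) == set(
                    node.member_ids
                )
                assert not set(left.member_ids) & set(right.member_ids)
        for leaf in tree.leaves:
            assert leaf.n_events >= tree.stopping.min_events
            assert len(leaf.member_ids) >= tree.stopping.min_subjects

    def test_missing_values_never_dropped(self):
        cfg = default_config(n_patients=80, seed=13)
        coh = make_cohort(cfg)
        coh.loc[coh.index[:10], "CHOP_fc"] = np.nan
        tree = grow_tree(coh, "os", ["DCK_fc", "CHOP_fc"], seed=13)
        assert sorted(tree.root.member_ids) == sorted(coh["patient_id"].astype(str))
        total_leaf_members = sum(len(l.member_ids) for l in tree.leaves)
        assert total_leaf_members == len(coh)

    def test_determinism_identical_reports(self, cohort26):
        covs = ["DCK_fc", "CHOP_fc", "hENT1_fc", "MRP1_fc"]
        out = []
        for _ in range(2):
            tree = grow_tree(cohort26, "pfs", covs, seed=99)
            classes = amalgamate(tree, cohort26)
            out.append(report_tree(tree, classes))
        assert out[0] == out[1]


class TestAmalgamate:
    def _three_leaf_cohort(self, rng, n_per=200, hrs=(1.0, 1.0, 8.0)):
        g = np.repeat([0.0, 1.0, 2.0], n_per)
        lam = 0.4 * np.array(hrs)[g.astype(int)]
        t_event = rng.exponential(1.0 / lam)
        censor = (1.0 - rng.random(g.size)) * 1e6
        t = np.minimum(t_event, censor)
        e = (t_event <= censor).astype(int)
        return pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(g.size)],
                "os_time": t,
                "os_event": e,
                "g_fc": g,
            }
        )

    def test_alpha_one_keeps_leaves_as_classes(self, cohort26):
        tree = grow_tree(cohort26, "os", ["DCK_fc", "CHOP_fc"], seed=3)
        classes = amalgamate(tree, cohort26, amalgamation_alpha=1.0)
        assert classes.classes.shape[0] == len(tree.leaves)

    def test_equal_risk_leaves_merge(self, rng):
        coh = self._three_leaf_cohort(rng)
        # open the gate so the two equal-hazard groups end up in separate
        # leaves; amalgamation must then merge exactly those two
        tree = grow_tree(
            coh, "os", ["g_fc"], seed=5, n_permutations=99, alpha=1.0, max_depth=2
        )
        assert len(tree.leaves) == 3
        classes = amalgamate(tree, coh, amalgamation_alpha=0.05)
        assert classes.classes.shape[0] == 2
        assert classes.classes.iloc[0]["hr"] > 4  # the HR~8 leaf stays apart

    def test_single_leaf_tree_single_reference_class(self, cohort26):
        tree = grow_tree(cohort26, "os", ["DCK_fc"], alpha=0.0, seed=1)
        classes = amalgamate(tree, cohort26)
        assert classes.classes.shape[0] == 1
        assert classes.reference_class_id == classes.classes.iloc[0]["class_id"]
        assert classes.classes.iloc[0]["hr"] == 1.0

    def test_classes_sorted_by_decreasing_hr_reference_unit(self, rng):
        coh = self._three_leaf_cohort(rng, hrs=(1.0, 3.0, 9.0))
        tree = grow_tree(coh, "os", ["g_fc"], seed=5, n_permutations=99)
        classes = amalgamate(tree, coh)
        hrs = classes.classes["hr"].to_numpy()
        assert np.all(np.diff(hrs) <= 1e-12)
        ref_row = classes.classes[
            classes.classes["class_id"] == classes.reference_class_id
        ]
        assert ref_row["hr"].iloc[0] == 1.0
        # every patient assigned to exactly one class
        assert classes.assignment.notna().all()
        assert classes.classes["n"].sum() == len(coh)


class TestClassProfiles:
    def test_fisher_2x2_hand_example(self):
        assert fisher_exact_rxc([[2, 0], [0, 2]]) == pytest.approx(1 / 3, abs=1e-12)

    def test_fisher_matches_scipy_on_random_2x2(self, rng):
        for _ in range(20):
            tab = rng.integers(0, 8, size=(2, 2))
            if tab.sum() == 0:
                continue
            ref = ss.fisher_exact(tab)[1]
            assert fisher_exact_rxc(tab) == pytest.approx(ref, abs=1e-10)

    def test_fisher_rxc_against_independent_exact_values(self):
        # frozen from R 4.3 fisher.test on the same tables
        assert fisher_exact_rxc([[3, 1, 0], [1, 2, 1], [0, 1, 3]]) == pytest.approx(
            0.139740259740, abs=1e-9
        )
        assert fisher_exact_rxc([[5, 2, 1], [1, 4, 3]]) == pytest.approx(
            0.230769230769, abs=1e-9
        )

    def test_kruskal_identical_distributions(self, rng):
        h, _ = ss.kruskal([1, 2, 3], [1, 2, 3])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_kruskal_hand_rank_formula(self):
        # groups (1,2,3) vs (4,5,6): H = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        h, _ = ss.kruskal([1, 2, 3], [4, 5, 6])
        n = 6
        hand = 12.0 / (n * (n + 1)) * (3 * (2 - 3.5) ** 2 + 3 * (5 - 3.5) ** 2)
        assert h == pytest.approx(hand, rel=1e-12)

    def test_profiles_table(self, rng):
        coh = make_cohort(default_config(n_patients=200, seed=32))
        tree = grow_tree(coh, "os", ["DCK_fc", "CHOP_fc"], seed=32)
        classes = amalgamate(tree, coh)
        assert classes.classes.shape[0] >= 2
        prof = class_profiles(
            coh, classes, ["jaundice", "lymph_node_ratio", "grading", "cea_preop"]
        )
        assert set(prof["covariate"]) == {
            "jaundice",
            "lymph_node_ratio",
            "grading",
            "cea_preop",
        }
        assert (prof.loc[prof["covariate"] == "jaundice", "test"] == "fisher").all()
        assert (
            prof.loc[prof["covariate"] == "cea_preop", "test"] == "kruskal-wallis"
        ).all()
        assert prof["p_value"].between(0, 1).all()


class TestReportTree:
    def test_json_round_trip(self, cohort26):
        tree = grow_tree(cohort26, "os", ["DCK_fc", "CHOP_fc"], seed=17)
        classes = amalgamate(tree, cohort26)
        js, txt = report_tree(tree, classes)
        parsed = json.loads(js)
        assert set(parsed["nodes"]) == {str(i) for i in tree.nodes}
        for nid, node in tree.nodes.items():
            got = parsed["nodes"][str(nid)]
            assert got["member_ids"] == node.member_ids
            assert got["n_events"] == node.n_events
            if node.split:
                assert got["split"]["covariate"] == node.split.covariate

    def test_single_leaf_report_single_class(self, cohort26):
        tree = grow_tree(cohort26, "os", ["DCK_fc"], alpha=0.0, seed=1)
        classes = amalgamate(tree, cohort26)
        payload = tree_to_dict(tree, classes)
        assert len(payload["classes"]) == 1
        _, txt = report_tree(tree, classes)
        assert "C1" in txt
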