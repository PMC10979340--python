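"""Unit tests for the nonparametric evaluation battery."""

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import (
    cliff_delta_oracle,
    mw_exact_oracle,
    tie_free_samples,
    wilcoxon_exact_oracle,
)
from socratiq.scales import CENSORED
from socratiq.stats import (
    Alternative,
    assign_subgroup,
    change_summary,
    cliff_delta,
    condition_summary,
    holm_correction,
    mann_whitney_u,
    per_question_summaries,
    subgroup_analysis,
    welch_t_and_cohen_d,
    wilcoxon_signed_rank,
)


class TestMannWhitney:
    def test_worked_example_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], Alternative.LESS)
        assert res.p_value == pytest.approx(1 / 20)
        assert res.method == "mann_whitney_u[exact]"
        assert res.statistic == 0.0

    def test_identical_samples_two_sided(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)
        assert res.effect_size == pytest.approx(0.0)

    def test_symmetry_of_one_sided_p(self):
        a, b = [1.5, 3.2, 7.1], [2.4, 5.5]
        p1 = mann_whitney_u(a, b, Alternative.GREATER).p_value
        p2 = mann_whitney_u(b, a, Alternative.LESS).p_value
        assert p1 == pytest.approx(p2)

    def test_ties_fall_back_to_asymptotic(self):
        res = mann_whitney_u([1, 2, 2, 3], [2, 3, 4, 5])
        assert res.method == "mann_whitney_u[asymptotic]"
        assert 0.0 <= res.p_value <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])

    def test_against_enumeration_oracle_spot(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n, m = rng.integers(2, 7), rng.integers(2, 7)
            x, y = tie_free_samples(rng, int(n), int(m))
            for alt in Alternative:
                res = mann_whitney_u(x, y, alt)
                u_o, p_o = mw_exact_oracle(x, y, alt.value.replace("_", "-"))
                assert res.statistic == pytest.approx(u_o)
                assert res.p_value == pytest.approx(p_o, abs=1e-12)


class TestWilcoxon:
    def test_worked_example_exact(self):
        res = wilcoxon_signed_rank([2, 3, 4], [1, 1, 1], Alternative.GREATER)
        assert res.p_value == pytest.approx(1 / 8)
        assert res.method == "wilcoxon[exact]"

    def test_zero_differences_dropped(self):
        # pairs (5,5) contribute nothing; effective n becomes 3
        res = wilcoxon_signed_rank([2, 3, 4, 5], [1, 1, 1, 5], Alternative.GREATER)
        assert res.n == (3,)
        assert res.p_value == pytest.approx(1 / 8)

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert res.degenerate
        assert res.p_value == 1.0
        assert res.effect_size == 0.0

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2, 3], [1, 2])

    def test_effect_size_sign_follows_median_difference(self):
        up = wilcoxon_signed_rank([5, 6, 7, 8], [1, 2, 3, 4])
        down = wilcoxon_signed_rank([1, 2, 3, 4], [5, 6, 7, 8])
        assert up.effect_size > 0
        assert down.effect_size < 0
        assert up.effect_size == pytest.approx(-down.effect_size)

    def test_against_enumeration_oracle_spot(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            d, _ = tie_free_samples(rng, n)
            pre = list(d)
            post = [0.0] * n
            for alt in Alternative:
                res = wilcoxon_signed_rank(pre, post, alt)
                w_o, p_o = wilcoxon_exact_oracle(d, alt.value.replace("_", "-"))
                assert res.p_value == pytest.approx(p_o, abs=1e-12)


class TestEffectSizes:
    def test_cliff_delta_example(self):
        assert cliff_delta([1, 2], [2, 3]) == pytest.approx(-0.75)

    def test_cliff_delta_bounds_and_extremes(self):
        assert cliff_delta([10, 11], [1, 2]) == 1.0
        assert cliff_delta([1, 2], [10, 11]) == -1.0
        assert cliff_delta([3], [3]) == 0.0

    def test_cliff_delta_matches_pairwise_definition(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.integers(0, 10, size=rng.integers(1, 8)).tolist()
            y = rng.integers(0, 10, size=rng.integers(1, 8)).tolist()
            assert cliff_delta(x, y) == pytest.approx(cliff_delta_oracle(x, y))

    def test_cliff_delta_u_identity(self):
        """delta = 2U/(nm) - 1 for tie-free samples."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, m = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            x, y = tie_free_samples(rng, n, m)
            u = mann_whitney_u(x, y).statistic
            assert cliff_delta(x, y) == pytest.approx(2 * u / (n * m) - 1)

    def test_welch_cohen_d_example(self):
        res = welch_t_and_cohen_d([1, 2, 3], [2, 3, 4])
        assert res.effect_size == pytest.approx(-1.0)
        assert res.effect_size_kind == "cohen_d"
        assert 0 < res.p_value < 1

    def test_welch_degenerate_equal_constants(self):
        res = welch_t_and_cohen_d([2, 2], [2, 2])
        assert res.degenerate and res.p_value == 1.0

    def test_welch_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            welch_t_and_cohen_d([1, 1], [2, 2])


class TestHolm:
    def test_holm_monotone_and_bounded(self):
        ps = [0.01, 0.04, 0.03, 0.9]
        adj = holm_correction(ps)
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= p for a, p in zip(adj, ps))
        # smallest raw p gets the full multiplicity factor
        assert adj[0] == pytest.approx(0.04)

    def test_holm_single_p_unchanged(self):
        assert holm_correction([0.2]) == [pytest.approx(0.2)]


# ---------------------------------------------------------------------------
# experiment-table analyses
# ---------------------------------------------------------------------------


def _toy_table() -> pd.DataFrame:
    rng = np.random.default_rng(0)
    rows = []
    for i in range(24):
        arm = "adapted" if i < 12 else "random"
        k6_pre = int(rng.integers(5, 15))
        drop = 4 if arm == "adapted" else 1
        k6_post = max(0, k6_pre - drop + int(rng.integers(0, 2)))
        mood_pre = 10 + k6_pre * 4
        mood_post = max(1, mood_pre - drop * 6)
        delivered = int(rng.integers(1, 22))
        estimated = delivered if i % 3 else max(1, delivered - 1)
        dets = [
            {"label": "distressed" if j + 1 < estimated else "nondistressed"}
            for j in range(delivered)
        ]
        rows.append(
            dict(
                participant_id=f"p{i}", arm=arm,
                k6_pre=k6_pre, k6_post=k6_post,
                mood_pre=mood_pre, mood_post=mood_post,
                stai_s_pre=int(rng.integers(35, 60)),
                stai_s_post=int(rng.integers(25, 50)),
                cci=int(rng.integers(0, 31)),
                delivered_questions=delivered,
                estimated_questions=estimated,
                detections=dets,
            )
        )
    return pd.DataFrame(rows)


class TestSubgroups:
    def test_assignment_rules(self):
        assert assign_subgroup(5, 5) == "same"
        assert assign_subgroup(3, 5) == "fewer"
        assert assign_subgroup(7, 5) == "more"
        assert assign_subgroup(3, CENSORED) == "fewer"

    def test_percentages_from_printed_counts(self):
        """Counts 28/7/14 give the 57%/14%/29% percentage row."""
        rows = []
        for grp, n in (("same", 28), ("fewer", 7), ("more", 14)):
            for _ in range(n):
                delivered = 5
                est = {"same": 5, "fewer": 9, "more": 2}[grp]
                rows.append(
                    dict(arm="adapted", k6_pre=8, k6_post=4, mood_pre=50,
                         mood_post=30, stai_s_pre=40, stai_s_post=35, cci=10,
                         delivered_questions=delivered,
                         estimated_questions=est, detections=[])
                )
        table = pd.DataFrame(rows)
        summary = subgroup_analysis(table)["summary"]
        pct = dict(zip(summary["subgroup"], summary["percent"]))
        assert round(pct["same"]) == 57
        assert round(pct["fewer"]) == 14
        assert round(pct["more"]) == 29
        assert summary["n"].sum() == 49

    def test_empty_subgroup_tests_are_skipped_not_fabricated(self):
        table = _toy_table()
        table["estimated_questions"] = table["delivered_questions"]  # all same
        out = subgroup_analysis(table)
        tests = out["tests"]
        assert tests["skipped"].all()
        assert (out["summary"].set_index("subgroup").loc["more", "n"]) == 0

    def test_full_battery_shapes(self):
        table = _toy_table()
        ch = change_summary(table)
        assert list(ch["metric"]) == [
            "change_in_distress", "cognitive_change", "mood_change",
            "change_in_stai_s",
        ]
        assert ((ch["p_value"] >= 0) & (ch["p_value"] <= 1)).all()
        cond = condition_summary(table)
        assert set(cond["measure"]) == {"k6", "mood", "stai_s"}


class TestPerQuestion:
    def test_missing_counts_reported_not_available(self):
        table = _toy_table()
        # force: nobody in the random arm got exactly 21 questions;
        # exactly one participant got 1 question
        rnd_idx = table.index[table["arm"] == "random"]
        table.loc[rnd_idx, "delivered_questions"] = 5
        table.loc[rnd_idx[0], "delivered_questions"] = 1
        table["detections"] = [
            [{"label": "distressed"}] * d for d in table["delivered_questions"]
        ]
        by_count = per_question_summaries(table)["by_count"].set_index("n_questions")
        assert by_count.loc[21, "n"] == 0
        assert math.isnan(by_count.loc[21, "change_in_distress_mean"])
        assert by_count.loc[1, "n"] == 1  # single participant: mean printed,
        assert not math.isnan(by_count.loc[1, "change_in_distress_mean"])
        assert math.isnan(by_count.loc[1, "change_in_distress_sd"])  # SD n/a

    def test_detection_counts_per_question_index(self):
        table = _toy_table().iloc[:2].copy()
        table["detections"] = [
            [{"label": "distressed"}, {"label": "nondistressed"}],
            [{"label": "distressed"}],
        ]
        table["delivered_questions"] = [2, 1]
        det = per_question_summaries(table)["detections"].set_index("question_index")
        assert det.loc[1, "distressed"] == 2
        assert det.loc[2, "nondistressed"] == 1
        assert det.loc[3, "distressed"] == 0 and det.loc[3, "nondistressed"] == 0
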