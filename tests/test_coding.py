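"""Consensus coding, mind-brain scores, prevalence, and Cohen's kappa."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import painattrib as pa
from painattrib.coding import round_percent

CB = pa.DEFAULT_CODEBOOK


def codings_frame(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "timepoint", "rank", "coder_id", "category"]
    )


# --------------------------------------------------------------------------
# consensus


class TestConsensus:
    def test_agreement_passes_through(self):
        cod = codings_frame(
            [("p1", "pre", 1, "a", "stress"), ("p1", "pre", 1, "b", "stress")]
        )
        consensus, disagreements = pa.consensus_assignments(cod)
        assert consensus["category"].tolist() == ["stress"]
        assert disagreements.empty

    def test_disagreement_is_listed_and_blocks_scoring(self):
        cod = codings_frame(
            [("p1", "pre", 1, "a", "injury"), ("p1", "pre", 1, "b", "psychological")]
        )
        consensus, disagreements = pa.consensus_assignments(cod)
        assert len(disagreements) == 1
        assert consensus["category"].isna().all()
        with pytest.raises(ValueError, match="unresolved"):
            pa.mind_brain_score(consensus, CB)

    def test_resolution_table_settles_disagreement(self):
        cod = codings_frame(
            [("p1", "pre", 1, "a", "injury"), ("p1", "pre", 1, "b", "psychological")]
        )
        res = pd.DataFrame(
            [("p1", "pre", 1, "injury")],
            columns=["participant_id", "timepoint", "rank", "category"],
        )
        consensus, disagreements = pa.consensus_assignments(cod, resolutions=res)
        assert consensus["category"].tolist() == ["injury"]
        assert len(disagreements) == 1  # still reported

    def test_single_coder_warns_with_count(self):
        cod = codings_frame([("p1", "pre", 1, "a", "stress")])
        with pytest.warns(UserWarning, match="1 attribution"):
            consensus, _ = pa.consensus_assignments(cod, require_two_coders=True)
        assert consensus["category"].tolist() == ["stress"]

    def test_disagreement_rate_matches_engineered_fixture(self):
        """891 codings with 38 engineered disagreements report 4%."""
        rows = []
        k = 0
        for pid in range(297):
            for rank in (1, 2, 3):
                cat_a = CB.categories[(pid + rank) % 11]
                cat_b = cat_a
                if k < 38:
                    cat_b = CB.categories[(pid + rank + 1) % 11]
                    k += 1
                rows.append((f"p{pid}", "pre", rank, "a", cat_a))
                rows.append((f"p{pid}", "pre", rank, "b", cat_b))
        n_dis, n_attr, pct = pa.disagreement_rate(codings_frame(rows))
        assert (n_dis, n_attr) == (38, 891)
        assert pct == 4


# --------------------------------------------------------------------------
# mind-brain scores


def consensus_frame(cats_by_pid, timepoint="pre"):
    rows = []
    for pid, cats in cats_by_pid.items():
        for rank, cat in enumerate(cats, start=1):
            rows.append((pid, timepoint, rank, cat))
    return pd.DataFrame(rows, columns=["participant_id", "timepoint", "rank", "category"])


class TestMindBrainScore:
    @pytest.mark.parametrize(
        "cats,expected",
        [
            (["stress", "injury", "activity"], 1),
            (["stress", "psychological", "brain"], 3),
            (["injury", "activity", "age"], 0),
        ],
    )
    def test_count_definition(self, cats, expected):
        scores = pa.mind_brain_score(consensus_frame({"p1": cats}), CB)
        assert scores["score"].tolist() == [expected]

    def test_rank_order_invariance(self):
        a = pa.mind_brain_score(consensus_frame({"p": ["stress", "injury", "brain"]}), CB)
        b = pa.mind_brain_score(consensus_frame({"p": ["brain", "stress", "injury"]}), CB)
        assert a["score"].tolist() == b["score"].tolist()

    def test_more_than_three_rejected(self):
        frame = consensus_frame({"p1": ["stress", "injury", "activity"]})
        extra = pd.DataFrame(
            [("p1", "pre", 4, "age")], columns=frame.columns
        )
        with pytest.raises(ValueError, match="more than 3"):
            pa.mind_brain_score(pd.concat([frame, extra]), CB)

    def test_paper_scale_baseline_mean(self):
        """151 participants with exactly 41 mind-brain attributions: mean 0.27."""
        cats_by_pid = {}
        mb = ["stress"] * 30 + ["psychological"] * 10 + ["brain"] * 1
        for i in range(151):
            cats = ["activity", "injury", "physiological"]
            if i < 41:
                cats[0] = mb[i]
            cats_by_pid[f"p{i:03d}"] = cats
        scores = pa.mind_brain_score(consensus_frame(cats_by_pid), CB)
        assert len(scores) == 151
        assert scores["score"].sum() == 41
        assert round(scores["score"].mean(), 2) == 0.27
        assert scores["score"].median() == 0


# --------------------------------------------------------------------------
# prevalence


class TestPrevalence:
    def test_paper_pretreatment_percents(self):
        """Printed counts over 453 attributions reproduce printed percents."""
        spread = (
            ["activity"] * 111 + ["injury"] * 85 + ["physiological"] * 71
            + ["stress"] * 30 + ["psychological"] * 10 + ["brain"] * 1
            + ["spinal_condition"] * 60 + ["sedentariness"] * 40
            + ["hereditary_congenital"] * 20 + ["age"] * 15 + ["neglect"] * 10
        )
        assert len(spread) == 453
        cats_by_pid = {
            f"p{i:03d}": spread[3 * i : 3 * i + 3] for i in range(151)
        }
        table = pa.prevalence_table(consensus_frame(cats_by_pid), CB)
        pct = dict(zip(table["category"], table["percent"]))
        assert pct["activity"] == 25
        assert pct["injury"] == 19
        assert pct["physiological"] == 16
        assert pct["stress"] == 7
        assert pct["psychological"] == 2
        assert pct["brain"] == 0.2
        assert table["count"].sum() == 453

    def test_counts_sum_and_percents_sum(self, small_trial):
        _, dataset, truth = small_trial
        consensus = truth.categories
        table = pa.prevalence_table(consensus, CB)
        assert table["count"].sum() == len(consensus)
        assert abs(table["percent_exact"].sum() - 100.0) < 1e-9
        assert abs(table["percent"].sum() - 100.0) <= 0.5 * 11  # rounding slack

    def test_single_category_group(self):
        table = pa.prevalence_table(consensus_frame({"p": ["age", "age", "age"]}), CB)
        pct = dict(zip(table["category"], table["percent"]))
        assert pct["age"] == 100
        assert sum(v for k, v in pct.items() if k != "age") == 0

    def test_grouped_by_arm_and_timepoint(self, small_trial):
        _, dataset, truth = small_trial
        table = pa.prevalence_table(
            truth.categories, CB, group_by=["arm", "timepoint"],
            participants=dataset.participants,
        )
        grp = table.groupby(["arm", "timepoint"])["count"].sum()
        assert set(grp.index.get_level_values("arm")) == {"prt", "placebo", "usual_care"}

    def test_rounding_convention(self):
        assert round_percent(24.50) == 25
        assert round_percent(18.76) == 19
        assert round_percent(0.2207) == 0.2
        assert round_percent(0.0) == 0.0
        assert round_percent(1.5) == 2


# --------------------------------------------------------------------------
# Cohen kappa


def kappa_oracle(table):
    """Independent brute-force kappa with Fleiss-Cohen-Everitt variances."""
    table = np.asarray(table, float)
    n = table.sum()
    p = table / n
    row, col = p.sum(1), p.sum(0)
    po = np.trace(p)
    pe = float(row @ col)
    kappa = (po - pe) / (1 - pe)
    k = len(row)
    t1 = sum(p[i, i] * ((1 - pe) - (col[i] + row[i]) * (1 - po)) ** 2 for i in range(k))
    t2 = (1 - po) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(k) for j in range(k) if i != j
    )
    t3 = (po * pe - 2 * pe + po) ** 2
    var = (t1 + t2 - t3) / (n * (1 - pe) ** 4)
    var0 = (pe + pe**2 - sum(row[i] * col[i] * (row[i] + col[i]) for i in range(k))) / (
        n * (1 - pe) ** 2
    )
    return kappa, var, var0


class TestCohenKappa:
    def test_perfect_agreement(self):
        res = pa.cohen_kappa(["a", "b", "a", "c"], ["a", "b", "a", "c"])
        assert res.kappa == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        """Contingency [[45,5],[15,35]]: p_o=0.80, p_e=0.50, kappa=0.60."""
        a = ["x"] * 50 + ["y"] * 50
        b = ["x"] * 45 + ["y"] * 5 + ["x"] * 15 + ["y"] * 35
        res = pa.cohen_kappa(a, b)
        assert res.kappa == pytest.approx(0.60)
        k, v, v0 = kappa_oracle(res.table)
        assert res.kappa == pytest.approx(k)
        assert res.se == pytest.approx(np.sqrt(v))
        assert res.se0 == pytest.approx(np.sqrt(v0))
        assert res.ci_low == pytest.approx(k - 1.96 * np.sqrt(v))
        assert res.z == pytest.approx(k / np.sqrt(v0))

    def test_independent_raters_near_zero(self, rng):
        a = rng.integers(0, 4, size=10_000)
        b = rng.integers(0, 4, size=10_000)
        res = pa.cohen_kappa(a, b)
        assert abs(res.kappa) < 0.05

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_oracle_equivalence_random_tables(self, seed):
        r = np.random.default_rng(seed)
        a = r.integers(0, 3, size=40)
        b = np.where(r.random(40) < 0.6, a, r.integers(0, 3, size=40))
        res = pa.cohen_kappa(a, b, levels=[0, 1, 2])
        k, v, v0 = kappa_oracle(res.table)
        assert res.kappa == pytest.approx(k, abs=1e-12)
        assert res.se == pytest.approx(np.sqrt(v), abs=1e-12)
        assert res.se0 == pytest.approx(np.sqrt(v0), abs=1e-12)

    def test_symmetry_and_relabeling_invariance(self):
        r = np.random.default_rng(7)
        a = r.integers(0, 3, size=60)
        b = np.where(r.random(60) < 0.5, a, r.integers(0, 3, size=60))
        k_ab = pa.cohen_kappa(a, b, levels=[0, 1, 2]).kappa
        k_ba = pa.cohen_kappa(b, a, levels=[0, 1, 2]).kappa
        assert k_ab == pytest.approx(k_ba)
        perm = {0: "z", 1: "m", 2: "q"}
        k_perm = pa.cohen_kappa(
            [perm[v] for v in a], [perm[v] for v in b], levels=["m", "q", "z"]
        ).kappa
        assert k_perm == pytest.approx(k_ab)

    def test_degenerate_identical_constant_raters(self):
        with pytest.raises(ValueError, match="p_e = 1"):
            pa.cohen_kappa(["a"] * 10, ["a"] * 10)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            pa.cohen_kappa(["a"], ["a", "b"])
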