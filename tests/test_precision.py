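import numpy as np
import pandas as pd
import pytest

from gazehmm import (
    BoundsError,
    GaussianHMM,
    TouchEvent,
    aoi_label_of,
    aoi_labels_of,
    classify_fixations,
    distractor_states,
    link_states_to_aois,
    overlap_matrix,
    precision_scores,
    score_touches,
)
from gazehmm.hmm import FitResult
from gazehmm.precision import OverlapMatrix
from conftest import make_sequence


def _fit_of(model, n_obs=100):
    return FitResult(model=model, log_likelihood=-1.0, loglik_trace=[-1.0],
                     n_iterations=1, converged=True, seed=0, n_observations=n_obs)


@pytest.fixture
def two_state_model():
    return GaussianHMM(
        pi=[0.5, 0.5], A=[[0.5, 0.5], [0.5, 0.5]],
        means=[[100.0, 100.0], [800.0, 500.0]], covars=np.full((2, 2), 100.0),
    )


class TestClassification:
    def test_separated_states_assigned_correctly(self, two_state_model, rng):
        near0 = rng.normal([100, 100], 10, (20, 2))
        seq = make_sequence(near0, image="toy")
        out = classify_fixations(_fit_of(two_state_model), [seq])
        assert (out["state"] == 0).all()

    def test_single_state_all_zero(self, rng):
        m = GaussianHMM(pi=[1.0], A=[[1.0]], means=[[0, 0]], covars=[[25.0, 25.0]])
        seq = make_sequence(rng.uniform(0, 50, (15, 2)))
        out = classify_fixations(_fit_of(m), [seq])
        assert (out["state"] == 0).all()

    def test_exhaustive_and_disjunctive(self, two_state_model, rng):
        seqs = [make_sequence(rng.uniform(0, 900, (30, 2)), subject=f"s{i}")
                for i in range(3)]
        for mode in ("posterior_argmax", "viterbi"):
            out = classify_fixations(_fit_of(two_state_model), seqs, mode=mode)
            assert len(out) == 90  # one state per fixation, none dropped
            assert out["state"].isin([0, 1]).all()


class TestAOILabels:
    def test_polygon_centroid_label(self, toy_aoiset):
        assert aoi_label_of((900, 300), toy_aoiset) == "P2"

    def test_white_space(self, toy_aoiset):
        assert aoi_label_of((600, 100), toy_aoiset) == "WS"

    def test_vertex_counts_as_inside(self, toy_aoiset):
        assert aoi_label_of((150, 50), toy_aoiset) == "T1"  # corner of T1

    def test_outside_canvas_raises(self, toy_aoiset):
        with pytest.raises(BoundsError):
            aoi_label_of((1500, 100), toy_aoiset)
        with pytest.raises(BoundsError):
            aoi_labels_of(np.array([10.0, -1.0]), np.array([10.0, 10.0]), toy_aoiset)


class TestOverlapMatrix:
    def test_all_one_state_one_aoi(self, toy_aoiset, rng):
        xy = rng.uniform([860, 60], [940, 140], (10, 2))  # inside P1
        assignment = pd.DataFrame(
            {"subject_id": "s1", "image_id": "toy", "fixation_index": range(10),
             "x": xy[:, 0], "y": xy[:, 1], "state": 2}
        )
        m = overlap_matrix(assignment, toy_aoiset, n_states=3)
        assert m.counts.loc[2, "P1"] == 10
        assert m.grand_total == 10
        assert (m.counts.to_numpy().sum(axis=None) - m.counts.loc[2, "P1"]) == 0

    def test_matches_per_fixation_count(self, toy_aoiset, rng):
        pts = np.array(
            [[900, 100], [900, 300], [900, 500], [200, 100], [200, 300], [500, 450],
             [600, 100], [10, 10], [900, 100], [200, 300], [500, 450], [600, 200]],
            dtype=float,
        )
        states = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2, 0, 1, 2])
        assignment = pd.DataFrame(
            {"subject_id": "s1", "image_id": "toy", "fixation_index": range(12),
             "x": pts[:, 0], "y": pts[:, 1], "state": states}
        )
        m = overlap_matrix(assignment, toy_aoiset, n_states=3)
        # brute-force recount
        expected = {}
        for (x, y), s in zip(pts, states):
            lab = aoi_label_of((x, y), toy_aoiset)
            expected[(s, lab)] = expected.get((s, lab), 0) + 1
        for (s, lab), cnt in expected.items():
            assert m.counts.loc[s, lab] == cnt
        assert m.grand_total == 12
        np.testing.assert_array_equal(
            m.state_totals.to_numpy(), np.bincount(states, minlength=3)
        )


class TestLinkage:
    def _matrix(self, data, labels=("P1", "P2", "P3", "T1", "T2", "T3", "WS")):
        return OverlapMatrix(counts=pd.DataFrame(data, columns=list(labels)))

    def test_argmax_per_column(self):
        m = self._matrix([[0, 0, 0, 0, 0, 2, 5],
                          [0, 0, 0, 0, 0, 9, 1],
                          [3, 1, 1, 1, 4, 0, 0]])
        linkage = link_states_to_aois(m)
        assert linkage["T3"] == 1
        assert linkage["P1"] == 2

    def test_many_to_one_primes_share_a_state(self):
        # one diffuse state dominates all three primes
        m = self._matrix([[8, 7, 9, 0, 0, 0, 3],
                          [1, 2, 0, 6, 5, 4, 2]])
        linkage = link_states_to_aois(m)
        assert linkage["P1"] == linkage["P2"] == linkage["P3"] == 0

    def test_tie_goes_to_lower_state(self):
        m = self._matrix([[4, 0, 0, 0, 0, 0, 0],
                          [2, 1, 1, 1, 1, 1, 0],
                          [4, 0, 0, 0, 0, 0, 0]])
        assert link_states_to_aois(m)["P1"] == 0

    def test_empty_aoi_undefined_and_distractors_reported(self):
        m = self._matrix([[5, 0, 3, 1, 1, 1, 0],
                          [0, 0, 2, 4, 4, 4, 9]])
        linkage = link_states_to_aois(m)
        assert linkage["P2"] is None
        m2 = self._matrix([[5, 2, 3, 1, 1, 1, 0],
                          [0, 0, 0, 0, 0, 0, 9]])
        linkage2 = link_states_to_aois(m2)
        assert distractor_states(m2, linkage2) == [1]


class TestPrecision:
    def test_seven_of_ten(self):
        m = OverlapMatrix(counts=pd.DataFrame(
            [[7, 0, 0, 0, 0, 0, 3]], columns=["P1", "P2", "P3", "T1", "T2", "T3", "WS"]
        ))
        table = precision_scores(m, {"P1": 0}, group="g", image_id="i")
        assert table.iloc[0]["precision_percent"] == pytest.approx(70.0)

    def test_upper_bound_attained(self):
        m = OverlapMatrix(counts=pd.DataFrame(
            [[10, 0, 0, 0, 0, 0, 0]], columns=["P1", "P2", "P3", "T1", "T2", "T3", "WS"]
        ))
        table = precision_scores(m, {"P1": 0})
        assert table.iloc[0]["precision_percent"] == 100.0

    def test_per_subject_zero_denominator_flagged(self, toy_aoiset):
        assignment = pd.DataFrame(
            {"subject_id": ["a"] * 4 + ["b"] * 4,
             "image_id": "toy", "fixation_index": list(range(4)) * 2,
             "x": [900.0] * 4 + [200.0] * 4, "y": [100.0] * 4 + [100.0] * 4,
             "state": [0] * 4 + [1] * 4}
        )
        m = overlap_matrix(assignment, toy_aoiset, n_states=2)
        linkage = link_states_to_aois(m)
        table = precision_scores(
            m, linkage, per_subject=True, assignment=assignment, aoiset=toy_aoiset
        )
        # subject b never visits state 0 (linked to P1): precision 0, flagged
        row = table.query("subject_id == 'b' and aoi_label == 'P1'").iloc[0]
        assert row["precision_percent"] == 0.0 and row["flagged"] == 1

    def test_group_equals_weighted_subject_aggregation(self, toy_aoiset, rng):
        n = 60
        xy = np.column_stack(
            [rng.uniform(0, 1000, n), rng.uniform(0, 600, n)]
        )
        assignment = pd.DataFrame(
            {"subject_id": rng.choice(["a", "b", "c"], n), "image_id": "toy",
             "fixation_index": range(n), "x": xy[:, 0], "y": xy[:, 1],
             "state": rng.integers(0, 3, n)}
        )
        m = overlap_matrix(assignment, toy_aoiset, n_states=3)
        linkage = link_states_to_aois(m)
        group_tab = precision_scores(m, linkage)
        subj_tab = precision_scores(
            m, linkage, per_subject=True, assignment=assignment, aoiset=toy_aoiset
        )
        for aoi in group_tab["aoi_label"]:
            g = group_tab.query("aoi_label == @aoi").iloc[0]
            s = subj_tab.query("aoi_label == @aoi")
            assert s["n_in_aoi"].sum() == g["n_in_aoi"]
            assert s["n_state_fixations"].sum() == g["n_state_fixations"]

    @pytest.mark.parametrize("seed", range(5))
    def test_structured_beats_shuffled_null(self, toy_aoiset, seed):
        """States generated inside their AOIs score higher precision than a
        label-permuted null assignment."""
        rng = np.random.default_rng(seed)
        centers = {0: (900, 100), 1: (900, 300), 2: (200, 100)}
        rows = []
        for s, c in centers.items():
            pts = rng.normal(c, 20, (40, 2))
            pts[:, 0] = pts[:, 0].clip(0, 1000)
            pts[:, 1] = pts[:, 1].clip(0, 600)
            for x, y in pts:
                rows.append({"subject_id": "a", "image_id": "toy",
                             "fixation_index": len(rows), "x": x, "y": y, "state": s})
        assignment = pd.DataFrame(rows)
        m = overlap_matrix(assignment, toy_aoiset, n_states=3)
        linkage = link_states_to_aois(m)
        structured = precision_scores(m, linkage)
        shuffled = assignment.assign(state=rng.permutation(assignment["state"].to_numpy()))
        m0 = overlap_matrix(shuffled, toy_aoiset, n_states=3)
        null = precision_scores(m0, link_states_to_aois(m0))
        merged = structured.merge(null, on="aoi_label", suffixes=("", "_null"))
        assert (merged["precision_percent"] > merged["precision_percent_null"]).all()
        assert structured["precision_percent"].between(0, 100).all()


class TestTouchScoring:
    def test_exact_center_and_inclusive_boundary(self, toy_aoiset):
        t1 = toy_aoiset["T1"].center
        events = [
            TouchEvent("a", "toy", t1[0], t1[1], 100.0),          # dead center
            TouchEvent("b", "toy", t1[0] + 50.0, t1[1], 100.0),   # exactly 50 px
            TouchEvent("c", "toy", t1[0] + 50.1, t1[1], 100.0),   # just outside
        ]
        scores = score_touches(events, toy_aoiset)
        by = scores.set_index("subject_id")
        assert by.loc["a", "hit_T1"] == 1
        assert by.loc["b", "hit_T1"] == 1
        assert by.loc["c", "hit_T1"] == 0

    def test_three_distinct_targets_score_three(self, toy_aoiset):
        events = [
            TouchEvent("a", "toy", *toy_aoiset[lab].center, time_ms=i * 100.0)
            for i, lab in enumerate(["T1", "T2", "T3"])
        ]
        scores = score_touches(events, toy_aoiset)
        assert scores.iloc[0]["n_identified"] == 3

    def test_repeated_touches_count_once(self, toy_aoiset):
        c = toy_aoiset["T2"].center
        events = [TouchEvent("a", "toy", c[0] + dx, c[1], 100.0) for dx in (0, 5, -5)]
        scores = score_touches(events, toy_aoiset)
        assert scores.iloc[0]["n_identified"] == 1
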