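import numpy as np
import pytest

import brainstates as bs


def seq(labels, K=4, bounds=(0,)):
    return bs.StateSequence(np.asarray(labels), K=K, run_boundary_index=list(bounds))


def forced_post_boundary_sequence(T, boundaries, forced_state, forced_len, K, seed):
    """Random occupancy except `forced_state` for `forced_len` TRs after each boundary."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, K, size=T)
    for b in boundaries:
        labels[b : b + forced_len] = forced_state
    return labels


class TestBoundaryAlignedOccurrence:
    def test_single_boundary_raw_indicators(self):
        labels = np.array([0, 0, 1, 1, 2, 2, 3, 3, 0, 0])
        out = bs.boundary_aligned_occurrence(
            seq(labels), bs.EventBoundaries([4], ["A", "B"]), window=(-2, 3)
        )
        assert out.n_boundaries == 1
        for i, off in enumerate(out.offsets):
            k = labels[4 + off]
            assert out.per_state_prob[k, i] == 1.0
            assert out.per_state_prob[:, i].sum() == pytest.approx(1.0)

    def test_fully_occupied_state_probability_one(self):
        out = bs.boundary_aligned_occurrence(
            seq(np.full(60, 2)), bs.EventBoundaries([20, 40], ["A", "B", "A"])
        )
        valid = np.isfinite(out.per_state_prob[2])
        assert np.all(out.per_state_prob[2][valid] == 1.0)

    def test_out_of_range_offsets_dropped_per_boundary(self):
        labels = np.arange(30) % 4
        out = bs.boundary_aligned_occurrence(
            seq(labels), bs.EventBoundaries([25], ["A", "B"]), window=(-2, 20)
        )
        # offsets beyond the run end (25+5 ≥ 30) have no data
        far = out.offsets >= 5
        assert np.all(np.isnan(out.per_state_prob[:, far]))

    def test_forced_post_boundary_state_detected(self):
        boundaries = np.array([50, 120, 200, 270, 340])
        labels = forced_post_boundary_sequence(400, boundaries, 1, 10, K=4, seed=0)
        out = bs.boundary_aligned_occurrence(
            seq(labels), bs.EventBoundaries(boundaries, list("ABABAB")), window=(-2, 20)
        )
        inside = (out.offsets >= 0) & (out.offsets < 10)
        outside = out.offsets < 0
        assert np.all(out.per_state_prob[1, inside] == 1.0)
        assert np.nanmean(out.per_state_prob[1, outside]) < 0.6

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(1)
        out = bs.boundary_aligned_occurrence(
            seq(rng.integers(0, 4, 300)),
            bs.EventBoundaries([40, 90, 160, 230], list("ABABA")),
        )
        valid = np.isfinite(out.per_state_prob).all(axis=0)
        np.testing.assert_allclose(out.per_state_prob[:, valid].sum(axis=0), 1.0)


class TestBoundaryOccurrenceNull:
    def test_power_for_forced_state(self):
        boundaries = np.array([60, 140, 220, 300, 380, 460])
        seqs = [
            seq(forced_post_boundary_sequence(540, boundaries, 2, 10, 4, seed=i))
            for i in range(8)
        ]
        ev = bs.EventBoundaries(boundaries, list("ABABABA"))
        res = bs.boundary_occurrence_null(seqs, ev, n_iter=200, seed=3, q=0.05)
        inside = (np.arange(-2, 21) >= 0) & (np.arange(-2, 21) < 10)
        assert res["reject"][2, inside].mean() > 0.8

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        s = seq(rng.integers(0, 4, 200))
        ev = bs.EventBoundaries([50, 120], ["A", "B", "A"])
        a = bs.boundary_occurrence_null(s, ev, n_iter=50, seed=5)
        b = bs.boundary_occurrence_null(s, ev, n_iter=50, seed=5)
        np.testing.assert_array_equal(a["p"], b["p"])


class TestBoundaryTransitionClassification:
    def test_no_boundaries_all_non_boundary(self):
        rng = np.random.default_rng(6)
        seqs = [seq(rng.integers(0, 4, 300)) for _ in range(4)]
        ev = bs.EventBoundaries([299], ["A", "B"])  # window 5..15 never lands
        res = bs.boundary_transition_classification(seqs, ev, target_state=0)
        assert np.all(np.isnan(np.asarray(res["boundary_proportions"])))

    def test_proportions_sum_to_one_per_class(self):
        rng = np.random.default_rng(7)
        boundaries = np.arange(40, 560, 60)
        seqs = [seq(rng.integers(0, 4, 600)) for _ in range(6)]
        ev = bs.EventBoundaries(boundaries, ["A", "B"] * 5)
        res = bs.boundary_transition_classification(seqs, ev, target_state=0)
        for arr in (res["boundary_proportions"], res["non_boundary_proportions"]):
            sums = np.nansum(arr, axis=1)
            ok = sums > 0
            np.testing.assert_allclose(sums[ok], 1.0)

    def test_boundary_specific_source_detected(self):
        # source state 1 feeds the target (3) only inside post-boundary windows
        rng = np.random.default_rng(8)
        boundaries = np.arange(50, 950, 100)
        seqs = []
        for i in range(8):
            labels = rng.integers(0, 3, size=1000)  # states 0..2 elsewhere
            for b in boundaries:
                labels[b + 6] = 1
                labels[b + 7] = 3  # 1→3 transition 7 TRs after boundary
                labels[b + 30] = 3  # non-boundary 3-entry from a random source
            seqs.append(seq(labels))
        ev = bs.EventBoundaries(boundaries, ["A", "B"] * 5)
        res = bs.boundary_transition_classification(seqs, ev, target_state=3, seed=9)
        i1 = res["sources"].index(1)
        assert np.all(
            res["boundary_proportions"][:, i1] > res["non_boundary_proportions"][:, i1]
        )
        assert res["fdr_p"][i1] < 0.05


class TestAttentionByState:
    def test_hand_counting(self):
        s = seq([0, 0, 1, 1, 2, 2, 0, 1, 2, 0], K=4)
        trace = bs.BehavioralTrace(np.arange(10.0), tr=1.0)
        out = bs.attention_by_state(trace, s)
        assert out[0] == pytest.approx((0 + 1 + 6 + 9) / 4)
        assert out[1] == pytest.approx((2 + 3 + 7) / 3)
        assert out[2] == pytest.approx((4 + 5 + 8) / 3)
        assert np.isnan(out[3])

    def test_constant_trace_no_state_significant(self):
        rng = np.random.default_rng(10)
        seqs = [seq(rng.integers(0, 4, 300)) for _ in range(5)]
        traces = [bs.BehavioralTrace(np.zeros(300) + 1.0, tr=1.0) for _ in range(5)]
        res = bs.attention_by_state_group(traces, seqs, n_iter=100, seed=11)
        assert np.allclose(res["means"], 1.0)
        assert not res["reject"].any()

    def test_power_for_single_state_effect(self, four_state_params):
        seqs, traces = [], []
        rng = np.random.default_rng(12)
        for i in range(8):
            _, s = bs.simulate_run(four_state_params, T=600, seed=int(rng.integers(2**31)))
            tr = bs.simulate_attention_trace(
                s, [1.0, 0, 0, 0], noise_sd=0.5, seed=int(rng.integers(2**31))
            )
            seqs.append(s)
            traces.append(tr)
        res = bs.attention_by_state_group(traces, seqs, n_iter=1000, seed=13, q=0.01)
        assert res["reject"][0]
        assert res["means"][0] > 0


class TestBlockwiseOccupancy:
    def test_single_block_equals_fractional_occupancy(self):
        rng = np.random.default_rng(14)
        s = seq(rng.integers(0, 4, 200))
        res = bs.blockwise_occupancy([s], [(0, 200, "task")])
        np.testing.assert_allclose(
            res["occupancy"]["task"][0], bs.fractional_occupancy(s)
        )

    def test_occupancies_sum_to_one_per_block_type(self):
        rng = np.random.default_rng(15)
        seqs = [seq(rng.integers(0, 4, 400)) for _ in range(4)]
        blocks = [(0, 100, "task"), (100, 150, "rest"), (150, 300, "task"), (300, 400, "rest")]
        res = bs.blockwise_occupancy(seqs, blocks)
        for lab in ("task", "rest"):
            np.testing.assert_allclose(res["occupancy"][lab].sum(axis=1), 1.0)

    def test_enrichment_detected(self):
        # state 3 heavily enriched during "rest" blocks
        rng = np.random.default_rng(16)
        blocks = [(0, 100, "task"), (100, 160, "rest"), (160, 260, "task"), (260, 320, "rest")]
        seqs = []
        for i in range(8):
            labels = rng.integers(0, 3, size=320)
            for a, b, lab in blocks:
                if lab == "rest":
                    mask = rng.random(b - a) < 0.7
                    labels[a:b][mask] = 3
            seqs.append(seq(labels))
        res = bs.blockwise_occupancy(seqs, blocks, seed=17)
        con = res["contrasts"][("rest", "task")]
        assert con["mean_diff"][3] > 0.4
        assert con["fdr_p"][3] < 0.05

    def test_overlapping_blocks_rejected(self):
        s = seq(np.zeros(50, dtype=int), K=1)
        with pytest.raises(ValueError, match="overlap"):
            bs.blockwise_occupancy([s], [(0, 30, "a"), (20, 50, "b")])


class TestSignPermutation:
    def test_exact_enumeration_small_n(self):
        # n=3, diffs all positive: only the all-positive flip attains |mean| ≥ obs
        # plus its mirror → p = 2/8
        p = bs.sign_permutation_test([1.0, 2.0, 3.0])
        assert p == pytest.approx(2.0 / 8.0)

    def test_null_differences_uniformish(self):
        rng = np.random.default_rng(18)
        ps = [
            bs.sign_permutation_test(rng.normal(size=10), seed=19) for _ in range(100)
        ]
        assert np.mean(np.asarray(ps) < 0.05) < 0.15

    def test_monte_carlo_branch_matches_exact_roughly(self):
        rng = np.random.default_rng(20)
        d = rng.normal(loc=0.8, size=16)
        p_exact = bs.sign_permutation_test(d, exact_limit=16)
        p_mc = bs.sign_permutation_test(d, exact_limit=8, n_perm=20000, seed=21)
        assert abs(p_exact - p_mc) < 0.01


class TestBoundaryWindow:
    def test_tr_scaling(self):
        assert bs.behavior_events.boundary_window_trs(1.0) == (5, 15)
        assert bs.behavior_events.boundary_window_trs(1.5) == (3, 10)
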