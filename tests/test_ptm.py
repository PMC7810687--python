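"""u-region extraction, backward merging and the PtM duration algebra.

The central identity: the span-minus-gaps formula for a merged run of
u-regions equals the sum of the merged regions' durations.
"""

import numpy as np
import pytest

from ptm.config import PtmConfig
from ptm.ptm_extract import (
    URegion,
    binarize_upwards,
    compute_ptm,
    extract_meal_ptm,
    extract_uregions,
    merge_backward,
)


def _regions(spans):
    return [URegion(s, e) for s, e in spans]


def _random_regions(rng, n):
    """n sorted, non-overlapping regions with random gaps."""
    t = rng.uniform(0, 0.5)
    out = []
    for _ in range(n):
        start = t + rng.uniform(0.05, 1.2)  # gap
        end = start + rng.uniform(0.1, 1.0)  # duration
        out.append(URegion(start, end))
        t = end
    return out


class TestBinarize:
    def test_direct_rule(self):
        np.testing.assert_array_equal(
            binarize_upwards(["p", "u", "u", "m", "d"]), [0, 1, 1, 0, 0])

    def test_all_idle_is_all_zero(self):
        np.testing.assert_array_equal(binarize_upwards(["n"] * 6), np.zeros(6))

    def test_matches_elementwise_comparison(self, rng):
        labs = rng.choice(list("pumdn"), size=200)
        np.testing.assert_array_equal(
            binarize_upwards(labs), (labs == "u").astype(int))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            binarize_upwards(["p", "x"])


class TestExtractURegions:
    def test_run_counting(self):
        y = np.array([0, 1, 1, 0, 1, 0])
        t = 0.05 + np.arange(6) * 0.1
        regions = extract_uregions(y, t, (0.0, 1.0), 0.1)
        assert len(regions) == 2
        assert regions[0].t_s == pytest.approx(0.1)
        assert regions[0].t_e == pytest.approx(0.3)
        assert regions[1].t_s == pytest.approx(0.4)
        assert regions[1].t_e == pytest.approx(0.5)

    def test_all_zeros_give_empty_list(self):
        t = np.arange(10) * 0.1
        assert extract_uregions(np.zeros(10, int), t, (0.0, 1.0), 0.1) == []

    def test_matches_run_length_encoding_oracle(self, rng):
        for _ in range(100):
            y = rng.integers(0, 2, size=50)
            t = 0.05 + np.arange(50) * 0.1
            regions = extract_uregions(y, t, (0.0, 5.0), 0.1)
            # RLE oracle
            runs = []
            start = None
            for i, v in enumerate(y):
                if v and start is None:
                    start = i
                if (not v or i == 49) and start is not None:
                    end = i if v else i - 1
                    runs.append((start, end))
                    start = None
            assert len(regions) == len(runs)
            for r, (a, b) in zip(regions, runs):
                assert r.t_s == pytest.approx(t[a] - 0.05)
                assert r.t_e == pytest.approx(t[b] + 0.05)

    def test_interval_selection_is_half_open(self):
        y = np.ones(10, int)
        t = np.arange(10) * 0.1  # 0.0 .. 0.9
        regions = extract_uregions(y, t, (0.0, 0.5), 0.1)
        assert len(regions) == 1
        assert regions[0].t_e == pytest.approx(0.45)  # frame at 0.5 excluded


class TestMergeBackward:
    def test_both_gaps_merge(self):
        tau_s, tau_e, j, gap_sum = merge_backward(
            _regions([(0.2, 0.5), (0.9, 1.3), (1.5, 2.0)]), 0.5)
        assert (tau_s, tau_e, j) == (0.2, 2.0, 2)
        assert gap_sum == pytest.approx(0.6)

    def test_first_gap_fails_stops_walk(self):
        tau_s, tau_e, j, gap_sum = merge_backward(
            _regions([(0.2, 0.5), (1.2, 1.5), (2.5, 3.0)]), 0.5)
        assert (tau_s, tau_e, j, gap_sum) == (2.5, 3.0, 0, 0.0)

    def test_single_region_nothing_to_merge(self):
        assert merge_backward(_regions([(1.0, 1.7)]), 0.5) == (1.0, 1.7, 0, 0.0)

    def test_tie_at_exactly_lambda_d_fails(self):
        # strict "< lambda_d": a gap of exactly 0.5 does not merge
        _, _, j, _ = merge_backward(_regions([(0.0, 0.5), (1.0, 1.5)]), 0.5)
        assert j == 0

    def test_unsorted_regions_rejected(self):
        with pytest.raises(ValueError):
            merge_backward(_regions([(1.0, 2.0), (0.5, 1.5)]), 0.5)

    def test_matches_exhaustive_merge_oracle(self, rng):
        for _ in range(200):
            regions = _random_regions(rng, int(rng.integers(1, 7)))
            lam = float(rng.uniform(0.05, 1.3))
            tau_s, tau_e, j, gap_sum = merge_backward(regions, lam)
            # oracle: walk indices backwards explicitly
            d = len(regions) - 1
            want_j, want_gaps = 0, 0.0
            while d > 0 and regions[d].t_s - regions[d - 1].t_e < lam:
                want_gaps += regions[d].t_s - regions[d - 1].t_e
                want_j += 1
                d -= 1
            assert j == want_j
            assert tau_s == pytest.approx(regions[d].t_s)
            assert tau_e == pytest.approx(regions[-1].t_e)
            assert gap_sum == pytest.approx(want_gaps)


class TestComputePtm:
    def test_unmerged_case_is_last_region_duration(self):
        rec = compute_ptm(2.5, 3.0, 0, 0.0, b_i=3.2, lambda_b=5.0)
        assert rec.ptm == pytest.approx(0.5)
        assert rec.status == "ok"

    def test_worked_merge_example(self):
        # three regions, last two merged (J=1), gap to the first too large:
        # PtM = tau_e - tau_s - d(r3, r2)
        regions = _regions([(0.2, 0.5), (1.9, 2.3), (2.6, 3.1)])
        tau_s, tau_e, j, gap_sum = merge_backward(regions, 0.5)
        assert j == 1
        rec = compute_ptm(tau_s, tau_e, j, gap_sum, b_i=3.3, lambda_b=5.0)
        assert rec.ptm == pytest.approx((3.1 - 1.9) - (2.6 - 2.3))

    def test_span_minus_gaps_equals_sum_of_durations(self):
        regions = _regions([(0.2, 0.5), (0.9, 1.3), (1.5, 2.0)])
        tau_s, tau_e, j, gap_sum = merge_backward(regions, 0.5)
        rec = compute_ptm(tau_s, tau_e, j, gap_sum, b_i=2.1, lambda_b=5.0)
        assert rec.ptm == pytest.approx(0.3 + 0.4 + 0.5)

    def test_identity_on_random_region_sets(self, rng):
        for _ in range(300):
            regions = _random_regions(rng, int(rng.integers(1, 8)))
            lam = float(rng.uniform(0.05, 1.3))
            tau_s, tau_e, j, gap_sum = merge_backward(regions, lam)
            rec = compute_ptm(tau_s, tau_e, j, gap_sum,
                              b_i=regions[-1].t_e, lambda_b=np.inf)
            merged = regions[len(regions) - 1 - j:]
            assert rec.ptm == pytest.approx(sum(r.duration for r in merged))

    def test_lambda_b_discard(self):
        rec = compute_ptm(1.0, 1.5, 0, 0.0, b_i=10.0, lambda_b=5.0)
        assert rec.status == "discarded_lambda_b"

    def test_invalid_gap_bookkeeping_rejected(self):
        with pytest.raises(ValueError):
            compute_ptm(1.0, 1.5, 0, 0.3, b_i=2.0, lambda_b=5.0)


class TestExtractMealPtm:
    def _frames(self, labels):
        t = 0.05 + np.arange(len(labels)) * 0.1
        return np.array(labels), t

    def test_no_bites_give_empty_set(self):
        y, t = self._frames(["u"] * 20)
        out = extract_meal_ptm(y, t, [], PtmConfig())
        assert out.records == []

    def test_one_record_per_interbite_interval(self):
        y, t = self._frames((["n"] * 10 + ["u"] * 5 + ["m"] * 5) * 3)
        out = extract_meal_ptm(y, t, [1.7, 3.7, 5.7], PtmConfig())
        assert len(out.records) == 3
        assert [r.interval_index for r in out.records] == [0, 1, 2]

    def test_interval_without_upwards_is_no_uregions(self):
        y, t = self._frames(["n"] * 20 + ["u"] * 5 + ["n"] * 15)
        out = extract_meal_ptm(y, t, [1.0, 3.5], PtmConfig())
        assert out.records[0].status == "no_uregions"
        assert out.records[1].status == "ok"
        assert out.u_prime == 1

    def test_lambda_d_zero_reduces_to_final_region_only(self, rng):
        labs = rng.choice(list("un"), size=100, p=[0.4, 0.6])
        y, t = self._frames(list(labs))
        bites = [4.0, 9.9]
        lax = extract_meal_ptm(y, t, bites, PtmConfig(lambda_d=0.0))
        for rec in lax.records:
            if rec.status == "ok":
                assert rec.J == 0
                assert rec.ptm == pytest.approx(rec.tau_e - rec.tau_s)

    def test_ptm_monotone_in_lambda_d(self, rng):
        labs = list(rng.choice(list("un"), size=200, p=[0.35, 0.65]))
        y, t = self._frames(labs)
        bites = [6.0, 13.0, 19.9]
        prev = None
        for lam in (0.0, 0.2, 0.5, 1.0, 3.0):
            out = extract_meal_ptm(y, t, bites, PtmConfig(lambda_d=lam))
            cur = {r.interval_index: r.ptm for r in out.records if r.status == "ok"}
            if prev is not None:
                for k, v in prev.items():
                    assert cur[k] >= v - 1e-12
            prev = cur

    def test_ok_durations_bounded_by_interval(self, rng):
        labs = list(rng.choice(list("un"), size=300, p=[0.3, 0.7]))
        y, t = self._frames(labs)
        bites = [5.0, 11.0, 18.0, 29.9]
        out = extract_meal_ptm(y, t, bites, PtmConfig())
        for rec in out.records:
            if rec.status == "ok":
                assert 0 < rec.ptm <= (rec.b_i - rec.b_prev) + 0.1  # frame-step slack

    def test_recovers_simulator_ground_truth(self):
        import ptm as pkg
        sim = pkg.simulate_label_sequence(pkg.preset("easy"), seed=77)
        out = extract_meal_ptm(np.array(sim.labels), sim.slot_times,
                               sim.annotations.gt_bites, PtmConfig())
        assert out.u_prime == len(sim.gt_ptm)
        np.testing.assert_allclose(sorted(out.durations), sorted(sim.gt_ptm), atol=0.2)
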