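"""Reverse minimal-shift mapping: weighting, gates, greedy matching."""

import math

import numpy as np
import pytest

from ligmap.csp import (
    GateSpec,
    compute_weight,
    filter_by_height,
    minimal_shift_profile,
    reverse_assign,
    weighted_distance,
)
from ligmap.peaks import Peak

W = 0.147
GATES = GateSpec(max_dh=0.1, max_dn=0.68, height_floor_fraction=0.05)


def pk(pid, h, n, height=1.0, assignment=None):
    return Peak(pid, h, n, height, assignment)


class TestWeight:
    def test_assigned_range_ratio(self):
        assert compute_weight(4.504, 30.616).weight == pytest.approx(0.147, abs=5e-4)

    @pytest.mark.parametrize("rh, rn, expected", [(1.0, 1.0, 1.0), (2.5, 12.5, 0.2)])
    def test_simple_ratios(self, rh, rn, expected):
        assert compute_weight(rh, rn).weight == pytest.approx(expected)

    @pytest.mark.parametrize("rh, rn", [(0, 1), (1, -2)])
    def test_nonpositive_ranges_rejected(self, rh, rn):
        with pytest.raises(ValueError):
            compute_weight(rh, rn)


class TestWeightedDistance:
    def test_coincident_peaks(self):
        assert weighted_distance(pk("a", 8, 120), pk("b", 8, 120), W) == 0.0

    def test_single_axis(self):
        d = weighted_distance(pk("a", 8.03, 120), pk("b", 8.0, 120), 0.5)
        assert d == pytest.approx(0.03)

    def test_hand_computed_combination(self):
        # dh=0.06, dn=0.5, w=0.147 -> sqrt(0.06^2 + 0.0735^2)
        d = weighted_distance(pk("a", 8.06, 120.5), pk("b", 8.0, 120.0), 0.147)
        assert d == pytest.approx(math.sqrt(0.06**2 + 0.0735**2), rel=1e-12)

    def test_symmetry(self):
        a, b = pk("a", 8.02, 121.3), pk("b", 7.95, 119.8)
        assert weighted_distance(a, b, W) == weighted_distance(b, a, W)


class TestHeightFilter:
    def test_strict_floor(self):
        peaks = [pk("a", 8, 120, 100), pk("b", 8.2, 121, 6), pk("c", 8.4, 122, 4)]
        kept, ref = filter_by_height(peaks, 0.05)
        assert [p.id for p in kept] == ["a", "b"]
        assert ref == "a"

    def test_zero_floor_keeps_all_nonzero(self):
        peaks = [pk("a", 8, 120, 10), pk("b", 8.2, 121, 0.01)]
        kept, _ = filter_by_height(peaks, 0.0)
        assert len(kept) == 2

    def test_all_zero_heights_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            filter_by_height([pk("a", 8, 120, 0.0)], 0.05)

    def test_against_comprehension_oracle(self):
        rng = np.random.default_rng(0)
        heights = rng.lognormal(0, 1, 500)
        peaks = [pk(f"p{i}", 8, 120, h) for i, h in enumerate(heights)]
        kept, _ = filter_by_height(peaks, 0.05)
        floor = 0.05 * heights.max()
        assert [p.id for p in kept] == [
            p.id for p in peaks if p.height > floor
        ]


def brute_force_greedy(free, bound, weight, gates):
    """Independent O(n^2 m) oracle: repeatedly take the closest gated pair."""
    pairs = []
    used_b, used_f = set(), set()
    while True:
        best = None
        for b in bound:
            if b.id in used_b:
                continue
            for f in free:
                if f.id in used_f:
                    continue
                if abs(b.shift_h - f.shift_h) > gates.max_dh:
                    continue
                if abs(b.shift_n - f.shift_n) > gates.max_dn:
                    continue
                d = math.hypot(b.shift_h - f.shift_h,
                               weight * (b.shift_n - f.shift_n))
                key = (d, b.id, f.id)
                if best is None or key < best:
                    best = key
        if best is None:
            return pairs
        d, bid, fid = best
        pairs.append((bid, fid, d))
        used_b.add(bid)
        used_f.add(fid)


def grid_peaklists(n, rng, scale_h=0.02, scale_n=0.15, dropout=0.0):
    """Well-separated bound grid + free copies perturbed within the gates."""
    bound, free = [], []
    for i in range(n):
        h = 7.0 + (i % 10) * 0.35
        nn = 106.0 + (i // 10) * 3.0
        bound.append(pk(f"b{i + 1}", h, nn, 100.0, f"A{i + 1}"))
        if rng.uniform() >= dropout:
            dh = rng.uniform(-scale_h, scale_h)
            dn = rng.uniform(-scale_n, scale_n)
            free.append(pk(f"f{i + 1}", h + dh, nn + dn, 90.0))
    return bound, free


class TestReverseAssign:
    def test_unique_nearest_neighbours(self):
        bound = [pk("b1", 8.0, 120.0, assignment="A1"),
                 pk("b2", 9.0, 125.0, assignment="A2")]
        free = [pk("f1", 8.02, 120.3), pk("f2", 9.05, 124.8)]
        mapping = reverse_assign(free, bound, W, GATES)
        assert mapping.as_dict() == {"b1": "f1", "b2": "f2"}

    def test_proton_gate_takes_precedence_over_distance(self):
        """A small weighted distance cannot rescue a peak past the 1H gate."""
        bound = [pk("b1", 8.00, 120.0, assignment="A1")]
        free = [pk("f1", 8.12, 120.0)]
        mapping = reverse_assign(free, bound, W, GATES)
        assert mapping.pairs == []
        assert mapping.unmatched_bound == ["b1"]
        assert mapping.unmatched_free == ["f1"]

    def test_empty_bound_list_rejected(self):
        with pytest.raises(ValueError):
            reverse_assign([pk("f1", 8, 120)], [], W, GATES)

    def test_no_gated_candidates_is_valid(self):
        mapping = reverse_assign([pk("f1", 10, 130)],
                                 [pk("b1", 7, 110, assignment="A1")], W, GATES)
        assert mapping.pairs == []

    def test_first_pair_is_global_minimum(self):
        rng = np.random.default_rng(21)
        bound, free = grid_peaklists(40, rng)
        mapping = reverse_assign(free, bound, W, GATES)
        all_pairs = [
            (weighted_distance(b, f, W), b.id, f.id)
            for b in bound for f in free
            if abs(b.shift_h - f.shift_h) <= GATES.max_dh
            and abs(b.shift_n - f.shift_n) <= GATES.max_dn
        ]
        assert (mapping.pairs[0].distance, mapping.pairs[0].bound_id,
                mapping.pairs[0].free_id) == min(all_pairs)

    def test_deterministic_tie_break(self):
        # two bound peaks exactly equidistant from two free peaks
        bound = [pk("b1", 8.0, 120.0, assignment="A1"),
                 pk("b2", 8.04, 120.0, assignment="A2")]
        free = [pk("f1", 8.02, 120.0), pk("f2", 8.02, 120.0)]
        mapping = reverse_assign(free, bound, W, GATES)
        assert mapping.as_dict() == {"b1": "f1", "b2": "f2"}

    @pytest.mark.parametrize("seed, n", [(1, 15), (2, 30), (3, 50)])
    def test_equivalence_with_brute_force_oracle(self, seed, n):
        """Global greedy equals the exhaustive min-pair oracle, dense lists."""
        rng = np.random.default_rng(seed)
        # dense random clouds: many cross-candidates inside the gates
        bound = [pk(f"b{i}", rng.uniform(7.9, 8.3), rng.uniform(118, 122),
                    100, f"A{i}") for i in range(n)]
        free = [pk(f"f{i}", rng.uniform(7.9, 8.3), rng.uniform(118, 122))
                for i in range(n)]
        mapping = reverse_assign(free, bound, W, GATES)
        oracle = brute_force_greedy(free, bound, W, GATES)
        assert [(p.bound_id, p.free_id) for p in mapping.pairs] == [
            (b, f) for b, f, _ in oracle
        ]

    def test_ground_truth_recovery_with_dropout(self):
        """Unique-neighbour lists with 30% dropout: every survivor correct."""
        rng = np.random.default_rng(42)
        bound, free = grid_peaklists(60, rng, dropout=0.3)
        mapping = reverse_assign(free, bound, W, GATES)
        surviving = {f.id for f in free}
        assert len(mapping.pairs) == len(surviving)
        for p in mapping.pairs:
            assert p.free_id == "f" + p.bound_id[1:]

    def test_matched_fraction_decreases_past_the_gates(self):
        """Scaling perturbations beyond the gates loses matches monotonically."""
        rng = np.random.default_rng(7)
        n = 50
        directions = rng.uniform(0.5, 1.0, n) * rng.choice([-1, 1], n)
        fractions = []
        for scale in (0.02, 0.06, 0.1, 0.15, 0.25, 0.4):
            bound, free = [], []
            for i in range(n):
                h = 7.0 + (i % 10) * 0.8
                nn = 106.0 + (i // 10) * 5.0
                bound.append(pk(f"b{i}", h, nn, 100, f"A{i}"))
                free.append(pk(f"f{i}", h + directions[i] * scale, nn))
            mapping = reverse_assign(free, bound, W, GATES)
            fractions.append(len(mapping.pairs) / n)
        assert fractions[0] == 1.0
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))
        assert fractions[-1] == 0.0

    def test_sequential_strategy_matches_global_on_unique_neighbours(self):
        rng = np.random.default_rng(4)
        bound, free = grid_peaklists(40, rng, dropout=0.2)
        g = reverse_assign(free, bound, W, GATES, strategy="global")
        s = reverse_assign(free, bound, W, GATES, strategy="sequential")
        assert g.as_dict() == s.as_dict()

    def test_one_to_one_even_when_contested(self):
        rng = np.random.default_rng(17)
        n = 30
        bound = [pk(f"b{i}", rng.uniform(8.0, 8.1), rng.uniform(119, 121),
                    100, f"A{i}") for i in range(n)]
        free = [pk(f"f{i}", rng.uniform(8.0, 8.1), rng.uniform(119, 121))
                for i in range(n + 10)]
        for strategy in ("global", "sequential"):
            mapping = reverse_assign(free, bound, W, GATES, strategy=strategy)
            bids = [p.bound_id for p in mapping.pairs]
            fids = [p.free_id for p in mapping.pairs]
            assert len(set(bids)) == len(bids)
            assert len(set(fids)) == len(fids)


class TestProfile:
    def test_perfect_overlay_gives_zero_shifts(self):
        bound = [pk(f"b{i}", 7 + i, 110 + i, 100, f"A{i + 1}") for i in range(5)]
        free = [pk(f"f{i}", 7 + i, 110 + i) for i in range(5)]
        mapping = reverse_assign(free, bound, W, GATES)
        profile = minimal_shift_profile(mapping, bound)
        assert all(s.status == "matched" and s.delta_min == 0.0
                   for s in profile.shifts)

    def test_constructed_perturbations_rank_highest(self):
        rng = np.random.default_rng(2)
        bound, free = grid_peaklists(30, rng, scale_h=0.004, scale_n=0.03)
        perturbed = [3, 8, 14, 21, 27]
        free_by_id = {f.id: f for f in free}
        for res in perturbed:
            f = free_by_id[f"f{res}"]
            free_by_id[f"f{res}"] = Peak(f.id, f.shift_h + 0.06,
                                         f.shift_n + 0.4, f.height)
        free = list(free_by_id.values())
        mapping = reverse_assign(free, bound, W, GATES)
        profile = minimal_shift_profile(mapping, bound)
        top5 = {s.residue for s in profile.ranked()[:5]}
        assert top5 == set(perturbed)

    def test_missing_free_peaks_flagged_bound_only(self):
        bound = [pk(f"b{i}", 7 + i, 110 + i, 100, f"A{i + 1}") for i in range(6)]
        free = [pk(f"f{i}", 7 + i, 110 + i) for i in range(6) if i not in (2, 4)]
        mapping = reverse_assign(free, bound, W, GATES)
        profile = minimal_shift_profile(mapping, bound,
                                        all_residues=list(range(1, 9)))
        by_res = profile.by_residue()
        assert by_res[3].status == "bound-only"
        assert by_res[5].status == "bound-only"
        assert by_res[7].status == "unobserved"
        assert by_res[8].status == "unobserved"
        assert by_res[1].status == "matched"
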