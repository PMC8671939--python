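"""Reverse minimal chemical-shift mapping between free and bound peak lists.

When a ligand stabilises a protein so strongly that only the bound-state
spectrum can be assigned, chemical-shift perturbations are estimated in
reverse: each *unassigned* free-state peak is matched to the nearest
*assigned* bound-state peak, subject to per-dimension gates, and the
weighted distance of each accepted match is a lower bound on that residue's
true perturbation ("minimal shift").  Bound peaks left unmatched are
candidates for large perturbations or exchange broadening and are reported
categorically, never given an imputed shift.

The combined 1H/15N distance is the Williamson-style weighted Euclidean

    d = sqrt(ddelta_H^2 + (w * ddelta_N)^2)

with the 15N weighting ``w`` derived from the ratio of the assigned-shift
ranges of the two dimensions (0.147 for the AGP2-UCN-01 data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .peaks import Peak


@dataclass(frozen=True)
class WeightSpec:
    """15N weighting derived from the assigned chemical-shift ranges."""

    range_h: float  # 1H assigned-shift range (ppm)
    range_n: float  # 15N assigned-shift range (ppm)
    weight: float   # range_h / range_n (1H ppm per 15N ppm)

    def __post_init__(self) -> None:
        if self.range_h <= 0 or self.range_n <= 0:
            raise ValueError("shift ranges must be positive")


@dataclass(frozen=True)
class GateSpec:
    """Per-dimension matching gates and the relative-height floor."""

    max_dh: float = 0.1    # 1H gate (ppm)
    max_dn: float = 0.68   # 15N gate (ppm)
    height_floor_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.max_dh <= 0 or self.max_dn <= 0:
            raise ValueError("gates must be positive")
        if not 0 <= self.height_floor_fraction < 1:
            raise ValueError("height_floor_fraction must be in [0, 1)")


@dataclass(frozen=True)
class MatchedPair:
    bound_id: str
    free_id: str
    distance: float  # weighted distance, ppm


@dataclass
class CSPMapping:
    """One-to-one free<->bound peak matching under the gates."""

    pairs: list[MatchedPair]
    unmatched_bound: list[str]
    unmatched_free: list[str]

    def as_dict(self) -> dict[str, str]:
        """bound id -> free id for all accepted pairs."""
        return {p.bound_id: p.free_id for p in self.pairs}


@dataclass(frozen=True)
class ResidueShift:
    """Per-residue outcome of the minimal-shift profile."""

    residue: int
    status: str  # "matched" | "bound-only" | "unobserved"
    delta_min: float | None = None  # weighted minimal shift (ppm)
    bound_id: str | None = None
    free_id: str | None = None


@dataclass
class CSPProfile:
    shifts: list[ResidueShift] = field(default_factory=list)

    def by_residue(self) -> dict[int, ResidueShift]:
        return {s.residue: s for s in self.shifts}

    def ranked(self) -> list[ResidueShift]:
        """Matched residues sorted by minimal shift, largest first."""
        matched = [s for s in self.shifts if s.status == "matched"]
        return sorted(matched, key=lambda s: -s.delta_min)


def compute_weight(range_h: float, range_n: float) -> WeightSpec:
    """Derive the 15N weighting from the two assigned-shift ranges."""
    if range_h <= 0 or range_n <= 0:
        raise ValueError("shift ranges must be positive")
    return WeightSpec(range_h, range_n, range_h / range_n)


def weighted_distance(peak_a: Peak, peak_b: Peak, weight: float) -> float:
    """Weighted Euclidean combined-shift distance (ppm)."""
    dh = peak_a.shift_h - peak_b.shift_h
    dn = peak_a.shift_n - peak_b.shift_n
    return math.hypot(dh, weight * dn)


def filter_by_height(
    peaklist: list[Peak], floor_fraction: float
) -> tuple[list[Peak], str]:
    """Drop peaks at or below ``floor_fraction`` of the tallest peak.

    The comparison is strict (a peak is kept only if it is *more than* the
    floor fraction of the reference height).  Returns the retained peaks
    and the id of the reference (tallest) peak.
    """
    if not peaklist:
        raise ValueError("empty peak list")
    reference = max(peaklist, key=lambda p: p.height)
    if reference.height == 0:
        raise ValueError("all peak heights are zero; no reference peak")
    floor = floor_fraction * reference.height
    return [p for p in peaklist if p.height > floor], reference.id


def _gated_pairs(
    free_list: list[Peak],
    bound_list: list[Peak],
    weight: float,
    gates: GateSpec,
) -> list[tuple[float, str, str]]:
    """All (distance, bound id, free id) passing both per-dimension gates."""
    out = []
    for b in bound_list:
        for f in free_list:
            if abs(b.shift_h - f.shift_h) > gates.max_dh:
                continue
            if abs(b.shift_n - f.shift_n) > gates.max_dn:
                continue
            out.append((weighted_distance(b, f, weight), b.id, f.id))
    return out


def reverse_assign(
    free_list: list[Peak],
    bound_list: list[Peak],
    weight: float | WeightSpec,
    gates: GateSpec,
    strategy: str = "global",
) -> CSPMapping:
    """Match free-state peaks onto assigned bound-state peaks.

    ``strategy="global"`` (default): all cross-list pairs passing both
    gates are ranked by weighted distance and accepted greedily, skipping
    any pair whose bound or free member is already used.  The closest free
    peaks are therefore assigned first and progressively more distant free
    peaks claim the closest *remaining* bound peak.

    ``strategy="sequential"``: free peaks are processed in order of their
    distance to the nearest gated bound peak; each claims the nearest
    still-unassigned bound peak within the gates at its turn.

    Ties in distance are broken lexicographically on (bound id, free id)
    for determinism.
    """
    if isinstance(weight, WeightSpec):
        weight = weight.weight
    if not bound_list:
        raise ValueError("bound peak list is empty")
    if strategy not in ("global", "sequential"):
        raise ValueError(f"unknown strategy {strategy!r}")

    candidates = _gated_pairs(free_list, bound_list, weight, gates)
    pairs: list[MatchedPair] = []
    used_bound: set[str] = set()
    used_free: set[str] = set()

    if strategy == "global":
        for d, bid, fid in sorted(candidates):
            if bid in used_bound or fid in used_free:
                continue
            pairs.append(MatchedPair(bid, fid, d))
            used_bound.add(bid)
            used_free.add(fid)
    else:
        # order free peaks by their best gated distance, then id
        by_free: dict[str, list[tuple[float, str]]] = {}
        for d, bid, fid in candidates:
            by_free.setdefault(fid, []).append((d, bid))
        order = sorted(
            by_free, key=lambda fid: (min(by_free[fid])[0], fid)
        )
        for fid in order:
            for d, bid in sorted(by_free[fid]):
                if bid not in used_bound:
                    pairs.append(MatchedPair(bid, fid, d))
                    used_bound.add(bid)
                    used_free.add(fid)
                    break

    unmatched_bound = [b.id for b in bound_list if b.id not in used_bound]
    unmatched_free = [f.id for f in free_list if f.id not in used_free]
    mapping = CSPMapping(pairs, unmatched_bound, unmatched_free)
    _audit_mapping(mapping, free_list, bound_list, gates)
    return mapping


def _audit_mapping(
    mapping: CSPMapping,
    free_list: list[Peak],
    bound_list: list[Peak],
    gates: GateSpec,
) -> None:
    """Self-check: one-to-one pairing and gate soundness."""
    bids = [p.bound_id for p in mapping.pairs]
    fids = [p.free_id for p in mapping.pairs]
    if len(set(bids)) != len(bids) or len(set(fids)) != len(fids):
        raise AssertionError("mapping is not one-to-one")
    free = {p.id: p for p in free_list}
    bound = {p.id: p for p in bound_list}
    for pair in mapping.pairs:
        b, f = bound[pair.bound_id], free[pair.free_id]
        if abs(b.shift_h - f.shift_h) > gates.max_dh + 1e-12:
            raise AssertionError(f"pair {pair} violates the 1H gate")
        if abs(b.shift_n - f.shift_n) > gates.max_dn + 1e-12:
            raise AssertionError(f"pair {pair} violates the 15N gate")


def minimal_shift_profile(
    mapping: CSPMapping,
    bound_list: list[Peak],
    all_residues: list[int] | None = None,
) -> CSPProfile:
    """Per-residue minimal weighted shifts from an accepted mapping.

    Each assigned bound peak contributes one entry: its pair's weighted
    distance if matched, otherwise status ``bound-only`` (a candidate
    large-shift or exchange-broadened residue).  Residues listed in
    ``all_residues`` that have no bound peak are reported ``unobserved``
    (prolines and unassigned amides fall here).
    """
    pair_by_bound = {p.bound_id: p for p in mapping.pairs}
    shifts: list[ResidueShift] = []
    seen: set[int] = set()
    for peak in bound_list:
        res = peak.residue_number
        if res is None:
            continue
        seen.add(res)
        pair = pair_by_bound.get(peak.id)
        if pair is not None:
            shifts.append(
                ResidueShift(res, "matched", pair.distance, peak.id, pair.free_id)
            )
        else:
            shifts.append(ResidueShift(res, "bound-only", None, peak.id, None))
    if all_residues is not None:
        for res in all_residues:
            if res not in seen:
                shifts.append(ResidueShift(res, "unobserved"))
    shifts.sort(key=lambda s: s.residue)
    return CSPProfile(shifts)


def write_mapping_tsv(path, mapping: CSPMapping) -> None:
    with open(path, "w") as fh:
        fh.write("bound_id\tfree_id\tweighted_distance_ppm\n")
        for p in mapping.pairs:
            fh.write(f"{p.bound_id}\t{p.free_id}\t{p.distance:.5f}\n")
        for bid in mapping.unmatched_bound:
            fh.write(f"{bid}\t\t\n")
        for fid in mapping.unmatched_free:
            fh.write(f"\t{fid}\t\n")


def write_profile_tsv(path, profile: CSPProfile) -> None:
    with open(path, "w") as fh:
        fh.write("residue\tstatus\tdelta_min_ppm\n")
        for s in profile.shifts:
            val = "" if s.delta_min is None else f"{s.delta_min:.5f}"
            fh.write(f"{s.residue}\t{s.status}\t{val}\n")
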