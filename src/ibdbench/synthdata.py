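"""Seeded generators for tracks, panels and truth/reported scenarios.

These generators let every pipeline stage be exercised without external
simulations:

* :func:`gen_track` — a local-tree stand-in with per-pair exponential
  breakpoints (it is *not* coalescently consistent across pairs; truth
  extraction only needs label runs).
* :func:`gen_panel` — a biallelic phased panel with controlled MAF
  distribution.
* :func:`gen_scenario` — a pseudo-caller: truth segments plus a reported
  set derived by boundary jitter, fragmentation, drops and false
  positives, together with the expected metric report computed by an
  independent brute-force oracle (never by the metrics module itself).

All randomness flows from one integer seed through a named
``numpy.random.Generator``; no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    GeneticMap,
    HapPair,
    HaplotypeId,
    IBDSegment,
    MetricConfig,
    segment_from_bp,
)
from .metrics import MetricReport, MetricRow, bin_label
from .panelops import HaplotypePanel
from .track import ArrayTrack

__all__ = ["ScenarioSpec", "gen_track", "gen_panel", "gen_scenario", "oracle_report"]


def gen_track(
    n_haplotypes: int,
    region_bp: int,
    mean_segment_bp: float = 1_000_000,
    seed: int = 0,
    chrom: str = "1",
) -> ArrayTrack:
    """Random local-tree track: each unordered haplotype pair gets
    independent piecewise-constant MRCA labels with Exponential(mean)
    breakpoint spacing. Deterministic per seed."""
    if n_haplotypes < 4 or n_haplotypes % 2 != 0:
        raise ValueError(f"n_haplotypes must be even and >= 4, got {n_haplotypes}")
    if region_bp < 1:
        raise ValueError(f"region_bp must be >= 1, got {region_bp}")
    rng = np.random.default_rng(seed)
    haplotypes = [
        HaplotypeId(f"s{k:04d}", h) for k in range(n_haplotypes // 2) for h in (0, 1)
    ]
    intervals: Dict[HapPair, Tuple[np.ndarray, np.ndarray]] = {}
    for i in range(len(haplotypes)):
        for j in range(i + 1, len(haplotypes)):
            pair = HapPair(haplotypes[i], haplotypes[j])
            # expected breakpoint count ~ region/mean; draw with headroom
            n_draw = max(8, int(3 * region_bp / mean_segment_bp) + 8)
            gaps = rng.exponential(mean_segment_bp, size=n_draw)
            while gaps.sum() < region_bp:  # pragma: no cover - rare top-up
                gaps = np.concatenate([gaps, rng.exponential(mean_segment_bp, n_draw)])
            ends = np.cumsum(gaps).astype(np.int64)
            ends = ends[: int(np.searchsorted(ends, region_bp)) + 1]
            ends = np.unique(np.minimum(ends, region_bp))
            if ends.size == 0 or ends[-1] != region_bp:
                ends = np.concatenate([ends, [region_bp]]).astype(np.int64)
            # strictly increasing labels => adjacent intervals always differ
            labels = np.cumsum(rng.integers(1, 1000, size=ends.size), dtype=np.int64)
            intervals[pair] = (ends, labels)
    return ArrayTrack(chrom, region_bp, haplotypes, intervals)


def gen_panel(
    n_haplotypes: int,
    n_sites: int,
    maf_distribution: Tuple = ("uniform", 0.05, 0.5),
    seed: int = 0,
    region_bp: int = 10_000_000,
    chrom: str = "1",
) -> HaplotypePanel:
    """Random biallelic phased panel with site MAFs drawn from the given
    distribution (``("uniform", lo, hi)`` or ``("beta", a, b)``) and
    positions uniform over ``[1, region_bp]``."""
    if n_haplotypes < 1 or n_sites < 1:
        raise ValueError("n_haplotypes and n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(region_bp, size=n_sites, replace=False)) + 1
    family, *params = maf_distribution
    if family == "uniform":
        mafs = rng.uniform(params[0], params[1], size=n_sites)
    elif family == "beta":
        mafs = np.clip(rng.beta(params[0], params[1], size=n_sites), 1e-6, 0.5)
    else:
        raise ValueError(f"unknown MAF distribution family {family!r}")
    alleles = (rng.random((n_sites, n_haplotypes)) < mafs[:, None]).astype(np.int8)
    haplotypes = [
        HaplotypeId(f"s{k:04d}", h)
        for k in range((n_haplotypes + 1) // 2)
        for h in (0, 1)
    ][:n_haplotypes]
    return HaplotypePanel(
        haplotypes=haplotypes, chrom=chrom, positions=positions, alleles=alleles
    )


@dataclass
class ScenarioSpec:
    """Pseudo-caller scenario parameters.

    Truth segments are drawn per pair with genetic lengths from
    ``length_dist`` (``("uniform", lo, hi)`` cM). The reported set is the
    truth set degraded by, in order: segment drops, fragmentation (a
    split at the midpoint leaving a ``gap_cm`` hole — real detectors
    tend to break long segments into pieces), boundary jitter
    (uniform +/- jitter on each end), and appended false positives.
    """

    n_pairs: int = 10
    segments_per_pair: Tuple[int, int] = (1, 3)
    length_dist: Tuple = ("uniform", 2.0, 10.0)
    boundary_jitter_cm: float = 0.0
    fragmentation_prob: float = 0.0
    gap_cm: float = 0.5
    false_positive_rate: float = 0.0
    drop_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fragmentation_prob", "false_positive_rate", "drop_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.boundary_jitter_cm < 0 or self.gap_cm < 0:
            raise ValueError("boundary_jitter_cm and gap_cm must be >= 0")


def _draw_length(rng, dist) -> float:
    family, *params = dist
    if family == "uniform":
        return float(rng.uniform(params[0], params[1]))
    if family == "exponential":
        return params[1] + float(rng.exponential(params[0]))
    raise ValueError(f"unknown length distribution family {family!r}")


def _make_segment(pair, gmap, start_cm, end_cm) -> Optional[IBDSegment]:
    """Place a cM interval on the bp axis and re-derive exact cM bounds
    from the map, so segment coordinates are always map-consistent."""
    lo = max(gmap.first_cm, min(start_cm, end_cm))
    hi = min(gmap.last_cm, max(start_cm, end_cm))
    start_bp = int(round(gmap.cm_to_bp(lo)))
    end_bp = int(round(gmap.cm_to_bp(hi)))
    if end_bp <= start_bp:
        return None
    return segment_from_bp(pair, gmap.chrom, start_bp, end_bp, gmap)


def gen_scenario(
    spec: ScenarioSpec,
    gmap: GeneticMap,
    cfg: Optional[MetricConfig] = None,
) -> Tuple[List[IBDSegment], List[IBDSegment], MetricReport]:
    """Generate a (truth, reported, expected-report) triple.

    The expected report is computed by :func:`oracle_report`, a naive
    all-pairs implementation independent of the metrics module.
    """
    cfg = cfg or MetricConfig()
    rng = np.random.default_rng(spec.seed)
    pairs = [
        HapPair(HaplotypeId(f"p{i:03d}a", 0), HaplotypeId(f"p{i:03d}b", 0))
        for i in range(spec.n_pairs)
    ]
    truth: List[IBDSegment] = []
    reported: List[IBDSegment] = []
    lo_k, hi_k = spec.segments_per_pair
    for pair in pairs:
        k = int(rng.integers(lo_k, hi_k + 1))
        cursor = gmap.first_cm
        for _ in range(k):
            cursor += float(rng.uniform(0.2, 2.0))  # inter-segment gap
            length = _draw_length(rng, spec.length_dist)
            if cursor + length > gmap.last_cm:
                break
            seg = _make_segment(pair, gmap, cursor, cursor + length)
            cursor += length
            if seg is None:
                continue
            truth.append(seg)
            reported.extend(_perturb(rng, seg, spec, gmap))
    # false positives on random pairs, lengths from the truth distribution
    n_fp = int(rng.binomial(max(len(truth), 1), spec.false_positive_rate))
    for _ in range(n_fp):
        pair = pairs[int(rng.integers(0, len(pairs)))]
        length = _draw_length(rng, spec.length_dist)
        start = float(rng.uniform(gmap.first_cm, max(gmap.first_cm + 1e-9,
                                                     gmap.last_cm - length)))
        seg = _make_segment(pair, gmap, start, start + length)
        if seg is not None:
            reported.append(seg)
    expected = oracle_report(truth, reported, cfg)
    return truth, reported, expected


def _perturb(rng, seg: IBDSegment, spec: ScenarioSpec, gmap) -> List[IBDSegment]:
    if rng.random() < spec.drop_rate:
        return []
    if rng.random() < spec.fragmentation_prob:
        mid = 0.5 * (seg.start_cm + seg.end_cm)
        halves = [
            (seg.start_cm, mid - spec.gap_cm / 2),
            (mid + spec.gap_cm / 2, seg.end_cm),
        ]
    else:
        halves = [(seg.start_cm, seg.end_cm)]
    out = []
    j = spec.boundary_jitter_cm
    for s, e in halves:
        if j > 0:
            s += float(rng.uniform(-j, j))
            e += float(rng.uniform(-j, j))
        if e - s <= 0:
            continue
        made = _make_segment(seg.pair, gmap, s, e)
        if made is not None:
            out.append(made)
    return out


# ---------------------------------------------------------------------------
# Independent metrics oracle (naive all-pairs loops; no SegmentIndex, no
# calls into the metrics evaluation functions).

def _oracle_overlap(x: IBDSegment, y: IBDSegment, pair_mode: str) -> float:
    if x.chrom != y.chrom:
        return 0.0
    if pair_mode == "haplotype":
        if x.pair != y.pair:
            return 0.0
    else:
        if x.pair.sample_pair != y.pair.sample_pair:
            return 0.0
    return max(0.0, min(x.end_cm, y.end_cm) - max(x.start_cm, y.start_cm))


def _oracle_best(subject: IBDSegment, candidates, pair_mode: str):
    best = None
    best_ov = 0.0
    for cand in candidates:
        ov = _oracle_overlap(subject, cand, pair_mode)
        if ov <= 0.0:
            continue
        take = False
        if best is None or ov > best_ov:
            take = True
        elif ov == best_ov:
            d_new = abs(subject.length_cm - cand.length_cm)
            d_old = abs(subject.length_cm - best.length_cm)
            if d_new < d_old:
                take = True
            elif d_new == d_old and (cand.start_cm, cand.start_bp) < (
                best.start_cm, best.start_bp
            ):
                take = True
        if take:
            best, best_ov = cand, ov
    return best, best_ov


def _oracle_reported_side(reported, truth_ref, cfg: MetricConfig):
    if not reported:
        return math.nan, math.nan, math.nan
    covered = 0
    fracs = []
    sq = []
    for r in reported:
        best, ov = _oracle_best(r, truth_ref, cfg.pair_mode)
        L = r.length_cm
        if best is not None and (ov >= cfg.coverage_threshold * L if L > 0 else True):
            covered += 1
        fracs.append((ov / L) if L > 0 else (1.0 if best is not None else 0.0))
        if best is not None:
            sq.append((L - best.length_cm) ** 2)
    disc = math.sqrt(sum(sq) / len(sq)) if sq else math.nan
    return covered / len(reported), sum(fracs) / len(fracs), disc


def _oracle_truth_side(truth, reported_ref, cfg: MetricConfig):
    if not truth:
        return math.nan, math.nan, math.nan
    recalled = 0
    powers = []
    acc = []
    for t in truth:
        best, ov = _oracle_best(t, reported_ref, cfg.pair_mode)
        L = t.length_cm
        if best is not None and (ov >= cfg.coverage_threshold * L if L > 0 else True):
            recalled += 1
        powers.append((ov / L) if L > 0 else (1.0 if best is not None else 0.0))
        # union coverage by all overlapping reported segments
        pieces = sorted(
            (max(t.start_cm, r.start_cm), min(t.end_cm, r.end_cm))
            for r in reported_ref
            if _oracle_overlap(t, r, cfg.pair_mode) > 0.0
        )
        total = 0.0
        cur = None
        for s, e in pieces:
            if cur is None:
                cur = [s, e]
            elif s > cur[1]:
                total += cur[1] - cur[0]
                cur = [s, e]
            else:
                cur[1] = max(cur[1], e)
        if cur is not None:
            total += cur[1] - cur[0]
        acc.append((total / L) if L > 0 else (1.0 if total > 0 else 0.0))
    return recalled / len(truth), sum(powers) / len(powers), sum(acc) / len(acc)


def oracle_report(
    truth: Sequence[IBDSegment],
    reported: Sequence[IBDSegment],
    cfg: Optional[MetricConfig] = None,
    reference: str = "full",
) -> MetricReport:
    """Brute-force metric report over all segment pairs; the reference
    implementation that the fast engine must reproduce exactly."""
    cfg = cfg or MetricConfig()
    edges = list(cfg.bin_edges_cm)

    def subset(segs, i):
        lo = edges[i]
        hi = edges[i + 1] if i + 1 < len(edges) else math.inf
        return [s for s in segs if lo <= s.length_cm < hi]

    rows: Dict[str, MetricRow] = {}

    def make(rep_subset, truth_subset, rep_ref, truth_ref):
        a, la, d = _oracle_reported_side(rep_subset, truth_ref, cfg)
        r, p, ap = _oracle_truth_side(truth_subset, rep_ref, cfg)
        return MetricRow(
            accuracy=a, length_accuracy=la, length_discrepancy_cm=d,
            recall=r, power=p, accumulative_power=ap,
            n_reported=len(rep_subset), n_truth=len(truth_subset),
        )

    rows["all"] = make(list(reported), list(truth), list(reported), list(truth))
    for i in range(len(edges)):
        rep_b = subset(reported, i)
        truth_b = subset(truth, i)
        if reference == "full":
            rows[bin_label(edges, i)] = make(rep_b, truth_b, list(reported), list(truth))
        else:
            rows[bin_label(edges, i)] = make(rep_b, truth_b, rep_b, truth_b)
    return MetricReport(rows, cfg.bin_edges_cm)
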