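"""Evaluation metrics for reported IBD segments against ground truth.

Interval calls cannot be scored with plain precision/recall: a reported
segment may be partially true, a true segment may be reported in
pieces. Six metrics, all computed on genetic (cM) coordinates, capture
the two sides:

Reported side (is what was reported real?)
    * **accuracy** — fraction of reported segments at least half covered
      by a *single* best-matching truth segment (1 - accuracy is the
      false-positive fraction).
    * **length accuracy** — mean covered fraction of reported segments
      (0 for unmatched ones).
    * **length discrepancy** — RMS of |reported length - best truth
      length| over reported segments that have a match.

Truth side (was what is real reported?)
    * **recall** — fraction of truth segments at least half covered by a
      single best-matching reported segment.
    * **power** — mean covered fraction of truth segments by their best
      match.
    * **accumulative power** — like power but crediting the union of
      *all* overlapping reported segments.

Length-stratified reports bin the evaluated set by segment length while
always matching against the **full** opposite set, so a 2.9 cM call of a
3.0 cM truth segment is still scored as accurate inside its bin. The
rejected alternative (per-bin reference sets) is available for
comparison via ``reference="binned"``.
"""

from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import dataclass, fields
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import IBDSegment, MetricConfig, overlap_cm, pair_key

__all__ = [
    "MatchResult",
    "MetricRow",
    "MetricReport",
    "SegmentIndex",
    "best_match",
    "evaluate_reported",
    "evaluate_truth",
    "bin_segments",
    "bin_label",
    "evaluate_binned",
]


@dataclass
class MatchResult:
    """Best single match of ``subject`` among same-pair candidates."""

    subject: IBDSegment
    best: Optional[IBDSegment]
    best_overlap_cm: float
    covered: bool


@dataclass
class MetricRow:
    """One row (one length bin, or "all") of a metric report.

    Fractions are NaN when their denominator is zero; discrepancy is NaN
    when no reported segment has a match.
    """

    accuracy: float = math.nan
    length_accuracy: float = math.nan
    length_discrepancy_cm: float = math.nan
    recall: float = math.nan
    power: float = math.nan
    accumulative_power: float = math.nan
    n_reported: int = 0
    n_truth: int = 0

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class MetricReport:
    """Mapping of bin label -> :class:`MetricRow`, with an "all" row."""

    def __init__(self, rows: Dict[str, MetricRow], bin_edges_cm: Sequence[float]):
        self.rows = rows
        self.bin_edges_cm = tuple(bin_edges_cm)

    def __getitem__(self, label: str) -> MetricRow:
        return self.rows[label]

    @property
    def labels(self) -> List[str]:
        return list(self.rows)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({k: v.as_dict() for k, v in self.rows.items()}).T
        df.index.name = "bin"
        df["n_reported"] = df["n_reported"].astype(int)
        df["n_truth"] = df["n_truth"].astype(int)
        return df

    def to_json(self) -> str:
        payload = {
            "bin_edges_cm": list(self.bin_edges_cm),
            "bins": {
                k: {f: (None if isinstance(v, float) and math.isnan(v) else v)
                    for f, v in row.as_dict().items()}
                for k, row in self.rows.items()
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)


class SegmentIndex:
    """Segments grouped by their comparison key under a pair mode."""

    def __init__(self, segments: Sequence[IBDSegment], pair_mode: str = "haplotype"):
        self.pair_mode = pair_mode
        self._by_key: Dict[object, List[IBDSegment]] = defaultdict(list)
        for seg in segments:
            self._by_key[(seg.chrom, pair_key(seg.pair, pair_mode))].append(seg)

    def candidates(self, subject: IBDSegment) -> List[IBDSegment]:
        return self._by_key.get(
            (subject.chrom, pair_key(subject.pair, self.pair_mode)), []
        )


def _better(ov: float, cand: IBDSegment, best_ov: float, best: Optional[IBDSegment],
            subject: IBDSegment) -> bool:
    """Tie-breaking order for best matches: larger overlap, then smaller
    |length difference|, then earlier start. Ties affect only the length
    discrepancy, never accuracy or power."""
    if best is None or ov > best_ov:
        return True
    if ov < best_ov:
        return False
    d_new = abs(subject.length_cm - cand.length_cm)
    d_old = abs(subject.length_cm - best.length_cm)
    if d_new != d_old:
        return d_new < d_old
    return (cand.start_cm, cand.start_bp) < (best.start_cm, best.start_bp)


def best_match(
    subject: IBDSegment,
    candidates: Sequence[IBDSegment] | SegmentIndex,
    cfg: Optional[MetricConfig] = None,
) -> MatchResult:
    """Find the single candidate with the longest overlap with ``subject``.

    Zero overlap means no match (``best`` is None). ``covered`` is True
    when the best overlap reaches ``coverage_threshold`` times the
    subject's genetic length (boundary inclusive).
    """
    cfg = cfg or MetricConfig()
    if isinstance(candidates, SegmentIndex):
        cands = candidates.candidates(subject)
    else:
        cands = candidates
    best: Optional[IBDSegment] = None
    best_ov = 0.0
    for cand in cands:
        ov = overlap_cm(subject, cand, cfg.pair_mode)
        if ov <= 0.0:
            continue
        if _better(ov, cand, best_ov, best, subject):
            best, best_ov = cand, ov
    covered = best is not None and _covered(best_ov, subject.length_cm, cfg)
    return MatchResult(subject=subject, best=best, best_overlap_cm=best_ov, covered=covered)


def _covered(overlap: float, length: float, cfg: MetricConfig) -> bool:
    if length <= 0.0:
        return overlap >= 0.0
    return overlap >= cfg.coverage_threshold * length


def _frac(overlap: float, length: float, matched: bool) -> float:
    if length <= 0.0:
        return 1.0 if matched else 0.0
    return overlap / length


def evaluate_reported(
    reported: Sequence[IBDSegment],
    truth_full: Sequence[IBDSegment] | SegmentIndex,
    cfg: Optional[MetricConfig] = None,
    penalize_unmatched_discrepancy: bool = False,
) -> Tuple[float, float, float]:
    """Accuracy, length accuracy and length discrepancy (cM) of a
    reported set against the full truth set.

    Unmatched reported segments contribute 0 to length accuracy and are
    excluded from the discrepancy RMS (they have no best-matching truth
    length); ``penalize_unmatched_discrepancy`` instead charges them
    their full length.
    """
    cfg = cfg or MetricConfig()
    index = truth_full if isinstance(truth_full, SegmentIndex) else SegmentIndex(
        truth_full, cfg.pair_mode
    )
    n = len(reported)
    if n == 0:
        return math.nan, math.nan, math.nan
    n_covered = 0
    frac_sum = 0.0
    sq = []
    for seg in reported:
        m = best_match(seg, index, cfg)
        if m.covered:
            n_covered += 1
        frac_sum += _frac(m.best_overlap_cm, seg.length_cm, m.best is not None)
        if m.best is not None:
            sq.append((seg.length_cm - m.best.length_cm) ** 2)
        elif penalize_unmatched_discrepancy:
            sq.append(seg.length_cm ** 2)
    discrepancy = math.sqrt(sum(sq) / len(sq)) if sq else math.nan
    return n_covered / n, frac_sum / n, discrepancy


def _union_coverage(subject: IBDSegment, cands: Sequence[IBDSegment],
                    pair_mode: str) -> float:
    """Genetic length of subject covered by the union of all overlapping
    candidates (merged so shared coverage is not double counted)."""
    pieces = []
    for cand in cands:
        if overlap_cm(subject, cand, pair_mode) <= 0.0:
            continue
        pieces.append(
            (max(subject.start_cm, cand.start_cm), min(subject.end_cm, cand.end_cm))
        )
    if not pieces:
        return 0.0
    pieces.sort()
    total = 0.0
    cur_s, cur_e = pieces[0]
    for s, e in pieces[1:]:
        if s > cur_e:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    total += cur_e - cur_s
    return total


def evaluate_truth(
    truth: Sequence[IBDSegment],
    reported_full: Sequence[IBDSegment] | SegmentIndex,
    cfg: Optional[MetricConfig] = None,
) -> Tuple[float, float, float]:
    """Recall, power and accumulative power of a truth set against the
    full reported set."""
    cfg = cfg or MetricConfig()
    index = reported_full if isinstance(reported_full, SegmentIndex) else SegmentIndex(
        reported_full, cfg.pair_mode
    )
    n = len(truth)
    if n == 0:
        return math.nan, math.nan, math.nan
    n_recalled = 0
    power_sum = 0.0
    acc_sum = 0.0
    for seg in truth:
        m = best_match(seg, index, cfg)
        if m.covered:
            n_recalled += 1
        power_sum += _frac(m.best_overlap_cm, seg.length_cm, m.best is not None)
        union = _union_coverage(seg, index.candidates(seg), cfg.pair_mode)
        acc_sum += _frac(union, seg.length_cm, union > 0.0)
    return n_recalled / n, power_sum / n, acc_sum / n


def bin_label(edges: Sequence[float], i: int) -> str:
    if i == len(edges) - 1:
        return f"[{edges[i]:g},inf)"
    return f"[{edges[i]:g},{edges[i + 1]:g})"


def bin_segments(
    segments: Sequence[IBDSegment], edges: Sequence[float]
) -> Dict[str, List[IBDSegment]]:
    """Group segments by genetic length into ``[e_i, e_{i+1})`` bins,
    final bin open-ended; segments shorter than the first edge are not
    assigned to any bin."""
    edges = list(edges)
    bins: Dict[str, List[IBDSegment]] = {
        bin_label(edges, i): [] for i in range(len(edges))
    }
    arr = np.asarray(edges, dtype=float)
    for seg in segments:
        i = int(np.searchsorted(arr, seg.length_cm, side="right")) - 1
        if i >= 0:
            bins[bin_label(edges, i)].append(seg)
    return bins


def evaluate_binned(
    truth_full: Sequence[IBDSegment],
    reported_full: Sequence[IBDSegment],
    cfg: Optional[MetricConfig] = None,
    reference: str = "full",
) -> MetricReport:
    """Length-stratified metric report.

    Every bin of reported segments is scored against the full truth set
    and every bin of truth segments against the full reported set
    (``reference="full"``, the default); ``reference="binned"`` restricts
    the reference to the same bin, the scheme that undercounts
    near-boundary matches. An "all" row covers the unbinned sets.
    """
    cfg = cfg or MetricConfig()
    if reference not in ("full", "binned"):
        raise ValueError(f"reference must be 'full' or 'binned', got {reference!r}")
    truth_index = SegmentIndex(truth_full, cfg.pair_mode)
    reported_index = SegmentIndex(reported_full, cfg.pair_mode)
    rows: Dict[str, MetricRow] = {}

    def make_row(rep_subset, truth_subset, rep_ref, truth_ref) -> MetricRow:
        acc, lacc, disc = evaluate_reported(rep_subset, truth_ref, cfg)
        rec, pw, apw = evaluate_truth(truth_subset, rep_ref, cfg)
        return MetricRow(
            accuracy=acc,
            length_accuracy=lacc,
            length_discrepancy_cm=disc,
            recall=rec,
            power=pw,
            accumulative_power=apw,
            n_reported=len(rep_subset),
            n_truth=len(truth_subset),
        )

    rows["all"] = make_row(list(reported_full), list(truth_full),
                           reported_index, truth_index)
    truth_bins = bin_segments(truth_full, cfg.bin_edges_cm)
    reported_bins = bin_segments(reported_full, cfg.bin_edges_cm)
    for label in truth_bins:
        rep_subset = reported_bins[label]
        truth_subset = truth_bins[label]
        if reference == "full":
            rows[label] = make_row(rep_subset, truth_subset, reported_index, truth_index)
        else:
            rows[label] = make_row(
                rep_subset,
                truth_subset,
                SegmentIndex(rep_subset, cfg.pair_mode),
                SegmentIndex(truth_subset, cfg.pair_mode),
            )
    return MetricReport(rows, cfg.bin_edges_cm)
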