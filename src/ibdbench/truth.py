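"""Ground-truth IBD extraction from local-tree tracks.

Two haplotypes are IBD over a region where they keep the same most
recent common ancestor (MRCA) in every local tree. The extractor samples
the local trees on a regular physical grid (default every 5,000 bp),
finds maximal runs of identical MRCA labels per haplotype pair, and
keeps runs whose genetic length reaches a minimum (default 1 cM).

Boundary convention for a run: the segment starts at the first sampled
position of the run and ends at the first sampled position *after* the
run; the terminal run closes at the region end rather than the last
sampled position, so the final segment is not truncated by up to one
step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .core import ConfigError, GeneticMap, HapPair, IBDSegment, segment_from_bp
from .track import LocalTreeTrack

__all__ = ["TruthConfig", "extract_truth_ibd", "extract_truth_ibd_oracle", "mrca_labels"]


@dataclass
class TruthConfig:
    """Parameters of truth extraction.

    sample_step_bp
        Physical spacing of the tree-sampling grid. Default 5,000 bp.
    min_length_cm
        Minimum genetic length of an emitted segment. Default 1.0 cM.
    boundaries
        ``"sampled"`` (default) places segment bounds on the sampling
        grid; ``"exact"`` uses the track's exact label breakpoints.
    include_within_individual
        Whether to also extract segments between the two haplotypes of
        one sample. Default False.
    """

    sample_step_bp: int = 5000
    min_length_cm: float = 1.0
    boundaries: str = "sampled"
    include_within_individual: bool = False

    def __post_init__(self) -> None:
        if self.sample_step_bp < 1:
            raise ConfigError(f"truth.sample_step_bp: must be >= 1, got {self.sample_step_bp}")
        if self.min_length_cm < 0:
            raise ConfigError(f"truth.min_length_cm: must be >= 0, got {self.min_length_cm}")
        if self.boundaries not in ("sampled", "exact"):
            raise ConfigError(f"truth.boundaries: unknown mode {self.boundaries!r}")


def mrca_labels(track: LocalTreeTrack, pair: HapPair, positions) -> np.ndarray:
    """MRCA label of ``pair`` at each (sorted, in-region) position."""
    return track.pair_labels(pair, np.asarray(positions, dtype=np.int64))


def _runs_to_segments(
    pair: HapPair,
    chrom: str,
    starts_bp: np.ndarray,
    ends_bp: np.ndarray,
    labels: np.ndarray,
    gmap: GeneticMap,
    min_length_cm: float,
) -> List[IBDSegment]:
    out = []
    start_cm = np.atleast_1d(gmap.bp_to_cm(starts_bp))
    end_cm = np.atleast_1d(gmap.bp_to_cm(ends_bp))
    keep = (end_cm - start_cm) >= min_length_cm
    for i in np.nonzero(keep)[0]:
        if labels[i] < 0:
            continue  # no common ancestor in this local tree
        out.append(
            IBDSegment(
                pair=pair,
                chrom=chrom,
                start_bp=int(starts_bp[i]),
                end_bp=int(ends_bp[i]),
                start_cm=float(start_cm[i]),
                end_cm=float(end_cm[i]),
            )
        )
    return out


def extract_truth_ibd(
    track: LocalTreeTrack,
    gmap: GeneticMap,
    cfg: Optional[TruthConfig] = None,
) -> List[IBDSegment]:
    """Extract ground-truth IBD segments for every haplotype pair.

    Returns segments sorted by (pair, start_bp). An empty track (or one
    whose runs all fall below ``min_length_cm``) yields an empty list.
    """
    cfg = cfg or TruthConfig()
    L = track.sequence_length
    segments: List[IBDSegment] = []
    if L <= 0:
        return segments
    grid = np.arange(0, L, cfg.sample_step_bp, dtype=np.int64)
    for pair in track.pairs(cfg.include_within_individual):
        if cfg.boundaries == "exact":
            ends, labels = track.pair_intervals(pair)
            # merge adjacent intervals carrying the same label
            change = np.nonzero(labels[1:] != labels[:-1])[0]
            run_last = np.concatenate([change, [labels.size - 1]])
            run_first = np.concatenate([[0], change + 1])
            starts_bp = np.concatenate([[0], ends[:-1]])[run_first]
            ends_bp = ends[run_last]
            run_labels = labels[run_first]
        else:
            labels = track.pair_labels(pair, grid)
            change = np.nonzero(labels[1:] != labels[:-1])[0]
            run_first = np.concatenate([[0], change + 1])
            starts_bp = grid[run_first]
            ends_bp = np.concatenate([grid[run_first[1:]], [L]])
            run_labels = labels[run_first]
        segments.extend(
            _runs_to_segments(
                pair, track.chrom, starts_bp, ends_bp, run_labels, gmap, cfg.min_length_cm
            )
        )
    segments.sort(key=lambda s: s.sort_key())
    return segments


def extract_truth_ibd_oracle(
    track: LocalTreeTrack,
    gmap: GeneticMap,
    cfg: Optional[TruthConfig] = None,
) -> List[IBDSegment]:
    """Brute-force reference for :func:`extract_truth_ibd`.

    Walks every sampled position one at a time in plain Python,
    accumulating label runs with no vectorized run detection. Supports
    the default ``"sampled"`` boundary mode only. Intended for tests.
    """
    cfg = cfg or TruthConfig()
    if cfg.boundaries != "sampled":
        raise ConfigError("truth oracle: only boundaries='sampled' supported")
    L = track.sequence_length
    segments: List[IBDSegment] = []
    if L <= 0:
        return segments
    grid = list(range(0, L, cfg.sample_step_bp))
    for pair in track.pairs(cfg.include_within_individual):
        labels = track.pair_labels(pair, np.asarray(grid, dtype=np.int64))
        run_start = None
        run_label = None
        for pos, lab in zip(grid, labels):
            if run_label is None:
                run_start, run_label = pos, lab
            elif lab != run_label:
                seg = _close_run(pair, track.chrom, run_start, pos, run_label, gmap, cfg)
                if seg is not None:
                    segments.append(seg)
                run_start, run_label = pos, lab
        if run_label is not None:
            seg = _close_run(pair, track.chrom, run_start, L, run_label, gmap, cfg)
            if seg is not None:
                segments.append(seg)
    segments.sort(key=lambda s: s.sort_key())
    return segments


def _close_run(pair, chrom, start_bp, end_bp, label, gmap, cfg):
    if label < 0:
        return None
    seg = segment_from_bp(pair, chrom, start_bp, end_bp, gmap)
    if seg.length_cm < cfg.min_length_cm:
        return None
    return seg
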