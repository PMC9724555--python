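"""Downstream summaries of IBD call sets.

Two applications the segment calls feed directly:

* **Coverage profiles** — how many segments (above a length cutoff,
  default 2 cM) cover each marker position. Comparing a detector's
  profile against the truth profile shows where along the chromosome it
  over- or under-calls.
* **Relatedness inference** — total pairwise IBD sharing converted to a
  kinship estimate and a pedigree degree (up to 4th degree by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import ConfigError, IBDSegment

__all__ = [
    "CoverageProfile",
    "RelatednessConfig",
    "coverage_profile",
    "total_ibd_per_pair",
    "assign_degree",
    "relatedness_table",
    "UNRELATED",
    "default_kinship_bounds",
]

UNRELATED = "unrelated"


@dataclass
class CoverageProfile:
    """Per-site counts of covering IBD segments."""

    positions: np.ndarray
    counts: np.ndarray
    min_length_cm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pos_bp": self.positions, "count": self.counts})


def coverage_profile(
    segments: Sequence[IBDSegment],
    site_positions: Sequence[int] | np.ndarray,
    min_length_cm: float = 2.0,
) -> CoverageProfile:
    """Count, per marker position, the segments covering it.

    Only segments with genetic length >= ``min_length_cm`` contribute;
    a site s is covered by a segment when ``start_bp <= s < end_bp``.
    Counts are invariant to segment order.
    """
    sites = np.asarray(site_positions, dtype=np.int64)
    if sites.size > 1 and not np.all(np.diff(sites) > 0):
        raise ValueError("site positions must be strictly increasing")
    counts = np.zeros(sites.size, dtype=np.int64)
    for seg in segments:
        if seg.length_cm < min_length_cm:
            continue
        lo = np.searchsorted(sites, seg.start_bp, side="left")
        hi = np.searchsorted(sites, seg.end_bp, side="left")
        counts[lo:hi] += 1
    return CoverageProfile(positions=sites, counts=counts, min_length_cm=min_length_cm)


def default_kinship_bounds(max_degree: int = 4) -> List[Tuple[int, float, float]]:
    """Standard kinship ranges per degree: degree d spans
    phi in (2^-(d+3/2), 2^-(d+1/2)], with degree 0 (duplicate or
    monozygotic pair) open-ended above."""
    bounds = [(0, 2.0 ** -1.5, math.inf)]
    for d in range(1, max_degree + 1):
        bounds.append((d, 2.0 ** -(d + 1.5), 2.0 ** -(d + 0.5)))
    return bounds


@dataclass
class RelatednessConfig:
    """Degree-of-relatedness calling from total IBD sharing.

    genome_length_cm
        Genetic length of the genome (or the region under study) in cM;
        the kinship estimate is phi = total_cm / (4 * genome_length_cm).
    kinship_bounds
        ``(degree, lower, upper)`` triples; degree d is assigned when
        phi falls in (lower, upper]. The inclusive upper edge assigns a
        boundary value to the closer relation. Defaults to the standard
        powers-of-two ranges up to ``max_degree``; no adjustment for
        detector power loss is applied.
    """

    genome_length_cm: float
    max_degree: int = 4
    kinship_bounds: Optional[List[Tuple[int, float, float]]] = None

    def __post_init__(self) -> None:
        if self.genome_length_cm <= 0:
            raise ConfigError(
                f"relatedness.genome_length_cm: must be > 0, got {self.genome_length_cm}"
            )
        if self.kinship_bounds is None:
            self.kinship_bounds = default_kinship_bounds(self.max_degree)
        for d, lo, hi in self.kinship_bounds:
            if not lo < hi:
                raise ConfigError(
                    f"relatedness.kinship_bounds: degree {d} has empty range ({lo}, {hi}]"
                )


def total_ibd_per_pair(
    segments: Sequence[IBDSegment],
) -> Dict[Tuple[str, str], float]:
    """Total genetic length of segments shared by each unordered sample
    pair, summing over all four haplotype combinations. Within-sample
    segments are ignored; absent pairs mean zero sharing."""
    totals: Dict[Tuple[str, str], float] = {}
    for seg in segments:
        key = seg.pair.sample_pair
        if key[0] == key[1]:
            continue
        totals[key] = totals.get(key, 0.0) + seg.length_cm
    return totals


def assign_degree(total_cm: float, cfg: RelatednessConfig):
    """Degree of relatedness implied by total IBD sharing.

    Returns an integer degree, or :data:`UNRELATED` when the kinship
    estimate falls below every bound. Monotone: more sharing never gives
    a more distant degree.
    """
    if total_cm < 0:
        raise ValueError(f"total_cm must be >= 0, got {total_cm}")
    phi = total_cm / (4.0 * cfg.genome_length_cm)
    for d, lo, hi in sorted(cfg.kinship_bounds):
        if lo < phi <= hi:
            return d
    return UNRELATED


def relatedness_table(
    truth_segments: Sequence[IBDSegment],
    reported_segments: Sequence[IBDSegment],
    cfg: RelatednessConfig,
) -> pd.DataFrame:
    """Per-degree counts of sample pairs under truth vs reported calls.

    Pairs considered are those sharing at least one segment in either
    set; a pair absent from one set has zero total there. Columns:
    ``degree``, ``n_truth``, ``n_reported``.
    """
    t = total_ibd_per_pair(truth_segments)
    r = total_ibd_per_pair(reported_segments)
    degrees = [d for d, _, _ in sorted(cfg.kinship_bounds)] + [UNRELATED]
    counts = {d: [0, 0] for d in degrees}
    for pair in set(t) | set(r):
        counts[assign_degree(t.get(pair, 0.0), cfg)][0] += 1
        counts[assign_degree(r.get(pair, 0.0), cfg)][1] += 1
    return pd.DataFrame(
        {
            "degree": [str(d) for d in degrees],
            "n_truth": [counts[d][0] for d in degrees],
            "n_reported": [counts[d][1] for d in degrees],
        }
    )


def pair_totals_frame(
    segments: Sequence[IBDSegment], cfg: RelatednessConfig
) -> pd.DataFrame:
    """Long-form table (sample1, sample2, total_cm, degree) per pair."""
    totals = total_ibd_per_pair(segments)
    rows = [
        (s1, s2, tot, str(assign_degree(tot, cfg)))
        for (s1, s2), tot in sorted(totals.items())
    ]
    return pd.DataFrame(rows, columns=["sample1", "sample2", "total_cm", "degree"])
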