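"""Shared domain types for IBD-segment benchmarking.

Conventions used throughout the package:

* Physical coordinates are base pairs on a single chromosome; every
  segment occupies a half-open interval ``[start_bp, end_bp)``.
* Genetic coordinates are centiMorgans obtained by piecewise-linear
  interpolation of a genetic map; the genetic length of a segment is
  ``cm(end_bp) - cm(start_bp)``.
* A haplotype is identified by ``(sample_id, hap_index)`` with
  ``hap_index`` in {0, 1}; haplotype pairs are unordered and
  canonicalized lexicographically on ``(sample_id, hap_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np

__all__ = [
    "IbdBenchError",
    "ConfigError",
    "FormatError",
    "HaplotypeId",
    "HapPair",
    "IBDSegment",
    "GeneticMap",
    "MetricConfig",
    "segment_from_bp",
    "overlap_cm",
    "pair_key",
]


class IbdBenchError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(IbdBenchError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(IbdBenchError):
    """Malformed input file; the message names the file and location."""


@dataclass(frozen=True, order=True)
class HaplotypeId:
    """One phased haplotype of a diploid sample.

    Ordering (used for pair canonicalization) is lexicographic on
    ``(sample_id, hap_index)``.
    """

    sample_id: str
    hap_index: int

    def __post_init__(self) -> None:
        if self.hap_index not in (0, 1):
            raise ValueError(f"hap_index must be 0 or 1, got {self.hap_index}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.sample_id}.{self.hap_index}"


@dataclass(frozen=True)
class HapPair:
    """Unordered pair of distinct haplotypes.

    ``HapPair(a, b) == HapPair(b, a)``: the constructor swaps the two
    ids into canonical (sorted) order, so equality and hashing are
    order-insensitive.
    """

    a: HaplotypeId
    b: HaplotypeId

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"degenerate pair: {self.a} twice")
        if self.b < self.a:
            lo, hi = self.b, self.a
            object.__setattr__(self, "a", lo)
            object.__setattr__(self, "b", hi)

    @property
    def within_individual(self) -> bool:
        """True when both haplotypes belong to one sample."""
        return self.a.sample_id == self.b.sample_id

    @property
    def sample_pair(self) -> Tuple[str, str]:
        """Sorted ``(sample_id, sample_id)`` tuple, ignoring hap indices."""
        s1, s2 = self.a.sample_id, self.b.sample_id
        return (s1, s2) if s1 <= s2 else (s2, s1)

    def sort_key(self):
        return (self.a.sample_id, self.a.hap_index, self.b.sample_id, self.b.hap_index)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.a}-{self.b}"


@dataclass(frozen=True)
class IBDSegment:
    """A shared segment between one haplotype pair.

    Physical bounds are half-open ``[start_bp, end_bp)``; genetic bounds
    must come from the same map that all segments in a comparison use.
    """

    pair: HapPair
    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float

    def __post_init__(self) -> None:
        if self.start_bp < 0:
            raise ValueError(f"start_bp must be >= 0, got {self.start_bp}")
        if self.end_bp <= self.start_bp:
            raise ValueError(
                f"end_bp must exceed start_bp, got [{self.start_bp}, {self.end_bp})"
            )
        if self.end_cm < self.start_cm:
            raise ValueError(
                f"end_cm must be >= start_cm, got [{self.start_cm}, {self.end_cm}]"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    def sort_key(self):
        return (*self.pair.sort_key(), self.chrom, self.start_bp, self.end_bp)


class GeneticMap:
    """Monotone piecewise-linear map between physical (bp) and genetic (cM)
    position on one chromosome.

    Positions outside the mapped bp range are clamped to the terminal cM
    values rather than extrapolated, which protects sparse maps from
    producing negative or inflated genetic lengths.
    """

    def __init__(
        self,
        pos_bp: Sequence[int] | np.ndarray,
        pos_cm: Sequence[float] | np.ndarray,
        chrom: str = "1",
    ) -> None:
        bp = np.asarray(pos_bp, dtype=np.int64)
        cm = np.asarray(pos_cm, dtype=np.float64)
        if bp.ndim != 1 or bp.shape != cm.shape:
            raise ConfigError("genetic map: pos_bp and pos_cm must be equal-length 1-d")
        if bp.size < 2:
            raise ConfigError("genetic map: at least 2 points required")
        if not np.all(np.diff(bp) > 0):
            raise ConfigError("genetic map: bp positions must be strictly increasing")
        if not np.all(np.diff(cm) >= 0):
            raise ConfigError("genetic map: cM positions must be non-decreasing")
        self.pos_bp = bp
        self.pos_cm = cm
        self.chrom = str(chrom)

    @property
    def first_bp(self) -> int:
        return int(self.pos_bp[0])

    @property
    def last_bp(self) -> int:
        return int(self.pos_bp[-1])

    @property
    def first_cm(self) -> float:
        return float(self.pos_cm[0])

    @property
    def last_cm(self) -> float:
        return float(self.pos_cm[-1])

    @property
    def total_cm(self) -> float:
        return float(self.pos_cm[-1] - self.pos_cm[0])

    def bp_to_cm(self, pos_bp):
        """Interpolate genetic position at one or many physical positions.

        Accepts a scalar or array; returns the same shape. Out-of-range
        positions clamp to the terminal cM values.
        """
        out = np.interp(np.asarray(pos_bp, dtype=np.float64), self.pos_bp, self.pos_cm)
        if np.isscalar(pos_bp) or np.ndim(pos_bp) == 0:
            return float(out)
        return out

    def cm_to_bp(self, pos_cm):
        """Inverse interpolation, genetic to physical position.

        On flat map stretches (zero recombination) the left edge is
        returned; out-of-range genetic positions clamp to terminal bp.
        """
        out = np.interp(np.asarray(pos_cm, dtype=np.float64), self.pos_cm, self.pos_bp)
        if np.isscalar(pos_cm) or np.ndim(pos_cm) == 0:
            return float(out)
        return out

    @classmethod
    def uniform(cls, length_bp: int, cm_per_mb: float = 1.0, chrom: str = "1") -> "GeneticMap":
        """Constant-rate map over ``[0, length_bp]``; handy for simulation."""
        return cls([0, int(length_bp)], [0.0, length_bp / 1e6 * cm_per_mb], chrom=chrom)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GeneticMap(chrom={self.chrom!r}, n_points={self.pos_bp.size}, "
            f"bp=[{self.first_bp}, {self.last_bp}], total_cm={self.total_cm:.3f})"
        )


@dataclass
class MetricConfig:
    """Knobs shared by the evaluation metrics.

    coverage_threshold
        Fraction of a segment's genetic length that must be covered by a
        single best-matching segment for it to count as accurate
        (reported side) or recalled (truth side). Default 0.5.
    bin_edges_cm
        Length-bin edges in cM; bins are ``[e_i, e_{i+1})`` with the last
        bin open-ended, and segments shorter than the first edge are not
        binned. Default produces [2,3), [3,4), [4,5), [5,6), [6,7), [7,inf).
    pair_mode
        ``"haplotype"`` compares segments only within the identical
        unordered haplotype pair; ``"individual"`` pools the four
        haplotype combinations of a sample pair, for detectors that do
        not emit haplotype indices.
    """

    coverage_threshold: float = 0.5
    bin_edges_cm: Tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
    pair_mode: str = "haplotype"

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage_threshold <= 1.0):
            raise ConfigError(
                f"metrics.coverage_threshold: must be in (0, 1], got {self.coverage_threshold}"
            )
        edges = tuple(float(e) for e in self.bin_edges_cm)
        if len(edges) >= 2 and not all(a < b for a, b in zip(edges, edges[1:])):
            raise ConfigError("metrics.bin_edges_cm: edges must be strictly increasing")
        self.bin_edges_cm = edges
        if self.pair_mode not in ("haplotype", "individual"):
            raise ConfigError(
                f"metrics.pair_mode: must be 'haplotype' or 'individual', got {self.pair_mode!r}"
            )


def segment_from_bp(
    pair: HapPair, chrom: str, start_bp: int, end_bp: int, gmap: GeneticMap
) -> IBDSegment:
    """Build a segment from physical bounds, interpolating its genetic bounds."""
    return IBDSegment(
        pair=pair,
        chrom=chrom,
        start_bp=int(start_bp),
        end_bp=int(end_bp),
        start_cm=gmap.bp_to_cm(int(start_bp)),
        end_cm=gmap.bp_to_cm(int(end_bp)),
    )


def pair_key(pair: HapPair, pair_mode: str = "haplotype"):
    """Grouping key under which two segments are comparable."""
    if pair_mode == "haplotype":
        return pair
    if pair_mode == "individual":
        return pair.sample_pair
    raise ConfigError(f"pair_mode: unknown mode {pair_mode!r}")


def overlap_cm(x: IBDSegment, y: IBDSegment, pair_mode: str = "haplotype") -> float:
    """Genetic length of the intersection of two segments.

    Zero when the segments are on different chromosomes, belong to
    different pairs under ``pair_mode``, or are disjoint in cM.
    """
    if x.chrom != y.chrom:
        return 0.0
    if pair_key(x.pair, pair_mode) != pair_key(y.pair, pair_mode):
        return 0.0
    lo = max(x.start_cm, y.start_cm)
    hi = min(x.end_cm, y.end_cm)
    return max(0.0, hi - lo)


def sort_segments(segments: Iterable[IBDSegment]) -> list[IBDSegment]:
    """Canonical (pair, start) ordering used by all writers."""
    return sorted(segments, key=lambda s: s.sort_key())
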