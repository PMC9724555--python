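"""Local-tree tracks: piecewise-constant genealogies along a chromosome.

A track answers one question: for a given haplotype pair, what is the
label of the pair's most recent common ancestor (MRCA) at each genomic
position? Ground-truth IBD extraction only needs label *equality* along
the chromosome, so labels are opaque integers.

Two concrete tracks are provided:

``ArrayTrack``
    Per-pair piecewise-constant labels stored as breakpoint/label
    arrays. This is the synthetic-track form and the text file format's
    in-memory image.
``TreeSequenceTrack``
    Adapter over a tskit tree sequence (e.g. msprime output); the MRCA
    label at a position is the MRCA node id in the local tree.
"""

from __future__ import annotations

import itertools
from abc import ABC, abstractmethod
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np

from .core import HapPair, HaplotypeId

__all__ = ["LocalTreeTrack", "ArrayTrack", "TreeSequenceTrack"]


class LocalTreeTrack(ABC):
    """Abstract pairwise-MRCA lookup over a chromosome region ``[0, L)``."""

    chrom: str
    sequence_length: int
    haplotypes: List[HaplotypeId]

    def pairs(self, include_within_individual: bool = False) -> Iterator[HapPair]:
        """All unordered haplotype pairs, by default excluding pairs whose
        two haplotypes belong to one sample."""
        for a, b in itertools.combinations(self.haplotypes, 2):
            pair = HapPair(a, b)
            if pair.within_individual and not include_within_individual:
                continue
            yield pair

    @abstractmethod
    def pair_labels(self, pair: HapPair, positions: np.ndarray) -> np.ndarray:
        """MRCA label of ``pair`` in the local tree containing each position.

        ``positions`` must be sorted and inside ``[0, L)``.
        """

    @abstractmethod
    def pair_intervals(self, pair: HapPair) -> Tuple[np.ndarray, np.ndarray]:
        """``(ends_bp, labels)`` for the pair's piecewise-constant label
        function: interval i is ``[ends[i-1], ends[i])`` (first starts at
        0) and carries ``labels[i]``. ``ends[-1] == sequence_length``."""

    def _check_positions(self, positions: np.ndarray) -> np.ndarray:
        pos = np.asarray(positions, dtype=np.int64)
        if pos.size and (pos[0] < 0 or pos[-1] >= self.sequence_length):
            raise ValueError(
                f"positions outside region [0, {self.sequence_length}): "
                f"[{pos[0]}, {pos[-1]}]"
            )
        return pos


class ArrayTrack(LocalTreeTrack):
    """Track with independent per-pair breakpoints.

    ``intervals`` maps each HapPair to ``(ends_bp, labels)`` arrays where
    ``ends_bp`` is strictly increasing and terminates at the region
    length. Pairs absent from the mapping get a single whole-region
    interval with a pair-unique label (MRCA never changes).
    """

    def __init__(
        self,
        chrom: str,
        sequence_length: int,
        haplotypes: Sequence[HaplotypeId],
        intervals: Dict[HapPair, Tuple[np.ndarray, np.ndarray]],
    ) -> None:
        self.chrom = str(chrom)
        self.sequence_length = int(sequence_length)
        self.haplotypes = list(haplotypes)
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("duplicate haplotype ids in track")
        self._intervals: Dict[HapPair, Tuple[np.ndarray, np.ndarray]] = {}
        for pair, (ends, labels) in intervals.items():
            ends = np.asarray(ends, dtype=np.int64)
            labels = np.asarray(labels, dtype=np.int64)
            if ends.size == 0 or ends.size != labels.size:
                raise ValueError(f"pair {pair}: ends/labels size mismatch")
            if ends[-1] != self.sequence_length or not np.all(np.diff(ends) > 0):
                raise ValueError(
                    f"pair {pair}: interval ends must increase to region length"
                )
            self._intervals[pair] = (ends, labels)

    @classmethod
    def from_segments(
        cls,
        chrom: str,
        sequence_length: int,
        haplotypes: Sequence[HaplotypeId],
        pair_segments: Dict[HapPair, Sequence[Tuple[int, int, int]]],
    ) -> "ArrayTrack":
        """Build from explicit ``(start_bp, end_bp, label)`` triples that
        partition the region for each pair (convenient in tests)."""
        intervals = {}
        for pair, segs in pair_segments.items():
            segs = sorted(segs)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            labels = np.array([lab for _, _, lab in segs], dtype=np.int64)
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            expect_starts = np.concatenate([[0], ends[:-1]])
            if not np.array_equal(starts, expect_starts):
                raise ValueError(f"pair {pair}: intervals do not partition region")
            intervals[pair] = (ends, labels)
        return cls(chrom, sequence_length, haplotypes, intervals)

    def pair_intervals(self, pair: HapPair) -> Tuple[np.ndarray, np.ndarray]:
        got = self._intervals.get(pair)
        if got is None:
            # constant MRCA over the whole region, unique to the pair
            lab = hash(pair) & 0x7FFFFFFF
            return (
                np.array([self.sequence_length], dtype=np.int64),
                np.array([lab], dtype=np.int64),
            )
        return got

    def pair_labels(self, pair: HapPair, positions: np.ndarray) -> np.ndarray:
        pos = self._check_positions(positions)
        ends, labels = self.pair_intervals(pair)
        idx = np.searchsorted(ends, pos, side="right")
        return labels[idx]


class TreeSequenceTrack(LocalTreeTrack):
    """Adapter exposing a tskit tree sequence as a local-tree track.

    Sample nodes are grouped into diploid individuals: via the tree
    sequence's individual table when populated, otherwise consecutive
    sample nodes ``(2k, 2k+1)`` form individual ``tsk_k``. The MRCA label
    is the MRCA node id; positions where the pair has no common ancestor
    (multi-root trees) get label -1, which truth extraction skips.
    """

    def __init__(self, ts, chrom: str = "1") -> None:
        self.ts = ts
        self.chrom = str(chrom)
        self.sequence_length = int(ts.sequence_length)
        self.haplotypes = []
        self._node_of: Dict[HaplotypeId, int] = {}
        samples = list(ts.samples())
        individuals = {}
        for node in samples:
            ind = ts.node(node).individual
            individuals.setdefault(ind, []).append(node)
        if -1 not in individuals and all(len(v) == 2 for v in individuals.values()):
            items = sorted(individuals.items())
            for ind, nodes in items:
                for h, node in enumerate(sorted(nodes)):
                    hid = HaplotypeId(f"tsk_{ind}", h)
                    self.haplotypes.append(hid)
                    self._node_of[hid] = node
        else:
            if len(samples) % 2 != 0:
                raise ValueError("tree sequence has an odd number of sample nodes")
            for i, node in enumerate(samples):
                hid = HaplotypeId(f"tsk_{i // 2}", i % 2)
                self.haplotypes.append(hid)
                self._node_of[hid] = node
        self._breakpoints = np.array(list(ts.breakpoints()), dtype=np.int64)

    def node_of(self, hap: HaplotypeId) -> int:
        return self._node_of[hap]

    def pair_intervals(self, pair: HapPair) -> Tuple[np.ndarray, np.ndarray]:
        u, v = self._node_of[pair.a], self._node_of[pair.b]
        labels = np.fromiter(
            (t.mrca(u, v) for t in self.ts.trees()),
            dtype=np.int64,
            count=self.ts.num_trees,
        )
        ends = self._breakpoints[1:]
        return ends, labels

    def pair_labels(self, pair: HapPair, positions: np.ndarray) -> np.ndarray:
        pos = self._check_positions(positions)
        ends, labels = self.pair_intervals(pair)
        idx = np.searchsorted(ends, pos, side="right")
        return labels[idx]
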