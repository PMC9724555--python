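"""Operations on phased haplotype panels.

The pipeline turns a full sequencing-density panel into the test panels
a detector sees:

1. :func:`filter_sites` — drop multiallelic sites and singletons.
2. :func:`downsample_to_array` — emulate a genotyping array by picking
   an evenly spaced, high-MAF marker subset (two-pass interval/window
   selection).
3. :func:`inject_genotyping_errors` — flip alleles at a controlled
   per-allele rate, supporting incremental chaining from a lower rate.
4. :func:`merge_haplotypes_to_genotypes` — collapse phased haplotypes
   into unphased genotypes (input to an external rephasing step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Sequence, Tuple

import numpy as np

from .core import ConfigError, GeneticMap, HaplotypeId

__all__ = [
    "HaplotypePanel",
    "GenotypeTable",
    "DownsampleConfig",
    "ErrorSpec",
    "filter_sites",
    "downsample_to_array",
    "inject_genotyping_errors",
    "merge_haplotypes_to_genotypes",
]


class HaplotypePanel:
    """Phased haplotype matrix on one chromosome.

    ``alleles`` has shape (n_sites, n_haplotypes) with small integer
    codes (0 = REF, k = k-th ALT). Positions are the physical (VCF POS)
    coordinates and must be strictly increasing, which also pins the
    panel to a single chromosome.
    """

    def __init__(
        self,
        haplotypes: Sequence[HaplotypeId],
        chrom: str,
        positions: Sequence[int] | np.ndarray,
        alleles: np.ndarray,
        ref: Optional[Sequence[str]] = None,
        alt: Optional[Sequence[Tuple[str, ...]]] = None,
    ) -> None:
        self.haplotypes = list(haplotypes)
        self.chrom = str(chrom)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.alleles = np.asarray(alleles, dtype=np.int8)
        n_sites = self.positions.size
        if self.alleles.shape != (n_sites, len(self.haplotypes)):
            raise ValueError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{n_sites} sites x {len(self.haplotypes)} haplotypes"
            )
        if n_sites > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("site positions must be strictly increasing")
        if len(set(self.haplotypes)) != len(self.haplotypes):
            raise ValueError("duplicate haplotype ids in panel")
        self.ref = list(ref) if ref is not None else ["A"] * n_sites
        self.alt = [tuple(a) for a in alt] if alt is not None else [("C",)] * n_sites
        if len(self.ref) != n_sites or len(self.alt) != n_sites:
            raise ValueError("ref/alt length does not match site count")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def allele_value_counts(self) -> np.ndarray:
        """Number of distinct allele values observed per site."""
        return np.array(
            [np.unique(self.alleles[i]).size for i in range(self.n_sites)]
        )

    def minor_allele_count(self) -> np.ndarray:
        """Per-site count of the rarer observed allele (biallelic view:
        total haplotypes minus the majority-allele count)."""
        counts = np.empty(self.n_sites, dtype=np.int64)
        for i in range(self.n_sites):
            _, c = np.unique(self.alleles[i], return_counts=True)
            counts[i] = self.n_haplotypes - c.max()
        return counts

    def maf(self) -> np.ndarray:
        """Per-site minor allele frequency (folded)."""
        return self.minor_allele_count() / float(self.n_haplotypes)

    def is_biallelic(self) -> np.ndarray:
        return self.allele_value_counts() <= 2

    def subset_sites(self, index) -> "HaplotypePanel":
        """Panel restricted to the given site indices (kept in order)."""
        idx = np.asarray(index)
        return HaplotypePanel(
            haplotypes=self.haplotypes,
            chrom=self.chrom,
            positions=self.positions[idx],
            alleles=self.alleles[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
        )

    def copy(self) -> "HaplotypePanel":
        return HaplotypePanel(
            haplotypes=list(self.haplotypes),
            chrom=self.chrom,
            positions=self.positions.copy(),
            alleles=self.alleles.copy(),
            ref=list(self.ref),
            alt=list(self.alt),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"HaplotypePanel(chrom={self.chrom!r}, n_sites={self.n_sites}, "
            f"n_haplotypes={self.n_haplotypes})"
        )


@dataclass
class GenotypeTable:
    """Unphased diploid genotypes, one column per individual.

    ``dosage`` holds the ALT-allele count per (site, individual); the
    unordered allele pair at a biallelic site is recoverable as
    (0,0), (0,1) or (1,1).
    """

    individuals: List[str]
    chrom: str
    positions: np.ndarray
    dosage: np.ndarray

    def alleles_at(self, site: int, individual: int) -> Tuple[int, int]:
        d = int(self.dosage[site, individual])
        return {0: (0, 0), 1: (0, 1), 2: (1, 1)}[d]


@dataclass
class DownsampleConfig:
    """Array-density downsampling parameters.

    target_sites
        Desired marker count; the chromosome's genetic length divided by
        this gives the ideal inter-marker interval I (cM). Default
        17,197 (the UK Biobank chromosome-20 array count used as the
        reference density).
    window_w
        Number of consecutive I-intervals pooled when an interval has no
        marker of its own. Default 5.
    """

    target_sites: int = 17197
    window_w: int = 5

    def __post_init__(self) -> None:
        if self.target_sites < 1:
            raise ConfigError(f"downsample.target_sites: must be >= 1, got {self.target_sites}")
        if self.window_w < 1:
            raise ConfigError(f"downsample.window_w: must be >= 1, got {self.window_w}")


@dataclass(frozen=True)
class ErrorSpec:
    """Genotyping-error injection parameters.

    rate
        Target marginal flip probability per haploid allele call
        (e.g. 0.001 for 0.1%).
    seed
        Seed for the flip draw; same spec and panel give identical output.
    base_errors
        Cells (site_index, haplotype_index) already flipped in the input
        panel by a previous, lower-rate injection. New flips are drawn
        only on the remaining cells with the top-up probability
        (rate - r1) / (1 - r1), so the marginal rate is exactly ``rate``
        and error sets are nested across an incremental chain.
    """

    rate: float
    seed: int = 0
    base_errors: FrozenSet[Tuple[int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0.0 <= self.rate <= 1.0):
            raise ConfigError(f"errors.rate: must be in [0, 1], got {self.rate}")


def filter_sites(panel: HaplotypePanel) -> HaplotypePanel:
    """Drop sites with more than two observed allele values and sites
    whose minor allele count is <= 1 (singletons and monomorphic sites).

    Idempotent; the haplotype set is unchanged and an empty result is
    allowed.
    """
    keep = panel.is_biallelic() & (panel.minor_allele_count() >= 2)
    return panel.subset_sites(np.nonzero(keep)[0])


def downsample_to_array(
    panel: HaplotypePanel,
    gmap: GeneticMap,
    cfg: Optional[DownsampleConfig] = None,
) -> HaplotypePanel:
    """Select an evenly spaced, high-MAF marker subset emulating an array.

    The chromosome's mapped genetic length is cut into ``target_sites``
    consecutive intervals of width I = total_cm / target_sites, grouped
    into windows of ``window_w`` intervals (a final partial window keeps
    its available intervals). Pass 1 gives every interval its highest-MAF
    site, if it has any. Pass 2 walks the still-empty intervals left to
    right and fills each with the highest-MAF unused site from its
    window, until window leftovers run out. MAF ties break toward the
    lower bp position. Site order is preserved in the output.
    """
    cfg = cfg or DownsampleConfig()
    if cfg.target_sites >= panel.n_sites:
        if cfg.target_sites > panel.n_sites:
            warnings.warn(
                f"downsample target {cfg.target_sites} exceeds available "
                f"{panel.n_sites} sites; returning all sites"
            )
        return panel.subset_sites(np.arange(panel.n_sites))

    site_cm = np.atleast_1d(gmap.bp_to_cm(panel.positions))
    total_cm = gmap.total_cm
    if total_cm <= 0:
        raise ConfigError("downsample: genetic map has zero total length")
    interval_width = total_cm / cfg.target_sites
    interval = np.floor((site_cm - gmap.first_cm) / interval_width).astype(np.int64)
    np.clip(interval, 0, cfg.target_sites - 1, out=interval)
    window = interval // cfg.window_w

    maf = panel.maf()
    # Deterministic preference order: higher MAF first, then lower bp.
    order = np.lexsort((panel.positions, -maf))

    best_in_interval: dict[int, int] = {}
    sites_by_window: dict[int, list[int]] = {}
    for s in order:
        iv = int(interval[s])
        if iv not in best_in_interval:
            best_in_interval[iv] = int(s)
        sites_by_window.setdefault(int(window[s]), []).append(int(s))

    selected = set(best_in_interval.values())
    # Pass 2: empty intervals draw the best unused site from their window.
    for iv in range(cfg.target_sites):
        if iv in best_in_interval:
            continue
        for s in sites_by_window.get(iv // cfg.window_w, ()):
            if s not in selected:
                selected.add(s)
                break

    return panel.subset_sites(np.array(sorted(selected), dtype=np.int64))


def inject_genotyping_errors(
    panel: HaplotypePanel, spec: ErrorSpec
) -> Tuple[HaplotypePanel, FrozenSet[Tuple[int, int]]]:
    """Flip alleles 0<->1 so the panel carries errors at ``spec.rate``.

    Returns the perturbed panel and the full error set (base errors plus
    new flips). The panel must be biallelic (allele codes 0/1 only).
    """
    if panel.n_sites and int(panel.alleles.max(initial=0)) > 1:
        raise ConfigError("errors: panel must be biallelic (allele codes 0/1)")
    n_cells = panel.n_sites * panel.n_haplotypes
    if n_cells == 0:
        return panel.copy(), frozenset(spec.base_errors)
    r1 = len(spec.base_errors) / n_cells
    if spec.rate < r1:
        raise ConfigError(
            f"errors.rate: target rate {spec.rate} below realized base rate {r1:.6g}"
        )
    p_add = 0.0 if r1 >= 1.0 else (spec.rate - r1) / (1.0 - r1)

    rng = np.random.default_rng(spec.seed)
    draw = rng.random(panel.alleles.shape) < p_add
    if spec.base_errors:
        base_idx = np.array(sorted(spec.base_errors), dtype=np.int64)
        draw[base_idx[:, 0], base_idx[:, 1]] = False
    out = panel.copy()
    out.alleles[draw] ^= 1
    new_cells = {(int(i), int(j)) for i, j in zip(*np.nonzero(draw))}
    return out, frozenset(spec.base_errors) | frozenset(new_cells)


def merge_haplotypes_to_genotypes(panel: HaplotypePanel) -> GenotypeTable:
    """Merge every two consecutive haplotype columns into one unphased
    diploid genotype.

    Requires an even haplotype count and a biallelic panel. When columns
    2k and 2k+1 share a sample id that id names individual k; otherwise
    a synthetic ``ind{k}`` id is used.
    """
    if panel.n_haplotypes % 2 != 0:
        raise ValueError(f"odd haplotype count {panel.n_haplotypes}; cannot pair")
    if panel.n_sites and int(panel.alleles.max(initial=0)) > 1:
        raise ValueError("merge: panel must be biallelic (allele codes 0/1)")
    individuals = []
    for k in range(panel.n_haplotypes // 2):
        a, b = panel.haplotypes[2 * k], panel.haplotypes[2 * k + 1]
        individuals.append(a.sample_id if a.sample_id == b.sample_id else f"ind{k}")
    dosage = panel.alleles[:, 0::2].astype(np.int8) + panel.alleles[:, 1::2]
    return GenotypeTable(
        individuals=individuals,
        chrom=panel.chrom,
        positions=panel.positions.copy(),
        dosage=dosage,
    )
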