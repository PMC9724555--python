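"""Readers and writers for every external format the pipeline touches.

Formats
-------
* Phased VCF 4.2 — haplotype panels in, perturbed panels out (cyvcf2
  reads, pysam writes; uncompressed or bgzipped input both work).
* Genetic maps — PLINK ``.map`` (chrom, id, cM, bp) and HapMap-style
  text (chrom, pos, rate, cM; header line).
* Reported-IBD call files — hap-IBD-style 8-column TSV plus a
  configurable generic dialect for other detectors.
* Truth-IBD TSV — this framework's own segment serialization.
* Local-tree tracks — tskit ``.trees`` files (the only binary input) or
  the framework's text track format.

Coordinate handling: detector call files are assumed 1-based inclusive
in bp (the common VCF-derived convention) and converted to the internal
half-open 0-based representation on read; the dialect can override
this. Genetic start/end positions are always (re)computed from the
supplied map so every detector is scored against one map; a stored cM
length disagreeing by more than 0.01 cM is counted and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    FormatError,
    GeneticMap,
    HapPair,
    HaplotypeId,
    IBDSegment,
    sort_segments,
)
from .panelops import HaplotypePanel
from .track import ArrayTrack, LocalTreeTrack, TreeSequenceTrack

logger = logging.getLogger(__name__)

__all__ = [
    "IbdDialect",
    "HAPIBD_DIALECT",
    "TRUTH_DIALECT",
    "read_vcf",
    "write_vcf",
    "read_genetic_map",
    "write_plink_map",
    "read_ibd_calls",
    "read_truth_ibd",
    "write_truth_ibd",
    "read_track",
    "write_track",
    "load_tree_sequence_track",
]

TRUTH_COLUMNS = (
    "sample1", "hap1", "sample2", "hap2", "chrom",
    "start_bp", "end_bp", "start_cm", "end_cm",
)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path, phased_required: bool = True) -> HaplotypePanel:
    """Read a (single-chromosome) VCF into a haplotype panel.

    Multiallelic records are permitted (alleles coded 0..k) and flagged
    for downstream filtering. An unphased diploid genotype is a hard
    error when ``phased_required``.
    """
    import cyvcf2

    path = str(path)
    vcf = cyvcf2.VCF(path)
    samples = list(vcf.samples)
    haplotypes = [HaplotypeId(s, h) for s in samples for h in (0, 1)]
    positions: List[int] = []
    rows: List[np.ndarray] = []
    ref: List[str] = []
    alt: List[Tuple[str, ...]] = []
    chrom: Optional[str] = None
    for var in vcf:
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise FormatError(
                f"{path}: multiple chromosomes ({chrom}, {var.CHROM}); "
                "panels are single-chromosome"
            )
        row = np.empty(2 * len(samples), dtype=np.int8)
        for j, gt in enumerate(var.genotypes):
            if len(gt) < 3:
                raise FormatError(
                    f"{path}: {var.CHROM}:{var.POS} sample {samples[j]}: "
                    "haploid genotype unsupported"
                )
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise FormatError(
                    f"{path}: {var.CHROM}:{var.POS} sample {samples[j]}: missing allele"
                )
            if phased_required and not phased:
                raise FormatError(
                    f"{path}: {var.CHROM}:{var.POS} sample {samples[j]}: "
                    "unphased genotype in phased panel"
                )
            row[2 * j] = a
            row[2 * j + 1] = b
        positions.append(var.POS)
        rows.append(row)
        ref.append(var.REF)
        alt.append(tuple(var.ALT))
    alleles = (
        np.vstack(rows) if rows else np.empty((0, 2 * len(samples)), dtype=np.int8)
    )
    return HaplotypePanel(
        haplotypes=haplotypes,
        chrom=chrom if chrom is not None else "1",
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        ref=ref,
        alt=alt,
    )


def write_vcf(panel: HaplotypePanel, path, extra_header: Sequence[str] = ()) -> None:
    """Write a panel as uncompressed VCF 4.2 with phased GT fields."""
    import pysam

    samples = []
    for k in range(0, panel.n_haplotypes, 2):
        a = panel.haplotypes[k]
        b = panel.haplotypes[k + 1] if k + 1 < panel.n_haplotypes else None
        if b is None or a.sample_id != b.sample_id:
            raise FormatError(
                "write_vcf: haplotypes must come in consecutive (sample,0),(sample,1) pairs"
            )
        samples.append(a.sample_id)
    header = pysam.VariantHeader()
    contig_len = int(panel.positions[-1]) + 1 if panel.n_sites else 1
    header.contigs.add(panel.chrom, length=contig_len)
    header.formats.add("GT", 1, "String", "Genotype")
    for line in extra_header:
        header.add_line(line)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in range(panel.n_sites):
            rec = out.new_record(
                contig=panel.chrom,
                start=int(panel.positions[i]) - 1,
                alleles=(panel.ref[i], *panel.alt[i]),
            )
            rec.id = f"site{i}"
            row = panel.alleles[i]
            for j, s in enumerate(samples):
                rec.samples[s]["GT"] = (int(row[2 * j]), int(row[2 * j + 1]))
                rec.samples[s].phased = True
            out.write(rec)


# ---------------------------------------------------------------------------
# Genetic maps

def read_genetic_map(path, dialect: str = "plink") -> GeneticMap:
    """Read a genetic map in PLINK or HapMap-style text layout.

    PLINK: four whitespace-separated columns (chrom, id, cM, bp), no
    header. HapMap: header line then (chrom, pos, rate, cM). Points are
    sorted by bp; a cM column that decreases after sorting is an error.
    """
    path = str(path)
    if dialect not in ("plink", "hapmap"):
        raise FormatError(f"{path}: unknown genetic map dialect {dialect!r}")
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=0 if dialect == "hapmap" else None,
            comment="#",
            dtype=str,
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse genetic map: {exc}") from exc
    if df.shape[1] < 4:
        raise FormatError(f"{path}: genetic map needs 4 columns, found {df.shape[1]}")
    if df.isna().any().any():
        raise FormatError(f"{path}: truncated or ragged genetic map file")
    if dialect == "plink":
        chrom = df.iloc[0, 0]
        cm = df.iloc[:, 2].astype(float).to_numpy()
        bp = df.iloc[:, 3].astype(int).to_numpy()
    else:
        chrom = df.iloc[0, 0]
        bp = df.iloc[:, 1].astype(int).to_numpy()
        cm = df.iloc[:, 3].astype(float).to_numpy()
    order = np.argsort(bp, kind="stable")
    bp, cm = bp[order], cm[order]
    bad = np.nonzero(np.diff(cm) < 0)[0]
    if bad.size:
        raise FormatError(
            f"{path}: cM decreases between map lines {bad[0] + 1} and {bad[0] + 2} "
            "(after sorting by bp)"
        )
    return GeneticMap(bp, cm, chrom=str(chrom))


def write_plink_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        for i, (bp, cm) in enumerate(zip(gmap.pos_bp, gmap.pos_cm)):
            fh.write(f"{gmap.chrom}\tm{i}\t{float(cm)!r}\t{int(bp)}\n")


# ---------------------------------------------------------------------------
# IBD call files

@dataclass
class IbdDialect:
    """Column layout of a detector's IBD call file.

    ``column_map`` maps logical fields (sample1, hap1, sample2, hap2,
    chrom, start_bp, end_bp, length_cm) to 0-based column indices; hap
    fields may be omitted for detectors that report individual pairs
    only. ``hap_base`` is the value the file uses for the first
    haplotype (hap-IBD writes 1/2). ``one_based_inclusive`` says whether
    bp coordinates are 1-based inclusive (converted to internal
    half-open 0-based on read).
    """

    name: str
    column_map: Dict[str, int]
    has_header: bool = False
    separator: str = "\t"
    hap_base: int = 0
    one_based_inclusive: bool = True

    def required_fields(self, pair_mode: str) -> Tuple[str, ...]:
        base = ("sample1", "sample2", "chrom", "start_bp", "end_bp")
        if pair_mode == "haplotype":
            return base + ("hap1", "hap2")
        return base


HAPIBD_DIALECT = IbdDialect(
    name="hapibd",
    column_map={
        "sample1": 0, "hap1": 1, "sample2": 2, "hap2": 3,
        "chrom": 4, "start_bp": 5, "end_bp": 6, "length_cm": 7,
    },
    has_header=False,
    hap_base=1,
    one_based_inclusive=True,
)

# The framework's own truth TSV doubles as a generic dialect: 0-based
# half-open bp, hap indices 0/1, header line present.
TRUTH_DIALECT = IbdDialect(
    name="truth",
    column_map={
        "sample1": 0, "hap1": 1, "sample2": 2, "hap2": 3, "chrom": 4,
        "start_bp": 5, "end_bp": 6, "start_cm": 7, "end_cm": 8,
    },
    has_header=True,
    hap_base=0,
    one_based_inclusive=False,
)

DIALECTS = {"hapibd": HAPIBD_DIALECT, "truth": TRUTH_DIALECT}


def _read_rows(path, dialect: IbdDialect, pair_mode: str) -> List[List[str]]:
    need = dialect.required_fields(pair_mode)
    missing = [f for f in need if f not in dialect.column_map]
    if missing:
        raise FormatError(
            f"{path}: dialect {dialect.name!r} lacks required columns {missing} "
            f"for pair_mode={pair_mode!r}"
        )
    max_col = max(dialect.column_map.values())
    rows = []
    header_pending = dialect.has_header
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                continue
            if header_pending:
                header_pending = False
                continue
            stripped = line.rstrip("\n")
            if not stripped:
                continue
            fields = stripped.split(dialect.separator) if dialect.separator != " " \
                else stripped.split()
            if len(fields) <= max_col:
                raise FormatError(
                    f"{path}: line {lineno}: {len(fields)} fields, "
                    f"need at least {max_col + 1} (truncated file?)"
                )
            rows.append(fields)
    return rows


def read_ibd_calls(
    path,
    dialect: IbdDialect | str,
    gmap: GeneticMap,
    pair_mode: str = "haplotype",
) -> List[IBDSegment]:
    """Parse a detector output file into canonical segments.

    Genetic bounds are recomputed from ``gmap``; records with
    non-positive physical length are skipped (counted in a warning log).
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise FormatError(f"{path}: unknown IBD dialect {dialect!r}") from None
    cm_col = dialect.column_map.get("length_cm")
    col = dialect.column_map
    segments: List[IBDSegment] = []
    n_skipped = 0
    n_cm_mismatch = 0
    for fields in _read_rows(path, dialect, pair_mode):
        h1 = int(fields[col["hap1"]]) - dialect.hap_base if "hap1" in col else 0
        h2 = int(fields[col["hap2"]]) - dialect.hap_base if "hap2" in col else 0
        start = int(fields[col["start_bp"]])
        end = int(fields[col["end_bp"]])
        if dialect.one_based_inclusive:
            start -= 1  # [start-1, end) half-open equals 1-based [start, end]
        if end <= start:
            n_skipped += 1
            continue
        pair = HapPair(
            HaplotypeId(fields[col["sample1"]], h1),
            HaplotypeId(fields[col["sample2"]], h2),
        )
        start_cm = gmap.bp_to_cm(start)
        end_cm = gmap.bp_to_cm(end)
        if cm_col is not None:
            stated = float(fields[cm_col])
            if abs((end_cm - start_cm) - stated) > 0.01:
                n_cm_mismatch += 1
        segments.append(
            IBDSegment(
                pair=pair,
                chrom=fields[col["chrom"]],
                start_bp=start,
                end_bp=end,
                start_cm=start_cm,
                end_cm=end_cm,
            )
        )
    if n_skipped:
        logger.warning("%s: skipped %d non-positive-length records", path, n_skipped)
    if n_cm_mismatch:
        logger.debug(
            "%s: %d records whose stated cM length differs from the map by > 0.01",
            path, n_cm_mismatch,
        )
    return segments


def read_truth_ibd(path) -> List[IBDSegment]:
    """Read the framework truth-IBD TSV (half-open 0-based bp, stored cM)."""
    segments: List[IBDSegment] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        return segments
    header = lines[0].split("\t")
    if tuple(header) != TRUTH_COLUMNS:
        raise FormatError(f"{path}: unexpected truth header {header}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != len(TRUTH_COLUMNS):
            raise FormatError(
                f"{path}: line {lineno}: {len(fields)} fields, expected "
                f"{len(TRUTH_COLUMNS)} (truncated file?)"
            )
        s1, h1, s2, h2, chrom, sb, eb, sc, ec = fields
        segments.append(
            IBDSegment(
                pair=HapPair(HaplotypeId(s1, int(h1)), HaplotypeId(s2, int(h2))),
                chrom=chrom,
                start_bp=int(sb),
                end_bp=int(eb),
                start_cm=float(sc),
                end_cm=float(ec),
            )
        )
    return segments


def write_truth_ibd(segments: Sequence[IBDSegment], path, header_comments: Sequence[str] = ()) -> None:
    """Write segments as the framework truth-IBD TSV (stable ordering,
    full-precision floats so read/write round-trips exactly)."""
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for seg in sort_segments(segments):
            fh.write(
                f"{seg.pair.a.sample_id}\t{seg.pair.a.hap_index}\t"
                f"{seg.pair.b.sample_id}\t{seg.pair.b.hap_index}\t"
                f"{seg.chrom}\t{seg.start_bp}\t{seg.end_bp}\t"
                f"{seg.start_cm!r}\t{seg.end_cm!r}\n"
            )


# ---------------------------------------------------------------------------
# Local-tree tracks

def write_track(track: LocalTreeTrack, path, header_comments: Sequence[str] = ()) -> None:
    """Serialize a track as the framework's text format: a header naming
    the region and haplotypes, then one (pair, interval end, label) row
    per piecewise-constant interval."""
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"## {comment}\n")
        fh.write(f"#chrom\t{track.chrom}\n")
        fh.write(f"#length\t{track.sequence_length}\n")
        haps = ",".join(f"{h.sample_id}:{h.hap_index}" for h in track.haplotypes)
        fh.write(f"#haplotypes\t{haps}\n")
        fh.write("sample1\thap1\tsample2\thap2\tend_bp\tlabel\n")
        for pair in track.pairs(include_within_individual=True):
            ends, labels = track.pair_intervals(pair)
            for e, lab in zip(ends, labels):
                fh.write(
                    f"{pair.a.sample_id}\t{pair.a.hap_index}\t"
                    f"{pair.b.sample_id}\t{pair.b.hap_index}\t{e}\t{lab}\n"
                )


def read_track(path) -> ArrayTrack:
    """Read the framework's text track format back into an ArrayTrack."""
    chrom = None
    length = None
    haplotypes: List[HaplotypeId] = []
    pair_rows: Dict[HapPair, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#chrom\t"):
                chrom = line.split("\t")[1]
                continue
            if line.startswith("#length\t"):
                length = int(line.split("\t")[1])
                continue
            if line.startswith("#haplotypes\t"):
                for tok in line.split("\t")[1].split(","):
                    sid, h = tok.rsplit(":", 1)
                    haplotypes.append(HaplotypeId(sid, int(h)))
                continue
            if line.startswith("sample1\t"):
                saw_header = True
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(
                    f"{path}: line {lineno}: expected 6 fields, got {len(fields)} "
                    "(truncated file?)"
                )
            s1, h1, s2, h2, end, lab = fields
            pair = HapPair(HaplotypeId(s1, int(h1)), HaplotypeId(s2, int(h2)))
            pair_rows.setdefault(pair, []).append((int(end), int(lab)))
    if chrom is None or length is None or not haplotypes or not saw_header:
        raise FormatError(f"{path}: incomplete track header")
    intervals = {}
    for pair, rows in pair_rows.items():
        rows.sort()
        intervals[pair] = (
            np.array([e for e, _ in rows], dtype=np.int64),
            np.array([lab for _, lab in rows], dtype=np.int64),
        )
    return ArrayTrack(chrom, length, haplotypes, intervals)


def load_tree_sequence_track(path, chrom: Optional[str] = None) -> TreeSequenceTrack:
    """Load a tskit ``.trees`` file as a local-tree track."""
    import tskit

    ts = tskit.load(str(path))
    return TreeSequenceTrack(ts, chrom=chrom or "1")
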