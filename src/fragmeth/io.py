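"""Readers for the standard genomic formats this package consumes.

Everything downstream works in a single coordinate convention: 0-based,
half-open intervals on the forward strand of the reference. SAM/BAM 1-based
positions are converted on ingest, bedMethyl/Bismark methylome positions are
normalized to the coordinate of the C of the forward-strand CpG wherever the
file dialect makes that possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")

# SAM FLAG bits
_FLAG_PAIRED = 0x1
_FLAG_PROPER_PAIR = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_SECONDARY = 0x100
_FLAG_QC_FAIL = 0x200
_FLAG_DUPLICATE = 0x400
_FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class Genome:
    """Reference genome held fully in memory as uppercase strings."""

    sequences: Dict[str, str]

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Return the 0-based half-open slice [start, end) of a chromosome."""
        return self.sequences[chrom][start:end]


@dataclass(frozen=True)
class CpGIsland:
    """A CpG island interval; the unit classified by this package.

    ``start``/``end`` are 0-based half-open; ``sequence`` is the genome slice
    of length L = end - start.
    """

    id: str
    chrom: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"island {self.id}: start >= end")
        if self.end - self.start < 2:
            raise ValueError(f"island {self.id}: must span at least one dinucleotide")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(f"island {self.id}: sequence length != end - start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedReadRecord:
    """A filtered alignment reduced to what break-site inference needs.

    ``start`` is the leftmost mapped position (1-based), ``end`` the rightmost
    (1-based, inclusive). ``five_prime_clipped`` is True when the CIGAR clips
    the 5' end of the read (on its own strand), in which case the mapped start
    does not mark a fragmentation site.
    """

    chrom: str
    start: int
    end: int
    strand: str
    five_prime_clipped: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("alignment end < start")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class MethylomeRecord:
    """One CpG of a WGBS methylome: coverage and methylated fraction.

    ``pos`` is the 0-based coordinate of the C of the forward-strand CpG
    (where the input dialect allows normalization; see load_methylome).
    """

    chrom: str
    pos: int
    coverage: int
    meth_fraction: float

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("negative coverage")
        if not 0.0 <= self.meth_fraction <= 1.0:
            raise ValueError("meth_fraction outside [0, 1]")


# ---------------------------------------------------------------------------
# FASTA


def load_genome(fasta_path) -> Genome:
    """Load a FASTA reference, uppercasing all bases.

    Soft-masked (lowercase) bases are kept as their uppercase nucleotide.
    Raises on a file that does not look like FASTA or repeats a chromosome
    name.
    """
    fasta_path = Path(fasta_path)
    with open(fasta_path) as handle:
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{fasta_path}: not FASTA, first record line is {line.strip()!r}"
                    )
                break
        else:
            raise ValueError(f"{fasta_path}: empty file")
    sequences: Dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{fasta_path}: duplicate chromosome name {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"{fasta_path}: chromosome {record.id!r} contains non-nucleotide "
                f"characters {sorted(bad)}"
            )
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"{fasta_path}: no FASTA records found")
    logger.info("loaded %d chromosomes from %s", len(sequences), fasta_path)
    return Genome(sequences)


# ---------------------------------------------------------------------------
# BED


def load_intervals(bed_path) -> List[Tuple[str, int, int, Optional[str]]]:
    """Parse a BED3/BED4 file into (chrom, start, end, name) tuples.

    Coordinates are 0-based half-open as in BED. Records with start >= end are
    rejected with a warning; non-numeric coordinates raise.
    """
    bed_path = Path(bed_path)
    out: List[Tuple[str, int, int, Optional[str]]] = []
    n_rejected = 0
    with open(bed_path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{bed_path}:{lineno}: non-numeric coordinates {fields[1:3]}"
                ) from exc
            if start >= end:
                logger.warning(
                    "%s:%d: rejecting empty/inverted interval %s:%d-%d",
                    bed_path, lineno, chrom, start, end,
                )
                n_rejected += 1
                continue
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else None
            out.append((chrom, start, end, name))
    logger.info("%s: %d intervals accepted, %d rejected", bed_path, len(out), n_rejected)
    return out


def load_islands(bed_path, genome: Genome) -> List[CpGIsland]:
    """Load CpG islands from BED and attach their genome sequence.

    Islands on chromosomes absent from the genome are dropped (with a logged
    count). Islands without a BED name get the stable id "chrom:start-end".
    Returned sorted by (chrom, start).
    """
    islands: List[CpGIsland] = []
    n_dropped = 0
    for chrom, start, end, name in load_intervals(bed_path):
        if chrom not in genome:
            n_dropped += 1
            continue
        island_id = name if name is not None else f"{chrom}:{start}-{end}"
        islands.append(
            CpGIsland(island_id, chrom, start, end, genome.slice(chrom, start, end))
        )
    if n_dropped:
        logger.warning("%s: dropped %d islands on chromosomes absent from genome",
                       bed_path, n_dropped)
    islands.sort(key=lambda i: (i.chrom, i.start))
    return islands


def write_islands_bed(islands: Sequence[CpGIsland], bed_path) -> None:
    """Write islands back out as BED4 (0-based half-open)."""
    with open(bed_path, "w") as handle:
        for isl in islands:
            handle.write(f"{isl.chrom}\t{isl.start}\t{isl.end}\t{isl.id}\n")


# ---------------------------------------------------------------------------
# SAM/BAM


def flags_pass(flag: int, mapq: int, mapq_min: int = 0) -> bool:
    """Pure filtering predicate on a SAM FLAG integer and mapping quality.

    Keeps reads that are paired and properly paired; mapped; primary (not
    secondary, not supplementary/chimeric); not PCR/optical duplicates; not
    QC-fail; with MAPQ >= mapq_min. Both mates of a passing pair pass
    independently: each read 5' end is a separate break observation.
    """
    if not flag & _FLAG_PAIRED:
        return False
    if not flag & _FLAG_PROPER_PAIR:
        return False
    forbidden = (_FLAG_UNMAPPED | _FLAG_SECONDARY | _FLAG_SUPPLEMENTARY
                 | _FLAG_DUPLICATE | _FLAG_QC_FAIL)
    if flag & forbidden:
        return False
    return mapq >= mapq_min


def _is_five_prime_clipped(aln: pysam.AlignedSegment) -> bool:
    cigar = aln.cigartuples
    if not cigar:
        return False
    # soft (4) or hard (5) clip at the read's 5' end on its own strand
    op = cigar[-1][0] if aln.is_reverse else cigar[0][0]
    return op in (4, 5)


def stream_filtered_reads(alignment_path, mapq_min: int = 0) -> Iterator[AlignedReadRecord]:
    """Stream alignment records that pass the read-filtering contract.

    Input must be coordinate-sorted; BAM additionally requires an index.
    Yields both mates of proper pairs; drops unmapped, secondary,
    supplementary (chimeric), duplicate and QC-fail records and those below
    ``mapq_min``.
    """
    alignment_path = str(alignment_path)
    is_sam = alignment_path.endswith(".sam")
    save = pysam.set_verbosity(0)  # silence missing-index chatter; we check below
    afile = pysam.AlignmentFile(alignment_path, "r" if is_sam else "rb")
    pysam.set_verbosity(save)
    try:
        so = afile.header.to_dict().get("HD", {}).get("SO")
        if so != "coordinate":
            raise ValueError(
                f"{alignment_path}: input must be coordinate-sorted (header SO={so!r}); "
                "sort with 'samtools sort'"
            )
        if not is_sam and not afile.has_index():
            raise FileNotFoundError(
                f"{alignment_path}: BAM index not found; create one with 'samtools index'"
            )
        n_seen = n_kept = 0
        for aln in afile:
            n_seen += 1
            if not flags_pass(aln.flag, aln.mapping_quality, mapq_min):
                continue
            n_kept += 1
            yield AlignedReadRecord(
                chrom=aln.reference_name,
                start=aln.reference_start + 1,
                end=aln.reference_end,  # pysam end is 0-based excl == 1-based incl
                strand="-" if aln.is_reverse else "+",
                five_prime_clipped=_is_five_prime_clipped(aln),
            )
        logger.info("%s: %d/%d records passed filters", alignment_path, n_kept, n_seen)
    finally:
        afile.close()


# ---------------------------------------------------------------------------
# Methylomes


def _detect_methylome_dialect(path) -> str:
    with open(path) as handle:
        for line in handle:
            if line.strip() and not line.startswith(("#", "track")):
                ncols = len(line.rstrip("\n").split("\t"))
                break
        else:
            raise ValueError(f"{path}: empty methylome file")
    if ncols == 6:
        return "bismark_cov"
    if ncols >= 10:
        return "bedMethyl"
    raise ValueError(f"{path}: cannot detect methylome dialect from {ncols} columns")


def load_methylome(path, dialect: str = "auto", merge_strands: bool = False
                   ) -> List[MethylomeRecord]:
    """Load WGBS methylome calls from bedMethyl or Bismark coverage files.

    bedMethyl (UCSC 11-column): position is the 0-based start; records on the
    '-' strand are shifted by -1 to the forward-strand C of the CpG. Bismark
    coverage (6-column, 1-based): position becomes start - 1; the methylated
    fraction is recomputed from the two count columns. With
    ``merge_strands=True`` records landing on the same normalized position are
    merged (coverages summed, coverage-weighted fraction).
    """
    if dialect == "auto":
        dialect = _detect_methylome_dialect(path)
    if dialect not in ("bedMethyl", "bismark_cov"):
        raise ValueError(f"unknown methylome dialect {dialect!r}")

    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    records: List[MethylomeRecord] = []
    n_rejected = 0
    if dialect == "bedMethyl":
        for row in table.itertuples(index=False):
            chrom, start = str(row[0]), int(row[1])
            strand = str(row[5]) if len(row) > 5 else "+"
            coverage, percent = int(row[9]), float(row[10])
            if coverage < 0 or not 0.0 <= percent <= 100.0:
                logger.warning("rejecting bedMethyl record at %s:%d", chrom, start)
                n_rejected += 1
                continue
            pos = start - 1 if strand == "-" else start
            records.append(MethylomeRecord(chrom, pos, coverage, percent / 100.0))
    else:  # bismark_cov: chrom, start(1-based), end, percent, n_meth, n_unmeth
        for row in table.itertuples(index=False):
            chrom, start = str(row[0]), int(row[1])
            n_meth, n_unmeth = int(row[4]), int(row[5])
            if n_meth < 0 or n_unmeth < 0:
                logger.warning("rejecting Bismark record at %s:%d (negative count)",
                               chrom, start)
                n_rejected += 1
                continue
            coverage = n_meth + n_unmeth
            fraction = n_meth / coverage if coverage else 0.0
            records.append(MethylomeRecord(chrom, start - 1, coverage, fraction))
    if n_rejected:
        logger.warning("%s: rejected %d methylome records", path, n_rejected)

    if merge_strands:
        merged: Dict[Tuple[str, int], Tuple[int, float]] = {}
        for rec in records:
            key = (rec.chrom, rec.pos)
            if key in merged:
                cov, meth = merged[key]
                merged[key] = (cov + rec.coverage, meth + rec.coverage * rec.meth_fraction)
            else:
                merged[key] = (rec.coverage, rec.coverage * rec.meth_fraction)
        records = [
            MethylomeRecord(chrom, pos, cov, (meth / cov) if cov else 0.0)
            for (chrom, pos), (cov, meth) in sorted(merged.items())
        ]
    logger.info("%s: loaded %d methylome records (dialect=%s)", path, len(records), dialect)
    return records


def write_bismark_cov(records: Sequence[MethylomeRecord], path) -> None:
    """Write methylome records in the Bismark coverage dialect (1-based)."""
    with open(path, "w") as handle:
        for rec in records:
            n_meth = round(rec.coverage * rec.meth_fraction)
            n_unmeth = rec.coverage - n_meth
            pct = 100.0 * rec.meth_fraction
            handle.write(
                f"{rec.chrom}\t{rec.pos + 1}\t{rec.pos + 1}\t{pct:.6g}\t{n_meth}\t{n_unmeth}\n"
            )
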