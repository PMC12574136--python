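"""Break-site inference and the per-island dinucleotide odds-ratio features.

Mechanical shearing of genomic DNA during library preparation hydrolyses the
sugar-phosphate backbone preferentially at some dinucleotides (notably CpG,
more so when the cytosine is methylated). The 5' end of a mapped read marks
where a break happened: the break dinucleotide is the read's first aligned
base together with its upstream neighbor in the reference, read 5'->3' on the
read's strand. Per island i we summarize the break spectrum as the odds ratio

    rho^i_XY = (n^i_XY / N^i) / (m^i_XY / (L^i - 1))

where n_XY counts break events at XY, N = sum of all n_XY, m_XY counts XY
occurrences in the island sequence and L is the island length. Under uniform
fragmentation every rho_XY with m_XY > 0 is ~1; rho_XY > 1 means breaks start
at XY more often than chance. If XY never occurs in the island or receives no
events, rho_XY = 0 by convention.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import AlignedReadRecord, CpGIsland, Genome, stream_filtered_reads

logger = logging.getLogger(__name__)

#: canonical dinucleotide order (row-major over A < C < G < T); fixed for all
#: downstream feature matrices.
DINUCLEOTIDES: Tuple[str, ...] = tuple(
    a + b for a, b in itertools.product("ACGT", repeat=2)
)
FEATURE_COLUMNS: Tuple[str, ...] = tuple(f"rho_{d}" for d in DINUCLEOTIDES)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BreakEvent:
    """One inferred hydrolysis site.

    ``break_pos`` is the 0-based reference coordinate of the base aligned to
    the read's 5'-terminal base. ``dinuc`` is (upstream neighbor, first read
    base) written 5'->3' on the read's strand; for '-' strand reads this is
    the reverse complement of the two reference bases.
    """

    chrom: str
    break_pos: int
    strand: str
    dinuc: str

    def __post_init__(self) -> None:
        if self.dinuc not in DINUCLEOTIDES:
            raise ValueError(f"invalid break dinucleotide {self.dinuc!r}")

    @property
    def ref_span(self) -> Tuple[int, int]:
        """The two 0-based reference positions the break dinucleotide covers,
        as (lower, upper) with upper = lower + 1."""
        if self.strand == "+":
            return self.break_pos - 1, self.break_pos
        return self.break_pos, self.break_pos + 1


@dataclass
class IslandCounts:
    """Sufficient statistics for one island's rho vector."""

    island_id: str
    n: Dict[str, int]
    m: Dict[str, int]
    N: int
    L: int


@dataclass(frozen=True)
class RhoVector:
    """The 16 rho_XY features of one island, in canonical order."""

    island_id: str
    rho: np.ndarray
    uncovered: bool = False

    def __post_init__(self) -> None:
        if self.rho.shape != (16,):
            raise ValueError("rho vector must have exactly 16 entries")
        if not np.all(np.isfinite(self.rho)) or np.any(self.rho < 0):
            raise ValueError("rho entries must be finite and non-negative")


def break_dinucleotide(genome: Genome, read: AlignedReadRecord) -> Optional[BreakEvent]:
    """Infer the break dinucleotide marked by a read's 5' end.

    Forward read mapped at 1-based position p: the break lies between
    reference bases p-1 and p, dinucleotide genome[p-2..p-1] (0-based).
    Reverse read with 1-based inclusive end e: the read's 5'-terminal base is
    at e, its upstream neighbor at e+1, and the dinucleotide is the reverse
    complement of genome[e-1..e] (0-based).

    Returns None when the upstream neighbor falls off the chromosome, either
    base is N, or the read's 5' end is clipped (the mapped start then does
    not mark the molecule's end).
    """
    if read.chrom not in genome:
        raise KeyError(f"chromosome {read.chrom!r} absent from genome")
    if read.five_prime_clipped:
        return None
    seq = genome.sequences[read.chrom]
    if read.strand == "+":
        p = read.start  # 1-based
        if p < 2:
            return None
        dinuc = seq[p - 2 : p]
        break_pos = p - 1
    else:
        e = read.end  # 1-based inclusive
        if e >= len(seq):  # neighbor at 0-based index e must exist
            return None
        dinuc = reverse_complement(seq[e - 1 : e + 1])
        break_pos = e - 1
    if "N" in dinuc:
        return None
    return BreakEvent(read.chrom, break_pos, read.strand, dinuc)


def reads_to_events(genome: Genome, reads: Iterable[AlignedReadRecord]
                    ) -> Iterable[BreakEvent]:
    """Map filtered reads to break events, dropping indeterminate ones."""
    for read in reads:
        event = break_dinucleotide(genome, read)
        if event is not None:
            yield event


def count_island_dinucleotides(sequence: str) -> Dict[str, int]:
    """Count the L-1 overlapping dinucleotide windows of an island sequence.

    Windows containing N are excluded (symmetric with the event-side N
    policy).
    """
    if len(sequence) < 2:
        raise ValueError("sequence must contain at least one dinucleotide")
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    for i in range(len(sequence) - 1):
        window = sequence[i : i + 2]
        if window in counts:
            counts[window] += 1
    return counts


def accumulate_counts(islands: Sequence[CpGIsland], events: Iterable[BreakEvent]
                      ) -> List[IslandCounts]:
    """Attribute break events to islands and tally per-dinucleotide counts.

    An event belongs to an island iff BOTH reference bases of its break
    dinucleotide lie inside [start, end), so the numerator of rho ranges over
    exactly the same L-1 dinucleotide positions as the denominator.
    Overlapping islands each receive the event independently.
    """
    counts = [
        IslandCounts(
            island_id=isl.id,
            n=dict.fromkeys(DINUCLEOTIDES, 0),
            m=count_island_dinucleotides(isl.sequence),
            N=0,
            L=isl.length,
        )
        for isl in islands
    ]
    trees: Dict[str, IntervalTree] = {}
    for idx, isl in enumerate(islands):
        trees.setdefault(isl.chrom, IntervalTree())[isl.start : isl.end] = idx

    n_events = n_attributed = 0
    for event in events:
        n_events += 1
        tree = trees.get(event.chrom)
        if tree is None:
            continue
        lo, hi = event.ref_span
        for iv in tree[lo]:  # islands with start <= lo < end
            if hi < iv.end:  # and the upper base inside too
                rec = counts[iv.data]
                rec.n[event.dinuc] += 1
                rec.N += 1
                n_attributed += 1
    logger.info("accumulated %d/%d events into %d islands",
                n_attributed, n_events, len(islands))
    return counts


def compute_rho(counts: IslandCounts) -> RhoVector:
    """Compute the 16-entry odds-ratio vector from island counts.

    rho_XY = (n_XY / N) / (m_XY / (L - 1)); any dinucleotide with zero events
    or zero sequence occurrences gets rho_XY = 0, and an island with no
    events at all yields the zero vector, flagged uncovered.
    """
    if counts.L < 2:
        raise ValueError("island shorter than one dinucleotide")
    rho = np.zeros(16)
    if counts.N == 0:
        return RhoVector(counts.island_id, rho, uncovered=True)
    denom_L = counts.L - 1
    for k, dinuc in enumerate(DINUCLEOTIDES):
        n_xy = counts.n[dinuc]
        m_xy = counts.m[dinuc]
        if n_xy == 0 or m_xy == 0:
            continue
        rho[k] = (n_xy / counts.N) / (m_xy / denom_L)
    return RhoVector(counts.island_id, rho)


def featurize_events(islands: Sequence[CpGIsland], events: Iterable[BreakEvent]
                     ) -> pd.DataFrame:
    """Build the per-island feature table from an in-memory event stream.

    Returns a DataFrame with columns island_id, chrom, start, end, N,
    rho_AA ... rho_TT (canonical order).
    """
    counts = accumulate_counts(islands, events)
    rows = []
    n_uncovered = 0
    for isl, cnt in zip(islands, counts):
        vec = compute_rho(cnt)
        n_uncovered += vec.uncovered
        rows.append(
            {"island_id": isl.id, "chrom": isl.chrom, "start": isl.start,
             "end": isl.end, "N": cnt.N,
             **dict(zip(FEATURE_COLUMNS, vec.rho))}
        )
    if n_uncovered:
        logger.info("%d/%d islands uncovered (zero events)", n_uncovered, len(islands))
    return pd.DataFrame(rows, columns=["island_id", "chrom", "start", "end", "N",
                                       *FEATURE_COLUMNS])


def featurize(alignment_path, genome: Genome, islands: Sequence[CpGIsland],
              mapq_min: int = 0) -> pd.DataFrame:
    """Full path from an alignment file to the rho feature table."""
    reads = stream_filtered_reads(alignment_path, mapq_min=mapq_min)
    return featurize_events(islands, reads_to_events(genome, reads))


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns {sorted(missing)}")
    return table
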