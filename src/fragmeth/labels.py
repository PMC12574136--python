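"""Ground-truth island labels from WGBS methylomes.

A CpG is called methylated (unmethylated) when more than 90% of bisulfite
reads agree on that status and it is covered by more than 10 reads; anything
else is unknown. An island is methylated when its methylated CpGs outnumber
its unmethylated ones, and vice versa; islands with no confidently called CpG,
tied counts, or any overlap with a segmental-duplication exclusion interval
are excluded from training and evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .io import CpGIsland, MethylomeRecord

logger = logging.getLogger(__name__)

METHYLATED = "methylated"
UNMETHYLATED = "unmethylated"
UNKNOWN = "unknown"

MIN_COVERAGE = 11      # "more than 10 reads", strict
METH_FRACTION = 0.9    # ">90% agree", strict inequality on both sides


@dataclass(frozen=True)
class CpGStatus:
    pos: int
    status: str  # methylated | unmethylated | unknown


@dataclass(frozen=True)
class IslandLabel:
    """Ground-truth status of one island with its supporting CpG tallies.

    ``y`` is 1 (methylated), 0 (unmethylated) or None (unknown/excluded, with
    ``excluded_reason`` in {no_assigned_cpg, tie, segdup_overlap}).
    """

    island_id: str
    y: Optional[int]
    n_meth: int
    n_unmeth: int
    excluded_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.y is not None:
            if self.n_meth == self.n_unmeth:
                raise ValueError("definite label requires a strict majority")
            if self.n_meth + self.n_unmeth < 1:
                raise ValueError("definite label requires at least one assigned CpG")


def call_cpg_status(record: MethylomeRecord) -> str:
    """Classify a single CpG from its WGBS coverage and methylated fraction."""
    if record.coverage >= MIN_COVERAGE:
        if record.meth_fraction > METH_FRACTION:
            return METHYLATED
        if record.meth_fraction < 1.0 - METH_FRACTION:
            return UNMETHYLATED
    return UNKNOWN


def island_cpg_positions(island: CpGIsland) -> List[int]:
    """0-based genome coordinates of the C of each forward-strand CpG in the
    island sequence."""
    seq = island.sequence
    return [island.start + i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


def label_island(island: CpGIsland, statuses: Iterable[CpGStatus]) -> IslandLabel:
    """Majority vote over confidently called CpGs within the island."""
    n_meth = n_unmeth = 0
    for st in statuses:
        if not island.start <= st.pos < island.end:
            raise ValueError(f"CpG status at {st.pos} outside island {island.id}")
        if st.status == METHYLATED:
            n_meth += 1
        elif st.status == UNMETHYLATED:
            n_unmeth += 1
    if n_meth + n_unmeth == 0:
        return IslandLabel(island.id, None, 0, 0, excluded_reason="no_assigned_cpg")
    if n_meth == n_unmeth:
        return IslandLabel(island.id, None, n_meth, n_unmeth, excluded_reason="tie")
    return IslandLabel(island.id, 1 if n_meth > n_unmeth else 0, n_meth, n_unmeth)


def label_islands(islands: Sequence[CpGIsland],
                  methylome: Sequence[MethylomeRecord]) -> List[IslandLabel]:
    """Label every island from a methylome.

    CpG positions are enumerated from the island sequence (forward-strand CG
    occurrences); methylome records not matching a reference CpG inside an
    island are ignored (counted in the log).
    """
    by_pos: Dict[Tuple[str, int], MethylomeRecord] = {
        (rec.chrom, rec.pos): rec for rec in methylome
    }
    used = set()
    labels = []
    for island in islands:
        statuses = []
        for pos in island_cpg_positions(island):
            rec = by_pos.get((island.chrom, pos))
            if rec is None:
                continue
            used.add((island.chrom, pos))
            statuses.append(CpGStatus(pos, call_cpg_status(rec)))
        labels.append(label_island(island, statuses))
    n_unused = len(by_pos) - len(used)
    if n_unused:
        logger.warning("%d methylome records matched no reference CpG inside any island",
                       n_unused)
    tally = {"methylated": sum(l.y == 1 for l in labels),
             "unmethylated": sum(l.y == 0 for l in labels),
             "unknown": sum(l.y is None for l in labels)}
    logger.info("island labels: %s", tally)
    return labels


def exclude_segdup_overlaps(labels: Sequence[IslandLabel],
                            islands: Sequence[CpGIsland],
                            segdups: Sequence[Tuple[str, int, int]]) -> List[IslandLabel]:
    """Mark islands overlapping any exclusion interval (>= 1 bp, half-open
    arithmetic) as unknown/segdup_overlap."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, start, end, *_ in segdups:
        by_chrom.setdefault(chrom, []).append((start, end))
    island_by_id = {isl.id: isl for isl in islands}
    out = []
    n_excluded = 0
    for label in labels:
        isl = island_by_id[label.island_id]
        hits = any(isl.start < e and s < isl.end
                   for s, e in by_chrom.get(isl.chrom, ()))
        if hits:
            out.append(IslandLabel(label.island_id, None, label.n_meth,
                                   label.n_unmeth, excluded_reason="segdup_overlap"))
            n_excluded += 1
        else:
            out.append(label)
    if n_excluded:
        logger.info("excluded %d islands overlapping segmental duplications", n_excluded)
    return out


def labeled_fraction(labels: Sequence[IslandLabel]) -> float:
    """Fraction of definitively labeled islands that are methylated — the
    natural estimate of the expected methylated fraction r."""
    n_meth = sum(l.y == 1 for l in labels)
    n_labeled = sum(l.y in (0, 1) for l in labels)
    if n_labeled == 0:
        raise ValueError("no labeled islands; cannot estimate r")
    return n_meth / n_labeled


def write_label_table(labels: Sequence[IslandLabel], path) -> None:
    """TSV: island_id, label in {0,1,NA}, n_meth, n_unmeth, excluded_reason."""
    with open(path, "w") as handle:
        handle.write("island_id\tlabel\tn_meth\tn_unmeth\texcluded_reason\n")
        for l in labels:
            y = "NA" if l.y is None else str(l.y)
            reason = l.excluded_reason or ""
            handle.write(f"{l.island_id}\t{y}\t{l.n_meth}\t{l.n_unmeth}\t{reason}\n")
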