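"""Synthetic fragmentation data with known ground truth.

The generator emits (i) a reference genome with non-overlapping CpG-rich
islands embedded in a CpG-depleted background, (ii) break events drawn from a
dinucleotide fragility model in which CpG dinucleotides are ~1.5x more
fragile than others and methylated CpGs a further ~30% more fragile, (iii) a
mock WGBS methylome with a symmetric bisulfite miscall rate, and (iv)
optionally a coordinate-sorted minimal SAM file so the real alignment path is
exercised end to end. Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

from .classify import (apply_top_r, balance_by_undersampling, cross_validate,
                       evaluate, make_dataset, predict_posteriors, train_forest)
from .features import (DINUCLEOTIDES, BreakEvent, featurize_events,
                       reverse_complement)
from .io import CpGIsland, Genome, MethylomeRecord
from .labels import label_islands

logger = logging.getLogger(__name__)


def default_fragility_weights() -> Dict[str, float]:
    """Relative fragmentation propensities: all dinucleotides 1.0 except CpG
    at 1.5 (mechanochemical hydrolysis is ~1.5x more frequent at CpG)."""
    weights = dict.fromkeys(DINUCLEOTIDES, 1.0)
    weights["CG"] = 1.5
    return weights


@dataclass
class FragilityModel:
    """Per-dinucleotide break propensities plus the methylated-CpG boost.

    ``meth_cpg_multiplier`` multiplies the CG weight at CpGs whose cytosine
    is methylated; ~1.3 reflects the ~30% higher hydrolysis rate of
    methylated CpG.
    """

    weights: Dict[str, float] = field(default_factory=default_fragility_weights)
    meth_cpg_multiplier: float = 1.3

    def __post_init__(self) -> None:
        if set(self.weights) != set(DINUCLEOTIDES):
            raise ValueError("weights must cover all 16 dinucleotides")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("all fragility weights must be positive")
        if self.meth_cpg_multiplier <= 0:
            raise ValueError("meth_cpg_multiplier must be positive")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic sample.

    Defaults emulate a single high-coverage short-read WGS experiment over a
    small genome: islands of 500-2000 bp with ~10% CpG dinucleotide density
    in a CpG-depleted background, ~20% of islands methylated, and a few
    hundred read 5'-end events per island (roughly what a 30x genome with
    ~150 bp reads deposits on a 1 kb island).
    """

    n_islands: int = 100
    island_length_range: Tuple[int, int] = (500, 2000)
    island_cpg_unit_prob: float = 0.05
    genome_length: Optional[int] = None  # auto-sized when None
    min_gap: int = 150
    r_star: float = 0.2
    mean_events_per_island: float = 300.0
    wgbs_mean_coverage: float = 30.0
    wgbs_error_rate: float = 0.01
    mosaic_fraction: float = 0.0  # within-island fraction of discordant CpGs
    read_length: int = 75
    chrom_name: str = "chrSim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_star <= 1.0:
            raise ValueError("r_star must lie in [0, 1]")
        if not 0.0 <= self.wgbs_error_rate < 0.5:
            raise ValueError("wgbs_error_rate must lie in [0, 0.5)")
        if self.n_islands < 1 or self.mean_events_per_island < 0:
            raise ValueError("counts must be positive")
        lo, hi = self.island_length_range
        if lo < 2 or hi < lo:
            raise ValueError("bad island length range")


# ---------------------------------------------------------------------------
# genome


_BG_BASES = np.array(list("ACGT"))
_BG_PROBS = np.array([0.3, 0.2, 0.2, 0.3])  # 40% GC background
_BG_CG_SUPPRESSION = 0.8  # fraction of background CpGs mutated away (low o/e)


def _background_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    seq = rng.choice(_BG_BASES, size=length, p=_BG_PROBS)
    # deplete CpG as in vertebrate background (5mC deamination)
    cg = np.flatnonzero((seq[:-1] == "C") & (seq[1:] == "G"))
    mutate = cg[rng.random(len(cg)) < _BG_CG_SUPPRESSION]
    seq[mutate + 1] = rng.choice(np.array(list("AT")), size=len(mutate))
    return seq


def _island_sequence(length: int, cpg_unit_prob: float,
                     rng: np.random.Generator) -> str:
    """CpG-rich sequence built from units: 'CG' with prob q, otherwise a
    single base drawn uniformly. Yields ~q/(1+q) deliberate CpGs plus
    incidental C.G adjacencies (~10% CpG density at q = 0.05, GC ~55%)."""
    parts: List[str] = []
    n = 0
    while n < length:
        if rng.random() < cpg_unit_prob:
            parts.append("CG")
            n += 2
        else:
            parts.append("ACGT"[rng.integers(4)])
            n += 1
    return "".join(parts)[:length]


def simulate_genome(config: SimulationConfig
                    ) -> Tuple[Genome, List[CpGIsland], Dict[str, int]]:
    """Generate the reference, island intervals and true methylation states.

    Islands are non-overlapping, separated by at least ``min_gap`` bp of
    background sequence, and each is methylated independently with
    probability r*. Deterministic given config.seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.island_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_islands)
    required = int(lengths.sum()) + (config.n_islands + 1) * config.min_gap
    genome_length = config.genome_length
    if genome_length is None:
        genome_length = required
    if genome_length < required:
        raise ValueError(
            f"genome_length {genome_length} cannot fit {config.n_islands} islands "
            f"(need >= {required})"
        )
    slack = genome_length - required
    extra = rng.multinomial(slack, np.full(config.n_islands + 1, 1.0 / (config.n_islands + 1)))
    gaps = extra + config.min_gap

    chrom = np.empty(genome_length, dtype="<U1")
    islands: List[CpGIsland] = []
    true_states: Dict[str, int] = {}
    cursor = 0
    for i, (gap, length) in enumerate(zip(gaps[:-1], lengths)):
        chrom[cursor : cursor + gap] = _background_sequence(int(gap), rng)
        cursor += int(gap)
        start, end = cursor, cursor + int(length)
        seq = _island_sequence(int(length), config.island_cpg_unit_prob, rng)
        chrom[start:end] = list(seq)
        island_id = f"cgi_{i:04d}"
        islands.append(CpGIsland(island_id, config.chrom_name, start, end, seq))
        true_states[island_id] = int(rng.random() < config.r_star)
        cursor = end
    chrom[cursor:] = _background_sequence(genome_length - cursor, rng)

    genome = Genome({config.chrom_name: "".join(chrom)})
    logger.info("simulated %d bp genome with %d islands (%d methylated)",
                genome_length, len(islands), sum(true_states.values()))
    return genome, islands, true_states


# ---------------------------------------------------------------------------
# breaks


def simulate_breaks(genome: Genome, islands: Sequence[CpGIsland],
                    true_states: Dict[str, int], fragility: FragilityModel,
                    mean_events_per_island: float, seed: int) -> List[BreakEvent]:
    """Draw break events inside each island from the fragility model.

    Every dinucleotide boundary on each strand is a candidate break site
    sampled with probability proportional to its weight; CG boundaries in
    methylated islands get the additional ``meth_cpg_multiplier``. The event
    count per island is Poisson with the given mean. Events carry the same
    strand-aware dinucleotide convention used on the inference side.
    """
    rng = np.random.default_rng(seed)
    events: List[BreakEvent] = []
    for island in islands:
        seq = island.sequence
        boundaries = len(seq) - 1
        methylated = bool(true_states[island.id])
        fwd = np.zeros(boundaries)
        rev = np.zeros(boundaries)
        for j in range(boundaries):
            dinuc = seq[j : j + 2]
            if "N" in dinuc:
                continue
            boost = (fragility.meth_cpg_multiplier
                     if methylated and dinuc == "CG" else 1.0)
            fwd[j] = fragility.weights[dinuc] * boost
            # reverse-strand reads see the reverse complement of the window;
            # CG is its own reverse complement so the boost applies alike
            rc = reverse_complement(dinuc)
            rev[j] = fragility.weights[rc] * (fragility.meth_cpg_multiplier
                                              if methylated and rc == "CG" else 1.0)
        weights = np.concatenate([fwd, rev])
        total = weights.sum()
        if total == 0:
            continue
        n_events = rng.poisson(mean_events_per_island)
        if n_events == 0:
            continue
        counts = rng.multinomial(n_events, weights / total)
        for idx in np.flatnonzero(counts):
            j = idx % boundaries
            g = island.start + j
            dinuc = seq[j : j + 2]
            if idx < boundaries:  # forward: read starts at g+1, neighbor at g
                ev = BreakEvent(island.chrom, g + 1, "+", dinuc)
            else:  # reverse: read 5' base at g, neighbor at g+1
                ev = BreakEvent(island.chrom, g, "-", reverse_complement(dinuc))
            events.extend([ev] * int(counts[idx]))
    logger.info("simulated %d break events in %d islands", len(events), len(islands))
    return events


def write_events_sam(genome: Genome, events: Sequence[BreakEvent], sam_path,
                     read_length: int = 75) -> None:
    """Write events as a coordinate-sorted minimal SAM file.

    Each event becomes one primary, properly-paired, MAPQ 60 read whose 5'
    end sits exactly at the break position, so streaming the file back
    through the alignment reader reproduces the events.
    """
    chroms = list(genome.sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": len(genome.sequences[name])} for name in chroms],
    }
    ref_id = {name: i for i, name in enumerate(chroms)}
    rows = []
    for k, ev in enumerate(events):
        chrom_len = len(genome.sequences[ev.chrom])
        if ev.strand == "+":
            start0 = ev.break_pos
            length = min(read_length, chrom_len - start0)
            flag = 0x1 | 0x2 | 0x20 | 0x40  # paired, proper, mate-reverse, read1
        else:
            end0 = ev.break_pos
            start0 = max(0, end0 - read_length + 1)
            length = end0 - start0 + 1
            flag = 0x1 | 0x2 | 0x10 | 0x40  # paired, proper, reverse, read1
        rows.append((ref_id[ev.chrom], start0, length, flag, k))
    rows.sort(key=lambda r: (r[0], r[1]))

    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for rid, start0, length, flag, k in rows:
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = f"sim_{k:07d}"
            aln.flag = flag
            aln.reference_id = rid
            aln.reference_start = start0
            aln.mapping_quality = 60
            aln.cigartuples = [(0, length)]
            aln.query_sequence = genome.sequences[chroms[rid]][start0 : start0 + length]
            aln.next_reference_id = rid
            aln.next_reference_start = start0
            aln.template_length = 0
            out.write(aln)
    logger.info("wrote %d simulated reads to %s", len(rows), sam_path)


# ---------------------------------------------------------------------------
# WGBS


def simulate_wgbs(islands: Sequence[CpGIsland], true_states: Dict[str, int],
                  mean_coverage: float, error_rate: float, seed: int,
                  mosaic_fraction: float = 0.0) -> List[MethylomeRecord]:
    """Mock bisulfite methylome over the CpGs of each island.

    Coverage per CpG is Poisson; the methylated-read count is binomial with
    success probability 1 - error_rate in methylated islands and error_rate
    in unmethylated ones (symmetric miscall model). Island methylation is
    all-or-none; ``mosaic_fraction`` optionally flips that fraction of CpGs
    to the discordant state, as a robustness knob.
    """
    rng = np.random.default_rng(seed)
    records: List[MethylomeRecord] = []
    for island in islands:
        methylated = bool(true_states[island.id])
        seq = island.sequence
        for i in range(len(seq) - 1):
            if seq[i : i + 2] != "CG":
                continue
            coverage = int(rng.poisson(mean_coverage))
            if coverage == 0:
                continue
            state = methylated
            if mosaic_fraction and rng.random() < mosaic_fraction:
                state = not state
            p_meth = 1.0 - error_rate if state else error_rate
            n_meth = int(rng.binomial(coverage, p_meth))
            records.append(MethylomeRecord(island.chrom, island.start + i,
                                           coverage, n_meth / coverage))
    return records


# ---------------------------------------------------------------------------
# bundles and end-to-end experiments


@dataclass
class SimulatedSample:
    """Everything one synthetic experiment produces, in memory."""

    config: SimulationConfig
    genome: Genome
    islands: List[CpGIsland]
    true_states: Dict[str, int]
    events: List[BreakEvent]
    methylome: List[MethylomeRecord]


def simulate_sample(config: SimulationConfig,
                    fragility: Optional[FragilityModel] = None) -> SimulatedSample:
    """Run the full generator once; all randomness derives from config.seed."""
    fragility = fragility or FragilityModel()
    genome, islands, true_states = simulate_genome(config)
    events = simulate_breaks(genome, islands, true_states, fragility,
                             config.mean_events_per_island, seed=config.seed + 1)
    methylome = simulate_wgbs(islands, true_states, config.wgbs_mean_coverage,
                              config.wgbs_error_rate, seed=config.seed + 2,
                              mosaic_fraction=config.mosaic_fraction)
    return SimulatedSample(config, genome, islands, true_states, events, methylome)


def sample_dataset(sample: SimulatedSample) -> pd.DataFrame:
    """Feature table joined with WGBS-derived labels for a simulated sample."""
    features = featurize_events(sample.islands, sample.events)
    labels = label_islands(sample.islands, sample.methylome)
    return make_dataset(features, labels, sample=f"sim_seed{sample.config.seed}")


def holdout_auc(dataset: pd.DataFrame, seed: int, test_fraction: float = 0.3,
                hyperparams: Optional[Dict] = None) -> float:
    """Held-out ROC AUC from one stratified train/test split with
    undersampling applied to the training part only."""
    rng = np.random.default_rng(seed)
    test_idx = []
    for _, group in dataset.groupby("y", sort=True):
        n_test = max(1, int(round(test_fraction * len(group))))
        test_idx.extend(rng.choice(group.index.to_numpy(), n_test, replace=False))
    test_mask = dataset.index.isin(test_idx)
    train, test = dataset[~test_mask], dataset[test_mask]
    balanced = balance_by_undersampling(train, seed=seed)
    model = train_forest(balanced, seed=seed, hyperparams=hyperparams)
    preds = predict_posteriors(model, test)
    from sklearn.metrics import roc_auc_score
    return float(roc_auc_score(test["y"], preds["posterior"]))


def coverage_ladder(base_config: SimulationConfig,
                    multipliers: Sequence[float] = (1, 5, 10, 20),
                    seeds: Sequence[int] = range(5),
                    fragility: Optional[FragilityModel] = None,
                    hyperparams: Optional[Dict] = None) -> pd.DataFrame:
    """Held-out AUC across an event-coverage ladder, per seed.

    Mirrors pooling reads from multiple samples of the same cell type:
    more 5'-end events per island resolve the break spectrum better.
    """
    rows = []
    for seed in seeds:
        for mult in multipliers:
            config = replace(base_config, seed=int(seed),
                             mean_events_per_island=base_config.mean_events_per_island * mult)
            sample = simulate_sample(config, fragility)
            dataset = sample_dataset(sample)
            auc = holdout_auc(dataset, seed=int(seed), hyperparams=hyperparams)
            rows.append({"seed": int(seed), "multiplier": mult, "auc": auc})
    return pd.DataFrame(rows)


def r_sweep(config: SimulationConfig,
            deltas: Sequence[float] = (-0.2, -0.1, 0.0, 0.1, 0.2),
            fragility: Optional[FragilityModel] = None,
            hyperparams: Optional[Dict] = None) -> pd.DataFrame:
    """Macro accuracy of the top-r rule as the supplied r moves around the
    true methylated fraction r*.

    Trains on one half of the islands (balanced), scores the other half at
    its natural class distribution, and applies each candidate r. Accuracy
    peaks when r matches the test set's true methylated fraction.
    """
    sample = simulate_sample(config, fragility)
    dataset = sample_dataset(sample)
    rng = np.random.default_rng(config.seed)
    test_mask = np.zeros(len(dataset), dtype=bool)
    for _, group in dataset.groupby("y", sort=True):
        idx = rng.choice(group.index.to_numpy(), len(group) // 2, replace=False)
        test_mask[dataset.index.isin(idx)] = True
    train, test = dataset[~test_mask], dataset[test_mask]
    balanced = balance_by_undersampling(train, seed=config.seed)
    model = train_forest(balanced, seed=config.seed, hyperparams=hyperparams)
    preds = predict_posteriors(model, test)
    r_true = float(test["y"].mean())
    rows = []
    for delta in deltas:
        r = min(1.0, max(0.0, r_true + delta))
        hard = apply_top_r(preds, r)
        metrics = evaluate(test["y"], preds["posterior"], hard["label"])
        rows.append({"delta": delta, "r": r, "r_true": r_true,
                     "macro_accuracy": metrics["macro_accuracy"]})
    return pd.DataFrame(rows)


def end_to_end(config: SimulationConfig,
               fragility: Optional[FragilityModel] = None,
               k: int = 10) -> Dict:
    """Simulate -> featurize -> label -> cross-validate -> evaluate.

    Returns the cross-validation report plus a comparison of the WGBS-derived
    labels against the generator's true island states.
    """
    sample = simulate_sample(config, fragility)
    dataset = sample_dataset(sample)
    cv = cross_validate(dataset, k=min(k, len(dataset)), seed=config.seed)
    truth = dataset["island_id"].map(sample.true_states)
    label_agreement = float((dataset["y"] == truth).mean())
    return {
        "n_islands": len(sample.islands),
        "n_labeled": len(dataset),
        "labeled_methylated_fraction": float(dataset["y"].mean()),
        "label_vs_truth_agreement": label_agreement,
        "cv_pooled": {k_: v for k_, v in cv["pooled"].items()
                      if k_ in ("macro_accuracy", "auc_roc", "average_precision",
                                "confusion_matrix")},
        "cv_fold_macro_accuracy": [f.get("macro_accuracy") for f in cv["folds"]],
    }
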