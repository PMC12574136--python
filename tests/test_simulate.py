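import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fragmeth.features import (DINUCLEOTIDES, FEATURE_COLUMNS, featurize,
                               featurize_events, reverse_complement)
from fragmeth.labels import label_islands
from fragmeth.simulate import (FragilityModel, SimulationConfig,
                               default_fragility_weights, end_to_end,
                               simulate_breaks, simulate_genome,
                               simulate_sample, simulate_wgbs,
                               write_events_sam)


def test_genome_is_deterministic_given_seed():
    cfg = SimulationConfig(n_islands=10, seed=42)
    g1, islands1, states1 = simulate_genome(cfg)
    g2, islands2, states2 = simulate_genome(cfg)
    assert g1.sequences == g2.sequences
    assert [(i.id, i.start, i.end) for i in islands1] == \
           [(i.id, i.start, i.end) for i in islands2]
    assert states1 == states2


def test_island_lengths_within_configured_range_and_non_overlapping():
    cfg = SimulationConfig(n_islands=30, seed=1)
    _, islands, _ = simulate_genome(cfg)
    lo, hi = cfg.island_length_range
    assert all(lo <= isl.length <= hi for isl in islands)
    for a, b in zip(islands, islands[1:]):
        assert a.end + cfg.min_gap <= b.start


def test_r_star_zero_means_no_methylated_islands():
    cfg = SimulationConfig(n_islands=25, r_star=0.0, seed=3)
    _, _, states = simulate_genome(cfg)
    assert set(states.values()) == {0}


def test_island_sequences_match_genome_slices():
    cfg = SimulationConfig(n_islands=10, seed=5)
    genome, islands, _ = simulate_genome(cfg)
    for isl in islands:
        assert genome.slice(isl.chrom, isl.start, isl.end) == isl.sequence


def test_genome_too_small_for_islands_errors():
    cfg = SimulationConfig(n_islands=10, genome_length=1000, seed=0)
    with pytest.raises(ValueError, match="cannot fit"):
        simulate_genome(cfg)


# ---------------------------------------------------------------------------
# break model


def test_uniform_fragility_matches_strand_symmetric_null():
    """Under flat fragility, events arrive on both strands and reverse reads
    observe the reverse-complement window, so rho_XY converges to
    (m_XY + m_revcomp(XY)) / (2 m_XY) — exactly 1 for self-complementary
    dinucleotides (CG, GC, AT, TA) and 1 on average for the rest."""
    from fragmeth.features import count_island_dinucleotides
    cfg = SimulationConfig(n_islands=5, mean_events_per_island=50_000, seed=9)
    genome, islands, states = simulate_genome(cfg)
    flat = FragilityModel(weights=dict.fromkeys(DINUCLEOTIDES, 1.0),
                          meth_cpg_multiplier=1.0)
    events = simulate_breaks(genome, islands, states, flat, 50_000, seed=10)
    table = featurize_events(islands, events)
    for _, row in table.iterrows():
        isl = next(i for i in islands if i.id == row["island_id"])
        m = count_island_dinucleotides(isl.sequence)
        for d in DINUCLEOTIDES:
            if m[d] == 0:
                continue
            expected = (m[d] + m[reverse_complement(d)]) / (2 * m[d])
            assert row[f"rho_{d}"] == pytest.approx(expected, abs=0.05), d
        for d in ("CG", "GC", "AT", "TA"):  # palindromic: expectation is 1
            if m[d] > 0:
                assert row[f"rho_{d}"] == pytest.approx(1.0, abs=0.05)


def test_break_spectrum_matches_configured_weights():
    """Chi-square goodness of fit of each island's empirical break
    dinucleotide counts against the fragility model's expectation, computed
    from that island's sequence (per island, events are multinomial over
    strand-aware windows with probabilities proportional to the weights)."""
    cfg = SimulationConfig(n_islands=2, r_star=0.0, seed=11)
    genome, islands, states = simulate_genome(cfg)
    fragility = FragilityModel()
    events = simulate_breaks(genome, islands, states, fragility, 30_000, seed=12)
    for isl in islands:
        observed = {d: 0 for d in DINUCLEOTIDES}
        for ev in events:
            lo, hi = ev.ref_span
            if isl.start <= lo and hi < isl.end:
                observed[ev.dinuc] += 1
        expected = {d: 0.0 for d in DINUCLEOTIDES}
        seq = isl.sequence
        for j in range(len(seq) - 1):
            window = seq[j:j + 2]
            expected[window] += fragility.weights[window]  # forward reads
            rc = reverse_complement(window)
            expected[rc] += fragility.weights[rc]          # reverse reads
        keys = [d for d in DINUCLEOTIDES if expected[d] > 0]
        obs = np.array([observed[d] for d in keys], dtype=float)
        exp = np.array([expected[d] for d in keys])
        exp *= obs.sum() / exp.sum()
        assert stats.chisquare(obs, exp).pvalue > 0.01


def test_corrected_rho_cg_ratio_recovers_multiplier():
    """Parameter recovery with the within-island normalization cancelled:
    relative to a flat palindromic reference dinucleotide (GC), rho_CG is
    1.5*w in methylated and 1.5 in unmethylated islands — both the total-N
    normalization and the island's sequence composition drop out of the
    double ratio, which recovers the configured multiplier exactly."""
    w = 1.5
    cfg = SimulationConfig(n_islands=40, r_star=0.5, mean_events_per_island=10_000,
                           seed=13)
    sample = simulate_sample(cfg, FragilityModel(meth_cpg_multiplier=w))
    table = featurize_events(sample.islands, sample.events)
    truth = table["island_id"].map(sample.true_states)
    double = table["rho_CG"] / table["rho_GC"]
    ratio = double[truth == 1].mean() / double[truth == 0].mean()
    assert ratio == pytest.approx(w, rel=0.05)


def test_zero_events_yield_empty_stream():
    cfg = SimulationConfig(n_islands=5, seed=2)
    genome, islands, states = simulate_genome(cfg)
    events = simulate_breaks(genome, islands, states, FragilityModel(), 0.0, seed=3)
    assert events == []


def test_breaks_are_deterministic_given_seed():
    cfg = SimulationConfig(n_islands=5, seed=4)
    genome, islands, states = simulate_genome(cfg)
    a = simulate_breaks(genome, islands, states, FragilityModel(), 100, seed=5)
    b = simulate_breaks(genome, islands, states, FragilityModel(), 100, seed=5)
    assert a == b


# ---------------------------------------------------------------------------
# SAM writer round trip


def test_sam_round_trip_reproduces_in_memory_features(tmp_path):
    cfg = SimulationConfig(n_islands=15, mean_events_per_island=150, seed=6)
    sample = simulate_sample(cfg)
    in_memory = featurize_events(sample.islands, sample.events)
    sam = tmp_path / "reads.sam"
    write_events_sam(sample.genome, sample.events, sam,
                     read_length=cfg.read_length)
    streamed = featurize(sam, sample.genome, sample.islands)
    pd.testing.assert_frame_equal(in_memory, streamed)


def test_sam_output_is_byte_identical_across_runs(tmp_path):
    cfg = SimulationConfig(n_islands=5, mean_events_per_island=50, seed=8)
    sample = simulate_sample(cfg)
    p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
    write_events_sam(sample.genome, sample.events, p1)
    write_events_sam(sample.genome, sample.events, p2)
    assert p1.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# WGBS mock


def test_error_free_wgbs_gives_pure_fractions():
    cfg = SimulationConfig(n_islands=10, seed=14)
    _, islands, states = simulate_genome(cfg)
    records = simulate_wgbs(islands, states, mean_coverage=20, error_rate=0.0,
                            seed=15)
    by_island = {isl.id: [] for isl in islands}
    for rec in records:
        for isl in islands:
            if isl.start <= rec.pos < isl.end:
                by_island[isl.id].append(rec.meth_fraction)
    for isl in islands:
        want = 1.0 if states[isl.id] else 0.0
        assert all(f == want for f in by_island[isl.id])


def test_labeling_recovers_true_states_at_realistic_noise():
    """Binomial tail check: at 2% miscall and ~20x coverage, the >90%/>10
    filter plus majority vote recovers nearly every island with >= 3 CpGs."""
    cfg = SimulationConfig(n_islands=120, seed=16)
    _, islands, states = simulate_genome(cfg)
    records = simulate_wgbs(islands, states, mean_coverage=20, error_rate=0.02,
                            seed=17)
    labels = label_islands(islands, records)
    cpg_counts = {isl.id: isl.sequence.count("CG") for isl in islands}
    eligible = [l for l in labels if cpg_counts[l.island_id] >= 3]
    correct = sum(l.y == states[l.island_id] for l in eligible)
    assert correct / len(eligible) >= 0.99


def test_low_coverage_leaves_all_cpgs_unknown():
    """Capping WGBS coverage at 10 reads makes every CpG unknown and every
    island excluded for lack of assigned CpGs."""
    from fragmeth.io import MethylomeRecord
    cfg = SimulationConfig(n_islands=10, seed=18)
    _, islands, states = simulate_genome(cfg)
    records = simulate_wgbs(islands, states, mean_coverage=30, error_rate=0.0,
                            seed=19)
    capped = [MethylomeRecord(r.chrom, r.pos, min(r.coverage, 10),
                              r.meth_fraction) for r in records]
    labels = label_islands(islands, capped)
    assert all(l.y is None and l.excluded_reason == "no_assigned_cpg"
               for l in labels)


def test_mosaic_fraction_flips_some_cpgs():
    cfg = SimulationConfig(n_islands=20, r_star=1.0, seed=20)
    _, islands, states = simulate_genome(cfg)
    records = simulate_wgbs(islands, states, mean_coverage=30, error_rate=0.0,
                            seed=21, mosaic_fraction=0.3)
    fractions = [r.meth_fraction for r in records]
    assert 0.55 < np.mean([f > 0.5 for f in fractions]) < 0.85


# ---------------------------------------------------------------------------
# end to end


def test_strong_signal_end_to_end_reaches_high_auc():
    cfg = SimulationConfig(n_islands=60, mean_events_per_island=1000, seed=22)
    report = end_to_end(cfg, FragilityModel(meth_cpg_multiplier=2.0), k=5)
    assert report["cv_pooled"]["auc_roc"] > 0.9
    assert report["label_vs_truth_agreement"] > 0.98
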