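# Methods

## Model

DNA fragmentation during short-read library preparation is mechanochemical:
backbone hydrolysis is accelerated by shear forces and is sequence
dependent. CpG dinucleotides break ~1.5x more often than other
dinucleotides, and methylation of the cytosine raises the CpG rate by a
further ~30%. Because the 5' end of a mapped read is left intact by library
chemistry (3' ends are blunted and quality-trimmed), the reference base
aligned to a read's first base, together with its upstream neighbor, marks
the dinucleotide at which the molecule was hydrolysed. For a reverse-strand
read the break dinucleotide is the reverse complement of the two reference
bases at its alignment end: complementary dinucleotides are tracked
separately, since single-strand nicks on the two strands are offset and
their rates need not be equal.

Per CpG island *i* and dinucleotide *XY* we compute the odds ratio

    rho_XY^i = (n_XY^i / N^i) / (m_XY^i / (L^i - 1))

with n the island's event count at *XY*, N the island's total events, m the
sequence occurrence count and L the island length. rho is 1 under uniform
fragmentation, >1 for preferential breakage. Degenerate cases map to 0: a
dinucleotide with zero events or zero sequence occurrences, and the whole
vector of an island with N = 0 (flagged uncovered). Classification is a
two-class random forest on the 16-vector of rho values; the posterior is the
average tree vote. Because training data are class-balanced (majority-class
undersampling), implied priors are 0.5/0.5 and posteriors are comparable
across islands; the final decision ranks islands by posterior and calls the
top r fraction methylated, r being the expected genome-wide methylated
fraction.

## Coordinate and counting conventions

* Internal coordinates are 0-based half-open; SAM positions are converted on
  ingest; bedMethyl '-'-strand records are shifted to the forward-strand C.
  Bismark coverage files carry no strand column, so their positions are
  taken as given (start - 1); strand merging for Bismark therefore merges
  identical positions only. CpG strand merging defaults OFF.
* Read filtering keeps paired, properly paired, primary, non-supplementary,
  non-duplicate, non-QC-fail records with MAPQ >= mapq_min (default 0: the
  filtering contract is flag-based; no MAPQ threshold is invented). Both
  mates are counted — each 5' end is an independent break observation.
  5'-soft/hard-clipped reads are dropped: their mapped start is not the
  molecule end.
* An event is attributed to an island only when BOTH bases of its break
  dinucleotide lie inside [start, end), so the numerator of rho ranges over
  exactly the same L-1 dinucleotide positions as the denominator; uniform
  placement then calibrates rho to exactly 1. Overlapping islands each count
  the event independently.
* N-containing windows are excluded symmetrically from n and m; soft-masked
  bases are treated as ordinary nucleotides.
* Labels: a CpG is methylated iff meth fraction > 0.9 and coverage >= 11
  (strict readings of ">90%" and "more than 10 reads"), unmethylated iff
  fraction < 0.1 and coverage >= 11, else unknown. Islands need a strict
  majority; ties and islands with no assigned CpG are excluded, as is any
  island overlapping a segmental-duplication interval by >= 1 bp.
* Top-r cutoff: round-half-up of r*K islands; posterior ties broken by
  (chrom, start, id) for determinism.
* Forest defaults: 500 trees, unlimited depth, sqrt features per split,
  min leaf 1; an optional small grid {trees 100/500, min leaf 1/5} can be
  searched by cross-validation on the training split. Stratified folds are
  used for k-fold CV (falling back to unstratified with a warning when a
  class has fewer than k members); undersampling happens inside each
  training split only. Cross-sample application performs no batch
  correction or per-sample renormalization.

## Simulator

The generator emulates the inputs of a single WGS + WGBS experiment:

* **Genome.** Islands of 500–2000 bp are placed non-overlapping (>= 150 bp
  apart) in a 40% GC background whose CpGs are depleted ~5-fold (mimicking
  deamination-driven CpG loss); island sequences are built from units that
  are "CG" with probability 0.05 and a uniform single base otherwise,
  giving ~10% CpG dinucleotide density and ~55% GC — a strong CGI.
  Each island is methylated independently with probability r* (default 0.2,
  as in somatic human methylomes where ~19% of CGIs are methylated).
* **Breaks.** Every dinucleotide boundary on each strand is a candidate
  site sampled with probability proportional to its fragility weight
  (default: all 1.0, CG 1.5) times the methylated-CpG multiplier (default
  1.3) at CG sites of methylated islands; the per-island event count is
  Poisson with mean `mean_events_per_island` (default 300, roughly the
  read-start density a 30x genome with ~150 bp reads deposits on a 1 kb
  island). Breaks are independent per-position draws; no fragment-length
  model is needed because only 5'-end positions enter the method. An
  optional writer emits the events as a coordinate-sorted, flag-correct
  minimal SAM file that round-trips through the alignment reader to
  identical feature tables.
* **WGBS.** Per island CpG, coverage is Poisson (default mean 30) and the
  methylated-read count binomial with success probability 1 - e for
  methylated and e for unmethylated islands (symmetric miscall rate,
  default e = 0.01). Island methylation is all-or-none, matching the
  bimodality of real CGI methylomes; a `mosaic_fraction` knob flips a
  fraction of CpGs for robustness testing only. Records are emitted only
  for CpGs inside islands, which is all the labeler consults.

Everything is deterministic given the config seed (sub-seeds seed, seed+1,
seed+2 drive genome, breaks and WGBS).

What the simulator does **not** model: PCR amplification and GC bias,
sequencing errors and mapping ambiguity, fragment-length distributions,
cfDNA nuclease end motifs, copy-number variation, and partially methylated
domains. Passing tests on simulated data therefore demonstrate the internal
consistency and statistical behavior of the method under its own generative
assumptions, not its accuracy on real libraries.

## A note on recovering the methylation fragility multiplier from rho

The between-class ratio of mean rho_CG is a *biased* estimator of the
methylated-CpG multiplier w. Writing Z for an island's total fragility mass
over its 2(L-1) stranded boundaries, the expected event fraction at CG is
1.5w·2m_CG/Z_meth in a methylated island and 1.5·2m_CG/Z_unmeth in an
unmethylated one, so

    E[rho_CG | meth] / E[rho_CG | unmeth]  =  w · Z_unmeth / Z_meth  <  w,

with Z_meth/Z_unmeth = 1 + 1.5(w-1)·2m_CG/Z. The shortfall grows with the
island's CpG density (~3% at w=1.2 up to ~12% at w=2.0 at the generator's
~10% CpG density) and does not vanish with more events — it is a property of
the per-island normalization by N, not of sampling noise. The
package's parameter-recovery check therefore uses the normalization-free
double ratio rho_CG/rho_GC (GC is palindromic and has flat weight), whose
between-class ratio is exactly w: both N and the island's sequence
composition cancel. The same normalization effect slightly shrinks rho_CG
contrasts in real data but affects classification only through a monotone
per-island rescaling.

A related structural fact: with reads from both strands, a reverse read
observes the reverse complement of its reference window, so under flat
fragility rho_XY converges to (m_XY + m_revcomp(XY)) / (2·m_XY) rather than
exactly 1; for palindromic dinucleotides (CG, GC, AT, TA) and in expectation
over random sequences this is 1. This mirrors real libraries and is why the
uniform calibration checks use either palindromic dinucleotides or
single-strand placement.

## Problem sizes

The test suite and reproduction script run the method at desk scale chosen
to make the statistical assertions sharp while staying quick: rho
calibration with 1e5 events on a 2 kb island; brute-force agreement over 120
islands; multiplier recovery with 80 islands at 1e4 events each; a
1x/5x/10x/20x coverage ladder over 400 islands and 5 seeds starting from 20
events per island (so the 1x point is genuinely information-poor); an
r-threshold sweep over 240 islands at strong signal; and a null run over 800
islands. These sizes are the package's own defaults for its validation
experiments and can be scaled up freely through `SimulationConfig`.

## Known limitations

* The method needs substantial read depth per island; at single-sample
  coverage the posterior ordering is informative but individual island
  calls are noisy. Pooling reads across samples of the same type is the
  main lever on accuracy.
* r must be approximately right: the top-r rule converts posteriors to hard
  calls, and macro accuracy peaks when r matches the dataset's true
  methylated fraction.
* Labels inherit WGBS limitations; the >90%/>10-read filter discards
  low-coverage CpGs and the majority rule ignores partial methylation.
* No batch correction is attempted across samples or platforms by design;
  the fragility signal is assumed universal.
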