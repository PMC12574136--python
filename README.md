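# fragmeth

Predict the methylation status of CpG islands (CGIs) directly from ordinary
short-read whole-genome sequencing (WGS), with no bisulfite or long-read data.

## The idea

Mechanical DNA fragmentation during sequencing library preparation is a
mechanochemical reaction and is sequence dependent: the sugar-phosphate
backbone hydrolyses roughly 1.5x more often at CpG dinucleotides than
elsewhere, and roughly 30% more often again when the CpG is methylated. The
5' end of every mapped read marks one such break — the break dinucleotide is
the read's first aligned base together with its upstream reference neighbor,
read 5'→3' on the read's strand. Methylated islands therefore accumulate an
excess of reads starting inside CpGs, and that bias is measurable from read
coordinates alone.

Per island *i* the break spectrum is summarized by an odds ratio for each of
the 16 dinucleotides *XY*:

```
rho_XY^i = (n_XY^i / N^i) / (m_XY^i / (L^i - 1))
```

where `n_XY` counts filtered read 5'-end events whose break dinucleotide is
*XY* (both bases inside the island), `N` is the island's total event count,
`m_XY` counts occurrences of *XY* in the island sequence, and `L` is the
island length. Under uniform fragmentation every rho with `m_XY > 0` is ~1;
`rho_XY = 0` by convention when *XY* is absent from the sequence or receives
no events. A random forest is trained on the 16-vector
`y^i ~ [rho_AA^i ... rho_TT^i]` against WGBS-derived island labels
(a CpG is called methylated/unmethylated when >90% of bisulfite reads agree
and coverage exceeds 10 reads; islands are labeled by strict majority over
their CpGs; islands overlapping segmental duplications are excluded).
Training is class-balanced by undersampling, so forest posteriors are
average tree votes under 0.5/0.5 priors; final calls rank islands by
posterior and label the top *r* fraction methylated, where *r* is the
expected genome-wide methylated fraction (supplied, or inferred from the
training labels).

A built-in simulator generates genomes with CpG-rich islands, break events
from a configurable dinucleotide fragility model, minimal coordinate-sorted
SAM output, and mock WGBS methylomes, so the whole pipeline is testable
end-to-end without any downloads.

## Worked example

```bash
fragmeth run-all --seed 1 --n-islands 100 --mean-events 300 --out runs/demo
```

simulates 100 islands (~20% methylated) at ~300 read 5'-end events per
island — about what a single 30x WGS sample deposits on a 1 kb island —
then featurizes, labels from the mock WGBS methylome, and reports 10-fold
cross-validated metrics:

```
"labeled_methylated_fraction": 0.17,
"label_vs_truth_agreement": 1.0,
"cv_pooled": {
  "macro_accuracy": 0.73,
  "auc_roc": 0.94,
  ...
}
```

Macro accuracy is the unweighted mean of the per-class accuracies over
methylated and unmethylated islands; 0.73 at single-sample coverage rises
with event coverage (try `--mean-events 3000`). The same workflow is
available step by step (`simulate`, `featurize`, `label`, `train`,
`predict`, `evaluate`) and from Python — see `examples/` for narrative
scripts covering feature extraction, labeling, training with the top-r rule,
and the coverage/r-threshold behavior of the classifier.

To run on real data you need a coordinate-sorted, duplicate-marked BAM/SAM,
the matching reference FASTA, CGI intervals in BED, and (for training or
evaluation) a bedMethyl or Bismark-coverage methylome:

```bash
fragmeth featurize --alignment sample.bam --genome ref.fa --islands cgi.bed --out out/
fragmeth predict --model model.joblib --features out/features.tsv --r 0.19 --out calls/
```

Only properly paired, primary, non-duplicate, non-supplementary reads are
used; 5'-clipped reads are dropped.

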