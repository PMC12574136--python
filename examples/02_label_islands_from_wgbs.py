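"""Derive ground-truth island labels from a WGBS methylome.

Each CpG is called methylated/unmethylated only when >90% of bisulfite reads
agree and coverage exceeds 10 reads; islands are labeled by strict majority
over their CpGs, and the labeled methylated fraction estimates the r
parameter of the top-r decision rule.
"""

from fragmeth import SimulationConfig, label_islands, labeled_fraction, simulate_sample
from fragmeth.labels import exclude_segdup_overlaps

config = SimulationConfig(n_islands=50, seed=4)
sample = simulate_sample(config)

labels = label_islands(sample.islands, sample.methylome)
n_meth = sum(l.y == 1 for l in labels)
n_unmeth = sum(l.y == 0 for l in labels)
n_unknown = sum(l.y is None for l in labels)
print(f"islands labeled methylated:   {n_meth}")
print(f"islands labeled unmethylated: {n_unmeth}")
print(f"islands excluded:             {n_unknown}")
print(f"estimated r (methylated fraction): {labeled_fraction(labels):.3f}")

agreement = sum(l.y == sample.true_states[l.island_id]
                for l in labels if l.y is not None)
print(f"agreement with simulated truth: {agreement}/{n_meth + n_unmeth}")

# islands overlapping segmental duplications are excluded from training
segdups = [(sample.islands[0].chrom, sample.islands[0].start,
            sample.islands[0].start + 1)]
filtered = exclude_segdup_overlaps(labels, sample.islands, segdups)
print(f"after masking one segdup: {sum(l.y is not None for l in filtered)} labeled")
print()
print("At ~30x WGBS coverage and a 1% miscall rate the filters recover the "
      "true all-or-none island states essentially perfectly; the estimated r "
      "tracks the simulated methylated fraction (r* = 0.2) up to binomial "
      "noise at 50 islands.")
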