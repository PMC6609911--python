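"""Simulate a two-population isolation-with-migration amplicon study.

Builds the default sampling design (2 basins x 2 sites, 93 diploid
individuals), simulates 42 loci under the default IM demography, and
prints per-locus polymorphism summaries.
"""

import numpy as np

import amplipop as ap

rng = np.random.default_rng(1)
study = ap.generate_study(ap.default_design(), ap.default_params(),
                          n_loci=42, rng=rng)

n_reads = sum(len(r) for r in study.reads.values())
counts = [study.haplotypes[locus].n_sites for locus in study.loci]
print(f"individuals: {len(study.individuals)}  loci: {len(study.loci)}  "
      f"reads: {n_reads}")
print(f"segregating sites per locus: min {min(counts)}, "
      f"median {int(np.median(counts))}, max {max(counts)}")
ind = study.individuals[0]
a1, a2 = study.true_genotype(ind, study.loci[0])
het = sum(x != y for x, y in zip(a1, a2))
print(f"{ind} at {study.loci[0]}: {het} heterozygous sites, "
      f"{len(study.reads[(ind, study.loci[0])])} reads")
# The counts above are the raw material of every downstream stage: reads
# per individual-locus group feed phasing, segregating sites feed the
# infinite-sites filter and the SNP matrix.
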