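# amplipop

Amplicon-based population genetics for two-population
isolation-with-migration (IM) studies: from individually barcoded reads to
phased diploid alleles, infinite-sites-compliant alignments,
population-structure summaries, and nested demographic model tests.

## Who this is for

Population geneticists sequencing tens of PCR amplicons at depth in tens
of diploid individuals from two populations — the study design used to ask
whether strongly differentiated populations (for example hydrothermal-vent
invertebrates in separate back-arc basins) still exchange migrants, and in
which direction. The package implements the full desk-side chain of that
analysis and ships a truth-tracked coalescent + read simulator, so every
stage is testable end to end without external data.

## What it computes

- **Simulator** (`amplipop.simulate`): structured-coalescent genealogies
  under the IM model — an ancestral population of size θ_A splitting at
  time *t* into populations of sizes θ₁, θ₂ exchanging migrants at
  forward-time rates m₁→₂, m₂→₁ (all mutation-scaled: θ = 4Nu per locus) —
  with infinite-sites mutations, diploid individuals, and amplicon reads
  carrying substitution errors and intra-individual PCR chimeras.
- **Read sorting** (`amplipop.io`): barcode demultiplexing and primer-based
  locus sorting; EIGENSTRAT, Structure-genotype and IM-sampler input
  writers, all round-trip safe.
- **Phasing** (`amplipop.phasing`): "read-only" allele reconstruction —
  every allele realizable by chaining reads that agree at overlapping
  variant columns — followed by a <5%-support sequencing-error filter,
  PCR-recombinant (chimera) removal via the mosaic rule, and a 1–2 allele
  diploid call; anything unresolvable is flagged, never guessed.
- **Infinite-sites filter** (`amplipop.recomb`): drop >2-allele sites,
  four-gamete compatibility testing, and extraction of the longest
  nonrecombinant block with bounded individual removal, oracle-verified
  against exhaustive search.
- **Structure summaries** (`amplipop.popstruct`): haplotype-number diploid
  coding, a minor-allele dosage matrix with per-locus "chromosome" labels,
  allele-frequency-normalized PCA, Hudson's F_ST, and a permutation test
  of between-population differentiation along PC1.
- **Nested model tests** (`amplipop.immodels`): the 25 nested IM models
  (5 θ patterns × 5 migration patterns), constraint-counting degrees of
  freedom, 2LLR = 2(log p_full − log p_nested) against χ²_df, and the
  posterior probability of directional migration.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

```python
import numpy as np
import amplipop as ap

rng = np.random.default_rng(1)
study = ap.generate_study(ap.default_design(), ap.default_params(),
                          n_loci=42, rng=rng)
phased = ap.phase_study(study)
```

`examples/` contains one narrative script per capability. Running them
prints, among other things:

```
individuals: 93  loci: 42  reads: 117331
segregating sites per locus: min 14, median 23, max 34

exact genotype recovery among phased: 182/188 = 96.8%

|corr(PC1, population)| = 0.995
Hudson F_ST = 0.428
PC1 between-group variance fraction = 0.990, permutation p = 0.001

non-rejected models at alpha=0.05: [(3, 'm_2to1=0')]
P(m_1to2 > m_2to1) = 0.795 (closed form 0.793 for these marginals)
```

meaning: the default design simulates 93 diploids at 42 amplicons with a
median of 23 segregating sites per locus; phasing recovers the true allele
pair exactly for ~97% of callable individual-locus groups; after two
mutation-scaled time units of isolation the leading PCA axis is the
between-population axis and differentiation is maximally significant; and
on the bundled published 25-model log(p) column exactly one demographic
model survives — the one constraining migration into population 1 to zero,
i.e. one-directional gene flow.

A thin CLI mirrors the pipeline stages
(`amplipop demux | sortloci | phase | imfilter | structure-summary | imtest`).

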