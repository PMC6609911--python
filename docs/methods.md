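# Methods

`amplipop` implements the desk-side analysis chain for multilocus amplicon
resequencing of diploid individuals sampled from two populations under an
isolation-with-migration (IM) history. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## The IM coalescent simulator (`amplipop.simulate`)

**Model.** An ancestral population of mutation-scaled size θ_A splits at
time *t* into populations 1 and 2 of sizes θ₁ and θ₂, which then exchange
migrants at forward-in-time rates m₁→₂ and m₂→₁. Everything is in
mutation-scaled units: θ = 4*N·u* per locus, time in expected mutations per
locus per lineage, migration per mutation-scaled time unit. These are the
units in which IM samplers report estimates, so published parameter
magnitudes plug in directly; to convert, divide θ by 4*u* and *t* by *u*
(*u* = per-locus mutation rate per generation).

**Simulation.** Backward in time, within population *i* each lineage pair
coalesces at rate 2/θᵢ; lineages migrate at the time-reversal of the
forward rates (a lineage sampled in population 2 traces its ancestry into
population 1 at rate m₁→₂); at *t* all surviving lineages enter the
ancestral population. Public parameters are forward-in-time; one tested
function (`backward_migration_rates`) performs the reversal, and migration
events are logged in the forward convention. Each diploid individual
contributes two lineages sampled jointly (no selfing).

**Mutation.** Infinite sites: per-branch mutation counts are Poisson with
mean equal to branch length; each mutation occupies a fresh integer
position on the locus. Consequences used by the tests: every column is
biallelic, all site pairs are four-gamete compatible (no intralocus
recombination is simulated), E[π] = θ within a panmictic population, and
E[TMRCA] = *t* + θ_A/2 for two isolated lineages. The simulator is
cross-checked against msprime on within- and between-population branch
diversity under migration.

**Reads.** Per individual-locus group the read count is Poisson(coverage);
each read derives from allele 1 or 2 with equal probability or, with
probability `chimera_rate`, from an intra-individual PCR chimera formed by
crossing the two alleles at a breakpoint uniform over the gaps between
adjacent heterozygous sites (for homozygotes the chimera equals the
parent). Substitution errors are i.i.d. per base; there are no indel
errors (indel regions are excised from analysis anyway, so modeling them
would only exercise code the pipeline deliberately avoids). The default
`layout="amplicon"` anchors reads at either amplicon end, emulating
sequencing from both directions of a short amplicon; `"sheared"` draws
uniform offsets, emulating a fragmented long-amplicon library.

**Default study conditions.** The default design is 2 basins × 2 sites
with 23/24/23/23 diploids (93 individuals), 42 loci of 237 bp, coverage
30×, read length 200, error rate 0.002, chimera rate 0.1. The default
demography (θ₁ = 9.4764, θ₂ = 3.0266, θ_A = 0.7161, *t* = 0.299,
m₁→₂ = 0.7333, m₂→₁ = 0) follows the non-rejected nested model of the
two-basin vent-limpet analysis this pipeline reimplements. Per-locus
mutation-rate multipliers default to 1 (the source analysis does not state
per-locus scalars).

A note on regimes: at the default demography most within-individual
coalescence happens in the small ancestral population, so individuals
carry only ~1.4 heterozygous sites per locus. The end-to-end phasing tests
instead use θ = 5 for all three populations (*t* = 0.3, m = 0.5/0.1),
which puts per-individual heterozygous-site counts in the 2–8 band — the
regime in which read-backed phasing is actually stressed (multiple columns
to chain, chimeras that bridge them).

## Read-backed phasing (`amplipop.phasing`)

Within one individual at one locus:

1. **Variant columns** — a position is a variant column iff ≥2 base states
   are each supported by ≥`min_state_reads` reads (default 2: a singleton
   state is indistinguishable from sequencing error). Columns containing
   gap characters are excluded.
2. **Allele reconstruction** — every state vector over the variant columns
   realizable as a chain of mutually consistent overlapping reads is
   enumerated. Because reads cover contiguous position ranges, a vector is
   realizable iff its consistent reads cover every column and every
   adjacent column pair is co-covered by a consistent read; the
   implementation enumerates left-to-right with pruning and applies that
   exact check at the end, and is tested against full cartesian-product
   enumeration. If some adjacent column pair is co-covered by no read at
   all, phase across the gap is unresolvable and the group is flagged
   *ambiguous* rather than guessed — downstream coalescent input must be
   true haplotypes. Support = number of reads fully consistent with the
   vector (reads covering no variant column support nothing).
3. **Low-support filter** — candidates with support strictly below 5% of
   the group's reads are removed (a candidate at exactly 5% is kept; the
   rule is read literally as "less than"). The fraction is per
   individual-locus group, the unit at which coverage is meaningful.
4. **PCR-recombinant removal** — while >2 candidates remain, a candidate
   is identifiable as a chimera when (a) its state vector is a
   (possibly multi-breakpoint) mosaic of two other remaining candidates at
   every variant column, and (b) it does not out-support either putative
   parent. Condition (b) is this package's addition to the classic triple
   rule: chimeras arise in later PCR cycles and cannot out-amplify their
   templates, and without it a well-supported true allele can be
   mistaken for a mosaic of the *other* true allele and a rare
   sequencing-error allele — at 30× coverage and error 0.002 that
   misidentification affects ~2.5% of groups and deletes true alleles.
   The lowest-support identifiable candidate is removed first; iteration
   generalizes the published 3-allele rule to larger candidate sets.
5. **Genotype call** — one survivor: homozygote (sequence duplicated);
   two: heterozygote; zero: *failed*; more than two: *ambiguous* and
   excluded downstream.

Consensus sequences are rendered for filter survivors only: at variant
columns the candidate's states; elsewhere the majority base across
supporting reads (ties go to the alphabetically first base with a logged
warning; positions uncovered by supporting reads fall back to the
all-read majority, then N).

At the study conditions above, ≥95% of phased genotypes match the true
allele pair exactly (measured 97–98% across seeds); the residual errors
are homozygotes mis-called heterozygous when two reads share an error at
one position (the threshold rule cannot distinguish this from a real rare
allele at 30×), plus occasional consensus errors at thinly covered
positions. Roughly 7% of groups end ambiguous rather than phased.

## Infinite-sites filtering (`amplipop.recomb`)

Columns with more than two non-gap states are dropped (with a coordinate
map back to input positions). The four-gamete test marks a pair of
biallelic segregating sites incompatible iff all four two-site gametes are
observed; a gamete requires both states observed in the same row, so
missing data never fabricates gametes.

The longest nonrecombinant block maximizes, over contiguous intervals of
segregating sites and optionally over removal of a bounded number of rows
(never keeping fewer than `min_keep_fraction` of them, default 0.9), the
number of retained segregating sites; ties go to more retained
individuals, then the leftmost start. Published tools for this step
optimize a weighted individuals×sites score whose weighting is not
standardized; this package fixes the simpler objective above and verifies
it against exhaustive search over every (interval, removal subset)
combination at small sizes. Row-removal subsets are searched exhaustively
(restricted, without loss of optimality, to rows carrying a gamete rare
enough to be eliminable) up to a combinatorial budget, beyond which a
greedy most-conflicts-resolved heuristic takes over; the returned interval
spans from just after the previous excluded segregating site to the next
one, and the result is idempotent under re-filtering.

## Structure summaries (`amplipop.popstruct`)

Haplotype-number coding assigns each distinct allele sequence at a locus
an integer by first appearance in a fixed individual order, making diploid
genotypes unordered integer pairs (missing = −9); the coding is
deterministic and order-invariant given the individual ordering. The SNP
dosage matrix counts copies of the globally minor allele (frequency ties
break to the alphabetically smaller base) at biallelic sites, each site
labeled with its locus — loci are assigned distinct "chromosomes" so
downstream tools treat them as unlinked.

PCA uses the standard allele-frequency normalization: center by mean
dosage, scale by √(p(1−p)), mean-impute missing dosages, then an SVD of
the normalized matrix; eigenvalues (σ²/(n−1)) sum to the total normalized
variance. The leading axis is summarized by its correlation with the
binary population label. Differentiation is tested by permutation: the
observed between-group variance fraction of PC1 coordinates (η²) is
compared to its distribution under random relabeling,
p = (1 + #{perm ≥ obs})/(n_perm + 1). This is an explicit, calibrated
stand-in for the AMOVA-style significance summaries produced by PCA
packages, whose exact statistic varies; Hudson's F_ST (ratio of averages
of (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1) over
p₁(1−p₂) + p₂(1−p₁)) is reported alongside and cross-checked against the
same estimator applied to msprime output.

## Nested IM model testing (`amplipop.immodels`)

The six-parameter full model is constrained by the cross of five θ
patterns (unconstrained; θ₁=θ₂; θ₁=θ_A; θ₂=θ_A; all equal) and five
migration patterns (unconstrained; equal; m₂→₁=0; m₁→₂=0; none), giving 25
models with migration patterns cycling fastest. Degrees of freedom count
independent constraints (pairwise θ equality 1, triple equality 2, each
zero migration 1, migration equality 1). Each nested model is tested with
2LLR = 2(log p_full − log p_nested) against a plain χ²_df upper tail — the
convention of the source analyses; the boundary-corrected mixture for
m = 0 tests is noted but not the default. Negative 2LLR (possible when
log p comes from sampled genealogies) is clamped to zero with a warning.
Log joint probabilities are *inputs*: re-implementing the
genealogy-sampling MCMC is out of scope, so they come from an external
sampler run or, in tests, from simple composite likelihoods on simulated
data. A bundled worked example (`EXAMPLE_LMODE_LOGP`) carries the
published 25-model log(p) column of the two-basin limpet study; recomputed
2LLR values match the published statistics to within the rounding of the
printed log(p) values, and exactly one model (no migration from population
2 into population 1) survives at α = 0.05.

`direction_probability` summarizes a paired posterior sample of the two
forward migration rates as the fraction with m₁→₂ > m₂→₁ (ties count
half); it is invariant under common rescaling and matches the closed form
μ₁/(μ₁+μ₂) for independent exponential marginals.

## What the synthetic data do not show

The generator emulates the statistical structure the analysis assumes —
an IM history, infinite sites, intra-individual chimeras, uniform
substitution error. Real amplicon data add alignment uncertainty and
indels (excised here by assumption), quality-correlated and
homopolymer-clustered errors, inter-individual contamination, PCR drift in
allele ratios, and loci that violate single-copy assumptions. Passing
tests therefore establish correctness of the algorithms under the stated
model, not robustness to every artifact of a real sequencing run.

## Problem sizes used in the test and acceptance runs

Monte-Carlo closed forms use 10,000 replicates (3-SE bands); oracle
comparisons use 500 random phasing groups and 200 random alignments;
end-to-end recovery uses full-design studies (93 individuals × 42 loci)
over seeds 1–20; null calibration uses 500 panmictic studies with
99 permutations each. The acceptance script scales the stochastic suites
down (5 studies, 200/80 oracle cases, 200 calibration runs) while keeping
the full-design study size.
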