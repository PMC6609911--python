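"""Two-population isolation-with-migration (IM) coalescent and amplicon-read simulator.

The generator emulates a multilocus amplicon resequencing study of diploid
individuals sampled from two populations that split from a common ancestor
and subsequently exchanged migrants asymmetrically.  Everything is expressed
in mutation-scaled units: population sizes as theta = 4*N*u per locus, time
in expected mutations per locus, and migration rates per mutation-scaled
time unit, so that published IM parameter magnitudes are directly usable.

Public migration parameters are *forward in time* (``m_1to2`` is the rate at
which individuals move from population 1 into population 2).  The internal
structured-coalescent simulation runs backward in time and uses the
time-reversed rates; :func:`backward_migration_rates` is the single
conversion point.

Mutations follow the infinite-sites model: every mutation hits a previously
unused position, so all simulated loci are biallelic and four-gamete
compatible (no intralocus recombination is simulated).  Sequencing is
emulated with fixed-length substitution-error reads from both amplicon ends
plus intra-individual PCR chimeras formed by template switching between the
two alleles of one individual.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._seq import BASES, decode

logger = logging.getLogger(__name__)

__all__ = [
    "IMParams",
    "SampleSite",
    "SampleDesign",
    "MigrationEvent",
    "Genealogy",
    "LocusHaplotypes",
    "SimRead",
    "SimulatedStudy",
    "backward_migration_rates",
    "simulate_im_genealogy",
    "drop_mutations",
    "render_sequences",
    "simulate_amplicon_reads",
    "generate_study",
    "default_params",
    "default_design",
]


@dataclass(frozen=True)
class IMParams:
    """Demographic parameters of the two-population IM model.

    theta_pop1, theta_pop2, theta_anc
        Mutation-scaled population sizes (4*N*u per locus) of the two
        extant populations and their common ancestor.
    t_split
        Split time, in mutation-scaled time units (expected mutations per
        locus along one lineage).
    m_1to2, m_2to1
        Forward-in-time migration rates: ``m_1to2`` moves individuals from
        population 1 into population 2.  To convert theta to a diploid
        effective size divide by ``4*u``; to convert t to generations
        divide by ``u`` (u = per-locus mutation rate per generation).
    """

    theta_pop1: float
    theta_pop2: float
    theta_anc: float
    t_split: float
    m_1to2: float = 0.0
    m_2to1: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.theta_pop1, self.theta_pop2, self.theta_anc,
                self.t_split, self.m_1to2, self.m_2to1)
        if any(not math.isfinite(v) or v < 0 for v in vals):
            raise ValueError(f"IM parameters must be finite and >= 0, got {vals}")
        if self.theta_pop1 <= 0 or self.theta_pop2 <= 0 or self.theta_anc <= 0:
            raise ValueError("theta parameters must be > 0")

    def as_tuple(self) -> Tuple[float, float, float, float, float, float]:
        return (self.theta_pop1, self.theta_pop2, self.theta_anc,
                self.t_split, self.m_1to2, self.m_2to1)


def backward_migration_rates(params: IMParams) -> Tuple[float, float]:
    """Per-lineage backward-in-time migration rates ``(from_pop1, from_pop2)``.

    A lineage currently traced in population 1 jumps (backward) into
    population 2 at the forward rate of 2 -> 1 movement, and vice versa:
    ancestry flows against the forward migration direction.
    """
    return params.m_2to1, params.m_1to2


@dataclass(frozen=True)
class SampleSite:
    label: str
    population: int  # 1 or 2
    n_individuals: int

    def __post_init__(self) -> None:
        if self.population not in (1, 2):
            raise ValueError("population index must be 1 or 2")
        if self.n_individuals < 0:
            raise ValueError("individual count must be >= 0")


@dataclass(frozen=True)
class SampleDesign:
    """Sampling design: sites, each assigned to one of the two populations."""

    sites: Tuple[SampleSite, ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("design needs at least one site")

    def n_individuals(self, population: Optional[int] = None) -> int:
        return sum(s.n_individuals for s in self.sites
                   if population is None or s.population == population)


@dataclass(frozen=True)
class MigrationEvent:
    """A lineage migration, recorded in the forward-time convention.

    ``node`` identifies the lineage by the tree node at the bottom of the
    migrating branch; forward in time the lineage moved ``source -> dest``
    at ``time`` (so the backward trace jumped dest -> source).
    """

    node: int
    time: float
    source: int
    dest: int


@dataclass
class Genealogy:
    """A binary coalescent tree over sampled lineages.

    Nodes ``0 .. n_leaves-1`` are leaves at time 0; internal nodes are
    numbered in coalescence order.  ``parent[root] == -1``.
    """

    n_leaves: int
    parent: np.ndarray          # (2n-1,) int32
    time: np.ndarray            # (2n-1,) float64, increasing into the past
    leaf_population: np.ndarray  # (n,) int8, 1 or 2
    migrations: List[MigrationEvent] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (root entry is 0)."""
        out = np.zeros(self.n_nodes)
        nonroot = np.arange(self.n_nodes - 1)
        out[nonroot] = self.time[self.parent[nonroot]] - self.time[nonroot]
        return out

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaves_below(self) -> List[np.ndarray]:
        """For every node, the sorted array of leaf indices in its subtree."""
        kids: List[List[int]] = [[] for _ in range(self.n_nodes)]
        for c in range(self.n_nodes - 1):
            kids[self.parent[c]].append(c)
        out: List[Optional[np.ndarray]] = [None] * self.n_nodes
        for v in range(self.n_leaves):
            out[v] = np.array([v], dtype=np.int64)
        for v in range(self.n_leaves, self.n_nodes):  # coalescence order
            out[v] = np.sort(np.concatenate([out[c] for c in kids[v]]))
        return out  # type: ignore[return-value]


def simulate_im_genealogy(params: IMParams, n1: int, n2: int,
                          rng: np.random.Generator) -> Genealogy:
    """Simulate one structured-coalescent genealogy under the IM model.

    Within population i a pair of lineages coalesces at rate ``2/theta_i``;
    lineages migrate backward in time at the time-reversal of the forward
    rates; at ``t_split`` all surviving lineages enter the ancestral
    population (pair rate ``2/theta_anc``).
    """
    if n1 < 0 or n2 < 0 or n1 + n2 < 2:
        raise ValueError("need at least two sampled lineages")
    n = n1 + n2
    parent = np.full(2 * n - 1, -1, dtype=np.int32)
    time = np.zeros(2 * n - 1)
    leaf_pop = np.array([1] * n1 + [2] * n2, dtype=np.int8)

    # active lineages: node id -> current population
    pop_of: Dict[int, int] = {i: int(leaf_pop[i]) for i in range(n)}
    migrations: List[MigrationEvent] = []
    back1, back2 = backward_migration_rates(params)
    next_node = n
    t = 0.0

    # phase 1: two islands, until t_split
    while len(pop_of) > 1 and t < params.t_split:
        in1 = [v for v, p in pop_of.items() if p == 1]
        in2 = [v for v, p in pop_of.items() if p == 2]
        k1, k2 = len(in1), len(in2)
        r_c1 = k1 * (k1 - 1) / params.theta_pop1
        r_c2 = k2 * (k2 - 1) / params.theta_pop2
        r_m1 = k1 * back1   # lineages in pop1 jump (backward) to pop2
        r_m2 = k2 * back2
        total = r_c1 + r_c2 + r_m1 + r_m2
        if total == 0.0:
            break
        wait = rng.exponential(1.0 / total)
        if t + wait >= params.t_split:
            break
        t += wait
        u = rng.random() * total
        if u < r_c1:
            a, b = rng.choice(k1, size=2, replace=False)
            _coalesce(in1[a], in1[b], next_node, t, parent, time, pop_of, 1)
            next_node += 1
        elif u < r_c1 + r_c2:
            a, b = rng.choice(k2, size=2, replace=False)
            _coalesce(in2[a], in2[b], next_node, t, parent, time, pop_of, 2)
            next_node += 1
        elif u < r_c1 + r_c2 + r_m1:
            v = in1[int(rng.integers(k1))]
            pop_of[v] = 2
            # backward jump 1 -> 2 means the lineage moved 2 -> 1 forward
            migrations.append(MigrationEvent(node=v, time=t, source=2, dest=1))
        else:
            v = in2[int(rng.integers(k2))]
            pop_of[v] = 1
            migrations.append(MigrationEvent(node=v, time=t, source=1, dest=2))

    # phase 2: ancestral panmictic population
    t = max(t, params.t_split)
    active = list(pop_of)
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1) / params.theta_anc
        t += rng.exponential(1.0 / rate)
        a, b = rng.choice(k, size=2, replace=False)
        va, vb = active[a], active[b]
        parent[va] = parent[vb] = next_node
        time[next_node] = t
        active = [v for v in active if v not in (va, vb)] + [next_node]
        next_node += 1

    return Genealogy(n_leaves=n, parent=parent, time=time,
                     leaf_population=leaf_pop, migrations=migrations)


def _coalesce(va: int, vb: int, node: int, t: float, parent: np.ndarray,
              time: np.ndarray, pop_of: Dict[int, int], pop: int) -> None:
    parent[va] = parent[vb] = node
    time[node] = t
    del pop_of[va], pop_of[vb]
    pop_of[node] = pop


@dataclass
class LocusHaplotypes:
    """Derived/ancestral (1/0) states per sampled lineage at segregating sites."""

    derived: np.ndarray    # (n_lineages, n_sites) uint8 in {0,1}
    positions: np.ndarray  # (n_sites,) int64, strictly increasing
    length: int            # locus length in bp

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_lineages(self) -> int:
        return int(self.derived.shape[0])


def drop_mutations(gen: Genealogy, rng: np.random.Generator,
                   locus_length: int = 237,
                   rate_multiplier: float = 1.0) -> LocusHaplotypes:
    """Drop infinite-sites mutations on a genealogy.

    The mutation count on each branch is Poisson with mean equal to the
    branch length (times an optional per-locus rate multiplier); every
    mutation occupies a previously unused integer position in
    ``[0, locus_length)``.
    """
    if rate_multiplier < 0:
        raise ValueError("rate multiplier must be >= 0")
    lengths = gen.branch_lengths() * rate_multiplier
    counts = rng.poisson(lengths)
    total = int(counts.sum())
    if total > locus_length:
        raise ValueError(
            f"{total} mutations cannot occupy distinct sites on a "
            f"{locus_length} bp locus; increase locus_length or lower theta")
    positions = np.sort(rng.choice(locus_length, size=total, replace=False))
    derived = np.zeros((gen.n_leaves, total), dtype=np.uint8)
    if total:
        below = gen.leaves_below()
        # assign mutation slots to branches in node order, then shuffle
        # slot -> position so positions are exchangeable across branches
        order = rng.permutation(total)
        j = 0
        for node in range(gen.n_nodes):
            for _ in range(int(counts[node])):
                derived[below[node], order[j]] = 1
                j += 1
    return LocusHaplotypes(derived=derived, positions=positions,
                           length=locus_length)


def render_sequences(haps: LocusHaplotypes,
                     rng: np.random.Generator) -> np.ndarray:
    """Render haplotypes as full-length sequences (uint8 base codes).

    The ancestral sequence is uniform random over ACGT; each segregating
    site gets a derived base distinct from the ancestral one.
    """
    anc = rng.integers(0, 4, size=haps.length, dtype=np.uint8)
    seqs = np.tile(anc, (haps.n_lineages, 1))
    if haps.n_sites:
        der = (anc[haps.positions]
               + rng.integers(1, 4, size=haps.n_sites, dtype=np.uint8)) % 4
        rows, cols = np.nonzero(haps.derived)
        seqs[rows, haps.positions[cols]] = der[cols]
    return seqs


@dataclass
class SimRead:
    """One simulated read with its recorded truth origin."""

    individual: str
    locus: str
    start: int                  # 0-based offset on the locus
    codes: np.ndarray           # uint8 base codes
    origin: str                 # "allele-1" | "allele-2" | "chimera"
    breakpoint: Optional[int] = None  # chimera crossover position, if any

    @property
    def sequence(self) -> str:
        return decode(self.codes)

    def __len__(self) -> int:
        return int(self.codes.size)


def simulate_amplicon_reads(allele1: np.ndarray, allele2: np.ndarray,
                            coverage: float, read_length: int,
                            error_rate: float, chimera_rate: float,
                            rng: np.random.Generator,
                            individual: str = "ind", locus: str = "locus",
                            layout: str = "amplicon") -> List[SimRead]:
    """Simulate substitution-error reads from one individual's two alleles.

    Each read derives from allele 1 or 2 with equal probability or, with
    probability ``chimera_rate``, from a PCR chimera formed by crossing the
    two alleles at a breakpoint chosen uniformly among the gaps between
    adjacent heterozygous sites (for a homozygote the chimera is identical
    to the parent allele).  ``layout="amplicon"`` anchors reads at either
    amplicon end (sequencing from both directions, already normalized to
    the forward strand); ``layout="sheared"`` draws uniform start offsets.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    if not (0 <= error_rate <= 1 and 0 <= chimera_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    L = int(allele1.size)
    if allele2.size != L:
        raise ValueError("alleles must have equal length")
    if read_length > L:
        logger.warning("read_length %d exceeds locus length %d; emitting "
                       "full-length reads", read_length, L)
    rl = min(read_length, L)

    n = int(rng.poisson(coverage))
    if n == 0:
        return []
    pick = rng.integers(0, 2, size=n)
    is_chim = rng.random(n) < chimera_rate
    het = np.nonzero(allele1 != allele2)[0]

    tmpl = np.where((pick == 0)[:, None], allele1[None, :], allele2[None, :])
    breakpoints: List[Optional[int]] = [None] * n
    if het.size >= 2 and is_chim.any():
        idx = np.nonzero(is_chim)[0]
        gap = rng.integers(0, het.size - 1, size=idx.size)
        bps = het[gap] + 1  # first position taken from the partner allele
        other = np.where((pick[idx] == 0)[:, None],
                         allele2[None, :], allele1[None, :])
        mask = np.arange(L)[None, :] >= bps[:, None]
        tmpl[idx] = np.where(mask, other, tmpl[idx])
        for i, b in zip(idx, bps):
            breakpoints[int(i)] = int(b)

    if rl == L:
        starts = np.zeros(n, dtype=np.int64)
    elif layout == "sheared":
        starts = rng.integers(0, L - rl + 1, size=n)
    elif layout == "amplicon":
        starts = np.where(rng.random(n) < 0.5, 0, L - rl).astype(np.int64)
    else:
        raise ValueError(f"unknown read layout {layout!r}")

    cols = starts[:, None] + np.arange(rl)[None, :]
    reads = np.take_along_axis(tmpl, cols, axis=1)
    err = rng.random(reads.shape) < error_rate
    n_err = int(err.sum())
    if n_err:
        reads[err] = (reads[err]
                      + rng.integers(1, 4, size=n_err, dtype=np.uint8)) % 4

    out = []
    for i in range(n):
        origin = "chimera" if is_chim[i] else f"allele-{pick[i] + 1}"
        out.append(SimRead(individual=individual, locus=locus,
                           start=int(starts[i]), codes=reads[i].copy(),
                           origin=origin, breakpoint=breakpoints[i]))
    return out


@dataclass
class SimulatedStudy:
    """A full simulated study: reads grouped per individual and locus, plus truth."""

    params: IMParams
    design: SampleDesign
    individuals: List[str]
    individual_site: Dict[str, str]
    individual_population: Dict[str, int]
    loci: List[str]
    locus_length: int
    truth_alleles: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]]
    haplotypes: Dict[str, LocusHaplotypes]
    genealogies: Dict[str, Genealogy]
    reads: Dict[Tuple[str, str], List[SimRead]]

    def true_genotype(self, individual: str, locus: str) -> Tuple[str, str]:
        """The individual's two true allele sequences at a locus (strings)."""
        a1, a2 = self.truth_alleles[(individual, locus)]
        return decode(a1), decode(a2)

    def true_alignment(self, locus: str) -> Dict[str, Tuple[str, str]]:
        """Map individual -> (allele1, allele2) strings for one locus."""
        return {ind: self.true_genotype(ind, locus) for ind in self.individuals}

    @property
    def population_labels(self) -> Dict[str, int]:
        return dict(self.individual_population)


def default_params() -> IMParams:
    """The study-scale IM parameter regime used as the simulator default.

    Magnitudes follow the non-rejected nested model of the two-basin vent
    limpet analysis this pipeline reimplements: a large population 1, a
    ~3x smaller population 2, a much smaller ancestor, split time ~0.3,
    and one-directional forward migration from population 1 into 2.
    """
    return IMParams(theta_pop1=9.4764, theta_pop2=3.0266, theta_anc=0.7161,
                    t_split=0.299, m_1to2=0.7333, m_2to1=0.0)


def default_design() -> SampleDesign:
    """Two sites per basin, 23-24 diploids per site (93 individuals total)."""
    return SampleDesign(sites=(
        SampleSite("SW8", 1, 23),
        SampleSite("SW1", 1, 24),
        SampleSite("ABE", 2, 23),
        SampleSite("TM", 2, 23),
    ))


def generate_study(design: SampleDesign, params: IMParams,
                   n_loci: int = 42, locus_length: int = 237,
                   coverage: float = 30.0, read_length: int = 200,
                   error_rate: float = 0.002, chimera_rate: float = 0.1,
                   rng: Optional[np.random.Generator] = None,
                   locus_rate_multipliers: Optional[Sequence[float]] = None,
                   layout: str = "amplicon",
                   simulate_reads: bool = True) -> SimulatedStudy:
    """Simulate a complete amplicon study under the IM model.

    Each diploid individual contributes two lineages, sampled jointly, to
    every locus genealogy.  Reads are generated per individual and locus
    (``simulate_reads=False`` skips read generation for analyses that only
    need true haplotypes).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_loci < 0:
        raise ValueError("n_loci must be >= 0")
    if locus_rate_multipliers is not None and len(locus_rate_multipliers) != n_loci:
        raise ValueError("need one rate multiplier per locus")

    individuals: List[str] = []
    ind_site: Dict[str, str] = {}
    ind_pop: Dict[str, int] = {}
    # population 1 individuals first, matching lineage layout below
    for pop in (1, 2):
        for site in design.sites:
            if site.population != pop:
                continue
            for i in range(site.n_individuals):
                name = f"{site.label}_{i + 1:02d}"
                individuals.append(name)
                ind_site[name] = site.label
                ind_pop[name] = pop
    n1 = 2 * design.n_individuals(1)
    n2 = 2 * design.n_individuals(2)

    loci = [f"L{j + 1:02d}" for j in range(n_loci)]
    truth: Dict[Tuple[str, str], Tuple[np.ndarray, np.ndarray]] = {}
    haps: Dict[str, LocusHaplotypes] = {}
    gens: Dict[str, Genealogy] = {}
    reads: Dict[Tuple[str, str], List[SimRead]] = {}

    for j, locus in enumerate(loci):
        gen = simulate_im_genealogy(params, n1, n2, rng)
        mult = 1.0 if locus_rate_multipliers is None else float(locus_rate_multipliers[j])
        lh = drop_mutations(gen, rng, locus_length=locus_length,
                            rate_multiplier=mult)
        seqs = render_sequences(lh, rng)
        gens[locus] = gen
        haps[locus] = lh
        for i, ind in enumerate(individuals):
            a1, a2 = seqs[2 * i], seqs[2 * i + 1]
            truth[(ind, locus)] = (a1, a2)
            if simulate_reads:
                reads[(ind, locus)] = simulate_amplicon_reads(
                    a1, a2, coverage=coverage, read_length=read_length,
                    error_rate=error_rate, chimera_rate=chimera_rate,
                    rng=rng, individual=ind, locus=locus, layout=layout)

    return SimulatedStudy(params=params, design=design,
                          individuals=individuals, individual_site=ind_site,
                          individual_population=ind_pop, loci=loci,
                          locus_length=locus_length, truth_alleles=truth,
                          haplotypes=haps, genealogies=gens, reads=reads)
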