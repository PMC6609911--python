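"""Population-structure summaries over phased multilocus amplicon data.

Covers the descriptive layer of the pipeline: coding phased allele
sequences as per-locus haplotype numbers (diploid genotypes become
unordered integer pairs), building an individuals x SNPs dosage matrix with
a per-locus "chromosome" label for linkage bookkeeping, a principal
components analysis with the standard allele-frequency (binomial)
normalization, Hudson's F_ST, and a label-permutation test of between-group
differentiation along the leading axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from ._seq import encode

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeGenotypeTable",
    "SNPGenotypeMatrix",
    "PCAResult",
    "DifferentiationResult",
    "encode_haplotypes",
    "genotypes_from_phasing",
    "build_snp_matrix",
    "snp_matrix_from_truth",
    "run_pca",
    "hudson_fst",
    "permutation_differentiation",
]

MISSING_GENOTYPE = -9

SeqLike = Union[str, np.ndarray]
PerLocusGenotypes = Dict[str, Dict[str, Tuple[SeqLike, SeqLike]]]


def _as_codes(seq: SeqLike) -> np.ndarray:
    if isinstance(seq, str):
        return encode(seq)
    return np.asarray(seq, dtype=np.uint8)


@dataclass
class HaplotypeGenotypeTable:
    """Diploid genotypes coded as per-locus haplotype numbers."""

    loci: List[str]
    individuals: List[str]
    # locus -> individual -> (h1, h2); individuals absent at a locus are missing
    genotypes: Dict[str, Dict[str, Tuple[int, int]]]
    # locus -> haplotype number -> sequence
    haplotypes: Dict[str, Dict[int, str]]

    def genotype(self, locus: str, individual: str) -> Tuple[int, int]:
        return self.genotypes[locus].get(
            individual, (MISSING_GENOTYPE, MISSING_GENOTYPE))


def genotypes_from_phasing(phased: Mapping[Tuple[str, str], "object"],
                           individuals: Sequence[str],
                           loci: Sequence[str]) -> PerLocusGenotypes:
    """Convert ``phase_study`` output to per-locus sequence-pair mappings,
    keeping only genotypes with status ``phased``."""
    out: PerLocusGenotypes = {locus: {} for locus in loci}
    for (ind, locus), g in phased.items():
        if getattr(g, "status", None) == "phased" and g.alleles is not None:
            out[locus][ind] = g.alleles
    return out


def encode_haplotypes(per_locus: PerLocusGenotypes,
                      individuals: Sequence[str]) -> HaplotypeGenotypeTable:
    """Number the distinct allele sequences of each locus.

    Numbers are assigned by first appearance while scanning individuals in
    the given fixed order (allele slot 1 before slot 2), so the coding is
    deterministic and invariant to the input mapping's iteration order.
    Identical sequences share a number; numbers are dense from 1.
    """
    loci = sorted(per_locus)
    genotypes: Dict[str, Dict[str, Tuple[int, int]]] = {}
    haplotypes: Dict[str, Dict[int, str]] = {}
    for locus in loci:
        number: Dict[str, int] = {}
        gmap: Dict[str, Tuple[int, int]] = {}
        for ind in individuals:
            if ind not in per_locus[locus]:
                continue
            pair = []
            for seq in per_locus[locus][ind]:
                s = seq if isinstance(seq, str) else "".join(map(str, seq))
                if s not in number:
                    number[s] = len(number) + 1
                pair.append(number[s])
            gmap[ind] = (pair[0], pair[1])
        genotypes[locus] = gmap
        haplotypes[locus] = {v: k for k, v in number.items()}
    return HaplotypeGenotypeTable(loci=loci, individuals=list(individuals),
                                  genotypes=genotypes, haplotypes=haplotypes)


@dataclass
class SNPGenotypeMatrix:
    """Individuals x biallelic sites diploid dosage matrix.

    Entries count copies of the globally minor allele (0/1/2; -1 missing).
    Every site carries its locus label — the "chromosome" assignment that
    keeps loci in linkage equilibrium downstream — and its position within
    the locus alignment.
    """

    genotypes: np.ndarray            # (n_ind, n_snp) int8, -1 = missing
    individuals: List[str]
    populations: List                # per-individual population label
    snp_locus: List[str]             # per-site locus ("chromosome") label
    snp_position: np.ndarray         # per-site position within its locus
    snp_alleles: List[Tuple[str, str]] = field(default_factory=list)  # (major, minor)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return int(self.genotypes.shape[1])


def build_snp_matrix(per_locus: PerLocusGenotypes,
                     individuals: Sequence[str],
                     populations: Mapping[str, object]) -> SNPGenotypeMatrix:
    """Build the dosage matrix from per-locus phased sequence pairs.

    Sites must be at most biallelic (run the infinite-sites filter first);
    monomorphic sites are skipped.  Dosage counts the minor allele defined
    across all individuals; at a frequency tie the alphabetically smaller
    base is counted.  Individuals missing a locus get -1 at its sites.
    """
    inds = list(individuals)
    idx = {ind: i for i, ind in enumerate(inds)}
    cols: List[np.ndarray] = []
    col_locus: List[str] = []
    col_pos: List[int] = []
    col_alleles: List[Tuple[str, str]] = []

    for locus in sorted(per_locus):
        gmap = per_locus[locus]
        if not gmap:
            continue
        present = [ind for ind in inds if ind in gmap]
        if not present:
            continue
        h = np.stack([_as_codes(seq) for ind in present
                      for seq in gmap[ind]])  # (2*len(present), L)
        L = h.shape[1]
        for j in range(L):
            col = h[:, j]
            obs = col[col < 4]
            states, counts = np.unique(obs, return_counts=True)
            if states.size < 2:
                continue
            if states.size > 2:
                raise ValueError(
                    f"locus {locus} column {j} has >2 alleles; apply the "
                    "infinite-sites filter first")
            # minor allele: lower count; tie -> alphabetically smaller base
            # (np.unique returns states in ascending code order)
            if counts[1] < counts[0]:
                minor, major = states[1], states[0]
            else:
                minor, major = states[0], states[1]
            dosage = np.full(len(inds), -1, dtype=np.int8)
            for pi, ind in enumerate(present):
                pair = col[2 * pi: 2 * pi + 2]
                if (pair >= 4).any():
                    continue
                dosage[idx[ind]] = int((pair == minor).sum())
            cols.append(dosage)
            col_locus.append(locus)
            col_pos.append(j)
            col_alleles.append(("ACGT"[major], "ACGT"[minor]))

    geno = (np.stack(cols, axis=1) if cols
            else np.zeros((len(inds), 0), dtype=np.int8))
    return SNPGenotypeMatrix(genotypes=geno, individuals=inds,
                             populations=[populations[i] for i in inds],
                             snp_locus=col_locus,
                             snp_position=np.array(col_pos, dtype=np.int64),
                             snp_alleles=col_alleles)


def snp_matrix_from_truth(study) -> SNPGenotypeMatrix:
    """Dosage matrix straight from a simulated study's true alleles."""
    per_locus = {locus: {ind: study.truth_alleles[(ind, locus)]
                         for ind in study.individuals}
                 for locus in study.loci}
    return build_snp_matrix(per_locus, study.individuals,
                            study.individual_population)


@dataclass
class PCAResult:
    """Principal components of the normalized dosage matrix."""

    eigenvalues: np.ndarray          # descending
    coordinates: np.ndarray          # (n_ind, n_components)
    corr_pc1_population: float       # axis-1 / binary-label correlation
    degenerate: bool = False         # zero-variance input; correlation set to 0


def _binary_labels(populations: Sequence) -> Optional[np.ndarray]:
    uniq = sorted(set(populations), key=str)
    if len(uniq) != 2:
        return None
    return np.array([0 if p == uniq[0] else 1 for p in populations], float)


def run_pca(matrix: SNPGenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of the dosage matrix with allele-frequency normalization.

    Each site is centered by its mean dosage and scaled by the binomial
    standard deviation sqrt(p(1-p)) at its allele frequency p; missing
    dosages are mean-imputed.  Eigenvalues are of the individual covariance
    (SVD of the normalized matrix divided by n-1) and sum to the total
    normalized variance.
    """
    if matrix.n_individuals < 2:
        raise ValueError("PCA needs at least two individuals")
    G = matrix.genotypes.astype(float)
    G[matrix.genotypes < 0] = np.nan
    p = np.nanmean(G, axis=0) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        X = (G - 2.0 * p[None, :]) / np.sqrt(p * (1.0 - p))[None, :]
    X[:, (p <= 0) | (p >= 1) | ~np.isfinite(p)] = 0.0
    X[np.isnan(X)] = 0.0  # mean imputation after centering

    n = matrix.n_individuals
    ncomp = min(n_components, *X.shape) if X.size else 0
    if X.size == 0 or not X.any():
        return PCAResult(eigenvalues=np.zeros(max(ncomp, 1)),
                         coordinates=np.zeros((n, max(ncomp, 1))),
                         corr_pc1_population=0.0, degenerate=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    eigenvalues = (s ** 2) / (n - 1)
    coords = U * s[None, :]
    eigenvalues = eigenvalues[:ncomp]
    coords = coords[:, :ncomp]

    labels = _binary_labels(matrix.populations)
    pc1 = coords[:, 0]
    if labels is None or np.std(pc1) == 0 or np.std(labels) == 0:
        return PCAResult(eigenvalues=eigenvalues, coordinates=coords,
                         corr_pc1_population=0.0, degenerate=True)
    corr = float(np.corrcoef(pc1, labels)[0, 1])
    return PCAResult(eigenvalues=eigenvalues, coordinates=coords,
                     corr_pc1_population=corr)


def hudson_fst(matrix: SNPGenotypeMatrix) -> float:
    """Hudson's F_ST between the two labeled populations.

    Per-site numerator ``(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)``
    and denominator ``p1(1-p2) + p2(1-p1)`` are combined as a ratio of
    averages across sites (allele counts per population must be >= 2).
    """
    labels = _binary_labels(matrix.populations)
    if labels is None:
        raise ValueError("Hudson F_ST needs exactly two population labels")
    G = matrix.genotypes.astype(float)
    G[matrix.genotypes < 0] = np.nan
    g1 = G[labels == 0.0]
    g2 = G[labels == 1.0]
    n1 = 2.0 * np.sum(~np.isnan(g1), axis=0)
    n2 = 2.0 * np.sum(~np.isnan(g2), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.nansum(g1, axis=0) / n1
        p2 = np.nansum(g2, axis=0) / n2
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(num) & np.isfinite(den)
    num_sum = float(num[ok].sum())
    den_sum = float(den[ok].sum())
    if den_sum == 0.0:
        return 0.0
    return num_sum / den_sum


@dataclass
class DifferentiationResult:
    """Observed differentiation and its permutation p-value."""

    statistic: float                 # between-group variance fraction on PC1
    fst: float                       # Hudson F_ST, reported alongside
    n_permutations: int
    p_value: float


def permutation_differentiation(matrix: SNPGenotypeMatrix,
                                n_perm: int = 999,
                                rng: Optional[np.random.Generator] = None
                                ) -> DifferentiationResult:
    """Permutation test of between-population differentiation along PC1.

    The observed statistic is the between-group variance fraction of the
    axis-1 coordinates (eta-squared); the null distribution comes from
    random relabeling of individuals, and
    ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    labels = _binary_labels(matrix.populations)
    if labels is None or labels.sum() in (0, len(labels)):
        raise ValueError("need two non-empty labeled populations")
    pca = run_pca(matrix)
    pc1 = pca.coordinates[:, 0]

    def eta2(lab: np.ndarray) -> float:
        sst = float(((pc1 - pc1.mean()) ** 2).sum())
        if sst == 0.0:
            return 0.0
        ssb = 0.0
        for v in (0.0, 1.0):
            grp = pc1[lab == v]
            ssb += grp.size * (grp.mean() - pc1.mean()) ** 2
        return ssb / sst

    obs = eta2(labels)
    count = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        if eta2(lab) >= obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return DifferentiationResult(statistic=obs, fst=hudson_fst(matrix),
                                 n_permutations=n_perm, p_value=p)
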