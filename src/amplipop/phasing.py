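"""Read-backed ("read-only") diploid allele reconstruction for amplicon data.

Within one individual at one locus, every possible allele is reconstructed
by chaining reads that agree at overlapping variant columns; candidate
alleles arising from sequencing error are then removed by a low-support
filter, and candidates arising from intra-individual PCR template switching
(chimeras) are removed because a chimera is expressible, column by column,
as a recombinant of two other candidates.  One or two surviving candidates
yield a homozygous or heterozygous diploid call; anything else is flagged
rather than guessed, since downstream coalescent analyses require true
haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._seq import GAP_CODE, MISSING, decode

logger = logging.getLogger(__name__)

__all__ = [
    "VariantColumn",
    "CandidateAllele",
    "PhasedGenotype",
    "identify_variant_columns",
    "reconstruct_alleles",
    "filter_low_support",
    "remove_pcr_recombinants",
    "call_genotype",
    "phase_read_group",
    "phase_study",
]


@dataclass(frozen=True)
class VariantColumn:
    """A locus position where at least two base states are well supported."""

    position: int
    state_counts: Dict[int, int]  # base code -> supporting read count

    @property
    def states(self) -> Tuple[int, ...]:
        return tuple(sorted(self.state_counts))


@dataclass
class CandidateAllele:
    """A reconstructed candidate allele over the variant columns of a group."""

    states: Tuple[int, ...]       # base code per variant column
    support: int                  # reads fully consistent with the vector
    fraction: float               # support / total reads in the group
    _sequence: Optional[str] = field(default=None, repr=False)

    @property
    def sequence(self) -> Optional[str]:
        """Full-length consensus sequence (rendered by the phasing pipeline)."""
        return self._sequence


@dataclass
class PhasedGenotype:
    """Final diploid call for one individual at one locus."""

    individual: str
    locus: str
    status: str                   # "phased" | "ambiguous" | "failed"
    alleles: Optional[Tuple[str, str]] = None  # identical if homozygous

    @property
    def is_heterozygous(self) -> Optional[bool]:
        if self.status != "phased" or self.alleles is None:
            return None
        return self.alleles[0] != self.alleles[1]


class _Group:
    """Internal dense view of an aligned read group (codes + offsets)."""

    def __init__(self, starts: Sequence[int], codes: Sequence[np.ndarray]):
        self.starts = np.asarray(starts, dtype=np.int64)
        self.codes = [np.asarray(c, dtype=np.uint8) for c in codes]
        self.n_reads = len(self.codes)
        self.length = int(max((s + c.size for s, c in zip(self.starts, self.codes)),
                              default=0))

    def base_counts(self, rows: Optional[np.ndarray] = None) -> np.ndarray:
        """(length, 5) counts of A,C,G,T,'-' per column over given rows."""
        counts = np.zeros((self.length, 5), dtype=np.int32)
        rows_iter = range(self.n_reads) if rows is None else np.nonzero(rows)[0]
        for i in rows_iter:
            c = self.codes[i]
            s = int(self.starts[i])
            ok = c <= GAP_CODE
            pos = np.nonzero(ok)[0]
            counts[s + pos, c[pos]] += 1
        return counts


def _as_group(group) -> _Group:
    if isinstance(group, _Group):
        return group
    # duck-typed AlignedReadGroup / list of SimRead-like objects
    reads = getattr(group, "reads", group)
    return _Group([r.start for r in reads], [r.codes for r in reads])


def identify_variant_columns(group, min_state_reads: int = 2) -> List[VariantColumn]:
    """Call variant columns: positions with >=2 states each seen in
    >= ``min_state_reads`` reads.

    A state seen in fewer reads is indistinguishable from sequencing error
    and does not count toward the two-state requirement.  Columns where any
    read shows a gap character are excluded (indel regions are excised from
    analysis rather than phased).
    """
    g = _as_group(group)
    if g.n_reads == 0:
        return []
    counts = g.base_counts()
    qualifying = (counts[:, :4] >= min_state_reads).sum(axis=1)
    has_gap = counts[:, GAP_CODE] > 0
    positions = np.nonzero((qualifying >= 2) & ~has_gap)[0]
    cols = []
    for p in positions:
        sc = {b: int(counts[p, b]) for b in range(4)
              if counts[p, b] >= min_state_reads}
        cols.append(VariantColumn(position=int(p), state_counts=sc))
    return cols


def _read_state_matrix(g: _Group, columns: Sequence[VariantColumn]) -> np.ndarray:
    """(n_reads, k) base code per read per variant column; 255 = not covered."""
    k = len(columns)
    rs = np.full((g.n_reads, k), MISSING, dtype=np.uint8)
    pos = np.array([c.position for c in columns], dtype=np.int64)
    for i in range(g.n_reads):
        s = int(g.starts[i])
        e = s + g.codes[i].size
        j = np.nonzero((pos >= s) & (pos < e))[0]
        if j.size:
            vals = g.codes[i][pos[j] - s]
            vals = np.where(vals < 4, vals, MISSING).astype(np.uint8)
            rs[i, j] = vals
    return rs


def _consistent_rows(rs: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """Reads that cover >=1 column and agree with ``vec`` everywhere covered."""
    covered = rs != MISSING
    agree = (~covered) | (rs == vec[None, :])
    return agree.all(axis=1) & covered.any(axis=1)


def _realizable(rs: np.ndarray, vec: np.ndarray) -> Tuple[bool, int, np.ndarray]:
    """Exact read-chain realizability of a full state vector.

    The vector is realizable when its consistent reads cover every variant
    column and every adjacent column pair is co-covered by at least one
    consistent read (reads span contiguous position ranges, so adjacent-pair
    linkage implies a connected chain).
    """
    rows = _consistent_rows(rs, vec)
    if not rows.any():
        return False, 0, rows
    cov = rs[rows] != MISSING
    if not cov.any(axis=0).all():
        return False, 0, rows
    k = rs.shape[1]
    for j in range(k - 1):
        if not (cov[:, j] & cov[:, j + 1]).any():
            return False, 0, rows
    return True, int(rows.sum()), rows


def reconstruct_alleles(group, columns: Sequence[VariantColumn],
                        max_candidates: int = 64,
                        ) -> Tuple[List[CandidateAllele], bool]:
    """Enumerate every candidate allele realizable as a chain of consistent
    overlapping reads.

    Returns ``(candidates, ambiguous)``.  ``ambiguous`` is True when the
    variant columns are not connected by overlapping reads (phase across
    the gap cannot be resolved from reads alone) or when the enumeration
    exceeds ``max_candidates`` — both cases leave the group uncallable.
    Candidates are ordered by descending support.  Consensus sequences are
    rendered later, for filter survivors only (see :func:`phase_read_group`).
    """
    g = _as_group(group)
    if g.n_reads == 0:
        return [], False
    k = len(columns)
    if k == 0:
        cand = CandidateAllele(states=(), support=g.n_reads, fraction=1.0)
        return [cand], False

    rs = _read_state_matrix(g, columns)
    covered = rs != MISSING
    for j in range(k - 1):
        if not (covered[:, j] & covered[:, j + 1]).any():
            return [], True  # disconnected linkage graph

    allowed = [np.array(c.states, dtype=np.uint8) for c in columns]
    partials: List[Tuple[int, ...]] = [()]
    for j in range(k):
        nxt: List[Tuple[int, ...]] = []
        for p in partials:
            for s in allowed[j]:
                v = p + (int(s),)
                if j > 0:
                    vec = np.array(v, dtype=np.uint8)
                    rows = covered[:, j] & covered[:, j - 1]
                    sub = rs[rows, : j + 1]
                    ok = (((sub == MISSING) | (sub == vec[None, :]))
                          .all(axis=1).any())
                    if not ok:
                        continue
                nxt.append(v)
        if len(nxt) > 4 * max_candidates:
            return [], True
        partials = nxt

    cands: List[CandidateAllele] = []
    for v in partials:
        vec = np.array(v, dtype=np.uint8)
        ok, support, _rows = _realizable(rs, vec)
        if ok:
            cands.append(CandidateAllele(states=v, support=support,
                                         fraction=support / g.n_reads))
    if len(cands) > max_candidates:
        return [], True
    cands.sort(key=lambda c: (-c.support, c.states))
    return cands, False


def filter_low_support(cands: Sequence[CandidateAllele], total_reads: int,
                       min_fraction: float = 0.05) -> List[CandidateAllele]:
    """Drop candidates supported by strictly less than ``min_fraction`` of
    the group's reads (the low-coverage sequencing-error filter).

    A candidate at exactly the threshold is retained.  Survivors keep
    descending-support order.  An empty result signals a failed locus to
    the caller.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    out = [c for c in cands if c.support / total_reads >= min_fraction]
    out.sort(key=lambda c: (-c.support, c.states))
    return out


def _is_recombinant_of(child: Tuple[int, ...], p: Tuple[int, ...],
                       q: Tuple[int, ...]) -> bool:
    """True if ``child`` is a (possibly multi-breakpoint) mosaic of p and q."""
    if child == p or child == q:
        return False
    return all(c == a or c == b for c, a, b in zip(child, p, q))


def remove_pcr_recombinants(cands: Sequence[CandidateAllele]
                            ) -> List[CandidateAllele]:
    """Iteratively remove candidates identifiable as PCR recombinants.

    While more than two candidates remain, a candidate is identifiable as a
    PCR recombinant when its state vector is expressible, at every variant
    column, as a mosaic of two other remaining candidates (for a triple
    ABCD / abcd / ABcd only ABcd can be written this way) *and* it does not
    out-support either putative parent — chimeras arise in later PCR cycles
    and cannot out-amplify their template alleles, and without the support
    condition a well-supported true allele can be mistaken for a mosaic of
    the other allele and a rare sequencing-error allele.  The
    lowest-support identifiable candidate is removed first; removal stops
    when two candidates remain or nothing further is identifiable.
    """
    if not cands:
        raise ValueError("need at least one candidate")
    pool = list(cands)
    while len(pool) > 2:
        removable = []
        for c in pool:
            others = [o for o in pool if o is not c]
            for a in range(len(others)):
                for b in range(a + 1, len(others)):
                    if (c.support <= others[a].support
                            and c.support <= others[b].support
                            and _is_recombinant_of(c.states, others[a].states,
                                                   others[b].states)):
                        removable.append(c)
                        break
                else:
                    continue
                break
        if not removable:
            break
        victim = min(removable, key=lambda c: (c.support, c.states))
        pool = [c for c in pool if c is not victim]
    pool.sort(key=lambda c: (-c.support, c.states))
    return pool


def call_genotype(cands: Sequence[CandidateAllele], individual: str = "ind",
                  locus: str = "locus") -> PhasedGenotype:
    """Call the diploid genotype from filtered candidates.

    One survivor yields a homozygote (sequence duplicated), two a
    heterozygote; zero survivors mean the locus failed and more than two
    mean the group stays ambiguous and is excluded downstream.
    """
    if len(cands) == 1:
        seq = cands[0].sequence
        return PhasedGenotype(individual, locus, "phased", (seq, seq))
    if len(cands) == 2:
        seqs = tuple(sorted(c.sequence for c in cands))
        return PhasedGenotype(individual, locus, "phased", seqs)  # type: ignore[arg-type]
    status = "failed" if len(cands) == 0 else "ambiguous"
    return PhasedGenotype(individual, locus, status, None)


def _render_consensus(g: _Group, rows: np.ndarray,
                      columns: Sequence[VariantColumn],
                      states: Tuple[int, ...]) -> str:
    """Majority-base consensus over supporting reads; variant columns take
    the candidate's states; uncovered positions fall back to the all-read
    majority, then to N."""
    counts = g.base_counts(rows)[:, :4]
    best = counts.argmax(axis=1).astype(np.uint8)
    tot = counts.sum(axis=1)
    top = counts.max(axis=1)
    ties = (counts == top[:, None]).sum(axis=1) > 1
    if (ties & (tot > 0)).any():
        logger.warning("consensus tie at %d position(s); taking the "
                       "alphabetically first base", int((ties & (tot > 0)).sum()))
    seq = best
    uncovered = tot == 0
    if uncovered.any():
        allc = g.base_counts()[:, :4]
        fallback = allc.argmax(axis=1).astype(np.uint8)
        seq = np.where(uncovered & (allc.sum(axis=1) > 0), fallback, seq)
        seq = np.where(uncovered & (allc.sum(axis=1) == 0),
                       np.uint8(MISSING), seq)
    for col, s in zip(columns, states):
        seq[col.position] = s
    return decode(seq)


def phase_read_group(group, individual: str = "ind", locus: str = "locus",
                     min_state_reads: int = 2, min_fraction: float = 0.05,
                     max_candidates: int = 64) -> PhasedGenotype:
    """Run the full phasing chain on one individual-locus read group.

    Steps: variant-column calling, read-chain allele reconstruction, the
    low-support (sequencing error) filter, PCR-recombinant removal, and the
    final diploid call.  Consensus sequences are rendered for the filter
    survivors only.
    """
    g = _as_group(group)
    if g.n_reads == 0:
        return PhasedGenotype(individual, locus, "failed", None)
    columns = identify_variant_columns(g, min_state_reads=min_state_reads)
    cands, ambiguous = reconstruct_alleles(g, columns,
                                           max_candidates=max_candidates)
    if ambiguous:
        return PhasedGenotype(individual, locus, "ambiguous", None)
    cands = filter_low_support(cands, total_reads=g.n_reads,
                               min_fraction=min_fraction)
    if not cands:
        return PhasedGenotype(individual, locus, "failed", None)
    cands = remove_pcr_recombinants(cands)
    if len(cands) <= 2:
        rs = _read_state_matrix(g, columns)
        for c in cands:
            vec = np.array(c.states, dtype=np.uint8)
            rows = (_consistent_rows(rs, vec) if columns
                    else np.ones(g.n_reads, dtype=bool))
            c._sequence = _render_consensus(g, rows, columns, c.states)
    return call_genotype(cands, individual=individual, locus=locus)


def phase_study(study, **kwargs) -> Dict[Tuple[str, str], PhasedGenotype]:
    """Phase every individual-locus read group of a simulated or loaded study.

    ``study`` needs ``individuals``, ``loci`` and a ``reads`` mapping
    ``(individual, locus) -> reads``; missing groups are reported as failed.
    """
    out: Dict[Tuple[str, str], PhasedGenotype] = {}
    for ind in study.individuals:
        for locus in study.loci:
            reads = study.reads.get((ind, locus), [])
            out[(ind, locus)] = phase_read_group(reads, individual=ind,
                                                 locus=locus, **kwargs)
    return out
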