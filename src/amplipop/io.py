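"""File formats and read sorting for the amplicon pipeline.

Demultiplexes individually barcoded reads, sorts reads to loci by primer
match, and reads/writes the formats the pipeline touches: FASTA/FASTQ
reads, per-locus FASTA alignments, EIGENSTRAT (geno/snp/ind), a
Structure-style haplotype-number genotype table, and the multi-locus
sequence input consumed by IM coalescent samplers.  All writers round-trip.

Internal coordinates are 0-based and half-open; read offsets on the locus
coordinate system travel in the FASTA/FASTQ description as ``offset=N``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import decode, encode, revcomp
from .popstruct import (MISSING_GENOTYPE, HaplotypeGenotypeTable,
                        SNPGenotypeMatrix)

logger = logging.getLogger(__name__)

__all__ = [
    "Read",
    "AlignedReadGroup",
    "BarcodeTable",
    "PrimerTable",
    "Alignment",
    "read_fasta_reads",
    "read_fastq_reads",
    "write_reads",
    "demultiplex",
    "sort_by_locus",
    "tag_reads",
    "write_eigenstrat",
    "read_eigenstrat",
    "write_structure_genotypes",
    "read_structure_genotypes",
    "write_ima_input",
    "read_ima_input",
    "make_barcode_table",
    "make_primer_table",
]


@dataclass
class Read:
    """A sequencing read; ``start`` is its 0-based offset on the locus."""

    id: str
    sequence: str
    start: int = 0

    @property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignedReadGroup:
    """All reads of one (individual, locus) pair on locus coordinates."""

    individual: str
    locus: str
    reads: List[Read] = field(default_factory=list)

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def _parse_offset(description: str) -> int:
    for token in description.split():
        if token.startswith("offset="):
            return int(token.split("=", 1)[1])
    return 0


def read_fasta_reads(path) -> List[Read]:
    return [Read(id=r.id, sequence=str(r.seq).upper(),
                 start=_parse_offset(r.description))
            for r in SeqIO.parse(str(path), "fasta")]


def read_fastq_reads(path) -> List[Read]:
    return [Read(id=r.id, sequence=str(r.seq).upper(),
                 start=_parse_offset(r.description))
            for r in SeqIO.parse(str(path), "fastq")]


def write_reads(reads: Iterable[Read], path, fmt: str = "fasta",
                quality: int = 40) -> None:
    """Write reads as FASTA or FASTQ (uniform quality); offsets are kept
    in the description."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description=f"offset={r.start}")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [quality] * len(r.sequence)
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


# ---------------------------------------------------------------------------
# barcode demultiplexing and primer sorting


@dataclass(frozen=True)
class BarcodeTable:
    """Individual id -> barcode sequence; barcodes must be distinct."""

    barcodes: Mapping[str, str]

    def __post_init__(self) -> None:
        vals = list(self.barcodes.values())
        if any(not b for b in vals):
            raise ValueError("barcodes must be non-empty")
        if len(set(vals)) != len(vals):
            raise ValueError("duplicate barcodes in table")

    @classmethod
    def from_tsv(cls, path) -> "BarcodeTable":
        table = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            ind, bc = line.split("\t")[:2]
            table[ind] = bc.upper()
        return cls(table)

    def to_tsv(self, path) -> None:
        Path(path).write_text("".join(f"{i}\t{b}\n"
                                      for i, b in self.barcodes.items()))


@dataclass(frozen=True)
class PrimerTable:
    """Locus id -> (forward primer, reverse primer, length range)."""

    primers: Mapping[str, Tuple[str, str]]
    length_ranges: Mapping[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.primers)) != len(self.primers):
            raise ValueError("duplicate locus ids")

    @classmethod
    def from_tsv(cls, path) -> "PrimerTable":
        primers, ranges = {}, {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            locus, fwd, rev = parts[:3]
            primers[locus] = (fwd.upper(), rev.upper())
            if len(parts) >= 5:
                ranges[locus] = (int(parts[3]), int(parts[4]))
        return cls(primers, ranges)

    def to_tsv(self, path) -> None:
        lines = []
        for locus, (fwd, rev) in self.primers.items():
            lo, hi = self.length_ranges.get(locus, ("", ""))
            lines.append(f"{locus}\t{fwd}\t{rev}\t{lo}\t{hi}\n")
        Path(path).write_text("".join(lines))


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(reads: Sequence[Read], barcodes: BarcodeTable,
                max_mismatch: int = 0
                ) -> Tuple[Dict[str, List[Read]], List[Read]]:
    """Assign reads to individuals by barcode prefix.

    A read is assigned iff exactly one barcode matches its prefix within
    ``max_mismatch``; ambiguous and unmatched reads go to the unassigned
    bin.  Assigned reads are returned with the barcode stripped.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    assigned: Dict[str, List[Read]] = {ind: [] for ind in barcodes.barcodes}
    unassigned: List[Read] = []
    for read in reads:
        hits = []
        for ind, bc in barcodes.barcodes.items():
            if len(read.sequence) >= len(bc) and \
                    _mismatches(read.sequence[:len(bc)], bc) <= max_mismatch:
                hits.append((ind, len(bc)))
        if len(hits) == 1:
            ind, blen = hits[0]
            assigned[ind].append(Read(id=read.id,
                                      sequence=read.sequence[blen:],
                                      start=read.start))
        else:
            unassigned.append(read)
    return assigned, unassigned


def sort_by_locus(reads: Sequence[Read], primers: PrimerTable,
                  max_mismatch: int = 0
                  ) -> Tuple[Dict[str, List[Read]], List[Read]]:
    """Assign reads to loci by primer match.

    A read matches a locus when its prefix matches the forward primer
    (forward orientation) or the reverse primer (reverse orientation;
    such reads are normalized to the forward strand by reverse
    complementation).  Reads matching zero or more than one locus go to
    the unmatched bin.
    """
    out: Dict[str, List[Read]] = {locus: [] for locus in primers.primers}
    unmatched: List[Read] = []
    for read in reads:
        hits: List[Tuple[str, bool]] = []
        for locus, (fwd, rev) in primers.primers.items():
            if len(read.sequence) >= len(fwd) and \
                    _mismatches(read.sequence[:len(fwd)], fwd) <= max_mismatch:
                hits.append((locus, False))
            elif len(read.sequence) >= len(rev) and \
                    _mismatches(read.sequence[:len(rev)], rev) <= max_mismatch:
                hits.append((locus, True))
        if len(hits) == 1:
            locus, reverse = hits[0]
            seq = revcomp(read.sequence) if reverse else read.sequence
            out[locus].append(Read(id=read.id, sequence=seq, start=read.start))
        else:
            unmatched.append(read)
    return out, unmatched


def tag_reads(study, barcodes: BarcodeTable, primers: PrimerTable
              ) -> List[Read]:
    """Render a simulated study as one pooled, tagged read list
    (barcode + forward primer + read sequence), as produced by a barcoded
    amplicon sequencing run before any sorting."""
    pooled: List[Read] = []
    for (ind, locus), reads in study.reads.items():
        bc = barcodes.barcodes[ind]
        fwd = primers.primers[locus][0]
        for i, r in enumerate(reads):
            pooled.append(Read(id=f"{ind}.{locus}.{i}",
                               sequence=bc + fwd + decode(r.codes),
                               start=r.start))
    return pooled


def make_barcode_table(individuals: Sequence[str], length: int = 8,
                       rng: Optional[np.random.Generator] = None
                       ) -> BarcodeTable:
    """Random distinct barcodes for a set of individuals."""
    if rng is None:
        rng = np.random.default_rng()
    seen, table = set(), {}
    for ind in individuals:
        while True:
            bc = decode(rng.integers(0, 4, size=length).astype(np.uint8))
            if bc not in seen:
                seen.add(bc)
                table[ind] = bc
                break
    return BarcodeTable(table)


def make_primer_table(loci: Sequence[str], length: int = 20,
                      amplicon_range: Tuple[int, int] = (150, 300),
                      rng: Optional[np.random.Generator] = None
                      ) -> PrimerTable:
    """Random distinct primer pairs for a set of loci."""
    if rng is None:
        rng = np.random.default_rng()
    seen, primers = set(), {}
    for locus in loci:
        while True:
            fwd = decode(rng.integers(0, 4, size=length).astype(np.uint8))
            rev = decode(rng.integers(0, 4, size=length).astype(np.uint8))
            if fwd not in seen and rev not in seen and fwd != rev:
                seen.update((fwd, rev))
                primers[locus] = (fwd, rev)
                break
    return PrimerTable(primers, {locus: amplicon_range for locus in loci})


# ---------------------------------------------------------------------------
# alignments


@dataclass
class Alignment:
    """An aligned set of equal-length sequences (uint8 code matrix)."""

    ids: List[str]
    codes: np.ndarray  # (n, L) uint8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or len(self.ids) != self.codes.shape[0]:
            raise ValueError("ids and matrix rows must correspond")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return int(self.codes.shape[1])

    def sequence(self, i: int) -> str:
        return decode(self.codes[i])

    @classmethod
    def from_sequences(cls, ids: Sequence[str],
                       seqs: Sequence[str]) -> "Alignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        mat = (np.stack([encode(s) for s in seqs]) if seqs
               else np.zeros((0, 0), dtype=np.uint8))
        return cls(ids=list(ids), codes=mat)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        recs = list(SeqIO.parse(str(path), "fasta"))
        return cls.from_sequences([r.id for r in recs],
                                  [str(r.seq).upper() for r in recs])

    def to_fasta(self, path) -> None:
        recs = [SeqRecord(Seq(self.sequence(i)), id=self.ids[i], description="")
                for i in range(self.n)]
        SeqIO.write(recs, str(path), "fasta")

    @classmethod
    def from_genotypes(cls, genotypes: Mapping[str, Tuple[str, str]]
                       ) -> "Alignment":
        """Two rows per individual, ids ``<ind>/1`` and ``<ind>/2``."""
        ids, seqs = [], []
        for ind in genotypes:
            a1, a2 = genotypes[ind]
            ids.extend([f"{ind}/1", f"{ind}/2"])
            seqs.extend([a1 if isinstance(a1, str) else decode(a1),
                         a2 if isinstance(a2, str) else decode(a2)])
        return cls.from_sequences(ids, seqs)


# ---------------------------------------------------------------------------
# EIGENSTRAT


def write_eigenstrat(matrix: SNPGenotypeMatrix, prefix) -> Tuple[Path, Path, Path]:
    """Write the genotype matrix as an EIGENSTRAT trio.

    ``<prefix>.geno`` has one row per SNP and one character per individual
    (minor-allele dosage, 9 = missing); ``<prefix>.snp`` assigns every
    locus a distinct "chromosome" label; ``<prefix>.ind`` lists individuals
    with their population label.
    """
    prefix = Path(prefix)
    geno_path = prefix.with_suffix(".geno")
    snp_path = prefix.with_suffix(".snp")
    ind_path = prefix.with_suffix(".ind")

    G = matrix.genotypes
    rows = []
    for j in range(matrix.n_sites):
        col = G[:, j]
        rows.append("".join("9" if g < 0 else str(int(g)) for g in col))
    geno_path.write_text("".join(r + "\n" for r in rows))

    chrom_of = {locus: i + 1 for i, locus in
                enumerate(dict.fromkeys(matrix.snp_locus))}
    with snp_path.open("w") as fh:
        for j in range(matrix.n_sites):
            locus = matrix.snp_locus[j]
            alleles = (matrix.snp_alleles[j] if matrix.snp_alleles
                       else ("A", "C"))
            fh.write(f"{locus}_{int(matrix.snp_position[j])}\t"
                     f"{chrom_of[locus]}\t0.0\t{int(matrix.snp_position[j])}\t"
                     f"{alleles[1]}\t{alleles[0]}\n")
    with ind_path.open("w") as fh:
        for ind, pop in zip(matrix.individuals, matrix.populations):
            fh.write(f"{ind}\tU\t{pop}\n")
    return geno_path, snp_path, ind_path


def read_eigenstrat(prefix) -> SNPGenotypeMatrix:
    """Read an EIGENSTRAT trio back into a :class:`SNPGenotypeMatrix`."""
    prefix = Path(prefix)
    geno_lines = prefix.with_suffix(".geno").read_text().splitlines()
    snp_lines = prefix.with_suffix(".snp").read_text().splitlines()
    ind_lines = prefix.with_suffix(".ind").read_text().splitlines()

    individuals, populations = [], []
    for line in ind_lines:
        ind, _gender, pop = line.split("\t")
        individuals.append(ind)
        populations.append(pop)
    snp_locus, snp_pos, snp_alleles = [], [], []
    for line in snp_lines:
        snpid, _chrom, _gpos, ppos, minor, major = line.split("\t")
        snp_locus.append(snpid.rsplit("_", 1)[0])
        snp_pos.append(int(ppos))
        snp_alleles.append((major, minor))
    geno = np.full((len(individuals), len(geno_lines)), -1, dtype=np.int8)
    for j, row in enumerate(geno_lines):
        vals = np.frombuffer(row.encode(), dtype=np.uint8) - ord("0")
        geno[:, j] = np.where(vals == 9, -1, vals).astype(np.int8)
    return SNPGenotypeMatrix(genotypes=geno, individuals=individuals,
                             populations=populations, snp_locus=snp_locus,
                             snp_position=np.array(snp_pos, dtype=np.int64),
                             snp_alleles=snp_alleles)


# ---------------------------------------------------------------------------
# Structure-format haplotype-number genotypes


def write_structure_genotypes(table: HaplotypeGenotypeTable, path,
                              populations: Optional[Mapping[str, object]] = None
                              ) -> None:
    """Write haplotype-number genotypes in Structure's two-rows-per-
    individual layout; missing loci are coded -9."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["individual", "population"] + table.loci) + "\n")
        for ind in table.individuals:
            pop = populations.get(ind, 1) if populations else 1
            g = [table.genotype(locus, ind) for locus in table.loci]
            for slot in (0, 1):
                vals = "\t".join(str(pair[slot]) for pair in g)
                fh.write(f"{ind}\t{pop}\t{vals}\n")


def read_structure_genotypes(path) -> HaplotypeGenotypeTable:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    loci = header[2:]
    genotypes: Dict[str, Dict[str, List[int]]] = {locus: {} for locus in loci}
    individuals: List[str] = []
    for line in lines[1:]:
        parts = line.split("\t")
        ind = parts[0]
        if ind not in individuals:
            individuals.append(ind)
        for locus, val in zip(loci, parts[2:]):
            genotypes[locus].setdefault(ind, []).append(int(val))
    out: Dict[str, Dict[str, Tuple[int, int]]] = {}
    for locus in loci:
        out[locus] = {}
        for ind, pair in genotypes[locus].items():
            if tuple(pair) != (MISSING_GENOTYPE, MISSING_GENOTYPE):
                out[locus][ind] = (pair[0], pair[1])
    return HaplotypeGenotypeTable(loci=loci, individuals=individuals,
                                  genotypes=out, haplotypes={l: {} for l in loci})


# ---------------------------------------------------------------------------
# IM sampler input


def write_ima_input(alignments: Mapping[str, Alignment],
                    populations: Mapping[str, object], path,
                    pop_names: Tuple[str, str] = ("pop1", "pop2"),
                    inheritance: float = 1.0,
                    title: str = "amplipop multilocus export") -> None:
    """Write per-locus alignments in the multi-locus IM sampler layout.

    Sequence ids must look like ``<individual>/<slot>`` or equal the
    individual id; every individual must carry a population assignment and
    sequences may not contain gaps.  Within each locus, population-1
    sequences are written before population-2 sequences.
    """
    path = Path(path)
    pops = sorted(set(populations.values()), key=str)
    if len(pops) != 2:
        raise ValueError("IM input needs exactly two populations")
    lines = [title, "2", f"{pop_names[0]} {pop_names[1]}", "(0,1):2",
             str(len(alignments))]
    for locus in alignments:
        aln = alignments[locus]
        groups: Dict[object, List[int]] = {p: [] for p in pops}
        for i, sid in enumerate(aln.ids):
            ind = sid.split("/")[0]
            if ind not in populations:
                raise ValueError(f"individual {ind} has no population "
                                 f"assignment (locus {locus})")
            groups[populations[ind]].append(i)
        seqs = []
        for p in pops:
            for i in groups[p]:
                s = aln.sequence(i)
                if "-" in s:
                    raise ValueError(
                        f"gap character in {aln.ids[i]} at locus {locus}; "
                        "IM input must be gap-free")
                seqs.append((aln.ids[i], s))
        n1, n2 = len(groups[pops[0]]), len(groups[pops[1]])
        lines.append(f"{locus} {n1} {n2} {aln.length} I {inheritance}")
        for sid, s in seqs:
            name = sid.replace("/", "_")[:10].ljust(10)
            lines.append(name + s)
    path.write_text("".join(l + "\n" for l in lines))


def read_ima_input(path) -> Dict[str, Alignment]:
    """Parse an IM-format multilocus file back to per-locus alignments
    (used for round-trip checks)."""
    lines = Path(path).read_text().splitlines()
    n_loci = int(lines[4])
    out: Dict[str, Alignment] = {}
    i = 5
    for _ in range(n_loci):
        name, n1, n2, length = lines[i].split()[:4]
        n1, n2, length = int(n1), int(n2), int(length)
        i += 1
        ids, seqs = [], []
        for _ in range(n1 + n2):
            ids.append(lines[i][:10].strip())
            seqs.append(lines[i][10:10 + length])
            i += 1
        out[name] = Alignment.from_sequences(ids, seqs)
    return out
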