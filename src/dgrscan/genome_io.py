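"""Sequence I/O, ORF calling, translation and pairwise identity.

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive (GenBank convention). The default genetic code is the
bacterial/plastid table 11, appropriate for gut phages and their hosts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation

NUCLEOTIDES = set("ACGTN")
START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")  # table 11


class ParseError(ValueError):
    """Raised for malformed sequence files."""


@dataclass
class GenomeRecord:
    """A nucleotide sequence with identifier and topology."""

    id: str
    seq: str
    topology: str = "linear"  # or "circular"
    source: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise ParseError(
                f"record {self.id!r}: characters outside A/C/G/T/N: {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear or circular, got {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlap(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "Interval") -> float:
        ov = self.overlap(other)
        return min(ov / len(self), ov / len(other)) if ov else 0.0


@dataclass
class OrfRecord:
    """An open reading frame with its translation.

    ``start``/``end`` are 0-based half-open on the forward strand; the coding
    sequence is ``seq[start:end]`` reverse-complemented first when strand is
    ``-``.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    protein: str
    label: str = ""

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end, self.strand)

    def __len__(self) -> int:
        return self.end - self.start


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fasta(path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into GenomeRecords.

    Sequences are uppercased and U is mapped to T. A record with an empty
    header or empty sequence, or characters outside A/C/G/T/N, raises
    :class:`ParseError`.
    """
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise ParseError(f"{path}: record {i + 1} has an empty header")
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(GenomeRecord(id=rec.id, seq=str(rec.seq), source=str(path)))
    return records


def write_fasta(records: list[GenomeRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_genbank(path) -> tuple[GenomeRecord, list[OrfRecord]]:
    """Read a GenBank flat file; CDS features become OrfRecords.

    Simple two-segment joins are flattened to their spanning interval; more
    complex compound locations are skipped with a warning. Requires an
    ORIGIN block with sequence.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(rec.seq) == 0:
        raise ParseError(f"{path}: missing or empty ORIGIN block")
    genome = GenomeRecord(id=rec.id or rec.name, seq=str(rec.seq), source=str(path))
    orfs: list[OrfRecord] = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        loc = feat.location
        if isinstance(loc, CompoundLocation) and len(loc.parts) > 2:
            warnings.warn(
                f"{path}: skipping CDS with {len(loc.parts)}-segment location {loc}"
            )
            continue
        strand = "-" if loc.strand == -1 else "+"
        protein = feat.qualifiers.get("translation", [None])[0]
        if protein is None:
            cds = str(feat.extract(rec.seq))
            protein = translate(cds[: len(cds) - len(cds) % 3]).rstrip("*")
        label = feat.qualifiers.get("product", feat.qualifiers.get("gene", [""]))[0]
        orfs.append(
            OrfRecord(
                genome_id=genome.id,
                start=int(loc.start),
                end=int(loc.end),
                strand=strand,
                protein=protein,
                label=label,
            )
        )
    orfs.sort(key=lambda o: (o.start, o.end))
    return genome, orfs


def translate(seq: str, table: int = 11) -> str:
    """Translate a nucleotide sequence; stop codons render as '*'."""
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    return str(Seq(seq).translate(table=table))


def find_orfs(genome: GenomeRecord, min_aa: int) -> list[OrfRecord]:
    """Call ORFs on both strands.

    An ORF runs from the first ATG/GTG/TTG after the previous in-frame stop
    to the next stop codon (table 11) and must encode at least ``min_aa``
    residues. Results are sorted by start coordinate.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    L = genome.length
    orfs: list[OrfRecord] = []
    for strand in "+-":
        seq = genome.seq if strand == "+" else revcomp(genome.seq)
        for frame in range(3):
            pending = None
            for i in range(frame, len(seq) - 2, 3):
                codon = seq[i : i + 3]
                if pending is None and codon in START_CODONS:
                    pending = i
                if codon in STOP_CODONS:
                    if pending is not None and (i - pending) // 3 >= min_aa:
                        s, e = pending, i + 3
                        if strand == "-":
                            s, e = L - e, L - s
                        orfs.append(
                            OrfRecord(
                                genome_id=genome.id,
                                start=s,
                                end=e,
                                strand=strand,
                                protein=translate(seq[pending : i + 3])[:-1],
                            )
                        )
                    pending = None
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def orf_coding_sequence(genome: GenomeRecord, orf: OrfRecord) -> str:
    cds = genome.seq[orf.start : orf.end]
    return revcomp(cds) if orf.strand == "-" else cds


_BLOSUM62 = None


def _protein_aligner() -> PairwiseAligner:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def _nucleotide_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, mode: str = "nucleotide") -> float:
    """Global-alignment identity between two sequences.

    Needleman–Wunsch with +1/−1 (nucleotide) or BLOSUM62 (protein), gap open
    −10 / extend −0.5. Identity is the number of identical columns divided by
    the full alignment length, gap columns included. The input pair is
    ordered canonically before aligning so the value is symmetric.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if mode not in ("nucleotide", "protein"):
        raise ValueError(f"mode must be nucleotide or protein, got {mode!r}")
    a, b = sorted((a.upper(), b.upper()))
    aligner = _nucleotide_aligner() if mode == "nucleotide" else _protein_aligner()
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    ident = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return ident / len(sa)
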