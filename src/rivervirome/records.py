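"""Core record types (reads, contigs, protein databases) and text IO.

FASTA/FASTQ parsing and writing go through Biopython; the thin wrappers
here only adapt to the pipeline's in-memory types and to the structured
taxonomy header dialect used by the synthetic reference databases:

    >record_id|species|family|genome_type|host|gene

NVNR (non-virus non-redundant) records carry a bare identifier and no
viral taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


@dataclass
class Read:
    """One sequencing read with per-base Phred qualities and a library label."""

    read_id: str
    library: str
    seq: str
    qual: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.read_id}: sequence and quality lengths differ "
                f"({len(self.seq)} vs {len(self.qual)})"
            )
        if not set(self.seq) <= VALID_BASES:
            bad = sorted(set(self.seq) - VALID_BASES)
            raise ValueError(f"read {self.read_id}: invalid bases {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Contig:
    """Assembled consensus sequence with member-read provenance."""

    contig_id: str
    library: str
    seq: str
    member_read_ids: list[str] = field(default_factory=list)
    n_reads_mapped: int = 0

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinRecord:
    """A database protein, optionally with viral taxonomy attached."""

    rec_id: str
    seq: str
    species: str | None = None
    family: str | None = None
    genome_type: str | None = None
    host: str | None = None
    gene: str | None = None

    @property
    def is_viral(self) -> bool:
        return self.species is not None

    def header(self) -> str:
        if self.is_viral:
            return "|".join(
                [self.rec_id, self.species, self.family, self.genome_type,
                 self.host, self.gene]
            )
        return self.rec_id


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# FASTQ

def _handle_or_str(path):
    return path if hasattr(path, "write") or hasattr(path, "read") else str(path)


def write_fastq(reads: Iterable[Read], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qual]
        records.append(rec)
    SeqIO.write(records, _handle_or_str(path), "fastq")


def read_fastq(path, library: str) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(
                read_id=rec.id,
                library=library,
                seq=str(rec.seq).upper(),
                qual=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


# ---------------------------------------------------------------------------
# FASTA (protein databases and contigs)

def write_protein_fasta(records: Iterable[ProteinRecord], path) -> None:
    seqs = [SeqRecord(Seq(r.seq), id=r.header(), description="") for r in records]
    SeqIO.write(seqs, _handle_or_str(path), "fasta")


def read_protein_fasta(path) -> list[ProteinRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) == 6:
            out.append(ProteinRecord(parts[0], str(rec.seq), *parts[1:]))
        else:
            out.append(ProteinRecord(rec.id, str(rec.seq)))
    return out


def write_nucleotide_fasta(items: Sequence[tuple[str, str]], path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(seqs, _handle_or_str(path), "fasta")


def read_nucleotide_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
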