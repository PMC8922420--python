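"""Mock community, reference databases, profile HMMs and read simulation.

This module stands in for the sequencer and the public protein
databases.  It generates:

* a mock viral community spanning 17 families (9 dsDNA, 4 ssDNA and 4
  RNA) with gene-dense genomes whose ORFs encode hallmark proteins
  (TerL for tailed phages, MCP for *Microviridae*, NS1 for
  *Parvoviridae*, Rep for CRESS-DNA viruses, RdRp for RNA viruses) plus
  accessory proteins;
* a viral protein database with structured taxonomy headers and a
  non-virus non-redundant (NVNR) database, a configurable fraction of
  which are "decoys" sharing k-mer windows with viral proteins so that
  the competitive false-positive filter has something to do;
* non-viral background genomes encoding the NVNR proteins;
* profile HMMs built from each hallmark gene's members;
* per-library FASTQ read sets with PCR duplicates, linear 3' quality
  decay and residual 3' adapters, with the full ground truth encoded in
  the read headers.

Hallmark proteins within a group descend from a common ancestor peptide
by point substitution, so homology search, HMM rescue and hallmark
phylogenies all see realistic (non-trivial but unambiguous) signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import spawn_rng
from .records import ProteinRecord, Read, reverse_complement

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP_CODONS = ("TAA", "TAG", "TGA")

#: codons per amino acid, standard genetic code
_CODONS: dict[str, list[str]] = {}
from Bio.Data.CodonTable import standard_dna_table as _tab  # noqa: E402

for _codon, _aa in _tab.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()

#: (family, genome_type, host, hallmark gene, hallmark group)
FAMILY_ROSTER: list[tuple[str, str, str, str, str | None]] = [
    ("Siphoviridae", "dsDNA", "bacteria", "TerL", "Caudovirales"),
    ("Podoviridae", "dsDNA", "bacteria", "TerL", "Caudovirales"),
    ("Myoviridae", "dsDNA", "bacteria", "TerL", "Caudovirales"),
    ("Herelleviridae", "dsDNA", "bacteria", "TerL", "Caudovirales"),
    ("Ackermannviridae", "dsDNA", "bacteria", "TerL", "Caudovirales"),
    ("Autographiviridae", "dsDNA", "bacteria", "TerL", "Caudovirales"),
    ("Phycodnaviridae", "dsDNA", "algae", "other", None),
    ("Mimiviridae", "dsDNA", "protist", "other", None),
    ("Lavidaviridae", "dsDNA", "protist", "other", None),
    ("Microviridae", "ssDNA", "bacteria", "MCP", "Microviridae"),
    ("Parvoviridae", "ssDNA", "invertebrate", "NS1", "Parvoviridae"),
    ("Circoviridae", "ssDNA", "vertebrate", "Rep", "CRESS-DNA"),
    ("Genomoviridae", "ssDNA", "vertebrate", "Rep", "CRESS-DNA"),
    ("Astroviridae", "RNA", "vertebrate", "RdRp", "Riboviria"),
    ("Hepeviridae", "RNA", "vertebrate", "RdRp", "Riboviria"),
    ("Dicistroviridae", "RNA", "invertebrate", "RdRp", "Riboviria"),
    ("Virgaviridae", "RNA", "plant", "RdRp", "Riboviria"),
]

#: ancestor peptide length per hallmark gene (amino acids)
HALLMARK_LENGTHS = {"TerL": 180, "MCP": 150, "NS1": 160, "Rep": 140, "RdRp": 170}

#: hallmark gene -> virus group it places phylogenetically
HALLMARK_GROUPS = {
    "MCP": "Microviridae",
    "NS1": "Parvoviridae",
    "Rep": "CRESS-DNA",
    "TerL": "Caudovirales",
    "RdRp": "Riboviria",
}

#: divergence of each taxon's hallmark from the group ancestor
HALLMARK_DIVERGENCE = 0.25

GENOME_LENGTH = 4000
N_ACCESSORY_ORFS = 6
SPACER_LENGTH = 30


@dataclass
class MockTaxon:
    """One mock viral species with its genome and encoded proteins."""

    species_name: str
    family: str
    genome_type: str
    host_group: str
    genome_seq: str
    proteins: list[tuple[str, str]]  # (gene_name, peptide)
    orf_coords: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.genome_seq) < 1000:
            raise ValueError(f"{self.species_name}: genome shorter than 1,000 nt")


@dataclass
class CommunityDesign:
    """Per-library simulation recipe (one library label)."""

    library_label: str
    abundance: dict[str, float]  # species -> weight
    non_viral_fraction: float = 0.35
    n_reads: int = 10_000
    duplicate_rate: float = 0.2
    adapter_seq: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
    adapter_fraction: float = 0.05
    quality_start: int = 38
    quality_end: int = 8
    read_length: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.abundance and sum(self.abundance.values()) <= 0:
            raise ValueError("abundance weights must sum > 0")
        if not 0.0 <= self.non_viral_fraction <= 1.0:
            raise ValueError("non_viral_fraction must be in [0,1]")


def random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_peptide(pep: str, rate: float, rng: np.random.Generator) -> str:
    """Point-substitute each residue with probability ``rate``."""
    out = []
    for aa in pep:
        if rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != aa]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def random_nucleotides(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def encode_orf(pep: str, rng: np.random.Generator) -> str:
    """ATG + random synonymous codons + a stop codon."""
    codons = ["ATG"]
    for aa in pep:
        opts = _CODONS[aa]
        codons.append(opts[rng.integers(len(opts))])
    codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return "".join(codons)


def _assemble_genome(orfs: list[tuple[str, str]], rng: np.random.Generator,
                     target_len: int) -> tuple[str, list[tuple[str, int, int, str]]]:
    """Concatenate ORFs with random spacers; returns genome and coordinates.

    The peptide itself is re-encoded here, so the caller passes
    (gene_name, nucleotide ORF).  Genomes are gene-dense by design so
    that nearly every >=500 nt window overlaps coding sequence.
    """
    parts: list[str] = []
    coords: list[tuple[str, int, int, str]] = []
    pos = 0
    for gene, orf_nt in orfs:
        spacer = random_nucleotides(rng, SPACER_LENGTH)
        parts.append(spacer)
        pos += len(spacer)
        coords.append((gene, pos, pos + len(orf_nt), "+"))
        parts.append(orf_nt)
        pos += len(orf_nt)
    tail = max(target_len - pos, SPACER_LENGTH)
    parts.append(random_nucleotides(rng, tail))
    return "".join(parts), coords


def _hallmark_ancestors(seed: int) -> dict[str, str]:
    rng = spawn_rng(seed, "hallmark-ancestors")
    return {g: random_peptide(rng, n) for g, n in sorted(HALLMARK_LENGTHS.items())}


def build_mock_community(n_viral_taxa: int, seed: int,
                         hallmark_divergence: float = HALLMARK_DIVERGENCE,
                         ) -> list[MockTaxon]:
    """Generate ``n_viral_taxa`` mock species cycling through the roster.

    With n <= 17 every taxon gets a distinct family, so the distinct
    family count equals n; beyond 17 families gain extra species.
    """
    if n_viral_taxa < 1:
        raise ValueError("n_viral_taxa must be >= 1")
    ancestors = _hallmark_ancestors(seed)
    taxa = []
    for i in range(n_viral_taxa):
        family, gtype, host, hallmark, _group = FAMILY_ROSTER[i % len(FAMILY_ROSTER)]
        rng = spawn_rng(seed, "taxon", i)
        species = f"{family[:-4]} virus {i + 1}"  # e.g. 'Siphovir virus 1'
        species = species.replace(" ", "_")
        proteins: list[tuple[str, str]] = []
        if hallmark != "other":
            pep = mutate_peptide(ancestors[hallmark], hallmark_divergence, rng)
            proteins.append((hallmark, pep))
        n_acc = N_ACCESSORY_ORFS + (1 if hallmark == "other" else 0)
        for a in range(n_acc):
            length = int(rng.integers(140, 210))
            proteins.append(("other", random_peptide(rng, length)))
        orfs = [(g, encode_orf(p, rng)) for g, p in proteins]
        genome, coords = _assemble_genome(orfs, rng, GENOME_LENGTH)
        taxa.append(
            MockTaxon(
                species_name=species,
                family=family,
                genome_type=gtype,
                host_group=host,
                genome_seq=genome,
                proteins=proteins,
                orf_coords=coords,
            )
        )
    return taxa


def _make_decoy(viral_pep: str, rng: np.random.Generator,
                keep: int = 14, scramble: int = 14) -> str:
    """Mosaic of a viral protein: alternating kept and randomized windows.

    Keeps exact k-mer windows of the viral protein (so translated search
    finds the decoy's reads in the viral DB) while the NVNR self-match
    stays far stronger.
    """
    out = []
    i = 0
    while i < len(viral_pep):
        out.append(viral_pep[i:i + keep])
        i += keep
        n_scr = max(0, min(scramble, len(viral_pep) - i))
        if n_scr:
            out.append(random_peptide(rng, n_scr))
        i += n_scr
    return "".join(out)


def reference_sets_from_taxa(
    taxa: list[MockTaxon], n_nvnr_proteins: int, seed: int,
    decoy_fraction: float = 0.2,
) -> tuple[list[ProteinRecord], list[ProteinRecord], pd.DataFrame]:
    """Viral DB, NVNR DB and truth table from an existing community."""
    if n_nvnr_proteins < 0:
        raise ValueError("n_nvnr_proteins must be >= 0")
    viral_records: list[ProteinRecord] = []
    rows = []
    for t in taxa:
        for k, (gene, pep) in enumerate(t.proteins):
            rec_id = f"VP_{t.species_name}_{k:02d}"
            viral_records.append(
                ProteinRecord(rec_id, pep, species=t.species_name,
                              family=t.family, genome_type=t.genome_type,
                              host=t.host_group, gene=gene)
            )
            rows.append({"record_id": rec_id, "kind": "viral",
                         "species": t.species_name, "family": t.family,
                         "genome_type": t.genome_type, "host": t.host_group,
                         "gene": gene, "decoy_source": ""})
    rng = spawn_rng(seed, "nvnr")
    n_decoys = int(round(decoy_fraction * n_nvnr_proteins))
    viral_peps = [(r.rec_id, r.seq) for r in viral_records]
    nvnr_records: list[ProteinRecord] = []
    for i in range(n_nvnr_proteins):
        rec_id = f"NVNR_{i:04d}"
        if i < n_decoys and viral_peps:
            src_id, src_pep = viral_peps[int(rng.integers(len(viral_peps)))]
            pep = _make_decoy(src_pep, rng)
            rows.append({"record_id": rec_id, "kind": "decoy", "species": "",
                         "family": "", "genome_type": "", "host": "",
                         "gene": "", "decoy_source": src_id})
        else:
            pep = random_peptide(rng, int(rng.integers(150, 260)))
            rows.append({"record_id": rec_id, "kind": "nvnr", "species": "",
                         "family": "", "genome_type": "", "host": "",
                         "gene": "", "decoy_source": ""})
        nvnr_records.append(ProteinRecord(rec_id, pep))
    truth = pd.DataFrame(rows)
    return viral_records, nvnr_records, truth


def generate_reference_sets(
    n_viral_taxa: int, n_nvnr_proteins: int, seed: int,
    decoy_fraction: float = 0.2,
) -> tuple[list[ProteinRecord], list[ProteinRecord], pd.DataFrame]:
    """One-call generation of viral DB, NVNR DB and truth table."""
    taxa = build_mock_community(n_viral_taxa, seed)
    return reference_sets_from_taxa(taxa, n_nvnr_proteins, seed,
                                    decoy_fraction=decoy_fraction)


@dataclass
class BackgroundGenome:
    """Non-viral (bacterial/host) genome encoding NVNR proteins."""

    name: str
    seq: str
    is_decoy_genome: bool
    member_records: list[str]


def build_background_genomes(
    nvnr_records: list[ProteinRecord], truth: pd.DataFrame, seed: int,
    proteins_per_genome: int = 10,
) -> list[BackgroundGenome]:
    """Pack NVNR proteins into gene-dense genomes.

    Decoy proteins are segregated into their own genome(s) so that
    "decoy contigs" are well defined for specificity checks.
    """
    kind = dict(zip(truth["record_id"], truth["kind"]))
    decoys = [r for r in nvnr_records if kind.get(r.rec_id) == "decoy"]
    plains = [r for r in nvnr_records if kind.get(r.rec_id) == "nvnr"]
    genomes: list[BackgroundGenome] = []

    def pack(records: list[ProteinRecord], tag: str, is_decoy: bool) -> None:
        for g, start in enumerate(range(0, len(records), proteins_per_genome)):
            chunk = records[start:start + proteins_per_genome]
            rng = spawn_rng(seed, "background", tag, g)
            orfs = [("other", encode_orf(r.seq, rng)) for r in chunk]
            genome, _ = _assemble_genome(orfs, rng, 0)
            genomes.append(
                BackgroundGenome(
                    name=f"bg_{tag}_{g}",
                    seq=genome,
                    is_decoy_genome=is_decoy,
                    member_records=[r.rec_id for r in chunk],
                )
            )

    pack(decoys, "decoy", True)
    pack(plains, "plain", False)
    return genomes


def build_hallmark_hmms(taxa: list[MockTaxon], seed: int):
    """Profile HMMs, one per hallmark gene with >= 2 member peptides.

    Members of a hallmark gene descend from one ancestor by substitution
    only, so they form a trivially aligned (gap-free) training set.
    """
    from .phmm import ProfileHMM

    by_gene: dict[str, list[str]] = {}
    for t in taxa:
        for gene, pep in t.proteins:
            if gene in HALLMARK_GROUPS:
                by_gene.setdefault(gene, []).append(pep)
    hmms = []
    for gene in sorted(by_gene):
        peps = by_gene[gene]
        hmms.append(ProfileHMM.from_aligned(gene, peps))
    return hmms


def simulate_library(
    design: CommunityDesign,
    taxa: list[MockTaxon],
    background: list[BackgroundGenome] | None = None,
) -> list[Read]:
    """Emit FASTQ-ready reads for one library with ground-truth headers.

    Header fields (| separated): running id, lib, src (species or
    background genome), pos, strand, dup (source read index or '.'),
    ad (1 if the 3' adapter is present).  Duplicates are exact
    re-emissions of an earlier read's sequence and qualities.
    """
    if not taxa and design.non_viral_fraction < 1.0 and design.n_reads > 0:
        raise ValueError("empty taxa list requires non_viral_fraction == 1")
    background = background or []
    if design.n_reads == 0:
        return []
    if design.non_viral_fraction > 0 and not background:
        raise ValueError("non_viral_fraction > 0 requires background genomes")
    rng = spawn_rng(design.seed, "simulate", design.library_label)
    species = sorted(design.abundance)
    weights = np.array([design.abundance[s] for s in species], dtype=float)
    if weights.size:
        weights = weights / weights.sum()
    genome_of = {t.species_name: t.genome_seq for t in taxa}
    bg_weights = np.array([len(b.seq) for b in background], dtype=float)
    if bg_weights.size:
        bg_weights = bg_weights / bg_weights.sum()
    L = design.read_length
    n_qual = np.round(np.linspace(design.quality_start, design.quality_end, L)
                      ).astype(int)
    reads: list[Read] = []
    truth: list[tuple] = []  # parallel provenance to build headers
    for i in range(design.n_reads):
        if reads and rng.random() < design.duplicate_rate:
            j = int(rng.integers(len(reads)))
            src, pos, strand, ad = truth[j]
            rid = f"r{i:06d}|{design.library_label}|{src}|{pos}|{strand}|{j}|{ad}"
            reads.append(Read(rid, design.library_label, reads[j].seq,
                              list(reads[j].qual)))
            truth.append((src, pos, strand, ad))
            continue
        if species and rng.random() >= design.non_viral_fraction:
            sp = species[int(rng.choice(len(species), p=weights))]
            genome = genome_of[sp]
            src = sp
        else:
            b = background[int(rng.choice(len(background), p=bg_weights))]
            genome = b.seq
            src = b.name
        has_adapter = rng.random() < design.adapter_fraction
        if has_adapter:
            insert_len = int(rng.integers(L - len(design.adapter_seq), L - 9))
        else:
            insert_len = L
        insert_len = min(insert_len, len(genome))
        pos = int(rng.integers(0, len(genome) - insert_len + 1))
        frag = genome[pos:pos + insert_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = reverse_complement(frag)
        seq = (frag + design.adapter_seq)[:L] if has_adapter else frag
        qual = list(n_qual[: len(seq)])
        ad = 1 if has_adapter else 0
        rid = f"r{i:06d}|{design.library_label}|{src}|{pos}|{strand}|.|{ad}"
        reads.append(Read(rid, design.library_label, seq, qual))
        truth.append((src, pos, strand, ad))
    return reads


def parse_read_header(read_id: str) -> dict:
    """Recover the ground truth encoded by :func:`simulate_library`."""
    rid, lib, src, pos, strand, dup, ad = read_id.split("|")
    return {
        "id": rid,
        "library": lib,
        "source": src,
        "pos": int(pos),
        "strand": strand,
        "duplicate_of": None if dup == "." else int(dup),
        "adapter": ad == "1",
    }
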