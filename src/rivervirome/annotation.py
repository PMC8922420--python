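"""Contig extension/merging, ORF prediction and hallmark-gene extraction.

ORFs are predicted on both strands in all frames with the standard
genetic code, ATG start codons and a minimum size of 300 nt (stop codon
included in the span, excluded from the peptide).  Nested ORFs sharing
a stop report only the longest (first ATG).  Open-ended ORFs at contig
edges — a missing stop at the 3' edge, or a 5'-truncated frame segment
with no upstream stop — are reported with ``complete=False``.

Predicted peptides are annotated against the viral protein database;
ORFs whose best hit is a hallmark gene (MCP, NS1, Rep, TerL, RdRp) are
collected into per-gene hallmark sets for phylogenetic analysis, where
only complete ORFs are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .homology import Hit, ProteinDatabase, protein_search
from .records import Contig
from .scoring import ScoringScheme
from .synthetic import HALLMARK_GROUPS

MERGE_SPACER = "N" * 100


@dataclass
class OrfRecord:
    contig_id: str
    strand: str  # '+' or '-'
    frame: int
    start: int  # 0-based half-open on the forward strand
    end: int
    peptide: str
    annotation: str = "putative protein"
    gene_name: str | None = None
    e_value: float | None = None
    complete: bool = True

    @property
    def orf_id(self) -> str:
        return f"{self.contig_id}|{self.start}-{self.end}({self.strand})"


@dataclass
class HallmarkSet:
    gene: str
    group: str
    members: list[tuple[str, str, bool]] = field(default_factory=list)
    # (orf_id, peptide, complete)


def _orfs_in_frame(seq: str, offset: int, min_size: int
                   ) -> list[tuple[int, int, str, bool]]:
    """(start, end, peptide, complete) in one forward frame.

    Coordinates are on the given sequence; ``end`` includes the stop
    codon when present.
    """
    codons = [(i, seq[i:i + 3]) for i in range(offset, len(seq) - 2, 3)]
    out = []
    start = None
    region_start_is_edge = True  # no stop seen yet in this frame
    region_first = offset
    for pos, codon in codons:
        if codon in ("TAA", "TAG", "TGA"):
            if start is not None:
                span = pos + 3 - start
                if span >= min_size:
                    pep = str(Seq(seq[start:pos]).translate())
                    out.append((start, pos + 3, pep, True))
            elif region_start_is_edge:
                # 5'-truncated: frame runs from the edge into this stop
                span = pos + 3 - region_first
                if span >= min_size:
                    pep = str(Seq(seq[region_first:pos]).translate())
                    out.append((region_first, pos + 3, pep, False))
            start = None
            region_start_is_edge = False
        elif codon == "ATG" and start is None:
            start = pos
    if start is not None:
        # runs off the 3' edge without a stop
        last = codons[-1][0] + 3 if codons else offset
        span = last - start
        if span >= min_size:
            pep = str(Seq(seq[start:last]).translate())
            out.append((start, last, pep, False))
    return out


def predict_orfs(contig: Contig, min_size: int = 300) -> list[OrfRecord]:
    """Both-strand, all-frame ORF prediction (ATG starts, standard code)."""
    seq = contig.seq
    L = len(seq)
    out: list[OrfRecord] = []
    for offset in range(3):
        for s, e, pep, complete in _orfs_in_frame(seq, offset, min_size):
            out.append(OrfRecord(contig.contig_id, "+", offset + 1,
                                 s, e, pep, complete=complete))
    rc = str(Seq(seq).reverse_complement())
    for offset in range(3):
        for s, e, pep, complete in _orfs_in_frame(rc, offset, min_size):
            out.append(OrfRecord(contig.contig_id, "-", -(offset + 1),
                                 L - e, L - s, pep, complete=complete))
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def merge_nonoverlapping_contigs(contigs: list[Contig],
                                 best_hits: dict[str, Hit]) -> list[Contig]:
    """Join contigs hitting disjoint parts of the same subject protein.

    Contigs whose best hits target the same subject with non-overlapping
    subject intervals are concatenated in subject order with a 100-N
    spacer; anything else passes through unchanged.
    """
    by_subject: dict[str, list[Contig]] = {}
    for c in contigs:
        h = best_hits.get(c.contig_id)
        if h is None:
            continue
        by_subject.setdefault(h.subject_id, []).append(c)
    merged_ids: set[str] = set()
    merged: list[Contig] = []
    idx = 0
    for subject in sorted(by_subject):
        group = by_subject[subject]
        if len(group) < 2:
            continue
        group.sort(key=lambda c: (best_hits[c.contig_id].s_start, c.contig_id))
        chain: list[Contig] = []
        last_end = -1
        ok = True
        for c in group:
            h = best_hits[c.contig_id]
            if h.s_start < last_end:
                ok = False
                break
            chain.append(c)
            last_end = h.s_end
        if not ok or len(chain) < 2:
            continue
        seq = MERGE_SPACER.join(c.seq for c in chain)
        members = [rid for c in chain for rid in c.member_read_ids]
        merged.append(
            Contig(
                contig_id=f"merged_{idx:04d}",
                library=chain[0].library,
                seq=seq,
                member_read_ids=members,
                n_reads_mapped=sum(c.n_reads_mapped for c in chain),
            )
        )
        idx += 1
        merged_ids.update(c.contig_id for c in chain)
    passthrough = [c for c in contigs if c.contig_id not in merged_ids]
    return passthrough + merged


def extend_by_mapping(contig: Contig, reads, rounds: int = 2,
                      min_overlap: int = 20,
                      min_identity: float = 0.95) -> Contig:
    """Iteratively extend contig ends with overhanging reads.

    A read whose prefix matches the contig's 3' suffix (or suffix the
    5' prefix, either strand) over >= ``min_overlap`` bases at
    >= ``min_identity`` extends the consensus by its overhang; within a
    round the longest qualifying overhang is applied first.  Stops at a
    fixpoint or after ``rounds`` rounds; the output is never shorter.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    from .records import reverse_complement

    def _mism_ok(a: str, b: str) -> bool:
        limit = (1 - min_identity) * len(a)
        mism = 0
        for x, y in zip(a, b):
            if x != y:
                mism += 1
                if mism > limit:
                    return False
        return True

    seq = contig.seq
    anchor = min_overlap  # junction anchor: exact anchor-mer locates the
    # candidate overlap; the full overlap is then verified with the
    # identity tolerance
    for _ in range(rounds):
        grew = False
        for end in ("right", "left"):
            best_ext = ""
            junction = seq[-anchor:] if end == "right" else seq[:anchor]
            for r in reads:
                for rs in (r.seq, reverse_complement(r.seq)):
                    if len(rs) <= min_overlap:
                        continue
                    p = rs.find(junction)
                    while p != -1:
                        if end == "right":
                            ov = p + anchor
                            if ov <= len(seq) and _mism_ok(seq[-ov:], rs[:ov]):
                                ext = rs[ov:]
                                if len(ext) > len(best_ext):
                                    best_ext = ext
                        else:
                            ov = len(rs) - p
                            if ov <= len(seq) and _mism_ok(rs[p:], seq[:ov]):
                                ext = rs[:p]
                                if len(ext) > len(best_ext):
                                    best_ext = ext
                        p = rs.find(junction, p + 1)
            if best_ext:
                seq = seq + best_ext if end == "right" else best_ext + seq
                grew = True
        if not grew:
            break
    return Contig(contig.contig_id, contig.library, seq,
                  list(contig.member_read_ids), contig.n_reads_mapped)


def annotate_orfs(orfs: list[OrfRecord], viral_db: ProteinDatabase,
                  scheme: ScoringScheme | None = None,
                  e_cutoff: float = 1e-5) -> list[OrfRecord]:
    """Attach each ORF's best peptide-vs-database hit (else putative)."""
    scheme = scheme or ScoringScheme()
    for orf in orfs:
        pep = orf.peptide.rstrip("*")
        if "*" in pep or len(pep) < 4:
            continue
        hits = protein_search(pep, viral_db, scheme, e_cutoff, orf.orf_id)
        if hits:
            best = hits[0]
            orf.annotation = best.subject_id
            orf.gene_name = best.gene
            orf.e_value = best.e_value
    return orfs


def extract_hallmarks(orfs: list[OrfRecord]) -> list[HallmarkSet]:
    """Group hallmark-annotated ORFs by gene; flags completeness."""
    sets: dict[str, HallmarkSet] = {}
    for orf in orfs:
        gene = orf.gene_name
        if gene not in HALLMARK_GROUPS:
            continue
        hs = sets.setdefault(gene, HallmarkSet(gene, HALLMARK_GROUPS[gene]))
        hs.members.append((orf.orf_id, orf.peptide, orf.complete))
    return [sets[g] for g in sorted(sets)]


def annotate_and_extract_hallmarks(
    orfs: list[OrfRecord], viral_db: ProteinDatabase,
    scheme: ScoringScheme | None = None, e_cutoff: float = 1e-5,
) -> list[HallmarkSet]:
    return extract_hallmarks(annotate_orfs(orfs, viral_db, scheme, e_cutoff))


def orfs_to_gff3(orfs: list[OrfRecord]) -> str:
    """GFF3 (1-based inclusive) serialisation of ORF records."""
    lines = ["##gff-version 3"]
    for i, o in enumerate(orfs):
        attrs = f"ID=orf{i:04d};complete={'true' if o.complete else 'false'}"
        if o.gene_name:
            attrs += f";gene={o.gene_name}"
        attrs += f";product={o.annotation.replace(';', ',')}"
        lines.append(
            "\t".join([
                o.contig_id, "rivervirome", "CDS", str(o.start + 1),
                str(o.end), ".", o.strand, "0", attrs,
            ])
        )
    return "\n".join(lines) + "\n"
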