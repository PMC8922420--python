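"""Translated homology classification with competitive false-positive
filtering and profile-HMM rescue.

The classifier mirrors a BLASTx-style workflow: each query nucleotide
sequence is translated in six frames, 4-mer exact amino-acid seeds are
located in the database index, extended ungapped with X-drop pruning,
and promising extensions are re-aligned by banded Smith-Waterman.  The
best local score S per (query, subject) yields the Karlin-Altschul
E-value  E = K * m * n * exp(-lambda*S)  with m the query peptide
length of the scoring frame and n the total database residues; only
hits with E below the cutoff (default 1e-5) are reported.

Queries with a significant viral hit are searched against the NVNR
(non-virus non-redundant) database and pass a competitive filter: the
verdict is viral only when no NVNR hit under the cutoff scores at least
as high in bits (ties are conservatively non-viral).  Queries with no
viral hit are scored against a set of hallmark profile HMMs; stop-free
translated segments of at least 30 aa are scored and the query becomes
``viral_by_hmm`` when the best Viterbi log-odds reaches the bit cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .phmm import ProfileHMM
from .records import Contig, ProteinRecord, Read
from .scoring import (
    LocalAlignment,
    ScoringScheme,
    banded_smith_waterman,
    ungapped_extend,
)

SEED_K = 4
BAND = 16
XDROP = 20
#: ungapped score needed before a banded gapped extension is attempted;
#: spurious random 4-mer seeds die far below this
GAPPED_TRIGGER = 40
#: minimum stop-free segment length scored against profile HMMs
HMM_MIN_SEGMENT = 30
DEFAULT_HMM_CUTOFF = 25.0


def six_frame_translate(seq: str) -> list[tuple[int, str]]:
    """All six reading frames as (frame, peptide); stops rendered '*'.

    Frames +1..+3 read the forward strand with offsets 0..2; frames
    -1..-3 read the reverse complement likewise.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    out = []
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    for off in range(3):
        for sign, s in ((1, fwd), (-1, rev)):
            sub = s[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            out.append((sign * (off + 1), str(sub.translate())))
    out.sort(key=lambda t: (t[0] < 0, abs(t[0])))
    return out


@dataclass(frozen=True)
class Hit:
    query_id: str
    subject_id: str
    species: str | None
    family: str | None
    genome_type: str | None
    host: str | None
    gene: str | None
    raw_score: int
    bit_score: float
    e_value: float
    pct_identity: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    frame: int


@dataclass
class Classification:
    query_id: str
    verdict: str  # viral | non_viral | unclassified | viral_by_hmm
    best_viral: Hit | None = None
    best_nvnr: Hit | None = None
    hmm_name: str | None = None
    hmm_score: float | None = None
    library: str = ""
    n_reads: int = 1  # weight: 1 for singlets, mapped-read total for contigs
    is_contig: bool = False
    query_length: int = 0


class ProteinDatabase:
    """Seed index over a set of protein records."""

    def __init__(self, records: list[ProteinRecord]):
        if not records:
            raise ValueError("empty protein database")
        self.records = list(records)
        self.total_residues = sum(len(r.seq) for r in records)
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ri, rec in enumerate(records):
            s = rec.seq
            for p in range(len(s) - SEED_K + 1):
                self.index.setdefault(s[p:p + SEED_K], []).append((ri, p))

    def __len__(self) -> int:
        return len(self.records)


def _best_alignment_for_subject(pep: str, subject: str,
                                seeds: list[tuple[int, int]],
                                scheme: ScoringScheme) -> LocalAlignment | None:
    """Extend this frame's seeds against one subject; return the best."""
    best_by_diag: dict[int, LocalAlignment] = {}
    covered: dict[int, tuple[int, int]] = {}
    for qi, si in seeds:
        diag = qi - si
        span = covered.get(diag)
        if span and span[0] <= qi < span[1]:
            continue
        aln = ungapped_extend(pep, subject, qi, si, SEED_K, scheme, XDROP)
        covered[diag] = (aln.q_start, aln.q_end)
        prev = best_by_diag.get(diag)
        if prev is None or aln.score > prev.score:
            best_by_diag[diag] = aln
    if not best_by_diag:
        return None
    ranked = sorted(best_by_diag.items(), key=lambda kv: -kv[1].score)
    best: LocalAlignment | None = None
    for diag, ung in ranked[:3]:
        if ung.score >= GAPPED_TRIGGER:
            aln = banded_smith_waterman(pep, subject, diag, BAND, scheme)
            cand = aln if aln.score >= ung.score else ung
        else:
            cand = ung
        if best is None or cand.score > best.score:
            best = cand
    return best


def translated_search(query: str, db: ProteinDatabase,
                      scheme: ScoringScheme | None = None,
                      e_cutoff: float = 1e-5,
                      query_id: str = "query") -> list[Hit]:
    """Six-frame seed-and-extend search; hits sorted by E then score."""
    scheme = scheme or ScoringScheme()
    if len(db) == 0:
        raise ValueError("empty protein database")
    n = db.total_residues
    best_per_subject: dict[int, tuple[LocalAlignment, int, int]] = {}
    for frame, pep in six_frame_translate(query):
        m = len(pep)
        if m < SEED_K:
            continue
        # collect seeds per subject for this frame
        per_subject: dict[int, list[tuple[int, int]]] = {}
        for qi in range(m - SEED_K + 1):
            kmer = pep[qi:qi + SEED_K]
            if "*" in kmer:
                continue
            for ri, sp in db.index.get(kmer, ()):
                per_subject.setdefault(ri, []).append((qi, sp))
        for ri, seeds in per_subject.items():
            aln = _best_alignment_for_subject(pep, db.records[ri].seq,
                                              seeds, scheme)
            if aln is None or aln.score <= 0:
                continue
            prev = best_per_subject.get(ri)
            if prev is None or aln.score > prev[0].score:
                best_per_subject[ri] = (aln, frame, m)
    hits: list[Hit] = []
    for ri, (aln, frame, m) in best_per_subject.items():
        e = scheme.e_value(aln.score, m, n)
        if e >= e_cutoff:
            continue
        rec = db.records[ri]
        hits.append(
            Hit(
                query_id=query_id,
                subject_id=rec.rec_id,
                species=rec.species,
                family=rec.family,
                genome_type=rec.genome_type,
                host=rec.host,
                gene=rec.gene,
                raw_score=aln.score,
                bit_score=scheme.bit_score(aln.score),
                e_value=e,
                pct_identity=aln.pct_identity,
                q_start=aln.q_start,
                q_end=aln.q_end,
                s_start=aln.s_start,
                s_end=aln.s_end,
                frame=frame,
            )
        )
    hits.sort(key=lambda h: (h.e_value, -h.raw_score, h.subject_id))
    return hits


def protein_search(pep: str, db: ProteinDatabase,
                   scheme: ScoringScheme | None = None,
                   e_cutoff: float = 1e-5,
                   query_id: str = "query") -> list[Hit]:
    """Peptide-vs-protein-database search (frame 0), same seed-and-extend."""
    scheme = scheme or ScoringScheme()
    m = len(pep)
    n = db.total_residues
    per_subject: dict[int, list[tuple[int, int]]] = {}
    for qi in range(m - SEED_K + 1):
        kmer = pep[qi:qi + SEED_K]
        if "*" in kmer:
            continue
        for ri, sp in db.index.get(kmer, ()):
            per_subject.setdefault(ri, []).append((qi, sp))
    hits: list[Hit] = []
    for ri, seeds in per_subject.items():
        aln = _best_alignment_for_subject(pep, db.records[ri].seq, seeds, scheme)
        if aln is None or aln.score <= 0:
            continue
        e = scheme.e_value(aln.score, m, n)
        if e >= e_cutoff:
            continue
        rec = db.records[ri]
        hits.append(
            Hit(query_id=query_id, subject_id=rec.rec_id, species=rec.species,
                family=rec.family, genome_type=rec.genome_type, host=rec.host,
                gene=rec.gene, raw_score=aln.score,
                bit_score=scheme.bit_score(aln.score), e_value=e,
                pct_identity=aln.pct_identity, q_start=aln.q_start,
                q_end=aln.q_end, s_start=aln.s_start, s_end=aln.s_end,
                frame=0)
        )
    hits.sort(key=lambda h: (h.e_value, -h.raw_score, h.subject_id))
    return hits


def competitive_filter(viral_hits: list[Hit], nvnr_hits: list[Hit],
                       e_cutoff: float = 1e-5,
                       query_id: str | None = None) -> Classification:
    """Remove false-positive viral hits by comparison with NVNR.

    viral  : a significant viral hit exists and strictly outscores (in
             bits) every significant NVNR hit;
    non_viral : a significant NVNR hit scores at least as high as the
             best significant viral hit (or no viral hit exists);
    unclassified : neither database yields a significant hit.
    """
    sig_viral = [h for h in viral_hits if h.e_value < e_cutoff]
    sig_nvnr = [h for h in nvnr_hits if h.e_value < e_cutoff]
    qid = query_id or (sig_viral[0].query_id if sig_viral
                       else sig_nvnr[0].query_id if sig_nvnr else "query")
    best_viral = sig_viral[0] if sig_viral else None
    best_nvnr = max(sig_nvnr, key=lambda h: h.bit_score) if sig_nvnr else None
    if best_viral is not None:
        if best_nvnr is None or best_viral.bit_score > best_nvnr.bit_score:
            return Classification(qid, "viral", best_viral, best_nvnr)
        return Classification(qid, "non_viral", best_viral, best_nvnr)
    if best_nvnr is not None:
        return Classification(qid, "non_viral", None, best_nvnr)
    return Classification(qid, "unclassified")


def _stop_free_segments(pep: str, min_len: int) -> list[str]:
    return [s for s in pep.split("*") if len(s) >= min_len]


def best_hmm_score(query_nt: str, hmms: list[ProfileHMM]
                   ) -> tuple[str | None, float]:
    """Best Viterbi bit score over all profiles and stop-free segments."""
    best_name, best = None, float("-inf")
    if len(query_nt) < 3:
        return None, best
    for _frame, pep in six_frame_translate(query_nt):
        for seg in _stop_free_segments(pep, HMM_MIN_SEGMENT):
            for hmm in hmms:
                s = hmm.viterbi_score(seg)
                if s > best:
                    best, best_name = s, hmm.name
    return best_name, best


def classify_all(contigs: list[Contig], singlets: list[Read],
                 viral_db: ProteinDatabase, nvnr_db: ProteinDatabase,
                 hmms: list[ProfileHMM] | None = None,
                 scheme: ScoringScheme | None = None,
                 hmm_bitscore_cutoff: float = DEFAULT_HMM_CUTOFF,
                 e_cutoff: float = 1e-5) -> list[Classification]:
    """Classify every contig and singlet read of a run.

    Contigs carry their mapped-read total as weight; singlets count 1.
    """
    scheme = scheme or ScoringScheme()
    hmms = hmms or []
    queries: list[tuple[str, str, str, int, bool]] = []
    for c in contigs:
        weight = c.n_reads_mapped if c.n_reads_mapped else len(c.member_read_ids)
        queries.append((c.contig_id, c.seq, c.library, weight, True))
    for r in singlets:
        queries.append((r.read_id, r.seq, r.library, 1, False))
    out: list[Classification] = []
    for qid, seq, lib, weight, is_contig in queries:
        if len(seq) < 3:
            cls = Classification(qid, "unclassified")
        else:
            viral_hits = translated_search(seq, viral_db, scheme, e_cutoff, qid)
            if viral_hits:
                nvnr_hits = translated_search(seq, nvnr_db, scheme, e_cutoff, qid)
                cls = competitive_filter(viral_hits, nvnr_hits, e_cutoff, qid)
            elif hmms:
                name, score = best_hmm_score(seq, hmms)
                if name is not None and score >= hmm_bitscore_cutoff:
                    cls = Classification(qid, "viral_by_hmm",
                                         hmm_name=name, hmm_score=score)
                else:
                    cls = Classification(qid, "unclassified")
            else:
                cls = Classification(qid, "unclassified")
        cls.library = lib
        cls.n_reads = weight
        cls.is_contig = is_contig
        cls.query_length = len(seq)
        out.append(cls)
    return out


def hits_to_rows(hits: list[Hit]) -> list[dict]:
    """BLAST outfmt-6-style rows plus taxonomy columns (for TSV export)."""
    rows = []
    for h in hits:
        rows.append({
            "qseqid": h.query_id, "sseqid": h.subject_id,
            "pident": round(h.pct_identity, 2),
            "length": h.q_end - h.q_start, "qstart": h.q_start,
            "qend": h.q_end, "sstart": h.s_start, "send": h.s_end,
            "frame": h.frame, "score": h.raw_score,
            "bitscore": round(h.bit_score, 2), "evalue": h.e_value,
            "species": h.species or "", "family": h.family or "",
            "genome_type": h.genome_type or "", "host": h.host or "",
            "gene": h.gene or "",
        })
    return rows
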