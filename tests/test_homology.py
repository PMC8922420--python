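"""Translated search, alignment scoring, E-values, competitive filter."""

from __future__ import annotations

import math

import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from conftest import random_dna
from rivervirome.homology import (
    Classification,
    Hit,
    ProteinDatabase,
    classify_all,
    competitive_filter,
    protein_search,
    six_frame_translate,
    translated_search,
)
from rivervirome.records import Contig, ProteinRecord, reverse_complement
from rivervirome.scoring import (
    ScoringScheme,
    banded_smith_waterman,
    smith_waterman_full,
)
from rivervirome.synthetic import AMINO_ACIDS, encode_orf, random_peptide

#: independent codon table for the translation oracle
_CODON = {}
for _c in ["".join((a, b, c)) for a in "TCAG" for b in "TCAG" for c in "TCAG"]:
    _CODON[_c] = str(Seq(_c).translate())


def _biopython_local_score(q: str, s: str, scheme: ScoringScheme) -> int:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST-style gap cost open + extend*L:
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return int(aligner.score(q, s))


class TestSixFrameTranslate:
    def test_forward_frame_basics(self):
        frames = dict(six_frame_translate("ATGAAATAG"))
        assert frames[1] == "MK*"

    def test_reverse_symmetry(self, rng):
        seq = random_dna(rng, 120)
        fw = dict(six_frame_translate(seq))
        rv = dict(six_frame_translate(reverse_complement(seq)))
        assert fw[1] == rv[-1]
        assert fw[-1] == rv[1]

    def test_against_codon_table_oracle(self, rng):
        seq = random_dna(rng, 300)
        frames = dict(six_frame_translate(seq))
        for f in (1, 2, 3):
            s = seq[f - 1:]
            s = s[: len(s) - len(s) % 3]
            expect = "".join(_CODON[s[i:i + 3]] for i in range(0, len(s), 3))
            assert frames[f] == expect
        rc = reverse_complement(seq)
        for f in (1, 2, 3):
            s = rc[f - 1:]
            s = s[: len(s) - len(s) % 3]
            expect = "".join(_CODON[s[i:i + 3]] for i in range(0, len(s), 3))
            assert frames[-f] == expect

    def test_frame_lengths(self, rng):
        seq = random_dna(rng, 100)
        for f, pep in six_frame_translate(seq):
            assert len(pep) == (100 - (abs(f) - 1)) // 3

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            six_frame_translate("AT")


class TestScoringStatistics:
    def test_e_value_closed_form(self, scheme):
        """bit 20 with m=100, n=1000 gives E = 100*1000*2^-20."""
        S = (20.0 * math.log(2) + math.log(scheme.K)) / scheme.lam
        assert abs(scheme.bit_score(S) - 20.0) < 1e-9
        e = scheme.e_value(S, 100, 1000)
        assert abs(e - 100 * 1000 * 2.0 ** -20.0) < 1e-9

    def test_e_value_monotone_in_score(self, scheme):
        es = [scheme.e_value(s, 100, 10_000) for s in range(10, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_full_sw_matches_biopython(self, scheme, rng):
        """Seedless SW equals Biopython's local aligner, with homology."""
        for _ in range(10):
            core = random_peptide(rng, 15)
            q = random_peptide(rng, 8) + core + random_peptide(rng, 7)
            mutated = list(core)
            mutated[3] = "A" if mutated[3] != "A" else "G"
            s = random_peptide(rng, 5) + "".join(mutated) + random_peptide(rng, 6)
            assert smith_waterman_full(q, s, scheme) == \
                _biopython_local_score(q, s, scheme)

    def test_banded_sw_recovers_full_optimum(self, scheme, rng):
        for _ in range(10):
            core = random_peptide(rng, 20)
            q = random_peptide(rng, 5) + core
            s = core + random_peptide(rng, 5)
            full = smith_waterman_full(q, s, scheme)
            width = max(len(q), len(s))
            banded = banded_smith_waterman(q, s, 0, width, scheme)
            assert banded.score == full


def _db(records):
    return ProteinDatabase(records)


class TestTranslatedSearch:
    def test_self_match_identity_and_score(self, scheme, rng):
        pep = random_peptide(rng, 60)
        orf = encode_orf(pep, rng)
        db = _db([ProteinRecord("p0", pep, "sp", "fam", "dsDNA", "bacteria",
                                "other")])
        hits = translated_search(orf, db, scheme)
        assert hits and hits[0].subject_id == "p0"
        assert hits[0].pct_identity == 100.0
        diag = sum(scheme.score_pair(a, a) for a in pep)
        # the query peptide is M + pep (+ stop beyond the alignment)
        assert hits[0].raw_score >= diag

    def test_evalue_cutoff_excludes_weak_hits(self, scheme, rng):
        """A hit whose E-value is above the cutoff is not reported."""
        pep = random_peptide(rng, 200)
        implant = pep[:9]  # short shared segment -> weak similarity
        query_pep = random_peptide(rng, 40) + implant + random_peptide(rng, 40)
        orf = encode_orf(query_pep, rng)
        db = _db([ProteinRecord("weak", pep)])
        all_hits = translated_search(orf, db, scheme, e_cutoff=float("inf"))
        if all_hits:
            e = all_hits[0].e_value
            if e >= 1e-5:
                assert translated_search(orf, db, scheme, e_cutoff=1e-5) == []
        # and the stated closed form holds for whatever was found
        for h in all_hits:
            m = next(len(p) for f, p in six_frame_translate(orf)
                     if f == h.frame)
            expect = scheme.K * m * db.total_residues * math.exp(
                -scheme.lam * h.raw_score)
            assert abs(h.e_value - expect) < 1e-12 * max(1.0, expect)

    def test_reverse_complement_symmetry(self, scheme, rng):
        pep = random_peptide(rng, 80)
        orf = encode_orf(pep, rng)
        db = _db([ProteinRecord("p0", pep, "sp", "fam", "dsDNA", "bacteria",
                                "other")])
        fwd = translated_search(orf, db, scheme)
        rev = translated_search(reverse_complement(orf), db, scheme)
        assert fwd and rev
        assert fwd[0].subject_id == rev[0].subject_id
        assert fwd[0].raw_score == rev[0].raw_score
        assert fwd[0].frame == -rev[0].frame

    def test_empty_db_errors(self, scheme):
        with pytest.raises(ValueError):
            ProteinDatabase([])


def _mk_hit(bit: float, e: float, qid="q", sid="s", **kw) -> Hit:
    defaults = dict(query_id=qid, subject_id=sid, species="sp", family="fam",
                    genome_type="dsDNA", host="bacteria", gene="other",
                    raw_score=int(bit), bit_score=bit, e_value=e,
                    pct_identity=90.0, q_start=0, q_end=10, s_start=0,
                    s_end=10, frame=1)
    defaults.update(kw)
    return Hit(**defaults)


class TestCompetitiveFilter:
    def test_nvnr_over_cutoff_is_ignored(self):
        cls = competitive_filter([_mk_hit(60, 1e-8)], [_mk_hit(50, 1e-3)])
        assert cls.verdict == "viral"

    def test_stronger_nvnr_wins(self):
        cls = competitive_filter([_mk_hit(60, 1e-8)], [_mk_hit(80, 1e-10)])
        assert cls.verdict == "non_viral"

    def test_exact_tie_is_non_viral(self):
        cls = competitive_filter([_mk_hit(60, 1e-8)], [_mk_hit(60, 1e-8)])
        assert cls.verdict == "non_viral"

    def test_no_hits_unclassified(self):
        assert competitive_filter([], []).verdict == "unclassified"


class TestClassifyAll:
    def test_synthetic_truth(self, mock_refs, scheme):
        """Viral contigs get the right family; decoys non-viral;
        random sequence unclassified."""
        taxa = mock_refs["taxa"]
        vdb = ProteinDatabase(mock_refs["viral"])
        ndb = ProteinDatabase(mock_refs["nvnr"])
        t = taxa[0]
        viral_contig = Contig("vc", "lib", t.genome_seq[:1200], ["r"], 5)
        decoy_genome = next(b for b in mock_refs["background"]
                            if b.is_decoy_genome)
        decoy_contig = Contig("dc", "lib", decoy_genome.seq[:1200], ["r"], 5)
        rng = np.random.default_rng(0)
        random_contig = Contig("rc", "lib", random_dna(rng, 600), ["r"], 1)
        cls = classify_all([viral_contig, decoy_contig, random_contig], [],
                           vdb, ndb, [], scheme)
        by_id = {c.query_id: c for c in cls}
        assert by_id["vc"].verdict == "viral"
        assert by_id["vc"].best_viral.family == t.family
        assert by_id["dc"].verdict == "non_viral"
        assert by_id["rc"].verdict == "unclassified"

    def test_hmm_rescue_of_remote_homolog(self, mock_refs, scheme):
        """A diverged hallmark absent from the DB is rescued by its HMM."""
        from rivervirome.synthetic import (
            _hallmark_ancestors,
            mutate_peptide,
        )
        rng = np.random.default_rng(5)
        anc = _hallmark_ancestors(11)["TerL"]
        novel = mutate_peptide(anc, 0.30, rng)
        orf = encode_orf(novel, rng)
        # restrict the viral DB to proteins unrelated to TerL so the
        # translated search finds nothing
        unrelated = [r for r in mock_refs["viral"] if r.gene == "other"][:20]
        vdb = ProteinDatabase(unrelated)
        ndb = ProteinDatabase(mock_refs["nvnr"])
        contig = Contig("novel", "lib", orf, ["r"], 1)
        cls = classify_all([contig], [], vdb, ndb, mock_refs["hmms"], scheme)
        assert cls[0].verdict == "viral_by_hmm"
        assert cls[0].hmm_name == "TerL"

    def test_protein_search_agrees_with_translated(self, mock_refs, scheme):
        pep = mock_refs["viral"][0].seq
        db = ProteinDatabase(mock_refs["viral"][:10])
        hits = protein_search(pep, db, scheme)
        assert hits and hits[0].subject_id == mock_refs["viral"][0].rec_id
        assert hits[0].pct_identity == 100.0
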