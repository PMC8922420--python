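"""ORF prediction, contig merge/extension, hallmark extraction,
progressive alignment with gap masking, and NJ trees."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest
from Bio.Seq import Seq

from conftest import make_read, random_dna
from rivervirome.annotation import (
    MERGE_SPACER,
    annotate_and_extract_hallmarks,
    annotate_orfs,
    extend_by_mapping,
    merge_nonoverlapping_contigs,
    predict_orfs,
)
from rivervirome.homology import Hit, ProteinDatabase
from rivervirome.msa import (
    MultipleAlignment,
    align_and_mask,
    mask_gappy_columns,
    nj_tree,
    progressive_align,
)
from rivervirome.records import Contig, ProteinRecord, reverse_complement
from rivervirome.synthetic import encode_orf, mutate_peptide, random_peptide
from rivervirome.trees import DistanceMatrix, neighbor_joining


def _contig(seq, cid="c0"):
    return Contig(cid, "lib", seq, ["r0"], 1)


class TestPredictOrfs:
    def test_short_orf_dropped(self, rng):
        # 9 nt ORF alone in a 400 nt contig: below the 300 nt minimum
        filler1 = "C" * 200
        filler2 = "C" * 191
        seq = filler1 + "ATGAAATAA" + filler2
        orfs = [o for o in predict_orfs(_contig(seq)) if o.strand == "+"]
        assert all(o.end - o.start >= 300 for o in orfs)

    def test_single_complete_orf(self, rng):
        pep = random_peptide(rng, 99)
        orf_nt = encode_orf(pep, rng)  # ATG + 99 codons + stop = 303 nt
        assert len(orf_nt) == 303
        orfs = predict_orfs(_contig(orf_nt))
        plus = [o for o in orfs if o.strand == "+"]
        assert len(plus) == 1
        o = plus[0]
        assert (o.start, o.end) == (0, 303)
        assert o.complete
        assert o.peptide == "M" + pep

    def test_reverse_strand_mirrored_coordinates(self, rng):
        pep = random_peptide(rng, 99)
        orf_nt = encode_orf(pep, rng)
        pad = random_dna(rng, 30)
        fwd_seq = pad + orf_nt + pad
        fwd = predict_orfs(_contig(fwd_seq))
        rev = predict_orfs(_contig(reverse_complement(fwd_seq)))
        f = next(o for o in fwd if o.peptide == "M" + pep)
        r = next(o for o in rev if o.peptide == "M" + pep)
        assert f.strand == "+" and r.strand == "-"
        L = len(fwd_seq)
        assert (r.start, r.end) == (L - f.end, L - f.start)

    def test_nested_orfs_report_longest(self, rng):
        # ATG ... ATG ... stop in one frame: first ATG wins
        inner = random_peptide(rng, 120).replace("M", "A")
        seq = "ATG" + "GCT" * 30 + "ATG" + encode_orf(inner, rng)[3:]
        orfs = [o for o in predict_orfs(_contig(seq)) if o.strand == "+"
                and o.complete]
        starts = [o.start for o in orfs]
        assert 0 in starts
        assert 93 not in starts  # nested start swallowed

    def test_open_ended_at_edge_incomplete(self, rng):
        pep = random_peptide(rng, 150)
        orf_nt = encode_orf(pep, rng)
        truncated = orf_nt[: len(orf_nt) - 30]  # no stop in contig
        orfs = [o for o in predict_orfs(_contig(truncated))
                if o.strand == "+"]
        assert orfs and not orfs[0].complete

    def test_peptides_retranslate_from_coordinates(self, rng):
        pep = random_peptide(rng, 110)
        seq = random_dna(rng, 50) + encode_orf(pep, rng) + random_dna(rng, 40)
        for o in predict_orfs(_contig(seq)):
            sub = seq[o.start:o.end]
            if o.strand == "-":
                sub = reverse_complement(sub)
            got = str(Seq(sub).translate()).rstrip("*")
            assert got.startswith(o.peptide) or o.peptide.startswith(got)


def _hit(qid, sid, s_start, s_end):
    return Hit(qid, sid, "sp", "fam", "dsDNA", "bacteria", "other",
               100, 50.0, 1e-30, 99.0, 0, 10, s_start, s_end, 1)


class TestMergeContigs:
    def test_disjoint_halves_merge_with_spacer(self, rng):
        a = _contig(random_dna(rng, 300), "a")
        b = _contig(random_dna(rng, 300), "b")
        hits = {"a": _hit("a", "prot1", 0, 80),
                "b": _hit("b", "prot1", 100, 180)}
        merged = merge_nonoverlapping_contigs([a, b], hits)
        assert len(merged) == 1
        assert merged[0].seq == a.seq + MERGE_SPACER + b.seq

    def test_different_subjects_unmerged(self, rng):
        a = _contig(random_dna(rng, 300), "a")
        b = _contig(random_dna(rng, 300), "b")
        hits = {"a": _hit("a", "p1", 0, 80), "b": _hit("b", "p2", 100, 180)}
        merged = merge_nonoverlapping_contigs([a, b], hits)
        assert sorted(c.contig_id for c in merged) == ["a", "b"]

    def test_overlapping_intervals_unmerged(self, rng):
        a = _contig(random_dna(rng, 300), "a")
        b = _contig(random_dna(rng, 300), "b")
        hits = {"a": _hit("a", "p1", 0, 120), "b": _hit("b", "p1", 100, 180)}
        merged = merge_nonoverlapping_contigs([a, b], hits)
        assert sorted(c.contig_id for c in merged) == ["a", "b"]


class TestExtendByMapping:
    def test_no_overlapping_reads_unchanged(self, rng):
        c = _contig(random_dna(rng, 400))
        reads = [make_read(random_dna(rng, 100), f"r{i}") for i in range(5)]
        assert extend_by_mapping(c, reads).seq == c.seq

    def test_three_prime_overhang_extends(self, rng):
        genome = random_dna(rng, 500)
        c = _contig(genome[:400])
        read = make_read(genome[360:440], "r")  # 40 nt overlap, 40 overhang
        ext = extend_by_mapping(c, [read], rounds=1)
        assert ext.seq == genome[:440]

    def test_fixpoint_idempotent(self, rng):
        genome = random_dna(rng, 500)
        c = _contig(genome[:400])
        reads = [make_read(genome[360:440], "r")]
        once = extend_by_mapping(c, reads, rounds=3)
        again = extend_by_mapping(once, reads, rounds=3)
        assert once.seq == again.seq

    def test_never_shrinks(self, rng):
        c = _contig(random_dna(rng, 300))
        reads = [make_read(random_dna(rng, 120), f"r{i}") for i in range(10)]
        assert len(extend_by_mapping(c, reads).seq) >= 300


class TestHallmarkAnnotation:
    def test_exact_db_match_is_hallmark(self, mock_refs, scheme, rng):
        terl = next(r for r in mock_refs["viral"] if r.gene == "TerL")
        orf_nt = encode_orf(terl.seq, rng)
        orfs = predict_orfs(_contig(orf_nt))
        db = ProteinDatabase(mock_refs["viral"])
        sets = annotate_and_extract_hallmarks(orfs, db, scheme)
        genes = {s.gene for s in sets}
        assert "TerL" in genes
        terl_set = next(s for s in sets if s.gene == "TerL")
        assert terl_set.group == "Caudovirales"
        assert any(comp for _id, _pep, comp in terl_set.members)

    def test_no_hit_is_putative(self, mock_refs, scheme, rng):
        pep = random_peptide(rng, 120)
        orfs = predict_orfs(_contig(encode_orf(pep, rng)))
        db = ProteinDatabase(mock_refs["viral"])
        annotated = annotate_orfs([o for o in orfs if o.strand == "+"], db,
                                  scheme)
        assert annotated[0].annotation == "putative protein"

    def test_implanted_rep_recovered_in_cress_set(self, mock_refs, scheme):
        rep_taxon = next(t for t in mock_refs["taxa"]
                         if t.family == "Circoviridae")
        contig = _contig(rep_taxon.genome_seq)
        orfs = predict_orfs(contig)
        db = ProteinDatabase(mock_refs["viral"])
        sets = annotate_and_extract_hallmarks(orfs, db, scheme)
        rep = next((s for s in sets if s.gene == "Rep"), None)
        assert rep is not None and rep.group == "CRESS-DNA"
        rep_pep = dict(rep_taxon.proteins)["Rep"]
        assert any(p.rstrip("*") == "M" + rep_pep for _i, p, _c in rep.members)


class TestAlignment:
    def test_identical_sequences_gap_free(self, rng):
        pep = random_peptide(rng, 40)
        msa = align_and_mask([("a", pep), ("b", pep), ("c", pep)])
        assert all(r == pep for r in msa.rows)

    def test_degapping_recovers_inputs(self, rng):
        anc = random_peptide(rng, 50)
        items = [(f"s{i}", mutate_peptide(anc, 0.15, rng)) for i in range(4)]
        msa = progressive_align(items)
        for i, (_l, seq) in enumerate(items):
            assert msa.degapped(i) == seq

    def test_strict_gap_fraction_rule(self):
        rows = ["A-CA", "A-CA", "AAC-", "A-C-"]
        msa = MultipleAlignment(list("wxyz"), rows)
        masked = mask_gappy_columns(msa)
        # col 1 has 3/4 gaps (>50%) -> dropped; col 3 has 2/4 (=50%) -> kept
        assert masked.rows == ["ACA", "ACA", "AC-", "AC-"]
        assert len(masked.labels) == 4

    def test_masking_idempotent(self, rng):
        anc = random_peptide(rng, 45)
        items = [(f"s{i}", mutate_peptide(anc, 0.2, rng)) for i in range(4)]
        msa = align_and_mask(items)
        again = mask_gappy_columns(msa)
        assert again.rows == msa.rows


class TestNjTree:
    def test_three_point_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        lengths = {c.label: c.length for c in tree.children}
        assert abs(lengths["A"] - 1.0) < 1e-12
        assert abs(lengths["B"] - 2.0) < 1e-12
        assert abs(lengths["C"] - 3.0) < 1e-12

    def test_additive_matrix_recovers_topology(self):
        # tree ((A:2,B:3):1,(C:2,D:4)): split AB|CD
        d = np.array([
            [0, 5, 5, 7],
            [5, 0, 6, 8],
            [5, 6, 0, 6],
            [7, 8, 6, 0],
        ], dtype=float)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        splits = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
                  for e in t.edges() if e.head_node.parent_node}
        assert frozenset("AB") in splits or frozenset("CD") in splits

    def test_identical_rows_star_tree(self, rng):
        pep = random_peptide(rng, 30)
        msa = MultipleAlignment(["a", "b", "c"], [pep, pep, pep])
        tree = nj_tree(msa)
        assert all(abs(c.length) < 1e-12 for c in tree.children)

    def test_nj_on_ultrametric_agrees_with_upgma(self, rng):
        from rivervirome.trees import upgma

        # ultrametric distances from a fixed clock tree
        d = np.array([
            [0, 2, 8, 8],
            [2, 0, 8, 8],
            [8, 8, 0, 4],
            [8, 8, 4, 0],
        ], dtype=float)
        labels = list("ABCD")
        nj = neighbor_joining(DistanceMatrix(labels, d))
        up = upgma(DistanceMatrix(labels, d))
        t1 = dendropy.Tree.get(data=nj.to_newick(), schema="newick")
        t2 = dendropy.Tree.get(data=up.to_newick(), schema="newick")
        s1 = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
              for e in t1.edges()
              if e.head_node.parent_node and not e.head_node.is_leaf()}
        s2 = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
              for e in t2.edges()
              if e.head_node.parent_node and not e.head_node.is_leaf()}
        # every non-trivial NJ split appears in the UPGMA tree
        assert s1 <= s2 | {frozenset(labels)}

    def test_too_few_rows_error(self, rng):
        pep = random_peptide(rng, 20)
        with pytest.raises(ValueError):
            nj_tree(MultipleAlignment(["a", "b"], [pep, pep]))
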