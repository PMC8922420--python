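"""Community profiles, rarefaction, Bray-Curtis, PCoA, UPGMA, Friedman,
shared species and top-k tables."""

from __future__ import annotations

from fractions import Fraction

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from rivervirome.community import (
    TaxProfile,
    bray_curtis,
    build_profiles,
    family_counts_by_genome_type,
    friedman_matrix,
    friedman_test,
    pcoa,
    rarefaction_curve,
    shared_species,
    top_species,
    upgma_tree,
)
from rivervirome.homology import Classification, Hit
from rivervirome.trees import DistanceMatrix


def _viral_cls(lib, species, family, n_reads=1, gtype="dsDNA",
               host="bacteria"):
    hit = Hit("q", "s", species, family, gtype, host, "other", 100, 50.0,
              1e-20, 99.0, 0, 10, 0, 10, 1)
    c = Classification("q", "viral", best_viral=hit)
    c.library = lib
    c.n_reads = n_reads
    return c


def _profile(counts: dict[str, dict[str, int]], rank="species",
             meta=None) -> TaxProfile:
    df = pd.DataFrame(counts).T.fillna(0).astype(int)
    taxa = list(df.columns)
    meta = meta or {}
    meta_df = pd.DataFrame(
        {t: {"genome_type": meta.get(t, ("dsDNA", "bacteria"))[0],
             "host": meta.get(t, ("dsDNA", "bacteria"))[1]} for t in taxa}).T
    return TaxProfile(rank, df, meta_df)


class TestBuildProfiles:
    def test_single_singlet_single_cell(self):
        prof = build_profiles([_viral_cls("L1", "spA", "famA")], "species")
        assert prof.counts.shape == (1, 1)
        assert prof.counts.loc["L1", "spA"] == 1

    def test_contig_weight_counts_mapped_reads(self):
        cls = [_viral_cls("L1", "spA", "famA", n_reads=7),
               _viral_cls("L1", "spA", "famA", n_reads=1)]
        prof = build_profiles(cls, "species")
        assert prof.counts.loc["L1", "spA"] == 8

    def test_family_rank_and_genome_type_triple(self):
        cls = [
            _viral_cls("L1", "a", "F1", gtype="dsDNA"),
            _viral_cls("L1", "b", "F2", gtype="dsDNA"),
            _viral_cls("L2", "c", "F3", gtype="ssDNA"),
            _viral_cls("L2", "d", "F4", gtype="RNA"),
        ]
        prof = build_profiles(cls, "family")
        triple = family_counts_by_genome_type(prof)
        assert triple == {"dsDNA": 2, "ssDNA": 1, "RNA": 1}

    def test_invalid_rank(self):
        with pytest.raises(ValueError):
            build_profiles([], "genus")

    def test_hmm_rescued_goes_to_reserved(self):
        c = Classification("q", "viral_by_hmm", hmm_name="TerL",
                           hmm_score=60.0)
        c.library = "L1"
        prof = build_profiles([c], "family")
        assert prof.counts.loc["L1", "unclassified"] == 1


class TestRarefaction:
    def test_worked_example(self):
        """counts {4,2}, n=2: E[S2] = 2 - (C(2,2)+C(4,2))/C(6,2) = 23/15."""
        curve = rarefaction_curve({"A": 4, "B": 2}, [2])
        assert abs(curve[0][1] - float(Fraction(23, 15))) < 1e-12

    def test_boundaries(self):
        counts = {"A": 5, "B": 3, "C": 1}
        curve = rarefaction_curve(counts, [0, 9])
        assert curve[0] == (0, 0.0)
        assert abs(curve[1][1] - 3.0) < 1e-12

    def test_monotone_and_concave(self):
        counts = {"A": 30, "B": 12, "C": 5, "D": 1}
        depths = list(range(0, 49))
        ys = [s for _, s in rarefaction_curve(counts, depths)]
        diffs = np.diff(ys)
        assert np.all(diffs > 0)
        assert np.all(np.diff(diffs) < 1e-9)

    def test_depth_beyond_total_errors(self):
        with pytest.raises(ValueError):
            rarefaction_curve({"A": 3}, [4])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        prof = _profile({"L1": {"a": 3, "b": 1}, "L2": {"a": 3, "b": 1}})
        assert bray_curtis(prof).value("L1", "L2") == 0.0

    def test_disjoint_support_one(self):
        prof = _profile({"L1": {"a": 3, "b": 0}, "L2": {"a": 0, "b": 5}})
        assert bray_curtis(prof).value("L1", "L2") == 1.0

    def test_worked_example(self):
        prof = _profile({"L1": {"a": 6, "b": 2}, "L2": {"a": 2, "b": 2}})
        assert abs(bray_curtis(prof).value("L1", "L2") - 1 / 3) < 1e-12

    def test_range_and_symmetry(self, rng):
        counts = {f"L{i}": {f"t{j}": int(rng.integers(0, 50))
                            for j in range(8)} for i in range(5)}
        dm = bray_curtis(_profile(counts))
        assert np.all(dm.d >= 0) and np.all(dm.d <= 1)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)


class TestPcoa:
    def test_all_zero_distances(self):
        dm = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = pcoa(dm)
        assert res.coordinates.shape[1] == 0 or \
            np.allclose(res.coordinates.values, 0)

    def test_two_point_closed_form(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]))
        res = pcoa(dm)
        coords = res.coordinates.values.ravel()
        assert np.allclose(sorted(coords), [-0.25, 0.25])
        assert abs(res.eigenvalues[0] - 0.125) < 1e-12

    def test_round_trip_euclidean(self, rng):
        pts = rng.normal(size=(4, 3))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(list("abcd"), D))
        C = res.coordinates.values
        D2 = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
        assert np.allclose(D, D2, atol=1e-9)
        assert np.all(res.eigenvalues > -1e-9)
        assert abs(res.proportion_explained.sum() - 1.0) < 1e-9

    def test_asymmetric_errors(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.5], [0.5, 0]]))
        dm.d = np.array([[0, 0.4], [0.5, 0]])
        with pytest.raises(ValueError):
            pcoa(dm)


def _patristic(newick: str) -> dict[frozenset, float]:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1 in tree.taxon_namespace:
        for t2 in tree.taxon_namespace:
            if t1.label < t2.label:
                out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


class TestUpgma:
    def test_two_leaves(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        tree = upgma_tree(dm)
        depths = tree.leaf_depths()
        assert abs(depths["A"] - 1.0) < 1e-12
        assert abs(depths["B"] - 1.0) < 1e-12

    def test_three_taxa_hand_agglomeration(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = upgma_tree(DistanceMatrix(["A", "B", "C"], d))
        # ((A:1,B:1):1,C:2): A-B patristic 2, A-C and B-C 4
        pat = _patristic(tree.to_newick())
        assert abs(pat[frozenset(("A", "B"))] - 2.0) < 1e-9
        assert abs(pat[frozenset(("A", "C"))] - 4.0) < 1e-9
        assert abs(pat[frozenset(("B", "C"))] - 4.0) < 1e-9

    def test_matches_scipy_average_linkage(self, rng):
        """Cophenetic distances equal scipy 'average' linkage (random 5x5)."""
        pts = rng.random((5, 4))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = list("abcde")
        tree = upgma_tree(DistanceMatrix(labels, D))
        Z = linkage(squareform(D), method="average")
        coph = squareform(cophenet(Z))
        pat = _patristic(tree.to_newick())
        for i in range(5):
            for j in range(i + 1, 5):
                key = frozenset((labels[i], labels[j]))
                # newick serialisation carries 6 decimals
                assert abs(pat[key] - coph[i, j]) < 5e-6

    def test_ultrametric(self, rng):
        pts = rng.random((6, 3))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        tree = upgma_tree(DistanceMatrix(list("abcdef"), D))
        depths = list(tree.leaf_depths().values())
        assert max(depths) - min(depths) < 1e-9


class TestFriedman:
    def test_consistent_ranking_worked_example(self):
        """Three blocks all ranking (1,2,3): chi2=6, df=2, p~0.0498."""
        X = np.array([[1, 2, 3], [4, 5, 6], [1, 5, 9]], dtype=float)
        res = friedman_matrix(X)
        assert abs(res.statistic - 6.0) < 1e-12
        assert res.df == 2
        assert abs(res.p_value - stats.chi2.sf(6, 2)) < 1e-12
        assert abs(res.p_value - 0.0498) < 5e-4

    def test_all_tied_no_discrimination(self):
        X = np.full((4, 3), 7.0)
        res = friedman_matrix(X)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy_oracle(self, rng):
        X = rng.random((10, 4))
        res = friedman_matrix(X)
        stat, p = stats.friedmanchisquare(*[X[:, j] for j in range(4)])
        assert abs(res.statistic - stat) < 1e-9
        assert abs(res.p_value - p) < 1e-9

    def test_matches_scipy_with_ties(self, rng):
        X = rng.integers(0, 4, size=(12, 5)).astype(float)
        res = friedman_matrix(X)
        stat, p = stats.friedmanchisquare(*[X[:, j] for j in range(5)])
        assert abs(res.statistic - stat) < 1e-9
        assert abs(res.p_value - p) < 1e-9

    def test_orientation_taxa_blocks_libraries_treatments(self):
        prof = _profile({"L1": {"a": 1, "b": 2}, "L2": {"a": 3, "b": 4},
                         "L3": {"a": 5, "b": 6}})
        res = friedman_test(prof)
        assert res.df == 2  # k = 3 libraries

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            friedman_matrix(np.ones((1, 3)))


class TestSharedAndTop:
    def test_identical_sets_full_core(self):
        prof = _profile({"L1": {"a": 1, "b": 1}, "L2": {"a": 2, "b": 3}})
        rep = shared_species(prof)
        assert rep.core_species == ["a", "b"]
        assert rep.per_library_fraction == {"L1": 1.0, "L2": 1.0}

    def test_partial_overlap_regions(self):
        prof = _profile({"L1": {"a": 1, "b": 1, "c": 0},
                         "L2": {"a": 0, "b": 2, "c": 3}})
        rep = shared_species(prof)
        assert rep.core_species == ["b"]
        assert rep.union_size == 3
        assert rep.per_library_fraction == {"L1": 0.5, "L2": 0.5}
        assert rep.region_counts[("L1",)] == 1
        assert rep.region_counts[("L2",)] == 1
        assert rep.region_counts[("L1", "L2")] == 1

    def test_disjoint_sets_empty_core(self):
        prof = _profile({"L1": {"a": 1, "b": 0}, "L2": {"a": 0, "b": 2}})
        assert shared_species(prof).core_species == []

    def test_single_species_hundred_percent(self):
        prof = _profile({"L1": {"x": 5}})
        top = top_species(prof, k=10)
        assert top["L1"].iloc[0]["relative_abundance"] == 1.0

    def test_relative_abundance_arithmetic(self):
        prof = _profile({"L1": {"X": 30, "Y": 10}})
        df = top_species(prof, k=10)["L1"]
        assert list(df["species"]) == ["X", "Y"]
        assert list(df["relative_abundance"]) == [0.75, 0.25]

    def test_shared_flag(self):
        prof = _profile({"L1": {"a": 3, "b": 1}, "L2": {"a": 2, "b": 0}})
        df = top_species(prof, k=10)["L1"]
        flags = dict(zip(df["species"], df["shared_in_all"]))
        assert flags["a"] and not flags["b"]

    def test_invalid_k(self):
        prof = _profile({"L1": {"a": 1}})
        with pytest.raises(ValueError):
            top_species(prof, k=0)
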