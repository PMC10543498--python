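"""Abundance vectors, quality filters, clustering, and benchmarking."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from microatlas import (
    AbundanceVector,
    FilterThresholds,
    annotate,
    assemble_matrix,
    embed_cluster,
    evaluate_benchmark,
    filter_vectors,
    integrate_contigs,
    subcluster,
    to_abundance_vector,
)
from microatlas.classify import RankAbundance


def vec(uid, abund, reads=2000, batch="single_cell", rank="genus"):
    """Fully classified unit whose per-taxon counts follow ``abund``."""
    counts = {t: a * reads for t, a in abund.items()}
    ra = RankAbundance(uid, rank, counts)
    return to_abundance_vector(ra, reads, batch=batch)


class TestAbundanceVector:
    def test_normalization_purity_and_classified_fraction(self):
        v = to_abundance_vector(RankAbundance("b", "genus", {1: 90, 2: 10}), 200)
        assert v.abundances == {1: 0.9, 2: 0.1}
        assert v.purity == 0.9
        assert v.classified_fraction == 0.5

    def test_fully_classified_single_taxon(self):
        v = to_abundance_vector(RankAbundance("b", "genus", {1: 100}), 100)
        assert v.purity == 1.0 and v.classified_fraction == 1.0

    def test_empty_counts_give_zero_vector(self):
        v = to_abundance_vector(RankAbundance("b", "genus", {}), 100)
        assert v.abundances == {} and v.purity == 0.0 and v.classified_fraction == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            to_abundance_vector(RankAbundance("b", "genus", {1: -5}), 100)

    def test_purity_invariant_under_count_permutation(self):
        """Purity and classified fraction depend on the multiset of
        per-taxon counts, not their order."""
        counts = {1: 50, 2: 30, 3: 20}
        v1 = to_abundance_vector(RankAbundance("b", "genus", counts), 200)
        shuffled = dict(reversed(list(counts.items())))
        v2 = to_abundance_vector(RankAbundance("b", "genus", shuffled), 200)
        assert v1.purity == v2.purity
        assert v1.classified_fraction == v2.classified_fraction


class TestFilters:
    def test_boundary_values_retained(self):
        thr = FilterThresholds()
        ok = vec("ok", {1: 0.8, 2: 0.2}, reads=1000)
        assert ok.purity == pytest.approx(0.8)
        retained, log = filter_vectors([ok], thr)
        assert [v.unit_id for v in retained] == ["ok"] and log.empty

    def test_rejections_logged_with_reason(self):
        thr = FilterThresholds()
        low_purity = vec("p", {1: 0.79, 2: 0.21})
        few_reads = vec("r", {1: 1.0}, reads=999)
        half = RankAbundance("c", "genus", {1: 980})
        low_classified = to_abundance_vector(half, 2000)  # classified 49%
        retained, log = filter_vectors([low_purity, few_reads, low_classified], thr)
        assert not retained
        assert dict(zip(log["unit_id"], log["failed"])) == {
            "p": "purity",
            "r": "read_count",
            "c": "classified_fraction",
        }

    def test_contig_units_use_stricter_purity(self):
        thr = FilterThresholds()
        cell = vec("cell", {1: 0.85, 2: 0.15}, batch="single_cell")
        contig_lo = vec("ctg1", {1: 0.85, 2: 0.15}, batch="contig")
        contig_hi = vec("ctg2", {1: 0.95, 2: 0.05}, batch="contig")
        retained, _ = filter_vectors([cell, contig_lo, contig_hi], thr)
        assert {v.unit_id for v in retained} == {"cell", "ctg2"}

    def test_retention_monotone_in_each_threshold(self):
        rng = np.random.default_rng(0)
        vectors = []
        for i in range(100):
            a = rng.dirichlet([1, 1, 1])
            vectors.append(vec(f"u{i}", dict(enumerate(a)), reads=int(rng.integers(10, 5000))))
        prev = None
        for purity in np.linspace(0, 1, 11):
            thr = FilterThresholds(min_reads=0, min_classified_fraction=0, min_purity=purity)
            n = len(filter_vectors(vectors, thr)[0])
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for reads in [0, 100, 1000, 2000, 5000]:
            thr = FilterThresholds(min_reads=reads, min_classified_fraction=0, min_purity=0)
            n = len(filter_vectors(vectors, thr)[0])
            if prev is not None:
                assert n <= prev
            prev = n


class TestMatrix:
    def test_disjoint_taxa_make_identity_blocks(self):
        m = assemble_matrix([vec("a", {1: 1.0}), vec("b", {2: 1.0})])
        assert m.taxids == [1, 2]
        np.testing.assert_array_equal(m.X, np.eye(2))

    def test_row_sums_are_one_over_union(self):
        m = assemble_matrix(
            [vec("a", {1: 0.5, 2: 0.5}), vec("b", {2: 1.0}), vec("c", {3: 1.0})]
        )
        np.testing.assert_allclose(m.X.sum(axis=1), 1.0)

    def test_reassembly_is_identical(self):
        vs = [vec("a", {1: 0.7, 2: 0.3}), vec("b", {2: 1.0})]
        m1, m2 = assemble_matrix(vs), assemble_matrix(vs)
        np.testing.assert_array_equal(m1.X, m2.X)
        assert m1.unit_ids == m2.unit_ids

    def test_rank_mismatch_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            assemble_matrix([vec("a", {1: 1.0}), vec("b", {1: 1.0}, rank="species")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assemble_matrix([])


def _one_hot_vectors(n_taxa=10, per_taxon=50, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    vectors, truth = [], {}
    for t in range(n_taxa):
        for i in range(per_taxon):
            uid = f"t{t}_u{i}"
            ab = {t: 1.0 - noise}
            if noise:
                other = int(rng.integers(0, n_taxa - 1))
                other += other >= t
                ab[other] = noise
            vectors.append(vec(uid, ab))
            truth[uid] = str(t)
    return vectors, truth


class TestClustering:
    def test_separable_populations_recovered_exactly(self):
        vectors, truth = _one_hot_vectors(10, 50, noise=0.1)
        cmap = embed_cluster(assemble_matrix(vectors), seed=0)
        assert cmap["cluster"].nunique() == 10
        true_labels = [truth[u] for u in cmap["unit_id"]]
        assert adjusted_rand_score(true_labels, cmap["cluster"]) == 1.0

    def test_same_seed_same_labels(self):
        vectors, _ = _one_hot_vectors(4, 20, noise=0.15, seed=1)
        m = assemble_matrix(vectors)
        c1 = embed_cluster(m, seed=7)
        c2 = embed_cluster(m, seed=7)
        pd.testing.assert_frame_equal(c1, c2)

    def test_identical_rows_collapse_to_one_cluster(self):
        vectors = [vec(f"u{i}", {1: 1.0}) for i in range(10)]
        cmap = embed_cluster(assemble_matrix(vectors), seed=0)
        assert cmap["cluster"].nunique() == 1

    def test_too_few_units_raise(self):
        with pytest.raises(ValueError):
            embed_cluster(assemble_matrix([vec("a", {1: 1.0})]))


class TestAnnotation:
    def test_dominant_taxon_and_cluster_mode(self):
        vectors = [
            vec("a", {1: 0.9, 2: 0.1}),
            vec("b", {1: 0.8, 2: 0.2}),
            vec("c", {2: 0.6, 1: 0.4}),
        ]
        cmap = pd.DataFrame(
            {"unit_id": ["a", "b", "c"], "batch": ["single_cell"] * 3,
             "x": 0.0, "y": 0.0, "cluster": [0, 0, 0]}
        )
        out = annotate(cmap, vectors)
        assert list(out["annotation"]) == ["1", "1", "2"]
        assert set(out["cluster_annotation"]) == {"1"}  # mode of {1,1,2}

    def test_tie_breaks_lexicographically_and_flags(self):
        vectors = [vec("a", {2: 0.5, 1: 0.5}), vec("b", {1: 1.0})]
        cmap = pd.DataFrame(
            {"unit_id": ["a", "b"], "batch": ["single_cell"] * 2,
             "x": 0.0, "y": 0.0, "cluster": [0, 1]}
        )
        out = annotate(cmap, vectors)
        assert out.loc[0, "annotation"] == "1"
        assert bool(out.loc[0, "tie"]) is True
        assert bool(out.loc[1, "tie"]) is False

    def test_names_resolved_through_taxonomy(self, toy_taxonomy):
        vectors = [vec("a", {10: 1.0}), vec("b", {11: 1.0})]
        cmap = pd.DataFrame(
            {"unit_id": ["a", "b"], "batch": ["single_cell"] * 2,
             "x": 0.0, "y": 0.0, "cluster": [0, 1]}
        )
        out = annotate(cmap, vectors, toy_taxonomy)
        assert list(out["annotation"]) == ["GenusA", "GenusB"]


class TestContigIntegration:
    def test_contig_purity_filter_and_row_count(self):
        cells = [vec(f"c{i}", {1: 1.0}) for i in range(100)]
        contigs = [vec(f"g{i}", {1: 0.95, 2: 0.05}, batch="contig") for i in range(30)]
        contigs += [vec(f"bad{i}", {1: 0.85, 2: 0.15}, batch="contig") for i in range(10)]
        m = integrate_contigs(cells, contigs, contig_min_purity=0.9)
        assert m.X.shape[0] == 130
        assert m.batches.count("contig") == 30

    def test_no_contigs_pass_equals_cells_only(self):
        cells = [vec(f"c{i}", {1: 1.0}) for i in range(5)]
        contigs = [vec("g", {1: 0.5, 2: 0.5}, batch="contig")]
        m = integrate_contigs(cells, contigs)
        np.testing.assert_array_equal(m.X, assemble_matrix(cells).X)

    def test_rank_mismatch_rejected(self):
        with pytest.raises(ValueError):
            integrate_contigs([vec("a", {1: 1.0})], [vec("b", {1: 1.0}, rank="species")])


class TestSubcluster:
    def test_two_species_within_one_genus_separate(self):
        species_vectors = []
        ids = []
        for s, taxid in enumerate([100, 101]):
            for i in range(30):
                uid = f"s{s}_u{i}"
                ids.append(uid)
                species_vectors.append(vec(uid, {taxid: 0.9, 100 + (1 - s): 0.1},
                                           rank="species"))
        out = subcluster(ids, species_vectors, seed=0)
        assert out["cluster"].nunique() == 2
        truth = [uid.split("_")[0] for uid in out["unit_id"]]
        assert adjusted_rand_score(truth, out["cluster"]) == 1.0

    def test_single_species_cluster_is_one_subcluster(self):
        vs = [vec(f"u{i}", {100: 1.0}, rank="species") for i in range(8)]
        out = subcluster([v.unit_id for v in vs], vs, seed=0)
        assert out["cluster"].nunique() == 1

    def test_too_small_subset_raises(self):
        vs = [vec("u0", {100: 1.0}, rank="species")]
        with pytest.raises(ValueError):
            subcluster(["u0"], vs)


class TestBenchmark:
    def test_hand_counted_accuracy(self):
        vectors, truth = _one_hot_vectors(2, 2)
        cmap = pd.DataFrame(
            {
                "unit_id": [v.unit_id for v in vectors],
                "batch": "single_cell",
                "x": 0.0,
                "y": 0.0,
                "cluster": [0, 0, 1, 1],
                "annotation": ["0", "0", "1", "0"],  # one wrong of four
            }
        )
        report = evaluate_benchmark(cmap, vectors, truth)
        assert report.identification_accuracy == 0.75
        assert report.retained_units == 4

    def test_retention_curve_monotone_non_increasing(self):
        rng = np.random.default_rng(3)
        vectors = []
        for i in range(200):
            a = float(rng.uniform(0.4, 1.0))
            vectors.append(vec(f"u{i}", {1: a, 2: 1 - a}))
        cmap = pd.DataFrame(
            {"unit_id": [v.unit_id for v in vectors], "batch": "single_cell",
             "x": 0.0, "y": 0.0, "cluster": 0, "annotation": "1"}
        )
        truth = {v.unit_id: "1" for v in vectors}
        report = evaluate_benchmark(cmap, vectors, truth,
                                    threshold_grid=np.arange(0.5, 1.0, 0.01))
        retained = report.retention_curve["retained"].to_numpy()
        assert (np.diff(retained) <= 0).all()

    def test_missing_truth_raises(self):
        vectors, truth = _one_hot_vectors(2, 1)
        cmap = pd.DataFrame(
            {"unit_id": [v.unit_id for v in vectors], "batch": "single_cell",
             "x": 0.0, "y": 0.0, "cluster": [0, 1], "annotation": ["0", "1"]}
        )
        with pytest.raises(KeyError):
            evaluate_benchmark(cmap, vectors, {})
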