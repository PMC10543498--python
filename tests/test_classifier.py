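"""K-mer LCA classifier: index semantics, path scoring vs a brute-force
oracle, rank redistribution, and external report import."""

import numpy as np
import pytest

from microatlas import (
    SimulationConfig,
    build_index,
    classify_group,
    classify_read_pair,
    import_external_report,
    iter_barcode_groups,
    redistribute_to_rank,
    simulate_barcode_group,
)
from microatlas._seq import revcomp
from microatlas.classify import TaxonCounts
from microatlas.simulate import ReadPair
from microatlas.taxonomy import GenomeRecord, RANKS, ReferenceSet, Taxonomy, TaxonomyNode


# -- independent oracle ----------------------------------------------------


def oracle_classify(seq1, seq2, refset, k):
    """Brute force: enumerate k-mers as strings, map each to the LCA of
    the genomes containing it, then score every root-to-leaf path."""
    tax = refset.taxonomy
    kmer_sources = {}
    for g in refset:
        for seq in g.sequences:
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k]
                if set(w) - set("ACGT"):
                    continue
                key = min(w, revcomp(w))
                kmer_sources.setdefault(key, set()).add(g.taxid)
    kmer_taxid = {}
    for w, taxids in kmer_sources.items():
        taxids = list(taxids)
        t = taxids[0]
        for other in taxids[1:]:
            t = tax.lca(t, other)
        kmer_taxid[w] = t
    hits = []
    for seq in (seq1, seq2):
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) - set("ACGT"):
                continue
            t = kmer_taxid.get(min(w, revcomp(w)))
            if t is not None:
                hits.append(t)
    if not hits:
        return None
    counts = {}
    for t in hits:
        counts[t] = counts.get(t, 0) + 1
    best_score, best = -1, []
    for cand in counts:
        anc = set(tax.ancestors(cand))
        score = sum(c for t, c in counts.items() if t in anc)
        if score > best_score:
            best_score, best = score, [cand]
        elif score == best_score:
            best.append(cand)
    t = best[0]
    for other in best[1:]:
        t = tax.lca(t, other)
    return t


@pytest.fixture(scope="module")
def shared_region_refset():
    """Two same-genus species sharing a long identical block, plus an
    unrelated genus — exercises LCA entries and path-score ties."""
    from microatlas import generate_genome, mutate_genome

    tax = Taxonomy(
        [
            TaxonomyNode(1, 1, "root", "root"),
            TaxonomyNode(2, 1, "superkingdom", "Bacteria"),
            TaxonomyNode(10, 2, "genus", "GenusA"),
            TaxonomyNode(11, 2, "genus", "GenusB"),
            TaxonomyNode(100, 10, "species", "spA1"),
            TaxonomyNode(101, 10, "species", "spA2"),
            TaxonomyNode(110, 11, "species", "spB1"),
        ]
    )
    shared = generate_genome(4000, seed=(21, 0)).sequences[0]
    uniq1 = generate_genome(4000, seed=(21, 1)).sequences[0]
    uniq2 = generate_genome(4000, seed=(21, 2)).sequences[0]
    other = generate_genome(8000, seed=(21, 3)).sequences[0]
    return ReferenceSet(
        [
            GenomeRecord("spA1", 100, [uniq1 + shared]),
            GenomeRecord("spA2", 101, [uniq2 + shared]),
            GenomeRecord("spB1", 110, [other]),
        ],
        tax,
    )


class TestIndex:
    def test_unique_kmer_maps_to_species(self, shared_region_refset):
        idx = build_index(shared_region_refset, k=21)
        seq = shared_region_refset["spA1"].sequences[0]
        assert idx.lookup_kmer(seq[100:121]) == 100

    def test_shared_kmer_maps_to_genus_lca(self, shared_region_refset):
        idx = build_index(shared_region_refset, k=21)
        seq = shared_region_refset["spA1"].sequences[0]
        shared_kmer = seq[4000 + 500 : 4000 + 521]  # inside the shared block
        assert idx.lookup_kmer(shared_kmer) == 10

    def test_canonicalization(self, shared_region_refset):
        idx = build_index(shared_region_refset, k=21)
        seq = shared_region_refset["spB1"].sequences[0]
        w = seq[10:31]
        assert idx.lookup_kmer(w) == idx.lookup_kmer(revcomp(w)) == 110

    def test_k_validation(self, shared_region_refset):
        with pytest.raises(ValueError):
            build_index(shared_region_refset, k=20)
        with pytest.raises(ValueError):
            build_index(shared_region_refset, k=9)

    def test_adding_a_genome_never_deepens_entries(self, shared_region_refset):
        """LCA of an existing k-mer can only move rootward."""
        rs = shared_region_refset
        partial = ReferenceSet([rs["spA1"], rs["spB1"]], rs.taxonomy)
        idx_small = build_index(partial, k=21)
        idx_full = build_index(rs, k=21)
        tax = rs.taxonomy
        pos = {c: t for c, t in zip(idx_full.codes, idx_full.taxids)}
        for code, t_small in zip(idx_small.codes, idx_small.taxids):
            t_full = pos[code]
            # t_full must be an ancestor-or-self of t_small
            assert t_full in tax.ancestors(int(t_small))


class TestClassifyReads:
    def test_read_from_unique_region(self, shared_region_refset):
        idx = build_index(shared_region_refset, k=21)
        seq = shared_region_refset["spA1"].sequences[0]
        pair = ReadPair("r", seq[200:350], "I" * 150, revcomp(seq[350:500]), "I" * 150)
        assert classify_read_pair(pair, idx) == 100

    def test_read_from_shared_region_goes_to_genus(self, shared_region_refset):
        idx = build_index(shared_region_refset, k=21)
        seq = shared_region_refset["spA1"].sequences[0]
        s = seq[4200:4350]
        pair = ReadPair("r", s, "I" * 150, revcomp(seq[4400:4550]), "I" * 150)
        assert classify_read_pair(pair, idx) == 10

    def test_foreign_read_unclassified(self, shared_region_refset):
        from microatlas import generate_genome

        idx = build_index(shared_region_refset, k=21)
        foreign = generate_genome(400, seed=99).sequences[0]
        pair = ReadPair("r", foreign[:150], "I" * 150, foreign[150:300], "I" * 150)
        assert classify_read_pair(pair, idx) is None

    def test_oracle_equivalence_on_simulated_reads(self, shared_region_refset):
        """classify_read_pair matches the brute-force k-mer/path oracle on
        every read of a small simulated dataset."""
        idx = build_index(shared_region_refset, k=21)
        cfg = SimulationConfig(
            n_species=3, barcodes_per_species=2,
            reads_per_barcode_range=(60, 100), contamination_range=(0.0, 0.4),
        )
        n_checked = 0
        for g in iter_barcode_groups(shared_region_refset, cfg, seed=17):
            for rp in g.read_pairs:
                assert classify_read_pair(rp, idx) == oracle_classify(
                    rp.seq1, rp.seq2, shared_region_refset, 21
                )
                n_checked += 1
        assert n_checked >= 300

    def test_group_classification_conserves_reads(self, shared_region_refset):
        idx = build_index(shared_region_refset, k=21)
        cfg = SimulationConfig(n_species=3)
        g = simulate_barcode_group(
            shared_region_refset, "spA1", cfg, seed=3, n_pairs=500, contamination=0.25
        )
        tc = classify_group(g, idx)
        assert tc.classified + tc.unclassified == tc.total == 500
        # reads classified outside genus A match the truth count of
        # reads actually drawn from the other genus
        genus_a = {10, 100, 101}
        foreign = sum(c for t, c in tc.counts.items() if t not in genus_a)
        truth_foreign = sum(rp.truth.source_genome == "spB1" for rp in g.read_pairs)
        assert foreign == truth_foreign

    def test_empty_group(self, shared_region_refset):
        from microatlas.simulate import BarcodeGroup

        idx = build_index(shared_region_refset, k=21)
        tc = classify_group(BarcodeGroup(barcode_id="x"), idx)
        assert tc.total == tc.unclassified == 0 and tc.counts == {}


class TestRedistribution:
    def test_lift_only(self, toy_taxonomy):
        tc = TaxonCounts("b", {100: 300, 101: 100})
        ra = redistribute_to_rank(tc, toy_taxonomy, "genus")
        assert ra.counts == {10: 400.0}

    def test_proportional_split_hand_example(self, toy_taxonomy):
        """100 reads at the superkingdom split 300:100 across the two
        genera -> 75:25 added to the lifted counts."""
        tc = TaxonCounts("b", {100: 300, 110: 100, 2: 100})
        ra = redistribute_to_rank(tc, toy_taxonomy, "genus")
        assert ra.counts == {10: 375.0, 11: 125.0}

    def test_uniform_fallback_when_no_lifted_counts(self, toy_taxonomy):
        tc = TaxonCounts("b", {1: 50})
        ra = redistribute_to_rank(tc, toy_taxonomy, "genus")
        assert ra.counts == {10: 25.0, 11: 25.0}

    def test_conservation_on_random_instances(self, toy_taxonomy):
        """lifted + redistributed + dropped == classified, over random
        toy trees and counts."""
        import random

        rng = random.Random(5)
        for trial in range(200):
            n = rng.randint(3, 40)
            nodes = [TaxonomyNode(1, 1, "root", "root")]
            rank_of = {1: 0}
            for taxid in range(2, n + 1):
                parent = rng.choice([nd.taxid for nd in nodes])
                r = rng.randint(min(rank_of[parent] + 1, len(RANKS) - 1), len(RANKS) - 1)
                rank_of[taxid] = r
                nodes.append(TaxonomyNode(taxid, parent, RANKS[r], f"n{taxid}"))
            tax = Taxonomy(nodes)
            counts = {
                t: rng.randint(0, 50)
                for t in rng.sample(list(tax.nodes), k=rng.randint(1, n))
            }
            tc = TaxonCounts("b", counts)
            ra = redistribute_to_rank(tc, tax, "genus")
            # dropped reads: on paths without a genus node, in both directions
            dropped = 0
            for t, c in counts.items():
                if rank_of[t] > 6 or rank_of[t] == 6:
                    if tax.ancestor_at_rank(t, "genus") is None:
                        dropped += c
                else:
                    if not tax.descendants_at_rank(t, "genus"):
                        dropped += c
            assert ra.classified_at_rank == pytest.approx(tc.classified - dropped)
            assert all(v >= 0 for v in ra.counts.values())

    def test_negative_counts_rejected(self, toy_taxonomy):
        with pytest.raises(ValueError):
            redistribute_to_rank(TaxonCounts("b", {100: -1}), toy_taxonomy, "genus")


class TestExternalReports:
    def test_kraken2_report_genus_rows(self, tmp_path):
        path = tmp_path / "report.txt"
        path.write_text(
            "90.00\t90\t0\tG\t10\t  GenusA\n"
            "10.00\t10\t10\tG\t11\t  GenusB\n"
            "5.00\t5\t5\tS\t100\t    spA1\n"
        )
        ra = import_external_report(path, "kraken2_report", rank="genus")
        assert ra.counts == {10: 90.0, 11: 10.0}

    def test_empty_report(self, tmp_path):
        path = tmp_path / "report.txt"
        path.write_text("")
        ra = import_external_report(path, "kraken2_report")
        assert ra.counts == {}

    def test_malformed_report_names_line(self, tmp_path):
        path = tmp_path / "report.txt"
        path.write_text("90.00\t90\t0\tG\t10\t  GenusA\nbadline\n")
        with pytest.raises(ValueError, match=":2"):
            import_external_report(path, "kraken2_report")

    def test_bracken_counts_from_new_est_reads(self, tmp_path):
        path = tmp_path / "bracken.tsv"
        path.write_text(
            "name\ttaxonomy_id\ttaxonomy_lvl\tkraken_assigned_reads\tadded_reads\t"
            "new_est_reads\tfraction_total_reads\n"
            "GenusA\t10\tG\t80\t15\t95\t0.95\n"
            "GenusB\t11\tG\t5\t0\t5\t0.05\n"
        )
        ra = import_external_report(path, "bracken_tsv", rank="genus")
        assert ra.counts == {10: 95.0, 11: 5.0}

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            import_external_report(tmp_path / "x", "metaphlan")
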