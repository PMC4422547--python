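"""Cluster-rule tests against a brute-force chain-assembly oracle."""

import numpy as np
import pytest

from rgene_atlas.annotation_io import GeneModel, GenomeAnnotation
from rgene_atlas.architecture_classifier import ArchitectureCall
from rgene_atlas.cluster_finder import (
    ClusterRule,
    chromosome_summary,
    find_clusters,
    label_homogeneity,
)

from conftest import make_genes

RULE = ClusterRule()


def brute_force_clusters(annotation, focal_ids, rule):
    """Naive oracle: test every consecutive focal pair, assemble chains.

    Independent of the implementation under test: scans the full per-sequence
    gene list, counts intervening genes by explicit list slicing, and chains
    greedily.
    """
    focal = set(focal_ids)
    out_clusters, out_singletons, out_unmapped = [], [], []
    seqs = sorted({annotation.gene(g).seq_id for g in focal})
    for seq_id in seqs:
        ordered = annotation.genes_on(seq_id)
        focal_genes = [g for g in ordered if g.gene_id in focal]
        if focal_genes and not focal_genes[0].anchored:
            out_unmapped.extend(g.gene_id for g in focal_genes)
            continue
        chains = []
        for g in focal_genes:
            if not chains:
                chains.append([g])
                continue
            prev = chains[-1][-1]
            between = ordered[ordered.index(prev) + 1:ordered.index(g)]
            n_intervening = sum(b.gene_id not in focal for b in between)
            gap = max(0, g.start - prev.end)
            if gap < rule.max_gap_bp and n_intervening <= rule.max_intervening:
                chains[-1].append(g)
            else:
                chains.append([g])
        for chain in chains:
            if len(chain) >= rule.min_members:
                out_clusters.append([g.gene_id for g in chain])
            else:
                out_singletons.extend(g.gene_id for g in chain)
    return (sorted(map(tuple, out_clusters)), sorted(out_singletons),
            sorted(out_unmapped))


def random_genome(rng, max_genes=200, max_focal=30, n_seqs=2):
    """Random small annotation with overlapping/nested genes allowed."""
    genes, focal = [], []
    gid = 0
    for s in range(n_seqs):
        n = int(rng.integers(2, max_genes // n_seqs + 1))
        starts = rng.integers(1, 2_000_000, size=n)
        lengths = rng.integers(200, 50_000, size=n)
        for st_, ln in zip(starts, lengths):
            gid += 1
            genes.append(GeneModel(f"r{gid}", f"chr{s+1}", int(st_),
                                   int(st_ + ln), anchored=True))
    ann = GenomeAnnotation(genes)
    ids = [g.gene_id for g in genes]
    k = int(rng.integers(1, min(max_focal, len(ids)) + 1))
    focal = list(rng.choice(ids, size=k, replace=False))
    return ann, focal


def assert_matches_oracle(ann, focal, rule):
    clusters, singletons, unmapped = find_clusters(ann, focal, rule)
    got = (sorted(tuple(c.members) for c in clusters), sorted(singletons),
           sorted(unmapped))
    assert got == brute_force_clusters(ann, focal, rule)


class TestRuleBoundaries:
    def test_gap_beyond_cap_gives_singletons(self):
        ann = GenomeAnnotation(make_genes([1_000, 303_000]))  # gap 300 kb
        clusters, singletons, _ = find_clusters(ann, ["g1", "g2"], RULE)
        assert clusters == [] and singletons == ["g1", "g2"]

    def test_nearby_pair_clusters(self):
        # gap 50 kb, 3 intervening background genes
        genes = make_genes([1_000, 10_000, 20_000, 30_000, 53_000])
        ann = GenomeAnnotation(genes)
        clusters, singletons, _ = find_clusters(ann, ["g1", "g5"], RULE)
        assert len(clusters) == 1 and clusters[0].members == ["g1", "g5"]
        assert singletons == []

    def test_gap_exactly_at_cap_does_not_link(self):
        # g1 ends at 2,999; g2 starts at 202,999: edge gap exactly 200,000,
        # and the rule says strictly closer than
        ann = GenomeAnnotation(make_genes([1_000, 202_999]))
        assert ann.gene("g2").start - ann.gene("g1").end == 200_000
        clusters, singletons, _ = find_clusters(ann, ["g1", "g2"], RULE)
        assert clusters == [] and len(singletons) == 2

    def test_gap_one_below_cap_links(self):
        ann = GenomeAnnotation(make_genes([1_000, 202_998]))  # gap 199,999
        clusters, _, _ = find_clusters(ann, ["g1", "g2"], RULE)
        assert len(clusters) == 1

    def test_intervening_exactly_at_cap_links(self):
        positions = [1_000] + [5_000 + 3_000 * i for i in range(8)] + [40_000]
        ann = GenomeAnnotation(make_genes(positions))
        clusters, _, _ = find_clusters(ann, ["g1", "g10"], RULE)
        assert len(clusters) == 1  # 8 intervening genes: 'no more than eight'

    def test_nine_intervening_does_not_link(self):
        positions = [1_000] + [5_000 + 3_000 * i for i in range(9)] + [40_000]
        ann = GenomeAnnotation(make_genes(positions))
        clusters, singletons, _ = find_clusters(ann, ["g1", "g11"], RULE)
        assert clusters == [] and len(singletons) == 2

    def test_overlapping_focal_genes_have_zero_gap(self):
        genes = [GeneModel("a", "chr1", 1_000, 9_000, anchored=True),
                 GeneModel("b", "chr1", 5_000, 12_000, anchored=True)]
        clusters, _, _ = find_clusters(GenomeAnnotation(genes), ["a", "b"], RULE)
        assert len(clusters) == 1


class TestChaining:
    def test_chain_can_exceed_total_span(self):
        # 10 pairwise-linked genes spanning far more than the distance cap
        positions = [1_000 + i * 150_000 for i in range(10)]
        ann = GenomeAnnotation(make_genes(positions))
        clusters, _, _ = find_clusters(ann, [f"g{i+1}" for i in range(10)], RULE)
        assert len(clusters) == 1 and clusters[0].size == 10
        assert clusters[0].span_end - clusters[0].span_start > RULE.max_gap_bp

    def test_unanchored_focal_reported_unmapped(self):
        genes = make_genes([1_000, 50_000]) + [
            GeneModel("s1", "scaffold_1", 100, 900, anchored=False)]
        clusters, singletons, unmapped = find_clusters(
            GenomeAnnotation(genes), ["g1", "g2", "s1"], RULE)
        assert unmapped == ["s1"] and len(clusters) == 1

    def test_unknown_focal_id_fatal(self):
        ann = GenomeAnnotation(make_genes([1_000]))
        with pytest.raises(KeyError):
            find_clusters(ann, ["nope"], RULE)

    def test_partition_invariant(self, rng):
        for _ in range(50):
            ann, focal = random_genome(rng)
            clusters, singletons, unmapped = find_clusters(ann, focal, RULE)
            n_clustered = sum(c.size for c in clusters)
            assert n_clustered + len(singletons) + len(unmapped) == len(focal)
            assert all(c.size >= RULE.min_members for c in clusters)

    def test_oracle_equivalence_on_random_genomes(self, rng):
        for _ in range(300):
            ann, focal = random_genome(rng)
            rule = ClusterRule(
                max_gap_bp=int(rng.choice([50_000, 200_000, 500_000])),
                max_intervening=int(rng.choice([0, 2, 8])),
            )
            assert_matches_oracle(ann, focal, rule)

    def test_rule_monotonicity(self, rng):
        """Enlarging either cap never shrinks clustering."""
        for _ in range(30):
            ann, focal = random_genome(rng)
            base = ClusterRule(max_gap_bp=100_000, max_intervening=3)
            wider = ClusterRule(max_gap_bp=300_000, max_intervening=6)
            c1, s1, _ = find_clusters(ann, focal, base)
            c2, s2, _ = find_clusters(ann, focal, wider)
            assert sum(c.size for c in c2) >= sum(c.size for c in c1)
            assert len(s2) <= len(s1)


def _call(gene_id, family, letter="X"):
    return ArchitectureCall(gene_id=gene_id, nbs_status="full",
                            letter_code=letter, family=family)


class TestHomogeneity:
    def test_same_family_is_homogeneous(self):
        from rgene_atlas.cluster_finder import GeneCluster

        c = GeneCluster("K", "chr1", ["a", "b", "c"], 1, 100)
        calls = {"a": _call("a", "TNL_type"), "b": _call("b", "TNL_type"),
                 "c": _call("c", "TNL_type")}
        assert label_homogeneity(c, calls).homogeneous_by_family is True

    def test_mixed_families_heterogeneous(self):
        from rgene_atlas.cluster_finder import GeneCluster

        c = GeneCluster("K", "chr1", ["a", "b"], 1, 100)
        calls = {"a": _call("a", "TNL_type"), "b": _call("b", "CNL_type")}
        assert label_homogeneity(c, calls).homogeneous_by_family is False

    def test_partial_members_do_not_break_homogeneity(self):
        from rgene_atlas.cluster_finder import GeneCluster

        c = GeneCluster("K", "chr1", ["a", "b", "p"], 1, 100)
        calls = {"a": _call("a", "CNL_type"), "b": _call("b", "CNL_type"),
                 "p": _call("p", "partial", "P")}
        out = label_homogeneity(c, calls)
        assert out.homogeneous_by_family is True
        assert out.partial_member_count == 1

    def test_clade_homogeneity_requires_map(self):
        from rgene_atlas.cluster_finder import GeneCluster

        c = GeneCluster("K", "chr1", ["a", "b"], 1, 100)
        calls = {"a": _call("a", "CNL_type"), "b": _call("b", "CNL_type")}
        assert label_homogeneity(c, calls).homogeneous_by_clade is None
        out = label_homogeneity(c, calls, {"a": "CC-1a", "b": "CC-1a"})
        assert out.homogeneous_by_clade is True
        out = label_homogeneity(c, calls, {"a": "CC-1a", "b": "CC-2"})
        assert out.homogeneous_by_clade is False


class TestChromosomeSummary:
    def test_counts_single_chromosome(self):
        genes = make_genes([1_000, 50_000, 900_000])
        ann = GenomeAnnotation(genes)
        clusters, singletons, _ = find_clusters(ann, ["g1", "g2", "g3"], RULE)
        table = chromosome_summary(clusters, singletons, ann)
        row = table.iloc[0]
        assert (row.n_genes, row.n_clusters, row.n_singletons) == (3, 1, 1)
        assert row.cluster_sizes == [2]

    def test_empty_input_gives_empty_table(self):
        ann = GenomeAnnotation(make_genes([1_000]))
        assert chromosome_summary([], [], ann).empty

    def test_totals_match_global_counts(self, small_synth):
        from rgene_atlas.annotation_io import read_gene_models

        cfg, paths, truth = small_synth
        ann = read_gene_models(paths.gff, [f"chr{i+1}" for i in range(cfg.n_chromosomes)])
        focal = list(truth["codes"])
        clusters, singletons, _ = find_clusters(ann, focal, RULE)
        table = chromosome_summary(clusters, singletons, ann)
        assert table.n_clusters.sum() == len(clusters)
        assert table.n_singletons.sum() == len(singletons)
        assert table.n_genes.sum() == sum(c.size for c in clusters) + len(singletons)
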