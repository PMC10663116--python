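"""Homolog pairing, chaining, depth, tandem arrays, duplicate classes."""

import numpy as np
import pytest

from paleodup.genome_io import GeneModel, Genome
from paleodup.simulate import SimulationConfig, WGDSpec, random_cds, simulate_genome
from paleodup.synteny import (
    AnchorPair,
    chain_anchors,
    classify_duplicates,
    detect_tandem,
    families_from_pairs,
    find_homolog_pairs,
    remove_tandem_anchors,
    syntenic_depth,
)

from _oracles import best_chain_bruteforce


def _toy_genome(n_chrom=2, n_genes=10, seed=0, shared_cds=True) -> Genome:
    """Chromosomes carrying the same gene order (every gene duplicated)."""
    rng = np.random.default_rng(seed)
    cds_list = [random_cds(80, rng) for _ in range(n_genes)]
    genes = []
    for c in range(n_chrom):
        for i in range(n_genes):
            cds = cds_list[i] if shared_cds else random_cds(80, rng)
            genes.append(
                GeneModel(f"c{c}g{i}", f"chr{c}", 100 + 500 * i, 340 + 500 * i, "+", cds=cds)
            )
    return Genome(
        name="toy",
        chrom_lengths={f"chr{c}": 500 * n_genes + 200 for c in range(n_chrom)},
        genes=genes,
    )


def _anchor(ra, rb, score=1.0, ca="A", cb="B", ga=None, gb=None):
    return AnchorPair(
        gene_a=ga or f"a{ra}", gene_b=gb or f"b{rb}",
        score=score, rank_a=ra, rank_b=rb, chrom_a=ca, chrom_b=cb,
    )


class TestHomologPairs:
    def test_duplicated_proteome_pairs_each_copy(self):
        g = _toy_genome()
        pairs = find_homolog_pairs(g, top_n=1)
        assert len(pairs) == 10
        for p in pairs:
            assert p.gene_a != p.gene_b
            assert p.gene_a.split("g")[1] == p.gene_b.split("g")[1]
            assert p.score == pytest.approx(1.0)

    def test_unrelated_sequences_yield_nothing(self):
        g = _toy_genome(shared_cds=False)
        assert find_homolog_pairs(g) == []

    def test_cross_genome_comparison(self):
        g = _toy_genome()
        other = _toy_genome()
        other.name = "other"
        pairs = find_homolog_pairs(g, other, top_n=1)
        # every gene finds its counterpart(s) across genomes
        assert len(pairs) >= 20


class TestChaining:
    def test_perfectly_collinear_run_is_one_block(self):
        anchors = [_anchor(i, i) for i in range(5)]
        blocks = chain_anchors(anchors, min_block=5)
        assert len(blocks) == 1
        assert len(blocks[0]) == 5
        assert blocks[0].orientation == "same"

    def test_min_block_threshold(self):
        anchors = [_anchor(i, i) for i in range(4)]
        assert chain_anchors(anchors, min_block=5) == []

    def test_inverted_blocks_detected(self):
        anchors = [_anchor(i, 10 - i) for i in range(5)]
        blocks = chain_anchors(anchors, min_block=5)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_anchor_used_in_at_most_one_block(self):
        anchors = [_anchor(i, i) for i in range(12)]
        blocks = chain_anchors(anchors, min_block=3)
        seen = [id(a) for b in blocks for a in b.anchors]
        assert len(seen) == len(set(seen))

    def test_block_monotonicity_invariant(self):
        rng = np.random.default_rng(0)
        anchors = [
            _anchor(int(ra), int(rb))
            for ra, rb in zip(rng.integers(0, 40, 60), rng.integers(0, 40, 60))
        ]
        for b in chain_anchors(anchors, min_block=2):
            ra = [a.rank_a for a in b.anchors]
            rb = [a.rank_b for a in b.anchors]
            assert ra == sorted(ra) and len(set(ra)) == len(ra)
            if b.orientation == "same":
                assert rb == sorted(rb) and len(set(rb)) == len(rb)
            else:
                assert rb == sorted(rb, reverse=True)

    def test_best_chain_matches_exhaustive_search(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 9))
            tuples = [
                (int(rng.integers(0, 12)), int(rng.integers(0, 12)),
                 float(rng.integers(1, 6)))
                for _ in range(n)
            ]
            anchors = [
                _anchor(ra, rb, s, ga=f"a{i}", gb=f"b{i}")
                for i, (ra, rb, s) in enumerate(tuples)
            ]
            blocks = chain_anchors(anchors, min_block=1, max_gap=4, gap_penalty=0.5)
            got = max(b.chain_score for b in blocks)
            want = best_chain_bruteforce(tuples, max_gap=4, gap_penalty=0.5)
            assert got == pytest.approx(want)

    def test_remove_tandem_anchors_only_drops_near_diagonal_self_pairs(self):
        keep = _anchor(3, 20, ca="A", cb="A")
        drop = _anchor(3, 4, ca="A", cb="A")
        cross = _anchor(3, 4, ca="A", cb="B")
        assert remove_tandem_anchors([keep, drop, cross]) == [keep, cross]


class TestDepth:
    def test_doubled_genome_has_modal_depth_two(self):
        cfg = SimulationConfig(
            seed=0, n_chroms=1, genes_per_chrom=40,
            wgd_events=(WGDSpec(0.3, 1.0),), tandem_rate=0.0,
            ortholog_divergence_ks=None, cds_length_codons=60,
            emit_sequences=False,
        )
        genome, truth = simulate_genome(cfg)
        blocks = chain_anchors(find_homolog_pairs(genome, truth.ancestor))
        profile = syntenic_depth(blocks, truth.ancestor)
        assert profile.modal_depth == 2
        assert sum(profile.depth_histogram.values()) == len(truth.ancestor.genes)

    def test_self_comparison_of_once_duplicated_genome_is_one_to_one(self):
        cfg = SimulationConfig(
            seed=1, n_chroms=1, genes_per_chrom=40,
            wgd_events=(WGDSpec(0.3, 1.0),), tandem_rate=0.0,
            ortholog_divergence_ks=None, cds_length_codons=60,
            emit_sequences=False,
        )
        genome, _ = simulate_genome(cfg)
        blocks = chain_anchors(remove_tandem_anchors(find_homolog_pairs(genome)))
        profile = syntenic_depth(blocks, genome)
        assert profile.modal_depth == 1

    def test_inverted_segments_recovered_as_inverted_blocks(self):
        cfg = SimulationConfig(
            seed=5, n_chroms=1, genes_per_chrom=80,
            wgd_events=(WGDSpec(0.3, 1.0),), tandem_rate=0.0,
            ortholog_divergence_ks=None, cds_length_codons=60,
            emit_sequences=False, inversions_per_chrom=2,
        )
        genome, _ = simulate_genome(cfg)
        pairs = find_homolog_pairs(genome)
        blocks = chain_anchors(remove_tandem_anchors(pairs), min_block=3)
        assert {b.orientation for b in blocks} == {"same", "inverted"}
        # chaining recovers every duplicate pair despite the rearrangement
        assert sum(len(b) for b in blocks) == len(pairs)

    def test_no_blocks_reports_zero(self):
        g = _toy_genome()
        profile = syntenic_depth([], g)
        assert profile.modal_depth == 0
        assert set(profile.coverage.values()) == {0}


class TestTandem:
    def test_adjacent_pair_forms_array(self):
        g = _toy_genome(n_chrom=1, n_genes=4)
        pairs = [_anchor(0, 1, ca="chr0", cb="chr0", ga="c0g0", gb="c0g1")]
        arrays = detect_tandem(g, pairs)
        assert len(arrays) == 1 and arrays[0].members == ["c0g0", "c0g1"]

    def test_distant_pair_rejected_by_threshold(self):
        g = _toy_genome(n_chrom=1, n_genes=8)
        pairs = [_anchor(0, 5, ca="chr0", cb="chr0", ga="c0g0", gb="c0g5")]
        assert detect_tandem(g, pairs, max_intervening=1) == []

    def test_transitive_closure_and_order_invariance(self):
        g = _toy_genome(n_chrom=1, n_genes=5)
        p01 = _anchor(0, 1, ca="chr0", cb="chr0", ga="c0g0", gb="c0g1")
        p12 = _anchor(1, 2, ca="chr0", cb="chr0", ga="c0g1", gb="c0g2")
        for order in ([p01, p12], [p12, p01]):
            arrays = detect_tandem(g, order)
            assert len(arrays) == 1
            assert arrays[0].members == ["c0g0", "c0g1", "c0g2"]


class TestClassification:
    def test_fully_syntenic_family_is_wgd(self):
        g = _toy_genome(n_chrom=4, n_genes=6)
        pairs = find_homolog_pairs(g)
        blocks = chain_anchors(pairs, min_block=3)
        fams = families_from_pairs(pairs, [x.gene_id for x in g.genes])
        labels = classify_duplicates(g, blocks, [], fams, min_copies=3)
        assert set(labels.values()) == {"WGD"}

    def test_adjacent_pair_without_synteny_is_td(self):
        g = _toy_genome(n_chrom=1, n_genes=2)
        pair = _anchor(0, 1, ca="chr0", cb="chr0", ga="c0g0", gb="c0g1")
        arrays = detect_tandem(g, [pair])
        fams = families_from_pairs([pair], [x.gene_id for x in g.genes])
        labels = classify_duplicates(g, [], arrays, fams)
        assert labels == {"c0g0": "TD", "c0g1": "TD"}

    def test_missing_family_entry_raises(self):
        g = _toy_genome(n_chrom=1, n_genes=2)
        with pytest.raises(KeyError):
            classify_duplicates(g, [], [], {"c0g0": "f0"})

    def test_lone_gene_is_singleton(self):
        g = _toy_genome(n_chrom=1, n_genes=3)
        fams = families_from_pairs([], [x.gene_id for x in g.genes])
        labels = classify_duplicates(g, [], [], fams)
        assert set(labels.values()) == {"singleton"}
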