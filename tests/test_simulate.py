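"""Synthetic-data generator: determinism, planted structure, divergence."""

import numpy as np
import pytest

from paleodup.ccm import phase_genes
from paleodup.kaks import CodonAlignment, ng86_pair
from paleodup.simulate import (
    EXPRESSION_PROFILES,
    SimulationConfig,
    WGDSpec,
    evolve_pair,
    make_pwm_from_consensus,
    plant_motifs,
    random_cds,
    simulate_ccm_family,
    simulate_expression,
    simulate_genome,
    simulate_promoters,
)


def small_config(**kw) -> SimulationConfig:
    base = dict(
        seed=0,
        n_chroms=2,
        genes_per_chrom=50,
        wgd_events=(WGDSpec(target_ks=0.5, retention=1.0),),
        tandem_rate=0.0,
        ortholog_divergence_ks=None,
        cds_length_codons=60,
        emit_sequences=False,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestGenomeSimulation:
    def test_full_retention_single_wgd(self):
        genome, truth = simulate_genome(small_config())
        assert len(genome.chrom_lengths) == 4
        assert len(genome.genes) == 200
        assert set(truth.origin.values()) == {"WGD1"}

    def test_same_seed_is_deterministic(self):
        cfg = small_config(tandem_rate=0.1, emit_sequences=True)
        g1, t1 = simulate_genome(cfg)
        g2, t2 = simulate_genome(cfg)
        assert [(g.gene_id, g.chrom, g.start, g.strand, g.cds) for g in g1.genes] == [
            (g.gene_id, g.chrom, g.start, g.strand, g.cds) for g in g2.genes
        ]
        assert t1.origin == t2.origin and t1.true_ks == t2.true_ks
        assert g1.sequences == g2.sequences

    def test_tandem_off_switch(self):
        _, truth = simulate_genome(small_config(tandem_rate=0.0))
        assert "TD" not in set(truth.origin.values())

    def test_retention_expectation_within_three_binomial_sd(self):
        rho = 0.5
        cfg = small_config(
            genes_per_chrom=300,
            wgd_events=(WGDSpec(target_ks=0.3, retention=rho),),
        )
        genome, _ = simulate_genome(cfg)
        n0 = 600
        expected = (1 + rho) * n0
        sd = (n0 * rho * (1 - rho)) ** 0.5
        assert abs(len(genome.genes) - expected) <= 3 * sd

    def test_planted_pair_ks_recovered_by_ng86(self):
        cfg = small_config(cds_length_codons=300)
        genome, truth = simulate_genome(cfg)
        cds = genome.cds_map()
        errs = []
        for (a, b), ks_true in list(truth.true_ks.items())[:40]:
            r = ng86_pair(CodonAlignment.from_aligned(cds[a], cds[b]))
            errs.append(r.Ks - ks_true)
        assert abs(np.mean(errs)) < 0.05

    def test_ancestor_snapshot_carries_one_copy_per_family(self):
        genome, truth = simulate_genome(small_config())
        assert truth.ancestor is not None
        assert len(truth.ancestor.genes) == 100
        fams = {g.gene_id.removeprefix("anc_") for g in truth.ancestor.genes}
        assert fams == set(truth.family.values())


class TestEvolvePair:
    def test_zero_divergence_is_identity(self):
        rng = np.random.default_rng(0)
        cds = random_cds(100, rng)
        assert evolve_pair(cds, 0.0, 0.0, rng) == cds

    @pytest.mark.parametrize("ks_true", [0.1, 0.5, 1.0, 1.5])
    def test_estimator_consistency_at_scale(self, ks_true):
        rng = np.random.default_rng(11)
        anc = random_cds(10000, rng)
        der = evolve_pair(anc, ks_true, 0.0, rng)
        r = ng86_pair(CodonAlignment.from_aligned(anc, der))
        assert abs(r.Ks - ks_true) <= 0.05

    def test_transition_bias_changes_spectrum(self):
        rng = np.random.default_rng(5)
        anc = random_cds(3000, rng)
        der = evolve_pair(anc, 0.3, 0.0, rng, transition_bias=20.0)
        ts = tv = 0
        for x, y in zip(anc, der):
            if x != y:
                if {x, y} in ({"A", "G"}, {"C", "T"}):
                    ts += 1
                else:
                    tv += 1
        assert ts > tv  # transitions dominate under strong bias

    def test_conservative_walk_preserves_site_structure(self):
        rng = np.random.default_rng(2)
        anc = random_cds(500, rng)
        der = evolve_pair(anc, 0.5, 0.3, rng, conservative_nonsyn=True)
        r = ng86_pair(CodonAlignment.from_aligned(anc, der))
        assert r.S == pytest.approx(500)  # one synonymous site per codon


class TestExpression:
    def test_planted_cam_induction_contract(self):
        cam = EXPRESSION_PROFILES["CAM-like"]
        assert cam[("D", "night")] / cam[("CK", "night")] >= 100

    def test_fixed_seed_identical_matrix(self):
        cfg = SimulationConfig(seed=4)
        truth = {"a": "C4-like", "b": "CAM-like", "c": "none"}
        m1 = simulate_expression(truth, cfg, np.random.default_rng(4))
        m2 = simulate_expression(truth, cfg, np.random.default_rng(4))
        assert np.array_equal(m1.values, m2.values)

    def test_none_class_passes_no_phasing_rule_at_planted_means(self):
        cfg = SimulationConfig(seed=1, expression_noise_cv=0.0)
        truth = {"flat": "none"}
        expr = simulate_expression(truth, cfg)
        assert phase_genes(expr)["flat"].label == "none"

    def test_family_recovery_single_seed(self):
        rng = np.random.default_rng(9)
        aln, ref, truth = simulate_ccm_family(rng)
        assert aln[ref][779] == "A"  # reference is the non-photosynthetic form
        assert sum(v == "C4-like" for v in truth.values()) >= 4


class TestMotifPlanting:
    def test_deterministic_rates_zero_and_one(self):
        rng = np.random.default_rng(0)
        proms = simulate_promoters([f"g{i}" for i in range(30)], 200, rng)
        pwm = make_pwm_from_consensus("ACGTACGTAC", "m1")
        module = {f"g{i}" for i in range(10)}
        out, planted, skipped = plant_motifs(proms, pwm, module, 1.0, 0.0, rng)
        assert set(planted) == module and not skipped
        for g, positions in planted.items():
            for pos in positions:
                assert 0 <= pos <= len(out[g]) - 10
                assert out[g][pos : pos + 10] == "ACGTACGTAC"

    def test_short_promoter_skipped(self):
        rng = np.random.default_rng(0)
        proms = {"g1": "ACGT"}
        pwm = make_pwm_from_consensus("ACGTACGTAC", "m1")
        out, planted, skipped = plant_motifs(proms, pwm, {"g1"}, 1.0, 0.0, rng)
        assert skipped == ["g1"] and planted == {} and out["g1"] == "ACGT"
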