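"""PWM scanning with exact p-values; Fisher/FDR enrichment statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleodup.genome_io import PWM
from paleodup.motifs import (
    _ScoreDistribution,
    _int_matrix,
    aggregate_clusters,
    bh_fdr,
    count_module_occurrences,
    fisher_enrichment,
    log_odds_matrix,
    module_enrichment,
    scan_promoters,
    scan_pwm,
)
from paleodup.simulate import make_pwm_from_consensus

from _oracles import fisher_greater_oracle, pwm_tail_oracle


def revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestScanning:
    def test_perfect_pwm_closed_form(self):
        # probability-1 PWM on ACGT: consensus scores 4*2 bits, p = (1/4)^4
        pwm = PWM("perfect", np.eye(4))
        hits = scan_pwm("TTACGTTT", pwm, pseudocount=0.0, p_threshold=0.004)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert plus[0].offset == 2
        assert plus[0].score == pytest.approx(8.0)
        assert plus[0].p_value == pytest.approx(1 / 256)

    def test_minus_strand_hit_on_reverse_complement(self):
        pwm = make_pwm_from_consensus("AACCGGTTAA", "m")
        site = "AACCGGTTAA"
        promoter = "T" * 30 + revcomp(site) + "T" * 30
        hits = scan_pwm(promoter, pwm, p_threshold=1e-4)
        assert any(h.strand == "-" and h.offset == 30 for h in hits)

    def test_strand_symmetry_of_scores(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        pwm = make_pwm_from_consensus("ACGTAC", "m")
        fwd = scan_pwm(seq, pwm, p_threshold=0.5)
        rev = scan_pwm(revcomp(seq), pwm, p_threshold=0.5)
        assert sorted((round(h.score, 6), h.strand) for h in fwd) == sorted(
            (round(h.score, 6), {"+": "-", "-": "+"}[h.strand]) for h in rev
        )

    def test_all_n_promoter_has_no_hits(self):
        pwm = make_pwm_from_consensus("ACGTACGT", "m")
        assert scan_pwm("N" * 50, pwm, p_threshold=1.0) == []

    def test_batch_scanner_matches_single_promoter_scan(self):
        rng = np.random.default_rng(1)
        proms = {
            f"g{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 150))
            for i in range(15)
        }
        pwm = make_pwm_from_consensus("ACGTAA", "m")
        bg = np.full(4, 0.25)
        batch = scan_promoters(proms, pwm, background=bg, p_threshold=1e-2)
        single = {
            g: len(scan_pwm(s, pwm, background=bg, p_threshold=1e-2))
            for g, s in proms.items()
        }
        assert batch == single

    @pytest.mark.parametrize("L", [2, 3, 5])
    def test_dp_tail_matches_enumeration(self, L):
        rng = np.random.default_rng(L)
        pwm = PWM("m", rng.integers(1, 30, size=(L, 4)).astype(float))
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        m = _int_matrix(log_odds_matrix(pwm, bg))
        dist = _ScoreDistribution(m, bg)
        for score, tail in pwm_tail_oracle(m.tolist(), bg).items():
            assert dist.p_value(score) == pytest.approx(tail, abs=1e-9)

    def test_zero_background_rejected(self):
        pwm = make_pwm_from_consensus("ACGT", "m")
        with pytest.raises(ValueError):
            scan_pwm("ACGTACGT", pwm, background=np.array([0.5, 0.5, 0.0, 0.0]))


class TestFisher:
    def test_textbook_table(self):
        odds, p = fisher_enrichment([[2, 0], [0, 2]])
        assert p == pytest.approx(1 / 6)
        assert odds == 25.0  # Haldane-corrected

    def test_null_table(self):
        odds, p = fisher_enrichment([[5, 5], [5, 5]])
        assert odds == pytest.approx(1.0)
        assert p >= 0.5

    def test_matches_exact_hypergeometric_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, 4))
            if a + b + c + d == 0:
                continue
            _, p = fisher_enrichment([[a, b], [c, d]])
            assert p == pytest.approx(
                float(fisher_greater_oracle(a, b, c, d)), abs=1e-12
            )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment([[0, 0], [0, 0]])


class TestFDR:
    def test_step_up_arithmetic(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.123]) == pytest.approx([0.123])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_monotone_in_sorted_p(self, pvals):
        qvals = bh_fdr(pvals)
        order = np.argsort(pvals)
        sorted_q = np.asarray(qvals)[order]
        assert (np.diff(sorted_q) >= -1e-12).all()
        assert all(0 <= q <= 1 for q in qvals)


class TestEnrichment:
    def test_membership_threshold_excludes_gene(self):
        hits = {"m1": {"g1", "g2"}}
        modules = {"g1": ("mod", 0.79), "g2": ("mod", 0.9), "g3": ("mod", 0.95)}
        counts = count_module_occurrences(hits, modules, "mod", {"g1", "g2", "g3"})
        assert counts["m1"] == (1, 2, 2, 3)

    def test_gene_counted_once_regardless_of_hits(self):
        hits = [
            type("H", (), {"motif_id": "m1", "gene_id": "g1"})() for _ in range(3)
        ]
        modules = {"g1": ("mod", 0.9), "g2": ("mod", 0.9)}
        counts = count_module_occurrences(hits, modules, "mod", {"g1", "g2"})
        assert counts["m1"][0] == 1

    def test_module_equal_to_background_scores_zero(self):
        hits = {"m1": {"g1", "g2"}}
        modules = {g: ("mod", 0.9) for g in ("g1", "g2", "g3")}
        counts = count_module_occurrences(hits, modules, "mod", {"g1", "g2", "g3"})
        results = module_enrichment(counts)
        assert results[0].enrichment_score == pytest.approx(0.0)
        assert not results[0].enriched

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            count_module_occurrences({"m1": set()}, {"g1": ("x", 0.9)}, "mod", {"g1"})

    def test_cluster_highlight_rule(self):
        def res(cluster, enriched):
            from paleodup.motifs import EnrichmentResult

            return EnrichmentResult(
                motif_id="m", cluster_id=cluster, genes_with_hit_module=1,
                module_size=10, genes_with_hit_background=1, background_size=100,
                odds_ratio=1, p_value=0.5, q_value=0.05 if enriched else 0.5,
                enrichment_score=0.0, enriched=enriched,
            )

        results = [res("A", True)] * 4 + [res("B", True)] * 3 + [res("C", False)] * 9
        assert aggregate_clusters(results) == {"A"}
        assert aggregate_clusters([]) == set()
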