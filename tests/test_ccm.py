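"""Expression phasing, diagnostic residues, C4/CAM classification."""

import numpy as np
import pytest

from paleodup.ccm import (
    classify_ccm,
    diagnose_residues,
    filter_expressed,
    map_reference_positions,
    phase_genes,
)
from paleodup.genome_io import ExpressionMatrix, Sample
from paleodup.simulate import SimulationConfig, simulate_ccm_family, simulate_expression


def matrix_from_means(
    means: dict[str, dict[tuple[str, str], float]], n_reps: int = 3
) -> ExpressionMatrix:
    """Noise-free matrix whose replicates equal the given group means."""
    samples = [
        Sample(c, t, r + 1)
        for c in ("CK", "D", "H", "DH")
        for t in ("day", "night")
        for r in range(n_reps)
    ]
    genes = list(means)
    values = np.array(
        [[means[g][(s.condition, s.time)] for s in samples] for g in genes]
    )
    return ExpressionMatrix(gene_ids=genes, samples=samples, values=values)


def flat(value: float) -> dict[tuple[str, str], float]:
    return {(c, t): value for c in ("CK", "D", "H", "DH") for t in ("day", "night")}


class TestFilterExpressed:
    def _matrix(self, reps):
        samples = [Sample("CK", "day", i + 1) for i in range(3)]
        return ExpressionMatrix(
            gene_ids=["g"], samples=samples, values=np.array([reps])
        )

    def test_two_replicates_above_threshold_kept(self):
        assert filter_expressed(self._matrix([1.5, 1.2, 0.1])) == {"g"}

    def test_single_replicate_not_enough(self):
        assert filter_expressed(self._matrix([5.0, 0.2, 0.1])) == set()

    def test_all_zero_dropped(self):
        assert filter_expressed(self._matrix([0.0, 0.0, 0.0])) == set()


class TestPhasing:
    def test_day_phased_stress_downregulated_is_c4(self):
        means = flat(0.0)
        means.update(
            {("CK", "day"): 100, ("CK", "night"): 5, ("D", "day"): 10, ("D", "night"): 6}
        )
        expr = matrix_from_means({"g": means})
        assert phase_genes(expr)["g"].label == "C4-like"

    def test_stress_night_induction_is_cam(self):
        means = flat(1.0)
        means.update(
            {("CK", "night"): 2, ("D", "night"): 800, ("D", "day"): 3}
        )
        expr = matrix_from_means({"g": means})
        result = phase_genes(expr)["g"]
        assert result.label == "CAM-like"
        assert result.evidence["D_night/CK_night"] > 100

    def test_flat_gene_is_none(self):
        expr = matrix_from_means({"g": flat(10.0)})
        assert phase_genes(expr)["g"].label == "none"

    def test_cam_wins_when_both_rules_fire(self):
        means = {
            ("CK", "day"): 100, ("CK", "night"): 5,
            ("D", "day"): 10, ("D", "night"): 900,
            ("H", "day"): 10, ("H", "night"): 5,
            ("DH", "day"): 10, ("DH", "night"): 900,
        }
        expr = matrix_from_means({"g": means})
        assert phase_genes(expr)["g"].label == "CAM-like"

    def test_labels_invariant_under_rescaling(self):
        means = flat(0.0)
        means.update(
            {("CK", "day"): 40, ("CK", "night"): 4, ("D", "day"): 5, ("D", "night"): 4}
        )
        expr = matrix_from_means({"g": means})
        base = phase_genes(expr, min_tpm=1.0, pseudocount=0.1)["g"].label
        scaled = matrix_from_means({"g": {k: 50 * v for k, v in means.items()}})
        rescaled = phase_genes(scaled, min_tpm=50.0, pseudocount=5.0)["g"].label
        assert base == rescaled == "C4-like"

    def test_missing_stress_condition_rejected(self):
        samples = [Sample("CK", t, r) for t in ("day", "night") for r in (1, 2)]
        expr = ExpressionMatrix(
            gene_ids=["g"], samples=samples, values=np.ones((1, 4))
        )
        with pytest.raises(ValueError, match="stress"):
            phase_genes(expr)


class TestResidues:
    def test_reference_gaps_shift_columns(self):
        aln = {"ref": "M-KT", "q": "MAKT"}
        mapping = map_reference_positions(aln, "ref")
        assert mapping == {1: 0, 2: 2, 3: 3}

    def test_gap_free_reference_is_identity(self):
        aln = {"ref": "MKT"}
        assert map_reference_positions(aln, "ref") == {1: 0, 2: 1, 3: 2}

    def test_absent_reference_rejected(self):
        with pytest.raises(KeyError):
            map_reference_positions({"q": "MKT"}, "ref")

    def test_position_beyond_reference_rejected(self):
        aln = {"ref": "MKT", "q": "MKT"}
        with pytest.raises(KeyError, match="beyond"):
            diagnose_residues(aln, "ref", positions=(5,))

    def test_mapping_is_bijective_on_ungapped_positions(self):
        aln = {"ref": "MA--KT-V"}
        mapping = map_reference_positions(aln, "ref")
        assert len(set(mapping.values())) == len(mapping) == 5

    def test_calls_from_position_780(self):
        rng = np.random.default_rng(0)
        aln, ref, _ = simulate_ccm_family(rng, n_c4=1, n_cam=1, n_nonphoto=1,
                                          n_unphased=0)
        diag = diagnose_residues(aln, ref)
        assert diag.calls["PoPEPC_c4_1"] == "functional-C4/CAM-type"
        assert diag.calls["PoPEPC_np_1"] == "non-photosynthetic-type"
        assert diag.residues["PoPEPC_c4_1"][890] == "M"

    def test_gap_at_diagnostic_position_is_ambiguous(self):
        ref = "M" * 900
        query = ref[:779] + "-" + ref[780:]
        diag = diagnose_residues({"r": ref, "q": query}, "r")
        assert diag.calls["q"] == "ambiguous"


class TestClassify:
    def test_conjunction_rules(self):
        rng = np.random.default_rng(3)
        aln, ref, truth = simulate_ccm_family(rng)
        cfg = SimulationConfig(seed=3)
        expr = simulate_expression(truth, cfg, rng)
        calls = classify_ccm(diagnose_residues(aln, ref), phase_genes(expr))
        # functional residue + day phasing -> C4; + night induction -> CAM
        assert calls["PoPEPC_c4_1"] == "C4-specific"
        assert calls["PoPEPC_cam_1"] == "CAM-specific"
        # phased but non-photosynthetic residue -> other
        assert calls["PoPEPC_np_1"] == "other"
        # functional residue but unphased -> other
        assert calls["PoPEPC_flat_1"] == "other"

    def test_phasing_recovery_accuracy_across_seeds(self):
        hits = total = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            _, _, truth = simulate_ccm_family(rng)
            expr = simulate_expression(truth, SimulationConfig(seed=seed), rng)
            phases = phase_genes(expr)
            for g, want in truth.items():
                total += 1
                hits += phases[g].label == want
        assert hits / total >= 0.95
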