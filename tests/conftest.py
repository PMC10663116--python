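"""Shared fixtures: seeded simulations reused across recovery tests."""

from __future__ import annotations

import pytest

from paleodup import synteny, wgd
from paleodup.pipeline import kaks_for_anchor_pairs
from paleodup.simulate import SimulationConfig, WGDSpec, simulate_genome

WGD_RECOVERY_SEEDS = (1, 2, 3, 4, 5)


def run_wgd_recovery(seed: int) -> dict:
    """Simulate a two-WGD genome and run the full recovery chain.

    Study conditions: 2 chromosomes x 500 ancestral genes, WGDs at Ks 1.0
    (retention 0.6) and 0.113 (retention 0.4) -- the purslane-like regime
    with an ancient and a recent duplication.
    """
    cfg = SimulationConfig(
        seed=seed,
        n_chroms=2,
        genes_per_chrom=500,
        wgd_events=(
            WGDSpec(target_ks=1.0, retention=0.6),
            WGDSpec(target_ks=0.113, retention=0.4),
        ),
        emit_sequences=False,
    )
    genome, truth = simulate_genome(cfg)
    pairs = synteny.find_homolog_pairs(genome)
    blocks = synteny.chain_anchors(synteny.remove_tandem_anchors(pairs))
    kaks_results = kaks_for_anchor_pairs(
        [a for b in blocks for a in b.anchors], genome.cds_map()
    )
    ks_values = wgd.anchor_ks_distribution(blocks, kaks_results)
    peaks = wgd.fit_ks_peaks(ks_values, seed=seed)
    cross_pairs = synteny.find_homolog_pairs(genome, truth.ancestor)
    cross_blocks = synteny.chain_anchors(cross_pairs)
    depth = synteny.syntenic_depth(cross_blocks, truth.ancestor)
    arrays = synteny.detect_tandem(genome, pairs)
    families = synteny.families_from_pairs(pairs, [g.gene_id for g in genome.genes])
    labels = synteny.classify_duplicates(
        genome, blocks, arrays, families, min_copies=2
    )
    return {
        "genome": genome,
        "truth": truth,
        "pairs": pairs,
        "blocks": blocks,
        "ks_values": ks_values,
        "peaks": peaks,
        "depth": depth,
        "labels": labels,
    }


@pytest.fixture(scope="session")
def wgd_recovery_runs() -> list[dict]:
    return [run_wgd_recovery(seed) for seed in WGD_RECOVERY_SEEDS]
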