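"""End-to-end orchestration: simulate -> homologs -> blocks -> Ka/Ks ->
Ks peaks -> WGD dating -> tandem/duplicate classification -> C4/CAM calls
-> promoter motif enrichment, with per-stage TSV outputs and a JSON
summary. Every stage is a pure function of its inputs plus the config, so
any stage can be re-run in isolation from the saved intermediates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ccm, genome_io, kaks, motifs, simulate, synteny, wgd

logger = logging.getLogger("paleodup")

__all__ = [
    "PipelineConfig",
    "run_all",
    "anchors_to_frame",
    "blocks_to_frame",
    "kaks_to_frame",
    "write_collinearity",
]


@dataclass
class PipelineConfig:
    """Flat configuration for a full (simulated) pipeline run."""

    outdir: str = "paleodup_out"
    seed: int = 0
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    # homolog search / chaining
    top_n: int = 5
    min_rel_score: float = 0.5
    min_block: int = 5
    max_gap: int = 25
    gap_penalty: float = 0.05
    # Ks / dating
    ks_cap: float = 3.0
    max_components: int = 4
    clock_rate: float = wgd.CARYOPHYLLALES_RATE
    # duplicate classification
    tandem_max_intervening: int = 1
    min_copies: int = 3
    # expression phasing
    day_fold: float = 4.0
    stress_fold: float = 4.0
    cam_induction_fold: float = 10.0
    min_tpm: float = 1.0
    # motif enrichment
    promoter_length: int = 2000
    motif_p_threshold: float = 1e-4
    fdr_threshold: float = 0.1
    n_null_motifs: int = 8
    motif_length: int = 10
    membership_min: float = 0.8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        if "wgd_events" in sim_raw:
            sim_raw["wgd_events"] = tuple(
                simulate.WGDSpec(**e) for e in sim_raw["wgd_events"]
            )
        sim = simulate.SimulationConfig(**sim_raw)
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"]["wgd_events"] = [
            dataclasses.asdict(e) for e in self.simulation.wgd_events
        ]
        return d


def anchors_to_frame(pairs: list[synteny.AnchorPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(p) for p in pairs],
        columns=["gene_a", "gene_b", "score", "rank_a", "rank_b", "chrom_a", "chrom_b"],
    )


def blocks_to_frame(blocks: list[synteny.SyntenyBlock]) -> pd.DataFrame:
    rows = []
    for i, b in enumerate(blocks):
        rows.append(
            {
                "block_id": i,
                "chrom_a": b.chrom_a,
                "chrom_b": b.chrom_b,
                "orientation": b.orientation,
                "n_anchors": len(b),
                "chain_score": b.chain_score,
                "median_ks": b.median_ks,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "block_id", "chrom_a", "chrom_b", "orientation",
            "n_anchors", "chain_score", "median_ks",
        ],
    )


def kaks_to_frame(results: dict[tuple[str, str], kaks.KaKsResult]) -> pd.DataFrame:
    rows = []
    for (ga, gb), r in results.items():
        rows.append(
            {
                "gene_a": ga, "gene_b": gb, "S": r.S, "N": r.N_sites,
                "Sd": r.Sd, "Nd": r.Nd, "Ka": r.Ka, "Ks": r.Ks,
                "saturated": r.saturated,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "S", "N", "Sd", "Nd", "Ka", "Ks", "saturated"],
    )


def write_collinearity(blocks: list[synteny.SyntenyBlock], path: str | Path) -> None:
    """MCScanX-like ``.collinearity`` text layout for interoperability."""
    with open(path, "w") as fh:
        fh.write("############### paleodup collinearity ###############\n")
        for i, b in enumerate(blocks):
            plus = "plus" if b.orientation == "same" else "minus"
            fh.write(
                f"## Alignment {i}: score={b.chain_score:.1f} "
                f"N={len(b)} {b.chrom_a}&{b.chrom_b} {plus}\n"
            )
            for j, a in enumerate(b.anchors):
                fh.write(f"{i:3d}-{j:3d}:\t{a.gene_a}\t{a.gene_b}\n")


def kaks_for_anchor_pairs(
    pairs: list[synteny.AnchorPair], cds: dict[str, str]
) -> dict[tuple[str, str], kaks.KaKsResult]:
    """NG86 Ka/Ks for every anchor pair (protein-guided codon alignment)."""
    out: dict[tuple[str, str], kaks.KaKsResult] = {}
    for p in pairs:
        key = (p.gene_a, p.gene_b)
        if key not in out:
            out[key] = kaks.kaks_for_cds_pair(cds[p.gene_a], cds[p.gene_b])
    return out


def enrichment_experiment(
    seed: int,
    n_genes: int = 2000,
    module_size: int = 200,
    promoter_length: int = 500,
    rate_module: float = 0.6,
    rate_background: float = 0.1,
    n_motifs: int = 10,
    motif_length: int = 10,
    p_threshold: float = 1e-4,
    fdr_threshold: float = 0.1,
) -> tuple[list[motifs.EnrichmentResult], str]:
    """One seeded promoter-enrichment experiment with a planted motif.

    Generates random promoters, plants the consensus of one PWM into module
    promoters at ``rate_module`` and background promoters at
    ``rate_background`` (equal rates give a null experiment), scans all
    ``n_motifs`` PWMs, and returns the per-motif enrichment results plus the
    planted motif's id.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]
    promoters = simulate.simulate_promoters(gene_ids, promoter_length, rng)
    module_genes = set(
        rng.choice(gene_ids, size=module_size, replace=False).tolist()
    )
    pwms = [
        simulate.make_pwm_from_consensus(
            "".join("ACGT"[i] for i in rng.integers(0, 4, motif_length)),
            f"M{i}",
            cluster_id=f"cluster_{i % 4}",
        )
        for i in range(n_motifs)
    ]
    planted = pwms[0]
    promoters, _, _ = simulate.plant_motifs(
        promoters, planted, module_genes, rate_module, rate_background, rng
    )
    expressed = set(gene_ids)
    modules = {
        g: ("mod", 0.9) if g in module_genes else ("other", 0.9) for g in gene_ids
    }
    bg = motifs.background_from_promoters(promoters)
    hit_sets = {}
    for pwm in pwms:
        counts = motifs.scan_promoters(
            promoters, pwm, background=bg, p_threshold=p_threshold
        )
        hit_sets[pwm.motif_id] = {g for g, n in counts.items() if n > 0}
    table = motifs.count_module_occurrences(hit_sets, modules, "mod", expressed)
    results = motifs.module_enrichment(
        table, {p.motif_id: p.cluster_id for p in pwms}, fdr_threshold=fdr_threshold
    )
    return results, planted.motif_id


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: PipelineConfig) -> dict:
    """Run every stage on a simulated genome; write TSVs and summary.json."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict()}

    def stage(name):
        logger.info("stage %s", name)
        return name

    # -- simulate ------------------------------------------------------------
    name = stage("simulate")
    try:
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        genome, truth = simulate.simulate_genome(sim_cfg)
        genome_io.write_gff(genome, outdir / "genome.gff3")
        genome_io.write_fasta(genome.cds_map(), outdir / "cds.fa")
        genome_io.write_fasta(genome.proteins(), outdir / "protein.fa")
        pd.DataFrame(
            {
                "gene_id": list(truth.origin),
                "origin": [truth.origin[g] for g in truth.origin],
                "family": [truth.family[g] for g in truth.origin],
            }
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        summary["n_genes"] = len(genome.genes)
        summary["n_chromosomes"] = len(genome.chrom_lengths)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(name, exc) from exc

    # -- homologs + chaining -------------------------------------------------
    name = stage("synteny")
    try:
        pairs = synteny.find_homolog_pairs(
            genome, top_n=config.top_n, min_rel_score=config.min_rel_score
        )
        anchors_to_frame(pairs).to_csv(outdir / "anchors.tsv", sep="\t", index=False)
        blocks = synteny.chain_anchors(
            synteny.remove_tandem_anchors(pairs, config.tandem_max_intervening),
            min_block=config.min_block,
            max_gap=config.max_gap,
            gap_penalty=config.gap_penalty,
        )
        write_collinearity(blocks, outdir / "blocks.collinearity")
        summary["n_homolog_pairs"] = len(pairs)
        summary["n_blocks"] = len(blocks)
    except Exception as exc:
        raise StageError(name, exc) from exc

    # -- Ka/Ks + peaks + dating ----------------------------------------------
    name = stage("wgd")
    try:
        cds = genome.cds_map()
        anchor_pairs = [a for b in blocks for a in b.anchors]
        kaks_results = kaks_for_anchor_pairs(anchor_pairs, cds)
        kaks_to_frame(kaks_results).to_csv(outdir / "kaks.tsv", sep="\t", index=False)
        ks_values = wgd.anchor_ks_distribution(blocks, kaks_results, config.ks_cap)
        blocks_to_frame(blocks).to_csv(outdir / "blocks.tsv", sep="\t", index=False)
        pd.Series(ks_values, name="ks").to_csv(outdir / "ks_values.tsv", sep="\t", index=False)
        peaks = wgd.fit_ks_peaks(
            ks_values, max_components=config.max_components, seed=config.seed
        )
        clock = wgd.ClockParams(r=config.clock_rate)
        events = [
            wgd.date_wgd(m, clock, label=f"WGD{i + 1}")
            for i, m in enumerate(reversed(peaks.means))
        ]
        pd.DataFrame(
            {
                "component": [e.label for e in events],
                "ks_mode": [e.ks_mode for e in events],
                "weight": list(reversed(peaks.weights)),
                "age_mya": [e.age_mya for e in events],
            }
        ).to_csv(outdir / "wgd.tsv", sep="\t", index=False)
        summary["ks_peaks"] = peaks.means
        summary["wgd_ages_mya"] = [e.age_mya for e in events]
        summary["n_ks_values"] = len(ks_values)
    except Exception as exc:
        raise StageError(name, exc) from exc

    # -- syntenic depth vs the pre-WGD ancestor ------------------------------
    name = stage("depth")
    try:
        depth_blocks = synteny.chain_anchors(
            synteny.find_homolog_pairs(
                genome, truth.ancestor, top_n=config.top_n,
                min_rel_score=config.min_rel_score,
            ),
            min_block=config.min_block,
            max_gap=config.max_gap,
            gap_penalty=config.gap_penalty,
        )
        profile = synteny.syntenic_depth(depth_blocks, truth.ancestor)
        pd.DataFrame(
            sorted(profile.depth_histogram.items()),
            columns=["depth", "n_genes"],
        ).to_csv(outdir / "depth_histogram.tsv", sep="\t", index=False)
        summary["modal_depth_vs_ancestor"] = profile.modal_depth
        summary["depth_ratio_label"] = f"{profile.modal_depth}:1"
    except Exception as exc:
        raise StageError(name, exc) from exc

    # -- tandem + duplicate classification -----------------------------------
    name = stage("classify")
    try:
        arrays = synteny.detect_tandem(
            genome, pairs, max_intervening=config.tandem_max_intervening
        )
        families = synteny.families_from_pairs(
            pairs, [g.gene_id for g in genome.genes]
        )
        labels = synteny.classify_duplicates(
            genome, blocks, arrays, families, min_copies=config.min_copies
        )
        pd.DataFrame(
            {"gene_id": list(labels), "class": list(labels.values())}
        ).to_csv(outdir / "duplicate_classes.tsv", sep="\t", index=False)
        counts = pd.Series(list(labels.values())).value_counts().to_dict()
        summary["duplicate_class_counts"] = {k: int(v) for k, v in counts.items()}
        summary["n_tandem_arrays"] = len(arrays)
    except Exception as exc:
        raise StageError(name, exc) from exc

    # -- C4/CAM classification ------------------------------------------------
    name = stage("ccm")
    try:
        rng = np.random.default_rng(config.seed + 101)
        alignment, ref_id, diel_truth = simulate.simulate_ccm_family(rng)
        expr = simulate.simulate_expression(diel_truth, sim_cfg, rng)
        expr.to_tsv(outdir / "expression.tsv")
        phases = ccm.phase_genes(
            expr,
            day_fold=config.day_fold,
            stress_fold=config.stress_fold,
            cam_induction_fold=config.cam_induction_fold,
            min_tpm=config.min_tpm,
        )
        diag = ccm.diagnose_residues(alignment, ref_id)
        calls = ccm.classify_ccm(diag, phases)
        pd.DataFrame(
            {
                "gene_id": list(calls),
                "res519": [diag.residues[g][519] for g in calls],
                "res780": [diag.residues[g][780] for g in calls],
                "res890": [diag.residues[g][890] for g in calls],
                "residue_call": [diag.calls[g] for g in calls],
                "diel_label": [phases[g].label for g in calls],
                "final_class": list(calls.values()),
                "evidence": [json.dumps(phases[g].evidence) for g in calls],
            }
        ).to_csv(outdir / "ccm_calls.tsv", sep="\t", index=False)
        summary["ccm_counts"] = {
            "C4-specific": sum(v == "C4-specific" for v in calls.values()),
            "CAM-specific": sum(v == "CAM-specific" for v in calls.values()),
            "other": sum(v == "other" for v in calls.values()),
        }
    except Exception as exc:
        raise StageError(name, exc) from exc

    # -- motif enrichment ------------------------------------------------------
    name = stage("motifs")
    try:
        rng = np.random.default_rng(config.seed + 202)
        if genome.sequences is not None:
            promoters = genome_io.extract_promoters(genome, config.promoter_length)
        else:
            promoters = simulate.simulate_promoters(
                [g.gene_id for g in genome.genes], config.promoter_length, rng
            )
        gene_ids = sorted(promoters)
        module_size = max(10, len(gene_ids) // 10)
        module_genes = set(
            rng.choice(gene_ids, size=module_size, replace=False).tolist()
        )
        planted_pwm = simulate.make_pwm_from_consensus(
            "".join("ACGT"[i] for i in rng.integers(0, 4, config.motif_length)),
            "PLANTED.1",
            cluster_id="cluster_planted",
        )
        null_pwms = [
            simulate.make_pwm_from_consensus(
                "".join("ACGT"[i] for i in rng.integers(0, 4, config.motif_length)),
                f"NULL.{i + 1}",
                cluster_id=f"cluster_{i % 3}",
            )
            for i in range(config.n_null_motifs)
        ]
        sim_cfg2 = sim_cfg
        promoters, planted_sites, _ = simulate.plant_motifs(
            promoters, planted_pwm, module_genes,
            sim_cfg2.motif_plant_rate_module,
            sim_cfg2.motif_plant_rate_background, rng,
        )
        genome_io.write_fasta(promoters, outdir / "promoters.fa")
        modules = {
            g: ("green", 0.9) if g in module_genes else ("grey", 0.5)
            for g in gene_ids
        }
        pd.DataFrame(
            [(g, m, s) for g, (m, s) in modules.items()],
            columns=["gene_id", "module", "membership"],
        ).to_csv(outdir / "modules.tsv", sep="\t", index=False)
        expressed = set(gene_ids)
        hit_sets = {}
        bg = motifs.background_from_promoters(promoters)
        for pwm in [planted_pwm] + null_pwms:
            hits = motifs.scan_promoters(
                promoters, pwm, background=bg, p_threshold=config.motif_p_threshold
            )
            hit_sets[pwm.motif_id] = {g for g, n in hits.items() if n > 0}
        counts2x2 = motifs.count_module_occurrences(
            hit_sets, modules, "green", expressed, config.membership_min
        )
        clusters = {p.motif_id: p.cluster_id for p in [planted_pwm] + null_pwms}
        results = motifs.module_enrichment(
            counts2x2, clusters, fdr_threshold=config.fdr_threshold
        )
        pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
        highlighted = motifs.aggregate_clusters(results)
        summary["enriched_motifs"] = sorted(
            r.motif_id for r in results if r.enriched
        )
        summary["highlighted_clusters"] = sorted(highlighted)
        summary["n_planted_motif_sites"] = sum(
            len(v) for v in planted_sites.values()
        )
    except Exception as exc:
        raise StageError(name, exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
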