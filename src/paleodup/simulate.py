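"""Synthetic genomes, expression tables and promoters with planted truth.

The generator builds an ancestral multi-chromosome genome of random coding
genes, applies whole-genome duplications (whole-chromosome duplication
followed by independent gene loss), plants tandem arrays, and diverges
coding sequences to target Ks values with a per-site Poisson substitution
process. Coding sequences are drawn from four fully 4-fold-degenerate codon
families (GCN/GTN/CCN/ACN: Ala, Val, Pro, Thr), so every codon contributes
exactly one synonymous site (the third position) and two nonsynonymous
sites, synonymous evolution at the third position is an exact Jukes-Cantor
process, and NG86 + JC estimation of the planted Ks is asymptotically
unbiased. Expression matrices and motif-planted promoters carry the
corresponding regulatory ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ccm import MAIZE_PEPC_REFERENCE
from .genome_io import (
    ExpressionMatrix,
    GeneModel,
    Genome,
    PWM,
    Sample,
    revcomp,
)
from .kaks import GENETIC_CODE, STOP_CODONS, ng86_sites

__all__ = [
    "WGDSpec",
    "SimulationConfig",
    "TruthTable",
    "simulate_genome",
    "evolve_pair",
    "simulate_expression",
    "simulate_ccm_family",
    "simulate_promoters",
    "plant_motifs",
    "random_cds",
    "make_pwm_from_consensus",
    "EXPRESSION_PROFILES",
]

_BASES = "ACGT"

#: (pos1, pos2) prefixes of fully 4-fold degenerate, stop-safe codon families.
SAFE_FAMILIES = ("GC", "GT", "CC", "AC")  # Ala, Val, Pro, Thr

# single-base moves between safe families (the nonsynonymous random walk
# used by the genome simulator; keeps NG86 site structure invariant)
_FAMILY_NEIGHBORS = {
    "GC": ("CC", "AC", "GT"),
    "CC": ("GC", "AC"),
    "AC": ("GC", "CC"),
    "GT": ("GC",),
}


@dataclass(frozen=True)
class WGDSpec:
    """One whole-genome duplication: target paralog Ks and retention rate."""

    target_ks: float
    retention: float

    def __post_init__(self) -> None:
        if self.target_ks <= 0:
            raise ValueError("target_ks must be positive")
        if not (0 < self.retention <= 1):
            raise ValueError("retention must lie in (0, 1]")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults emulate the purslane-like regime: two WGDs with paralog Ks
    modes near 1.0 (ancient) and 0.113 (recent), an ortholog divergence
    peak at Ks = 0.28, tandem arrays, diel/stress expression phases, and
    promoter motifs planted preferentially in one coexpression module.
    """

    seed: int = 0
    n_chroms: int = 2
    genes_per_chrom: int = 300
    wgd_events: tuple[WGDSpec, ...] = (
        WGDSpec(target_ks=1.0, retention=0.6),
        WGDSpec(target_ks=0.113, retention=0.4),
    )
    tandem_rate: float = 0.05
    tandem_max_copies: int = 3
    tandem_ks: float = 0.02
    inversions_per_chrom: int = 0  # random segment reversals, stresses chaining
    ortholog_divergence_ks: float | None = 0.28
    cds_length_codons: int = 200
    transition_bias: float = 1.0
    ka_ks_ratio: float = 0.2
    intergenic_bp: int = 2500
    emit_sequences: bool = True
    expression_noise_cv: float = 0.3
    motif_plant_rate_module: float = 0.6
    motif_plant_rate_background: float = 0.1
    min_block: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.tandem_rate < 1):
            raise ValueError("tandem_rate must lie in [0, 1)")
        for rate in (self.motif_plant_rate_module, self.motif_plant_rate_background):
            if not (0 <= rate <= 1):
                raise ValueError("motif plant rates must lie in [0, 1]")
        if self.transition_bias < 0:
            raise ValueError("transition_bias must be >= 0")


@dataclass
class TruthTable:
    """Planted ground truth accompanying a simulated genome."""

    origin: dict[str, str] = field(default_factory=dict)  # WGD1/WGD2/TD/singleton
    family: dict[str, str] = field(default_factory=dict)  # gene -> family id
    true_ks: dict[tuple[str, str], float] = field(default_factory=dict)
    blocks: list[tuple[str, str, int]] = field(default_factory=list)
    diel_class: dict[str, str] = field(default_factory=dict)
    motif_sites: dict[str, list[int]] = field(default_factory=dict)
    ancestor: Genome | None = None
    ortholog: Genome | None = None
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """A random CDS over the safe 4-fold-degenerate codon families."""
    fams = rng.integers(0, len(SAFE_FAMILIES), size=n_codons)
    pos3 = rng.integers(0, 4, size=n_codons)
    return "".join(
        SAFE_FAMILIES[f] + _BASES[b] for f, b in zip(fams.tolist(), pos3.tolist())
    )


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def _syn_neighbors(codon: str) -> list[str]:
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut not in STOP_CODONS and GENETIC_CODE[mut] == aa:
                out.append(mut)
    return out


def _nonsyn_neighbors(codon: str) -> list[str]:
    aa = GENETIC_CODE[codon]
    out = []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut not in STOP_CODONS and GENETIC_CODE[mut] != aa:
                out.append(mut)
    return out


def _pick_weighted(
    codon: str, neighbors: list[str], transition_bias: float, rng: np.random.Generator
) -> str:
    if transition_bias == 1.0:
        return neighbors[rng.integers(0, len(neighbors))]
    weights = []
    for n in neighbors:
        pos = next(i for i in range(3) if n[i] != codon[i])
        weights.append(transition_bias if _is_transition(codon[pos], n[pos]) else 1.0)
    w = np.asarray(weights) / sum(weights)
    return neighbors[rng.choice(len(neighbors), p=w)]


def _is_fast_codon(codon: str) -> bool:
    """True when the codon's only synonymous changes are the three at pos 3."""
    s, _ = ng86_sites(codon)
    if s != 1.0:
        return False
    aa = GENETIC_CODE[codon]
    return all(
        GENETIC_CODE[codon[:2] + b] == aa for b in _BASES if b != codon[2]
    )


_FAST_CODON = {c: _is_fast_codon(c) for c in GENETIC_CODE}


def evolve_pair(
    cds: str,
    target_ks: float,
    target_ka: float,
    rng: np.random.Generator,
    transition_bias: float = 1.0,
    conservative_nonsyn: bool = False,
) -> str:
    """Return a copy of ``cds`` carrying planted synonymous/nonsynonymous
    substitutions at expected densities ``target_ks`` per synonymous site
    and ``target_ka`` per nonsynonymous site (NG86 site definitions).

    Substitution counts are Poisson per codon; multiple hits are permitted,
    so Jukes-Cantor-corrected NG86 estimates of the planted densities are
    asymptotically unbiased (exactly so for fully 4-fold-degenerate codons,
    where the synonymous process is a textbook Jukes-Cantor chain at the
    third position). With ``conservative_nonsyn`` nonsynonymous changes are
    restricted to moves among the safe 4-fold codon families, keeping the
    site structure of every codon invariant (used by the genome simulator).
    """
    if target_ks < 0 or target_ka < 0:
        raise ValueError("target densities must be nonnegative")
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for c in codons:
        if c in STOP_CODONS or c not in GENETIC_CODE:
            raise ValueError(f"cannot evolve codon {c!r}")

    # --- synonymous process -------------------------------------------------
    if target_ks > 0:
        fast = np.array([_FAST_CODON[c] for c in codons])
        if transition_bias == 1.0 and fast.any():
            # closed-form Jukes-Cantor marginal at the third position
            idx = np.nonzero(fast)[0]
            p_change = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))
            changed = idx[rng.random(len(idx)) < p_change]
            offsets = rng.integers(1, 4, size=len(changed))
            for i, off in zip(changed.tolist(), offsets.tolist()):
                c = codons[i]
                b = _BASES[(_BASES.index(c[2]) + off) % 4]
                codons[i] = c[:2] + b
            slow_idx = np.nonzero(~fast)[0]
        else:
            slow_idx = np.arange(len(codons))
        for i in slow_idx.tolist():
            s_sites, _ = ng86_sites(codons[i])
            if s_sites == 0:
                continue
            for _ in range(rng.poisson(target_ks * s_sites)):
                nbrs = _syn_neighbors(codons[i])
                if not nbrs:
                    break
                codons[i] = _pick_weighted(codons[i], nbrs, transition_bias, rng)

    # --- nonsynonymous process ----------------------------------------------
    if target_ka > 0:
        for i in range(len(codons)):
            _, n_sites = ng86_sites(codons[i])
            for _ in range(rng.poisson(target_ka * n_sites)):
                c = codons[i]
                if conservative_nonsyn and c[:2] in _FAMILY_NEIGHBORS:
                    fam = _FAMILY_NEIGHBORS[c[:2]][
                        rng.integers(0, len(_FAMILY_NEIGHBORS[c[:2]]))
                    ]
                    codons[i] = fam + c[2]
                else:
                    nbrs = _nonsyn_neighbors(c)
                    if not nbrs:
                        break
                    codons[i] = _pick_weighted(c, nbrs, transition_bias, rng)
    return "".join(codons)


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


@dataclass
class _SimGene:
    family: str
    path: tuple[int, ...]  # 0/1 per WGD event: original or duplicate lineage
    cds: str
    tandem_of: str | None = None  # family-internal tandem source gene id
    gene_id: str = ""


def _materialize(
    name: str,
    chrom_genes: dict[str, list[_SimGene]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Genome:
    gene_len = 3 * config.cds_length_codons
    spacing = config.intergenic_bp
    genes: list[GeneModel] = []
    sequences: dict[str, str] | None = {} if config.emit_sequences else None
    chrom_lengths: dict[str, int] = {}
    for chrom in sorted(chrom_genes):
        sim_genes = chrom_genes[chrom]
        chrom_len = len(sim_genes) * (gene_len + spacing) + spacing
        chrom_lengths[chrom] = chrom_len
        if sequences is not None:
            arr = rng.integers(0, 4, size=chrom_len)
            seq = np.array(list(_BASES))[arr]
        strands = rng.random(len(sim_genes)) < 0.8  # mostly + strand
        for i, sg in enumerate(sim_genes):
            start = spacing + i * (gene_len + spacing)
            end = start + gene_len
            strand = "+" if strands[i] else "-"
            genes.append(
                GeneModel(
                    gene_id=sg.gene_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    cds=sg.cds,
                )
            )
            if sequences is not None:
                placed = sg.cds if strand == "+" else revcomp(sg.cds)
                seq[start:end] = list(placed)
        if sequences is not None:
            sequences[chrom] = "".join(seq.tolist())
    return Genome(
        name=name, chrom_lengths=chrom_lengths, genes=genes, sequences=sequences
    )


def simulate_genome(config: SimulationConfig) -> tuple[Genome, TruthTable]:
    """Simulate a genome shaped by WGDs and tandem duplication.

    Returns the present-day genome and a :class:`TruthTable` holding the
    per-gene origin labels, per-pair planted Ks, planted block inventory,
    the pre-WGD ancestor genome (chromosomes ``anc_*``) and, when
    ``ortholog_divergence_ks`` is set, a duplication-free calibration
    outgroup (chromosomes ``ort_*``) whose genes sit at that Ks distance
    from their ancestor counterparts.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()

    events = sorted(config.wgd_events, key=lambda e: -e.target_ks)
    if any(
        abs(events[i].target_ks - config.wgd_events[i].target_ks) > 0
        for i in range(len(events))
    ):
        truth.warnings.append("wgd_events reordered oldest-first by target_ks")

    # ancestral gene content
    chrom_genes: dict[str, list[_SimGene]] = {}
    counter = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        chrom_genes[chrom] = []
        for _ in range(config.genes_per_chrom):
            fam = f"f{counter:05d}"
            counter += 1
            chrom_genes[chrom].append(
                _SimGene(family=fam, path=(), cds=random_cds(config.cds_length_codons, rng))
            )

    # pre-WGD ancestor snapshot (and optional ortholog outgroup)
    anc_chrom_genes = {
        f"anc_{chrom}": [
            _SimGene(family=g.family, path=(), cds=g.cds, gene_id=f"anc_{g.family}")
            for g in genes
        ]
        for chrom, genes in chrom_genes.items()
    }
    if config.ortholog_divergence_ks:
        ort_chrom_genes = {}
        for chrom, genes in chrom_genes.items():
            ort_chrom_genes[f"ort_{chrom}"] = [
                _SimGene(
                    family=g.family,
                    path=(),
                    cds=evolve_pair(
                        g.cds,
                        config.ortholog_divergence_ks,
                        config.ortholog_divergence_ks * config.ka_ks_ratio,
                        rng,
                        transition_bias=config.transition_bias,
                        conservative_nonsyn=True,
                    ),
                    gene_id=f"ort_{g.family}",
                )
                for g in genes
            ]

    # WGD rounds: duplicate chromosomes, thin duplicates, evolve all lineages
    for k, event in enumerate(events):
        new_chroms: dict[str, list[_SimGene]] = {}
        for chrom in sorted(chrom_genes):
            originals = []
            duplicates = []
            for g in chrom_genes[chrom]:
                originals.append(replace(g, path=g.path + (0,)))
                if rng.random() < event.retention:
                    duplicates.append(replace(g, path=g.path + (1,)))
            new_chroms[chrom] = originals
            new_chroms[f"{chrom}w{k + 1}"] = duplicates
        chrom_genes = new_chroms
        t_next = events[k + 1].target_ks if k + 1 < len(events) else 0.0
        seg_ks = (event.target_ks - t_next) / 2.0
        seg_ka = seg_ks * config.ka_ks_ratio
        for chrom in sorted(chrom_genes):
            for g in chrom_genes[chrom]:
                g.cds = evolve_pair(
                    g.cds,
                    seg_ks,
                    seg_ka,
                    rng,
                    transition_bias=config.transition_bias,
                    conservative_nonsyn=True,
                )

    # assign gene ids (copy index per family, deterministic chromosome order)
    copy_counter: dict[str, int] = {}
    for chrom in sorted(chrom_genes):
        for g in chrom_genes[chrom]:
            n = copy_counter.get(g.family, 0)
            copy_counter[g.family] = n + 1
            g.gene_id = f"{g.family}.{n}"

    # tandem arrays: adjacent near-identical copies of the source gene
    if config.tandem_rate > 0 and config.tandem_max_copies >= 2:
        for chrom in sorted(chrom_genes):
            expanded: list[_SimGene] = []
            for g in chrom_genes[chrom]:
                expanded.append(g)
                if rng.random() < config.tandem_rate:
                    n_extra = int(rng.integers(1, config.tandem_max_copies))
                    for t in range(n_extra):
                        expanded.append(
                            _SimGene(
                                family=g.family,
                                path=g.path,
                                cds=evolve_pair(
                                    g.cds,
                                    config.tandem_ks,
                                    config.tandem_ks * config.ka_ks_ratio,
                                    rng,
                                    transition_bias=config.transition_bias,
                                    conservative_nonsyn=True,
                                ),
                                tandem_of=g.gene_id,
                                gene_id=f"{g.gene_id}t{t + 1}",
                            )
                        )
            chrom_genes[chrom] = expanded

    # optional inversions: reverse random gene-order segments per chromosome
    if config.inversions_per_chrom > 0:
        for chrom in sorted(chrom_genes):
            glist = chrom_genes[chrom]
            for _ in range(config.inversions_per_chrom):
                if len(glist) < 2:
                    break
                i = int(rng.integers(0, len(glist) - 1))
                j = int(rng.integers(i + 1, len(glist) + 1))
                glist[i:j] = glist[i:j][::-1]

    genome = _materialize("sim", chrom_genes, config, rng)
    truth.ancestor = _materialize(
        "ancestor", anc_chrom_genes, replace(config, emit_sequences=False), rng
    )
    if config.ortholog_divergence_ks:
        truth.ortholog = _materialize(
            "ortholog", ort_chrom_genes, replace(config, emit_sequences=False), rng
        )

    # truth: families, origins, pairwise Ks, planted blocks
    times = [e.target_ks for e in events]
    by_family: dict[str, list[_SimGene]] = {}
    for chrom in sorted(chrom_genes):
        for g in chrom_genes[chrom]:
            truth.family[g.gene_id] = g.family
            by_family.setdefault(g.family, []).append(g)

    for fam, members in by_family.items():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                key = tuple(sorted((a.gene_id, b.gene_id)))
                if a.path == b.path:
                    # tandem relationship: source-copy pairs sit at tandem_ks,
                    # two copies of the same source at twice that
                    direct = a.tandem_of == b.gene_id or b.tandem_of == a.gene_id
                    truth.true_ks[key] = (
                        config.tandem_ks if direct else 2 * config.tandem_ks
                    )
                else:
                    split = next(
                        k for k in range(len(times)) if a.path[k] != b.path[k]
                    )
                    truth.true_ks[key] = times[split]
        for g in members:
            if g.tandem_of is not None or any(
                (m.tandem_of == g.gene_id) for m in members
            ):
                truth.origin[g.gene_id] = "TD"
            else:
                wgd_partners = [
                    m for m in members if m is not g and m.path != g.path
                ]
                if not wgd_partners:
                    truth.origin[g.gene_id] = "singleton"
                else:
                    split = max(
                        next(k for k in range(len(times)) if m.path[k] != g.path[k])
                        for m in wgd_partners
                    )
                    truth.origin[g.gene_id] = f"WGD{split + 1}"

    # planted block inventory: each chromosome vs the copy made at each event
    chrom_sets = {c: {g.family for g in gs if g.tandem_of is None}
                  for c, gs in chrom_genes.items()}
    for chrom in sorted(chrom_sets):
        for k in range(len(events)):
            dup = f"{chrom}w{k + 1}"
            if dup in chrom_sets:
                n_pairs = len(chrom_sets[chrom] & chrom_sets[dup])
                truth.blocks.append((chrom, dup, n_pairs))
                if n_pairs < config.min_block:
                    truth.warnings.append(
                        f"planted block {chrom}/{dup} has only {n_pairs} "
                        f"surviving anchor pairs (min_block={config.min_block})"
                    )
    return genome, truth


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

#: Planted group-mean TPMs per diel class, (condition, time) -> mean.
EXPRESSION_PROFILES: dict[str, dict[tuple[str, str], float]] = {
    "C4-like": {
        ("CK", "day"): 200.0, ("CK", "night"): 10.0,
        ("D", "day"): 20.0, ("D", "night"): 10.0,
        ("H", "day"): 20.0, ("H", "night"): 10.0,
        ("DH", "day"): 20.0, ("DH", "night"): 10.0,
    },
    "CAM-like": {
        ("CK", "day"): 5.0, ("CK", "night"): 5.0,
        ("D", "day"): 8.0, ("D", "night"): 1000.0,
        ("H", "day"): 5.0, ("H", "night"): 5.0,
        ("DH", "day"): 8.0, ("DH", "night"): 1000.0,
    },
    "none": {
        (c, t): 20.0
        for c in ("CK", "D", "H", "DH")
        for t in ("day", "night")
    },
}


def simulate_expression(
    diel_class: dict[str, str] | TruthTable,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_replicates: int = 3,
) -> ExpressionMatrix:
    """TPM matrix realising the planted diel classes with lognormal noise.

    CAM-like genes are induced hundreds-fold at night under drought (D/DH)
    relative to the control night; C4-like genes are day-phased under
    control and downregulated under stress. Replicate noise is lognormal
    with the configured coefficient of variation and unit mean.
    """
    if isinstance(diel_class, TruthTable):
        diel_class = diel_class.diel_class
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genes = list(diel_class)
    samples = [
        Sample(condition=c, time=t, replicate=r + 1)
        for c in ("CK", "D", "H", "DH")
        for t in ("day", "night")
        for r in range(n_replicates)
    ]
    cv = config.expression_noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0
    values = np.zeros((len(genes), len(samples)))
    for i, g in enumerate(genes):
        profile = EXPRESSION_PROFILES[diel_class[g]]
        for j, s in enumerate(samples):
            mean = profile[(s.condition, s.time)]
            noise = math.exp(rng.normal(-0.5 * sigma * sigma, sigma)) if sigma else 1.0
            values[i, j] = mean * noise
    return ExpressionMatrix(gene_ids=genes, samples=samples, values=values)


# ---------------------------------------------------------------------------
# Diagnostic-residue family simulation
# ---------------------------------------------------------------------------

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def simulate_ccm_family(
    rng: np.random.Generator,
    n_c4: int = 4,
    n_cam: int = 2,
    n_nonphoto: int = 3,
    n_unphased: int = 2,
    length: int = 900,
    divergence: float = 0.03,
) -> tuple[dict[str, str], str, dict[str, str]]:
    """A synthetic PEPC-like family with planted diagnostic residues.

    Returns ``(alignment, reference_id, diel_truth)``. C4 members carry
    S780/M890/H519 and day-phased expression truth; CAM members carry
    S780/G890/D519 with stress-night truth; decoys are either
    non-photosynthetic (A780) but phased, or functional (S780) but
    unphased. The ungapped reference row uses maize PEPC numbering.
    """
    if length < 890:
        raise ValueError("reference must span position 890")
    ref = "".join(_AA20[i] for i in rng.integers(0, 20, size=length))
    ref = _set_residues(ref, {519: "D", 780: "A", 890: "R"})
    alignment = {MAIZE_PEPC_REFERENCE: ref}
    truth: dict[str, str] = {}

    def add(name: str, residues: dict[int, str], diel: str) -> None:
        seq = list(ref)
        n_mut = rng.binomial(length, divergence)
        for pos in rng.choice(length, size=n_mut, replace=False).tolist():
            if (pos + 1) in (519, 780, 890):
                continue
            seq[pos] = _AA20[rng.integers(0, 20)]
        alignment[name] = _set_residues("".join(seq), residues)
        truth[name] = diel

    for i in range(n_c4):
        add(f"PoPEPC_c4_{i + 1}", {519: "H", 780: "S", 890: "M"}, "C4-like")
    for i in range(n_cam):
        add(f"PoPEPC_cam_{i + 1}", {519: "D", 780: "S", 890: "G"}, "CAM-like")
    for i in range(n_nonphoto):
        # phased like a photosynthetic copy but ancestral A780
        diel = "C4-like" if i % 2 == 0 else "CAM-like"
        add(f"PoPEPC_np_{i + 1}", {519: "D", 780: "A", 890: "R"}, diel)
    for i in range(n_unphased):
        add(f"PoPEPC_flat_{i + 1}", {519: "H", 780: "S", 890: "M"}, "none")
    return alignment, MAIZE_PEPC_REFERENCE, truth


def _set_residues(seq: str, residues: dict[int, str]) -> str:
    chars = list(seq)
    for pos1, aa in residues.items():
        chars[pos1 - 1] = aa
    return "".join(chars)


# ---------------------------------------------------------------------------
# Promoters and motif planting
# ---------------------------------------------------------------------------


def simulate_promoters(
    gene_ids: list[str], length: int, rng: np.random.Generator
) -> dict[str, str]:
    """Uniform-composition random promoters, one per gene id."""
    out = {}
    for g in gene_ids:
        arr = rng.integers(0, 4, size=length)
        out[g] = "".join(_BASES[i] for i in arr.tolist())
    return out


def make_pwm_from_consensus(
    consensus: str, motif_id: str, cluster_id: str = "", weight: float = 0.85,
    total: float = 100.0,
) -> PWM:
    """An informative PWM whose maximum-probability word is ``consensus``."""
    mat = np.full((len(consensus), 4), total * (1 - weight) / 3.0)
    for i, base in enumerate(consensus):
        mat[i, _BASES.index(base)] = total * weight
    return PWM(motif_id=motif_id, matrix=mat, cluster_id=cluster_id)


def plant_motifs(
    promoters: dict[str, str],
    pwm: PWM,
    module_genes: set[str],
    rate_module: float,
    rate_background: float,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, list[int]], list[str]]:
    """Insert the PWM consensus into promoters at planted rates.

    Each module gene receives one consensus site with probability
    ``rate_module`` (background genes with ``rate_background``) at a uniform
    random offset, overwriting the underlying bases. Returns the modified
    promoters, the planted offsets per gene, and genes skipped because
    their promoter is shorter than the motif.
    """
    for rate in (rate_module, rate_background):
        if not (0 <= rate <= 1):
            raise ValueError("plant rates must lie in [0, 1]")
    site = pwm.consensus
    out = dict(promoters)
    planted: dict[str, list[int]] = {}
    skipped: list[str] = []
    for g in sorted(promoters):
        rate = rate_module if g in module_genes else rate_background
        if rng.random() >= rate:
            continue
        seq = promoters[g]
        if len(seq) < len(site):
            skipped.append(g)
            continue
        pos = int(rng.integers(0, len(seq) - len(site) + 1))
        out[g] = seq[:pos] + site + seq[pos + len(site) :]
        planted.setdefault(g, []).append(pos)
    return out, planted, skipped
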