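"""Homolog pairing, collinear block chaining, syntenic depth, tandem arrays
and duplicate-origin classification.

Chaining follows the MCScanX recipe: anchors (homologous gene pairs indexed
by gene rank on each chromosome) are chained by dynamic programming under a
rank-gap limit, and blocks are extracted greedily best-first with used
anchors removed. Defaults (min_block=5, max_gap=25) are the MCScanX default
parameter settings.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from .genome_io import Genome
from .kaks import _make_aligner

__all__ = [
    "AnchorPair",
    "SyntenyBlock",
    "DepthProfile",
    "TandemArray",
    "find_homolog_pairs",
    "chain_anchors",
    "remove_tandem_anchors",
    "syntenic_depth",
    "detect_tandem",
    "classify_duplicates",
    "families_from_pairs",
    "depth_ratio_label",
]


@dataclass
class AnchorPair:
    """A homologous gene pair, positioned by gene rank on each chromosome."""

    gene_a: str
    gene_b: str
    score: float
    rank_a: int
    rank_b: int
    chrom_a: str
    chrom_b: str

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError("anchor score must be positive")


@dataclass
class SyntenyBlock:
    """A chained run of anchors collinear on one chromosome pair."""

    anchors: list[AnchorPair]
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    chain_score: float
    median_ks: float | None = None

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        ranks = [a.rank_a for a in self.anchors]
        return min(ranks), max(ranks)

    @property
    def span_b(self) -> tuple[int, int]:
        ranks = [a.rank_b for a in self.anchors]
        return min(ranks), max(ranks)


@dataclass
class DepthProfile:
    """Per-gene syntenic block coverage over a reference genome."""

    coverage: dict[str, int]
    modal_depth: int
    depth_histogram: dict[int, int]
    ratio_label: str = ""


@dataclass
class TandemArray:
    """A run of near-adjacent homologs on one chromosome."""

    chrom: str
    members: list[str]  # gene ids ordered by rank
    max_intervening_used: int


# ---------------------------------------------------------------------------
# Homolog pair detection: shared k-mer prefilter + Needleman-Wunsch rescoring
# ---------------------------------------------------------------------------


def _kmer_sets(proteins: dict[str, str], k: int) -> dict[str, frozenset]:
    return {
        g: frozenset(p[i : i + k] for i in range(len(p) - k + 1))
        for g, p in proteins.items()
    }


def _self_score(protein: str, matrix) -> float:
    return float(sum(matrix[aa, aa] for aa in protein))


def find_homolog_pairs(
    genome_a: Genome,
    genome_b: Genome | None = None,
    top_n: int = 5,
    min_score: float = 0.0,
    min_rel_score: float = 0.5,
    kmer: int = 8,
    min_shared_kmers: int = 5,
    substitution_matrix: str = "BLOSUM62",
) -> list[AnchorPair]:
    """Detect homologous gene pairs between two genomes (or within one).

    Candidate pairs sharing at least ``min_shared_kmers`` protein k-mers are
    rescored with a global affine alignment; the reported anchor ``score`` is
    the alignment score normalised by the smaller self-score (1.0 for an
    identical pair). Pairs are kept when the normalised score reaches
    ``min_rel_score``, the raw score reaches ``min_score``, and the pair is
    within the ``top_n`` best partners of either gene. For a self-comparison
    (``genome_b is None``) self-hits are removed and each unordered pair is
    counted once. Ordering is deterministic: score descending, then ids.
    """
    self_cmp = genome_b is None
    gb = genome_a if self_cmp else genome_b
    prot_a = genome_a.proteins()
    prot_b = prot_a if self_cmp else gb.proteins()
    if not prot_a or not prot_b:
        raise ValueError("empty proteome")
    genes_a = genome_a.gene_map()
    genes_b = gb.gene_map()

    kmers_a = _kmer_sets(prot_a, kmer)
    kmers_b = kmers_a if self_cmp else _kmer_sets(prot_b, kmer)
    index: dict[str, list[str]] = defaultdict(list)
    for g, ks in kmers_b.items():
        for km in ks:
            index[km].append(g)

    aligner = _make_aligner(substitution_matrix)
    matrix = aligner.substitution_matrix
    selfscore_a = {g: _self_score(p, matrix) for g, p in prot_a.items()}
    selfscore_b = (
        selfscore_a if self_cmp else {g: _self_score(p, matrix) for g, p in prot_b.items()}
    )

    scored: dict[tuple[str, str], float] = {}
    for ga in sorted(prot_a):
        counts: Counter[str] = Counter()
        for km in kmers_a[ga]:
            for gbid in index[km]:
                counts[gbid] += 1
        for gbid, shared in counts.items():
            if shared < min_shared_kmers:
                continue
            if self_cmp:
                if ga == gbid:
                    continue
                key = (min(ga, gbid), max(ga, gbid))
            else:
                key = (ga, gbid)
            if key in scored:
                continue
            raw = float(aligner.score(prot_a[key[0]], prot_b[key[1]]))
            rel = raw / min(selfscore_a[key[0]], selfscore_b[key[1]])
            if raw >= min_score and rel >= min_rel_score and rel > 0:
                scored[key] = rel

    # top_n filter: keep a pair when it ranks within the top_n partners of
    # either member (ties broken by id).
    partners: dict[str, list[tuple[float, str]]] = defaultdict(list)
    for (ga, gbid), rel in scored.items():
        partners[f"a:{ga}"].append((rel, gbid))
        partners[f"b:{gbid}"].append((rel, ga))
    keep: set[tuple[str, str]] = set()
    for (ga, gbid), rel in scored.items():
        for side, gene, other in (("a", ga, gbid), ("b", gbid, ga)):
            ranked = sorted(partners[f"{side}:{gene}"], key=lambda t: (-t[0], t[1]))
            if (rel, other) in ranked[:top_n]:
                keep.add((ga, gbid))
                break

    pairs = []
    for ga, gbid in keep:
        a = genes_a[ga] if ga in genes_a else genes_b[ga]
        b = genes_b[gbid] if gbid in genes_b else genes_a[gbid]
        if self_cmp:
            # canonical orientation: gene_a precedes gene_b by (chrom, rank)
            if (b.chrom, b.rank) < (a.chrom, a.rank):
                a, b = b, a
        pairs.append(
            AnchorPair(
                gene_a=a.gene_id,
                gene_b=b.gene_id,
                score=scored[(ga, gbid)],
                rank_a=a.rank,
                rank_b=b.rank,
                chrom_a=a.chrom,
                chrom_b=b.chrom,
            )
        )
    pairs.sort(key=lambda p: (-p.score, p.gene_a, p.gene_b))
    return pairs


def remove_tandem_anchors(
    anchors: list[AnchorPair], max_intervening: int = 1
) -> list[AnchorPair]:
    """Drop self-comparison anchors that are themselves tandem pairs.

    Near-adjacent same-chromosome homolog pairs would otherwise chain into
    spurious diagonal "blocks" of tandem arrays; removing them before
    chaining mirrors how collinearity tools collapse local duplicates.
    """
    return [
        a
        for a in anchors
        if not (
            a.chrom_a == a.chrom_b and abs(a.rank_a - a.rank_b) - 1 <= max_intervening
        )
    ]


# ---------------------------------------------------------------------------
# Collinear chaining
# ---------------------------------------------------------------------------


def _best_chain(
    anchors: list[AnchorPair],
    orientation: str,
    max_gap: int,
    gap_penalty: float,
) -> tuple[float, list[int]]:
    """Best-scoring monotone chain (DP longest path) over one chromosome pair.

    Returns (score, indices into ``anchors``). ``anchors`` must be sorted by
    (rank_a, rank_b). Chain edges require rank_a strictly increasing with a
    delta in [1, max_gap], and rank_b strictly increasing (same) or strictly
    decreasing (inverted) with |delta| in [1, max_gap]. Each edge is charged
    gap_penalty * ((delta_a - 1) + (|delta_b| - 1)).
    """
    n = len(anchors)
    if n == 0:
        return 0.0, []
    dp = [a.score for a in anchors]
    back = [-1] * n
    sign = 1 if orientation == "same" else -1
    for j in range(n):
        aj = anchors[j]
        best = 0.0
        best_i = -1
        for i in range(j):
            ai = anchors[i]
            da = aj.rank_a - ai.rank_a
            if da < 1:
                continue
            if da > max_gap:
                continue
            db = sign * (aj.rank_b - ai.rank_b)
            if db < 1 or db > max_gap:
                continue
            cand = dp[i] - gap_penalty * ((da - 1) + (db - 1))
            if cand > best:
                best = cand
                best_i = i
        dp[j] = aj.score + best
        back[j] = best_i
    j = int(np.argmax(dp))
    chain = []
    while j != -1:
        chain.append(j)
        j = back[j]
    chain.reverse()
    return float(max(dp)), chain


def chain_anchors(
    anchors: list[AnchorPair],
    min_block: int = 5,
    max_gap: int = 25,
    gap_penalty: float = 0.05,
) -> list[SyntenyBlock]:
    """Chain anchors into collinear blocks, greedily best-chain-first.

    Per chromosome pair, the best-scoring chain over unused anchors (either
    orientation) is extracted repeatedly; chains shorter than ``min_block``
    anchors are discarded. Each anchor belongs to at most one block.
    """
    by_pair: dict[tuple[str, str], list[AnchorPair]] = defaultdict(list)
    for a in anchors:
        by_pair[(a.chrom_a, a.chrom_b)].append(a)

    blocks: list[SyntenyBlock] = []
    for (ca, cb) in sorted(by_pair):
        remaining = sorted(by_pair[(ca, cb)], key=lambda a: (a.rank_a, a.rank_b))
        while remaining:
            candidates = []
            for orientation in ("same", "inverted"):
                score, chain = _best_chain(remaining, orientation, max_gap, gap_penalty)
                if chain:
                    candidates.append((score, orientation, chain))
            if not candidates:
                break
            score, orientation, chain = max(candidates, key=lambda t: (t[0], t[1]))
            chosen = [remaining[i] for i in chain]
            used = set(chain)
            remaining = [a for i, a in enumerate(remaining) if i not in used]
            if len(chosen) >= min_block:
                blocks.append(
                    SyntenyBlock(
                        anchors=chosen,
                        chrom_a=ca,
                        chrom_b=cb,
                        orientation=orientation,
                        chain_score=score,
                    )
                )
            elif len(chosen) < 2:
                # nothing longer can remain once best chain is a singleton
                break
    blocks.sort(key=lambda b: (-b.chain_score, b.chrom_a, b.chrom_b))
    return blocks


# ---------------------------------------------------------------------------
# Syntenic depth
# ---------------------------------------------------------------------------


def syntenic_depth(blocks: list[SyntenyBlock], reference: Genome) -> DepthProfile:
    """Coverage of reference genes by block anchor spans.

    A reference gene is covered by a block when the block's anchor rank span
    on the gene's chromosome contains the gene's rank. For self-comparisons
    both sides of a block contribute a span. ``modal_depth`` is the most
    frequent nonzero coverage (0 when there are no blocks).
    """
    ref_chroms = set(reference.chrom_lengths)
    per_chrom_genes = {c: reference.genes_on(c) for c in ref_chroms}
    cover = {c: np.zeros(len(per_chrom_genes[c]), dtype=int) for c in ref_chroms}
    for b in blocks:
        spans = []
        if b.chrom_a in ref_chroms:
            spans.append((b.chrom_a, b.span_a))
        if b.chrom_b in ref_chroms:
            spans.append((b.chrom_b, b.span_b))
        for chrom, (lo, hi) in spans:
            arr = cover[chrom]
            arr[lo : min(hi, len(arr) - 1) + 1] += 1
    coverage: dict[str, int] = {}
    for c, genes in per_chrom_genes.items():
        for g in genes:
            coverage[g.gene_id] = int(cover[c][g.rank])
    hist = Counter(coverage.values())
    nonzero = {d: n for d, n in hist.items() if d > 0}
    modal = max(nonzero, key=lambda d: (nonzero[d], -d)) if nonzero else 0
    return DepthProfile(
        coverage=coverage, modal_depth=modal, depth_histogram=dict(hist)
    )


def depth_ratio_label(profile_a: DepthProfile, profile_b: DepthProfile) -> str:
    """Compare modal depths of two comparisons, e.g. ``"4:1"``."""
    return f"{profile_a.modal_depth}:{profile_b.modal_depth}"


# ---------------------------------------------------------------------------
# Tandem arrays
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = (ra, rb) if ra < rb else (rb, ra)
            self.parent[hi] = lo


def detect_tandem(
    genome: Genome,
    homolog_pairs: list[AnchorPair],
    max_intervening: int = 1,
) -> list[TandemArray]:
    """Group near-adjacent same-chromosome homologs into tandem arrays.

    Two homologs qualify when at most ``max_intervening`` genes lie between
    them by rank; arrays are the connected components (transitive closure)
    of size >= 2, members sorted by rank. Output is invariant to the order
    of the input pairs.
    """
    genes = genome.gene_map()
    uf = _UnionFind()
    for p in homolog_pairs:
        if p.gene_a == p.gene_b or p.chrom_a != p.chrom_b:
            continue
        if abs(p.rank_a - p.rank_b) - 1 <= max_intervening:
            uf.union(p.gene_a, p.gene_b)
    comps: dict[str, list[str]] = defaultdict(list)
    for g in uf.parent:
        comps[uf.find(g)].append(g)
    arrays = []
    for members in comps.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda g: genes[g].rank)
        arrays.append(
            TandemArray(
                chrom=genes[members[0]].chrom,
                members=members,
                max_intervening_used=max_intervening,
            )
        )
    arrays.sort(key=lambda t: (t.chrom, genes[t.members[0]].rank))
    return arrays


# ---------------------------------------------------------------------------
# Duplicate-origin classification
# ---------------------------------------------------------------------------


def families_from_pairs(
    pairs: list[AnchorPair], all_genes: list[str]
) -> dict[str, str]:
    """Gene families as connected components of the homolog-pair graph.

    Genes without any pair form singleton families. Family ids are the
    lexicographically smallest member id.
    """
    uf = _UnionFind()
    for g in all_genes:
        uf.find(g)
    for p in pairs:
        uf.union(p.gene_a, p.gene_b)
    return {g: uf.find(g) for g in all_genes}


def classify_duplicates(
    genome: Genome,
    self_blocks: list[SyntenyBlock],
    tandem_arrays: list[TandemArray],
    families: dict[str, str],
    min_copies: int = 3,
    td_precedence: bool = True,
) -> dict[str, str]:
    """Label each gene WGD / TD / dispersed / singleton.

    A gene is TD when it belongs to a tandem array; WGD when it is an anchor
    in at least one self-synteny block and its family retains at least
    ``min_copies`` syntenic copies (the 3-copies-after-two-WGDs criterion,
    counting the focal gene; configurable); otherwise dispersed when its
    family has >= 2 members, else singleton. With ``td_precedence`` (default)
    TD wins over WGD for genes qualifying as both.
    """
    for g in genome.genes:
        if g.gene_id not in families:
            raise KeyError(f"gene {g.gene_id} missing from families map")
    tandem_genes = {g for arr in tandem_arrays for g in arr.members}
    anchor_genes: set[str] = set()
    for b in self_blocks:
        for a in b.anchors:
            anchor_genes.add(a.gene_a)
            anchor_genes.add(a.gene_b)
    fam_sizes = Counter(families.values())
    fam_syntenic = Counter(families[g] for g in anchor_genes if g in families)

    labels: dict[str, str] = {}
    for g in genome.genes:
        gid = g.gene_id
        fam = families[gid]
        is_td = gid in tandem_genes
        is_wgd = gid in anchor_genes and fam_syntenic[fam] >= min_copies
        if is_td and (td_precedence or not is_wgd):
            labels[gid] = "TD"
        elif is_wgd:
            labels[gid] = "WGD"
        elif fam_sizes[fam] >= 2:
            labels[gid] = "dispersed"
        else:
            labels[gid] = "singleton"
    return labels
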