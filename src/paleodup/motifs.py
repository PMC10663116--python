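"""PWM scanning of promoters and motif-cluster enrichment testing.

Scanning is FIMO-style: each window on both strands is scored with a
log-odds matrix (bits, relative to a 0-order background), and the p-value
P(score >= s | background) is computed exactly by dynamic programming over
the discretised score distribution. Enrichment of a motif in a coexpression
module versus the genomic background (all expressed genes, module included)
uses a one-sided Fisher exact test with Benjamini-Hochberg FDR correction;
motifs with q < 0.1 count as enriched, and clusters with more than 3
enriched member motifs are highlighted.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genome_io import BASE_ORDER, PWM

__all__ = [
    "MotifHit",
    "EnrichmentResult",
    "scan_pwm",
    "scan_promoters",
    "count_module_occurrences",
    "fisher_enrichment",
    "bh_fdr",
    "aggregate_clusters",
    "module_enrichment",
    "background_from_promoters",
    "log_odds_matrix",
]

_GRANULARITY = 1e-3  # bits; score discretisation step for the p-value DP
_NEG = np.iinfo(np.int64).min // 4  # sentinel for log(0) cells


@dataclass
class MotifHit:
    motif_id: str
    gene_id: str
    offset: int  # 0-based window start within the promoter
    strand: str  # "+" | "-"
    score: float  # bits
    p_value: float


@dataclass
class EnrichmentResult:
    motif_id: str
    cluster_id: str
    genes_with_hit_module: int
    module_size: int
    genes_with_hit_background: int
    background_size: int
    odds_ratio: float
    p_value: float
    q_value: float
    enrichment_score: float
    enriched: bool


def _check_background(background: np.ndarray | None) -> np.ndarray:
    if background is None:
        return np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities")
    return bg / bg.sum()


def background_from_promoters(promoters: dict[str, str]) -> np.ndarray:
    """0-order base composition (A,C,G,T) of a promoter set; N ignored."""
    counts = np.zeros(4)
    for seq in promoters.values():
        for j, base in enumerate(BASE_ORDER):
            counts[j] += seq.count(base)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def log_odds_matrix(
    pwm: PWM, background: np.ndarray | None = None, pseudocount: float = 0.1
) -> np.ndarray:
    """L x 4 log2-odds matrix in bits; -inf where probability is zero."""
    bg = _check_background(background)
    probs = pwm.probabilities(pseudocount=pseudocount, background=bg)
    with np.errstate(divide="ignore"):
        return np.log2(probs / bg)


def _int_matrix(lom: np.ndarray) -> np.ndarray:
    """Discretise a log-odds matrix onto the DP grid (int64; _NEG = -inf)."""
    out = np.full(lom.shape, _NEG, dtype=np.int64)
    finite = np.isfinite(lom)
    out[finite] = np.rint(lom[finite] / _GRANULARITY).astype(np.int64)
    return out


class _ScoreDistribution:
    """Exact distribution of window scores under a 0-order background."""

    def __init__(self, int_matrix: np.ndarray, background: np.ndarray):
        mins = []
        maxs = []
        for row in int_matrix:
            finite = row[row != _NEG]
            if len(finite) == 0:
                raise ValueError("PWM row with no scorable base")
            mins.append(int(finite.min()))
            maxs.append(int(finite.max()))
        self.offset = sum(mins)
        size = sum(maxs) - self.offset + 1
        dist = np.zeros(size)
        dist[0] = 1.0
        for row, rmin in zip(int_matrix, mins):
            new = np.zeros(size)
            for j in range(4):
                v = row[j]
                if v == _NEG:
                    continue  # mass lost to unreachable (-inf) paths
                shift = int(v) - rmin
                new[shift : shift + size - shift] += background[j] * dist[: size - shift]
            dist = new
        self.dist = dist
        # tail[i] = P(score >= offset + i); scores below offset have tail
        # equal to the total reachable mass.
        self.tail = np.cumsum(dist[::-1])[::-1]

    def p_value(self, int_score: int) -> float:
        """P(window score >= int_score) for a finite integer score."""
        i = int_score - self.offset
        if i <= 0:
            return float(min(self.tail[0], 1.0)) if len(self.tail) else 1.0
        if i >= len(self.tail):
            return 0.0
        return float(self.tail[i])

    def threshold_for(self, p_threshold: float) -> int:
        """Smallest integer score with p-value <= p_threshold."""
        idx = np.searchsorted(-self.tail, -p_threshold, side="left")
        return self.offset + int(idx)


def _revcomp_matrix(m: np.ndarray) -> np.ndarray:
    return m[::-1, ::-1]


_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASE_ORDER):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_scores(enc: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    """Integer scores of all windows of one encoded sequence (N -> _NEG)."""
    L = len(int_matrix)
    W = len(enc) - L + 1
    if W <= 0:
        return np.zeros(0, dtype=np.int64)
    ext = np.hstack([int_matrix, np.full((L, 1), _NEG, dtype=np.int64)])
    scores = np.zeros(W, dtype=np.int64)
    bad = np.zeros(W, dtype=bool)
    for l in range(L):
        cell = ext[l, enc[l : l + W]]
        bad |= cell == _NEG
        scores += np.where(cell == _NEG, 0, cell)
    scores[bad] = _NEG
    return scores


def scan_pwm(
    promoter: str,
    pwm: PWM,
    background: np.ndarray | None = None,
    p_threshold: float = 1e-4,
    pseudocount: float = 0.1,
) -> list[MotifHit]:
    """Scan one promoter with a PWM on both strands.

    Reports every window (overlaps allowed) whose exact p-value is at most
    ``p_threshold``. Windows containing N are skipped. The minus-strand
    score of a window is the plus-strand score of its reverse complement.
    """
    bg = _check_background(background)
    L = len(pwm)
    if len(promoter) < L:
        raise ValueError("promoter shorter than the motif")
    lom = log_odds_matrix(pwm, bg, pseudocount)
    enc = _encode(promoter)
    hits: list[MotifHit] = []
    for strand in "+-":
        m = _int_matrix(lom) if strand == "+" else _int_matrix(_revcomp_matrix(lom))
        dist = _ScoreDistribution(m, bg)
        scores = _window_scores(enc, m)
        for off in np.nonzero(scores > _NEG // 2)[0]:
            p = dist.p_value(int(scores[off]))
            if p <= p_threshold:
                hits.append(
                    MotifHit(
                        motif_id=pwm.motif_id,
                        gene_id="",
                        offset=int(off),
                        strand=strand,
                        score=float(scores[off]) * _GRANULARITY,
                        p_value=p,
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoters(
    promoters: dict[str, str],
    pwm: PWM,
    background: np.ndarray | None = None,
    p_threshold: float = 1e-4,
    pseudocount: float = 0.1,
) -> dict[str, int]:
    """Number of hits of one PWM per promoter (vectorised batch scan).

    Uses the same integer scoring and exact p-value DP as :func:`scan_pwm`.
    The background defaults to the 0-order composition of the promoter set.
    """
    if background is None:
        background = background_from_promoters(promoters)
    bg = _check_background(background)
    L = len(pwm)
    lom = log_odds_matrix(pwm, bg, pseudocount)
    genes = [g for g, s in promoters.items() if len(s) >= L]
    if not genes:
        return {}
    maxlen = max(len(promoters[g]) for g in genes)
    batch = np.full((len(genes), maxlen), 4, dtype=np.int8)  # pad with N
    for i, g in enumerate(genes):
        enc = _encode(promoters[g])
        batch[i, : len(enc)] = enc
    counts = np.zeros(len(genes), dtype=int)
    W = maxlen - L + 1
    for strand in "+-":
        m = _int_matrix(lom) if strand == "+" else _int_matrix(_revcomp_matrix(lom))
        dist = _ScoreDistribution(m, bg)
        thr = dist.threshold_for(p_threshold)
        ext = np.hstack([m, np.full((L, 1), _NEG, dtype=np.int64)])
        scores = np.zeros((len(genes), W), dtype=np.int64)
        bad = np.zeros((len(genes), W), dtype=bool)
        for l in range(L):
            cell = ext[l][batch[:, l : l + W]]
            bad |= cell == _NEG
            scores += np.where(cell == _NEG, 0, cell)
        scores[bad] = _NEG
        counts += ((scores >= thr) & ~bad).sum(axis=1)
    return dict(zip(genes, counts.tolist()))


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------


def count_module_occurrences(
    hits: list[MotifHit] | dict[str, set[str]],
    module_assignments: dict[str, tuple[str, float]],
    module: str,
    expressed: set[str],
    membership_min: float = 0.8,
) -> dict[str, tuple[int, int, int, int]]:
    """Per-motif gene-level 2x2 inputs for one module vs the background.

    A gene "has" a motif when at least one hit falls in its promoter
    (gene-level occurrence). The module set is the expressed genes assigned
    to ``module`` with membership > ``membership_min``; the background is
    all expressed genes (module included). Returns, per motif,
    ``(genes_with_hit_module, module_size, genes_with_hit_background,
    background_size)``.
    """
    if isinstance(hits, dict):
        genes_by_motif = {m: set(gs) & expressed for m, gs in hits.items()}
    else:
        genes_by_motif = defaultdict(set)
        for h in hits:
            if h.gene_id in expressed:
                genes_by_motif[h.motif_id].add(h.gene_id)
    module_genes = {
        g
        for g, (mod, membership) in module_assignments.items()
        if mod == module and membership > membership_min and g in expressed
    }
    if not module_genes:
        raise ValueError(f"module {module!r} is empty after filtering")
    out = {}
    for motif_id, gset in sorted(genes_by_motif.items()):
        out[motif_id] = (
            len(gset & module_genes),
            len(module_genes),
            len(gset),
            len(expressed),
        )
    return out


def fisher_enrichment(table: list[list[int]]) -> tuple[float, float]:
    """One-sided (greater) Fisher exact test on a 2x2 count table.

    Returns ``(odds_ratio, p_value)`` where the p-value is the upper
    hypergeometric tail P(X >= a) and the odds ratio is (a/b)/(c/d) with a
    0.5 Haldane correction applied when any cell is zero.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative counts")
    total = a + b + c + d
    if total == 0:
        raise ValueError("all-zero table")
    p = float(hypergeom.sf(a - 1, total, a + b, a + c))
    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    odds = (a_ / b_) / (c_ / d_)
    return float(odds), min(p, 1.0)


def bh_fdr(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def module_enrichment(
    counts: dict[str, tuple[int, int, int, int]],
    clusters: dict[str, str] | None = None,
    fdr_threshold: float = 0.1,
) -> list[EnrichmentResult]:
    """Fisher + BH over the per-motif counts of one module.

    ``counts`` maps motif_id -> (hit_module, module_size, hit_background,
    background_size) as produced by :func:`count_module_occurrences`. The
    2x2 table drawn is module genes vs the rest of the background, with the
    background including the module. The enrichment score is the log2 ratio
    of occurrence frequencies (nan when either frequency is zero).
    """
    motif_ids = sorted(counts)
    results = []
    pvals = []
    for m in motif_ids:
        a, module_size, hit_bg, bg_size = counts[m]
        table = [
            [a, module_size - a],
            [hit_bg - a, bg_size - module_size - (hit_bg - a)],
        ]
        odds, p = fisher_enrichment(table)
        pvals.append(p)
        f_mod = a / module_size
        f_bg = hit_bg / bg_size
        score = math.log2(f_mod / f_bg) if f_mod > 0 and f_bg > 0 else math.nan
        results.append(
            EnrichmentResult(
                motif_id=m,
                cluster_id=(clusters or {}).get(m, ""),
                genes_with_hit_module=a,
                module_size=module_size,
                genes_with_hit_background=hit_bg,
                background_size=bg_size,
                odds_ratio=odds,
                p_value=p,
                q_value=math.nan,
                enrichment_score=score,
                enriched=False,
            )
        )
    qvals = bh_fdr(pvals)
    for r, q in zip(results, qvals):
        r.q_value = float(q)
        r.enriched = q < fdr_threshold
    return results


def aggregate_clusters(
    results: list[EnrichmentResult], min_enriched: int = 4
) -> set[str]:
    """Clusters with at least ``min_enriched`` enriched member motifs.

    The default of 4 implements the "more than 3 enriched motifs" highlight
    rule.
    """
    per_cluster: Counter[str] = Counter()
    for r in results:
        if r.enriched and r.cluster_id:
            per_cluster[r.cluster_id] += 1
    return {c for c, n in per_cluster.items() if n >= min_enriched}
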