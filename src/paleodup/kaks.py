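"""Nei-Gojobori (NG86) Ka/Ks estimation on codon alignments.

Synonymous/nonsynonymous *sites* are counted per codon as the fraction of
the three possible single-nucleotide changes at each position that preserve
the amino acid (changes to stop codons are excluded from the numerator but
kept in the denominator of 3). *Differences* between a codon pair differing
at k positions are averaged over the k! single-step mutational pathways,
with pathways passing through stop codons excluded. The proportions
ps = Sd/S and pn = Nd/N are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - 4p/3).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "ng86_sites",
    "ng86_pair",
    "jukes_cantor_correct",
    "align_proteins_global",
    "kaks_for_cds_pair",
    "SENSE_CODONS",
    "GENETIC_CODE",
]

_BASES = "ACGT"
_TABLE = unambiguous_dna_by_id[1]  # standard genetic code
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    c
    for c in ("".join(p) for p in itertools.product(_BASES, repeat=3))
    if c not in STOP_CODONS
)

_CODON_INDEX = {
    "".join(p): 16 * _BASES.index(p[0]) + 4 * _BASES.index(p[1]) + _BASES.index(p[2])
    for p in itertools.product(_BASES, repeat=3)
}


def ng86_sites(codon: str) -> tuple[float, float]:
    """NG86 synonymous and nonsynonymous site counts for one sense codon."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no NG86 site counts")
    if codon not in GENETIC_CODE:
        raise ValueError(f"not an unambiguous sense codon: {codon!r}")
    aa = GENETIC_CODE[codon]
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut not in STOP_CODONS and GENETIC_CODE[mut] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) difference counts for a codon pair.

    Pathways through stop codons are dropped from the average. If every
    pathway is blocked, fall back to classifying each differing position in
    the context of both end codons (equal syn/nonsyn split when neither
    single-position swap yields a sense codon).
    """
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diffs):
        cur = codon_a
        s = n = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            totals.append((s, n))
    if totals:
        s_avg = sum(t[0] for t in totals) / len(totals)
        n_avg = sum(t[1] for t in totals) / len(totals)
        return s_avg, n_avg
    # all pathways blocked: per-position fallback
    s_avg = n_avg = 0.0
    for pos in diffs:
        verdicts = []
        for src, other in ((codon_a, codon_b), (codon_b, codon_a)):
            swapped = src[:pos] + other[pos] + src[pos + 1 :]
            if swapped not in STOP_CODONS:
                verdicts.append(GENETIC_CODE[src] == GENETIC_CODE[swapped])
        if verdicts:
            frac_syn = sum(verdicts) / len(verdicts)
        else:
            frac_syn = 0.5
        s_avg += frac_syn
        n_avg += 1.0 - frac_syn
    return s_avg, n_avg


def _build_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    syn_sites = np.full(64, np.nan)
    nonsyn_sites = np.full(64, np.nan)
    for c in SENSE_CODONS:
        s, n = ng86_sites(c)
        syn_sites[_CODON_INDEX[c]] = s
        nonsyn_sites[_CODON_INDEX[c]] = n
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for ca in SENSE_CODONS:
        for cb in SENSE_CODONS:
            s, n = _pathway_counts(ca, cb)
            sd[_CODON_INDEX[ca], _CODON_INDEX[cb]] = s
            nd[_CODON_INDEX[ca], _CODON_INDEX[cb]] = n
    return syn_sites, nonsyn_sites, sd, nd


_SYN_SITES, _NONSYN_SITES, _SD, _ND = _build_tables()


@dataclass
class CodonAlignment:
    """A pairwise codon alignment reduced to comparable codon columns.

    ``pairs`` holds gap-free, N-free, stop-free codon pairs; ``n_excluded``
    counts the columns dropped during filtering. The raw aligned nucleotide
    strings are retained for round-tripping.
    """

    pairs: list[tuple[str, str]]
    n_excluded: int = 0
    aligned_a: str = ""
    aligned_b: str = ""

    @classmethod
    def from_aligned(cls, aligned_a: str, aligned_b: str) -> "CodonAlignment":
        if len(aligned_a) != len(aligned_b):
            raise ValueError("aligned nucleotide strings differ in length")
        if len(aligned_a) % 3 != 0:
            raise ValueError("aligned nucleotide length not divisible by 3")
        pairs: list[tuple[str, str]] = []
        excluded = 0
        for i in range(0, len(aligned_a), 3):
            ca = aligned_a[i : i + 3].upper()
            cb = aligned_b[i : i + 3].upper()
            if (
                "-" in ca
                or "-" in cb
                or "N" in ca
                or "N" in cb
                or ca in STOP_CODONS
                or cb in STOP_CODONS
            ):
                excluded += 1
                continue
            pairs.append((ca, cb))
        return cls(
            pairs=pairs, n_excluded=excluded, aligned_a=aligned_a, aligned_b=aligned_b
        )

    def ungapped(self, which: str) -> str:
        src = self.aligned_a if which == "a" else self.aligned_b
        return src.replace("-", "")


@dataclass
class KaKsResult:
    """NG86 site/difference counts and JC-corrected Ka, Ks for one pair."""

    S: float
    N_sites: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    saturated: bool = False


def jukes_cantor_correct(p: float) -> tuple[float, bool]:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Returns ``(d, saturated)``; ``saturated`` is True (with d = nan) when
    p >= 0.75, where the correction is undefined.
    """
    if p < 0:
        raise ValueError(f"proportion must be nonnegative, got {p}")
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return math.nan, True
    return -0.75 * math.log(arg), False


def ng86_pair(aln: CodonAlignment) -> KaKsResult:
    """NG86 Ka/Ks for a filtered pairwise codon alignment."""
    if not aln.pairs:
        raise ValueError("empty codon alignment")
    ia = np.array([_CODON_INDEX[a] for a, _ in aln.pairs])
    ib = np.array([_CODON_INDEX[b] for _, b in aln.pairs])
    s_a = _SYN_SITES[ia].sum()
    s_b = _SYN_SITES[ib].sum()
    S = 0.5 * (s_a + s_b)
    N = 3.0 * len(aln.pairs) - S
    Sd = _SD[ia, ib].sum()
    Nd = _ND[ia, ib].sum()
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks, sat_s = jukes_cantor_correct(ps)
    Ka, sat_n = jukes_cantor_correct(pn)
    return KaKsResult(
        S=S, N_sites=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, Ks=Ks, Ka=Ka,
        saturated=sat_s or sat_n,
    )


# ---------------------------------------------------------------------------
# Pairwise protein alignment (deterministic affine Needleman-Wunsch)
# ---------------------------------------------------------------------------

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")


def _make_aligner(
    substitution_matrix: str | object = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if isinstance(substitution_matrix, str):
        substitution_matrix = substitution_matrices.load(substitution_matrix)
    aligner.substitution_matrix = substitution_matrix
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_proteins_global(
    a: str,
    b: str,
    substitution_matrix: str | object = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> tuple[str, str, float]:
    """Optimal global (Needleman-Wunsch, affine-gap) protein alignment.

    Returns ``(aligned_a, aligned_b, score)``. A gap of length k costs
    ``gap_open + (k - 1) * gap_extend``. The first optimal traceback of the
    underlying dynamic program is returned, which is deterministic.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    for name, seq in (("a", a), ("b", b)):
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise ValueError(f"sequence {name} has non-amino-acid symbols: {bad}")
    aligner = _make_aligner(substitution_matrix, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


def kaks_for_cds_pair(cds_a: str, cds_b: str, **align_kwargs) -> KaKsResult:
    """Align two CDSs at the protein level, back-translate, and run NG86."""
    from .genome_io import backtranslate_alignment, translate_cds

    prot_a = translate_cds(cds_a, "a")
    prot_b = translate_cds(cds_b, "b")
    aln_a, aln_b, _score = align_proteins_global(prot_a, prot_b, **align_kwargs)
    codon_aln = backtranslate_alignment((aln_a, aln_b), cds_a, cds_b)
    return ng86_pair(codon_aln)
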