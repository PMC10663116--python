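"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive every quantity by exhaustive enumeration (with
exact Fraction arithmetic where possible) and share no code with the
library paths they verify.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]
_CODE = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------


def ng86_sites_oracle(codon: str) -> tuple[Fraction, Fraction]:
    """Exact NG86 site fractions by direct enumeration of the 9 changes."""
    aa = _CODE[codon]
    syn = Fraction(0)
    for pos in range(3):
        preserved = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut not in _STOPS and _CODE[mut] == aa:
                preserved += 1
        syn += Fraction(preserved, 3)
    return syn, Fraction(3) - syn


def _paths(codon_a: str, codon_b: str):
    """Yield (syn, nonsyn, blocked) for each mutational pathway ordering."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    for order in itertools.permutations(diffs):
        cur = codon_a
        s = n = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
                break
            if _CODE[cur] == _CODE[nxt]:
                s += 1
            else:
                n += 1
            cur = nxt
        yield s, n, blocked


def ng86_differences_oracle(codon_a: str, codon_b: str) -> tuple[Fraction, Fraction]:
    """Pathway-averaged (Sd, Nd) with exact arithmetic.

    Blocked pathways are excluded; when every pathway is blocked each
    differing position is classified by the single-position swap in the
    context of both codons (half/half when neither swap is a sense codon).
    """
    usable = [(s, n) for s, n, blocked in _paths(codon_a, codon_b) if not blocked]
    if usable:
        k = len(usable)
        return (
            Fraction(sum(s for s, _ in usable), k),
            Fraction(sum(n for _, n in usable), k),
        )
    sd = nd = Fraction(0)
    for pos in (i for i in range(3) if codon_a[i] != codon_b[i]):
        verdicts = []
        for src, other in ((codon_a, codon_b), (codon_b, codon_a)):
            swapped = src[:pos] + other[pos] + src[pos + 1 :]
            if swapped not in _STOPS:
                verdicts.append(_CODE[src] == _CODE[swapped])
        frac = (
            Fraction(sum(verdicts), len(verdicts)) if verdicts else Fraction(1, 2)
        )
        sd += frac
        nd += 1 - frac
    return sd, nd


def ng86_pair_oracle(pairs: list[tuple[str, str]]):
    """Exact (S, N, Sd, Nd) for a list of codon pairs."""
    S = N = Sd = Nd = Fraction(0)
    for ca, cb in pairs:
        sa, _ = ng86_sites_oracle(ca)
        sb, _ = ng86_sites_oracle(cb)
        S += (sa + sb) / 2
        N += 3 - (sa + sb) / 2
        s, n = ng86_differences_oracle(ca, cb)
        Sd += s
        Nd += n
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------
# Global affine alignment score
# ---------------------------------------------------------------------------


def nw_affine_bruteforce(
    a: str, b: str, matrix, gap_open: float, gap_extend: float
) -> float:
    """Maximum global alignment score over all alignments (lengths <= ~6).

    Gap convention matches Bio.Align.PairwiseAligner: a gap of length k
    costs gap_open + (k - 1) * gap_extend.
    """

    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            best = max(best, matrix[a[i], b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):  # a[i] aligned to a gap in b
            cost = gap_extend if last == "GB" else gap_open
            best = max(best, cost + rec(i + 1, j, "GB"))
        if j < len(b):  # gap in a
            cost = gap_extend if last == "GA" else gap_open
            best = max(best, cost + rec(i, j + 1, "GA"))
        return best

    return rec(0, 0, "M")


# ---------------------------------------------------------------------------
# Chain score
# ---------------------------------------------------------------------------


def best_chain_bruteforce(
    anchors: list[tuple[int, int, float]], max_gap: int, gap_penalty: float
) -> float:
    """Best chain score over all monotone subsequences (n <= ~10).

    Each anchor is (rank_a, rank_b, score); both orientations are tried.
    """
    n = len(anchors)
    best = 0.0
    for mask in range(1, 1 << n):
        chosen = sorted(
            (anchors[i] for i in range(n) if mask & (1 << i)),
            key=lambda t: (t[0], t[1]),
        )
        for sign in (1, -1):
            score = chosen[0][2]
            ok = True
            for (ra0, rb0, _), (ra1, rb1, s1) in zip(chosen, chosen[1:]):
                da = ra1 - ra0
                db = sign * (rb1 - rb0)
                if not (1 <= da <= max_gap and 1 <= db <= max_gap):
                    ok = False
                    break
                score += s1 - gap_penalty * ((da - 1) + (db - 1))
            if ok:
                best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# Fisher exact (one-sided greater), exact hypergeometric sum
# ---------------------------------------------------------------------------


def fisher_greater_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    from math import comb

    M = a + b + c + d
    K = a + b  # successes in the population (row 1)
    n = a + c  # draws (column 1)
    denom = comb(M, n)
    total = Fraction(0)
    for k in range(a, min(K, n) + 1):
        total += Fraction(comb(K, k) * comb(M - K, n - k), denom)
    return total


# ---------------------------------------------------------------------------
# PWM window-score distribution by enumeration
# ---------------------------------------------------------------------------


def pwm_tail_oracle(int_matrix, background) -> dict[int, float]:
    """P(score >= s) for every achievable integer window score.

    Enumerates all 4**L windows; windows hitting a -inf (sentinel) cell are
    unreachable-by-score and excluded from every tail.
    """
    L = len(int_matrix)
    probs: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=L):
        score = 0
        dead = False
        p = 1.0
        for l, j in enumerate(word):
            v = int(int_matrix[l][j])
            if v < -(10**12):  # the -inf sentinel
                dead = True
                break
            score += v
            p *= background[j]
        if not dead:
            probs[score] = probs.get(score, 0.0) + p
    tails: dict[int, float] = {}
    acc = 0.0
    for s in sorted(probs, reverse=True):
        acc += probs[s]
        tails[s] = acc
    return tails
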