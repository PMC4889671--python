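"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written from first principles — plain
dynamic programming, exact rational arithmetic, exhaustive scans — and
shares no code path with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction

# standard genetic code, written out independently of any library
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def translate_oracle(dna: str) -> str:
    """Frame +1 translation by direct codon table lookup."""
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        out.append(GENETIC_CODE.get(dna[i : i + 3], "X"))
    return "".join(out)


def revcomp_oracle(dna: str) -> str:
    return "".join(_COMP[b] for b in reversed(dna))


def sw_affine_oracle(query: str, subject: str, matrix, gap_open: int, gap_extend: int) -> float:
    """Smith–Waterman local alignment with affine gaps, plain 3-matrix DP.

    A gap of length L costs gap_open + L * gap_extend.  ``matrix`` is
    indexed as matrix[a, b].
    """
    n, m = len(query), len(subject)
    NEG = float("-inf")
    open_cost = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (move along subject)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - gap_extend)
            s = matrix[query[i - 1], subject[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def six_frame_best_score_oracle(query: str, dna: str, matrix, gap_open: int, gap_extend: int) -> float:
    """Best local-alignment score of query over all six frames of dna."""
    rc = revcomp_oracle(dna)
    best = 0.0
    for strand_seq in (dna, rc):
        for off in range(3):
            pep = translate_oracle(strand_seq[off:])
            best = max(best, sw_affine_oracle(query, pep, matrix, gap_open, gap_extend))
    return best


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration with exact rationals.

    Returns log10(p).  Sums P(k) over all tables with the observed
    margins whose point probability does not exceed the observed one.
    """
    r1, r2 = a + b, c + d
    c1, n = a + c, a + b + c + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 0.0
    denom = math.comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
    p_obs = probs[a]
    p = sum(v for v in probs.values() if v <= p_obs)
    return math.log10(p)


def n50_scan_oracle(lengths: list[int]) -> int:
    """Largest L with sum(lengths >= L) >= total/2, by exhaustive scan."""
    total = sum(lengths)
    best = 0
    for L in sorted(set(lengths)):
        if 2 * sum(x for x in lengths if x >= L) >= total:
            best = max(best, L)
    return best
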