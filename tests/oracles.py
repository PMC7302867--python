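"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's implementation routes: the scanner
oracle extends runs base by base in pure Python and uses its own
hand-transcribed species table; the probability oracles use exact rational
arithmetic; the overlap oracle iterates every nucleotide.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

ACGT = set("ACGT")

# species table written out group by group (independent of the package's
# orbit construction)
ORACLE_SPECIES = {}
for _label, _words in {
    "A/T": ["A", "T"],
    "C/G": ["C", "G"],
    "TA": ["TA", "AT"],
    "CT/GA": ["CT", "TC", "GA", "AG"],
    "CA/GT": ["CA", "AC", "GT", "TG"],
    "GC": ["GC", "CG"],
    "AAC": ["AAC", "ACA", "CAA", "GTT", "TGT", "TTG"],
    "AAG": ["AAG", "AGA", "GAA", "CTT", "TCT", "TTC"],
    "AAT": ["AAT", "ATA", "TAA", "ATT", "TAT", "TTA"],
    "ACC": ["ACC", "CCA", "CAC", "GGT", "TGG", "GTG"],
    "GAC": ["GAC", "ACG", "CGA", "GTC", "CGT", "TCG"],
    "ACT": ["ACT", "CTA", "TAC", "AGT", "TAG", "GTA"],
    "CAG": ["CAG", "AGC", "GCA", "CTG", "GCT", "TGC"],
    "AGG": ["AGG", "GGA", "GAG", "CCT", "TCC", "CTC"],
    "ATC": ["ATC", "TCA", "CAT", "GAT", "TGA", "ATG"],
    "CGG": ["CGG", "GGC", "GCG", "CCG", "GCC", "CGC"],
}.items():
    for _w in _words:
        ORACLE_SPECIES[_w] = _label

ORACLE_CLADE = {1: "MNR", 2: "DNR", 3: "TNR"}
ORACLE_MINLEN = {1: 6, 2: 6, 3: 9}


def oracle_smallest_period(s: str) -> int:
    for p in range(1, len(s) + 1):
        if all(s[i] == s[i - p] for i in range(p, len(s))):
            return p
    raise AssertionError("unreachable")


def oracle_scan(seq: str):
    """All maximal perfect repeat runs, as tuples
    (start, end, clade, species, unit_len), sorted by (start, unit_len)."""
    s = seq.upper()
    L = len(s)
    out = []
    for p in (1, 2, 3):
        for i in range(L - p + 1):
            if any(s[i + t] not in ACGT for t in range(p)):
                continue
            j = i + p
            while j < L and s[j] in ACGT and s[j] == s[j - p]:
                j += 1
            if j - i < ORACLE_MINLEN[p]:
                continue
            # left-maximality: position i-1 must not extend the period
            if i > 0 and s[i - 1] in ACGT and s[i - 1] == s[i - 1 + p]:
                continue
            if oracle_smallest_period(s[i:j]) != p:
                continue
            # explicit maximality double-check by one-base extension
            assert j == L or s[j] not in ACGT or s[j] != s[j - p]
            out.append((i, j, ORACLE_CLADE[p], ORACLE_SPECIES[s[i : i + p]], p))
    out.sort(key=lambda r: (r[0], r[4]))
    return out


def oracle_binom_over(k: int, M: int, n: int, N: int) -> Fraction:
    """Exact P(X >= k), X ~ Binomial(M, n/N), as a Fraction."""
    q = Fraction(n, N)
    return sum(
        comb(M, i) * q**i * (1 - q) ** (M - i) for i in range(k, M + 1)
    )


def oracle_binom_under(k: int, M: int, n: int, N: int) -> Fraction:
    q = Fraction(n, N)
    return sum(comb(M, i) * q**i * (1 - q) ** (M - i) for i in range(0, k + 1))


def oracle_hypergeom_over(E: int, k_e: int, N: int, n: int) -> Fraction:
    """Exact P(X >= k_e), X hypergeometric (population N, successes n, draws E)."""
    total = comb(N, E)
    return Fraction(
        sum(comb(n, x) * comb(N - n, E - x) for x in range(k_e, min(E, n) + 1)), total
    )


def oracle_overlap(features, territory_intervals, mode: str):
    """Per-nucleotide membership count.  ``territory_intervals`` maps chrom to
    a list of [start, end) pairs (need not be merged)."""
    member = {
        chrom: {pos for s, e in iv for pos in range(s, e)}
        for chrom, iv in territory_intervals.items()
    }
    k = 0
    M = 0
    for chrom, start, end in features:
        hits = sum(1 for pos in range(start, end) if pos in member.get(chrom, ()))
        if mode == "singleton":
            M += 1
            k += 1 if hits else 0
        else:
            M += end - start
            k += hits
    return k, M


def oracle_ks(a, b) -> float:
    """sup |ECDF_a - ECDF_b| evaluated at every sample point."""
    a, b = sorted(a), sorted(b)
    points = sorted(set(a) | set(b))

    def ecdf(sample, x):
        return sum(1 for v in sample if v <= x) / len(sample)

    return max(abs(ecdf(a, x) - ecdf(b, x)) for x in points)


def oracle_pearson(x, y):
    """Textbook covariance / variance arithmetic."""
    nx = len(x)
    mx = sum(x) / nx
    my = sum(y) / nx
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx**0.5 * vy**0.5)
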