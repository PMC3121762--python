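"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: digestion is
re-derived by enumerating every substring and checking the tryptic-boundary
rule, and Fisher's exact test by exact hypergeometric enumeration with
rational arithmetic.
"""

from fractions import Fraction
from math import comb


def oracle_digest(sequence, max_missed, min_len, max_len, proline_rule=True):
    """All tryptic peptides of ``sequence`` as (peptide, start, end, mc)
    with 1-based inclusive coordinates, by substring enumeration."""

    def is_cut(k):  # boundary between residues k-1 and k (0-based), 1 <= k < len
        if sequence[k - 1] not in "KR":
            return False
        if proline_rule and sequence[k] == "P":
            return False
        return True

    n = len(sequence)
    out = []
    for i in range(n):
        if not (i == 0 or is_cut(i)):
            continue
        for j in range(i + 1, n + 1):
            if not (j == n or is_cut(j)):
                continue
            internal = sum(1 for k in range(i + 1, j) if is_cut(k))
            if internal <= max_missed and min_len <= j - i <= max_len:
                out.append((sequence[i:j], i + 1, j, internal))
    return sorted(out)


def oracle_fisher_two_sided(table):
    """Exact two-sided Fisher p-value by hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed the observed table's (with a tiny relative
    tolerance against ties, as standard implementations do).
    """
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    denom = comb(n, col1)

    def prob(x):
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > row2:
            return Fraction(0)
        return Fraction(comb(row1, x) * comb(row2, col1 - x), denom)

    p_obs = prob(a)
    cutoff = p_obs * Fraction(10**7 + 1, 10**7)
    total = sum(prob(x) for x in range(col1 + 1) if prob(x) <= cutoff)
    return float(total)
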