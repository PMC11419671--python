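"""Independent brute-force oracles used only by the tests.

Both exact tests are re-derived here by enumeration in exact integer /
rational arithmetic (math.comb + fractions), sharing no code with the
implementation under test. The minimum-likelihood tie tolerance is the exact
value of the float constant the implementation documents.
"""

from fractions import Fraction
from math import comb

TIE_TOL = Fraction(1.0 + 1e-7)  # exact value of the documented float constant


def binomial_minlike_p(x: int, n: int, p0_num: int, p0_den: int) -> Fraction:
    """Two-sided minimum-likelihood binomial p-value, exact rational."""
    q_num = p0_den - p0_num
    if p0_num == 0:
        return Fraction(1) if x == 0 else Fraction(0)
    if p0_num == p0_den:
        return Fraction(1) if x == n else Fraction(0)
    # integer weights: C(n,k) * p^k * q^(n-k) scaled by p0_den^n
    w = [comb(n, k) * p0_num**k * q_num ** (n - k) for k in range(n + 1)]
    threshold = Fraction(w[x]) * TIE_TOL
    kept = sum(wk for wk in w if wk <= threshold)
    return Fraction(kept, p0_den**n)


def fisher_minlike_p(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided minimum-likelihood Fisher p-value, exact rational."""
    r1, c1, total = a + b, a + c, a + b + c + d
    if total == 0 or r1 in (0, total) or c1 in (0, total):
        return Fraction(1)
    lo, hi = max(0, r1 + c1 - total), min(r1, c1)
    w = {k: comb(c1, k) * comb(total - c1, r1 - k) for k in range(lo, hi + 1)}
    threshold = Fraction(w[a]) * TIE_TOL
    kept = sum(wk for wk in w.values() if wk <= threshold)
    return Fraction(kept, sum(w.values()))
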