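"""Independent brute-force oracles used to freeze expected values.

These deliberately avoid the code paths they check: exact rational
arithmetic for the Fisher test, and a direct transcription of the variant
triage rules.
"""

from fractions import Fraction
from math import comb


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration with
    exact rational arithmetic (total-probability method)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or n - c1 == 0:
        return Fraction(1)
    denom = comb(n, c1)
    kmin, kmax = max(0, c1 - r2), min(r1, c1)
    probs = [Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(kmin, kmax + 1)]
    p_obs = probs[a - kmin]
    return sum(p for p in probs if p <= p_obs)


def variant_survives(v, min_depth=5, max_depth=100, somatic_min_freq=0.2,
                     loh_high=0.75, loh_low=0.25, min_support=2) -> bool:
    """Literal transcription of the heuristic triage rules."""
    depths_ok = (min_depth <= v.donor_depth <= max_depth
                 and min_depth <= v.clone_depth <= max_depth)
    if v.claimed_class == "somatic":
        freq_ok = v.clone_var_freq > somatic_min_freq
    elif v.claimed_class == "LOH":
        freq_ok = v.clone_var_freq > loh_high or v.clone_var_freq < loh_low
    else:
        freq_ok = False
    return depths_ok and freq_ok and v.clone_alt_reads >= min_support
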