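"""Independent Fisher-exact oracle: exhaustive hypergeometric enumeration."""

import math


def fisher_enumeration(a, b, c, d):
    """Two-sided Fisher p summing hypergeometric probabilities <= observed,
    over all 2x2 tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(r1 + r2, c1))

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-9))
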