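"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the library code paths they are used to check.
"""

import math

import numpy as np


def poisson_sf_oracle(t: int, lam: float) -> float:
    """Direct summation of the upper tail P(X >= t), term by term in log
    space, so tiny tails keep full relative precision."""
    if t == 0:
        return 1.0
    terms = []
    first_log = None
    k = t
    while True:
        log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
        terms.append(math.exp(log_term))
        if first_log is None:
            first_log = log_term
        # stop once terms are negligible relative to the leading term
        # (compare in log space: exp() may underflow to exactly 0.0)
        if log_term < first_log - 45 and k > lam:
            break
        k += 1
    return math.fsum(terms)


def bh_oracle(p):
    """Naive O(m^2) step-up definition: q_i = min over j with p_j >= p_i of
    p_j * m / rank_j, capped at 1."""
    m = len(p)
    srt = sorted(p)
    out = []
    for pi in p:
        cands = [pj * m / (j + 1) for j, pj in enumerate(srt) if pj >= pi]
        out.append(min(min(cands), 1.0))
    return out


def hypergeom_tail_oracle(a: int, b: int, c: int, d: int) -> float:
    """Full enumeration of P(X >= a) with exact integer binomials."""
    n, k_set1, n_draw = a + b + c + d, a + b, a + c
    denom = math.comb(n, n_draw)
    num = sum(math.comb(k_set1, k) * math.comb(n - k_set1, n_draw - k)
              for k in range(a, min(k_set1, n_draw) + 1))
    return num / denom


def brute_force_profile_matrix(starts, ends, values, centers, flank, n_bins,
                               chrom_len=10_000):
    """Per-base oracle for metaprofiles: expand the track to a base vector
    (zeros outside) and average integer-width bins."""
    base = np.zeros(chrom_len + 4 * flank)
    offset = 2 * flank
    for s, e, v in zip(starts, ends, values):
        base[s + offset:e + offset] = v
    width = 2 * flank // n_bins
    rows = []
    for c in centers:
        mid = (c.start + c.end) // 2
        lo = mid - flank + offset
        rows.append(base[lo:lo + 2 * flank].reshape(n_bins, width).mean(axis=1))
    return np.array(rows)
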