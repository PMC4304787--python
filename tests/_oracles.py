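"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_min_error(hist):
    """Loop over all 256 levels minimizing the two-Gaussian classification
    error criterion, with the same variance floor (1/12) and
    plateau-midpoint convention the implementation promises."""
    hist = np.asarray(hist, dtype=float)
    levels = np.arange(256.0)
    best = []
    best_j = np.inf
    for T in range(256):
        w1 = hist[:T + 1].sum()
        w2 = hist[T + 1:].sum()
        if w1 == 0 or w2 == 0:
            continue
        m1 = (hist[:T + 1] * levels[:T + 1]).sum() / w1
        m2 = (hist[T + 1:] * levels[T + 1:]).sum() / w2
        v1 = max((hist[:T + 1] * (levels[:T + 1] - m1) ** 2).sum() / w1, 1 / 12)
        v2 = max((hist[T + 1:] * (levels[T + 1:] - m2) ** 2).sum() / w2, 1 / 12)
        P1 = w1 / (w1 + w2)
        P2 = w2 / (w1 + w2)
        J = 1 + P1 * np.log(v1) + P2 * np.log(v2) \
            - 2 * (P1 * np.log(P1) + P2 * np.log(P2))
        if J < best_j - 1e-12:
            best_j = J
            best = [T]
        elif abs(J - best_j) <= 1e-12:
            best.append(T)
    return best[(len(best) - 1) // 2]
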