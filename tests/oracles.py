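"""Independent brute-force oracles used by the test suite.

These are deliberately naive O(N^2) double-loop implementations of the
template-matching entropies, written directly from their definitions
and sharing no code with the package's vectorised versions.
"""

import math

import numpy as np


def brute_apen(x, m=2, r_coeff=0.15):
    x = np.asarray(x, dtype=float)
    N = len(x)
    r = r_coeff * np.std(x)

    def phi(mm):
        templates = [x[i:i + mm] for i in range(N - mm + 1)]
        total = 0.0
        for i in range(len(templates)):
            count = 0
            for j in range(len(templates)):
                if np.max(np.abs(templates[i] - templates[j])) <= r:
                    count += 1
            total += math.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def _brute_pair_counts(x, m, r):
    N = len(x)
    t_m = [x[i:i + m] for i in range(N - m)]
    t_m1 = [x[i:i + m + 1] for i in range(N - m)]
    B = sum(
        1
        for i in range(len(t_m))
        for j in range(len(t_m))
        if i != j and np.max(np.abs(t_m[i] - t_m[j])) <= r
    )
    A = sum(
        1
        for i in range(len(t_m1))
        for j in range(len(t_m1))
        if i != j and np.max(np.abs(t_m1[i] - t_m1[j])) <= r
    )
    return B, A


def brute_samen(x, m=2, r_coeff=0.15):
    x = np.asarray(x, dtype=float)
    B, A = _brute_pair_counts(x, m, r_coeff * np.std(x))
    if B == 0:
        return float("nan")
    return math.log(B) if A == 0 else math.log(B / A)


def brute_msamen(x, m=2, r_coeff=0.15, center_coeff=0.5):
    x = np.asarray(x, dtype=float)
    N = len(x)
    r = r_coeff * np.std(x)

    def weight(d):
        return 1.0 / (1.0 + math.exp(d - center_coeff * r))

    def weighted(mm):
        templates = [x[i:i + mm] for i in range(N - m)]
        return sum(
            weight(np.max(np.abs(templates[i] - templates[j])))
            for i in range(len(templates))
            for j in range(len(templates))
            if i != j
        )

    B, A = weighted(m), weighted(m + 1)
    if B == 0:
        return float("nan")
    return math.log(B / A) if A > 0 else math.log(B)
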