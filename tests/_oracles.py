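"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library routines they are checking: labeling is
a queue-based flood fill, Otsu is an exhaustive between-class-variance sweep,
the t-test p-value comes straight from the regularised incomplete beta
function, and the K² statistic is composed step by step from the published
skewness/kurtosis approximations.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def flood_fill_label(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """Connected-component labels by breadth-first flood fill."""
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=int)
    current = 0
    for r in range(binary.shape[0]):
        for c in range(binary.shape[1]):
            if binary[r, c] and labels[r, c] == 0:
                current += 1
                queue = deque([(r, c)])
                labels[r, c] = current
                while queue:
                    rr, cc = queue.popleft()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if (
                            0 <= nr < binary.shape[0]
                            and 0 <= nc < binary.shape[1]
                            and binary[nr, nc]
                            and labels[nr, nc] == 0
                        ):
                            labels[nr, nc] = current
                            queue.append((nr, nc))
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label images induce the same partition of the pixels."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or np.any((a > 0) != (b > 0)):
        return False
    fg = a > 0
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    # a bijection: each a-label maps to exactly one b-label and vice versa
    return len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})


def otsu_exhaustive(values: np.ndarray) -> float:
    """Maximise between-class variance over every possible cut."""
    values = np.asarray(values).ravel()
    candidates = np.unique(values)[:-1]  # cutting above the max leaves one class
    best_t, best_var = None, -1.0
    for t in candidates:
        lo, hi = values[values <= t], values[values > t]
        w0, w1 = lo.size / values.size, hi.size / values.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, float(t)
    return best_t


def t_p_value_betainc(t_stat: float, df: int) -> float:
    """Two-sided p from the regularised incomplete beta function."""
    from scipy.special import betainc

    return float(betainc(df / 2.0, 0.5, df / (df + t_stat**2)))


def k2_statistic(values) -> float:
    """D'Agostino–Pearson K² composed from its published pieces."""
    x = np.asarray(values, dtype=float)
    n = x.size
    m = x.mean()
    m2 = ((x - m) ** 2).mean()
    m3 = ((x - m) ** 3).mean()
    m4 = ((x - m) ** 4).mean()

    # skewness piece (D'Agostino 1970)
    b1 = m3 / m2**1.5
    y = b1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / ((n - 2) * (n + 5) * (n + 7) * (n + 9))
    w_sq = -1 + math.sqrt(2 * (beta2 - 1))
    delta = 1 / math.sqrt(0.5 * math.log(w_sq))
    alpha = math.sqrt(2.0 / (w_sq - 1))
    z1 = delta * math.log(y / alpha + math.sqrt((y / alpha) ** 2 + 1))

    # kurtosis piece (Anscombe & Glynn 1983)
    b2 = m4 / m2**2
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xx = (b2 - e_b2) / math.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n**2 - 5 * n + 2) / ((n + 7) * (n + 9))
        * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3)))
    )
    a = 6.0 + 8.0 / sqrt_beta1 * (2.0 / sqrt_beta1 + math.sqrt(1 + 4.0 / sqrt_beta1**2))
    z2 = (
        (1 - 2.0 / (9 * a)) - ((1 - 2.0 / a) / (1 + xx * math.sqrt(2.0 / (a - 4)))) ** (1.0 / 3)
    ) / math.sqrt(2.0 / (9 * a))

    return z1**2 + z2**2
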