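"""Independent brute-force oracles used only by the tests.

Each oracle recomputes a quantity by explicit enumeration (double loops,
explicit partitions, characteristic polynomials) so it shares no code path
with the implementation it checks.
"""

import numpy as np


def pairwise_mean_r(x: np.ndarray) -> float:
    """Mean pairwise Pearson correlation by explicit double loop."""
    n, k = x.shape
    rs = []
    for i in range(k):
        for j in range(i):
            a, b = x[:, i], x[:, j]
            am, bm = a - a.mean(), b - b.mean()
            rs.append(float(np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2))))
    return float(np.mean(rs))


def pooled_d(g1: np.ndarray, g0: np.ndarray) -> float:
    """Pooled-SD Cohen's d from first principles."""
    n1, n0 = len(g1), len(g0)
    v1 = sum((v - np.mean(g1)) ** 2 for v in g1) / (n1 - 1)
    v0 = sum((v - np.mean(g0)) ** 2 for v in g0) / (n0 - 1)
    sp = np.sqrt(((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2))
    return float((np.mean(g1) - np.mean(g0)) / sp)


def mambac_y(inp: np.ndarray, out: np.ndarray, cuts) -> np.ndarray:
    """MAMBAC by explicit partition at each cut (input must be tie-free)."""
    order = np.argsort(inp)
    sorted_out = out[order]
    ys = []
    for c in cuts:
        below = sorted_out[:c]
        above = sorted_out[c:]
        ys.append(float(np.mean(above)) - float(np.mean(below)))
    return np.array(ys)


def zero_diag_max_eig(cov: np.ndarray) -> float:
    """Largest eigenvalue of a zero-diagonal symmetric matrix via its
    characteristic polynomial (explicit minors), not an eigensolver."""
    a = cov.copy()
    np.fill_diagonal(a, 0.0)
    k = a.shape[0]
    if k == 2:
        return abs(a[0, 1])
    if k == 3:
        tr = 0.0
        minors = (
            a[1, 1] * a[2, 2] - a[1, 2] * a[2, 1]
            + a[0, 0] * a[2, 2] - a[0, 2] * a[2, 0]
            + a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
        )
        det = np.linalg.det(a)
        roots = np.roots([1.0, -tr, minors, -det])
        return float(np.max(roots.real))
    raise NotImplementedError


def window_cov(x: np.ndarray) -> np.ndarray:
    """Sample covariance by explicit loops."""
    n, k = x.shape
    m = x.mean(axis=0)
    c = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            c[i, j] = np.sum((x[:, i] - m[i]) * (x[:, j] - m[j])) / (n - 1)
    return c
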