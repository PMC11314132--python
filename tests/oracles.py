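"""Independent brute-force oracles used to cross-check the implementations.

These deliberately share no code with the package: DTW is checked by
enumerating every monotone warping path, Otsu by a naive per-threshold
class-statistics loop.
"""

from __future__ import annotations


def enumerate_warping_paths(n: int, m: int):
    """All monotone index paths from (0,0) to (n-1,m-1) with steps
    (1,0), (0,1), (1,1)."""

    def rec(i, j, path):
        if i == n - 1 and j == m - 1:
            yield path
            return
        for di, dj in ((1, 0), (0, 1), (1, 1)):
            ni, nj = i + di, j + dj
            if ni < n and nj < m:
                yield from rec(ni, nj, path + [(ni, nj)])

    yield from rec(0, 0, [(0, 0)])


def dtw_bruteforce(x, y) -> float:
    """Minimum path cost over the full enumeration (feasible for len <= ~7)."""
    return min(
        sum(abs(x[i] - y[j]) for i, j in path)
        for path in enumerate_warping_paths(len(x), len(y))
    )


def dtw2_bruteforce(x, y) -> float:
    """Two-component variant with Euclidean local cost."""
    return min(
        sum(
            ((x[i][0] - y[j][0]) ** 2 + (x[i][1] - y[j][1]) ** 2) ** 0.5
            for i, j in path
        )
        for path in enumerate_warping_paths(len(x), len(y))
    )


def otsu_bruteforce(counts) -> int:
    """Smallest t in [0, 255] maximizing between-class variance for the
    split {v < t} vs {v >= t}, computed with plain Python loops."""
    best_t, best_v = 0, -1.0
    for t in range(256):
        w0 = w1 = s0 = s1 = 0.0
        for v in range(256):
            c = float(counts[v])
            if v < t:
                w0 += c
                s0 += v * c
            else:
                w1 += c
                s1 += v * c
        mu0 = s0 / w0 if w0 else 0.0
        mu1 = s1 / w1 if w1 else 0.0
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_v:
            best_v, best_t = var, t
    return best_t
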