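"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain double loops over definitions, sharing no
code with the package's fast paths.
"""

from __future__ import annotations

import numpy as np


def sampen_bruteforce(x: np.ndarray, m: int, r_factor: float) -> float:
    """Sample entropy by explicit template double loop (Chebyshev distance)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_factor * x.std()

    def count(length: int) -> int:
        n_templates = n - m
        c = 0
        for i in range(n_templates):
            for j in range(n_templates):
                if i == j:
                    continue
                dist = max(abs(x[i + k] - x[j + k]) for k in range(length))
                if dist <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        return float("nan")
    return -np.log(a / b)


def _equiprobable_codes(x: np.ndarray, bins: int) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, bins + 1))
    edges[-1] += 1e-12
    codes = np.empty(len(x), dtype=int)
    for idx, v in enumerate(x):
        k = 0
        for e in range(1, bins + 1):
            if v >= edges[e]:
                k = e
        codes[idx] = min(k, bins - 1)
    return codes


def mi_bruteforce(x: np.ndarray, lag: int, bins: int = 16) -> float:
    """Histogram mutual information at one lag, nats, by explicit counting."""
    codes = _equiprobable_codes(np.asarray(x, dtype=float), bins)
    a, b = codes[:-lag], codes[lag:]
    joint = np.zeros((bins, bins))
    for ai, bi in zip(a, b):
        joint[ai, bi] += 1
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    mi = 0.0
    for i in range(bins):
        for j in range(bins):
            if joint[i, j] > 0:
                mi += joint[i, j] * np.log(joint[i, j] / (px[i] * py[j]))
    return mi


def fnn_fraction_bruteforce(x: np.ndarray, tau: int, d: int, rtol: float = 10.0) -> float:
    """Kennel false-nearest-neighbor fraction by all-pairs search."""
    x = np.asarray(x, dtype=float)
    n_usable = len(x) - d * tau
    pts = np.array([[x[i + k * tau] for k in range(d)] for i in range(n_usable)])
    floor = 1e-9 * x.std()
    false = 0
    for i in range(n_usable):
        best, best_j = np.inf, -1
        for j in range(n_usable):
            if j == i:
                continue
            dist = np.sqrt(((pts[i] - pts[j]) ** 2).sum())
            if dist < best:
                best, best_j = dist, j
        extra = abs(x[i + d * tau] - x[best_j + d * tau])
        if extra > rtol * max(best, floor):
            false += 1
    return false / n_usable


def recurrence_bruteforce(x: np.ndarray, d: int, tau: int, eps_frac: float) -> np.ndarray:
    """Recurrence plot by explicit pairwise Euclidean distances."""
    x = np.asarray(x, dtype=float)
    m = len(x) - (d - 1) * tau
    pts = np.array([[x[i + k * tau] for k in range(d)] for i in range(m)])
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            dist[i, j] = np.sqrt(((pts[i] - pts[j]) ** 2).sum())
    total = sum(dist[i, j] for i in range(m) for j in range(m) if i != j)
    eps = eps_frac * total / (m * (m - 1))
    return (dist <= eps).astype(int)


def det_bruteforce(r: np.ndarray, lmin: int) -> float:
    """Determinism by walking every off-main diagonal and counting runs."""
    r = np.asarray(r)
    n = len(r)
    total = 0
    on_long = 0
    for off in range(-(n - 1), n):
        if off == 0:
            continue
        i0, j0 = (0, off) if off > 0 else (-off, 0)
        run = 0
        cells = []
        i, j = i0, j0
        while i < n and j < n:
            cells.append(r[i, j])
            i += 1
            j += 1
        for v in cells + [0]:
            if v:
                run += 1
            else:
                if run:
                    total += run
                    if run >= lmin:
                        on_long += run
                run = 0
    return on_long / total if total else 0.0


def welch_bruteforce(x: np.ndarray, fs: float = 1000.0) -> tuple[np.ndarray, np.ndarray]:
    """Averaged modified periodogram: 4096-point Hamming, 50% overlap,
    8192-point FFT, one-sided density scaling, per-segment mean removal."""
    x = np.asarray(x, dtype=float)
    nper, nfft, step = 4096, 8192, 2048
    w = np.hamming(nper + 1)[:-1]  # periodic (DFT-even) Hamming window
    scale = 1.0 / (fs * (w**2).sum())
    psds = []
    start = 0
    while start + nper <= len(x):
        seg = x[start : start + nper]
        seg = seg - seg.mean()
        spec = np.fft.rfft(seg * w, nfft)
        p = scale * np.abs(spec) ** 2
        p[1:-1] *= 2.0
        psds.append(p)
        start += step
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    return freqs, np.mean(psds, axis=0)


def kruskal_h_bruteforce(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with tie correction from the rank definition."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    pos = 1
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        avg = (pos + pos + (j - i) - 1) / 2.0
        for k in range(i, j):
            ranks[order[k]] = avg
        pos += j - i
        i = j
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rsum = ranks[start : start + len(g)].sum()
        h += rsum**2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


def mannwhitney_p_enumeration(x: list[float], y: list[float]) -> float:
    """Exact two-sided p by enumerating all label assignments of the pooled
    sample (no ties assumed)."""
    from itertools import combinations

    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    us = []
    for idx in combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(xs, ys))
    us = np.asarray(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))
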