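"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive each quantity with the most literal
formulation available (exhaustive loops, explicit curve construction) so
they share no code path with the implementations they check.
"""

from __future__ import annotations

import numpy as np


def otsu_oracle(h: np.ndarray) -> int:
    """Exhaustive 256-way maximization of the between-class variance."""
    h = np.asarray(h, dtype=np.float64)
    levels = np.arange(256, dtype=np.float64)
    total = h.sum()
    best_t, best_v = None, -1.0
    for t in range(256):
        w0 = h[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mean0 = (levels[: t + 1] * h[: t + 1]).sum() / w0
        mean1 = (levels[t + 1 :] * h[t + 1 :]).sum() / w1
        v = w0 * w1 * (mean0 - mean1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    if best_t is None:
        return int(np.flatnonzero(h)[0])
    return best_t


def triangle_oracle(h: np.ndarray) -> int:
    """Exhaustive peak-to-tail perpendicular-distance maximization."""
    h = np.asarray(h, dtype=np.float64)
    if h.max() == h.min():
        return 127
    peak = int(np.argmax(h))
    nz = np.flatnonzero(h)
    first_nz, last_nz = int(nz[0]), int(nz[-1])
    end = last_nz if (last_nz - peak) >= (peak - first_nz) else first_nz
    if end == peak:
        return peak
    x1, y1, x2, y2 = float(peak), float(h[peak]), float(end), float(h[end])
    best_t, best_d = None, -1.0
    for t in range(min(peak, end), max(peak, end) + 1):
        d = abs((y2 - y1) * t - (x2 - x1) * h[t] + x2 * y1 - y2 * x1)
        if d > best_d:
            best_d, best_t = d, t
    return best_t


def random_histograms(rng: np.random.Generator, n: int):
    """A mix of dense, sparse and bimodal histogram shapes."""
    for i in range(n):
        kind = i % 3
        if kind == 0:
            h = rng.integers(0, 60, size=256)
        elif kind == 1:
            h = np.zeros(256, dtype=int)
            spikes = rng.integers(0, 256, size=rng.integers(1, 8))
            h[spikes] = rng.integers(1, 500, size=len(spikes))
        else:
            xs = np.arange(256)
            mu1, mu2 = rng.uniform(20, 100), rng.uniform(150, 240)
            s1, s2 = rng.uniform(3, 25, size=2)
            h = (
                rng.uniform(50, 400) * np.exp(-((xs - mu1) ** 2) / (2 * s1**2))
                + rng.uniform(50, 400) * np.exp(-((xs - mu2) ** 2) / (2 * s2**2))
            ).astype(int)
        if h.sum() == 0:
            h[128] = 1
        yield h


def ap_oracle(flags, n_gt: int) -> float:
    """Rectangle integration of the explicitly constructed PR curve."""
    if n_gt == 0 or not flags:
        return 0.0
    points = [(0.0, None)]
    tp = 0
    for k, f in enumerate(flags, start=1):
        tp += int(f)
        points.append((tp / n_gt, tp / k))
    area = 0.0
    for (r0, _), (r1, p1) in zip(points, points[1:]):
        area += (r1 - r0) * p1
    return area
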