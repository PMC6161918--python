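"""Independent brute-force implementations used as oracles.

These deliberately mirror the detection criterion sample by sample with
plain Python loops, independent of the vectorized implementations they
check.
"""

import math

import numpy as np


def brute_velocity(pos, dt):
    n = len(pos)
    v = [float("nan")] * n
    for i in range(2, n - 2):
        window = [pos[i - 2], pos[i - 1], pos[i], pos[i + 1], pos[i + 2]]
        if any(not math.isfinite(x) for x in window):
            v[i] = float("nan")
        else:
            v[i] = (pos[i + 2] + pos[i + 1] - pos[i - 1] - pos[i - 2]) / (6 * dt)
    return np.array(v)


def brute_threshold(vx, vy, lam):
    etas = []
    for v in (vx, vy):
        vals = sorted(float(x) for x in v if math.isfinite(x))
        med = _median(vals)
        med_sq = _median(sorted(x * x for x in vals))
        var = med_sq - med * med
        if var <= 0:
            raise ValueError("degenerate")
        etas.append(lam * math.sqrt(var))
    return tuple(etas)


def _median(sorted_vals):
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return sorted_vals[mid]
    return (sorted_vals[mid - 1] + sorted_vals[mid]) / 2


def brute_monocular(vx, vy, eta_x, eta_y, gaze_x, gaze_y, min_dur):
    """Sample-by-sample scan of the strict elliptic criterion."""
    events = []
    run = []
    n = len(vx)
    for i in range(n + 1):
        above = False
        if i < n and math.isfinite(vx[i]) and math.isfinite(vy[i]):
            above = (vx[i] / eta_x) ** 2 + (vy[i] / eta_y) ** 2 > 1.0
        if above:
            run.append(i)
        else:
            if len(run) >= min_dur:
                i0, i1 = run[0], run[-1]
                amp = math.hypot(gaze_x[i1] - gaze_x[i0],
                                 gaze_y[i1] - gaze_y[i0])
                peak = max(math.hypot(vx[j], vy[j]) for j in run)
                events.append((i0, i1, amp, peak))
            run = []
    return events


def brute_binocular(left, right, min_overlap):
    """Greedy max-overlap pairing, mirroring the merge contract."""
    merged = []
    used = set()
    for (l0, l1, la, lp) in left:
        best, best_ov = None, 0
        for j, (r0, r1, ra, rp) in enumerate(right):
            if j in used:
                continue
            ov = min(l1, r1) - max(l0, r0) + 1
            if ov >= min_overlap and ov > best_ov:
                best, best_ov = j, ov
        if best is not None:
            used.add(best)
            r0, r1, ra, rp = right[best]
            merged.append((min(l0, r0), max(l1, r1), (la + ra) / 2,
                           (lp + rp) / 2))
    merged.sort()
    return merged


def random_trace(seed, n=None):
    """Drift + tremor trace with a few injected displacement steps."""
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(400, 2000))
    x = np.cumsum(rng.normal(0, 0.004, n))
    y = np.cumsum(rng.normal(0, 0.004, n))
    for _ in range(int(rng.integers(0, 6))):
        i0 = int(rng.integers(10, n - 20))
        dur = int(rng.integers(3, 9))
        amp = float(rng.uniform(0.2, 3.0))
        theta = float(rng.uniform(0, 2 * math.pi))
        s = np.clip((np.arange(n) - i0) / dur, 0, 1)
        prof = amp * (1 - np.cos(math.pi * s)) / 2
        x = x + prof * math.cos(theta)
        y = y + prof * math.sin(theta)
    x += rng.normal(0, 0.015, n)
    y += rng.normal(0, 0.015, n)
    return x, y
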