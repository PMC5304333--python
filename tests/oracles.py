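"""Independent brute-force re-implementations used as test oracles.

Everything here is deliberately written in plain Python (loops, math,
itertools) with no reuse of the package's own vectorised code paths, so
that agreement between the two routes is evidence of correctness.
"""

from __future__ import annotations

import itertools
import math


def brute_step_metrics(frames, x, y, interval):
    """Per-step (displacement, dt, speed, turning angle or None)."""
    out = []
    for i in range(1, len(x)):
        dx, dy = x[i] - x[i - 1], y[i] - y[i - 1]
        d = math.sqrt(dx * dx + dy * dy)
        dt = (frames[i] - frames[i - 1]) * interval
        alpha = None
        if i >= 2:
            ax, ay = x[i - 1] - x[i - 2], y[i - 1] - y[i - 2]
            if not ((ax == 0 and ay == 0) or (dx == 0 and dy == 0)):
                alpha = math.degrees(math.atan2(ax * dy - ay * dx,
                                                ax * dx + ay * dy))
                if alpha == -180.0:
                    alpha = 180.0
        out.append((d, dt, d / dt, alpha))
    return out


def brute_track_summary(frames, x, y, interval):
    """(n_steps, d_tot, track_displacement, net, track_speed, ep_dr)."""
    steps = brute_step_metrics(frames, x, y, interval)
    d_tot = sum(s[0] for s in steps)
    net = math.sqrt((x[-1] - x[0]) ** 2 + (y[-1] - y[0]) ** 2)
    elapsed = (frames[-1] - frames[0]) * interval
    n = len(steps)
    return (n, d_tot, d_tot / n, net, d_tot / elapsed,
            net / d_tot if d_tot > 0 else 0.0)


def brute_two_step(step_displacements, threshold, fraction):
    """Retain decision by direct counting with inclusive comparisons."""
    n = len(step_displacements)
    if n == 0:
        return False
    motile = sum(1 for d in step_displacements if d >= threshold)
    return (motile / n) >= fraction


def brute_single_cutoff(step_displacements, threshold):
    d = sorted(step_displacements)
    n = len(d)
    if n == 0:
        return False
    med = d[n // 2] if n % 2 else (d[n // 2 - 1] + d[n // 2]) / 2
    return med >= threshold


def exact_mann_whitney(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration (no ties).

    Enumerates every way the pooled sample could have been split into
    groups of the observed sizes, builds the null distribution of U, and
    doubles the smaller tail probability (capped at 1) — the standard
    exact two-sided convention.
    """
    na, nb = len(a), len(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"

    def u_of(a_positions):
        # U = number of (a, b) pairs with a > b, via ranks of a's positions
        a_sorted = sorted(a_positions)
        r_sum = sum(p + 1 for p in a_sorted)
        return r_sum - na * (na + 1) / 2

    u_obs = sum(1 for x in a for y in b if x > y)
    dist = {}
    total = 0
    for positions in itertools.combinations(range(na + nb), na):
        u = u_of(positions)
        dist[u] = dist.get(u, 0) + 1
        total += 1
    cdf = sum(c for u, c in dist.items() if u <= u_obs) / total
    sf = sum(c for u, c in dist.items() if u >= u_obs) / total
    return u_obs, min(1.0, 2 * min(cdf, sf))


def bonferroni(p_list):
    return [min(1.0, len(p_list) * p) for p in p_list]


def benjamini_hochberg(p_list):
    """Step-up adjusted values with monotone enforcement, input order kept."""
    m = len(p_list)
    order = sorted(range(m), key=lambda i: p_list[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        val = min(1.0, m * p_list[i] / (rank_from_top + 1))
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def robust_z(values):
    v = sorted(values)
    n = len(v)
    med = v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2
    dev = sorted(abs(x - med) for x in values)
    mad = dev[n // 2] if n % 2 else (dev[n // 2 - 1] + dev[n // 2]) / 2
    return [(x - med) / (1.4826 * mad) for x in values]
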