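"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a pipeline quantity by direct definition (dense
search, enumeration, or explicit optimization) without sharing code with
the implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def dip_bruteforce(values: np.ndarray) -> float:
    """Dip by explicit sup-distance minimization over piecewise-linear
    unimodal CDFs.

    For every candidate mode placement (at a sample site, where the fitted
    CDF may carry an atom, or in a gap between sites) the best unimodal CDF
    is found by linear programming over its values at the sites: minimize d
    subject to band, monotonicity, and convex-before/concave-after
    second-difference constraints.  The dip is the smallest d over all
    placements.  Intended for small n only.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    sites, counts = np.unique(x, return_counts=True)
    m = sites.size
    if m == 1:
        return 0.0
    upper = np.cumsum(counts) / n  # F at site (right limit)
    lower = upper - counts / n  # F just below site

    best = np.inf
    # mode beyond all sites: entirely concave (split=0) or convex (split=m)
    for k in (0, m):
        val = _lp_mode_case(sites, upper, lower, split=k, atom_site=None)
        best = min(best, val)
    # mode at a site, where the fitted CDF may carry an atom; the shape
    # chains on each side include the segments into the mode, so a piece
    # cannot pause its curvature across a gap
    for s in range(m):
        val = _lp_mode_case(sites, upper, lower, split=None, atom_site=s)
        best = min(best, val)
    return float(best)


def _lp_mode_case(sites, upper, lower, split, atom_site):
    m = sites.size
    # variables: g_0..g_{m-1} (+ extra g_minus at an atom site), then d
    extra = atom_site is not None
    nv = m + (1 if extra else 0) + 1
    d_idx = nv - 1
    gm_idx = m  # g_minus variable when atom case

    A_ub, b_ub = [], []

    def add(coeffs: dict, rhs: float):
        row = np.zeros(nv)
        for idx, c in coeffs.items():
            row[idx] = c
        A_ub.append(row)
        b_ub.append(rhs)

    # band constraints
    for i in range(m):
        if extra and i == atom_site:
            # right value g_i vs upper F, left value g_minus vs lower F
            add({i: 1.0, d_idx: -1.0}, upper[i])
            add({i: -1.0, d_idx: -1.0}, -upper[i])
            add({gm_idx: 1.0, d_idx: -1.0}, lower[i])
            add({gm_idx: -1.0, d_idx: -1.0}, -lower[i])
        else:
            add({i: 1.0, d_idx: -1.0}, lower[i])  # g_i - d <= lower + ... upper bound
            add({i: -1.0, d_idx: -1.0}, -upper[i])  # g_i >= upper - d

    # monotonicity
    for i in range(m - 1):
        hi_of_i = gm_idx if (extra and i + 1 == atom_site) else None
        if extra and i + 1 == atom_site:
            add({i: 1.0, gm_idx: -1.0}, 0.0)  # g_i <= g_minus
            add({gm_idx: 1.0, (i + 1): -1.0}, 0.0)  # g_minus <= g_{i+1}
        else:
            add({i: 1.0, (i + 1): -1.0}, 0.0)

    def left_val(i):
        """Variable index holding G's left limit at site i."""
        return gm_idx if (extra and i == atom_site) else i

    # shape constraints: convex among sites < mode boundary, concave after
    if extra:
        conv_idx = list(range(atom_site)) + [gm_idx]  # left piece ends at g_minus
        conc_idx = list(range(atom_site, m))  # right piece starts at g_plus
    else:
        conv_idx = list(range(split))
        conc_idx = list(range(split, m))

    def site_of(idx):
        return atom_site if idx == gm_idx else idx

    for a, b, c in zip(conv_idx, conv_idx[1:], conv_idx[2:]):
        xa, xb, xc = sites[site_of(a)], sites[site_of(b)], sites[site_of(c)]
        # (g_c - g_b)/(xc-xb) >= (g_b - g_a)/(xb-xa)
        add({c: -(xb - xa), b: (xb - xa) + (xc - xb), a: -(xc - xb)}, 0.0)
    for a, b, c in zip(conc_idx, conc_idx[1:], conc_idx[2:]):
        xa, xb, xc = sites[site_of(a)], sites[site_of(b)], sites[site_of(c)]
        add({c: (xb - xa), b: -((xb - xa) + (xc - xb)), a: (xc - xb)}, 0.0)

    bounds = [(0.0, 1.0)] * (nv - 1) + [(0.0, 1.0)]
    cost = np.zeros(nv)
    cost[d_idx] = 1.0
    res = linprog(cost, A_ub=np.array(A_ub), b_ub=np.array(b_ub), bounds=bounds,
                  method="highs")
    if not res.success:
        return np.inf
    return res.x[d_idx]


def summary_oracle(distances):
    """Sort-based five-number summary with hand-rolled type-7 quantiles."""
    d = np.sort(np.asarray(distances, dtype=float))
    n = d.size

    def quantile(q):
        pos = q * (n - 1)
        lo = int(np.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        return d[lo] * (1 - frac) + d[hi] * frac

    return {
        "n": n,
        "mean_m": float(d.mean()),
        "median_m": float(quantile(0.5)),
        "q1_m": float(quantile(0.25)),
        "q3_m": float(quantile(0.75)),
        "max_m": float(d[-1]),
    }


def pinball_grid_oracle(x, y, tau=0.5, n_grid=201, refine=4):
    """Grid-search minimizer of the pinball loss for a line fit.

    Searches (intercept, slope) on a shrinking grid; returns
    (intercept, slope, loss).  Deliberately brute force.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def loss(a, b):
        u = y - a - b * x
        return np.sum(u * (tau - (u < 0.0)))

    span_y = max(np.ptp(y), 1.0)
    span_x = max(np.ptp(x), 1.0)
    a_lo, a_hi = y.min() - span_y, y.max() + span_y
    s = 2.0 * span_y / span_x
    b_lo, b_hi = -s, s
    best = (np.inf, 0.0, 0.0)
    for _ in range(refine):
        aa = np.linspace(a_lo, a_hi, n_grid)
        bb = np.linspace(b_lo, b_hi, n_grid)
        u = y[None, None, :] - aa[:, None, None] - bb[None, :, None] * x[None, None, :]
        losses = np.sum(u * (tau - (u < 0.0)), axis=2)
        i, j = np.unravel_index(np.argmin(losses), losses.shape)
        if losses[i, j] < best[0]:
            best = (losses[i, j], aa[i], bb[j])
        da = (a_hi - a_lo) / (n_grid - 1)
        db = (b_hi - b_lo) / (n_grid - 1)
        a_lo, a_hi = aa[i] - 2 * da, aa[i] + 2 * da
        b_lo, b_hi = bb[j] - 2 * db, bb[j] + 2 * db
    return best[1], best[2], best[0]


def bc_moment_oracle(values):
    """Bimodality coefficient from first-principles moment sums."""
    x = np.asarray(values, dtype=float)
    n = x.size
    mean = x.sum() / n
    dev = x - mean
    m2 = np.sum(dev**2) / n
    m3 = np.sum(dev**3) / n
    m4 = np.sum(dev**4) / n
    # bias-corrected sample skewness and excess kurtosis
    g1 = (np.sqrt(n * (n - 1)) / (n - 2)) * (m3 / m2**1.5)
    g2 = ((n + 1) * (m4 / m2**2 - 3.0) + 6.0) * ((n - 1) / ((n - 2) * (n - 3)))
    return (g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
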