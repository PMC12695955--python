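"""Distribution-shape diagnostics: dip statistic and bimodality coefficient.

The dip statistic of a sample is the smallest sup-norm (Kolmogorov)
distance between its empirical CDF and any unimodal CDF — a CDF convex up
to some mode and concave after it, possibly with an atom at the mode.  Here
it is computed exactly by bisection on the distance ``d``: the empirical
CDF is within ``d`` of some unimodal CDF iff the sample sites can be split
into a prefix admitting a convex band fit and a suffix admitting a concave
band fit (the mode, where the fit may jump, sits between them).  Each band
feasibility reduces to a greatest-convex-minorant check: the lower convex
hull of the band's upper edge must clear the band's lower edge.  Tied
values collapse into single sites, so samples with atoms (including a
constant sample, whose dip is 0) are handled exactly.

The bimodality coefficient is the moment diagnostic
``bc = (g1^2 + 1) / (g2 + 3(n-1)^2 / ((n-2)(n-3)))`` with bias-corrected
sample skewness ``g1`` and excess kurtosis ``g2``; values above 5/9 (the
uniform distribution's value) conventionally suggest bimodality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.stats import kurtosis, skew

_EPS = 1e-12


@njit(cache=True)
def _convex_scan(xs, lo, hi):  # pragma: no cover - exercised via dip
    """Scan convex-band feasibility over all prefixes of a site sequence.

    A convex nondecreasing function fits within ``[lo, hi]`` on sites
    ``0..k-1`` iff the upper envelope of the support lines
    ``lo[j] + s[j] * (x - xs[j])`` clears ``hi`` nowhere, where ``s[j]`` is
    the smallest exit slope any feasible convex function can have at site
    ``j`` (forced by convexity from earlier hi/lo bounds).  The envelope is
    itself a feasible witness, and its value at a site is the smallest
    value any feasible fit can take there.

    Returns ``(PL, env)``: the longest feasible prefix length and, for each
    site ``k``, the envelope of the support lines of *earlier* sites
    evaluated at ``xs[k]`` (-inf for k = 0).
    """
    m = xs.shape[0]
    s = np.empty(m)
    env = np.full(m, -np.inf)
    pl = m
    found = False
    for j in range(m):
        sj = 0.0
        for i in range(j):
            cand = (lo[j] - hi[i]) / (xs[j] - xs[i])
            if cand > sj:
                sj = cand
        s[j] = sj
        e = -np.inf
        for i in range(j):
            v = lo[i] + s[i] * (xs[j] - xs[i])
            if v > e:
                e = v
        env[j] = e
        if not found and max(e, lo[j]) > hi[j] + _EPS:
            pl = j
            found = True
    return pl, env


@njit(cache=True)
def _feasible(xs, A, B, d):  # pragma: no cover
    """Can a unimodal CDF sit within sup-distance d of the empirical CDF?

    A/B are the upper/lower empirical CDF values at each (tie-collapsed)
    site; standard bands are ``[A - d, B + d]``.  The fitted CDF splits
    into a convex prefix and a concave suffix, either across a gap between
    sites or at a site where it carries an atom (which re-centres that
    site's band on the CDF's left/right limits).  Besides per-piece
    feasibility the junction must be monotone: the prefix's smallest
    attainable end value cannot exceed the suffix's largest attainable
    start value.
    """
    m = xs.shape[0]
    lo = A - d
    hi = B + d
    # concave suffixes map to convex prefixes under (x, g) -> (-x, -g)
    xs_r = -xs[::-1]
    lo_r = -(hi[::-1])
    hi_r = -(lo[::-1])

    pl, env_l = _convex_scan(xs, lo, hi)
    pr, env_r = _convex_scan(xs_r, lo_r, hi_r)

    # mode beyond all sites: the fit is entirely convex or entirely concave
    if pl == m or pr == m:
        return True

    # mode at site k, where the fitted CDF may carry an atom: the convex
    # piece ends at (xs[k], a) with a in the left-limit band around B[k],
    # the concave piece starts at (xs[k], b) in the band around A[k], and
    # the jump a <= b carries the mode's probability mass.  The junction
    # slope chains are part of each piece's envelope, so a concave suffix
    # cannot, e.g., stay flat across a valley and then rise again.
    for k in range(m):
        if k > pl or (m - 1 - k) > pr:
            continue
        a_min = max(B[k] - d, env_l[k])
        if a_min > B[k] + d + _EPS:
            continue
        r = m - 1 - k
        b_neg_min = max(-A[k] - d, env_r[r])
        if b_neg_min > -A[k] + d + _EPS:
            continue
        if a_min <= -b_neg_min + _EPS:
            return True
    return False


@njit(cache=True)
def _dip_sorted(xs, A, B, n_iter):  # pragma: no cover
    lo, hi = 0.0, 0.5
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if _feasible(xs, A, B, mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _sites(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    sites, counts = np.unique(x, return_counts=True)
    upper = np.cumsum(counts) / n
    lower = upper - counts / n
    return sites, upper, lower


def dip_statistic(values) -> float:
    """Exact dip statistic of a sample (bisection to ~1e-13).

    Requires at least 4 finite observations.  Invariant under strictly
    increasing affine transformations; bounded by ``[0, 1/4]`` with the
    value ``1/(2n)`` for an evenly spread sample of distinct points.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("dip_statistic requires n >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("dip_statistic requires finite values")
    sites, upper, lower = _sites(x)
    if sites.size == 1:
        return 0.0
    # rescale x to [0, 1] so the bisection tolerance is scale-free; sites
    # whose spacing underflows after rescaling merge into one
    span = sites[-1] - sites[0]
    xs = (sites - sites[0]) / span
    keep = np.concatenate([[True], np.diff(xs) > 0.0])
    if not keep.all():
        xs = xs[keep]
        upper = np.maximum.reduceat(upper, np.flatnonzero(keep))
        lower = np.minimum.reduceat(lower, np.flatnonzero(keep))
        if xs.size == 1:
            return 0.0
    return float(_dip_sorted(xs, upper, lower, 50))


@dataclass(frozen=True)
class DipResult:
    dip: float
    p_value: float
    n: int
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "dip": self.dip,
            "p_value": self.p_value,
            "n": self.n,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }


def dip_test(values, n_boot: int = 2000, seed: int = 0) -> DipResult:
    """Monte-Carlo dip test of unimodality.

    The null reference distribution is the dip of uniform(0, 1) samples of
    the same size (the standard convention for this test); the p-value is
    the proportion of null dips at least as large as the observed one.
    """
    x = np.asarray(values, dtype=float)
    observed = dip_statistic(x)
    rng = np.random.default_rng(seed)
    null = null_dip_distribution(x.size, n_boot, rng)
    p = float(np.count_nonzero(null >= observed)) / n_boot
    return DipResult(dip=observed, p_value=p, n=int(x.size), n_boot=n_boot, seed=seed)


def null_dip_distribution(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Dip statistics of ``n_boot`` uniform samples of size ``n``."""
    out = np.empty(n_boot)
    for b in range(n_boot):
        u = np.sort(rng.random(n))
        upper = np.arange(1, n + 1) / n
        lower = upper - 1.0 / n
        span = u[-1] - u[0]
        out[b] = _dip_sorted((u - u[0]) / span, upper, lower, 50)
    return out


@dataclass(frozen=True)
class BimodalityResult:
    bc: float
    skewness_g1: float
    excess_kurtosis_g2: float
    n: int
    flagged_bimodal: bool

    def to_dict(self) -> dict:
        return {
            "bc": self.bc,
            "skewness_g1": self.skewness_g1,
            "excess_kurtosis_g2": self.excess_kurtosis_g2,
            "n": self.n,
            "flagged_bimodal": self.flagged_bimodal,
        }


def bimodality_coefficient(values, bias_corrected: bool = True) -> BimodalityResult:
    """Sarle's bimodality coefficient with finite-sample moment corrections.

    ``bc = (g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3)))`` using the
    bias-corrected sample skewness and excess kurtosis (the convention of
    the usual R implementations).  ``bias_corrected=False`` switches to
    naive moment estimates in both the numerator and denominator.  Values
    above 5/9 are flagged (reported, not enforced) as bimodal.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("bimodality_coefficient requires n >= 4")
    if np.ptp(x) == 0.0:
        raise ValueError("bimodality coefficient undefined for zero-variance sample")
    g1 = float(skew(x, bias=not bias_corrected))
    g2 = float(kurtosis(x, fisher=True, bias=not bias_corrected))
    bc = (g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    return BimodalityResult(
        bc=float(bc),
        skewness_g1=g1,
        excess_kurtosis_g2=g2,
        n=int(n),
        flagged_bimodal=bool(bc > 5.0 / 9.0),
    )
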