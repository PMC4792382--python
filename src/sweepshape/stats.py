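"""Per-window population-genetic summary statistics.

Nine statistics form the classifier's feature space when computed in each of
the 11 subwindows of a large region: pi, Watterson's theta, Fay & Wu's
theta_H, the number of distinct haplotypes K, average haplotype homozygosity
H1, H12 (pooling the two commonest haplotypes), H2/H1, Kelly's Z_nS (mean
pairwise r^2), and the maximised omega statistic contrasting LD within versus
across the two flanks of a candidate sweep site.  Tajima's D is computed as a
diagnostic only and is never part of the feature vector.

All functions take a 2-D binary haplotype matrix ``(n_haplotypes, n_sites)``
restricted to the window of interest; every column is assumed segregating in
the full sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StatBundle",
    "site_stats",
    "haplotype_stats",
    "ld_stats",
    "pairwise_r2",
    "stat_bundle",
]


@dataclass(frozen=True)
class StatBundle:
    """All per-window statistics, plus Tajima's D as a diagnostic."""

    pi: float
    theta_w: float
    theta_h: float
    tajd: float
    K: int
    H1: float
    H12: float
    H2H1: float
    zns: float
    omega_max: float


def _harmonic(n: int) -> float:
    return sum(1.0 / k for k in range(1, n))


def site_stats(window: np.ndarray, polarized: bool = True) -> tuple[float, float, float, float]:
    """Frequency-spectrum statistics: (pi, theta_W, theta_H, Tajima's D).

    pi is the mean number of pairwise differences, theta_W = S / a_n, and
    theta_H = sum_i S_i * 2 i^2 / (n (n-1)) with S_i the count of sites at
    derived-allele count i.  A window with no segregating sites returns all
    zeros (D is undefined there and reported as 0).

    Raises
    ------
    ValueError
        If ``polarized`` is false: theta_H requires known derived states.
    """
    if not polarized:
        raise ValueError("theta_H requires polarized (derived-state) input")
    window = np.asarray(window)
    n, S = window.shape
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if S == 0:
        return 0.0, 0.0, 0.0, 0.0
    c = window.sum(axis=0, dtype=np.int64).astype(float)
    denom = n * (n - 1.0)
    pi = float(np.sum(2.0 * c * (n - c)) / denom)
    a1 = _harmonic(n)
    theta_w = S / a1
    theta_h = float(np.sum(2.0 * c * c) / denom)
    tajd = _tajimas_d(n, S, pi, a1)
    return pi, theta_w, theta_h, tajd


def _tajimas_d(n: int, S: int, pi: float, a1: float) -> float:
    if S == 0:
        return 0.0
    a2 = sum(1.0 / (k * k) for k in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return 0.0
    return float((pi - S / a1) / math.sqrt(var))


def haplotype_stats(window: np.ndarray) -> tuple[int, float, float, float]:
    """Haplotype-frequency statistics: (K, H1, H12, H2/H1).

    Haplotypes are distinct row strings within the window.  With frequencies
    p1 >= p2 >= ...: H1 = sum p_i^2, H12 = (p1 + p2)^2 + sum_{i>2} p_i^2 and
    H2/H1 = (H1 - p1^2) / H1.  A monomorphic window gives (1, 1, 1, 0).

    Any two maximal-frequency haplotypes give the same (p1+p2)^2, so ties in
    the "two most frequent" are value-invariant.
    """
    window = np.asarray(window)
    n, S = window.shape
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if S == 0:
        return 1, 1.0, 1.0, 0.0
    _, counts = np.unique(window, axis=0, return_counts=True)
    p = np.sort(counts / float(n))[::-1]
    K = int(p.size)
    H1 = float(np.sum(p * p))
    if K >= 2:
        H12 = float((p[0] + p[1]) ** 2 + np.sum(p[2:] ** 2))
    else:
        H12 = H1
    H2H1 = float((H1 - p[0] ** 2) / H1)
    return K, H1, H12, H2H1


def pairwise_r2(window: np.ndarray) -> np.ndarray:
    """Matrix of gametic r^2 between all column pairs.

    r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)) with D = p_AB - p_A p_B estimated
    from phased haplotype counts.  Columns must be segregating.
    """
    X = np.asarray(window, dtype=float)
    n = X.shape[0]
    p = X.mean(axis=0)
    pab = (X.T @ X) / n
    D = pab - np.outer(p, p)
    het = p * (1.0 - p)
    denom = np.outer(het, het)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, D * D / denom, 0.0)
    return r2


def ld_stats(
    window: np.ndarray,
    max_sites: int = 1000,
    subsample_seed: int = 0,
) -> tuple[float, float]:
    """Linkage-disequilibrium statistics: (Z_nS, omega_max).

    Z_nS is the mean r^2 over all C(S,2) site pairs.  omega(l) contrasts the
    average r^2 within the left l and right S-l sites against the average r^2
    across the split, maximised over l in {2, ..., S-2}; splits whose
    cross-flank r^2 sum is zero are skipped (omega would be undefined), and
    if every split is skipped omega_max = 0.  Windows with S < 2 return
    zns = 0; with S < 4, omega_max = 0.

    Because the computation is O(S^2), windows with more than ``max_sites``
    segregating sites are thinned to ``max_sites`` sites chosen uniformly
    (deterministically, from ``subsample_seed``) for these two statistics
    only.
    """
    window = np.asarray(window)
    S = window.shape[1]
    if S < 2:
        return 0.0, 0.0
    if S > max_sites:
        rng = np.random.default_rng(subsample_seed)
        keep = np.sort(rng.choice(S, size=max_sites, replace=False))
        window = window[:, keep]
        S = max_sites
    r2 = pairwise_r2(window)
    iu = np.triu_indices(S, k=1)
    vals = r2[iu]
    zns = float(vals.mean())
    if S < 4:
        return zns, 0.0
    return zns, _omega_max(r2)


def _omega_max(r2: np.ndarray) -> float:
    S = r2.shape[0]
    # prefix sums over the upper triangle: pairs entirely left of l,
    # entirely right of l, and crossing the split
    colsum = np.array([r2[:j, j].sum() for j in range(S)])  # pairs (i<j)
    rowrest = np.array([r2[i, i + 1 :].sum() for i in range(S)])
    total = colsum.sum()
    left_cum = np.concatenate([[0.0], np.cumsum(colsum)])  # left_cum[l] = pairs i<j<l
    row_cum = np.concatenate([[0.0], np.cumsum(rowrest)])  # pairs with i < l
    best = 0.0
    for ell in range(2, S - 1):
        w_left = left_cum[ell]
        w_right = total - row_cum[ell]
        cross = total - w_left - w_right
        if cross <= 0.0:
            continue
        n_within = ell * (ell - 1) / 2 + (S - ell) * (S - ell - 1) / 2
        n_cross = ell * (S - ell)
        omega = ((w_left + w_right) / n_within) / (cross / n_cross)
        if omega > best:
            best = omega
    return float(best)


def stat_bundle(
    window: np.ndarray,
    polarized: bool = True,
    max_ld_sites: int = 1000,
    subsample_seed: int = 0,
) -> StatBundle:
    """Compute every per-window statistic at once."""
    pi, tw, th, tajd = site_stats(window, polarized=polarized)
    K, H1, H12, H2H1 = haplotype_stats(window)
    zns, omax = ld_stats(window, max_sites=max_ld_sites, subsample_seed=subsample_seed)
    return StatBundle(pi, tw, th, tajd, K, H1, H12, H2H1, zns, omax)
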