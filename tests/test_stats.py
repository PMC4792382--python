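"""Summary statistics against independent brute-force oracles."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest

from sweepshape.stats import haplotype_stats, ld_stats, site_stats

from conftest import random_haplotype_matrix


# ---------------------------------------------------------------------------
# brute-force oracles (independent implementations used only by the tests)


def oracle_pi(win: np.ndarray) -> float:
    n = win.shape[0]
    total = sum(
        np.sum(win[i] != win[j]) for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2)


def oracle_theta_w(win: np.ndarray) -> float:
    n, S = win.shape
    return S / sum(1 / k for k in range(1, n))


def oracle_theta_h(win: np.ndarray) -> float:
    n = win.shape[0]
    sfs = Counter(int(c) for c in win.sum(axis=0))
    return sum(cnt * 2 * i * i for i, cnt in sfs.items()) / (n * (n - 1))


def oracle_haplotypes(win: np.ndarray):
    counts = Counter(tuple(row) for row in win)
    p = sorted((c / win.shape[0] for c in counts.values()), reverse=True)
    H1 = sum(x * x for x in p)
    H12 = (sum(p[:2])) ** 2 + sum(x * x for x in p[2:]) if len(p) > 1 else H1
    return len(p), H1, H12, (H1 - p[0] ** 2) / H1


def oracle_r2(a: np.ndarray, b: np.ndarray) -> float:
    n = len(a)
    pa, pb = a.mean(), b.mean()
    pab = np.mean(a * b)
    D = pab - pa * pb
    return D * D / (pa * (1 - pa) * pb * (1 - pb))


def oracle_zns_omega(win: np.ndarray):
    S = win.shape[1]
    r2 = np.zeros((S, S))
    for i, j in itertools.combinations(range(S), 2):
        r2[i, j] = r2[j, i] = oracle_r2(win[:, i].astype(float), win[:, j].astype(float))
    pairs = [r2[i, j] for i, j in itertools.combinations(range(S), 2)]
    zns = float(np.mean(pairs)) if pairs else 0.0
    best = 0.0
    for ell in range(2, S - 1):
        left = [r2[i, j] for i, j in itertools.combinations(range(ell), 2)]
        right = [r2[i, j] for i, j in itertools.combinations(range(ell, S), 2)]
        cross = [r2[i, j] for i in range(ell) for j in range(ell, S)]
        if sum(cross) <= 0:
            continue
        within = (sum(left) + sum(right)) / (len(left) + len(right))
        omega = within / (sum(cross) / len(cross))
        best = max(best, omega)
    return zns, best


# ---------------------------------------------------------------------------


def test_all_statistics_match_brute_force_on_random_matrices():
    """Every statistic equals an independent O(S^2) oracle on 100 random
    small haplotype matrices."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        win = random_haplotype_matrix(rng)
        pi, tw, th, _ = site_stats(win)
        assert pi == pytest.approx(oracle_pi(win), abs=1e-12)
        assert tw == pytest.approx(oracle_theta_w(win), abs=1e-12)
        assert th == pytest.approx(oracle_theta_h(win), abs=1e-12)
        K, H1, H12, H2H1 = haplotype_stats(win)
        oK, oH1, oH12, oH2H1 = oracle_haplotypes(win)
        assert (K, H1, H12, H2H1) == pytest.approx((oK, oH1, oH12, oH2H1), abs=1e-12)
        zns, omax = ld_stats(win)
        ozns, oomax = oracle_zns_omega(win)
        assert zns == pytest.approx(ozns, abs=1e-12)
        assert omax == pytest.approx(oomax, abs=1e-12)


@pytest.mark.parametrize(
    "win, expected",
    [
        # no variation
        (np.zeros((4, 0), dtype=np.uint8), (0.0, 0.0, 0.0, 0.0)),
        # n=2, one singleton
        (np.array([[0], [1]], dtype=np.uint8), (1.0, 1.0, 1.0, 0.0)),
        # n=4, derived counts {1, 1, 2} over 3 sites
        (
            np.array(
                [[1, 0, 1], [0, 1, 1], [0, 0, 0], [0, 0, 0]], dtype=np.uint8
            ),
            (5 / 3, 18 / 11, 1.0, None),
        ),
    ],
)
def test_site_stats_worked_examples(win, expected):
    pi, tw, th, tajd = site_stats(win)
    assert (pi, tw, th) == pytest.approx(expected[:3], abs=1e-12)
    if expected[3] is not None:
        assert tajd == pytest.approx(expected[3], abs=1e-12)


def test_theta_h_requires_polarized_input():
    win = np.array([[0, 1], [1, 0]], dtype=np.uint8)
    with pytest.raises(ValueError, match="polarized"):
        site_stats(win, polarized=False)


def test_haplotype_stats_examples():
    # monomorphic window: one haplotype
    assert haplotype_stats(np.zeros((5, 0), dtype=np.uint8)) == (1, 1.0, 1.0, 0.0)
    # all rows unique (one-hot): K=n, H1=1/n, H12=(n+2)/n^2, H2/H1=1-1/n
    n = 4
    win = np.eye(n, dtype=np.uint8)
    K, H1, H12, H2H1 = haplotype_stats(win)
    assert K == n
    assert H1 == pytest.approx(1 / n)
    assert H12 == pytest.approx((n + 2) / n**2)
    assert H2H1 == pytest.approx(1 - 1 / n)
    # frequencies 0.5 / 0.3 / 0.2 over ten haplotypes
    win = np.array([[0, 0]] * 5 + [[1, 0]] * 3 + [[1, 1]] * 2, dtype=np.uint8)
    K, H1, H12, H2H1 = haplotype_stats(win)
    assert (K, H1, H12) == pytest.approx((3, 0.38, 0.68))
    assert H2H1 == pytest.approx(0.13 / 0.38)


def test_ld_stats_boundary_cases():
    # two identical columns: perfect LD
    win = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], dtype=np.uint8)
    zns, omax = ld_stats(win)
    assert zns == pytest.approx(1.0)
    assert omax == 0.0  # S < 4
    # four pairwise-independent columns: linkage equilibrium
    rows = [(a, b, c, a ^ b ^ c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
    win = np.array(rows, dtype=np.uint8)
    zns, omax = ld_stats(win)
    assert zns == pytest.approx(0.0, abs=1e-12)
    assert omax == 0.0  # every split has zero cross-flank r^2


def test_ld_subsampling_is_deterministic_and_bounded():
    rng = np.random.default_rng(5)
    cols = []
    while len(cols) < 40:
        c = rng.integers(0, 2, size=8)
        if 0 < c.sum() < 8:
            cols.append(c)
    win = np.column_stack(cols).astype(np.uint8)
    a = ld_stats(win, max_sites=20, subsample_seed=3)
    b = ld_stats(win, max_sites=20, subsample_seed=3)
    assert a == b
    assert 0 <= a[0] <= 1


def test_row_permutation_and_relabelling_invariances():
    """Permuting haplotypes changes nothing; swapping ancestral/derived
    labels changes only theta_H (and Tajima's D through pi - theta_W, which
    are label-free)."""
    rng = np.random.default_rng(11)
    win = random_haplotype_matrix(rng, n_max=10, s_max=12)
    perm = rng.permutation(win.shape[0])
    assert site_stats(win) == site_stats(win[perm])
    assert haplotype_stats(win) == haplotype_stats(win[perm])
    assert ld_stats(win) == ld_stats(win[perm])
    flipped = (1 - win).astype(np.uint8)
    pi0, tw0, th0, d0 = site_stats(win)
    pi1, tw1, th1, d1 = site_stats(flipped)
    assert (pi0, tw0, d0) == pytest.approx((pi1, tw1, d1))
    assert haplotype_stats(win)[:4] == pytest.approx(haplotype_stats(flipped)[:4])
    assert ld_stats(win) == pytest.approx(ld_stats(flipped))


def test_h12_exceeds_h1_except_single_haplotype():
    rng = np.random.default_rng(12)
    for _ in range(50):
        win = random_haplotype_matrix(rng)
        K, H1, H12, _ = haplotype_stats(win)
        assert H12 >= H1 - 1e-15
        if K == 1:
            assert H12 == pytest.approx(H1)
        else:
            assert H12 > H1
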