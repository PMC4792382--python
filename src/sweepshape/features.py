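"""Construction of the 99-dimensional "shape-only" feature vector.

A large window is split into 11 adjacent, equally sized subwindows.  Each of
the nine summary statistics is computed per subwindow and then normalized by
dividing each subwindow's value by the sum of that statistic across all 11
subwindows.  The resulting vector records only the spatial shape of each
statistic's curve, not its magnitude — which is what makes the classifier
robust to genome-wide shifts in diversity caused by demography.

Feature order is frozen (statistic-major, subwindows left to right) and
versioned so that serialized classifiers are portable.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .samples import HaplotypeSample
from .stats import haplotype_stats, ld_stats, site_stats

__all__ = [
    "N_SUBWINDOWS",
    "STAT_NAMES",
    "FEATURE_NAMES",
    "FEATURE_ORDER_VERSION",
    "partition_subwindows",
    "normalize_stat_vector",
    "raw_stat_matrix",
    "build_feature_vector",
    "masked_feature_vector",
    "SubwindowFeaturizer",
]

N_SUBWINDOWS = 11

#: statistic order of the feature vector (Tajima's D is intentionally absent)
STAT_NAMES = ("pi", "thetaW", "thetaH", "K", "H1", "H12", "H2H1", "ZnS", "omega")

FEATURE_NAMES = tuple(f"{s}_win{j}" for s in STAT_NAMES for j in range(N_SUBWINDOWS))

#: bump when the statistic order, subwindow count or normalization changes
FEATURE_ORDER_VERSION = "sweepshape-fv-1"


def partition_subwindows(positions: np.ndarray, n_sub: int = N_SUBWINDOWS) -> list[np.ndarray]:
    """Assign each site to a subwindow by ``floor(position * n_sub)``.

    Positions must lie on [0, 1); the index is clamped to ``n_sub - 1`` so a
    position of exactly 1.0 (possible after floating-point rescaling of
    physical coordinates) does not fall off the end.
    """
    positions = np.asarray(positions, dtype=float)
    idx = np.minimum((positions * n_sub).astype(int), n_sub - 1)
    return [np.flatnonzero(idx == j) for j in range(n_sub)]


def normalize_stat_vector(x: np.ndarray) -> np.ndarray:
    """Divide a statistic's per-subwindow values by their sum.

    If the sum is zero the shape is undefined; the uniform vector (1/n each)
    is returned as the least-informative shape.  Negative inputs are
    rejected: all nine feature statistics are nonnegative, so a negative
    value indicates a statistic (such as Tajima's D) that must not be
    normalized this way.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("normalize_stat_vector requires nonnegative values")
    total = x.sum()
    if total > 0:
        return x / total
    return np.full(x.shape, 1.0 / x.size)


def raw_stat_matrix(
    sample: HaplotypeSample,
    n_sub: int = N_SUBWINDOWS,
    max_ld_sites: int = 1000,
) -> np.ndarray:
    """Raw (unnormalized) statistic values: array of shape (9, n_sub)."""
    if sample.n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    slices = partition_subwindows(sample.positions, n_sub)
    out = np.zeros((len(STAT_NAMES), n_sub))
    for j, site_idx in enumerate(slices):
        win = sample.window(site_idx)
        pi, tw, th, _ = site_stats(win, polarized=sample.polarized)
        K, H1, H12, H2H1 = haplotype_stats(win)
        zns, omax = ld_stats(win, max_sites=max_ld_sites, subsample_seed=j)
        out[:, j] = (pi, tw, th, K, H1, H12, H2H1, zns, omax)
    return out


def _normalize_matrix(raw: np.ndarray) -> np.ndarray:
    return np.concatenate([normalize_stat_vector(row) for row in raw])


def build_feature_vector(
    sample: HaplotypeSample,
    n_sub: int = N_SUBWINDOWS,
    max_ld_sites: int = 1000,
) -> np.ndarray:
    """The 99-value feature vector for one large window.

    Statistic-major, subwindow-minor ordering (see ``FEATURE_NAMES``); for
    each statistic the 11 entries sum to 1 whenever the raw sum was positive.
    Deterministic for a fixed input.
    """
    raw = raw_stat_matrix(sample, n_sub=n_sub, max_ld_sites=max_ld_sites)
    return _normalize_matrix(raw)


def masked_feature_vector(
    sample: HaplotypeSample,
    accessible_sites: np.ndarray,
    subwindow_spans: np.ndarray,
    n_sub: int = N_SUBWINDOWS,
    max_masked_frac: float = 0.5,
    max_ld_sites: int = 1000,
) -> np.ndarray | None:
    """Feature vector for real data with an accessibility mask.

    Each raw statistic is divided by the number of accessible sites in its
    subwindow before normalization, so that subwindows with different
    amounts of usable sequence are comparable.  If any subwindow has more
    than ``max_masked_frac`` of its span masked, the window cannot be
    classified reliably and ``None`` ("omitted") is returned.

    Parameters
    ----------
    accessible_sites : array of shape (n_sub,)
        Number of accessible (unmasked, ancestral-state-resolved) bases per
        subwindow.
    subwindow_spans : array of shape (n_sub,)
        Total bases per subwindow.
    """
    accessible_sites = np.asarray(accessible_sites, dtype=float)
    subwindow_spans = np.asarray(subwindow_spans, dtype=float)
    if accessible_sites.shape != (n_sub,) or subwindow_spans.shape != (n_sub,):
        raise ValueError("accessibility arrays must have one entry per subwindow")
    if np.any(accessible_sites > subwindow_spans):
        raise ValueError("more accessible sites than bases in a subwindow")
    frac_masked = 1.0 - accessible_sites / subwindow_spans
    if np.any(frac_masked > max_masked_frac):
        return None
    raw = raw_stat_matrix(sample, n_sub=n_sub, max_ld_sites=max_ld_sites)
    per_site = raw / accessible_sites[np.newaxis, :]
    return _normalize_matrix(per_site)


class SubwindowFeaturizer(TransformerMixin, BaseEstimator):
    """sklearn transformer: list of :class:`HaplotypeSample` -> (n, 99) array.

    Stateless; ``fit`` only records the output dimensionality so the
    transformer composes with sklearn pipelines.
    """

    def __init__(self, n_sub: int = N_SUBWINDOWS, max_ld_sites: int = 1000):
        self.n_sub = n_sub
        self.max_ld_sites = max_ld_sites

    def fit(self, X, y=None):
        self.n_features_out_ = len(STAT_NAMES) * self.n_sub
        return self

    def transform(self, X) -> np.ndarray:
        return np.array(
            [
                build_feature_vector(s, n_sub=self.n_sub, max_ld_sites=self.max_ld_sites)
                for s in X
            ]
        )

    def get_feature_names_out(self, input_features=None):
        return np.array(
            [f"{s}_win{j}" for s in STAT_NAMES for j in range(self.n_sub)], dtype=object
        )
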