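"""Container for phased haplotype samples.

A :class:`HaplotypeSample` is the unit every summary statistic consumes: a
binary matrix of phased haplotypes (1 = derived allele when polarized) with
site positions on the unit interval.  Simulated data and VCF-derived data are
both funnelled into this container so that the downstream statistics and
feature construction are agnostic to the data source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaplotypeSample"]


@dataclass
class HaplotypeSample:
    """Phased binary haplotype matrix with site positions.

    Parameters
    ----------
    matrix : ndarray of shape (n_haplotypes, n_sites)
        0/1 entries; 1 denotes the derived allele when ``polarized``.
    positions : ndarray of shape (n_sites,)
        Site positions on ``[0, 1)``, strictly increasing.
    locus_bp : int, optional
        Physical length of the locus in base pairs, if meaningful.
    polarized : bool
        Whether derived/ancestral states are known.  Statistics that depend
        on the unfolded site frequency spectrum refuse unpolarized input.
    """

    matrix: np.ndarray
    positions: np.ndarray
    locus_bp: int | None = None
    polarized: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-dimensional")
        if self.positions.shape != (self.matrix.shape[1],):
            raise ValueError("positions length must equal number of sites")
        if self.positions.size:
            if np.any(self.positions < 0) or np.any(self.positions >= 1):
                raise ValueError("positions must lie on [0, 1)")
            if np.any(np.diff(self.positions) < 0):
                raise ValueError("positions must be sorted")
        if np.any(self.matrix > 1):
            raise ValueError("haplotype matrix must be binary")
        counts = self.matrix.sum(axis=0)
        if np.any((counts == 0) | (counts == self.n_haplotypes)):
            raise ValueError("every site must be segregating in the sample")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def window(self, site_indices: np.ndarray) -> np.ndarray:
        """Return the haplotype matrix restricted to the given site indices."""
        return self.matrix[:, site_indices]
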