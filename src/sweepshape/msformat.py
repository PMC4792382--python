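"""Reading and writing ms-style haplotype output.

The ms format (one ``//`` block per replicate with ``segsites:`` and
``positions:`` lines followed by one 0/1 row per chromosome) is the lingua
franca of coalescent simulators, so externally simulated data can be
exchanged with the internal simulator interchangeably.
"""

from __future__ import annotations

from typing import Iterable, Iterator, TextIO

import numpy as np

from .samples import HaplotypeSample

__all__ = ["write_ms", "read_ms", "iter_ms"]


def write_ms(samples: Iterable[HaplotypeSample], fh: TextIO, command: str = "sweepshape") -> None:
    """Write replicates in ms format to an open text handle."""
    samples = list(samples)
    n = samples[0].n_haplotypes if samples else 0
    fh.write(f"{command} {n} {len(samples)}\n\n")
    for sample in samples:
        fh.write("//\n")
        fh.write(f"segsites: {sample.n_sites}\n")
        pos = " ".join(f"{p:.6f}" for p in sample.positions)
        fh.write(f"positions: {pos}\n")
        for row in sample.matrix:
            fh.write("".join("1" if v else "0" for v in row) + "\n")
        fh.write("\n")


def iter_ms(fh: TextIO, polarized: bool = True) -> Iterator[HaplotypeSample]:
    """Yield one :class:`HaplotypeSample` per ``//`` replicate block."""
    segsites = None
    positions: np.ndarray | None = None
    rows: list[str] = []

    def flush():
        nonlocal segsites, positions, rows
        if segsites is None:
            return None
        if segsites == 0:
            raise ValueError("replicate with zero segregating sites cannot be represented")
        matrix = np.array([[int(ch) for ch in r] for r in rows], dtype=np.uint8)
        if matrix.shape[1] != segsites:
            raise ValueError("row length does not match segsites")
        out = HaplotypeSample(matrix=matrix, positions=positions, polarized=polarized)
        segsites, positions, rows = None, None, []
        return out

    for line in fh:
        line = line.strip()
        if line == "//":
            out = flush()
            if out is not None:
                yield out
        elif line.startswith("segsites:"):
            segsites = int(line.split(":", 1)[1])
        elif line.startswith("positions:"):
            positions = np.array([float(x) for x in line.split(":", 1)[1].split()])
            # clamp to [0, 1): some simulators print a site at exactly 1.0
            positions = np.minimum(positions, np.nextafter(1.0, 0.0))
        elif line and set(line) <= {"0", "1"} and segsites is not None:
            rows.append(line)
    out = flush()
    if out is not None:
        yield out


def read_ms(fh: TextIO, polarized: bool = True) -> list[HaplotypeSample]:
    """Read all replicates from an ms-format text handle."""
    return list(iter_ms(fh, polarized=polarized))
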