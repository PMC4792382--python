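"""Genome scans on phased resequencing data.

Applies a trained classifier to real data: phased biallelic variants are
read from a VCF, sites are filtered through an accessibility mask, ancestral
states are inferred from two outgroups (agreement, or a single aligned
outgroup, and the inferred base must match one of the human alleles),
summary statistics are computed per accessible site in adjacent 200 kb
subwindows, and each sliding 11-subwindow frame is classified at its centre.
Frames containing a subwindow with more than half of its bases masked are
omitted rather than classified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classifier import SweepShapeClassifier
from .features import (
    FEATURE_ORDER_VERSION,
    N_SUBWINDOWS,
    STAT_NAMES,
    normalize_stat_vector,
)
from .samples import HaplotypeSample
from .stats import haplotype_stats, ld_stats, site_stats

logger = logging.getLogger(__name__)

__all__ = [
    "MaskTrack",
    "ScanResult",
    "load_variants",
    "write_vcf",
    "infer_ancestral",
    "polarize",
    "scan",
    "write_intervals",
]

_VALID_BASES = frozenset("ACGT")
_MISSING = frozenset({None, "", ".", "-", "N", "n"})


@dataclass
class MaskTrack:
    """Per-base accessibility over a chromosome region (0-based half-open)."""

    start: int
    accessible: np.ndarray  # bool per base from `start`

    def __post_init__(self) -> None:
        self.accessible = np.asarray(self.accessible, dtype=bool)

    @property
    def end(self) -> int:
        return self.start + self.accessible.size

    @classmethod
    def fully_accessible(cls, start: int, end: int) -> "MaskTrack":
        return cls(start, np.ones(end - start, dtype=bool))

    @classmethod
    def from_bed(cls, path, start: int, end: int, masked: bool = True) -> "MaskTrack":
        """Build a track from BED intervals that are masked (default) or
        accessible within [start, end)."""
        acc = np.full(end - start, masked, dtype=bool)
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                _, b, e = line.split()[:3]
                b, e = max(int(b), start), min(int(e), end)
                if b < e:
                    acc[b - start : e - start] = not masked
        return cls(start, acc)

    def count(self, a: int, b: int) -> int:
        """Accessible bases on [a, b) intersected with the track."""
        a, b = max(a, self.start), min(b, self.end)
        if a >= b:
            return 0
        return int(self.accessible[a - self.start : b - self.start].sum())

    def is_accessible(self, pos: int) -> bool:
        if not self.start <= pos < self.end:
            return False
        return bool(self.accessible[pos - self.start])

    def mask_position(self, pos: int) -> None:
        if self.start <= pos < self.end:
            self.accessible[pos - self.start] = False


def load_variants(vcf_path, region: str | None = None, missing: str = "drop-site"):
    """Load phased biallelic SNPs from a VCF.

    Returns ``(matrix, positions, ref, alt, skipped)`` where ``matrix`` is
    the (2 x n_diploids, S) haplotype matrix coded 0 = REF, 1 = ALT,
    ``positions`` are 1-based VCF coordinates, and ``skipped`` counts the
    records dropped per reason.  Multi-allelic, non-SNP and unphased records
    are skipped; records with missing genotypes are dropped
    (``missing='drop-site'``) — the only policy currently implemented, kept
    as an explicit knob because other datasets may warrant imputation.
    """
    from cyvcf2 import VCF

    if missing != "drop-site":
        raise ValueError("only the 'drop-site' missing-genotype policy is implemented")
    vcf = VCF(str(vcf_path))
    columns, positions, refs, alts = [], [], [], []
    skipped = {"multiallelic": 0, "non_snp": 0, "unphased": 0, "missing": 0}
    for rec in vcf(region) if region else vcf:
        if len(rec.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped["non_snp"] += 1
            continue
        gts = rec.genotypes  # [a, b, phased] per sample
        if any(len(g) < 3 or not g[2] for g in gts):
            skipped["unphased"] += 1
            continue
        alleles = np.array([[g[0], g[1]] for g in gts]).reshape(-1)
        if np.any(alleles < 0):
            skipped["missing"] += 1
            continue
        columns.append(alleles.astype(np.uint8))
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    for reason, count in skipped.items():
        if count:
            logger.info("skipped %d %s records", count, reason)
    if not columns:
        raise ValueError(f"no usable phased biallelic SNPs in {vcf_path}")
    matrix = np.stack(columns, axis=1)
    return matrix, np.array(positions), refs, alts, skipped


def write_vcf(
    sample: HaplotypeSample,
    positions_bp: np.ndarray,
    fh,
    chrom: str = "1",
    ref: str = "A",
    alt: str = "T",
) -> None:
    """Write a haplotype sample as a phased VCF (ancestral allele as REF)."""
    n_dip = sample.n_haplotypes // 2
    fh.write("##fileformat=VCFv4.2\n")
    fh.write(f"##contig=<ID={chrom}>\n")
    fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    names = "\t".join(f"s{i}" for i in range(n_dip))
    fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
    for j, pos in enumerate(positions_bp):
        col = sample.matrix[:, j]
        gts = "\t".join(f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_dip))
        fh.write(f"{chrom}\t{int(pos)}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def infer_ancestral(
    human_alleles: tuple[str, ...] | None,
    chimp: str | None,
    macaque: str | None,
) -> str | None:
    """Infer the ancestral base from two outgroups.

    If both outgroups carry a base and agree, that base is ancestral; if
    exactly one outgroup has an aligned base, that base is used.  For SNPs
    the inferred base must additionally match one of the two human alleles.
    Returns ``None`` (discard the site) when no rule applies.
    """

    def norm(b):
        if b in _MISSING:
            return None
        b = b.upper()
        if b not in _VALID_BASES:
            raise ValueError(f"invalid base symbol {b!r}")
        return b

    chimp, macaque = norm(chimp), norm(macaque)
    if chimp is not None and macaque is not None:
        anc = chimp if chimp == macaque else None
    else:
        anc = chimp if chimp is not None else macaque
    if anc is None:
        return None
    if human_alleles is not None:
        alleles = {norm(a) for a in human_alleles}
        if anc not in alleles:
            return None
    return anc


def polarize(
    matrix: np.ndarray,
    positions: np.ndarray,
    refs: list[str],
    alts: list[str],
    ancestral: dict[int, str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orient alleles so 1 = derived, dropping unresolvable sites.

    ``ancestral`` maps a 1-based position to its inferred ancestral base.
    Sites without an inferred ancestral state, or whose ancestral base
    matches neither allele, are discarded.  Returns the polarized matrix,
    the retained positions, and the (1-based) positions discarded — which
    the caller must also remove from the accessible-site denominator.
    """
    keep, flip = [], []
    discarded = []
    for j, pos in enumerate(positions):
        anc = ancestral.get(int(pos))
        if anc is None or anc not in (refs[j], alts[j]):
            discarded.append(int(pos))
            continue
        keep.append(j)
        flip.append(anc == alts[j])
    keep = np.array(keep, dtype=int)
    out = matrix[:, keep].copy()
    flip = np.array(flip, dtype=bool)
    out[:, flip] = 1 - out[:, flip]
    # a site may become non-segregating after re-orientation never happens
    # (flipping is a relabelling); but fixed differences vs the outgroup do:
    seg = (out.sum(axis=0) > 0) & (out.sum(axis=0) < out.shape[0])
    discarded.extend(int(p) for p in positions[keep][~seg])
    return out[:, seg], positions[keep][seg], np.array(discarded, dtype=int)


@dataclass
class ScanResult:
    """Classification of one 200 kb window (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    label: str | None
    posteriors: dict[str, float] | None
    n_accessible: int
    omitted: bool = False
    reason: str | None = None


def scan(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    mask: MaskTrack,
    model: SweepShapeClassifier,
    chrom: str = "chr",
    window_bp: int = 200_000,
    n_sub: int = N_SUBWINDOWS,
    max_masked_frac: float = 0.5,
    max_ld_sites: int = 1000,
) -> list[ScanResult]:
    """Classify every window on a chromosome region.

    ``haplotypes`` must already be polarized (1 = derived) and restricted to
    accessible sites; ``positions`` are 1-based.  The window grid is
    anchored at the mask's start.  Every window yields a
    :class:`ScanResult`: windows whose surrounding frame is incomplete or
    contains a subwindow with more than ``max_masked_frac`` of its bases
    masked are flagged omitted rather than dropped.
    """
    if model.feature_order_version_ != FEATURE_ORDER_VERSION:
        raise ValueError(
            f"model feature order {model.feature_order_version_!r} does not match "
            f"this package's {FEATURE_ORDER_VERSION!r}"
        )
    if haplotypes.shape[0] != 100:
        logger.warning(
            "sample has %d chromosomes; classifiers are typically trained on 100 — "
            "statistics are frequency-based so the scan proceeds",
            haplotypes.shape[0],
        )
    n_windows = (mask.end - mask.start) // window_bp
    starts = mask.start + window_bp * np.arange(n_windows)
    pos0 = positions - 1  # 0-based
    raw = np.zeros((len(STAT_NAMES), n_windows))
    accessible = np.zeros(n_windows, dtype=int)
    for w, a in enumerate(starts):
        b = a + window_bp
        acc = mask.count(a, b)
        accessible[w] = acc
        idx = np.flatnonzero((pos0 >= a) & (pos0 < b))
        win = haplotypes[:, idx]
        if acc == 0:
            continue
        pi, tw, th, _ = site_stats(win)
        K, H1, H12, H2H1 = haplotype_stats(win)
        zns, omax = ld_stats(win, max_sites=max_ld_sites, subsample_seed=w)
        raw[:, w] = np.array((pi, tw, th, K, H1, H12, H2H1, zns, omax)) / acc
    half = n_sub // 2
    results: list[ScanResult] = []
    for w, a in enumerate(starts):
        b = a + window_bp
        base = ScanResult(chrom, int(a), int(b), None, None, int(accessible[w]))
        lo, hi = w - half, w + half + 1
        if lo < 0 or hi > n_windows:
            base.omitted, base.reason = True, "incomplete_frame"
            results.append(base)
            continue
        frame_acc = accessible[lo:hi]
        if np.any(frame_acc < (1.0 - max_masked_frac) * window_bp):
            base.omitted, base.reason = True, "masked"
            results.append(base)
            continue
        fv = np.concatenate([normalize_stat_vector(row) for row in raw[:, lo:hi]])
        proba = model.predict_proba(fv.reshape(1, -1))[0]
        base.posteriors = dict(zip(model.classes_.tolist(), proba.tolist()))
        base.label = str(model.classes_[int(np.argmax(proba))])
        results.append(base)
    return results


def write_intervals(results: list[ScanResult], bed_fh, tsv_fh) -> None:
    """Write classified windows as BED (name = class, score = max posterior
    scaled to 0–1000) and all windows as a TSV with the five posteriors."""
    if not results:
        raise ValueError("no scan results to write")
    classes = None
    for r in results:
        if r.posteriors is not None:
            classes = list(r.posteriors)
            break
    header = ["chrom", "start", "end", "label", "n_accessible", "omitted", "reason"]
    tsv_fh.write("\t".join(header + [f"p_{c}" for c in (classes or [])]) + "\n")
    for r in results:
        row = [r.chrom, str(r.start), str(r.end), r.label or ".", str(r.n_accessible),
               str(int(r.omitted)), r.reason or "."]
        if classes:
            if r.posteriors is None:
                row += ["."] * len(classes)
            else:
                row += [f"{r.posteriors[c]:.6f}" for c in classes]
        tsv_fh.write("\t".join(row) + "\n")
        if not r.omitted and r.label is not None:
            score = int(round(1000 * max(r.posteriors.values())))
            bed_fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t{score}\t.\n"
            )
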