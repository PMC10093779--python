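"""WGD-aware copy-number heterogeneity metrics.

Aberration is measured against the ploidy baseline of the tumor: in tumors
without whole-genome doubling (WGD) the expected state is {1,1} and the
expected allele copy number is 1; in WGD tumors they are {2,2} and 2. A
genomic region is deleted when either allele sits below the expected
allele copy number and amplified when either sits above it, so a single
bin can be both (e.g. {2,0} in a non-WGD tumor). The subclonal-SCNA
fraction of a cell is the fraction of its genome whose state differs from
the dataset's most common state for that region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeBins

__all__ = [
    "CellMetrics",
    "LocusStatus",
    "detect_wgd",
    "aberrant_fraction",
    "deletion_amplification_fractions",
    "subclonal_fraction",
    "modal_profile",
    "locus_status",
    "compute_cell_metrics",
    "TP53_LOCUS_HG19",
]

#: TP53 locus, hg19 coordinates (0-based half-open).
TP53_LOCUS_HG19 = ("chr17", 7_565_097, 7_590_856)

DEFAULT_WGD_THRESHOLD = 0.5


@dataclass
class CellMetrics:
    """Genome-fraction summary of one cell (all length-weighted)."""

    cell_id: str
    ploidy: float
    frac_aberrant: float
    frac_deleted: float
    frac_amplified: float
    frac_subclonal: float
    wgd: bool


@dataclass
class LocusStatus:
    """LOH classification of one locus against the tumor's WGD baseline."""

    locus: tuple[str, int, int]
    status: str  # {"no_loh", "loh", "cn_loh"}
    cn_at_locus: tuple[int, int]


def _as_cn(profile) -> np.ndarray:
    cn = getattr(profile, "cn", profile)
    return np.asarray(cn, dtype=np.int64)


def detect_wgd(
    profile,
    bins: GenomeBins,
    threshold: float = DEFAULT_WGD_THRESHOLD,
) -> bool:
    """True when more than ``threshold`` of the genome (length-weighted)
    carries both alleles at copy >= 2.

    A decision rule standing in for a model-based WGD call: a doubled
    genome keeps both haplotypes at >= 2 wherever the pre-doubling state
    was >= {1,1}, so profiles that are ~2x a non-WGD profile trip it.
    """
    cn = _as_cn(profile)
    frac = float(bins.weights[cn.min(axis=1) >= 2].sum())
    return frac > threshold


def aberrant_fraction(profile, bins: GenomeBins, wgd: bool) -> float:
    """Length-weighted fraction of the genome with any SCNA: unordered
    state != {1,1} (non-WGD) or != {2,2} (WGD)."""
    cn = _as_cn(profile)
    base = 2 if wgd else 1
    aberrant = ~np.all(cn == base, axis=1)
    return float(bins.weights[aberrant].sum())


def deletion_amplification_fractions(
    profile, bins: GenomeBins, wgd: bool
) -> tuple[float, float]:
    """Fractions of genome deleted / amplified against the expected allele
    copy number (1 non-WGD, 2 WGD); a bin may be both."""
    cn = _as_cn(profile)
    e = 2 if wgd else 1
    w = bins.weights
    deleted = float(w[cn.min(axis=1) < e].sum())
    amplified = float(w[cn.max(axis=1) > e].sum())
    return deleted, amplified


def modal_profile(profiles, bins: GenomeBins) -> np.ndarray:
    """Per-bin most common ordered (cnA, cnB) state across cells; ties
    resolve toward the lexicographically smallest state."""
    stack = np.stack([_as_cn(p) for p in profiles])
    codes = stack[:, :, 0] * 1024 + stack[:, :, 1]
    out = np.empty((bins.n_bins, 2), dtype=np.int64)
    for b in range(bins.n_bins):
        vals, counts = np.unique(codes[:, b], return_counts=True)
        top = vals[counts == counts.max()].min()
        out[b] = (top // 1024, top % 1024)
    return out


def subclonal_fraction(profile, modal: np.ndarray, bins: GenomeBins) -> float:
    """Length-weighted fraction of bins whose state differs from the
    dataset's modal state."""
    cn = _as_cn(profile)
    differs = np.any(cn != modal, axis=1)
    return float(bins.weights[differs].sum())


def locus_status(
    profile,
    bins: GenomeBins,
    locus: tuple[str, int, int],
    wgd: bool = False,
) -> LocusStatus:
    """Classify LOH at a locus from the overlap-weighted majority state of
    the bins it touches.

    LOH means complete loss of all copies of one allele with the retained
    allele below the expected total; copy-neutral LOH retains an allele at
    or above the expected total (e.g. {2,0} against a diploid baseline).
    """
    chrom, start, end = locus
    idx = bins.overlapping_bins(chrom, start, end)
    if len(idx) == 0:
        raise ValueError(f"locus {locus} overlaps no bins")
    cn = _as_cn(profile)
    overlaps = (
        np.minimum(bins.bin_end[idx], end) - np.maximum(bins.bin_start[idx], start)
    ).astype(float)
    codes = cn[idx, 0] * 1024 + cn[idx, 1]
    best_code, best_w = None, -1.0
    for code in np.unique(codes):
        wsum = overlaps[codes == code].sum()
        if wsum > best_w or (wsum == best_w and code < best_code):
            best_code, best_w = int(code), wsum
    a, b = best_code // 1024, best_code % 1024
    expected_total = 4 if wgd else 2
    if min(a, b) > 0:
        status = "no_loh"
    elif max(a, b) >= expected_total:
        status = "cn_loh"
    else:
        status = "loh"
    return LocusStatus(locus=locus, status=status, cn_at_locus=(int(a), int(b)))


def compute_cell_metrics(
    profile,
    bins: GenomeBins,
    modal: np.ndarray,
    wgd: bool,
    cell_id: str | None = None,
) -> CellMetrics:
    """Bundle all per-cell fractions; ploidy is recomputed from the calls."""
    cn = _as_cn(profile)
    lengths = bins.lengths.astype(float)
    ploidy = float((lengths * cn.sum(axis=1)).sum() / lengths.sum())
    deleted, amplified = deletion_amplification_fractions(cn, bins, wgd)
    return CellMetrics(
        cell_id=cell_id or getattr(profile, "cell_id", ""),
        ploidy=ploidy,
        frac_aberrant=aberrant_fraction(cn, bins, wgd),
        frac_deleted=deleted,
        frac_amplified=amplified,
        frac_subclonal=subclonal_fraction(cn, modal, bins),
        wgd=wgd,
    )
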