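"""Cross-sample SCNA comparison.

Two complementary views of between-sample agreement:

* the identical-window proportion — among genomic windows where at least
  one sample carries an SCNA, the fraction with identical copy-number
  assignments (allele-specific unordered pairs for single-cell consensus
  profiles, rounded totals for bulk segment tables); profiles of
  whole-genome-doubled samples are halved when compared against an
  undoubled partner;
* the Pearson correlation matrix of 1,000-bp binned median copy numbers
  computed from per-sample segment tables, with average-linkage
  hierarchical clustering of samples on 1 - r.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree

from .genome import GenomeBins, make_bins
from .metrics import aberrant_fraction

__all__ = [
    "SegmentTable",
    "ConcordanceResult",
    "window_concordance",
    "binned_median_cn",
    "correlation_matrix",
    "cluster_samples",
]

logger = logging.getLogger(__name__)


@dataclass
class SegmentTable:
    """Per-sample copy-number segments (BED-like, 0-based half-open).

    ``segments`` holds columns chrom, start, end and either ``total_cn``
    or the pair ``cn_a``/``cn_b``; segments must not overlap within a
    sample.
    """

    sample_id: str
    segments: pd.DataFrame
    source: str = "bulk"  # or "single_cell_consensus"

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end"}
        if not need.issubset(self.segments.columns):
            raise ValueError(f"segment table needs columns {sorted(need)}")
        if "total_cn" not in self.segments.columns:
            if {"cn_a", "cn_b"}.issubset(self.segments.columns):
                self.segments = self.segments.assign(
                    total_cn=self.segments["cn_a"] + self.segments["cn_b"]
                )
            else:
                raise ValueError("segment table needs total_cn or cn_a/cn_b")
        for chrom, grp in self.segments.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g["start"].values[1:] < g["end"].values[:-1]).any():
                raise ValueError(f"overlapping segments on {chrom} in {self.sample_id}")


@dataclass
class ConcordanceResult:
    """Pairwise agreement between two samples."""

    pair: tuple[str, str]
    prop_identical: float | None  # None when no window qualifies
    n_windows_considered: int
    corr: float | None = None

    @property
    def defined(self) -> bool:
        return self.prop_identical is not None


def window_concordance(
    a,
    b,
    bins: GenomeBins,
    wgd_a: bool = False,
    wgd_b: bool = False,
    names: tuple[str, str] = ("a", "b"),
    mode: str = "allele",
) -> ConcordanceResult:
    """Identical-window proportion between two profiles on a shared grid.

    Only bins where at least one profile is aberrant against its own WGD
    baseline count. When exactly one profile is doubled it is halved
    before comparison, so diagnosis/relapse pairs across a WGD remain
    comparable. ``mode="allele"`` compares unordered allele-specific
    pairs; ``mode="total"`` compares total copy numbers.
    """
    cn_a = np.asarray(getattr(a, "cn", a), dtype=float)
    cn_b = np.asarray(getattr(b, "cn", b), dtype=float)
    if cn_a.shape != cn_b.shape or cn_a.shape[0] != bins.n_bins:
        raise ValueError("profiles are not on the same bin grid")
    qual = (
        _aberrant_mask(cn_a, wgd_a) | _aberrant_mask(cn_b, wgd_b)
    )
    w = bins.weights
    n_windows = int(qual.sum())
    if n_windows == 0:
        return ConcordanceResult(pair=names, prop_identical=None, n_windows_considered=0)
    if wgd_a != wgd_b:
        if wgd_a:
            cn_a = cn_a / 2.0
        else:
            cn_b = cn_b / 2.0
    if mode == "allele":
        sa = np.sort(cn_a, axis=1)
        sb = np.sort(cn_b, axis=1)
        same = np.all(sa == sb, axis=1)
    elif mode == "total":
        same = np.rint(cn_a.sum(axis=1)) == np.rint(cn_b.sum(axis=1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    prop = float(w[qual & same].sum() / w[qual].sum())
    return ConcordanceResult(pair=names, prop_identical=prop, n_windows_considered=n_windows)


def _aberrant_mask(cn: np.ndarray, wgd: bool) -> np.ndarray:
    base = 2 if wgd else 1
    return ~np.all(cn == base, axis=1)


def binned_median_cn(
    seg: SegmentTable,
    chrom_lengths: dict[str, int],
    bin_size: int = 1000,
) -> tuple[GenomeBins, np.ndarray]:
    """Overlap-weighted median total copy number per fixed-size bin.

    Bins with no covering segment are NaN. With two half-covering
    segments the weighted median is the midpoint of their values.
    """
    bins = make_bins(chrom_lengths, bin_size)
    values = np.full(bins.n_bins, np.nan)
    pieces: dict[int, list[tuple[float, float]]] = {}
    coverage = np.zeros(bins.n_bins)
    for row in seg.segments.itertuples(index=False):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        cnv = float(row.total_cn)
        if chrom not in chrom_lengths:
            raise ValueError(f"segment chromosome {chrom!r} not in genome")
        if start < 0 or end > chrom_lengths[chrom] or start >= end:
            raise ValueError(f"segment {chrom}:{start}-{end} outside the genome")
        idx = bins.overlapping_bins(chrom, start, end)
        ov = (
            np.minimum(bins.bin_end[idx], end) - np.maximum(bins.bin_start[idx], start)
        ).astype(float)
        coverage[idx] += ov
        full = ov == bins.lengths[idx]
        for i, o, isfull in zip(idx.tolist(), ov.tolist(), full.tolist()):
            if isfull and i not in pieces:
                values[i] = cnv
            else:
                pieces.setdefault(i, []).append((cnv, o))
                if not np.isnan(values[i]):
                    pieces[i].append((values[i], float(bins.lengths[i])))
                    values[i] = np.nan
    if np.any(coverage > bins.lengths + 1e-9):
        raise ValueError(f"overlapping segments in sample {seg.sample_id}")
    for i, ps in pieces.items():
        values[i] = _weighted_median([v for v, _ in ps], [o for _, o in ps])
    return bins, values


def _weighted_median(vals, weights) -> float:
    order = np.argsort(vals)
    v = np.asarray(vals, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w)
    half = w.sum() / 2.0
    k = int(np.searchsorted(cum, half))
    if abs(cum[k] - half) < 1e-12 and k + 1 < len(v):
        return float((v[k] + v[k + 1]) / 2.0)
    return float(v[k])


def correlation_matrix(samples: dict[str, np.ndarray], min_bins: int = 100) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation of binned copy-number vectors.

    Samples with zero variance get missing correlations (with a warning);
    the diagonal is 1 by definition.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    df = pd.DataFrame(samples)
    complete = df.notna().astype(int)
    pair_counts = complete.T @ complete
    if (pair_counts.values[np.triu_indices(len(samples), 1)] < min_bins).any():
        warnings.warn(
            f"some sample pairs share fewer than {min_bins} complete bins",
            stacklevel=2,
        )
    for name in df.columns:
        col = df[name].dropna()
        if len(col) and float(col.std()) == 0.0:
            warnings.warn(f"sample {name!r} has zero variance; correlations set missing",
                          stacklevel=2)
    corr = df.corr(method="pearson")  # pairwise-complete by construction
    np.fill_diagonal(corr.values, 1.0)
    return corr


def cluster_samples(
    corr: pd.DataFrame,
    threshold: float,
) -> tuple[dict[str, int], np.ndarray, str]:
    """Group samples by hierarchical clustering on distance 1 - r.

    Average linkage, cut at ``threshold``; missing correlations are given
    the maximal distance 2. Returns (labels, linkage matrix, dendrogram in
    Newick). Group numbers follow sample order deterministically.
    """
    names = list(corr.columns)
    d = 1.0 - corr.values
    d = np.where(np.isnan(d), 2.0, d)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    condensed = d[np.triu_indices(len(names), k=1)]
    z = linkage(condensed, method="average")
    raw = fcluster(z, t=threshold, criterion="distance")
    # Renumber groups in order of first appearance.
    remap: dict[int, int] = {}
    labels = {}
    for name, g in zip(names, raw.tolist()):
        labels[name] = remap.setdefault(g, len(remap) + 1)
    newick = _linkage_to_newick(z, names)
    return labels, z, newick


def _linkage_to_newick(z: np.ndarray, names: list[str]) -> str:
    tree = to_tree(z)

    def fmt(node, parent_dist) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return fmt(tree, tree.dist) + ";"
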