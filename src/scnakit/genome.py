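"""Binned genome coordinate system shared by every analysis stage.

All coordinates are 0-based, half-open base-pair intervals. A genome is an
ordered set of chromosomes tiled by fixed-size bins; the last bin of each
chromosome may be shorter than ``bin_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "GenomeBins",
    "make_bins",
    "HG19_AUTOSOMES",
    "scaled_autosomes",
]

#: hg19 autosome lengths in bp (GRCh37 primary assembly).
HG19_AUTOSOMES: dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430,
    "chr4": 191154276, "chr5": 180915260, "chr6": 171115067,
    "chr7": 159138663, "chr8": 146364022, "chr9": 141213431,
    "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392,
    "chr16": 90354753, "chr17": 81195210, "chr18": 78077248,
    "chr19": 59128983, "chr20": 63025520, "chr21": 48129895,
    "chr22": 51304566,
}


def scaled_autosomes(total_bp: int = 550_000_000) -> dict[str, int]:
    """22 synthetic autosomes with hg19 length proportions scaled to ``total_bp``.

    Lengths are rounded to 2.5 Mb (and kept at least that long) so that the
    terminal bin of each chromosome stays large enough to carry useful read
    support at 0.01X-0.05X coverage. The default total (550 Mb, ~1/5 of the
    real autosomal genome) keeps several bins per chromosome at the default
    5 Mb bin size while staying fast to simulate.
    """
    full = sum(HG19_AUTOSOMES.values())
    quantum = 2_500_000
    out = {}
    for name, length in HG19_AUTOSOMES.items():
        scaled = int(round(length / full * total_bp / quantum)) * quantum
        out[name] = max(scaled, quantum)
    return out


@dataclass(frozen=True)
class GenomeBins:
    """Fixed binning of an ordered set of chromosomes.

    Attributes
    ----------
    chrom_names : tuple of str
        Chromosome identifiers in genome order.
    bin_start, bin_end : ndarray of int
        Per-bin coordinates in bp, 0-based half-open.
    bin_size : int
        Nominal bin width in bp; only the last bin of a chromosome may be
        shorter.
    chrom_of_bin : ndarray of int
        Index into ``chrom_names`` for every bin.
    """

    chrom_names: tuple[str, ...]
    bin_start: np.ndarray
    bin_end: np.ndarray
    bin_size: int
    chrom_of_bin: np.ndarray
    _chrom_index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_start", np.asarray(self.bin_start, dtype=np.int64))
        object.__setattr__(self, "bin_end", np.asarray(self.bin_end, dtype=np.int64))
        object.__setattr__(self, "chrom_of_bin", np.asarray(self.chrom_of_bin, dtype=np.int64))
        object.__setattr__(
            self, "_chrom_index", {c: i for i, c in enumerate(self.chrom_names)}
        )
        self._validate()

    def _validate(self) -> None:
        if len(self.chrom_names) == 0:
            raise ValueError("empty genome")
        if not (len(self.bin_start) == len(self.bin_end) == len(self.chrom_of_bin)):
            raise ValueError("bin coordinate arrays must have equal length")
        lengths = self.bin_end - self.bin_start
        if np.any(lengths <= 0):
            raise ValueError("bins must have positive length")
        for ci in range(len(self.chrom_names)):
            mask = self.chrom_of_bin == ci
            starts, ends = self.bin_start[mask], self.bin_end[mask]
            if len(starts) == 0:
                raise ValueError(f"chromosome {self.chrom_names[ci]} has no bins")
            if starts[0] != 0 or np.any(starts[1:] != ends[:-1]):
                raise ValueError(
                    f"bins of {self.chrom_names[ci]} are not contiguous from 0"
                )
            if np.any((ends - starts)[:-1] != self.bin_size):
                raise ValueError(
                    f"non-terminal bin of {self.chrom_names[ci]} has wrong size"
                )
            if ends[-1] - starts[-1] > self.bin_size:
                raise ValueError(
                    f"terminal bin of {self.chrom_names[ci]} exceeds bin_size"
                )

    # -- derived views -------------------------------------------------

    @property
    def n_bins(self) -> int:
        return len(self.bin_start)

    @property
    def lengths(self) -> np.ndarray:
        """Per-bin length in bp."""
        return self.bin_end - self.bin_start

    @property
    def weights(self) -> np.ndarray:
        """Per-bin length fraction of the genome (sums to 1)."""
        lengths = self.lengths.astype(float)
        return lengths / lengths.sum()

    @property
    def total_bp(self) -> int:
        return int(self.lengths.sum())

    @property
    def chrom_labels(self) -> np.ndarray:
        """Chromosome name of every bin."""
        return np.asarray(self.chrom_names, dtype=object)[self.chrom_of_bin]

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous global-bin-index slice covering ``chrom``."""
        ci = self._chrom_index[chrom]
        idx = np.flatnonzero(self.chrom_of_bin == ci)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chrom_slices(self) -> list[tuple[str, slice]]:
        return [(c, self.chrom_slice(c)) for c in self.chrom_names]

    def chrom_length(self, chrom: str) -> int:
        sl = self.chrom_slice(chrom)
        return int(self.bin_end[sl.stop - 1])

    def overlapping_bins(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of bins overlapping [start, end) on ``chrom``."""
        if chrom not in self._chrom_index:
            raise ValueError(f"unknown chromosome {chrom!r}")
        sl = self.chrom_slice(chrom)
        mask = (self.bin_start[sl] < end) & (self.bin_end[sl] > start)
        return np.flatnonzero(mask) + sl.start

    @classmethod
    def from_intervals(
        cls,
        chroms: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
    ) -> "GenomeBins":
        """Build bins from explicit per-bin (chrom, start, end) rows.

        Rows must already be in genome order; chromosome order is order of
        first appearance. Used when reading external call tables.
        """
        chroms = np.asarray(chroms, dtype=object)
        names: list[str] = []
        for c in chroms:
            if c not in names:
                names.append(c)
        name_idx = {c: i for i, c in enumerate(names)}
        chrom_of_bin = np.array([name_idx[c] for c in chroms], dtype=np.int64)
        lengths = np.asarray(ends) - np.asarray(starts)
        return cls(
            chrom_names=tuple(names),
            bin_start=np.asarray(starts),
            bin_end=np.asarray(ends),
            bin_size=int(lengths.max()),
            chrom_of_bin=chrom_of_bin,
        )


def make_bins(chrom_lengths: Mapping[str, int], bin_size: int) -> GenomeBins:
    """Tile each chromosome with fixed-size bins.

    Parameters
    ----------
    chrom_lengths : mapping of chromosome name to length in bp
    bin_size : nominal bin width in bp

    Returns
    -------
    GenomeBins
        ``ceil(length / bin_size)`` bins per chromosome; the terminal bin of
        a chromosome absorbs the remainder.
    """
    if len(chrom_lengths) == 0:
        raise ValueError("empty genome")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    starts, ends, chrom_of_bin = [], [], []
    names = tuple(chrom_lengths)
    for ci, name in enumerate(names):
        length = int(chrom_lengths[name])
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length")
        edges = list(range(0, length, bin_size)) + [length]
        for s, e in zip(edges[:-1], edges[1:]):
            starts.append(s)
            ends.append(e)
            chrom_of_bin.append(ci)
    return GenomeBins(
        chrom_names=names,
        bin_start=np.array(starts, dtype=np.int64),
        bin_end=np.array(ends, dtype=np.int64),
        bin_size=int(bin_size),
        chrom_of_bin=np.array(chrom_of_bin, dtype=np.int64),
    )
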