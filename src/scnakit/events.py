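"""Copy-number events: the atomic edits of the interval-event model.

An interval event adds or removes one copy of a single haplotype over a
contiguous run of bins within one chromosome. A whole-genome doubling (WGD)
doubles both haplotypes of every bin. Haplotypes lost completely (copy 0)
can never be regained (LOH irreversibility), so a gain event may not cover
a bin whose target haplotype is at 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genome import GenomeBins

__all__ = ["EventRecord", "apply_event", "apply_events", "diploid_profile"]

HAP_INDEX = {"A": 0, "B": 1}


@dataclass(frozen=True)
class EventRecord:
    """One copy-number event.

    ``kind`` is one of {"gain", "del", "loh", "cn_loh", "wgd"} once
    classified, or ``None`` for a raw +/-1 event. ``start_bin``/``end_bin``
    are half-open *global* bin indices confined to one chromosome; a WGD is
    genome-wide with ``haplotype="both"`` and ``delta=0``.
    """

    kind: str | None
    haplotype: str  # "A", "B" or "both"
    chrom: str
    start_bin: int
    end_bin: int
    delta: int

    def is_wgd(self) -> bool:
        return self.kind == "wgd" or self.haplotype == "both"

    def sort_key(self) -> tuple:
        return (self.chrom, self.start_bin, self.end_bin, self.haplotype, self.delta)


def diploid_profile(bins: GenomeBins) -> np.ndarray:
    """The normal germline profile: (1, 1) in every bin."""
    return np.ones((bins.n_bins, 2), dtype=np.int64)


def apply_event(profile: np.ndarray, event: EventRecord, check: bool = True) -> np.ndarray:
    """Return a copy of ``profile`` with ``event`` applied.

    With ``check=True``, violations of non-negativity or LOH
    irreversibility raise ``ValueError``.
    """
    out = profile.copy()
    if event.is_wgd():
        out *= 2
        return out
    h = HAP_INDEX[event.haplotype]
    sl = slice(event.start_bin, event.end_bin)
    if check:
        if event.delta > 0 and np.any(out[sl, h] == 0):
            raise ValueError("gain event covers a haplotype at copy 0 (irreversible LOH)")
        if event.delta < 0 and np.any(out[sl, h] + event.delta < 0):
            raise ValueError("deletion event drives a haplotype below 0")
    out[sl, h] += event.delta
    return out


def apply_events(profile: np.ndarray, events: list[EventRecord], check: bool = True) -> np.ndarray:
    for ev in events:
        profile = apply_event(profile, ev, check=check)
    return profile


def shift_event(event: EventRecord, **changes) -> EventRecord:
    return replace(event, **changes)
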