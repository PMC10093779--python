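"""Grouping cells into clones by copy-number similarity.

Cells are clustered on the length-weighted fraction of bins whose ordered
(cnA, cnB) pairs differ, with average-linkage agglomerative clustering cut
at the expected per-cell error rate (default 0.12, the tolerance used for
clone identification at ~0.02X coverage). Clusters below a minimum size
are dissolved into a NOISY pool; one reassignment pass then rescues any
noisy cell that sits within the error tolerance of a clone consensus, a
control that no coherent rare clone is being discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .genome import GenomeBins
from .infer import CellProfile

__all__ = [
    "NOISY",
    "CloneProfile",
    "CloneSet",
    "cell_distance",
    "identify_clones",
    "noisy_cell_audit",
]

logger = logging.getLogger(__name__)

NOISY = "NOISY"
DEFAULT_ERROR_RATE = 0.12


@dataclass
class CloneProfile:
    """Consensus profile of one clone: the per-bin modal state among member
    cells (ties resolved toward the medoid cell's state)."""

    clone_id: str
    cn: np.ndarray
    n_cells: int
    wgd: bool = False


@dataclass
class CloneSet:
    """Clone assignment of a cell population.

    ``labels`` maps cell_id to a clone id or ``NOISY``; every non-noisy
    cell lies within ``error_rate`` of its clone consensus.
    """

    labels: dict[str, str]
    clones: list[CloneProfile]
    error_rate: float = DEFAULT_ERROR_RATE

    def clone(self, clone_id: str) -> CloneProfile:
        for c in self.clones:
            if c.clone_id == clone_id:
                return c
        raise KeyError(clone_id)

    @property
    def noisy_cells(self) -> list[str]:
        return sorted(cid for cid, lab in self.labels.items() if lab == NOISY)


def _codes(cn: np.ndarray) -> np.ndarray:
    """Encode (cnA, cnB) pairs as single integers for fast comparison."""
    return cn[:, 0].astype(np.int64) * 1024 + cn[:, 1].astype(np.int64)


def cell_distance(a: CellProfile, b: CellProfile, bins: GenomeBins) -> float:
    """Length-weighted fraction of bins with different ordered (cnA, cnB)
    states; symmetric, zero iff identical."""
    if a.cn.shape != b.cn.shape or a.cn.shape[0] != bins.n_bins:
        raise ValueError("profiles are not on the same bin grid")
    w = bins.weights
    return float(w[np.any(a.cn != b.cn, axis=1)].sum())


def _distance_matrix(code_matrix: np.ndarray, weights: np.ndarray) -> np.ndarray:
    n = code_matrix.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = code_matrix[i + 1:] != code_matrix[i]
        d[i, i + 1:] = diff @ weights
    return d + d.T


def identify_clones(
    cells: list[CellProfile],
    bins: GenomeBins,
    error_rate: float = DEFAULT_ERROR_RATE,
    min_clone_size: int | None = None,
) -> CloneSet:
    """Group cells into clones, excluding outliers and likely noisy cells.

    Average-linkage agglomerative clustering on :func:`cell_distance`, cut
    at ``error_rate``. Clusters smaller than ``min_clone_size`` (default
    ``max(5, 1% of cells)``) are dissolved to NOISY. Consensus profiles
    are per-bin modal states; members farther than ``error_rate`` from
    their consensus are demoted to NOISY, and one reassignment pass
    rescues NOISY cells within ``error_rate`` of any consensus. The result
    is invariant to input order (cells are processed sorted by id).
    """
    if not cells:
        raise ValueError("at least one cell required")
    cells = sorted(cells, key=lambda c: c.cell_id)
    if min_clone_size is None:
        min_clone_size = max(5, round(0.01 * len(cells)))
    codes = np.stack([_codes(c.cn) for c in cells])
    w = bins.weights

    labels = np.zeros(len(cells), dtype=np.int64)
    if len(cells) > 1:
        d = _distance_matrix(codes, w)
        condensed = d[np.triu_indices(len(cells), k=1)]
        z = linkage(condensed, method="average")
        labels = fcluster(z, t=error_rate, criterion="distance")
    else:
        labels = np.array([1])

    assignment: dict[str, str] = {}
    clusters: list[np.ndarray] = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) >= min_clone_size or len(cells) < min_clone_size:
            clusters.append(members)
    # Order clones by size (desc), then by first member id, for determinism.
    clusters.sort(key=lambda m: (-len(m), cells[m[0]].cell_id))

    clone_profiles: list[CloneProfile] = []
    consensus_codes = []
    for k, members in enumerate(clusters, start=1):
        consensus = _consensus(codes[members], w)
        clone_profiles.append(CloneProfile(
            clone_id=f"clone_{k}",
            cn=_decode(consensus),
            n_cells=len(members),
        ))
        consensus_codes.append(consensus)
        for m in members:
            assignment[cells[m].cell_id] = f"clone_{k}"

    # Enforce the membership invariant and run one rescue pass for NOISY.
    demoted = 0
    if consensus_codes:
        cons = np.stack(consensus_codes)
        dist_to_cons = np.zeros((len(cells), len(cons)))
        for j in range(len(cons)):
            dist_to_cons[:, j] = (codes != cons[j]) @ w
        for i, cell in enumerate(cells):
            lab = assignment.get(cell.cell_id, NOISY)
            if lab != NOISY:
                j = int(lab.split("_")[1]) - 1
                if dist_to_cons[i, j] > error_rate:
                    assignment[cell.cell_id] = NOISY
                    demoted += 1
        for i, cell in enumerate(cells):
            if assignment.get(cell.cell_id, NOISY) == NOISY:
                j = int(np.argmin(dist_to_cons[i]))
                if dist_to_cons[i, j] <= error_rate:
                    assignment[cell.cell_id] = clone_profiles[j].clone_id
    for cell in cells:
        assignment.setdefault(cell.cell_id, NOISY)
    if demoted:
        logger.info("demoted %d cells beyond error_rate of their consensus", demoted)

    # Refresh member counts after demotion/rescue.
    counts = pd.Series(list(assignment.values())).value_counts()
    for cp in clone_profiles:
        cp.n_cells = int(counts.get(cp.clone_id, 0))

    return CloneSet(labels=assignment, clones=clone_profiles, error_rate=error_rate)


def _consensus(member_codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-bin modal state; ties resolved toward the medoid cell's state
    (falling back to the smallest state code for full determinism)."""
    n, nb = member_codes.shape
    # Medoid: cell minimising total distance to other members.
    if n > 1:
        d = _distance_matrix(member_codes, weights)
        medoid = int(np.argmin(d.sum(axis=1)))
    else:
        medoid = 0
    out = np.empty(nb, dtype=np.int64)
    for b in range(nb):
        vals, counts = np.unique(member_codes[:, b], return_counts=True)
        top = vals[counts == counts.max()]
        if len(top) == 1:
            out[b] = top[0]
        elif member_codes[medoid, b] in top:
            out[b] = member_codes[medoid, b]
        else:
            out[b] = top.min()
    return out


def _decode(codes: np.ndarray) -> np.ndarray:
    return np.stack([codes // 1024, codes % 1024], axis=1)


def noisy_cell_audit(
    cloneset: CloneSet,
    cells: list[CellProfile],
    bins: GenomeBins,
) -> pd.DataFrame:
    """Nearest-clone distance of every NOISY cell.

    Supports the control that no coherent rare clone was discarded: noisy
    cells should sit far (beyond the error rate) from every consensus.
    """
    rows = []
    by_id = {c.cell_id: c for c in cells}
    w = bins.weights
    for cid in cloneset.noisy_cells:
        codes = _codes(by_id[cid].cn)
        best_clone, best_d = None, np.inf
        for cp in cloneset.clones:
            dist = float(((codes != _codes(cp.cn)) @ w))
            if dist < best_d or (dist == best_d and best_clone is None):
                best_clone, best_d = cp.clone_id, dist
        rows.append({"cell_id": cid, "nearest_clone": best_clone, "distance": best_d})
    return pd.DataFrame(rows, columns=["cell_id", "nearest_clone", "distance"])
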