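"""Synthetic low-coverage single-cell DNA-seq from a clonal copy-number history.

The generator emulates the data regime of droplet-based single-cell
whole-genome sequencing of chromosomally complex tumors: hundreds to a few
thousand cells per sample at ~0.01X-0.05X coverage each, deletion-dominated
karyotypes, optional whole-genome doubling, a fraction of admixed normal
(diploid) cells, and a fraction of technically noisy cells. Every cell's
generating clone is recorded, so downstream stages can be scored against
ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .events import EventRecord, apply_events, diploid_profile
from .genome import GenomeBins
from .phylo import classify_events

__all__ = [
    "ClonalTruth",
    "CellObservation",
    "simulate_clonal_truth",
    "simulate_cells",
    "NORMAL",
    "NOISE",
]

logger = logging.getLogger(__name__)

NORMAL = "normal"
NOISE = "noise"
ROOT = "diploid"


@dataclass
class ClonalTruth:
    """Ground-truth clonal copy-number evolution of one simulated tumor.

    The tree is rooted at the diploid germline; ``parent`` maps each clone
    to its parent node, ``edge_events`` holds the events of the edge from
    the parent (a WGD record first when the edge carries one).
    """

    clone_ids: list[str]
    parent: dict[str, str]
    edge_events: dict[str, list[EventRecord]]
    clone_profiles: dict[str, np.ndarray]
    clone_proportions: dict[str, float]
    wgd_edges: set[str]
    normal_fraction: float
    seed: int
    n_resampled_events: int = 0

    def root_path(self, clone: str) -> list[str]:
        path = [clone]
        while path[-1] != ROOT:
            path.append(self.parent[path[-1]])
        return path[::-1]

    def replay_profile(self, clone: str, bins: GenomeBins) -> np.ndarray:
        """Recompute a clone profile by replaying its root-path events."""
        profile = diploid_profile(bins)
        for node in self.root_path(clone)[1:]:
            profile = apply_events(profile, self.edge_events[node], check=True)
        return profile

    def has_wgd(self, clone: str) -> bool:
        return any(node in self.wgd_edges for node in self.root_path(clone)[1:])


@dataclass
class CellObservation:
    """Binned read counts of one sequenced cell.

    ``b_count``/``snp_total`` are the phased B-haplotype and total
    SNP-overlapping read counts per bin; ``true_clone`` is the generating
    clone label, ``"normal"`` or ``"noise"``.
    """

    cell_id: str
    read_count: np.ndarray
    b_count: np.ndarray
    snp_total: np.ndarray
    true_clone: str

    def __post_init__(self) -> None:
        if np.any(self.b_count > self.snp_total) or np.any(self.b_count < 0):
            raise ValueError("b_count must satisfy 0 <= b_count <= snp_total")
        if np.any(self.read_count < 0):
            raise ValueError("read_count must be non-negative")


def _random_event(
    rng: np.random.Generator,
    bins: GenomeBins,
    profile: np.ndarray,
    deletion_bias: float,
    min_event_bins: int,
    max_tries: int = 10_000,
) -> tuple[EventRecord, int]:
    """Draw one valid interval event on ``profile``.

    A chromosome is chosen uniformly, then a uniformly random sub-interval
    of its bins. Events that would drive a haplotype below 0 or regain a
    haplotype at 0 are resampled (irreversible LOH); the resample count is
    returned for logging.
    """
    resampled = 0
    for _ in range(max_tries):
        chrom = bins.chrom_names[rng.integers(len(bins.chrom_names))]
        sl = bins.chrom_slice(chrom)
        n = sl.stop - sl.start
        if n < min_event_bins:
            resampled += 1
            continue
        span = int(rng.integers(min_event_bins, n + 1))
        start = sl.start + int(rng.integers(0, n - span + 1))
        end = start + span
        hap = "A" if rng.random() < 0.5 else "B"
        h = 0 if hap == "A" else 1
        delta = -1 if rng.random() < deletion_bias else 1
        segment = profile[start:end, h]
        if delta < 0 and np.any(segment < 1):
            resampled += 1
            continue
        if delta > 0 and np.any(segment == 0):
            resampled += 1
            continue
        return EventRecord(None, hap, chrom, start, end, delta), resampled
    raise RuntimeError("could not draw a valid event; profile too depleted")


def simulate_clonal_truth(
    bins: GenomeBins,
    n_clones: int,
    n_truncal_events: int,
    n_private_events: int,
    p_wgd: float,
    deletion_bias: float,
    seed: int,
    clone_proportions: list[float] | None = None,
    normal_fraction: float = 0.0,
    topology: str = "random",
    min_event_bins: int = 1,
) -> ClonalTruth:
    """Simulate a rooted clonal copy-number evolution.

    Truncal events land on the root edge to the founder clone; each later
    clone attaches to an existing clone (uniformly at random, or in a
    chain / star when ``topology`` says so) with ``n_private_events``
    private events. A whole-genome doubling is inserted on the truncal edge
    with probability ``p_wgd``, before the truncal interval events. Each
    interval event is a contiguous +/-1 on one haplotype, a loss with
    probability ``deletion_bias``.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if not (0 <= p_wgd <= 1 and 0 <= deletion_bias <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_truncal_events < 0 or n_private_events < 0:
        raise ValueError("event counts must be >= 0")
    if topology not in ("random", "chain", "star"):
        raise ValueError(f"unknown topology {topology!r}")
    rng = np.random.default_rng(seed)

    clone_ids = [f"clone_{i + 1}" for i in range(n_clones)]
    parent: dict[str, str] = {}
    edge_events: dict[str, list[EventRecord]] = {}
    profiles: dict[str, np.ndarray] = {}
    wgd_edges: set[str] = set()
    n_resampled = 0

    founder = clone_ids[0]
    parent[founder] = ROOT
    profile = diploid_profile(bins)
    events: list[EventRecord] = []
    wgd_on_truncal = rng.random() < p_wgd
    if wgd_on_truncal:
        events.append(EventRecord("wgd", "both", "*", 0, bins.n_bins, 0))
        profile = profile * 2
        wgd_edges.add(founder)
    for _ in range(n_truncal_events):
        ev, k = _random_event(rng, bins, profile, deletion_bias, min_event_bins)
        n_resampled += k
        profile = apply_events(profile, [ev])
        events.append(ev)
    edge_events[founder] = events
    profiles[founder] = profile

    for cid in clone_ids[1:]:
        existing = [c for c in clone_ids if c in profiles]
        if topology == "chain":
            anchor = existing[-1]
        elif topology == "star":
            anchor = founder
        else:
            anchor = existing[int(rng.integers(len(existing)))]
        parent[cid] = anchor
        profile = profiles[anchor].copy()
        events = []
        for _ in range(n_private_events):
            ev, k = _random_event(rng, bins, profile, deletion_bias, min_event_bins)
            n_resampled += k
            profile = apply_events(profile, [ev])
            events.append(ev)
        edge_events[cid] = events
        profiles[cid] = profile

    if n_resampled:
        logger.info("resampled %d invalid events", n_resampled)

    # Classify edge events against the WGD-aware allele baseline.
    for cid in clone_ids:
        path_wgd = any(
            node in wgd_edges
            for node in _root_path(parent, cid)
        )
        expected = 2 if path_wgd else 1
        anchor_profile = (
            diploid_profile(bins) if parent[cid] == ROOT else profiles[parent[cid]]
        )
        edge_events[cid] = classify_events(
            edge_events[cid], anchor_profile, expected_allele_cn=expected
        )

    if clone_proportions is None:
        props = rng.dirichlet(np.full(n_clones, 2.0))
    else:
        props = np.asarray(clone_proportions, dtype=float)
        if len(props) != n_clones:
            raise ValueError("clone_proportions length must equal n_clones")
    if abs(props.sum() - 1.0) > 1e-6 or np.any(props < 0):
        raise ValueError("clone_proportions must be non-negative and sum to 1")
    if not 0 <= normal_fraction < 1:
        raise ValueError("normal_fraction must lie in [0, 1)")

    return ClonalTruth(
        clone_ids=clone_ids,
        parent=parent,
        edge_events=edge_events,
        clone_profiles=profiles,
        clone_proportions=dict(zip(clone_ids, props.tolist())),
        wgd_edges=wgd_edges,
        normal_fraction=float(normal_fraction),
        seed=int(seed),
        n_resampled_events=n_resampled,
    )


def _root_path(parent: dict[str, str], clone: str) -> list[str]:
    path = [clone]
    while path[-1] != ROOT:
        path.append(parent[path[-1]])
    return path[::-1]


def simulate_cells(
    truth: ClonalTruth,
    bins: GenomeBins,
    n_cells: int,
    mean_coverage: float = 0.02,
    snp_density: float = 1 / 1500,
    noise_cell_fraction: float = 0.0,
    seed: int = 0,
    read_length: int = 100,
    coverage_cv: float = 0.25,
    noise_perturb_prob: float = 0.3,
    overdispersion: float = 0.0,
) -> list[CellObservation]:
    """Draw per-cell binned read counts and phased allele counts.

    Each cell is a normal diploid cell with probability
    ``truth.normal_fraction``, a noisy cell with probability
    ``noise_cell_fraction`` (a random clone profile with each bin
    resampled from {0..4}^2 with probability ``noise_perturb_prob``), and
    otherwise a tumor cell drawn by clone proportions.

    The cell's total read budget is ``coverage * genome_bp / read_length``
    with a per-cell Gamma-distributed coverage (mean ``mean_coverage``,
    CV ``coverage_cv``); bin counts are Poisson with mean proportional to
    bin length x total copy number (negative binomial when
    ``overdispersion`` > 0). SNP-overlapping reads are a binomial thinning
    at rate ``snp_density * read_length`` and B-haplotype reads are
    binomial with success probability cnB / (cnA + cnB) (0.5 in empty
    bins).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    props = np.array([truth.clone_proportions[c] for c in truth.clone_ids])
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValueError("clone_proportions do not sum to 1")
    rng = np.random.default_rng(seed)
    genome_bp = bins.total_bp
    lengths = bins.lengths.astype(float)
    snp_read_fraction = min(1.0, snp_density * read_length)
    n_digits = len(str(n_cells))

    cells: list[CellObservation] = []
    for i in range(n_cells):
        u = rng.random()
        if u < truth.normal_fraction:
            label = NORMAL
            profile = diploid_profile(bins)
        elif u < truth.normal_fraction + noise_cell_fraction:
            label = NOISE
            base = truth.clone_ids[rng.choice(len(props), p=props / props.sum())]
            profile = truth.clone_profiles[base].copy()
            mask = rng.random(bins.n_bins) < noise_perturb_prob
            profile[mask] = rng.integers(0, 5, size=(int(mask.sum()), 2))
        else:
            label = truth.clone_ids[rng.choice(len(props), p=props / props.sum())]
            profile = truth.clone_profiles[label]

        total_cn = profile.sum(axis=1)
        if coverage_cv > 0:
            shape = 1.0 / coverage_cv**2
            coverage = mean_coverage * rng.gamma(shape, 1.0 / shape)
        else:
            coverage = mean_coverage
        budget = coverage * genome_bp / read_length
        weights = lengths * total_cn
        wsum = weights.sum()
        mean_reads = budget * weights / wsum if wsum > 0 else np.zeros_like(weights)
        if overdispersion > 0:
            # NB parametrised by mean m and dispersion a: var = m + a m^2
            a = overdispersion
            r = 1.0 / a
            p = r / (r + mean_reads)
            read_count = np.where(
                mean_reads > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1)), 0
            )
        else:
            read_count = rng.poisson(mean_reads)
        snp_total = rng.binomial(read_count, snp_read_fraction)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_b = np.where(total_cn > 0, profile[:, 1] / np.maximum(total_cn, 1), 0.5)
        b_count = rng.binomial(snp_total, p_b)
        cells.append(CellObservation(
            cell_id=f"cell_{i:0{n_digits}d}",
            read_count=read_count.astype(np.int64),
            b_count=b_count.astype(np.int64),
            snp_total=snp_total.astype(np.int64),
            true_clone=label,
        ))
    return cells
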