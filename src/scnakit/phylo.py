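"""Maximum-parsimony interval-event phylogeny of clone copy-number profiles.

The evolutionary model: starting from the diploid germline profile
(1,1 in every bin), a tumor accumulates unit interval events (+/-1 on one
haplotype over a contiguous run of bins within a chromosome) and at most
one whole-genome doubling per lineage. A haplotype at copy 0 can never be
regained (LOH irreversibility). The directed distance between two profiles
is the minimum number of such events transforming the first into the
second; a rooted clone tree minimises the total event count over all edges.

Events are classified following the standard taxonomy: losses that leave a
haplotype at 0 are LOH, LOH whose retained allele ends above the expected
allele copy number are copy-neutral LOH, other losses are deletions, and
positive events are gains.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .events import EventRecord, apply_events, diploid_profile
from .genome import GenomeBins

__all__ = [
    "EventRecord",
    "CopyNumberTree",
    "interval_event_distance",
    "min_interval_events",
    "min_interval_events_matrix",
    "classify_events",
    "reconstruct_tree",
    "clone_ancestor_map",
]

logger = logging.getLogger(__name__)

_INF = np.inf


# ----------------------------------------------------------------------
# Interval-event distance
# ----------------------------------------------------------------------

def min_interval_events(parent: np.ndarray, child: np.ndarray) -> float:
    """Minimum number of unit interval events turning one per-bin copy-number
    vector into another, both on a single haplotype of a single chromosome.

    The count is the sum, over loss and gain phases separately, of the
    positive increments of the per-bin required change (each new "level" of
    a contiguous run costs one event). Returns ``inf`` when the child
    regains a haplotype the parent has lost (copy 0 -> >0).
    """
    parent = np.asarray(parent, dtype=np.int64)
    child = np.asarray(child, dtype=np.int64)
    if np.any((parent == 0) & (child > 0)):
        return _INF
    d = child - parent
    pos = np.maximum(d, 0)
    neg = np.maximum(-d, 0)
    count = 0
    for arr in (pos, neg):
        prev = np.concatenate(([0], arr[:-1]))
        count += int(np.maximum(arr - prev, 0).sum())
    return float(count)


def min_interval_events_matrix(parents: np.ndarray, children: np.ndarray) -> np.ndarray:
    """Vectorised ``min_interval_events`` for all (parent, child) pairs.

    ``parents`` is (P, n_bins), ``children`` is (C, n_bins); the result is a
    (P, C) float matrix with ``inf`` marking unreachable pairs. Bins are
    treated as one chromosome.
    """
    p = np.asarray(parents, dtype=np.int64)[:, None, :]
    c = np.asarray(children, dtype=np.int64)[None, :, :]
    d = c - p
    pos = np.maximum(d, 0)
    neg = np.maximum(-d, 0)
    counts = np.zeros(d.shape[:2], dtype=np.float64)
    for arr in (pos, neg):
        prev = np.concatenate([np.zeros_like(arr[..., :1]), arr[..., :-1]], axis=-1)
        counts += np.maximum(arr - prev, 0).sum(axis=-1)
    infeasible = ((p == 0) & (c > 0)).any(axis=-1)
    counts[infeasible] = _INF
    return counts


def _decompose_events(
    parent: np.ndarray, child: np.ndarray, bins: GenomeBins, haplotype: str
) -> list[EventRecord] | None:
    """One optimal event list realising ``child`` from ``parent`` on one
    haplotype, or None if unreachable. Events never cross chromosomes."""
    if np.any((parent == 0) & (child > 0)):
        return None
    events: list[EventRecord] = []
    for chrom, sl in bins.chrom_slices():
        d = child[sl] - parent[sl]
        for arr, sign in ((np.maximum(d, 0), 1), (np.maximum(-d, 0), -1)):
            open_levels: dict[int, int] = {}
            prev = 0
            for i, v in enumerate(arr.tolist()):
                if v > prev:
                    for k in range(prev + 1, v + 1):
                        open_levels[k] = i
                elif v < prev:
                    for k in range(v + 1, prev + 1):
                        events.append(EventRecord(
                            kind=None, haplotype=haplotype, chrom=chrom,
                            start_bin=sl.start + open_levels.pop(k),
                            end_bin=sl.start + i, delta=sign,
                        ))
                prev = v
            for k, start in open_levels.items():
                events.append(EventRecord(
                    kind=None, haplotype=haplotype, chrom=chrom,
                    start_bin=sl.start + start, end_bin=sl.stop, delta=sign,
                ))
    return events


def _plain_distance(
    parent: np.ndarray, child: np.ndarray, bins: GenomeBins
) -> tuple[float, list[EventRecord] | None]:
    total = 0.0
    events: list[EventRecord] = []
    for h, hap in enumerate("AB"):
        evs = _decompose_events(parent[:, h], child[:, h], bins, hap)
        if evs is None:
            return _INF, None
        events.extend(evs)
        total += len(evs)
    return total, events


def interval_event_distance(
    parent: np.ndarray,
    child: np.ndarray,
    bins: GenomeBins,
    allow_wgd: bool = False,
    expected_allele_cn: int = 1,
) -> tuple[int, list[EventRecord]]:
    """Minimal interval-event transformation of ``parent`` into ``child``.

    Parameters
    ----------
    parent, child : (n_bins, 2) int arrays of haplotype-specific copy numbers.
    allow_wgd : also consider spending one event on a whole-genome doubling,
        applied either before or after the interval events of this edge.
    expected_allele_cn : baseline allele copy number used when classifying
        the returned events (2 below a WGD).

    Returns
    -------
    (count, events) where replaying ``events`` on ``parent`` yields
    ``child`` exactly. Raises ``ValueError`` when no valid event path
    exists (LOH irreversibility).
    """
    parent = np.asarray(parent, dtype=np.int64)
    child = np.asarray(child, dtype=np.int64)
    if parent.shape != child.shape or parent.shape != (bins.n_bins, 2):
        raise ValueError("profiles must both be (n_bins, 2) on the given bin grid")

    candidates: list[tuple[float, list[EventRecord]]] = []
    count, events = _plain_distance(parent, child, bins)
    if events is not None:
        candidates.append((count, events))
    if allow_wgd:
        wgd = EventRecord(kind="wgd", haplotype="both", chrom="*",
                          start_bin=0, end_bin=bins.n_bins, delta=0)
        # WGD first: remaining events act on the doubled parent.
        count, events = _plain_distance(parent * 2, child, bins)
        if events is not None:
            candidates.append((count + 1, [wgd] + events))
        # WGD last: interval events reach child/2, then double.
        if np.all(child % 2 == 0):
            count, events = _plain_distance(parent, child // 2, bins)
            if events is not None:
                candidates.append((count + 1, events + [wgd]))
    if not candidates:
        raise ValueError("no valid event path (LOH irreversibility violated)")
    best_count, best_events = min(candidates, key=lambda t: (t[0], len(t[1])))
    interval_events = sorted(
        (e for e in best_events if not e.is_wgd()), key=EventRecord.sort_key
    )
    wgd_events = [e for e in best_events if e.is_wgd()]
    wgd_first = bool(best_events) and best_events[0].is_wgd()
    ordered = (wgd_events + interval_events) if wgd_first else (interval_events + wgd_events)
    ordered = classify_events(ordered, parent, expected_allele_cn=expected_allele_cn)
    return int(best_count), ordered


def classify_events(
    events: list[EventRecord],
    parent: np.ndarray,
    expected_allele_cn: int = 1,
) -> list[EventRecord]:
    """Fill the ``kind`` field of raw events applied to ``parent``.

    A loss whose covered bins all end at copy 0 is an LOH; if the retained
    (other) haplotype simultaneously sits above the expected allele copy
    number over that interval after the edge, the LOH is copy-neutral
    (``cn_loh``). Other losses are deletions, positive events gains, and
    genome-wide doublings ``wgd``. When the edge carries a WGD, the
    classification baseline downstream of it is the doubled one.
    """
    child = apply_events(np.asarray(parent, dtype=np.int64), list(events), check=False)
    baseline = expected_allele_cn * (2 if any(e.is_wgd() for e in events) else 1)
    out = []
    for ev in events:
        if ev.is_wgd():
            out.append(replace(ev, kind="wgd"))
            continue
        h = 0 if ev.haplotype == "A" else 1
        sl = slice(ev.start_bin, ev.end_bin)
        if ev.delta > 0:
            kind = "gain"
        elif np.all(child[sl, h] == 0):
            other = child[sl, 1 - h]
            kind = "cn_loh" if np.all(other > baseline) else "loh"
        else:
            kind = "del"
        out.append(replace(ev, kind=kind))
    return out


# ----------------------------------------------------------------------
# Tree reconstruction
# ----------------------------------------------------------------------

ROOT = "diploid"


@dataclass
class CopyNumberTree:
    """Rooted clone phylogeny under the interval-event model.

    ``nodes`` maps node name to its (n_bins, 2) profile; the root is the
    all-(1,1) diploid. ``edges`` is a list of (parent, child, events,
    count) with events replaying the parent into the child exactly.
    """

    nodes: dict[str, np.ndarray]
    edges: list[tuple[str, str, list[EventRecord], int]]
    total_events: int
    bins: GenomeBins
    root: str = ROOT

    def children(self, node: str) -> list[str]:
        return [c for p, c, _, _ in self.edges if p == node]

    def parent(self, node: str) -> str | None:
        for p, c, _, _ in self.edges:
            if c == node:
                return p
        return None

    def leaves(self) -> list[str]:
        parents = {p for p, _, _, _ in self.edges}
        return [n for n in self.nodes if n not in parents]

    def validate_replay(self) -> None:
        """Assert every edge's events transform parent into child exactly."""
        for p, c, evs, _ in self.edges:
            got = apply_events(self.nodes[p], list(evs), check=False)
            if not np.array_equal(got, self.nodes[c]):
                raise AssertionError(f"edge {p}->{c} does not replay")


def _set_partitions(items: tuple) -> "itertools.Iterator[list[tuple]]":
    """All partitions of ``items`` into unordered non-empty blocks."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [(first,) + part[i]] + part[i + 1:]
        yield [(first,)] + part


def _topo_key(topo) -> str:
    if isinstance(topo, int):
        return f"L{topo:03d}"
    return "(" + ",".join(_topo_key(t) for t in topo) + ")"


def _topologies(leaves: tuple[int, ...]):
    """All rooted multifurcating leaf-labelled topologies over ``leaves``.

    A topology is an int (leaf) or a tuple of >=2 child topologies."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    for part in _set_partitions(leaves):
        if len(part) < 2:
            continue
        child_sets = [list(_topologies(tuple(sorted(b)))) for b in part]
        for combo in itertools.product(*child_sets):
            yield tuple(sorted(combo, key=_topo_key))


_BIG = 10**6


def _distance_transform(cost: np.ndarray) -> np.ndarray:
    """min-plus convolution with the |s - t| kernel along the last axis."""
    out = cost.copy()
    for s in range(1, out.shape[-1]):
        np.minimum(out[..., s], out[..., s - 1] + 1, out=out[..., s])
    for s in range(out.shape[-1] - 2, -1, -1):
        np.minimum(out[..., s], out[..., s + 1] + 1, out=out[..., s])
    return out


def _assign_ancestors(topo, profiles: list[np.ndarray]):
    """Per-bin per-haplotype ancestor states minimising the summed |delta|
    over edges (Sankoff DP with a distance-transform transition), the root
    held at the diploid state.

    Candidate states are restricted to the [min, max] interval of the
    descendant clones' states, with 0 additionally forbidden whenever any
    descendant is positive (a haplotype lost once cannot return). The
    per-bin linear cost is a relaxation of the interval-event count; the
    interval-event distance of each edge is computed afterwards on the
    assigned profiles.

    Returns (top_node_id, structure, values) where ``structure`` maps
    internal node id -> children ids and ``values`` maps internal node id
    -> profile.
    """
    n_bins = profiles[0].shape[0]
    flat = [p.reshape(-1) for p in profiles]  # (n_bins*2,) per clone
    s_max = max(1, max(int(p.max()) for p in profiles))
    states = s_max + 1
    structure: dict[int, list] = {}
    cost: dict[int, np.ndarray] = {}
    lo: dict[int, np.ndarray] = {}
    hi: dict[int, np.ndarray] = {}
    counter = itertools.count(start=len(profiles))

    def build(t) -> int:
        if isinstance(t, int):
            leaf_cost = np.full((len(flat[t]), states), _BIG, dtype=np.int64)
            leaf_cost[np.arange(len(flat[t])), flat[t]] = 0
            cost[t] = leaf_cost
            lo[t] = flat[t]
            hi[t] = flat[t]
            return t
        nid = next(counter)
        kids = [build(c) for c in t]
        total = np.zeros((len(flat[0]), states), dtype=np.int64)
        for k in kids:
            total += _distance_transform(cost[k])
        lo[nid] = np.minimum.reduce([lo[k] for k in kids])
        hi[nid] = np.maximum.reduce([hi[k] for k in kids])
        allowed = (np.arange(states)[None, :] >= lo[nid][:, None]) & (
            np.arange(states)[None, :] <= hi[nid][:, None]
        )
        # irreversibility: an ancestor cannot be 0 above a positive leaf
        allowed[:, 0] &= hi[nid] == 0
        total[~allowed] = _BIG
        cost[nid] = total
        structure[nid] = kids
        return nid

    top = build(topo)
    values: dict[int, np.ndarray] = {}

    def choose(node_cost: np.ndarray, parent_state: np.ndarray) -> np.ndarray:
        grid = np.arange(states)[None, :]
        total = node_cost + np.abs(grid - parent_state[:, None])
        # tie-break: nearest to the parent, then the smaller state
        order = total * (4 * states) + np.abs(grid - parent_state[:, None]) * 2 + (
            grid > parent_state[:, None]
        )
        return np.argmin(order, axis=1)

    def assign(nid: int, parent_state: np.ndarray) -> None:
        state = choose(cost[nid], parent_state)
        values[nid] = state.reshape(n_bins, 2)
        for k in structure.get(nid, []):
            if k >= len(profiles):
                assign(k, state)

    root_state = np.ones(len(flat[0]), dtype=np.int64)
    if isinstance(topo, int):
        return top, structure, values
    assign(top, root_state)
    return top, structure, values


def _count_only(
    parent: np.ndarray, child: np.ndarray, slices, allow_wgd: bool
):
    """Edge event count without building event lists.

    Returns (count, wgd_used) or None when unreachable."""

    def plain(p, c):
        if np.any((p == 0) & (c > 0)):
            return None
        total = 0
        for _, sl in slices:
            d = c[sl] - p[sl]
            for arr in (np.maximum(d, 0), np.maximum(-d, 0)):
                prev = np.concatenate([np.zeros_like(arr[:1]), arr[:-1]])
                total += int(np.maximum(arr - prev, 0).sum())
        return total

    best = None
    base = plain(parent, child)
    if base is not None:
        best = (base, False)
    if allow_wgd:
        first = plain(parent * 2, child)
        if first is not None and (best is None or first + 1 < best[0]):
            best = (first + 1, True)
        if np.all(child % 2 == 0):
            last = plain(parent, child // 2)
            if last is not None and (best is None or last + 1 < best[0]):
                best = (last + 1, True)
    return best


def _tree_cost(top, structure, values, profiles, slices, allow_wgd):
    """Total event count of an assigned topology; None when infeasible.
    At most one WGD per root path, gated top-down."""
    root_profile = np.ones_like(profiles[0])
    total = 0

    def profile_of(nid):
        return values[nid] if nid >= len(profiles) else profiles[nid]

    def walk(nid, parent_profile, wgd_free) -> bool:
        nonlocal total
        res = _count_only(parent_profile, profile_of(nid), slices, wgd_free)
        if res is None:
            return False
        count, used_wgd = res
        total += count
        for k in structure.get(nid, []):
            if not walk(k, profile_of(nid), wgd_free and not used_wgd):
                return False
        return True

    if not walk(top, root_profile, allow_wgd):
        return None
    return total


def _descendant_clones(nid, structure, n_leaves):
    if nid < n_leaves:
        return [nid]
    out = []
    for k in structure[nid]:
        out.extend(_descendant_clones(k, structure, n_leaves))
    return out


def _refine_assignment(top, structure, values, profiles, slices, allow_wgd):
    """Local improvement of the ancestor assignment.

    The per-bin linear-cost assignment can fragment multi-level runs of a
    parent edge; trying each descendant clone's full profile (and the
    parent's) at every internal node repairs the common case where an
    observed clone *is* the ancestral state. Keeps a change only when it
    strictly lowers the interval-event total."""
    if not structure:
        return values
    best_cost = _tree_cost(top, structure, values, profiles, slices, allow_wgd)
    if best_cost is None:
        return values
    parent_of = {}

    def index_parents(nid):
        for k in structure.get(nid, []):
            parent_of[k] = nid
            index_parents(k)

    index_parents(top)
    order = [top] + [n for n in parent_of if n in structure]
    n_leaves = len(profiles)
    for _ in range(4):
        changed = False
        for nid in order:
            parent = parent_of.get(nid)
            candidates = [values[parent]] if parent is not None else []
            candidates += [profiles[c] for c in _descendant_clones(nid, structure, n_leaves)]
            current = values[nid]
            for cand in candidates:
                if np.array_equal(cand, current):
                    continue
                values[nid] = cand
                cost = _tree_cost(top, structure, values, profiles, slices, allow_wgd)
                # accept equal-cost moves too: ancestors that coincide with an
                # observed clone are the preferred representation of a tie
                if cost is not None and cost <= best_cost:
                    if cost < best_cost:
                        changed = True
                    best_cost = cost
                    current = cand
                else:
                    values[nid] = current
        if not changed:
            break
    return values


def _build_edges(top, structure, values, profiles, bins, allow_wgd):
    """Final event lists for an assigned topology (the winner only)."""
    root_profile = diploid_profile(bins)
    edges: list[tuple] = []
    total = 0

    def profile_of(nid):
        return values[nid] if nid >= len(profiles) else profiles[nid]

    def walk(nid, parent_name, parent_profile, wgd_free) -> bool:
        nonlocal total
        try:
            count, evs = interval_event_distance(
                parent_profile, profile_of(nid), bins, allow_wgd=wgd_free
            )
        except ValueError:
            return False
        total += count
        edges.append((parent_name, nid, evs, count))
        still_free = wgd_free and not any(e.is_wgd() for e in evs)
        for k in structure.get(nid, []):
            if not walk(k, nid, profile_of(nid), still_free):
                return False
        return True

    if not walk(top, ROOT, root_profile, allow_wgd):
        return None
    return total, edges


def reconstruct_tree(
    clones,
    bins: GenomeBins,
    allow_wgd: bool = True,
    method: str = "exhaustive",
) -> CopyNumberTree:
    """Reconstruct the rooted copy-number phylogeny of clone profiles.

    Parameters
    ----------
    clones : list of (clone_id, (n_bins, 2) profile) pairs, or a mapping.
    method : "exhaustive" enumerates every rooted multifurcating
        leaf-labelled topology (<= 8 clones) with candidate-set ancestors;
        "greedy" builds a minimum event-count arborescence over the clones
        themselves (no unobserved ancestors), usable at any size.

    Ties between equally parsimonious trees are broken toward fewer
    internal nodes, then lexicographic topology order.
    """
    if hasattr(clones, "items"):
        clones = list(clones.items())
    ids = [cid for cid, _ in clones]
    profiles = [np.asarray(p, dtype=np.int64) for _, p in clones]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate clone ids")
    if not ids:
        raise ValueError("at least one clone required")

    if method == "greedy":
        return _greedy_tree(ids, profiles, bins, allow_wgd)
    if method != "exhaustive":
        raise ValueError(f"unknown method {method!r}")
    if len(ids) > 8:
        raise ValueError(
            "exhaustive search supports at most 8 clones; use method='greedy'"
        )

    slices = bins.chrom_slices()
    scored = []
    for topo in sorted(_topologies(tuple(range(len(ids)))), key=_topo_key):
        top, structure, values = _assign_ancestors(topo, profiles)
        cost = _tree_cost(top, structure, values, profiles, slices, allow_wgd)
        if cost is None:
            continue
        scored.append((cost, len(structure), _topo_key(topo), top, structure, values))
    if not scored:
        raise ValueError("no feasible tree (LOH irreversibility violated)")
    scored.sort(key=lambda t: t[:3])

    best = None
    for cost, n_internal, key, top, structure, values in scored[:12]:
        values = _refine_assignment(top, structure, dict(values), profiles,
                                    slices, allow_wgd)
        refined_cost = _tree_cost(top, structure, values, profiles, slices, allow_wgd)
        cand = (refined_cost, n_internal, key, top, structure, values)
        if best is None or cand[:3] < best[:3]:
            best = cand
    _, _, _, top, structure, values = best
    result = _build_edges(top, structure, values, profiles, bins, allow_wgd)
    if result is None:  # pragma: no cover - cost walk already validated
        raise ValueError("no feasible tree (LOH irreversibility violated)")
    _, edges = result
    return _finalize_tree(ids, profiles, values, edges, bins)


def _finalize_tree(ids, profiles, internal_values, raw_edges, bins) -> CopyNumberTree:
    """Contract zero-event internal edges and name nodes deterministically."""
    n = len(ids)
    children: dict = {}
    for parent, child, evs, count in raw_edges:
        children.setdefault(parent, []).append((child, evs, count))

    # Contract internal->internal edges with zero events (identical profiles).
    def resolve(node):
        out = []
        for child, evs, count in children.get(node, []):
            if child >= n and count == 0:
                out.extend(resolve(child))
            else:
                out.append((child, evs, count))
        return out

    names: dict = {ROOT: ROOT}
    nodes: dict[str, np.ndarray] = {ROOT: diploid_profile(bins)}
    edges: list[tuple[str, str, list[EventRecord], int]] = []
    anc_counter = itertools.count(1)

    def emit(node, name):
        for child, evs, count in resolve(node):
            if child < n:
                cname = ids[child]
                cprofile = profiles[child]
            else:
                cname = f"anc_{next(anc_counter)}"
                cprofile = internal_values[child]
            names[child] = cname
            nodes[cname] = cprofile
            edges.append((name, cname, evs, count))
            emit(child, cname)

    # resolve() also contracts a top ancestor identical to the diploid root.
    emit(ROOT, ROOT)

    total = sum(count for _, _, _, count in edges)
    tree = CopyNumberTree(nodes=nodes, edges=edges, total_events=total, bins=bins)
    tree.validate_replay()
    return tree


def _greedy_tree(ids, profiles, bins, allow_wgd) -> CopyNumberTree:
    """Minimum event-count arborescence over {diploid root} + clones."""
    g = nx.DiGraph()
    all_nodes = [(ROOT, diploid_profile(bins))] + list(zip(ids, profiles))
    for (ni, pi), (nj, pj) in itertools.permutations(all_nodes, 2):
        if nj == ROOT:
            continue
        try:
            count, _ = interval_event_distance(pi, pj, bins, allow_wgd=allow_wgd)
        except ValueError:
            continue
        g.add_edge(ni, nj, weight=count)
    arb = nx.algorithms.tree.branchings.minimum_spanning_arborescence(g, preserve_attrs=True)
    node_map = dict(all_nodes)
    edges = []
    total = 0
    for p, c in sorted(arb.edges()):
        count, evs = interval_event_distance(
            node_map[p], node_map[c], bins, allow_wgd=allow_wgd
        )
        edges.append((p, c, evs, count))
        total += count
    tree = CopyNumberTree(nodes=dict(all_nodes), edges=edges, total_events=total, bins=bins)
    tree.validate_replay()
    return tree


def clone_ancestor_map(tree: CopyNumberTree, clone_ids: list[str]) -> dict[str, str]:
    """For each clone, the nearest ancestral node carrying another clone's
    profile (or the diploid root). Lets a reconstructed tree with unobserved
    ancestors be compared against a generating clone tree."""
    profile_of = {cid: tree.nodes[cid] for cid in clone_ids}
    out = {}
    for cid in clone_ids:
        node = tree.parent(cid)
        while node is not None and node != tree.root:
            match = [
                other for other in clone_ids
                if other != cid and np.array_equal(tree.nodes[node], profile_of[other])
            ]
            if match:
                out[cid] = sorted(match)[0]
                break
            node = tree.parent(node)
        else:
            out[cid] = tree.root
    return out
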