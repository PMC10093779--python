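"""Independent breadth-first-search oracle for the interval-event distance.

States are per-bin copy-number vectors on a single chromosome; one step
applies a +/-1 event over a contiguous interval, subject to
non-negativity, LOH irreversibility (no gain over a bin at 0) and a copy
cap. Deliberately brute force: shortest paths here are the reference the
analytic distance is checked against.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path


def enumerate_states(n_bins: int, max_cn: int) -> np.ndarray:
    """All copy-number vectors on ``n_bins`` bins with entries 0..max_cn."""
    return np.array(list(itertools.product(range(max_cn + 1), repeat=n_bins)),
                    dtype=np.int64)


def legal_moves(state: tuple, max_cn: int):
    """All states reachable by one legal interval event."""
    n = len(state)
    for i in range(n):
        for j in range(i + 1, n + 1):
            seg = state[i:j]
            if all(v >= 1 for v in seg) and all(v < max_cn for v in seg):
                yield state[:i] + tuple(v + 1 for v in seg) + state[j:]
            if all(v >= 1 for v in seg):
                yield state[:i] + tuple(v - 1 for v in seg) + state[j:]


def all_pairs_bfs(n_bins: int, max_cn: int) -> tuple[np.ndarray, np.ndarray]:
    """(states, dist) with dist[i, j] the BFS shortest path, inf if none."""
    states = enumerate_states(n_bins, max_cn)
    index = {tuple(s): k for k, s in enumerate(map(tuple, states))}
    rows, cols = [], []
    for k, s in enumerate(map(tuple, states)):
        for t in legal_moves(s, max_cn):
            rows.append(k)
            cols.append(index[t])
    n = len(states)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="D", directed=True, unweighted=True)
    return states, dist


def bfs_distance_at_most(parent: tuple, child: tuple, limit: int, max_cn: int):
    """Bidirectional BFS: shortest path length if <= limit, else None."""
    if parent == child:
        return 0
    if limit <= 0:
        return None

    def predecessors(state: tuple):
        n = len(state)
        for i in range(n):
            for j in range(i + 1, n + 1):
                seg = state[i:j]
                # undo a gain: predecessor had seg - 1 (all >= 1 pre-gain)
                if all(v >= 2 for v in seg):
                    yield state[:i] + tuple(v - 1 for v in seg) + state[j:]
                # undo a deletion: predecessor had seg + 1 (cap respected)
                if all(v < max_cn for v in seg):
                    yield state[:i] + tuple(v + 1 for v in seg) + state[j:]

    fwd = {parent: 0}
    bwd = {child: 0}
    fwd_frontier, bwd_frontier = {parent}, {child}
    for depth in range(1, limit + 1):
        # expand the smaller frontier
        if len(fwd_frontier) <= len(bwd_frontier):
            nxt = set()
            for s in fwd_frontier:
                for t in legal_moves(s, max_cn):
                    if t not in fwd:
                        fwd[t] = fwd[s] + 1
                        nxt.add(t)
            fwd_frontier = nxt
        else:
            nxt = set()
            for s in bwd_frontier:
                for t in predecessors(s):
                    if t not in bwd:
                        bwd[t] = bwd[s] + 1
                        nxt.add(t)
            bwd_frontier = nxt
        meet = [fwd[s] + bwd[s] for s in (set(fwd) & set(bwd))]
        if meet:
            best = min(meet)
            if best <= limit:
                return best
    return None


def joint_bfs_distance(parent: np.ndarray, child: np.ndarray, max_cn: int,
                       cap_states: int = 2_000_000):
    """BFS over joint (haplotype A, haplotype B) states; events act on one
    haplotype at a time. ``parent``/``child`` are (n_bins, 2) arrays."""
    start = (tuple(parent[:, 0]), tuple(parent[:, 1]))
    goal = (tuple(child[:, 0]), tuple(child[:, 1]))
    if start == goal:
        return 0
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        (a, b), d = queue.popleft()
        for na in legal_moves(a, max_cn):
            s = (na, b)
            if s == goal:
                return d + 1
            if s not in seen:
                seen.add(s)
                queue.append((s, d + 1))
        for nb in legal_moves(b, max_cn):
            s = (a, nb)
            if s == goal:
                return d + 1
            if s not in seen:
                seen.add(s)
                queue.append((s, d + 1))
        if len(seen) > cap_states:
            raise RuntimeError("joint BFS state space exceeded the cap")
    return None


def random_reachable_pair(rng: np.random.Generator, n_bins: int, max_cn: int,
                          max_events: int):
    """A random parent vector and a child derived by <= max_events legal
    events (the child may be nearer than the event count: events can merge)."""
    parent = tuple(int(v) for v in rng.integers(0, max_cn + 1, size=n_bins))
    child = parent
    k = int(rng.integers(0, max_events + 1))
    for _ in range(k):
        moves = list(legal_moves(child, max_cn))
        if not moves:
            break
        child = moves[int(rng.integers(len(moves)))]
    return parent, child, k
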