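"""Weighted network measures for connectome analysis.

Implements the six global measures (modularity, global efficiency,
clustering coefficient, mean strength, assortativity, density) and the
two nodal measures (nodal strength, local efficiency) in their standard
weighted formulations for undirected networks:

* path lengths use the inverse-weight transform ``l = 1/w``; disconnected
  pairs contribute zero efficiency;
* clustering is the Onnela geometric-mean-of-triangles variant with
  max-weight normalisation;
* local efficiency is the weighted neighbourhood-subgraph efficiency with
  cube-root neighbour-weight correction;
* assortativity is the Pearson correlation of endpoint strengths over
  edges (both orientations);
* modularity is Newman's weighted Q, optimised by a seeded Louvain scheme
  with a single-node refinement pass, or exactly by vectorised set-
  partition enumeration on small networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from ._rng import substream
from .errors import ParameterError, UndefinedMetricError

__all__ = [
    "MetricPanel", "density", "nodal_strength", "mean_strength",
    "global_efficiency", "local_efficiency", "clustering_coefficient",
    "modularity", "modularity_exact", "assortativity", "metric_panel",
    "GLOBAL_METRICS",
]

#: the six global measures, in reporting order
GLOBAL_METRICS = ["modularity", "global_efficiency", "clustering_coefficient",
                  "mean_strength", "assortativity", "density"]

#: largest network for which exact modularity enumeration is allowed
EXACT_MODULARITY_MAX_NODES = 12


def _as_matrix(C) -> np.ndarray:
    m = np.asarray(getattr(C, "matrix", C), dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ParameterError("expected a square connectivity matrix")
    return m


def density(C) -> float:
    """Fraction of present connections out of n(n-1)/2 possible."""
    m = _as_matrix(C)
    n = m.shape[0]
    if n < 2:
        raise UndefinedMetricError("density needs at least 2 nodes")
    present = np.count_nonzero(np.triu(m, 1))
    return present / (n * (n - 1) / 2)


def nodal_strength(C) -> np.ndarray:
    """Sum of the weights of links connected to each node."""
    return _as_matrix(C).sum(axis=1)


def mean_strength(C) -> float:
    """Average nodal strength."""
    return float(nodal_strength(C).mean())


def _pairwise_distances(m: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight."""
    n = m.shape[0]
    if n == 0:
        return np.empty((0, 0))
    iu, ju = np.nonzero(np.triu(m, 1))
    lengths = 1.0 / m[iu, ju]
    graph = csr_matrix((lengths, (iu, ju)), shape=(n, n))
    return dijkstra(graph, directed=False)


def global_efficiency(C) -> float:
    """Average inverse shortest-path length over ordered node pairs;
    disconnected pairs contribute zero (1/inf = 0)."""
    m = _as_matrix(C)
    n = m.shape[0]
    if n < 2:
        raise UndefinedMetricError("global efficiency needs at least 2 nodes")
    d = _pairwise_distances(m)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(C, node: int | None = None):
    """Weighted local efficiency.

    For node u with neighbours N(u): the efficiency of the subgraph
    induced by N(u), each term weighted by the cube root of the product
    of u's connections to the pair,
    ``E_loc(u) = sum_{j != h in N(u)} (w_uj w_uh d_jh^-1(N_u))^(1/3)
    / (k_u (k_u - 1))``, with distances computed inside the neighbourhood
    subgraph on lengths 1/w.  Nodes with fewer than 2 neighbours score 0.
    Returns the full vector when ``node`` is None.
    """
    m = _as_matrix(C)
    n = m.shape[0]

    def one(u: int) -> float:
        nb = np.flatnonzero(m[u] > 0)
        k = nb.size
        if k < 2:
            return 0.0
        sub = m[np.ix_(nb, nb)]
        d = _pairwise_distances(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        np.fill_diagonal(inv, 0.0)
        inv[~np.isfinite(inv)] = 0.0
        wu = m[u, nb]
        terms = np.cbrt(np.outer(wu, wu) * inv)
        np.fill_diagonal(terms, 0.0)
        return float(terms.sum() / (k * (k - 1)))

    if node is not None:
        return one(int(node))
    return np.array([one(u) for u in range(n)])


def clustering_coefficient(C, per_node: bool = False):
    """Onnela weighted clustering: geometric mean of triangle weights
    after max-weight normalisation, averaged over nodes; degree < 2
    contributes 0."""
    m = _as_matrix(C)
    n = m.shape[0]
    mx = m.max(initial=0.0)
    if mx == 0:
        values = np.zeros(n)
    else:
        w = np.cbrt(m / mx)
        tri = w @ w @ w
        deg = (m > 0).sum(axis=1)
        denom = deg * (deg - 1)
        values = np.where(denom > 0, np.diag(tri) / np.where(denom > 0, denom, 1),
                          0.0)
    if per_node:
        return values
    return float(values.mean())


# ---------------------------------------------------------------------------
# modularity


def _modularity_q(m: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    two_m = m.sum()
    if two_m == 0:
        raise UndefinedMetricError("modularity undefined for empty network")
    s = m.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        e_c = m[np.ix_(idx, idx)].sum() / two_m
        a_c = s[idx].sum() / two_m
        q += e_c - gamma * a_c**2
    return float(q)


def _louvain_one_level(m: np.ndarray, gamma: float,
                       order: np.ndarray) -> np.ndarray:
    """Greedy node moves until no single move improves Q."""
    n = m.shape[0]
    labels = np.arange(n)
    two_m = m.sum()
    s = m.sum(axis=1)
    comm_s = s.astype(float).copy()  # total strength per community
    improved = True
    while improved:
        improved = False
        for u in order:
            cu = labels[u]
            row = m[u].copy()
            row[u] = 0.0  # self-loops move with the node and cancel in dQ
            w_to = np.zeros(n)
            np.add.at(w_to, labels, row)
            comm_s[cu] -= s[u]
            # dQ(u: cu -> c) = 2(w_uc - w_u,cu)/2m - 2 gamma s_u (S_c - S_cu)/(2m)^2
            gains = 2.0 * (w_to - w_to[cu]) / two_m \
                - 2.0 * gamma * s[u] * (comm_s - comm_s[cu]) / two_m**2
            gains[cu] = 0.0
            best = int(np.argmax(gains))
            if gains[best] > 1e-12:
                labels[u] = best
                improved = True
            comm_s[labels[u]] += s[u]
    return labels


def _aggregate(m: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inv = np.unique(labels, return_inverse=True)
    B = (inv[:, None] == np.arange(uniq.size)[None, :]).astype(float)
    return B.T @ m @ B, inv


def _spectral_labels(m: np.ndarray, gamma: float) -> np.ndarray:
    """Newman leading-eigenvector partition by recursive bisection of the
    (generalized) modularity matrix; deterministic candidate start."""
    two_m = m.sum()
    s = m.sum(axis=1)
    B = m - gamma * np.outer(s, s) / two_m
    labels = np.zeros(m.shape[0], dtype=int)
    next_id = [1]

    def split(idx: np.ndarray) -> None:
        if idx.size < 2:
            return
        Bg = B[np.ix_(idx, idx)]
        Bg = Bg - np.diag(Bg.sum(axis=1))
        vals, vecs = np.linalg.eigh(Bg)
        if vals[-1] <= 1e-12:
            return
        sv = vecs[:, -1] >= 0
        if sv.all() or (~sv).all():
            return
        sign = sv.astype(float) * 2 - 1
        if sign @ Bg @ sign <= 1e-12:  # split does not raise Q
            return
        labels[idx[~sv]] = next_id[0]
        next_id[0] += 1
        split(idx[sv])
        split(idx[~sv])

    split(np.arange(m.shape[0]))
    return labels


def modularity(C, gamma: float = 1.0, seed: int = 0,
               n_runs: int = 1) -> tuple[float, np.ndarray]:
    """Louvain-optimised weighted Newman modularity.

    Each run uses a seeded node-visiting order with multi-level
    aggregation, then a refinement stage (single-node moves, community
    merges and a Kernighan–Lin escape pass) on the original network; a
    deterministic spectral-bisection candidate partition is refined the
    same way and the best Q wins.  ``n_runs`` restarts the Louvain phase
    with distinct sub-seeds.  Returns (Q, community labels).
    """
    m = _as_matrix(C)
    np.fill_diagonal(m := m.copy(), 0.0)
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    if m.sum() == 0:
        raise UndefinedMetricError("modularity undefined for empty network")
    n = m.shape[0]
    spec_labels = _refine(m, _spectral_labels(m, gamma), gamma)
    best_q, best_labels = _modularity_q(m, spec_labels, gamma), spec_labels
    for run in range(max(1, n_runs)):
        rng = substream(seed, f"louvain-{run}")
        labels = np.arange(n)
        work = m
        mapping = np.arange(n)
        while True:
            order = rng.permutation(work.shape[0])
            lab = _louvain_one_level(work, gamma, order)
            if np.unique(lab).size == work.shape[0]:
                break
            work, inv = _aggregate(work, lab)
            mapping = inv[mapping]
            if work.shape[0] == 1:
                break
        labels = mapping
        # refinement: single-node moves on the original graph
        labels = _refine(m, labels, gamma)
        q = _modularity_q(m, labels, gamma)
        if q > best_q:
            best_q, best_labels = q, labels
    _, relabel = np.unique(best_labels, return_inverse=True)
    return best_q, relabel


def _merge_pass(m: np.ndarray, labels: np.ndarray, gamma: float,
                two_m: float, s: np.ndarray) -> bool:
    """Greedy community merges; returns True if any merge improved Q."""
    improved = False
    while True:
        comms = np.unique(labels)
        if comms.size < 2:
            return improved
        best_gain, best_pair = 0.0, None
        for a_i in range(comms.size):
            for b_i in range(a_i + 1, comms.size):
                ia = labels == comms[a_i]
                ib = labels == comms[b_i]
                between = m[np.ix_(ia, ib)].sum()
                gain = 2.0 * between / two_m \
                    - 2.0 * gamma * s[ia].sum() * s[ib].sum() / two_m**2
                if gain > best_gain + 1e-12:
                    best_gain, best_pair = gain, (comms[a_i], comms[b_i])
        if best_pair is None:
            return improved
        labels[labels == best_pair[1]] = best_pair[0]
        improved = True


def _move_gain(m: np.ndarray, labels: np.ndarray, gamma: float,
               two_m: float, s: np.ndarray, u: int, c: int) -> float:
    """dQ of moving node u into community c."""
    cu = labels[u]
    if cu == c:
        return 0.0
    in_cu = labels == cu
    in_c = labels == c
    w_to_c = m[u, in_c].sum()
    w_to_cu = m[u, in_cu].sum()  # m[u,u] = 0
    s_cu = s[in_cu].sum() - s[u]
    s_c = s[in_c].sum()
    return 2.0 * (w_to_c - w_to_cu) / two_m \
        - 2.0 * gamma * s[u] * (s_c - s_cu) / two_m**2


def _kl_pass(m: np.ndarray, labels: np.ndarray, gamma: float,
             two_m: float, s: np.ndarray) -> bool:
    """Kernighan–Lin-style escape pass: apply the best single-node move
    (worsening moves allowed), freeze the moved node, and keep the best
    configuration visited along the sequence."""
    n = m.shape[0]
    cur = labels.copy()
    best = labels.copy()
    q_cur = _modularity_q(m, cur, gamma)
    q_best = q_cur
    frozen = np.zeros(n, dtype=bool)
    for _ in range(n):
        move, move_gain = None, -np.inf
        comms = list(np.unique(cur))
        free = [c for c in range(n) if c not in comms]
        if free:
            comms.append(free[0])
        for u in range(n):
            if frozen[u]:
                continue
            for c in comms:
                if c == cur[u]:
                    continue
                g = _move_gain(m, cur, gamma, two_m, s, u, c)
                if g > move_gain:
                    move_gain, move = g, (u, c)
        if move is None:
            break
        u, c = move
        cur[u] = c
        frozen[u] = True
        q_cur += move_gain
        if q_cur > q_best + 1e-12:
            q_best = q_cur
            best = cur.copy()
    if q_best > _modularity_q(m, labels, gamma) + 1e-12:
        labels[:] = best
        return True
    return False


def _refine(m: np.ndarray, labels: np.ndarray, gamma: float) -> np.ndarray:
    labels = labels.copy()
    two_m = m.sum()
    s = m.sum(axis=1)
    n = m.shape[0]
    improved = True
    while improved:
        improved = _merge_pass(m, labels, gamma, two_m, s)
        if n <= 32:
            improved |= _kl_pass(m, labels, gamma, two_m, s)
        for u in range(n):
            comm_s = np.zeros(n)
            np.add.at(comm_s, labels, s)
            w_to = np.zeros(n)
            np.add.at(w_to, labels, m[u])
            cu = labels[u]
            comm_s[cu] -= s[u]
            gains = 2.0 * (w_to - w_to[cu]) / two_m \
                - 2.0 * gamma * s[u] * (comm_s - comm_s[cu]) / two_m**2
            gains[cu] = 0.0
            # also consider moving u to an empty community (split off)
            empty = np.setdiff1d(np.arange(n), np.unique(labels))
            if empty.size:
                gains[empty[0]] = 2.0 * (0.0 - w_to[cu]) / two_m \
                    - 2.0 * gamma * s[u] * (0.0 - comm_s[cu]) / two_m**2
            best = int(np.argmax(gains))
            if gains[best] > 1e-12:
                labels[u] = best
                improved = True
    return labels


def _partition_labels(n: int) -> np.ndarray:
    """All set partitions of n items as restricted-growth label arrays."""
    out = []
    labels = np.zeros(n, dtype=np.int8)

    def rec(i: int, k: int) -> None:
        if i == n:
            out.append(labels.copy())
            return
        for c in range(k + 1):
            labels[i] = c
            rec(i + 1, max(k, c + 1))

    rec(1, 1)  # item 0 fixed in community 0
    return np.array(out) if out else np.zeros((1, n), dtype=np.int8)


def modularity_exact(C, gamma: float = 1.0) -> tuple[float, np.ndarray]:
    """Globally optimal weighted modularity by exhaustive set-partition
    enumeration (vectorised); limited to small networks."""
    m = _as_matrix(C)
    np.fill_diagonal(m := m.copy(), 0.0)
    n = m.shape[0]
    if n > EXACT_MODULARITY_MAX_NODES:
        raise ParameterError(
            f"exact enumeration limited to n <= {EXACT_MODULARITY_MAX_NODES}")
    two_m = m.sum()
    if two_m == 0:
        raise UndefinedMetricError("modularity undefined for empty network")
    s = m.sum(axis=1)
    parts = _partition_labels(n)
    best_q, best_labels = -np.inf, parts[0]
    chunk = 20000
    for lo in range(0, parts.shape[0], chunk):
        P = parts[lo:lo + chunk]
        B = (P[:, :, None] == np.arange(n)[None, None, :]).astype(float)
        within = np.einsum("pic,pjc,ij->p", B, B, m) / two_m
        a = np.einsum("pic,i->pc", B, s) / two_m
        q = within - gamma * (a**2).sum(axis=1)
        k = int(np.argmax(q))
        if q[k] > best_q:
            best_q = float(q[k])
            best_labels = P[k]
    return best_q, best_labels.astype(int)


def assortativity(C) -> float:
    """Weighted assortativity: Pearson correlation of the strengths of
    connected node pairs over edges (both orientations).  Returns NaN
    when the endpoint-strength variance is zero (undefined)."""
    m = _as_matrix(C)
    iu, ju = np.nonzero(np.triu(m, 1))
    if iu.size < 2:
        raise UndefinedMetricError("assortativity needs at least 2 edges")
    s = m.sum(axis=1)
    x = np.concatenate([s[iu], s[ju]])
    y = np.concatenate([s[ju], s[iu]])
    vx = x.std()
    if vx == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class MetricPanel:
    """The full per-subject panel: six global + two nodal measures."""

    modularity: float
    global_efficiency: float
    clustering_coefficient: float
    mean_strength: float
    assortativity: float
    density: float
    nodal_strength: np.ndarray
    local_efficiency: np.ndarray

    def to_row(self, node_labels: list[str] | None = None) -> dict:
        """Flatten to one dict row (for CSV/DataFrame export)."""
        out = {k: getattr(self, k) for k in GLOBAL_METRICS}
        n = self.nodal_strength.size
        names = node_labels or [f"node{i+1}" for i in range(n)]
        for name, v in zip(names, self.nodal_strength):
            out[f"strength [{name}]"] = v
        for name, v in zip(names, self.local_efficiency):
            out[f"local_efficiency [{name}]"] = v
        return out


def metric_panel(C, gamma: float = 1.0, seed: int = 0,
                 modularity_runs: int = 10) -> MetricPanel:
    """Compute the whole panel on one connectome.

    Modularity runs ``modularity_runs`` seeded Louvain restarts and keeps
    the best Q (the pipeline default).  An all-zero matrix yields
    modularity NaN rather than an error so cohort tables stay rectangular.
    """
    m = _as_matrix(C)
    try:
        q, _ = modularity(m, gamma=gamma, seed=seed, n_runs=modularity_runs)
    except UndefinedMetricError:
        q = float("nan")
    try:
        r = assortativity(m)
    except UndefinedMetricError:
        r = float("nan")
    return MetricPanel(
        modularity=q,
        global_efficiency=global_efficiency(m),
        clustering_coefficient=clustering_coefficient(m),
        mean_strength=mean_strength(m),
        assortativity=r,
        density=density(m),
        nodal_strength=nodal_strength(m),
        local_efficiency=local_efficiency(m),
    )
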