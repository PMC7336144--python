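"""Sensory-motor parcellation, connectome construction and thresholding.

The node scheme is the 14-node bilateral sensory-motor network (SMN):
seven regions {S-M1, M2, S2, AS Sens C, PFC, Deep GM, Cerebellum} per
hemisphere, each defined as a union of Desikan–Killiany regions.  Two
connectome kinds are built on the same streamline-to-node assignments:

* raw     — entry (i, j) counts the streamlines of bundle (i, j);
* commit  — entry (i, j) is the bundle's total intra-axonal signal
  fraction, ``a_ij = sum_k x_k l_k / (mean bundle length)``: the
  length-weighted sum of fitted streamline contributions divided by the
  bundle's mean streamline length.

Proportional (per-subject, rank the nonzero edges) and consistency
(group-level, rank all possible edges by inverse coefficient of
variation) thresholding are provided for the supplementary comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import (ContractError, DegenerateInputError, ParameterError)
from .phantom import Phantom, Tractogram

__all__ = [
    "NodeParcellation", "Connectome", "smn_parcellation_spec",
    "assign_endpoints", "build_raw_connectome", "build_commit_connectome",
    "proportional_threshold", "consistency_threshold",
    "random_group_connectomes", "degrade_connectome",
]

_SMN_REGIONS = [
    ("S-M1", ["postcentral", "precentral"]),
    ("M2", ["paracentral"]),
    ("S2", ["supramarginal"]),
    ("AS Sens C", ["precuneus", "superior parietal"]),
    ("PFC", ["lateral orbitofrontal", "medial orbitofrontal",
             "rostral middle frontal", "superior frontal"]),
    ("Deep GM", ["thalamus", "caudate", "putamen", "pallidum"]),
    ("Cerebellum", ["cerebellum"]),
]


@dataclass
class NodeParcellation:
    """Node table plus optional voxel label volume.

    ``table`` columns: node_id (1-based in the label volume, row order
    fixes matrix order), name, hemisphere, regions.
    """

    table: pd.DataFrame
    label_volume: np.ndarray | None = None

    def __post_init__(self) -> None:
        names = self.table["name"] + " " + self.table["hemisphere"]
        if names.duplicated().any():
            raise ParameterError("node names must be unique")
        if not set(self.table["hemisphere"]) <= {"L", "R"}:
            raise ParameterError("hemisphere must be L or R")

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    @property
    def node_labels(self) -> list[str]:
        return list(self.table["name"] + " " + self.table["hemisphere"])


def smn_parcellation_spec(label_volume: np.ndarray | None = None
                          ) -> NodeParcellation:
    """The static 14-node SMN table (7 bilateral regions with their
    Desikan–Killiany constituents)."""
    rows = []
    node_id = 1
    for name, regions in _SMN_REGIONS:
        for hemi in ("L", "R"):
            rows.append({"node_id": node_id, "name": name,
                         "hemisphere": hemi, "regions": list(regions)})
            node_id += 1
    return NodeParcellation(pd.DataFrame(rows), label_volume)


@dataclass
class Connectome:
    """Symmetric nonnegative node x node matrix with zero diagonal."""

    matrix: np.ndarray
    kind: str  # raw | commit | thresholded
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ContractError("connectome matrix must be square")
        if np.max(np.abs(m - m.T), initial=0.0) > 1e-12:
            raise ContractError("connectome matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ContractError("connectome diagonal must be zero")
        if np.any(m < 0):
            raise ContractError("connectome weights must be nonnegative")
        if self.kind not in ("raw", "commit", "thresholded"):
            raise ParameterError(f"unknown connectome kind {self.kind!r}")
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.matrix, 1)))

    def binary_density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)


def assign_endpoints(tractogram: Tractogram,
                     parcellation: NodeParcellation,
                     voxel_size: tuple[float, float, float] | None = None
                     ) -> np.ndarray:
    """Per-streamline unordered node pair, or (-1, -1) when unassigned.

    With a label volume present the assignment is geometric: each endpoint
    maps to the label of its containing voxel (background 0 -> unassigned).
    Otherwise the tractogram's own endpoint metadata is used.  Streamlines
    whose endpoints fall in the same node are self-connections and are
    excluded (marked unassigned).
    """
    n = len(tractogram)
    out = np.full((n, 2), -1, dtype=int)
    if parcellation.label_volume is not None:
        if voxel_size is None:
            raise ContractError("voxel_size required for geometric assignment")
        labels = parcellation.label_volume
        vsize = np.asarray(voxel_size, dtype=float)
        dims = np.asarray(labels.shape)
        for k, s in enumerate(tractogram.streamlines):
            pair = []
            for point in (s[0], s[-1]):
                idx = np.floor(np.asarray(point) / vsize).astype(int)
                if np.any(idx < 0) or np.any(idx >= dims):
                    pair.append(0)
                else:
                    pair.append(int(labels[tuple(idx)]))
            i, j = pair
            if i > 0 and j > 0 and i != j:
                out[k] = sorted((i, j))
    else:
        for k, pair in enumerate(tractogram.endpoint_nodes):
            if pair is None:
                continue
            i, j = pair
            if i != j:
                out[k] = sorted((int(i), int(j)))
    return out


def _empty_matrix(n_nodes: int) -> np.ndarray:
    return np.zeros((n_nodes, n_nodes))


def build_raw_connectome(assignments: np.ndarray, n_nodes: int,
                         node_labels: list[str] | None = None) -> Connectome:
    """Streamline-count connectome: entry (i, j) = bundle streamline
    count; unassigned streamlines are ignored."""
    m = _empty_matrix(n_nodes)
    for i, j in np.asarray(assignments, dtype=int):
        if i < 1 or j < 1:
            continue
        m[i - 1, j - 1] += 1
        m[j - 1, i - 1] += 1
    return Connectome(m, "raw", node_labels)


def build_commit_connectome(assignments: np.ndarray, weights: np.ndarray,
                            lengths: np.ndarray, n_nodes: int,
                            node_labels: list[str] | None = None
                            ) -> Connectome:
    """Microstructure-weighted connectome.

    ``a_ij = (sum_k x_k l_k) / ((sum_k l_k) / N_ij)``: total length-
    weighted streamline contribution of the bundle divided by its mean
    streamline length.  Bundles whose every streamline was filtered out
    do not appear (their entry stays 0).
    """
    assignments = np.asarray(assignments, dtype=int)
    weights = np.asarray(weights, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if not (len(assignments) == weights.size == lengths.size):
        raise ContractError("assignments, weights and lengths misaligned")
    m = _empty_matrix(n_nodes)
    num = {}
    den = {}
    cnt = {}
    for (i, j), x, l in zip(assignments, weights, lengths):
        if i < 1 or j < 1:
            continue
        key = (int(i), int(j))
        num[key] = num.get(key, 0.0) + x * l
        den[key] = den.get(key, 0.0) + l
        cnt[key] = cnt.get(key, 0) + 1
    for key in num:
        mean_len = den[key] / cnt[key]
        if mean_len <= 0:
            raise DegenerateInputError(f"bundle {key} has zero mean length")
        a = num[key] / mean_len
        i, j = key
        m[i - 1, j - 1] = a
        m[j - 1, i - 1] = a
    return Connectome(m, "commit", node_labels)


def proportional_threshold(connectome: Connectome,
                           proportion: float) -> Connectome:
    """Keep the ``ceil(proportion * E)`` largest of the E nonzero edges,
    zeroing the rest; ties broken by stable edge-index order."""
    if not (0 < proportion <= 1):
        raise ParameterError("proportion must be in (0, 1]")
    m = connectome.matrix
    n = connectome.n_nodes
    iu, ju = np.triu_indices(n, 1)
    w = m[iu, ju]
    nz = np.flatnonzero(w > 0)
    keep_k = math.ceil(proportion * nz.size)
    # stable sort descending by weight, ascending by edge index on ties
    order = nz[np.argsort(-w[nz], kind="stable")]
    kept = order[:keep_k]
    out = _empty_matrix(n)
    out[iu[kept], ju[kept]] = w[kept]
    out[ju[kept], iu[kept]] = w[kept]
    return Connectome(out, "thresholded", connectome.node_labels)


def consistency_threshold(connectomes: list[Connectome],
                          target_density: float) -> list[Connectome]:
    """Group-level consistency thresholding.

    Candidate edges (all P = n(n-1)/2 possible pairs) are ranked by
    consistency across subjects — the inverse coefficient of variation of
    their weights; edges absent in any subject rank last, mean weight
    breaks ties.  The top ``ceil(target_density * P)`` edges form one
    group mask applied to every subject, imposing a common binary density.
    """
    if len(connectomes) < 2:
        raise ContractError("need at least two subjects")
    if not (0 < target_density <= 1):
        raise ParameterError("target_density must be in (0, 1]")
    n = connectomes[0].n_nodes
    for c in connectomes:
        if c.n_nodes != n:
            raise ContractError("mismatched node sets")
    iu, ju = np.triu_indices(n, 1)
    W = np.stack([c.matrix[iu, ju] for c in connectomes])  # subjects x edges
    present_all = np.all(W > 0, axis=0)
    mean_w = W.mean(axis=0)
    sd_w = W.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_cv = np.where(sd_w > 0, mean_w / sd_w, np.inf)
    inv_cv = np.where(present_all, inv_cv, -np.inf)  # absent-anywhere last
    P = iu.size
    keep_k = math.ceil(target_density * P)
    # lexicographic rank: consistency desc, mean weight desc, index asc
    order = np.lexsort((np.arange(P), -mean_w, -inv_cv))
    mask_idx = order[:keep_k]
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[mask_idx], ju[mask_idx]] = True
    mask |= mask.T
    return [Connectome(np.where(mask, c.matrix, 0.0), "thresholded",
                       c.node_labels) for c in connectomes]


# ---------------------------------------------------------------------------
# synthetic cohort connectomes (shared template + subject variation)


def random_group_connectomes(n_subjects: int, n_nodes: int = 14,
                             template_density: float = 0.5,
                             dropout: float = 0.02, addition: float = 0.02,
                             weight_sigma: float = 0.3,
                             seed: int = 0,
                             kind: str = "commit") -> list[Connectome]:
    """Cohort of weighted connectomes sharing a common backbone.

    A group template support of the given density gets lognormal template
    weights; each subject multiplies them by lognormal noise
    (``weight_sigma`` on the log scale), drops template edges with
    probability ``dropout`` and adds off-template edges with probability
    ``addition`` — emulating the shared topology plus individual
    variability of real cohorts.
    """
    rng = substream(seed, "group-connectomes")
    iu, ju = np.triu_indices(n_nodes, 1)
    P = iu.size
    k = max(1, round(template_density * P))
    support = rng.choice(P, size=k, replace=False)
    template = np.zeros(P)
    template[support] = rng.lognormal(mean=0.0, sigma=0.5, size=k)
    out = []
    for _ in range(n_subjects):
        w = template * rng.lognormal(0.0, weight_sigma, size=P)
        drop = (rng.random(P) < dropout)
        w[drop] = 0.0
        add = (template == 0) & (rng.random(P) < addition)
        w[add] = rng.lognormal(-1.0, 0.5, size=int(add.sum()))[: int(add.sum())]
        m = np.zeros((n_nodes, n_nodes))
        m[iu, ju] = w
        m += m.T
        out.append(Connectome(m, kind))
    return out


def degrade_connectome(connectome: Connectome, scale_fraction: float = 0.3,
                       scale_factor: float = 0.5,
                       delete_fraction: float = 0.15,
                       seed: int = 0) -> Connectome:
    """Lesion-style degradation: scale a random fraction of edge weights
    down and delete a random edge subset — the qualitative fingerprint of
    fibre damage and loss."""
    rng = substream(seed, "degrade")
    m = connectome.matrix.copy()
    n = connectome.n_nodes
    iu, ju = np.triu_indices(n, 1)
    nz = np.flatnonzero(m[iu, ju] > 0)
    n_scale = round(scale_fraction * nz.size)
    n_del = round(delete_fraction * nz.size)
    chosen = rng.choice(nz, size=min(nz.size, n_scale + n_del), replace=False)
    scale_e, del_e = chosen[:n_scale], chosen[n_scale:]
    w = m[iu, ju]
    w[scale_e] *= scale_factor
    w[del_e] = 0.0
    out = np.zeros_like(m)
    out[iu, ju] = w
    out += out.T
    return Connectome(out, connectome.kind, connectome.node_labels)
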