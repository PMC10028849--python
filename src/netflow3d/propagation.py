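"""Insulated heat diffusion on the PPI network and module identification.

Cluster and LOF evidence is converted into node heats

    h_u = min(cap, -log10 min{p_C : C in C_u}) + min(cap, -log10 p_u)

(each addend 0 when its signal set is empty) and edge weights

    w_ij = min(cap, -log10 min{p_C : C in C_ij}) + w0

where C_ij are the inter-protein clusters specific to the PPI {i,j} and
w0 = 1 guarantees positive weights. At each diffusion step a node retains a
fraction beta of its heat and passes the rest to neighbors proportionally
to edge weights; the steady state is

    F = beta * (I - (1 - beta) W)^{-1},   W(i,j) = w_ij / sum_k w_kj,

and the exchanged-heat matrix is E = F D_h. A directed graph with an edge
j -> i wherever E(i,j) > delta is decomposed into strongly connected
components ("interconnected modules"); modules larger than 5 proteins are
significant. delta is chosen as the smallest value, over degree-preserving
edge-swap randomizations of the network with heats fixed and the weight
multiset reassigned, at which every randomized module has size <= 5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .clustering import Cluster3D

logger = logging.getLogger(__name__)

DEFAULT_BETA = 0.5
DEFAULT_W0 = 1.0
DEFAULT_SCORE_CAP = 300.0
DEFAULT_MODULE_SIZE_THRESHOLD = 5
DEFAULT_N_RANDOM_GRAPHS = 20


@dataclass
class HeatConfig:
    """Parameters of the diffusion model and delta selection."""

    beta: float = DEFAULT_BETA
    w0: float = DEFAULT_W0
    score_cap: float = DEFAULT_SCORE_CAP
    module_size_threshold: int = DEFAULT_MODULE_SIZE_THRESHOLD
    n_random_graphs: int = DEFAULT_N_RANDOM_GRAPHS
    rng_seed: int = 0
    delta: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.beta <= 1):
            raise ValueError("beta must lie in (0, 1]")
        if self.w0 <= 0:
            raise ValueError("w0 must be positive")
        if self.score_cap <= 0:
            raise ValueError("score_cap must be positive")


def neglog10_capped(p: float, cap: float = DEFAULT_SCORE_CAP) -> float:
    """min(cap, -log10 p), with underflowed p treated as the cap."""
    if p <= 0:
        return cap
    return min(cap, -math.log10(p))


def initial_heat(
    cluster_p_values: Sequence[float],
    lof_p: Optional[float],
    cap: float = DEFAULT_SCORE_CAP,
) -> float:
    """Node heat from the protein's clusters and its LOF enrichment p-value.

    ``cluster_p_values`` are the raw p-values of all tested clusters
    containing at least one residue of the protein (both families); an
    empty list contributes 0. ``lof_p=None`` (no LOF data) contributes 0.
    """
    h = 0.0
    if cluster_p_values:
        h += neglog10_capped(min(cluster_p_values), cap)
    if lof_p is not None:
        h += neglog10_capped(lof_p, cap)
    return h


def edge_weight(
    inter_cluster_p_values: Sequence[float],
    w0: float = DEFAULT_W0,
    cap: float = DEFAULT_SCORE_CAP,
) -> float:
    """Heat-transfer weight of one PPI from its inter-protein clusters."""
    if inter_cluster_p_values:
        return neglog10_capped(min(inter_cluster_p_values), cap) + w0
    return w0


def heats_from_scores(
    proteins: Iterable[str],
    clusters: Sequence[Cluster3D],
    lof_p_values: Mapping[str, float],
    cap: float = DEFAULT_SCORE_CAP,
) -> dict[str, float]:
    """Per-protein heats from scored clusters and LOF raw p-values."""
    by_protein: dict[str, list[float]] = {}
    for cluster in clusters:
        if cluster.p_raw is None:
            raise ValueError("clusters must be scored before heat assignment")
        for protein in cluster.proteins:
            by_protein.setdefault(protein, []).append(cluster.p_raw)
    return {
        protein: initial_heat(
            by_protein.get(protein, ()), lof_p_values.get(protein), cap
        )
        for protein in proteins
    }


def weights_from_scores(
    network: nx.Graph,
    clusters: Sequence[Cluster3D],
    w0: float = DEFAULT_W0,
    cap: float = DEFAULT_SCORE_CAP,
) -> dict[frozenset, float]:
    """Per-edge weights from the inter-protein clusters of each PPI."""
    by_pair: dict[frozenset, list[float]] = {}
    for cluster in clusters:
        if cluster.ppi is None:
            continue
        if cluster.p_raw is None:
            raise ValueError("clusters must be scored before weight assignment")
        by_pair.setdefault(cluster.ppi, []).append(cluster.p_raw)
    return {
        frozenset((u, v)): edge_weight(by_pair.get(frozenset((u, v)), ()), w0, cap)
        for u, v in network.edges
    }


def drop_isolated(network: nx.Graph) -> nx.Graph:
    """Copy of the network without degree-0 vertices (they break W)."""
    isolated = [n for n in network if network.degree(n) == 0]
    if isolated:
        logger.info("dropping %d isolated proteins before diffusion",
                    len(isolated))
        network = network.copy()
        network.remove_nodes_from(isolated)
    return network


def transition_matrix(
    network: nx.Graph,
    weights: Mapping[frozenset, float],
    node_order: Sequence[str],
) -> np.ndarray:
    """Column-stochastic transition matrix W(i,j) = w_ij / sum_k w_kj."""
    index = {node: i for i, node in enumerate(node_order)}
    n = len(node_order)
    W = np.zeros((n, n))
    for j, node in enumerate(node_order):
        neighbors = list(network.neighbors(node))
        if not neighbors:
            raise ValueError(f"degree-0 vertex {node!r} reached transition_matrix")
        w = np.array([weights[frozenset((node, nb))] for nb in neighbors])
        W[[index[nb] for nb in neighbors], j] = w / w.sum()
    return W


def compute_exchanged_heat(
    W: np.ndarray,
    beta: float,
    heats: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Diffusion matrix F = beta (I - (1-beta) W)^(-1) and E = F D_h.

    Solved as a linear system; the residual of (I-(1-beta)W) F = beta I is
    the numerical contract (<= 1e-9 on well-conditioned inputs).
    """
    n = W.shape[0]
    A = np.eye(n) - (1.0 - beta) * W
    try:
        F = np.linalg.solve(A, beta * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"diffusion system is singular: {exc}") from exc
    E = F * np.asarray(heats, dtype=float)[np.newaxis, :]
    return F, E


def strongly_connected_modules(digraph: nx.DiGraph) -> list[frozenset]:
    """Strongly connected components, largest first, deterministic order."""
    comps = [frozenset(c) for c in nx.strongly_connected_components(digraph)]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)))


def identify_modules(
    E: np.ndarray,
    node_order: Sequence[str],
    delta: float,
    size_threshold: int = DEFAULT_MODULE_SIZE_THRESHOLD,
) -> tuple[list[frozenset], list[frozenset]]:
    """Interconnected modules at threshold delta.

    Directed edge j -> i wherever E(i,j) > delta (strict); modules are the
    strongly connected components; those with more than ``size_threshold``
    proteins are significant. One-way configurations (stars) cannot form
    multi-node modules.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    digraph: nx.DiGraph = nx.DiGraph()
    digraph.add_nodes_from(node_order)
    rows, cols = np.nonzero(E > delta)
    for i, j in zip(rows, cols):
        if i != j:
            digraph.add_edge(node_order[j], node_order[i], weight=float(E[i, j]))
    modules = strongly_connected_modules(digraph)
    significant = [m for m in modules if len(m) > size_threshold]
    return modules, significant


def _max_scc_size(E: np.ndarray, node_order: Sequence[str], delta: float) -> int:
    modules, _ = identify_modules(E, node_order, delta, size_threshold=len(node_order))
    return max((len(m) for m in modules), default=0)


# ---------------------------------------------------------------------------
# delta selection on randomized networks
# ---------------------------------------------------------------------------

def double_edge_swap(
    network: nx.Graph, rng: np.random.Generator, n_attempts: Optional[int] = None
) -> nx.Graph:
    """Degree-preserving randomization by repeated double edge swaps.

    Each attempt picks two distinct edges (a,b), (c,d) and rewires to
    (a,d), (c,b); swaps creating self-loops or parallel edges are rejected.
    The default budget is 10 * |E| attempts. Raises if no swap succeeds,
    which signals a network too small or dense to randomize.
    """
    graph = network.copy()
    edges = [tuple(sorted(e)) for e in graph.edges]
    m = len(edges)
    if n_attempts is None:
        n_attempts = 10 * m
    if m < 2:
        raise ValueError("network too small to swap; supply delta explicitly")
    n_success = 0
    for _ in range(n_attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == d or c == b:
            continue
        if graph.has_edge(a, d) or graph.has_edge(c, b):
            continue
        graph.remove_edge(a, b)
        graph.remove_edge(c, d)
        graph.add_edge(a, d)
        graph.add_edge(c, b)
        edges[i] = tuple(sorted((a, d)))
        edges[j] = tuple(sorted((c, b)))
        n_success += 1
    if n_success == 0:
        raise ValueError(
            "no valid double edge swap found within the attempt budget; "
            "supply delta explicitly"
        )
    return graph


@dataclass
class DeltaReplicate:
    """One randomized replicate retained for post-hoc verification."""

    network: nx.Graph
    weights: dict[frozenset, float]
    node_order: list[str]
    exchanged_heat: np.ndarray
    delta: Optional[float]  # minimal candidate with all modules <= threshold


@dataclass
class DeltaSelection:
    delta: float
    replicates: list[DeltaReplicate] = field(default_factory=list)


def select_delta(
    network: nx.Graph,
    heats: Mapping[str, float],
    weights: Mapping[frozenset, float],
    config: HeatConfig,
) -> DeltaSelection:
    """Choose delta from degree-preserving randomizations of the network.

    For each replicate the edges are randomized by double edge swaps (node
    heats fixed), the original weight multiset is randomly reassigned to
    the swapped edges, and the exchanged-heat matrix is recomputed. The
    replicate's delta is the smallest distinct positive entry of its E at
    which every strongly connected component has size at most the module
    threshold (binary search over the sorted candidate grid; the directed
    edge rule E(i,j) > delta is strict). The final delta is the smallest
    over replicates.
    """
    network = drop_isolated(network)
    weight_values = np.array(
        [weights[frozenset(e)] for e in network.edges], dtype=float
    )
    threshold = config.module_size_threshold
    replicates: list[DeltaReplicate] = []
    for r in range(config.n_random_graphs):
        rng = np.random.default_rng((config.rng_seed + r) % (2**31))
        random_graph = double_edge_swap(network, rng)
        perm = rng.permutation(len(weight_values))
        random_weights = {
            frozenset(e): float(weight_values[perm[k]])
            for k, e in enumerate(random_graph.edges)
        }
        node_order = sorted(random_graph)
        W = transition_matrix(random_graph, random_weights, node_order)
        h = np.array([heats.get(n, 0.0) for n in node_order])
        _, E = compute_exchanged_heat(W, config.beta, h)
        candidates = np.unique(E[E > 0])
        delta_r: Optional[float] = None
        if len(candidates) > 0:
            # max SCC size is non-increasing in delta: binary search for the
            # first candidate where all components are small enough
            lo, hi = 0, len(candidates) - 1
            if _max_scc_size(E, node_order, float(candidates[hi])) <= threshold:
                while lo < hi:
                    mid = (lo + hi) // 2
                    if _max_scc_size(E, node_order, float(candidates[mid])) <= threshold:
                        hi = mid
                    else:
                        lo = mid + 1
                delta_r = float(candidates[lo])
        replicates.append(
            DeltaReplicate(random_graph, random_weights, node_order, E, delta_r)
        )
    found = [rep.delta for rep in replicates if rep.delta is not None]
    if not found:
        raise ValueError(
            "no randomized replicate produced a positive exchanged-heat "
            "entry; supply delta explicitly"
        )
    return DeltaSelection(delta=min(found), replicates=replicates)


# ---------------------------------------------------------------------------
# end-to-end helpers
# ---------------------------------------------------------------------------

@dataclass
class DiffusionResult:
    node_order: list[str]
    heats: np.ndarray
    transition: np.ndarray
    diffusion: np.ndarray
    exchanged_heat: np.ndarray
    delta: float
    modules: list[frozenset]
    significant_modules: list[frozenset]


def diffuse_and_identify(
    network: nx.Graph,
    heats: Mapping[str, float],
    weights: Mapping[frozenset, float],
    config: HeatConfig,
) -> DiffusionResult:
    """Run diffusion on the real network and report modules at delta.

    delta comes from ``config.delta`` when supplied, otherwise from
    :func:`select_delta`.
    """
    network = drop_isolated(network)
    node_order = sorted(network)
    W = transition_matrix(network, weights, node_order)
    h = np.array([heats.get(n, 0.0) for n in node_order])
    F, E = compute_exchanged_heat(W, config.beta, h)
    if config.delta is not None:
        delta = float(config.delta)
    else:
        delta = select_delta(network, heats, weights, config).delta
    modules, significant = identify_modules(
        E, node_order, delta, config.module_size_threshold
    )
    return DiffusionResult(node_order, h, W, F, E, delta, modules, significant)


def extract_driver_mutations(
    significant_modules: Sequence[frozenset],
    clusters: Sequence[Cluster3D],
    network: nx.Graph,
) -> dict[str, list]:
    """Potential driver mutations within significant modules.

    For each protein in a significant module, the mutations of its most
    significant (lowest raw p) cluster among its significant clusters; for
    each PPI whose endpoints lie in one module, the mutations of the most
    significant significant inter-protein cluster at that interface.
    Returns a mapping from provenance key to mutation lists.
    """
    module_of: dict[str, int] = {}
    for idx, module in enumerate(significant_modules):
        for protein in module:
            module_of[protein] = idx

    out: dict[str, list] = {}
    # protein rule
    for protein in sorted(module_of):
        eligible = [
            c for c in clusters
            if c.significant and protein in c.proteins
        ]
        if not eligible:
            continue
        best = min(eligible, key=lambda c: (c.p_raw, c.cluster_id))
        out[f"protein:{protein}"] = list(best.mutations)
    # PPI rule
    for u, v in network.edges:
        if module_of.get(u) is None or module_of.get(u) != module_of.get(v):
            continue
        pair = frozenset((u, v))
        eligible = [c for c in clusters if c.significant and c.ppi == pair]
        if not eligible:
            continue
        best = min(eligible, key=lambda c: (c.p_raw, c.cluster_id))
        a, b = sorted(pair)
        out[f"ppi:{a}--{b}"] = list(best.mutations)
    return out


def baseline_configuration(
    network: nx.Graph, records
) -> tuple[dict[str, float], dict[frozenset, float]]:
    """Ablation mode: mutated-sample-count heats and unit edge weights.

    h_u is the number of distinct tumor samples carrying at least one
    protein-altering (in-frame or LOF) mutation in u; every edge weight is
    1. Downstream diffusion, delta selection and module identification are
    unchanged.
    """
    from .io_preprocess import IN_FRAME, LOF

    samples: dict[str, set[str]] = {}
    for rec in records:
        if rec.consequence_class in (IN_FRAME, LOF):
            samples.setdefault(rec.protein_id, set()).add(rec.sample_id)
    heats = {n: float(len(samples.get(n, ()))) for n in network}
    weights = {frozenset((u, v)): 1.0 for u, v in network.edges}
    return heats, weights
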