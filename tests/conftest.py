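import numpy as np
import pytest

from netflow3d.structurome import MappedResidue, StructureSnapshot


def make_chain(protein_id: str, coords: np.ndarray) -> list[MappedResidue]:
    return [
        MappedResidue(protein_id, i + 1, np.asarray(c).reshape(-1, 3))
        for i, c in enumerate(coords)
    ]


def line_snapshot(protein_id: str, length: int, spacing: float = 3.8,
                  structure_id: str = "snap") -> StructureSnapshot:
    """Single-chain straight backbone: i,i+1 contacts only at the 6 A cutoff."""
    coords = np.zeros((length, 3))
    coords[:, 0] = spacing * np.arange(length)
    return StructureSnapshot(structure_id, {"A": make_chain(protein_id, coords)})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_components(nodes, edges):
    """Independent connected-components oracle: repeated set expansion."""
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    unseen = set(nodes)
    comps = []
    while unseen:
        start = unseen.pop()
        comp = {start}
        frontier = {start}
        while frontier:
            nxt = set()
            for n in frontier:
                nxt |= adj[n] & unseen
            unseen -= nxt
            comp |= nxt
            frontier = nxt
        comps.append(frozenset(comp))
    return set(comps)


def brute_force_scc(nodes, directed_edges):
    """Independent SCC oracle via boolean transitive closure."""
    nodes = list(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for u, v in directed_edges:
        reach[idx[u], idx[v]] = True
    for k in range(n):
        reach = reach | (reach[:, k:k + 1] & reach[k:k + 1, :])
    mutual = reach & reach.T
    comps = set()
    for i in range(n):
        comps.add(frozenset(nodes[j] for j in range(n) if mutual[i, j]))
    return comps
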