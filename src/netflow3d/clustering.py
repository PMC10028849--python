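"""3D cluster identification on contact graphs and PPI interfaces.

Four cluster families are built from in-frame mutations:

* C1 — connected components of the mutated-residue subgraph of G1
  (experimental intra-chain contacts),
* C2 — per PPI {A,B}, connected components of the merged graph of mutated
  intra subgraphs of A and B plus mutated inter-chain edges, keeping only
  components containing at least one inter-chain edge,
* C3 — as C1 on G3 (predicted models), with a redundancy rule removing C3
  clusters that share any residue with a C1 cluster,
* C4 — per annotated PPI, the set of mutated interface residues.

A cluster's observed count O_C is the number of in-frame mutation events
whose residue footprint intersects the cluster — recurrent hits on one
residue count every event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .io_preprocess import IN_FRAME, MutationRecord
from .structurome import ContactGraph, InterfaceAnnotation, Residue

logger = logging.getLogger(__name__)

C1 = "C1"
C2 = "C2"
C3 = "C3"
C4 = "C4"

#: family grouping for multiple-testing correction
STRUCTURE_FAMILY = frozenset({C1, C2, C3})
INTERFACE_FAMILY = frozenset({C4})


@dataclass
class MutatedResidueSet:
    """In-frame mutated residues per protein, with contributing records."""

    by_residue: dict[Residue, list[MutationRecord]] = field(default_factory=dict)

    def proteins(self) -> set[str]:
        return {p for p, _ in self.by_residue}

    def residues_of(self, protein_id: str) -> set[int]:
        return {r for p, r in self.by_residue if p == protein_id}

    def records_for(self, residues: Iterable[Residue]) -> list[MutationRecord]:
        """Distinct mutation records whose footprint touches ``residues``."""
        seen: dict[int, MutationRecord] = {}
        for res in residues:
            for rec in self.by_residue.get(res, ()):
                seen[id(rec)] = rec
        return list(seen.values())


def expand_to_residues(
    records: Iterable[MutationRecord],
    protein_lengths: Mapping[str, int],
) -> MutatedResidueSet:
    """Residue footprint of in-frame mutations.

    Missense and in-frame insertions mark the anchor residue(s) at the site
    (the start..end range as annotated); in-frame deletions mark every
    deleted residue. Residues beyond the protein length, and proteins with
    unknown length, are dropped with a warning.
    """
    out = MutatedResidueSet()
    n_out_of_range = 0
    skipped_proteins: set[str] = set()
    for rec in records:
        if rec.consequence_class != IN_FRAME:
            continue
        length = protein_lengths.get(rec.protein_id)
        if length is None:
            skipped_proteins.add(rec.protein_id)
            continue
        if rec.consequence_term == "missense_variant":
            footprint = [rec.residue_start]
        elif rec.consequence_term == "inframe_insertion":
            # anchor residues flanking the insertion point
            footprint = list(range(rec.residue_start, rec.residue_end + 1))
        else:  # inframe_deletion and compound in-frame terms: full range
            footprint = list(range(rec.residue_start, rec.residue_end + 1))
        for idx in footprint:
            if idx > length:
                n_out_of_range += 1
                continue
            out.by_residue.setdefault((rec.protein_id, idx), []).append(rec)
    if n_out_of_range:
        logger.warning("dropped %d mutated positions beyond protein length",
                       n_out_of_range)
    if skipped_proteins:
        logger.warning("skipped mutations on %d proteins with unknown length",
                       len(skipped_proteins))
    return out


@dataclass
class Cluster3D:
    """A connected set of mutated residues on one or two proteins."""

    cluster_id: str
    source: str  # C1 | C2 | C3 | C4
    proteins: tuple[str, ...]
    residues: dict[str, frozenset[int]]  # per protein
    mutations: list[MutationRecord]
    observed: int  # O_C: mutation events
    expected: Optional[float] = None  # E_C
    p_raw: Optional[float] = None
    p_adjusted: Optional[float] = None
    significant: Optional[bool] = None
    ppi: Optional[frozenset] = None  # the PPI pair for C2/C4

    @property
    def k(self) -> int:
        """Total number of residues in the cluster."""
        return sum(len(r) for r in self.residues.values())

    def residue_set(self) -> frozenset[Residue]:
        return frozenset(
            (p, r) for p, rs in self.residues.items() for r in rs
        )

    def __post_init__(self) -> None:
        if self.observed < 1:
            raise ValueError("a 3D cluster must contain at least one mutation")
        if self.k < 1:
            raise ValueError("a 3D cluster must contain at least one residue")


def _cluster_id(source: str, residues: Iterable[Residue]) -> str:
    first = min(residues)
    return f"{source}:{first[0]}:{first[1]}"


def _make_cluster(
    source: str,
    component: Iterable[Residue],
    mutated: MutatedResidueSet,
    ppi: Optional[frozenset] = None,
) -> Cluster3D:
    component = sorted(component)
    per_protein: dict[str, set[int]] = {}
    for p, r in component:
        per_protein.setdefault(p, set()).add(r)
    records = mutated.records_for(component)
    return Cluster3D(
        cluster_id=_cluster_id(source, component),
        source=source,
        proteins=tuple(sorted(per_protein)),
        residues={p: frozenset(rs) for p, rs in per_protein.items()},
        mutations=sorted(
            records, key=lambda m: (m.protein_id, m.residue_start, m.sample_id)
        ),
        observed=len(records),
        ppi=ppi,
    )


def intra_clusters(
    graph: ContactGraph, mutated: MutatedResidueSet
) -> list[Cluster3D]:
    """Connected components of the mutated-vertex-induced subgraph.

    Mutated residues outside the graph's vertex set are not part of this
    family. A mutated residue that is a vertex but has no mutated contact
    partner forms a singleton cluster.
    """
    source = C3 if graph.kind == "intra_predicted" else C1
    nodes = [v for v in mutated.by_residue if v in graph.vertices]
    sub: nx.Graph = nx.Graph()
    sub.add_nodes_from(nodes)
    node_set = set(nodes)
    for (u, v) in graph.edges():
        if u in node_set and v in node_set:
            sub.add_edge(u, v)
    clusters = [
        _make_cluster(source, comp, mutated)
        for comp in nx.connected_components(sub)
    ]
    return sorted(clusters, key=lambda c: c.cluster_id)


def inter_clusters(
    intra_graph: ContactGraph,
    inter_graph: ContactGraph,
    mutated: MutatedResidueSet,
    ppis: Iterable[frozenset | tuple[str, str]],
) -> list[Cluster3D]:
    """Inter-protein clusters (C2) for each PPI in the interaction set.

    For a PPI {A,B}: merge the mutated intra-chain subgraphs of A and B
    with the mutated inter-chain edges between them; connected components
    containing at least one inter-chain edge are C2 clusters.
    """
    mutated_set = set(mutated.by_residue)
    v1 = mutated_set & intra_graph.vertices  # mutated, experimentally covered
    intra_edges = [
        (u, v) for (u, v) in intra_graph.edges() if u in v1 and v in v1
    ]
    inter_edges = [
        (u, v)
        for (u, v) in inter_graph.edges()
        if u in v1 and v in v1
    ]
    clusters = []
    for pair in ppis:
        key = frozenset(pair)
        if len(key) != 2:
            continue  # self-interactions carry no inter-protein cluster
        a, b = sorted(key)
        nodes = {x for x in v1 if x[0] in key}
        if not nodes:
            continue
        merged: nx.Graph = nx.Graph()
        merged.add_nodes_from(nodes)
        for u, v in intra_edges:
            if u in nodes and v in nodes:
                merged.add_edge(u, v, inter=False)
        e2ab = []
        for u, v in inter_edges:
            if {u[0], v[0]} == {a, b}:
                merged.add_edge(u, v, inter=True)
                e2ab.append((u, v))
        if not e2ab:
            continue
        for comp in nx.connected_components(merged):
            if any(u in comp and v in comp for u, v in e2ab):
                clusters.append(_make_cluster(C2, comp, mutated, ppi=key))
    return sorted(clusters, key=lambda c: c.cluster_id)


def interface_clusters(
    annotations: InterfaceAnnotation,
    mutated: MutatedResidueSet,
    ppis: Optional[Iterable[frozenset | tuple[str, str]]] = None,
) -> list[Cluster3D]:
    """Interface clusters (C4): mutated interface residues of each PPI.

    Each annotated PPI with at least one mutated interface residue yields
    exactly one cluster; PPIs without mutated interface residues yield none.
    """
    allowed = None
    if ppis is not None:
        allowed = {frozenset(p) for p in ppis}
    mutated_set = set(mutated.by_residue)
    clusters = []
    for key, sides in annotations.pairs.items():
        if allowed is not None and key not in allowed:
            continue
        members = {
            (protein, residue)
            for protein, residues in sides.items()
            for residue in residues
            if (protein, residue) in mutated_set
        }
        if members:
            clusters.append(_make_cluster(C4, members, mutated, ppi=key))
    return sorted(clusters, key=lambda c: c.cluster_id)


def dedupe_predicted(
    c3: Sequence[Cluster3D], c1: Sequence[Cluster3D]
) -> list[Cluster3D]:
    """Remove C3 clusters that share any residue with a C1 cluster.

    The rule names C1 only: overlap with C2 or C4 clusters does not remove
    a predicted-structure cluster.
    """
    covered: set[Residue] = set()
    for cluster in c1:
        covered |= cluster.residue_set()
    return [c for c in c3 if not (c.residue_set() & covered)]
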