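"""Residue contact graphs and PPI interface annotations.

Three undirected residue-level graphs summarise the structural data:

* G1 — intra-chain contacts from experimental structures: vertices are all
  UniProt residues covered by at least one structure; an edge joins two
  residues of the same protein whose minimal closest-atom distance within a
  single polypeptide chain, over all structures, is <= 6 A.
* G2 — inter-chain contacts from experimental structures at <= 9 A; its
  vertex set is restricted to edge endpoints.
* G3 — intra-chain contacts from predicted single-protein models at <= 6 A,
  using residues at all levels of model confidence.

Distances are exact closest-atom euclidean distances; a k-d tree restricts
the candidate atom pairs but every reported distance equals the brute-force
all-atom-pairs minimum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

INTRA_EXPERIMENTAL = "intra_experimental"
INTER_EXPERIMENTAL = "inter_experimental"
INTRA_PREDICTED = "intra_predicted"

DEFAULT_INTRA_CUTOFF = 6.0
DEFAULT_INTER_CUTOFF = 9.0

#: ordered confidence labels for interface predictions
CONFIDENCE_ORDER = {"low": 0, "medium": 1, "high": 2, "very high": 3}

Residue = tuple[str, int]  # (protein_id, 1-based residue index)


@dataclass
class MappedResidue:
    """A structure residue mapped to protein coordinates, with its atoms."""

    protein_id: str
    residue_index: int  # 1-based protein coordinate
    coords: np.ndarray  # (n_atoms, 3) in Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] == 0:
            raise ValueError(
                f"residue {self.protein_id}:{self.residue_index} has no atoms"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError(
                f"non-finite coordinates at {self.protein_id}:{self.residue_index}"
            )


@dataclass
class StructureSnapshot:
    """One model of one structure: chains of mapped residues with coordinates."""

    structure_id: str
    chains: dict[str, list[MappedResidue]]

    def n_residues(self) -> int:
        return sum(len(rs) for rs in self.chains.values())


def residue_min_distance(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Minimum euclidean distance over all atom pairs of two residues."""
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("residue with no resolved atoms in distance query")
    return float(cdist(a, b).min())


class ContactGraph:
    """Undirected residue contact graph with per-edge minimum distances."""

    def __init__(self, kind: str, cutoff: float):
        if kind not in (INTRA_EXPERIMENTAL, INTER_EXPERIMENTAL, INTRA_PREDICTED):
            raise ValueError(f"unknown contact graph kind {kind!r}")
        self.kind = kind
        self.cutoff = float(cutoff)
        self.vertices: set[Residue] = set()
        self._edges: dict[tuple[Residue, Residue], float] = {}

    @staticmethod
    def _key(u: Residue, v: Residue) -> tuple[Residue, Residue]:
        return (u, v) if u <= v else (v, u)

    def add_vertex(self, v: Residue) -> None:
        self.vertices.add(v)

    def add_contact(self, u: Residue, v: Residue, distance: float) -> None:
        """Record a contact, keeping the minimum distance over snapshots."""
        if u == v:
            return
        if distance > self.cutoff:
            return
        if self.kind != INTER_EXPERIMENTAL and u[0] != v[0]:
            raise ValueError("intra-chain graph cannot join different proteins")
        key = self._key(u, v)
        old = self._edges.get(key)
        if old is None or distance < old:
            self._edges[key] = float(distance)
        self.vertices.add(u)
        self.vertices.add(v)

    def edges(self) -> dict[tuple[Residue, Residue], float]:
        return dict(self._edges)

    def has_edge(self, u: Residue, v: Residue) -> bool:
        return self._key(u, v) in self._edges

    def distance(self, u: Residue, v: Residue) -> float:
        return self._edges[self._key(u, v)]

    def neighbors(self, v: Residue) -> set[Residue]:
        out = set()
        for (a, b) in self._edges:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        return out

    def n_edges(self) -> int:
        return len(self._edges)

    # -- serialization (bit-exact round trip via repr of the float) --------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#kind\t%s\t%r\n" % (self.kind, self.cutoff))
            for v in sorted(self.vertices):
                fh.write(f"V\t{v[0]}\t{v[1]}\n")
            for (u, v), d in sorted(self._edges.items()):
                fh.write(f"E\t{u[0]}\t{u[1]}\t{v[0]}\t{v[1]}\t{d!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContactGraph":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            graph = cls(header[1], float(header[2]))
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "V":
                    graph.add_vertex((parts[1], int(parts[2])))
                elif parts[0] == "E":
                    u = (parts[1], int(parts[2]))
                    v = (parts[3], int(parts[4]))
                    graph._edges[cls._key(u, v)] = float(parts[5])
                    graph.vertices.update((u, v))
        return graph


def _contact_pairs(
    residues_a: Sequence[MappedResidue],
    residues_b: Optional[Sequence[MappedResidue]],
    cutoff: float,
):
    """Yield (i, j, min_distance) for residue pairs with min distance <= cutoff.

    With ``residues_b=None``, pairs within ``residues_a`` (i < j). Uses a
    k-d tree over atoms; distances of reported pairs are exact minima.
    """
    if not residues_a or (residues_b is not None and not residues_b):
        return
    atoms_a = np.concatenate([r.coords for r in residues_a])
    labels_a = np.concatenate(
        [np.full(len(r.coords), i) for i, r in enumerate(residues_a)]
    )
    tree_a = cKDTree(atoms_a)
    best: dict[tuple[int, int], float] = {}
    if residues_b is None:
        pairs = tree_a.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            return
        d = np.linalg.norm(atoms_a[pairs[:, 0]] - atoms_a[pairs[:, 1]], axis=1)
        ri, rj = labels_a[pairs[:, 0]], labels_a[pairs[:, 1]]
        for i, j, dist in zip(ri, rj, d):
            if i == j:
                continue
            key = (int(i), int(j)) if i < j else (int(j), int(i))
            if dist <= cutoff and (key not in best or dist < best[key]):
                best[key] = float(dist)
    else:
        atoms_b = np.concatenate([r.coords for r in residues_b])
        labels_b = np.concatenate(
            [np.full(len(r.coords), j) for j, r in enumerate(residues_b)]
        )
        tree_b = cKDTree(atoms_b)
        pairs = tree_a.query_ball_tree(tree_b, cutoff)
        for ia, hits in enumerate(pairs):
            if not hits:
                continue
            d = np.linalg.norm(atoms_b[hits] - atoms_a[ia], axis=1)
            for ib, dist in zip(hits, d):
                key = (int(labels_a[ia]), int(labels_b[ib]))
                if dist <= cutoff and (key not in best or dist < best[key]):
                    best[key] = float(dist)
    yield from ((i, j, d) for (i, j), d in best.items())


def build_intra_contact_graph(
    snapshots: Iterable[StructureSnapshot],
    cutoff: float = DEFAULT_INTRA_CUTOFF,
    kind: str = INTRA_EXPERIMENTAL,
) -> ContactGraph:
    """Same-chain residue contacts at the given cutoff, min over snapshots.

    Vertices are all mapped residues covered by at least one snapshot; an
    edge requires co-occurrence in one chain with closest-atom distance
    <= cutoff in at least one snapshot.
    """
    graph = ContactGraph(kind, cutoff)
    snapshots = list(snapshots)
    if not snapshots:
        logger.warning("building %s contact graph from zero snapshots", kind)
    for snap in snapshots:
        for chain_residues in snap.chains.values():
            for res in chain_residues:
                graph.add_vertex((res.protein_id, res.residue_index))
            for i, j, dist in _contact_pairs(chain_residues, None, cutoff):
                u = chain_residues[i]
                v = chain_residues[j]
                if (u.protein_id, u.residue_index) == (v.protein_id, v.residue_index):
                    continue
                graph.add_contact(
                    (u.protein_id, u.residue_index),
                    (v.protein_id, v.residue_index),
                    dist,
                )
    return graph


def build_inter_contact_graph(
    snapshots: Iterable[StructureSnapshot],
    cutoff: float = DEFAULT_INTER_CUTOFF,
) -> ContactGraph:
    """Inter-chain residue contacts at the given cutoff, min over snapshots.

    Chains may belong to different proteins or be two copies of the same
    protein (homomeric contacts are kept). The vertex set is exactly the
    set of edge endpoints.
    """
    graph = ContactGraph(INTER_EXPERIMENTAL, cutoff)
    for snap in snapshots:
        chain_ids = sorted(snap.chains)
        for a_idx in range(len(chain_ids)):
            for b_idx in range(a_idx + 1, len(chain_ids)):
                ra = snap.chains[chain_ids[a_idx]]
                rb = snap.chains[chain_ids[b_idx]]
                for i, j, dist in _contact_pairs(ra, rb, cutoff):
                    u = (ra[i].protein_id, ra[i].residue_index)
                    v = (rb[j].protein_id, rb[j].residue_index)
                    if u == v:
                        continue  # same protein residue seen in two chains
                    graph.add_contact(u, v, dist)
    return graph


def build_predicted_graph(
    snapshots: Iterable[StructureSnapshot],
    cutoff: float = DEFAULT_INTRA_CUTOFF,
) -> ContactGraph:
    """Intra-chain contacts from predicted single-protein models (G3).

    No confidence filtering is applied to residues. A multi-chain predicted
    snapshot is a fatal error: predicted models cover single proteins.
    """
    snapshots = list(snapshots)
    for snap in snapshots:
        if len(snap.chains) != 1:
            raise ValueError(
                f"predicted structure {snap.structure_id} has "
                f"{len(snap.chains)} chains; expected 1"
            )
    return build_intra_contact_graph(snapshots, cutoff, kind=INTRA_PREDICTED)


# ---------------------------------------------------------------------------
# Structure file loading (PDB / mmCIF via gemmi)
# ---------------------------------------------------------------------------

def read_residue_mapping(path: str | Path) -> dict[tuple[str, str, int], Residue]:
    """Read a SIFTS-like residue mapping table.

    Columns: structure_id, chain, author residue index, protein_id,
    protein residue index (1-based). Returns a dict keyed by
    (structure_id, chain, author_index).
    """
    df = pd.read_csv(
        path, sep="\t",
        names=["structure_id", "chain", "author_index", "protein_id", "protein_index"],
        dtype={"structure_id": str, "chain": str, "protein_id": str},
        comment="#",
    )
    mapping: dict[tuple[str, str, int], Residue] = {}
    for row in df.itertuples(index=False):
        key = (str(row.structure_id), str(row.chain), int(row.author_index))
        val = (str(row.protein_id), int(row.protein_index))
        if key in mapping and mapping[key] != val:
            raise ValueError(f"conflicting residue mapping for {key}")
        mapping[key] = val
    return mapping


def _residue_atom_coords(residue) -> np.ndarray:
    """Coordinates of a gemmi residue: non-hydrogen atoms, highest-occupancy
    altloc per atom name (ties broken by file order)."""
    import gemmi

    chosen: dict[str, tuple[float, np.ndarray]] = {}
    order: list[str] = []
    for atom in residue:
        if atom.is_hydrogen():
            continue
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = (atom.occ, pos)
            order.append(atom.name)
        elif atom.occ > prev[0]:
            chosen[atom.name] = (atom.occ, pos)
    if not chosen:
        return np.empty((0, 3))
    return np.array([chosen[name][1] for name in order])


def load_structure_snapshots(
    path: str | Path,
    mapping: Mapping[tuple[str, str, int], Residue],
    structure_id: Optional[str] = None,
) -> list[StructureSnapshot]:
    """Load a PDB/mmCIF file into mapped snapshots, one per model.

    Only standard polymer residues with a residue mapping and at least one
    resolved heavy atom are retained; waters and hetero ligands are
    excluded. Unmapped residues are skipped silently (partial mappings are
    expected).
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    sid = structure_id or st.name or Path(path).stem
    snapshots = []
    for model in st:
        model_id = f"{sid}" if len(st) == 1 else f"{sid}#model{model.num}"
        chains: dict[str, list[MappedResidue]] = {}
        for chain in model:
            residues: list[MappedResidue] = []
            for residue in chain:
                if residue.is_water():
                    continue
                info = gemmi.find_tabulated_residue(residue.name)
                if info is not None and not info.is_amino_acid() and not info.is_nucleic_acid():
                    continue
                key = (sid, chain.name, residue.seqid.num)
                if key not in mapping:
                    continue
                coords = _residue_atom_coords(residue)
                if coords.shape[0] == 0:
                    continue
                protein_id, protein_index = mapping[key]
                residues.append(MappedResidue(protein_id, protein_index, coords))
            if residues:
                chains[chain.name] = residues
        if chains:
            snapshots.append(StructureSnapshot(model_id, chains))
    if not snapshots:
        logger.warning("no mapped residues loaded from %s", path)
    return snapshots


# ---------------------------------------------------------------------------
# PPI interface annotations
# ---------------------------------------------------------------------------

@dataclass
class InterfaceAnnotation:
    """Interface residues per unordered protein pair, by prediction confidence."""

    pairs: dict[frozenset, dict[str, set[int]]] = field(default_factory=dict)

    def add(self, protein_a: str, protein_b: str, side: str, residue: int) -> None:
        key = frozenset((protein_a, protein_b))
        if side not in key:
            raise ValueError(f"side {side!r} is not in pair ({protein_a},{protein_b})")
        sides = self.pairs.setdefault(key, {p: set() for p in sorted(key)})
        sides.setdefault(side, set()).add(residue)

    def interface(self, protein_a: str, protein_b: str) -> Optional[dict[str, set[int]]]:
        return self.pairs.get(frozenset((protein_a, protein_b)))

    def __len__(self) -> int:
        return len(self.pairs)


def load_interface_annotations(
    path: str | Path, min_confidence: str = "very high"
) -> InterfaceAnnotation:
    """Read interface-residue predictions, keeping rows at or above
    ``min_confidence``.

    Columns: protein_a, protein_b, side (one of the two proteins), residue
    index (1-based), confidence label. Rows whose side names a protein not
    in the pair are rejected with a log message.
    """
    if min_confidence not in CONFIDENCE_ORDER:
        raise ValueError(f"unknown confidence label {min_confidence!r}")
    threshold = CONFIDENCE_ORDER[min_confidence]
    ann = InterfaceAnnotation()
    df = pd.read_csv(
        path, sep="\t",
        names=["protein_a", "protein_b", "side", "residue", "confidence"],
        dtype=str, comment="#",
    )
    n_rejected = 0
    for rownum, row in enumerate(df.itertuples(index=False), start=1):
        conf = str(row.confidence).strip()
        if CONFIDENCE_ORDER.get(conf, -1) < threshold:
            continue
        try:
            ann.add(str(row.protein_a), str(row.protein_b),
                    str(row.side), int(row.residue))
        except ValueError as exc:
            logger.warning("interface row %d rejected: %s", rownum, exc)
            n_rejected += 1
    if n_rejected:
        logger.info("rejected %d interface rows", n_rejected)
    # drop pairs where both sides ended up empty (cannot happen via add, but
    # normalize empty side sets for stored pairs)
    ann.pairs = {k: v for k, v in ann.pairs.items() if any(v.values())}
    return ann
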