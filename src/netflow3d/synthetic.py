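"""Deterministic synthetic data: structures, cohorts and networks.

Every stage of the pipeline can run on data produced here, with no
downloads. The generators emulate the statistical structure the method
assumes — Poisson mutation counts at locally uniform background rates with
optional planted rate elevations, simple backbone geometry that yields
known contact graphs, and an Erdos-Renyi interactome with optional planted
cliques — not realistic protein folds or mutational signatures.

Geometry: each protein is a straight C-alpha backbone with 3.8 A spacing,
so sequence-adjacent residues are in contact at the 6 A cutoff and all
pairs |i-j| >= 2 are not. Interface pairs place a second chain so that a
designated patch sits within the 9 A inter-chain cutoff and everything
else stays outside it.

Mutation counts: per-residue in-frame event counts over the cohort are
Poisson with mean (E_g^in-frame / l) * n_samples * multiplier, where
E_g^in-frame derives from the same per-base rates the background model
estimates, so the generator and the estimator share one parameterisation.
All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_preprocess import IN_FRAME, LOF, MutationRecord, classify_consequence
from .structurome import InterfaceAnnotation, MappedResidue, StructureSnapshot

DEFAULT_BACKBONE_SPACING = 3.8  # Angstrom between consecutive C-alpha atoms
DEFAULT_CONTACT_GAP = 5.0       # inter-chain distance inside an interface patch
DEFAULT_FAR_GAP = 14.0          # inter-chain distance outside the patch


@dataclass(frozen=True)
class PlantedCluster:
    """A contiguous residue patch with an elevated in-frame mutation rate."""

    protein_id: str
    residues: tuple[int, ...]
    multiplier: float


@dataclass(frozen=True)
class InterfacePair:
    """Two proteins co-crystallised with a designated contact patch."""

    protein_a: str
    protein_b: str
    patch_a: tuple[int, ...]
    patch_b: tuple[int, ...]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study; the seed fully determines output."""

    seed: int = 0
    n_proteins: int = 20
    protein_length: int = 200
    n_samples: int = 1000
    cancer_type: str = "CANCER_A"
    # per-base per-sample background rates
    mu_snv: float = 1e-6
    mu_indel: float = 5e-8
    alpha_indel_inframe: float = 0.09
    # mutation-type content (uniform across genes by default)
    a_missense: float = 0.70
    a_nonsense: float = 0.035
    a_splice: float = 0.015
    # geometry
    backbone_spacing: float = DEFAULT_BACKBONE_SPACING
    contact_gap: float = DEFAULT_CONTACT_GAP
    far_gap: float = DEFAULT_FAR_GAP
    # planted signal
    planted_clusters: tuple[PlantedCluster, ...] = ()
    planted_lof: dict = field(default_factory=dict)  # protein -> multiplier
    interface_pairs: tuple[InterfacePair, ...] = ()
    # network
    edge_probability: float = 0.1
    planted_cliques: tuple[tuple[str, ...], ...] = ()
    # expression
    n_expression_samples: int = 25
    unexpressed_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mu_snv < 0 or self.mu_indel < 0:
            raise ValueError("background rates must be >= 0")
        if self.a_missense + self.a_nonsense + self.a_splice > 1:
            raise ValueError("mutation-type probabilities exceed 1")
        for planted in self.planted_clusters:
            if planted.multiplier < 0:
                raise ValueError("planted multiplier must be >= 0")
            if any(not (1 <= r <= self.protein_length) for r in planted.residues):
                raise ValueError("planted residues outside protein length")

    @property
    def protein_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(self.n_proteins)]

    @property
    def n_coding(self) -> float:
        return 3.0 * self.protein_length

    @property
    def e_in_frame_true(self) -> float:
        """True expected in-frame events per sample over one gene."""
        return self.n_coding * self.a_missense * (
            self.mu_snv + self.alpha_indel_inframe * self.mu_indel
        )

    @property
    def e_lof_true(self) -> float:
        return self.n_coding * (self.a_nonsense + self.a_splice) * (
            self.mu_snv + (1 - self.alpha_indel_inframe) * self.mu_indel
        )


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def _backbone(length: int, spacing: float, offset=(0.0, 0.0, 0.0)) -> np.ndarray:
    coords = np.zeros((length, 3))
    coords[:, 0] = spacing * np.arange(length)
    return coords + np.asarray(offset)


def _chain(protein_id: str, coords: np.ndarray) -> list[MappedResidue]:
    return [
        MappedResidue(protein_id, i + 1, coords[i].reshape(1, 3))
        for i in range(len(coords))
    ]


def synth_structurome(
    spec: SyntheticSpec,
) -> tuple[list[StructureSnapshot], list[StructureSnapshot], InterfaceAnnotation]:
    """Predicted snapshots (one per protein), experimental two-chain
    snapshots (one per interface pair) and interface annotations.

    Interface annotations mirror the experimental contact patches at
    "very high" confidence.
    """
    predicted = []
    for protein in spec.protein_ids:
        coords = _backbone(spec.protein_length, spec.backbone_spacing)
        predicted.append(
            StructureSnapshot(f"AF-{protein}", {"A": _chain(protein, coords)})
        )
    experimental = []
    annotation = InterfaceAnnotation()
    for pair in spec.interface_pairs:
        coords_a = _backbone(spec.protein_length, spec.backbone_spacing)
        # chain B sits far from chain A except at the designated patch,
        # where matching residue ranks are brought within the 9 A cutoff
        coords_b = _backbone(
            spec.protein_length, spec.backbone_spacing, offset=(0, spec.far_gap, 0)
        )
        for ra, rb in zip(sorted(pair.patch_a), sorted(pair.patch_b)):
            coords_b[rb - 1, 0] = coords_a[ra - 1, 0]
            coords_b[rb - 1, 1] = spec.contact_gap
        experimental.append(
            StructureSnapshot(
                f"XTAL-{pair.protein_a}-{pair.protein_b}",
                {
                    "A": _chain(pair.protein_a, coords_a),
                    "B": _chain(pair.protein_b, coords_b),
                },
            )
        )
        for r in pair.patch_a:
            annotation.add(pair.protein_a, pair.protein_b, pair.protein_a, r)
        for r in pair.patch_b:
            annotation.add(pair.protein_a, pair.protein_b, pair.protein_b, r)
    return predicted, experimental, annotation


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _sample_ids(spec: SyntheticSpec) -> list[str]:
    return [f"S{i:05d}" for i in range(spec.n_samples)]


def synth_cohort(
    spec: SyntheticSpec,
) -> tuple[list[MutationRecord], pd.DataFrame, pd.DataFrame]:
    """Mutation records, expression table and covariate/coverage table.

    In-frame events are missense point mutations drawn per residue as
    Poisson with the spec's background rate times any planted multiplier;
    LOF events are nonsense mutations at uniform positions. Background
    (silent/noncoding) counts are drawn from the same per-base rates and
    reported pre-counted in the covariate table, alongside the A_t
    probabilities, coverage and five covariates.
    """
    rng = np.random.default_rng(spec.seed)
    samples = _sample_ids(spec)
    multipliers: dict[tuple[str, int], float] = {}
    for planted in spec.planted_clusters:
        for r in planted.residues:
            multipliers[(planted.protein_id, r)] = planted.multiplier

    records: list[MutationRecord] = []
    per_residue_rate = spec.e_in_frame_true / spec.protein_length
    for protein in spec.protein_ids:
        rates = np.full(spec.protein_length, per_residue_rate)
        for r in range(1, spec.protein_length + 1):
            mult = multipliers.get((protein, r))
            if mult is not None:
                rates[r - 1] *= mult
        counts = rng.poisson(rates * spec.n_samples)
        for r_idx in np.flatnonzero(counts):
            k = int(counts[r_idx])
            chosen = rng.choice(spec.n_samples, size=min(k, spec.n_samples),
                                replace=False)
            for s in chosen:
                records.append(
                    MutationRecord(
                        sample_id=samples[int(s)],
                        cancer_type=spec.cancer_type,
                        gene_id=protein,
                        protein_id=protein,
                        residue_start=int(r_idx) + 1,
                        residue_end=int(r_idx) + 1,
                        consequence_term="missense_variant",
                        consequence_class=IN_FRAME,
                        population_af=0.0,
                    )
                )
        lof_rate = spec.e_lof_true * spec.n_samples
        lof_rate *= spec.planted_lof.get(protein, 1.0)
        n_lof = int(rng.poisson(lof_rate))
        for _ in range(n_lof):
            pos = int(rng.integers(1, spec.protein_length + 1))
            s = int(rng.integers(0, spec.n_samples))
            records.append(
                MutationRecord(
                    sample_id=samples[s],
                    cancer_type=spec.cancer_type,
                    gene_id=protein,
                    protein_id=protein,
                    residue_start=pos,
                    residue_end=pos,
                    consequence_term="stop_gained",
                    consequence_class=LOF,
                    population_af=0.0,
                )
            )

    expression = _synth_expression(spec, rng)
    covariates = _synth_covariates(spec, rng)
    return records, expression, covariates


def _synth_expression(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    unexpressed = set(spec.unexpressed_genes)
    for gene in spec.protein_ids:
        for s in range(spec.n_expression_samples):
            if gene in unexpressed:
                fpkm = float(rng.uniform(0.0, 0.5))
            else:
                fpkm = float(rng.uniform(2.0, 50.0))
            rows.append((gene, spec.cancer_type, f"R{s:04d}", fpkm))
    return pd.DataFrame(rows, columns=["gene", "cancer_type", "sample", "fpkm"])


def _synth_covariates(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    genes = spec.protein_ids
    n = len(genes)
    covered = spec.n_coding  # silent/noncoding opportunity == coding footprint
    x_snv = rng.poisson(spec.mu_snv * covered * spec.n_samples, size=n)
    x_indel = rng.poisson(spec.mu_indel * covered * spec.n_samples, size=n)
    return pd.DataFrame(
        {
            "gene": genes,
            "expression": rng.normal(5.0, 1.0, size=n),
            "replication_timing": rng.normal(0.0, 1.0, size=n),
            "chromatin_compartment": rng.normal(0.0, 1.0, size=n),
            "gc_content": rng.uniform(0.35, 0.65, size=n),
            "gene_density": rng.uniform(0.0, 1.0, size=n),
            "N_coding": np.full(n, spec.n_coding),
            "A_missense": np.full(n, spec.a_missense),
            "A_nonsense": np.full(n, spec.a_nonsense),
            "A_splice": np.full(n, spec.a_splice),
            "covered_bases_snv": np.full(n, covered),
            "covered_bases_indel": np.full(n, covered),
            "x_snv": x_snv,
            "x_indel": x_indel,
        }
    )


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def synth_network(spec: SyntheticSpec) -> list[tuple[str, str]]:
    """Seeded Erdos-Renyi edge list over the spec's proteins with planted
    cliques; simple and self-loop-free by construction."""
    rng = np.random.default_rng(spec.seed + 1)
    proteins = spec.protein_ids
    edges: set[tuple[str, str]] = set()
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            if rng.random() < spec.edge_probability:
                edges.add((proteins[i], proteins[j]))
    for clique in spec.planted_cliques:
        members = sorted(clique)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                edges.add((members[i], members[j]))
    return sorted(edges)


# ---------------------------------------------------------------------------
# file output (a complete, immediately runnable input directory)
# ---------------------------------------------------------------------------

def _write_pdb(path: Path, snapshot: StructureSnapshot) -> None:
    import gemmi

    st = gemmi.Structure()
    st.name = snapshot.structure_id
    model = gemmi.Model("1")
    for chain_name, residues in snapshot.chains.items():
        chain = gemmi.Chain(chain_name)
        for rank, res in enumerate(residues, start=1):
            residue = gemmi.Residue()
            residue.name = "ALA"
            residue.seqid = gemmi.SeqId(rank, " ")
            for coord in res.coords:
                atom = gemmi.Atom()
                atom.name = "CA"
                atom.element = gemmi.Element("C")
                atom.occ = 1.0
                atom.pos = gemmi.Position(*coord)
                residue.add_atom(atom)
            chain.add_residue(residue)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_input_dir(spec: SyntheticSpec, outdir: str | Path) -> Path:
    """Write mutations, network, expression, covariates, structures, residue
    mapping, interface annotations and protein metadata under ``outdir``."""
    outdir = Path(outdir)
    (outdir / "structures" / "predicted").mkdir(parents=True, exist_ok=True)
    (outdir / "structures" / "experimental").mkdir(parents=True, exist_ok=True)

    records, expression, covariates = synth_cohort(spec)
    predicted, experimental, annotation = synth_structurome(spec)

    maf = pd.DataFrame(
        {
            "Hugo_Symbol": [r.gene_id for r in records],
            "Tumor_Sample_Barcode": [r.sample_id for r in records],
            "Cancer_Type": [r.cancer_type for r in records],
            "SWISSPROT": [r.protein_id for r in records],
            "Protein_position": [
                f"{r.residue_start}-{r.residue_end}"
                if r.residue_end > r.residue_start
                else str(r.residue_start)
                for r in records
            ],
            "Consequence": [r.consequence_term for r in records],
            "gnomADe_AF": [r.population_af for r in records],
        }
    )
    maf.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    covariates.to_csv(outdir / "covariates.tsv", sep="\t", index=False)

    with open(outdir / "network.tsv", "w") as fh:
        for u, v in synth_network(spec):
            fh.write(f"{u}\t{v}\n")

    with open(outdir / "proteins.tsv", "w") as fh:
        fh.write("protein_id\tlength\tgenes\n")
        for protein in spec.protein_ids:
            fh.write(f"{protein}\t{spec.protein_length}\t{protein}\n")

    mapping_rows = []
    for group, snaps in (("predicted", predicted), ("experimental", experimental)):
        for snap in snaps:
            _write_pdb(
                outdir / "structures" / group / f"{snap.structure_id}.pdb", snap
            )
    for snap in predicted + experimental:
        for chain_name, residues in snap.chains.items():
            for rank, res in enumerate(residues, start=1):
                mapping_rows.append(
                    (snap.structure_id, chain_name, rank,
                     res.protein_id, res.residue_index)
                )
    with open(outdir / "mapping.tsv", "w") as fh:
        for row in mapping_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    with open(outdir / "interfaces.tsv", "w") as fh:
        for key in sorted(annotation.pairs, key=sorted):
            a, b = sorted(key)
            sides = annotation.pairs[key]
            for protein in (a, b):
                for residue in sorted(sides.get(protein, ())):
                    fh.write(f"{a}\t{b}\t{protein}\t{residue}\tvery high\n")

    with open(outdir / "spec.yaml", "w") as fh:
        import yaml

        fh.write(yaml.safe_dump(spec_to_dict(spec), sort_keys=True))
    return outdir


def spec_to_dict(spec: SyntheticSpec) -> dict:
    return {
        "seed": spec.seed,
        "n_proteins": spec.n_proteins,
        "protein_length": spec.protein_length,
        "n_samples": spec.n_samples,
        "cancer_type": spec.cancer_type,
        "mu_snv": spec.mu_snv,
        "mu_indel": spec.mu_indel,
        "alpha_indel_inframe": spec.alpha_indel_inframe,
        "a_missense": spec.a_missense,
        "a_nonsense": spec.a_nonsense,
        "a_splice": spec.a_splice,
        "backbone_spacing": spec.backbone_spacing,
        "contact_gap": spec.contact_gap,
        "far_gap": spec.far_gap,
        "edge_probability": spec.edge_probability,
        "n_expression_samples": spec.n_expression_samples,
        "unexpressed_genes": list(spec.unexpressed_genes),
        "planted_clusters": [
            {"protein_id": p.protein_id, "residues": list(p.residues),
             "multiplier": p.multiplier}
            for p in spec.planted_clusters
        ],
        "planted_lof": dict(spec.planted_lof),
        "interface_pairs": [
            {"protein_a": p.protein_a, "protein_b": p.protein_b,
             "patch_a": list(p.patch_a), "patch_b": list(p.patch_b)}
            for p in spec.interface_pairs
        ],
        "planted_cliques": [list(c) for c in spec.planted_cliques],
    }


def spec_from_dict(data: dict) -> SyntheticSpec:
    data = dict(data)
    data["planted_clusters"] = tuple(
        PlantedCluster(d["protein_id"], tuple(d["residues"]), d["multiplier"])
        for d in data.get("planted_clusters", [])
    )
    data["interface_pairs"] = tuple(
        InterfacePair(d["protein_a"], d["protein_b"],
                      tuple(d["patch_a"]), tuple(d["patch_b"]))
        for d in data.get("interface_pairs", [])
    )
    data["planted_cliques"] = tuple(
        tuple(c) for c in data.get("planted_cliques", [])
    )
    data["unexpressed_genes"] = tuple(data.get("unexpressed_genes", []))
    return SyntheticSpec(**data)


def spec_from_yaml(path: str | Path) -> SyntheticSpec:
    import yaml

    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))
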