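"""End-to-end orchestration: preprocess -> structurome -> clusters ->
background -> significance -> propagation."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from . import background as bg
from . import clustering, propagation, significance
from .io_preprocess import (
    ExpressionTable,
    MutationRecord,
    filter_expression,
    filter_germline,
)
from .structurome import ContactGraph, InterfaceAnnotation, StructureSnapshot
from .structurome import (
    build_inter_contact_graph,
    build_intra_contact_graph,
    build_predicted_graph,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    records: list[MutationRecord]
    n_samples: int
    clusters: list[clustering.Cluster3D]
    lof_table: dict[str, tuple[float, float, bool]]
    protein_backgrounds: dict[str, bg.ProteinBackground]
    diffusion: Optional[propagation.DiffusionResult]
    driver_mutations: dict[str, list] = field(default_factory=dict)

    @property
    def significant_clusters(self) -> list[clustering.Cluster3D]:
        return [c for c in self.clusters if c.significant]


def build_clusters(
    mutated: clustering.MutatedResidueSet,
    g1: Optional[ContactGraph],
    g2: Optional[ContactGraph],
    g3: Optional[ContactGraph],
    interfaces: Optional[InterfaceAnnotation],
    ppis: Sequence,
) -> list[clustering.Cluster3D]:
    """All four cluster families with the predicted-vs-experimental dedup."""
    c1 = clustering.intra_clusters(g1, mutated) if g1 is not None else []
    c3 = clustering.intra_clusters(g3, mutated) if g3 is not None else []
    c3 = clustering.dedupe_predicted(c3, c1)
    c2 = (
        clustering.inter_clusters(g1, g2, mutated, ppis)
        if g1 is not None and g2 is not None
        else []
    )
    c4 = (
        clustering.interface_clusters(interfaces, mutated, ppis)
        if interfaces is not None
        else []
    )
    return c1 + c2 + c3 + c4


def run(
    records: Sequence[MutationRecord],
    network: nx.Graph,
    protein_lengths: Mapping[str, int],
    protein_to_genes: Mapping[str, Sequence[str]],
    covariates: pd.DataFrame,
    config: propagation.HeatConfig,
    predicted_snapshots: Sequence[StructureSnapshot] = (),
    experimental_snapshots: Sequence[StructureSnapshot] = (),
    interfaces: Optional[InterfaceAnnotation] = None,
    expression: Optional[ExpressionTable] = None,
    n_samples: Optional[int] = None,
    alpha_indel: float = bg.DEFAULT_ALPHA,
    alpha_level: float = significance.DEFAULT_ALPHA_LEVEL,
    baseline: bool = False,
    run_propagation: bool = True,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs.

    ``n_samples`` defaults to the number of distinct tumor samples among the
    preprocessed mutations. ``baseline`` switches heats and weights to the
    ablation mode (mutated-sample counts, unit weights) while keeping the
    diffusion and module stages unchanged.
    """
    records = filter_germline(records)
    if expression is not None:
        records = filter_expression(records, expression)
    if n_samples is None:
        n_samples = len({r.sample_id for r in records})
    if n_samples < 1:
        raise ValueError("empty cohort after preprocessing")

    mutated = clustering.expand_to_residues(records, protein_lengths)

    g1 = g2 = None
    if experimental_snapshots:
        g1 = build_intra_contact_graph(experimental_snapshots)
        g2 = build_inter_contact_graph(experimental_snapshots)
    g3 = build_predicted_graph(predicted_snapshots) if predicted_snapshots else None

    ppis = [frozenset((u, v)) for u, v in network.edges]
    clusters = build_clusters(mutated, g1, g2, g3, interfaces, ppis)

    model = bg.BackgroundModel(covariates, n_samples, alpha=alpha_indel)
    gene_backgrounds = model.fit()
    protein_backgrounds = bg.compute_protein_backgrounds(
        protein_lengths, protein_to_genes, gene_backgrounds
    )

    significance.score_clusters(
        clusters, protein_backgrounds, n_samples, alpha_level
    )
    lof_counts = significance.count_lof_events(records)
    lof_table = significance.lof_enrichment_table(
        lof_counts, protein_backgrounds, n_samples, alpha_level
    )

    diffusion = None
    drivers: dict[str, list] = {}
    if run_propagation:
        net = propagation.drop_isolated(network)
        if baseline:
            heats, weights = propagation.baseline_configuration(net, records)
        else:
            heats = propagation.heats_from_scores(
                net.nodes,
                clusters,
                {p: v[0] for p, v in lof_table.items()},
                config.score_cap,
            )
            weights = propagation.weights_from_scores(
                net, clusters, config.w0, config.score_cap
            )
        diffusion = propagation.diffuse_and_identify(net, heats, weights, config)
        drivers = propagation.extract_driver_mutations(
            diffusion.significant_modules, clusters, net
        )

    return PipelineResult(
        records=list(records),
        n_samples=n_samples,
        clusters=clusters,
        lof_table=lof_table,
        protein_backgrounds=protein_backgrounds,
        diffusion=diffusion,
        driver_mutations=drivers,
    )


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def _format_mutation(m: MutationRecord) -> str:
    pos = (
        f"{m.residue_start}-{m.residue_end}"
        if m.residue_end > m.residue_start
        else str(m.residue_start)
    )
    return f"{m.sample_id}@{m.protein_id}:{pos}:{m.consequence_term}"


def cluster_table(clusters: Sequence[clustering.Cluster3D]) -> pd.DataFrame:
    rows = []
    for c in sorted(clusters, key=lambda c: (c.source, c.cluster_id)):
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "source": c.source,
                "proteins": ",".join(c.proteins),
                "residues": ";".join(
                    f"{p}:" + "|".join(str(r) for r in sorted(rs))
                    for p, rs in sorted(c.residues.items())
                ),
                "ppi": ",".join(sorted(c.ppi)) if c.ppi else "",
                "O_C": c.observed,
                "E_C": c.expected,
                "p_raw": c.p_raw,
                "p_adjusted": c.p_adjusted,
                "significant": bool(c.significant),
                "mutations": ";".join(_format_mutation(m) for m in c.mutations),
            }
        )
    return pd.DataFrame(rows)


def lof_table_frame(lof_table: Mapping[str, tuple[float, float, bool]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"protein_id": p, "p_raw": v[0], "p_adjusted": v[1],
             "significant": v[2]}
            for p, v in sorted(lof_table.items())
        ]
    )


def module_table(diffusion: propagation.DiffusionResult) -> pd.DataFrame:
    rows = []
    sig = set(map(frozenset, diffusion.significant_modules))
    for idx, module in enumerate(diffusion.modules):
        rows.append(
            {
                "module_id": f"M{idx:04d}",
                "size": len(module),
                "significant": frozenset(module) in sig,
                "proteins": ",".join(sorted(module)),
            }
        )
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, outdir: str | Path,
                  config: propagation.HeatConfig) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cluster_table(result.clusters).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False
    )
    lof_table_frame(result.lof_table).to_csv(
        outdir / "lof_enrichment.tsv", sep="\t", index=False
    )
    summary = {
        "n_samples": result.n_samples,
        "n_mutations": len(result.records),
        "n_clusters": len(result.clusters),
        "n_significant_clusters": len(result.significant_clusters),
        "beta": config.beta,
        "w0": config.w0,
        "score_cap": config.score_cap,
        "seed": config.rng_seed,
        "family_sizes": {
            "structure": sum(
                1 for c in result.clusters
                if c.source in clustering.STRUCTURE_FAMILY
            ),
            "interface": sum(
                1 for c in result.clusters
                if c.source in clustering.INTERFACE_FAMILY
            ),
        },
    }
    if result.diffusion is not None:
        module_table(result.diffusion).to_csv(
            outdir / "modules.tsv", sep="\t", index=False
        )
        node_order = result.diffusion.node_order
        E = result.diffusion.exchanged_heat
        delta = result.diffusion.delta
        with open(outdir / "exchanged_heat.tsv", "w") as fh:
            fh.write("source\ttarget\texchanged_heat\n")
            import numpy as np

            rows_i, cols_j = np.nonzero(E > delta)
            for i, j in zip(rows_i, cols_j):
                if i != j:
                    fh.write(f"{node_order[j]}\t{node_order[i]}\t{E[i, j]!r}\n")
        with open(outdir / "driver_mutations.tsv", "w") as fh:
            fh.write("provenance\tmutation\n")
            for key in sorted(result.driver_mutations):
                for m in result.driver_mutations[key]:
                    fh.write(f"{key}\t{_format_mutation(m)}\n")
        summary["delta"] = delta
        summary["n_modules"] = len(result.diffusion.modules)
        summary["n_significant_modules"] = len(result.diffusion.significant_modules)
        summary["significant_module_sizes"] = [
            len(m) for m in result.diffusion.significant_modules
        ]
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
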