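"""Input readers, consequence classification and cohort-defining filters.

The analysis cohort is defined by three steps applied to a MAF-like,
VEP-consequence-annotated mutation table that has already been mapped to
UniProt accessions and 1-based protein residue coordinates:

1. consequence classification (in-frame / loss-of-function / background /
   excluded),
2. a germline filter removing variants seen at non-zero population allele
   frequency,
3. an expression filter removing mutations in genes not expressed in the
   mutation's cancer type (>=1 FPKM in >=80% of that type's tumor samples),
   with a fixed exemption list of cancer genes with low transcript detection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN_CANCER_TYPE = "UNKNOWN"

#: consequence classes
IN_FRAME = "in_frame"
LOF = "lof"
BACKGROUND = "background"
EXCLUDED = "excluded"

IN_FRAME_TERMS = frozenset(
    {"missense_variant", "inframe_deletion", "inframe_insertion"}
)

LOF_TERMS = frozenset(
    {
        "frameshift_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "splice_donor_5th_base_variant",
    }
)

#: silent and noncoding terms usable for background-rate estimation
BACKGROUND_TERMS = frozenset(
    {
        "synonymous_variant",
        "stop_retained_variant",
        "start_retained_variant",
        "5_prime_UTR_variant",
        "3_prime_UTR_variant",
        "intron_variant",
        "upstream_gene_variant",
        "downstream_gene_variant",
        "intergenic_variant",
        "non_coding_transcript_variant",
        "non_coding_transcript_exon_variant",
    }
)

#: well-known cancer genes with low transcript detection levels, exempted
#: from the RNA expression filter
EXPRESSION_EXEMPT_GENES = frozenset(
    {
        "AR", "CDH4", "EGFR", "EPHA3", "ERBB4", "FGFR2", "FLT3", "FOXA1",
        "FOXA2", "MECOM", "MIR142", "MSH4", "PDGFRA", "SOX1", "SOX9",
        "SOX17", "TBX3", "WT1",
    }
)


@dataclass(frozen=True)
class MutationRecord:
    """One somatic protein-altering mutation in protein coordinates."""

    sample_id: str
    cancer_type: str
    gene_id: str
    protein_id: str
    residue_start: int
    residue_end: int
    consequence_term: str
    consequence_class: str
    population_af: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.residue_start <= self.residue_end):
            raise ValueError(
                f"invalid residue range {self.residue_start}-{self.residue_end}"
            )
        if self.population_af is not None and not (0.0 <= self.population_af <= 1.0):
            raise ValueError(f"population_af out of [0,1]: {self.population_af}")


def classify_consequence(term: str) -> str:
    """Map a VEP consequence term to its analysis class.

    Compound annotations (``a&b`` or ``a,b``) are classified by the highest
    priority constituent: loss-of-function > in-frame > background. Unknown
    terms map to ``excluded``; the function is total.
    """
    parts = [p.strip() for p in term.replace("&", ",").split(",") if p.strip()]
    if any(p in LOF_TERMS for p in parts):
        return LOF
    if any(p in IN_FRAME_TERMS for p in parts):
        return IN_FRAME
    if any(p in BACKGROUND_TERMS for p in parts):
        return BACKGROUND
    return EXCLUDED


#: default column mapping, matching MC3/VEP MAF headers
DEFAULT_MUTATION_COLUMNS: Mapping[str, str] = {
    "sample": "Tumor_Sample_Barcode",
    "cancer_type": "Cancer_Type",
    "gene": "Hugo_Symbol",
    "protein": "SWISSPROT",
    "position": "Protein_position",
    "consequence": "Consequence",
    "allele_frequency": "gnomADe_AF",
}


class MutationParseError(ValueError):
    """Raised in strict mode for unparseable mutation rows."""


def _parse_position(raw: str) -> tuple[int, int]:
    """Parse a protein position like ``42``, ``10-12`` or VEP's ``42/500``."""
    text = str(raw).strip().split("/")[0]
    if "-" in text:
        lo, hi = text.split("-", 1)
    else:
        lo = hi = text
    start, end = int(lo), int(hi)
    if not (1 <= start <= end):
        raise ValueError(f"invalid 1-based residue range {raw!r}")
    return start, end


def read_mutations(
    path: str | Path,
    columns: Optional[Mapping[str, str]] = None,
    strict: bool = False,
) -> list[MutationRecord]:
    """Read a tab-delimited MAF-like mutation table.

    Rows failing validation are skipped with a row-numbered log message
    (permissive default) or raise :class:`MutationParseError` when
    ``strict=True``. Exact duplicates under the key
    (sample, protein, start, end, term) are collapsed to one record.
    """
    cols = dict(DEFAULT_MUTATION_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["sample", "protein", "position", "consequence"]
    missing = [cols[k] for k in required if cols[k] not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing required column(s): {missing}")

    has_ct = cols["cancer_type"] in df.columns
    has_gene = cols["gene"] in df.columns
    has_af = cols["allele_frequency"] in df.columns

    records: dict[tuple, MutationRecord] = {}
    n_skipped = 0
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        try:
            start, end = _parse_position(row[cols["position"]])
            term = str(row[cols["consequence"]]).strip()
            af_raw = row.get(cols["allele_frequency"]) if has_af else None
            af = None
            if af_raw is not None and str(af_raw).strip() not in ("", ".", "nan", "NA"):
                af = float(af_raw)
            rec = MutationRecord(
                sample_id=str(row[cols["sample"]]).strip(),
                cancer_type=(
                    str(row[cols["cancer_type"]]).strip()
                    if has_ct and not pd.isna(row[cols["cancer_type"]])
                    else UNKNOWN_CANCER_TYPE
                ),
                gene_id=str(row[cols["gene"]]).strip() if has_gene else "",
                protein_id=str(row[cols["protein"]]).strip(),
                residue_start=start,
                residue_end=end,
                consequence_term=term,
                consequence_class=classify_consequence(term),
                population_af=af,
            )
        except (ValueError, KeyError) as exc:
            if strict:
                raise MutationParseError(f"row {rownum}: {exc}") from exc
            logger.warning("skipping mutation row %d: %s", rownum, exc)
            n_skipped += 1
            continue
        key = (rec.sample_id, rec.protein_id, rec.residue_start,
               rec.residue_end, rec.consequence_term)
        records.setdefault(key, rec)
    if n_skipped:
        logger.info("skipped %d malformed mutation rows", n_skipped)
    return list(records.values())


def filter_germline(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    """Drop mutations observed at non-zero population allele frequency.

    A missing allele frequency means the variant was not seen in the
    population resource, so the record is kept.
    """
    return [r for r in records
            if r.population_af is None or r.population_af == 0.0]


@dataclass
class ExpressionTable:
    """Per (gene, cancer type, sample) FPKM values in long format."""

    data: pd.DataFrame  # columns: gene, cancer_type, sample, fpkm
    fpkm_threshold: float = 1.0
    sample_fraction: float = 0.8

    _expressed: dict[tuple[str, str], bool] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        need = {"gene", "cancer_type", "sample", "fpkm"}
        if not need.issubset(self.data.columns):
            raise ValueError(f"expression table needs columns {sorted(need)}")
        if (self.data["fpkm"] < 0).any():
            raise ValueError("negative FPKM value in expression table")
        df = self.data
        n_samples = df.groupby("cancer_type")["sample"].nunique()
        hits = (
            df[df["fpkm"] >= self.fpkm_threshold]
            .groupby(["gene", "cancer_type"])["sample"]
            .nunique()
        )
        frac = hits / hits.index.get_level_values("cancer_type").map(n_samples)
        self._expressed = (frac >= self.sample_fraction).to_dict()
        self._cancer_types = sorted(n_samples.index)

    @property
    def cancer_types(self) -> list[str]:
        return list(self._cancer_types)

    def is_expressed(self, gene: str, cancer_type: str) -> bool:
        """Whether ``gene`` meets the expression criterion in ``cancer_type``.

        For unknown cancer types the gene must be expressed in >=80% of the
        cancer types present in the table. Genes absent from the table are
        unexpressed.
        """
        if cancer_type == UNKNOWN_CANCER_TYPE:
            if not self._cancer_types:
                return False
            n_ok = sum(
                self._expressed.get((gene, ct), False) for ct in self._cancer_types
            )
            return n_ok / len(self._cancer_types) >= self.sample_fraction
        return self._expressed.get((gene, cancer_type), False)

    def expressed_anywhere(self, gene: str) -> bool:
        return any(self._expressed.get((gene, ct), False) for ct in self._cancer_types)


def read_expression(path: str | Path, **kwargs) -> ExpressionTable:
    """Read a long-format expression table (gene, cancer_type, sample, fpkm)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "cancer_type": str, "sample": str})
    df["fpkm"] = df["fpkm"].astype(float)
    return ExpressionTable(df, **kwargs)


def filter_expression(
    records: Iterable[MutationRecord],
    expression: ExpressionTable,
    exempt_genes: frozenset[str] | set[str] = EXPRESSION_EXEMPT_GENES,
) -> list[MutationRecord]:
    """Keep mutations whose gene is expressed in the mutation's cancer type.

    Exempt genes always pass. Genes absent from the expression table are
    treated as unexpressed and logged once.
    """
    kept = []
    dropped_genes: set[str] = set()
    for rec in records:
        if rec.gene_id in exempt_genes:
            kept.append(rec)
        elif expression.is_expressed(rec.gene_id, rec.cancer_type):
            kept.append(rec)
        else:
            dropped_genes.add(rec.gene_id)
    if dropped_genes:
        logger.info(
            "expression filter removed mutations in %d genes", len(dropped_genes)
        )
    return kept


def read_network(
    path: str | Path,
    expression: Optional[ExpressionTable] = None,
    exempt_genes: frozenset[str] | set[str] = EXPRESSION_EXEMPT_GENES,
) -> nx.Graph:
    """Read a two-column tab-delimited PPI edge list into a simple graph.

    Self-loops and duplicate edges (in either order) are dropped with
    counts logged. When an expression table is supplied, only edges whose
    endpoints are both expressed in at least one cancer type (or exempt)
    are retained.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2 or len(df) == 0:
        raise ValueError("network edge list is empty or not two-column")
    graph: nx.Graph = nx.Graph()
    n_self = n_dup = 0
    for a, b in zip(df[0], df[1]):
        a, b = str(a).strip(), str(b).strip()
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b)
    if n_self or n_dup:
        logger.info("network: dropped %d self-loops, %d duplicate edges", n_self, n_dup)
    if expression is not None:
        def ok(g: str) -> bool:
            return g in exempt_genes or expression.expressed_anywhere(g)

        drop = [(u, v) for u, v in graph.edges if not (ok(u) and ok(v))]
        graph.remove_edges_from(drop)
        graph.remove_nodes_from([n for n in list(graph) if graph.degree(n) == 0])
        if drop:
            logger.info("network: expression filter removed %d edges", len(drop))
    if graph.number_of_edges() == 0:
        raise ValueError("network has no edges after filtering")
    return graph
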