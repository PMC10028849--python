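"""Covariate-aware local background mutation model.

Each gene's background mutation rate (BMR) is estimated from its own silent
and noncoding mutations, pooled — when its own counts are too sparse — with
those of its nearest neighbors in a five-dimensional covariate space
(expression, replication timing, chromatin compartment, GC content, gene
density; z-scored, euclidean distance). Pooled rates are

    BMR_SNV   = sum(x_SNV)   / sum(X_SNV)
    BMR_indel = sum(x_indel) / sum(X_indel)

with x event counts and X opportunity in base*sample units (covered bases
times number of samples), so BMR is per base per sample. Per-gene expected
in-frame and loss-of-function (LOF) event counts per sample are

    E_in_frame = N_coding * A_missense * (BMR_SNV + alpha * BMR_indel)
    E_LOF      = N_coding * (A_nonsense + A_splice)
                          * (BMR_SNV + (1 - alpha) * BMR_indel)

where A_t is the probability that a random coding SNV in the gene is of
type t, and alpha is the fraction of coding indels that are in-frame
(default 0.09). Cohort-wide 1st-percentile floors guard against vanishing
local rates, and protein-level expectations sum over encoding genes with a
cohort-median default when no encoding gene has data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = [
    "expression",
    "replication_timing",
    "chromatin_compartment",
    "gc_content",
    "gene_density",
]

DEFAULT_ALPHA = 0.09
DEFAULT_MIN_SNV = 50
DEFAULT_MIN_INDEL = 10
DEFAULT_FLOOR_QUANTILE = 0.01


@dataclass
class GeneBackground:
    """Per-gene background counts, rates and expected event counts."""

    gene_id: str
    covariates: np.ndarray  # the 5 raw covariate values
    x_snv: float
    x_indel: float
    covered_bases_snv: float
    covered_bases_indel: float
    n_coding: float  # coding length in bp
    a_missense: float
    a_nonsense: float
    a_splice: float
    bmr_snv: float = 0.0
    bmr_indel: float = 0.0
    e_in_frame: float = 0.0  # expected in-frame events per sample, whole gene
    e_lof: float = 0.0
    pool: tuple[str, ...] = ()


@dataclass
class ProteinBackground:
    """Expected event counts per sample over a full protein."""

    protein_id: str
    length: int  # amino acids
    genes: tuple[str, ...]
    e_in_frame: float
    e_lof: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"protein {self.protein_id} has length {self.length}")
        if self.e_in_frame <= 0 or self.e_lof <= 0:
            raise ValueError(
                f"non-positive expected counts for {self.protein_id}"
            )


def read_covariate_table(path) -> pd.DataFrame:
    """Read the per-gene covariate/coverage table.

    Required columns: gene, the 5 covariates, N_coding, coverage and
    background counts. Mutation-type content may be given as fractional
    covered-base counts (N_missense, N_nonsense, N_splice) or directly as
    probabilities (A_missense, A_nonsense, A_splice).
    """
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError("covariate table needs a 'gene' column")
    return df


def _z_scores(values: np.ndarray) -> np.ndarray:
    """Column z-scores with median imputation; constant columns become 0."""
    values = np.array(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        bad = ~np.isfinite(col)
        if bad.any():
            med = np.nanmedian(np.where(np.isfinite(col), col, np.nan))
            col[bad] = med
            logger.info("imputed %d missing covariate values in column %d",
                        int(bad.sum()), j)
        values[:, j] = col
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    std[std == 0] = 1.0
    return (values - mean) / std


class BackgroundModel:
    """Holds the covariate space and per-gene counts for pooling."""

    def __init__(
        self,
        table: pd.DataFrame,
        n_samples: int,
        alpha: float = DEFAULT_ALPHA,
        min_snv: int = DEFAULT_MIN_SNV,
        min_indel: int = DEFAULT_MIN_INDEL,
        floor_quantile: float = DEFAULT_FLOOR_QUANTILE,
    ):
        if n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        self.n_samples = int(n_samples)
        self.alpha = float(alpha)
        self.min_snv = int(min_snv)
        self.min_indel = int(min_indel)
        self.floor_quantile = float(floor_quantile)

        self.genes: list[str] = [str(g) for g in table["gene"]]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene in covariate table")
        self._index = {g: i for i, g in enumerate(self.genes)}

        cov = np.column_stack(
            [table[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
        )
        self._z = _z_scores(cov)

        n_coding = table["N_coding"].to_numpy(dtype=float)
        if "A_missense" in table.columns:
            a_mis = table["A_missense"].to_numpy(dtype=float)
            a_non = table["A_nonsense"].to_numpy(dtype=float)
            a_spl = table["A_splice"].to_numpy(dtype=float)
        else:
            a_mis, a_non, a_spl = mutation_type_fractions_table(table)
        if np.any(n_coding <= 0):
            raise ValueError("N_coding must be positive for all genes")
        if np.any((a_mis < 0) | (a_non < 0) | (a_spl < 0)) or np.any(
            a_mis + a_non + a_spl > 1 + 1e-9
        ):
            raise ValueError("mutation-type probabilities must lie in [0,1] "
                             "and sum to at most 1")

        self.records: dict[str, GeneBackground] = {}
        for i, gene in enumerate(self.genes):
            self.records[gene] = GeneBackground(
                gene_id=gene,
                covariates=cov[i],
                x_snv=float(table["x_snv"].iloc[i]),
                x_indel=float(table["x_indel"].iloc[i]),
                covered_bases_snv=float(table["covered_bases_snv"].iloc[i]),
                covered_bases_indel=float(table["covered_bases_indel"].iloc[i]),
                n_coding=float(n_coding[i]),
                a_missense=float(a_mis[i]),
                a_nonsense=float(a_non[i]),
                a_splice=float(a_spl[i]),
            )

    # -- pooling -----------------------------------------------------------

    def neighbor_order(self, gene: str) -> list[str]:
        """All genes ordered by covariate-space distance to ``gene``.

        The gene itself comes first; ties break deterministically by
        gene id.
        """
        i = self._index[gene]
        dist = np.linalg.norm(self._z - self._z[i], axis=1)
        order = sorted(range(len(self.genes)),
                       key=lambda j: (j != i, dist[j], self.genes[j]))
        return [self.genes[j] for j in order]

    def neighbor_pool(self, gene: str) -> list[str]:
        """Smallest nearest-neighbor pool meeting the background-count minima.

        Expands outward from the gene itself until the pooled SNV and indel
        background counts reach their thresholds, or all genes are included.
        """
        pool: list[str] = []
        snv = indel = 0.0
        for g in self.neighbor_order(gene):
            pool.append(g)
            snv += self.records[g].x_snv
            indel += self.records[g].x_indel
            if snv >= self.min_snv and indel >= self.min_indel:
                break
        return pool

    def compute_bmr(self, pool: Sequence[str]) -> tuple[float, float]:
        """Pooled background rates (per base per sample) over a gene pool."""
        xs = sum(self.records[g].x_snv for g in pool)
        xi = sum(self.records[g].x_indel for g in pool)
        Xs = sum(self.records[g].covered_bases_snv for g in pool) * self.n_samples
        Xi = sum(self.records[g].covered_bases_indel for g in pool) * self.n_samples
        if Xs <= 0 or Xi <= 0:
            raise ValueError("pooled background opportunity is zero; "
                             "coverage input missing")
        return xs / Xs, xi / Xi

    # -- expected counts ---------------------------------------------------

    def expected_gene_counts(self, gene: str) -> tuple[float, float]:
        """Raw (un-floored) expected in-frame and LOF events per sample."""
        rec = self.records[gene]
        e_if = rec.n_coding * rec.a_missense * (
            rec.bmr_snv + self.alpha * rec.bmr_indel
        )
        e_lof = rec.n_coding * (rec.a_nonsense + rec.a_splice) * (
            rec.bmr_snv + (1 - self.alpha) * rec.bmr_indel
        )
        return e_if, e_lof

    def fit(self) -> dict[str, GeneBackground]:
        """Estimate all per-gene BMRs and floored expected counts."""
        for gene, rec in self.records.items():
            pool = self.neighbor_pool(gene)
            rec.pool = tuple(pool)
            rec.bmr_snv, rec.bmr_indel = self.compute_bmr(pool)
            rec.e_in_frame, rec.e_lof = self.expected_gene_counts(gene)
        for attr in ("e_in_frame", "e_lof"):
            values = np.array([getattr(r, attr) for r in self.records.values()])
            floor = float(np.quantile(values, self.floor_quantile))
            for rec in self.records.values():
                if getattr(rec, attr) < floor:
                    setattr(rec, attr, floor)
        return self.records

    def medians(self) -> tuple[float, float]:
        """Cohort medians of the per-gene expected counts (after flooring)."""
        e_if = float(np.median([r.e_in_frame for r in self.records.values()]))
        e_lof = float(np.median([r.e_lof for r in self.records.values()]))
        return e_if, e_lof


def mutation_type_fractions_table(table: pd.DataFrame):
    """A_t from fractional covered-base counts: A_t = N_t / N_coding."""
    n_coding = table["N_coding"].to_numpy(dtype=float)
    if np.any(n_coding <= 0):
        raise ValueError("N_coding must be positive")
    return (
        table["N_missense"].to_numpy(dtype=float) / n_coding,
        table["N_nonsense"].to_numpy(dtype=float) / n_coding,
        table["N_splice"].to_numpy(dtype=float) / n_coding,
    )


def mutation_type_fractions(
    per_base_counts: Iterable[tuple[float, float, float]],
) -> tuple[dict[str, float], dict[str, float], float]:
    """Aggregate a per-base substitution consequence table for one gene.

    Each element gives, for one covered coding base, the number of its three
    possible substitutions that are (missense, nonsense, splice-site); the
    remainder is silent. One base may contribute fractionally to multiple
    types (e.g. 2/3 missense, 1/3 nonsense). Returns the fractional
    covered-base counts N_t, the probabilities A_t = N_t / N_coding, and
    N_coding (the number of covered coding bases).
    """
    n = {"missense": 0.0, "nonsense": 0.0, "splice site": 0.0}
    n_coding = 0
    for mis, non, spl in per_base_counts:
        if mis + non + spl > 3:
            raise ValueError("a base has only 3 possible substitutions")
        n["missense"] += mis / 3.0
        n["nonsense"] += non / 3.0
        n["splice site"] += spl / 3.0
        n_coding += 1
    if n_coding == 0:
        raise ValueError("gene has no covered coding bases")
    a = {t: v / n_coding for t, v in n.items()}
    return n, a, float(n_coding)


def background_counts_from_records(
    records, genes: Iterable[str]
) -> dict[str, tuple[int, int]]:
    """Count background-class mutation events per gene from a record list.

    SNV-like background events are single-position records; multi-position
    background records are counted as indels.
    """
    from .io_preprocess import BACKGROUND

    counts = {g: [0, 0] for g in genes}
    for rec in records:
        if rec.consequence_class != BACKGROUND or rec.gene_id not in counts:
            continue
        if rec.residue_end > rec.residue_start:
            counts[rec.gene_id][1] += 1
        else:
            counts[rec.gene_id][0] += 1
    return {g: (c[0], c[1]) for g, c in counts.items()}


def expected_protein_counts(
    protein_id: str,
    length: int,
    encoding_genes: Sequence[str],
    gene_backgrounds: Mapping[str, GeneBackground],
    medians: tuple[float, float],
) -> ProteinBackground:
    """Protein-level expected counts: sum over encoding genes, median default.

    When none of the encoding genes has background data, the cohort medians
    of the per-gene expected counts stand in.
    """
    present = [g for g in encoding_genes if g in gene_backgrounds]
    if present:
        e_if = sum(gene_backgrounds[g].e_in_frame for g in present)
        e_lof = sum(gene_backgrounds[g].e_lof for g in present)
    else:
        e_if, e_lof = medians
    return ProteinBackground(
        protein_id=protein_id,
        length=int(length),
        genes=tuple(present),
        e_in_frame=e_if,
        e_lof=e_lof,
    )


def compute_protein_backgrounds(
    protein_lengths: Mapping[str, int],
    protein_to_genes: Mapping[str, Sequence[str]],
    gene_backgrounds: Mapping[str, GeneBackground],
) -> dict[str, ProteinBackground]:
    e_if_med = float(np.median([r.e_in_frame for r in gene_backgrounds.values()]))
    e_lof_med = float(np.median([r.e_lof for r in gene_backgrounds.values()]))
    out = {}
    for protein, length in protein_lengths.items():
        out[protein] = expected_protein_counts(
            protein,
            length,
            protein_to_genes.get(protein, ()),
            gene_backgrounds,
            (e_if_med, e_lof_med),
        )
    return out
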