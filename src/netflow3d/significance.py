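"""Poisson recurrence tests for 3D clusters and protein-level LOF enrichment.

A cluster of k mutated residues on protein u has expected in-frame count

    E_C = E_u^in-frame * (k / l_u) * n_p                  (intra-protein)
    E_C = (E_u * k_u / l_u + E_v * k_v / l_v) * n_p       (inter-protein)

over n_p tumor samples, and its significance is the one-sided Poisson
upper tail P(X >= O_C). Bonferroni correction is applied separately to the
structure-derived family (C1 u C2 u C3) and the interface family (C4).
Protein-level LOF enrichment uses the same test with mean E_u^LOF * n_p.

Raw p-values are carried forward to the network-propagation stage; adjusted
p-values set the significance flags only.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

from scipy.stats import poisson

from .background import ProteinBackground
from .clustering import Cluster3D, INTERFACE_FAMILY, STRUCTURE_FAMILY

#: floor applied when logging p-values; the heat cap makes smaller values moot
P_FLOOR = 1e-300

DEFAULT_ALPHA_LEVEL = 0.05


def _log_space_upper_tail(observed: int, expected: float) -> float:
    """Tail series evaluated in log space for extreme (O >> E) inputs.

    P(X >= O) = e^-E E^O/O! * sum_{k>=0} E^k / prod_{i<=k}(O+i); the leading
    term is computed via logarithms so results survive down to the subnormal
    floating-point range.
    """
    log_lead = -expected + observed * math.log(expected) - math.lgamma(
        observed + 1
    )
    total = term = 1.0
    k = 1
    while True:
        term *= expected / (observed + k)
        total += term
        if term <= total * 1e-20:
            break
        k += 1
    return math.exp(log_lead + math.log(total))


def poisson_upper_tail(observed: int, expected: float) -> float:
    """One-sided Poisson p-value P(X >= observed) at mean ``expected``.

    Exactly 1 for observed == 0. Computed via the regularized incomplete
    gamma survival function, with a log-space series fallback when the
    tail is so small that the gamma route underflows.
    """
    if expected <= 0:
        raise ValueError(f"Poisson mean must be positive, got {expected}")
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    if observed == 0:
        return 1.0
    p = float(poisson.sf(observed - 1, expected))
    if p < 1e-280:  # near/below the gamma implementation's underflow point
        p = _log_space_upper_tail(observed, expected)
    return p


def cluster_expected_count(
    cluster: Cluster3D,
    backgrounds: Mapping[str, ProteinBackground],
    n_samples: int,
) -> float:
    """Expected in-frame mutation count E_C of a cluster over the cohort."""
    total = 0.0
    for protein, residues in cluster.residues.items():
        bg = backgrounds[protein]
        total += bg.e_in_frame * len(residues) / bg.length
    return total * n_samples


def bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def score_clusters(
    clusters: Sequence[Cluster3D],
    backgrounds: Mapping[str, ProteinBackground],
    n_samples: int,
    alpha_level: float = DEFAULT_ALPHA_LEVEL,
) -> list[Cluster3D]:
    """Attach E_C, raw and family-Bonferroni-adjusted p-values in place.

    The correction factor m for a cluster counts all tested clusters in its
    family (structure-derived C1/C2/C3 vs interface C4); no pre-filtering
    by cluster size.
    """
    families = {
        "structure": [c for c in clusters if c.source in STRUCTURE_FAMILY],
        "interface": [c for c in clusters if c.source in INTERFACE_FAMILY],
    }
    for family in families.values():
        m = len(family)
        for cluster in family:
            cluster.expected = cluster_expected_count(
                cluster, backgrounds, n_samples
            )
            cluster.p_raw = poisson_upper_tail(cluster.observed, cluster.expected)
            cluster.p_adjusted = bonferroni(cluster.p_raw, m)
            cluster.significant = cluster.p_adjusted < alpha_level
    return list(clusters)


def lof_enrichment(
    observed: int,
    e_lof_per_sample: float,
    n_samples: int,
) -> float:
    """Raw p-value for LOF enrichment of one protein over the full cohort."""
    return poisson_upper_tail(observed, e_lof_per_sample * n_samples)


def lof_enrichment_table(
    observed_counts: Mapping[str, int],
    backgrounds: Mapping[str, ProteinBackground],
    n_samples: int,
    alpha_level: float = DEFAULT_ALPHA_LEVEL,
) -> dict[str, tuple[float, float, bool]]:
    """Per-protein (raw p, Bonferroni-adjusted p, significant) for LOF load.

    Every protein with background data is tested (an unmutated protein has
    p = 1); the Bonferroni factor counts all tested proteins.
    """
    proteins = sorted(backgrounds)
    m = len(proteins)
    out = {}
    for protein in proteins:
        p = lof_enrichment(
            int(observed_counts.get(protein, 0)),
            backgrounds[protein].e_lof,
            n_samples,
        )
        p_adj = bonferroni(p, m)
        out[protein] = (p, p_adj, p_adj < alpha_level)
    return out


def count_lof_events(records, proteins: Optional[set] = None) -> dict[str, int]:
    """Observed LOF mutation events per protein over the full sequence."""
    from .io_preprocess import LOF

    counts: dict[str, int] = {}
    for rec in records:
        if rec.consequence_class != LOF:
            continue
        if proteins is not None and rec.protein_id not in proteins:
            continue
        counts[rec.protein_id] = counts.get(rec.protein_id, 0) + 1
    return counts
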