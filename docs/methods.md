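# Methods

## Scope and data model

The package analyses somatic protein-altering mutations that are already
annotated with a single canonical VEP consequence and mapped to UniProt
accessions with 1-based residue coordinates (inclusive ranges everywhere; no
half-open intervals). Consequence classes are fixed vocabularies: in-frame =
{missense_variant, inframe_deletion, inframe_insertion}; loss-of-function
(LOF) = {frameshift_variant, stop_gained, stop_lost, start_lost,
splice_acceptor_variant, splice_donor_variant,
splice_donor_5th_base_variant}; silent/noncoding terms feed background-rate
estimation; everything else is excluded. Compound annotations are classified
by their most severe constituent (LOF > in-frame > background).

Cohort definition applies two filters. The germline filter removes records
with a non-zero population allele frequency; a missing frequency means the
variant was not observed in the population resource and the record is kept
(removing it would discard most somatic calls). The expression filter keeps a
mutation iff its gene reaches ≥ 1 FPKM in ≥ 80% of the tumor samples of the
mutation's cancer type, with a fixed 18-gene exemption list of cancer genes
with low transcript detection; mutations from samples of unknown cancer type
require the gene to be expressed in ≥ 80% of the cancer types present. The
two filters commute and are idempotent. Duplicate records collapse under the
key (sample, protein, start, end, consequence term). Cancer-type strings are
taken verbatim; any normalization is the caller's responsibility.

## Contact graphs

Residue–residue distance is the minimum euclidean distance over all heavy
(non-hydrogen) atom pairs of standard polymer residues; waters and hetero
ligands are excluded, and for alternate locations only the
highest-occupancy conformer of each atom is used (ties break by file
order). Multi-model files contribute one snapshot per model, so the
min-over-structures rule covers NMR ensembles automatically. Residues with
no resolved heavy atom cannot answer distance queries and are absent from
the graphs.

G1 (experimental intra-chain) has as vertices every mapped residue covered
by ≥ 1 structure and an edge wherever the same-chain minimal distance over
all structures is ≤ 6 Å. G2 (experimental inter-chain) uses a 9 Å cutoff and
keeps only edge endpoints as vertices; contacts between two chains of the
same protein (homodimers) are retained. G3 applies the G1 rule to predicted
single-protein models, using residues at every model-confidence level; a
multi-chain predicted file is rejected. Cutoffs are configuration parameters
with 6 Å / 9 Å defaults. Distances are computed exactly: a k-d tree over
atoms restricts candidate pairs, but each reported distance equals the
brute-force all-atom-pairs minimum (verified against an independent oracle
in the tests), and edge distances round-trip bit-exactly through the
tab-delimited cache format (floats serialized via `repr`).

## Cluster families

In-frame mutation footprints: missense marks its residue; in-frame deletions
mark every residue of the deleted range; in-frame insertions mark the
annotated anchor residue(s). This conservative convention matters only for
multi-residue indels. Positions beyond the protein length are dropped with a
warning.

Clusters are connected components of mutated-vertex-induced subgraphs, per
family (C1 on G1, C3 on G3; C2 per PPI from merged intra+inter mutated
subgraphs, requiring ≥ 1 inter-chain edge; C4 = the mutated subset of a
PPI's predicted interface). A mutated residue that is a covered vertex but
has no mutated contact partner forms a singleton cluster — in G3 every
residue of a predicted protein is a vertex, and singletons in G1 coverage
are treated the same way for consistency. C3 clusters sharing any residue
with a C1 cluster are removed as redundant; the rule consults C1 only. The
same residue may legitimately appear in one C1, one C2 (per PPI) and one C4
cluster; families are scored independently. The observed count O_C counts
mutation *events* (recurrent hits on one residue each count), not unique
residues; a multi-residue record intersecting a cluster counts once.
Cluster identifiers derive from the lexicographically first (protein,
residue) member, making outputs byte-reproducible.

## Background mutability model

Background counts x (events) and opportunity X (base·sample units: covered
bases × number of samples) are accumulated over a gene pool; BMR = Σx/ΣX is
per base per sample, estimated separately for SNVs and indels. When a gene's
own counts are sparse, the pool expands over nearest neighbors in z-scored
covariate space (euclidean distance; ties break by gene id) until the pooled
SNV count reaches 50 and the indel count 10, or all genes are included.
Covariate standardization and the distance are configurable; missing
covariate values are median-imputed.

Expected per-sample counts per gene multiply the per-base rates by coding
length: E_in-frame = N_coding · A_missense · (BMR_SNV + α·BMR_indel) and
E_LOF = N_coding · (A_nonsense + A_splice) · (BMR_SNV + (1−α)·BMR_indel),
with α = 0.09 (the in-frame fraction of coding indels; exposed as a
parameter). The length rescaling makes E a per-gene per-sample event count,
which is what the cluster test's mean E_C = E_u·(k/l_u)·n_p requires
dimensionally. A_t may be computed from a per-base substitution consequence
table (each covered base distributes its three possible substitutions
fractionally over missense/nonsense/splice/silent) or supplied directly —
synthetic runs supply it directly to avoid requiring a codon model. After
all genes are computed, each E family is floored at its cohort-wide 1st
percentile (monotone: values only rise, and only those below the percentile
change). Protein-level expectations sum over encoding genes, with the
cohort median as default when a protein has no gene-level data, so protein
expectations are always positive.

## Significance

The cluster and LOF tests are one-sided Poisson upper tails
P(X ≥ O) = 1 − Σ_{x<O} E^x e^{−E}/x!, computed through the regularized
incomplete gamma survival function with a log-space series fallback for
extreme tails (results remain meaningful down to the subnormal
floating-point range; the tests verify 1e-12 relative agreement with an
arbitrary-precision series oracle). Bonferroni correction is applied
separately to the structure-derived family (C1∪C2∪C3) and the interface
family (C4); m counts every constructed cluster in the family (all have
O_C ≥ 1 by construction, no size pre-filtering). LOF enrichment is corrected
across all tested proteins. Raw p-values are carried into the propagation
stage — the heat and weight formulas are monotone transforms of raw
evidence — while adjusted p-values set significance flags, which gate only
driver-mutation extraction. For logging, p-values are floored at 1e-300;
the heat cap of 300 makes smaller values indistinguishable anyway.

## Heat diffusion and modules

Heats and weights: h_u = min(300, −log₁₀ min{p_C : C ∈ C_u}) +
min(300, −log₁₀ p_u), where C_u contains all tested clusters of both
families with a residue in u; an empty C_u contributes 0, as does an
unmutated protein's p_u = 1. Edge weights use only the PPI's own
inter-protein clusters, w_ij = min(300, −log₁₀ min p_C) + w₀ with w₀ = 1
when the set is empty. The cap of 300 applies to each log term before
summation and protects against underflowed p-values. Degree-0 vertices are
dropped before building the transition matrix (a zero column would break
column-stochasticity and heat conservation).

F = β(I−(1−β)W)⁻¹ is obtained by a linear solve rather than explicit
inversion; the numerical contract is the residual bound
‖(I−(1−β)W)F − βI‖∞ ≤ 1e-9, plus the algebraic identities 1ᵀF = 1ᵀ and
Σ_i E(i,j) = h_j, which the tests check on random graphs. β defaults to
0.5. The module rule E(i,j) > δ is strict; modules are strongly connected
components, and only modules with more than 5 proteins are significant.

δ selection randomizes the network by double edge swaps (budget: 10·|E|
attempted swaps per replicate; proposals creating self-loops or parallel
edges are rejected), keeps each protein's heat fixed, and randomly
reassigns the original weight multiset to the swapped edges. Each of the
20 replicates contributes the smallest entry of its exchanged-heat matrix
(binary search over the sorted distinct positive entries, valid because
module sizes are non-increasing in δ) at which all its components have ≤ 5
proteins; the final δ is the smallest over replicates, so the real
network's modules are judged against the most permissive null replicate.
All randomness derives from one integer seed (replicate seeds are seed +
index), making δ bit-reproducible. If the network is too small or dense to
admit any swap, or no replicate has a positive exchanged-heat entry (e.g.
all heats zero), δ selection fails with an error asking for an explicit δ.

The baseline (ablation) configuration replaces heats with the number of
distinct samples carrying any protein-altering mutation in the protein and
sets every edge weight to 1, leaving all downstream stages unchanged; it
isolates the contribution of the 3D-cluster evidence to module calling.

## Synthetic data

The generator emulates the statistical structure the model assumes, not
biology. Geometry: straight Cα backbones with 3.8 Å spacing, so the contact
graph at 6 Å is exactly the sequence-adjacency graph — planted contiguous
patches are connected clusters, and there are no long-range contacts.
Interface pairs place a second chain 14 Å away except at a designated patch
brought within 5 Å, yielding known G2 edges and matching "very high"
confidence interface annotations. Cohorts: per-residue in-frame event
counts are Poisson with mean (E_g^in-frame/l)·n_samples·multiplier, with
E_g^in-frame derived from the same per-base rates (default
mu_SNV = 1e-6 /base/sample, mu_indel = 5e-8, exome-scale values) that the
background estimator assumes, so generator and estimator share one
parameterisation; LOF counts are gene-level Poisson draws; silent/noncoding
background counts use the same rates over the gene's covered footprint.
Covariates are uninformative draws (rates do not actually vary with them),
expression is uniform in [2, 50] FPKM for expressed genes, and networks are
seeded Erdős–Rényi graphs with optional planted cliques. Everything is
determined by one integer seed, and the file writer produces byte-identical
directories for equal seeds. What passing tests on these fixtures do *not*
show: robustness to covariate-correlated rate variation, realistic fold
topologies (long-range contacts), mutational signatures, or
coordinate-mapping noise.

## Known limitations

- **Cluster recurrence p-values are conditionally anti-conservative.**
  Clusters are constructed from mutated residues, so every cluster satisfies
  O_C ≥ k while the Poisson mean E_C = E_u·(k/l_u)·n_p is unconditional.
  Under a uniform background this selection effect inflates the familywise
  rate of Bonferroni-significant clusters well above the nominal level at
  every mutation density we simulated (the acceptance suite measures ~0.14
  at nominal 0.05 on null cohorts of 1,000 samples × 50 proteins of 200
  residues), and a planted 5-residue patch at 10× background with null
  E_C ≈ 1 is detected in ~75–80% of seeds. The package reports these rates
  honestly (`scripts/acceptance.py`); ranked significance and downstream
  module calling are the intended use of these p-values, not calibrated
  per-cluster error control.
- Module membership is winner-take-all at a single δ; no hierarchical
  decomposition or consensus across networks is attempted.
- Cluster p-values for overlapping families (a residue scored in C1, C2 and
  C4) are not mutually adjusted; the heat formula deliberately takes the
  minimum over them.
- The per-base substitution consequence machinery assumes a fixed coding
  model per gene; per-patient mutation spectra and trinucleotide signatures
  (as in full covariate-based driver callers) are out of scope.
- n_p is pooled over the whole preprocessed cohort, also when several cancer
  types are analysed together.
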