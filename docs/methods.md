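# Methods

This note documents the models, defaults and numerical choices behind the
package, and what the synthetic study does and does not establish.

## Synthetic study design

The generator emulates the statistical structure the analysis assumes,
not any particular genome.

**Species tree.** The default panel is four species:
`(outgroup:0.50,(witness:0.20,(focal:0.10,reference:0.15):0.15):0.15)`,
branch lengths in expected amino-acid substitutions per site.  The
outgroup plays the lamprey role (novelty judge), the focal tip the
tumor-bearing species, the reference tip the annotation-rich species
whose orthologs carry gained functions, and the witness supplies
third-genome distances for the non-orthology test.  Focal–outgroup
distance is ≈ 0.9 subs/site (≈ 42% identity under the replacement model),
deep enough that homology detection is non-trivial but far from the
Kimura saturation boundary.

**Gene content.** `n_root_families = 60` families exist at the root;
new families are born along branches as a Poisson process
(`birth_rate = 50`/unit length, giving ≈ 20 post-outgroup-split focal
genes).  Each gene lineage duplicates at `dup_rate = 0.08` and dies at
`loss_rate = 0.03` per unit length.  Orthology truth is read off the
gene tree: genes coalescing at a speciation node are orthologs, at a
duplication node paralogs.  Truth ages are binary — a focal gene is
`post_outgroup_split` iff its family was born after the root — matching
the single-stratum design of the analysis.

**Sequences.** Root sequences are uniform over the 20 amino acids,
lengths uniform in 80–200 residues.  Each gene-tree edge applies
Poisson(branch-length) substitutions per site with uniform replacement
(a Jukes–Cantor-style protein model).  This choice keeps the
Kimura-corrected distance in the orthology module approximately
consistent with the generating process; an empirical matrix (WAG, LG)
could be swapped in, at the cost of that consistency.  Indels are not
simulated; coverage filters are exercised instead by domain-truncated
duplicate copies (a `frac_truncated_duplicates = 0.25` fraction of new
duplicate lineages keeps only the first 40% of the sequence).

**GO annotations.** A fixed toy DAG with four category roots mirroring
the developmental / transcription-regulation / signaling / immune
grouping, plus molecular-function and cellular-component branches
(56 leaf terms, one multi-parent term).  All genes of a family share a
base term set (2–6 leaves).  Reference-lineage genes gain
Poisson(`gain_rate_reference_lineage = 3`) extra terms; when the gene has
a planted tumor-specific focal ortholog, development-category terms are
upweighted by `category_gain_bias = 4`.  Gains are drawn once per
reference gene (the gain event happens on the reference lineage), so all
focal orthologs of one reference gene share a truth gained set.

**Expression.** One library per condition (pooled samples, no
replicates) — presence calling, not differential testing, is the
contract.  Expressed genes draw negative-binomial counts with mean 50
and dispersion 5 (variance = m + m²/r = 550); planted TSEEN genes
(`frac_tseen = 0.4` of post-split focal genes) draw exactly 0 in normal
and NB counts in tumor and regressed; 10% of the remaining genes are
silent everywhere.  The depth/abundance distribution of real SAGE
libraries is not published at this granularity, so the NB
parameterization is a package choice: deep enough that a present gene is
essentially never missed, which matches the strict manual selection the
design models.

**Determinism.** All stages draw from `numpy` generators seeded as
`[stage_constant, seed]`; identical seeds give byte-identical FASTA, OBO,
TSV and JSON outputs.

## Expression selection

TPM here is counts-per-million (one 3' tag per transcript, no length
normalization).  Presence is a tri-state call: *present* iff
TPM ≥ `tau_present` (default 1.0), *absent* iff raw count ≤ `tau_absent`
(default 0), else *ambiguous*.  The original selection was manual and
threshold-free; the defaults encode its strict phrasing — "not expressed"
means literally zero tags — and an ambiguous gene is never a candidate
(conservative, mirroring manual curation).  Candidates are genes present
in tumor AND regressed AND absent in normal.  Raising `tau_present` can
only shrink the candidate set (tested invariant).  Integer input is
enforced so TPM cannot be applied twice silently.

## Homology search

Smith–Waterman with affine gaps (gap of length k costs
`gap_open + k·gap_extend`; defaults 11 + k·1), BLOSUM62, unknown residues
mapped to X scoring 0 against everything.  The DP kernel is
numba-compiled; the traceback reports one optimal alignment with ties
broken diagonal > up > left, so results are deterministic.  Coordinates
are 1-based inclusive; coverage = span length / full sequence length.

E-values use fixed Gumbel constants λ = 0.267, K = 0.041 — the standard
values for gapped BLOSUM62 at this penalty setting — with n the summed
target-proteome length.  No finite-size edge correction is applied; on
random sequences the realized hit rate at E ≤ x stays within a small
constant factor of x (tested), which is sufficient for a threshold three
orders of magnitude below 1.

Hit filter: E strictly below 10⁻³ AND coverage ≥ 25% of *either*
sequence.  The either-sequence reading is the default; a
`both_sequences` switch is exposed because the prose rule ("any of the
protein sequences") admits both readings.  A profile-iterated search is
deliberately not implemented: the published filter is defined by its
thresholds, which a single search round applies; a six-frame translation
front-end covers nucleotide queries.  Low-complexity masking is not
implemented — synthetic sequences are near-uniform — and would be needed
for real proteomes.

## Orthology

**RBH.** Per-direction best hits (lowest E, then highest score, then
lexicographic subject id), intersected; strictly one-to-one.

**Distance-based (OMA-like).** Distances are computed on the hit's
local-alignment columns (no global realignment — consistent with the
search engine and adequate at desk scale): mismatch fraction p over
ungapped columns, d = −ln(1 − p − p²/5),
var(d) = p(1−p)/L · ((1 + 2p/5)/(1 − p − p²/5))².  p ≥ 0.85 saturates the
correction and the pair is treated as infinitely distant.  A pair (x, y)
is *stable* when each is within `tolerance_k`·σ (default 1.5, σ pooled
from the two estimates) of the other's minimum distance; mutually stable
genes form connected components emitted as all cross pairs with a group
id, so duplication fan-out counts are exact.  The cited method publishes
no parameter values, so the tolerance default is a package choice,
exposed in the API.

**Witness of non-orthology.** A pair (x, y) is vetoed when a witness
genome holds genes z_x, z_y with d(x, z_x) and d(y, z_y) both below
d(x, y) − k·σ **and** z_x ≠ z_y (or more than one such gene exists).
Two distinct close witness genes are the paralogous copies retained
after the ancestral duplication that x and y descend from — the
differential-loss signature.  A *single* shared close witness gene is
not used as a veto: on a clean topology it is an ordinary outgroup
ortholog of the pair, and vetoing on it would mostly punish noise.  Any
one witness genome suffices (OR semantics); with no witness configured
the step is skipped with a warning.

This is a pairwise approximation of the full published algorithm: no
hierarchical groups, no genome-wide refinement iterations, no synteny.

## Novelty, TT_Rgr_EEN and consensus

Novelty is absence of any ortholog call in exactly one designated
outgroup (adding non-outgroup species never changes novelty — tested).
A documented strict mode — requiring absence from every outgroup-side
species — can be emulated by intersecting `classify_novelty` over
several species columns; the single-outgroup default matches the
original design and inherits its known caveat: a gene lost in the
outgroup looks novel (this is the irreducible error the simulation
reproduces at the configured loss rate).  TT_Rgr_EEN = expression
selection ∧ novelty, tracked per method; the consensus set is novel by
all methods, and each disagreement is attributed to the method declining
the call.  The stable-id filter of the original flow is modeled as an
id-mapping step that is the identity in synthetic mode.

## Function gain and enrichment

Distinct-function counts use direct annotations only and count each term
id once regardless of evidence codes; ancestor propagation is applied
only inside enrichment (standard practice).  Both behaviors are
switchable.  Gains are literal term-id set differences (reference minus
focal), per GO aspect — no semantic-similarity smoothing.  Category
membership is ancestor-closure containment of configurable root terms
(defaults: the four toy-ontology roots; on real GO data the user supplies
root ids, since the grouping names map to several plausible roots).
Enrichment: one-sided hypergeometric p (exact), fold enrichment
(k/n)/(K/N), BH q-values over tested terms; terms with no background
annotation are skipped.  Raw p is always reported alongside q for
comparability with analyses that print raw values.

## Conservation test

Pearson χ² on the 2×2 table without continuity correction, p from the
upper tail of χ²(1) computed as erfc(√(χ²/2)) — stable below 1e-300,
which matters at p ≈ 10⁻⁵².  The comparison row uses *all* novel genes,
including the study subset (overlapping rows): with the published
marginals this construction reproduces the printed p-value, and it is
flagged prominently because a disjoint-rows construction is also
defensible.  A continuity-correction flag exists for users who want it.

## Problem sizes and what passing shows

Default runs use ~340 genes over ~130 families per seed and three seeds
for recovery statistics — sizes at which every stage is exact rather
than heuristic, chosen as a desk-scale study.  Passing recovery tests
shows the pipeline's logic is faithful under the generator's assumptions
(no indels, uniform replacement, near-uniform composition, one tag per
transcript, annotation truth free of curation noise).  It does not show
robustness to real-data pathologies: low-complexity regions, domain
shuffling, alignment-length biases in distance estimates, GO annotation
incompleteness, or library-depth imbalance.  Those are the known
limitations of the synthetic contract.
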