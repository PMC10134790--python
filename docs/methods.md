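# Methods

## Problem and model

The package implements a genome-mining survey for LuxR solos: LuxR-family
quorum-sensing receptors (autoinducer-binding domain PF03472 plus a
helix-turn-helix domain) lacking a linked LuxI-family AHL synthase
(PF00765). The survey operates on per-genome annotated inputs — gene
models (GFF3), proteome (FASTA) and precomputed domain assignments
(HMMER3 domtblout dialect or a 5-column TSV). Domain calls are taken as
given; the package never runs a profile-HMM search, so no Pfam database is
required.

## Solo detection

The criterion is ordinal, not metric: a PF03472 protein is a solo iff no
gene within ±4 ranks on the same replicon (the "surrounding 8 genes")
encodes PF00765. Design choices:

* **Rank, not bp.** Gene rank is position in the coordinate-sorted gene
  order of a replicon. Non-coding genes occupy ranks — the criterion
  counts genes, not proteins.
* **Window truncation.** Replicon ends truncate the window; replicons
  (chromosomes, plasmids, contigs) are independent and never wrap.
* **Neighbor strand is ignored**: the rule is pure domain
  presence/absence.
* **Fused synthase–regulators** (one protein with both PF03472 and
  PF00765) are conservatively excluded from solo status and flagged.
* The 230–270 aa length range typical of QS LuxRs is recorded as advisory
  metadata (`luxr_length_ok`), never used as a filter.

Pair topology is classified geometrically from strands and rank order:
same strand and adjacent → *tandem*; opposite strands with tails meeting
(→ ←) → *convergent*; pointing apart (← →) → *divergent*; ≥1 intervening
gene → *complex*. Literature usage of head-to-head vs tail-to-tail
"convergent/divergent" labels is inconsistent, so this classifier commits
to the geometric reading and reports the intergenic distance and a
`linked` flag (< 3,000 bp) separately.

## Pairwise alignment and clustering

Clustering uses global Needleman–Wunsch with a linear gap model (match
+1, mismatch 0, gap −1), a deterministic traceback (diagonal > up > left)
and two derived statistics:

* **identity** = identical aligned columns / length of the *shorter*
  sequence. Redundancy-reduction tools do not all agree on the
  denominator; shorter-sequence is this package's documented convention
  and the scoring is configurable.
* **coverage** of each sequence = span between its first and last
  residue-vs-residue column / its length. "80% coverage of both"
  therefore penalizes dangling termini on either side.

Symmetry under argument exchange is guaranteed by aligning each pair in a
canonical order. Greedy clustering processes sequences longest-first
(ties by id), joining the first representative that passes both
thresholds (identity ≥ 0.80, coverage ≥ 0.80 both ways), else founding a
new cluster — a single pass, no re-clustering rounds. The only
optimization is a length-ratio short-circuit (candidate shorter than 80%
of the representative cannot realistically pass coverage). Complexity is
O(clusters × members × L²); at survey-on-desk scale (hundreds of solos of
~240 aa) this runs in seconds.

## Context profiles and subgrouping

For each cluster with **more than 50 members** (strict), the profile is
the fraction of members whose detection window (±4 ranks, reusing the
detection window) contains each Pfam at least once — member-level
presence, not raw counts, since rare multi-copy neighbors should not
dominate. The focal gene and PF03472 itself are excluded as constant
features. Accessions below the 5% floor are dropped (exactly 5% is
retained).

Profiles are vectorized over the union of retained accessions and
embedded in 3 dimensions. The default embedding is PCA with a fixed sign
convention (largest-magnitude loading positive), chosen because it is
fully deterministic and because the DBSCAN radius eps = 0.5 is only
meaningful relative to a reproducible embedding geometry; seeded UMAP is
available behind the same interface (`embed.method: umap`). DBSCAN
(Euclidean, eps 0.5, min_samples 10, self-inclusive core test) labels
non-dense profiles −1; cluster numbering follows the first-encountered
core point in id-sorted order, making labels reproducible.

## Residue classifier

Queries are globally aligned to a packaged **synthetic TraR-like anchor**:
240 aa with the nine consensus residues at the literal TraR positions
(W57, Y61, D70, P71, W85, G113; E178, L182, G188). The inter-key filler
is an arbitrary fixed sequence — it only has to provide a stable
coordinate system — and a real TraR sequence can be substituted through
the reference-map YAML. Scoring reports the aligned residue (or gap) at
each key position, `n_conserved` (0–9), the PAB signature (57 = M *and*
61 = W), and a whole-sequence scan for the exact 6-mers WYDPWG (canonical,
checked first), TYDQCS (PluR-like) and TYDQYI (PauR-like); anchored
position checking would be a stricter alternative, but the motifs'
location is not standardized, so the scan errs permissive.

Class hints compose residues with neighborhood context, precedence
pyrone/DAR > PAB > AHL:

* `pyrone_DAR_type` — TYDQCS or TYDQYI present;
* `PAB_type` — PAB signature, or a *pip* gene in the window. *pip*
  recognition is by Pfam accession (default PF00561, the alpha/beta
  hydrolase family containing proline iminopeptidase) since the pipeline
  sees domains, not gene names; configurable.
* `sdiA_like` neighborhood — the window contains the full configured
  context set (default PF00005 + PF00072: ABC transporter + receiver
  domain, after the conserved enteric sdiA context); affects the
  neighborhood class only.
* `AHL_type` — ≥ 8 of 9 residues conserved and no divergent motif.

The hint is explicitly heuristic: ligand-independent solos retain all
nine residues, so conservation does not imply AHL binding.

## Phylogeny

The representative tree uses 1 − identity distances and classical
neighbor joining, which is exact on additive matrices. A progressive
MSA + approximate-ML pipeline would be the field's default at corpus
scale, but for a summary tree over cluster representatives NJ is
deterministic, dependency-free and testable against closed forms; the
Newick interface permits substituting an externally built tree.
Q-criterion ties break on the lexically smallest label pair (internal
nodes inherit their smaller child label); negative branch lengths are
clamped to zero with the deficit moved to the sister branch, preserving
the pair's path length. Leaf labels may carry subgroup / class /
environment annotations (quoted Newick labels plus a sidecar TSV).

## Distribution summary

Percent of genomes with zero / one / multiple solos is computed before
rounding as 100·count/n and rounded **half-up** to one decimal (matching
the "~46.2%" style of survey reports); the three percentages may sum to
99.9–100.1 after rounding. On the published counts (31,034 genomes;
12,235 with one solo; 4,448 with several) this yields 46.2 / 39.4 / 14.3.

## Synthetic data

`simulate_corpus` emulates the statistical structure of a survey corpus,
not genome evolution:

* **Solo-count mixture** per genome defaults to (0.462, 0.394, 0.144) —
  the survey proportions, with the multi-solo term absorbing the 0.1%
  rounding remainder so the mixture sums to 1. Multi-solo genomes carry
  2–3 solos.
* **Pairs**: 40% of genomes carry a complete luxI/luxR pair, topology
  drawn as tandem 0.5 / convergent 0.3 / divergent 0.1 / complex 0.1 —
  tandem and convergent dominate in real pairs; the others are kept
  non-zero so every topology branch is exercised.
* **Sequence families**: each archetype ancestor derives from the anchor
  by substituting 35% of unconstrained positions, so cross-archetype
  identity (~45%) is far below the 80% clustering threshold; members
  substitute 5%, keeping within-family identity ~90%. The nine key
  positions and any implanted motif are never mutated, so planted
  signatures survive; substitutions are i.i.d. with no indels by default,
  making identity a direct function of the rate. Default archetypes:
  generic-AHL, PAB + *pip* neighbor (W57M/Y61W), PluR-like (TYDQCS),
  SdiA-like (ABC-transporter + receiver context) and an MFS-transporter
  context (PF07690).
* **Geometry guarantees**: planted solos sit ≥ 9 ranks apart and ≥ 5
  ranks from any luxI, so no detection window contains a foreign
  signature — planted truth is exactly recoverable by construction, which
  is the point: the generator validates the machinery, and deviations
  from perfect recovery indicate implementation defects, not biology.
* **Decoys** carry 0–2 accessions from a pool disjoint from all signature
  pfams; ~5% of genes are non-coding and occupy window slots.

What the generator does **not** emulate: indels and domain rearrangement,
pseudogenes, horizontal-transfer phylogenetic structure, realistic
taxonomic sampling, annotation noise (missed or spurious domain calls).
Perfect recovery on synthetic corpora therefore validates the algorithms'
correctness, not their robustness to annotation error in real data.

`generate_profile_blobs` fixes its own geometry for subgrouping tests:
k archetypes own disjoint 6-feature blocks at high prevalence (amplitude
scaled by a separation parameter; 0 merges all archetypes), members
jitter by ±0.05, noise profiles are uniform. Under the default PCA
embedding the planted archetype count and the −1 noise labels are
recovered in ≥ 95% of seeds at eps 0.5 / min_samples 10.

## Problem sizes and numerics

The validation suite uses corpora of 100 genomes (~70 solos), alignment
oracles at ~100 aa, DBSCAN oracles at ≤ 200 points, NJ recovery at ≤ 12
taxa (exhaustive topology enumeration at ≤ 6), and 20-seed subgroup
replicates — sizes at which every oracle is exact and the whole suite
runs in well under a minute. Floating-point tie tolerance in the NJ
Q-criterion and alignment traceback is 1e-12/1e-9; additive-tree
round-trips are asserted to 1e-9.

## Known limitations

* Identity denominators and coverage definitions differ between
  redundancy-reduction tools; cluster boundaries near the 80% threshold
  are convention-dependent.
* eps = 0.5 is calibrated to the package's own embedding geometry;
  applying it to a different embedding of real survey data requires
  re-calibration.
* Class hints are rule-based composites of a handful of residues and
  neighborhood accessions; they cannot discriminate endogenous from
  exogenous AHL response, nor detect ligand independence.
* The anchor's inter-key residues are synthetic; absolute alignment
  scores against it are not comparable to scores against real TraR,
  though key-position mapping is robust for sequences of typical LuxR
  length.
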