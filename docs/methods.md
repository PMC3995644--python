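# Methods

This note documents the models, rules, and numerical choices behind each
pipeline stage, the synthetic-data generator used to validate them, and the
known limitations. Parameter defaults are stated with their rationale; all of
them are exposed through `PipelineConfig` or the per-function arguments.

## Pairwise similarity model

Every unordered sequence pair is scored by optimal Smith–Waterman local
alignment with affine gaps. Defaults: BLOSUM62, gap existence 11, gap
extension 1 (a length-L gap costs 11 + L). The backend is Biopython's
`PairwiseAligner` in local mode; sequences are canonically ordered by
identifier before alignment so traceback ties cannot depend on argument
order, making `align_pair(a, b) == align_pair(b, a)` exact.

Raw scores S are converted to bit scores S′ = (λS − ln K)/ln 2 and E-values
E = m·n·2^(−S′), with m, n the two full sequence lengths (the
`product_of_lengths` search-space rule; a fixed search space is available).
λ = 0.267 nats and K = 0.041 are the standard gapped BLOSUM62/11/1 constants.
Because the aligner is optimal rather than heuristic and no composition-based
correction is applied, null-model E-values run slightly hot: over random
length-250 pairs the observed count of hits at E ≤ c tracks the expected
Poisson mean (≈ Σ E) to within a small factor, which is accurate enough for
thresholding at the 10⁻¹³-and-below cutoffs the pipeline uses.

Two edge attributes follow the network-figure convention: percent identity =
identities / alignment columns (gaps included) × 100, reported "over N
residues" where N is the alignment length. `all_by_all` reports one record
per unordered pair with E ≤ 10 (the reporting ceiling of standard search
tools); an external search's 12-column tabular output can be ingested
instead, keeping the lower E-value of the two search directions per pair and
back-computing the raw score from the bit score.

## Representative clustering and networks

Greedy incremental identity clustering processes sequences longest-first
(ties by identifier); each sequence joins the first cluster whose
representative it matches at ≥ the identity threshold (ID50 for sequence
networks, ID95 for structure chains), else founds a new cluster. The
representative is therefore the longest member (ties lexicographic).

**Identity denominator.** For *clustering decisions* the identity fraction is
identities / min(sequence lengths). Using identities / alignment-length here
would let a short, high-identity local alignment between otherwise unrelated
proteins clear a 50% threshold, merging unrelated clusters; the
shorter-sequence denominator is the convention of greedy identity clusterers.
For *edge attributes and medians* the alignment-length denominator is kept,
matching how network statistics are conventionally quoted.

Representative-network edges follow the least-significant rule: the edge
E-value between two representative nodes is the numerically largest E-value
among all reported member pairs spanning the two clusters, and the edge's
percent identity / alignment length are taken from that same pair (ties on
E broken toward lexicographically smallest pair ids). An edge thus certifies
even the weakest member-level relationship; cluster pairs with no reported
spanning pair get no edge. Full networks carry one node per sequence and one
edge per reported pair.

Medians over an even-sized edge set use the midpoint of the two central
values; an empty edge set yields an empty-result signal (None), not an error.

## Subgroup designation

Thresholding keeps edges with E ≤ cutoff (inclusive; the comparison direction
flips to ≥ for structure SN scores). Edge sets are nested and connected
components refine monotonically as the cutoff tightens — both are enforced by
property tests. Components at the level 1 cutoff (default 1×10⁻¹³) become
level 1 subgroups; components at the level 2 cutoff (default 1×10⁻²⁵) become
level 2 subgroups named `<parent>.<k>`, with k ordered by descending member
count within each parent. A component qualifies only with ≥ `min_members`
member *sequences* (default 50), counted after expanding representative
nodes to their cluster members — a three-node component totaling 59 members
qualifies while a 49-member component never does. Sub-threshold components
are recorded as unassigned clusters (singletons flagged); member sequences
inherit their representative's subgroup or unassigned status. Level 1 names
are auto-assigned G1, G2, … by descending member count unless a curated
label map supplies names; naming is deterministic for identical inputs.

A level 2 component spanning two level 1 parents is impossible when the
level 2 cutoff is stricter (refinement); it is asserted and raises a
consistency error otherwise. Components whose nodes were unassigned at
level 1 remain unassigned at level 2.

## Annotation overlay

Class and taxonomy labels follow the strict majority rule: a node is labeled
L iff count(L) > 50% of its *annotated* members; unannotated members are
excluded from the denominator and exact 50/50 ties yield no label. (The
strict ">50%" reading is used; the alternative "at least 50%" phrasing seen
in figure legends would label ties, and users wanting that behaviour can
pre-round their inputs.) Reaction types follow the any-evidence rule: the
node shows the union of member reaction types, with summary single/multiple
and an evidence-source flag this_work / literature / both; reaction codes are
validated against a configurable controlled vocabulary (DSBR, ERO, NA, NAS,
NS, RD, peroxidase, isomerase, DHAR, other). Taxonomy lineages are matched
by name against a precedence list ordered most-specific-first — Insecta,
Metazoa, Viridiplantae, Fungi, Eukaryota, Bacteria, Archaea — so an insect
lineage is categorized Insecta even though it also contains Metazoa and
Eukaryota; no live taxonomy service is queried. The length histogram bins
full-length sequences and reports fractions for named inclusive ranges
(e.g. the single-domain 190–275 band).

## Objective threshold selection

Candidate cutoffs are scanned in order of decreasing stringency. At each
cutoff the thresholded representative network is (a) decomposed into
connected components and (b) clustered with the Markov Cluster Algorithm, and
two adjusted Rand indices are computed: components vs the canonical-class
partition (restricted to labeled nodes — unlabeled nodes carry no class
information) and components vs the MCL partition. The combined score defaults
to the unweighted mean of the two (the combiner is pluggable); the selected
cutoff maximizes it, with ties broken toward the most stringent candidate.

MCL details: edge weights are −log10(E) capped at 200 (so E = 0 stays
finite); self-loops get each node's maximum incident weight (1.0 for isolated
nodes); the matrix is column-normalized and iterated through expansion
(matrix power, default 2) and inflation (elementwise power, default 2.0, then
renormalization), pruning entries below 10⁻¹², until the max-norm change
falls below 10⁻⁸ or 200 iterations (non-convergence is flagged on the result,
which still carries the last partition). Clusters are read from the attractor
structure (rows with diagonal mass), merging attractors that feed a common
column; columns numerically starved by pruning fall to their strongest row.
Column sums stay within 10⁻¹⁰ of 1 at every iteration (tracked on the
result). Flow cannot cross disconnected components, so components are never
merged; isolated nodes come out as singletons.

ARI is computed with the standard pair-counting formula (via scikit-learn)
after mapping both partitions to label vectors over the identical element
universe; identical partitions score 1 (including the degenerate
all-singletons case), independent random partitions ≈ 0.

## Structure networks

The structural aligner itself is out of scope: the module consumes its
symmetric pairwise score table (chain_a, chain_b, SN score, aligned
residues). Chains are deduplicated at ID95 by the same greedy clustering
(exact positional identity by default — appropriate for duplicate-chain
removal; a pair-source from real alignments can be supplied). Within each
cluster the representative is the member with the best quality value (a
generic numeric field, lower = better, e.g. crystallographic resolution in
Å; ties by identifier; chains without quality rank last). The
identity-to-representative invariant is exact for duplicate-chain clusters
and approximate when the representative differs from the greedy founder.
Edges require SN score ≥ cutoff (default 20; higher = more similar, the
opposite direction to E-values). Sequence-derived attributes (subgroup,
class, reactions) are transferred to structure nodes through chain→sequence
links; unlinked chains stay unannotated.

## Synthetic superfamilies

The generator emulates the statistical structure of a large divergent
superfamily with a two-level planted truth; it is the test bed for every
stage. Evolution is substitution-only on the 20-letter alphabet: each level 1
group descends from an independent random root ("unrelated") or from a common
ancestor mutated at `remote_ancestor_sub_rate` (default 0.50, putting
cross-group similarity near the level 1 threshold); each family root is the
group root mutated at `within_group_sub_rate` (default 0.35 → cross-family
identity ≈ 38%), and each member is its family root mutated at
`within_family_sub_rate` (default 0.10 → member–root identity ≈ 90.5%, since
per-site change probability is r·19/20 with uniform replacement). Lengths are
drawn per group root from a weighted mixture defaulting to 190–275 (0.71),
300–350 (0.17), 400–430 (0.12) — the dominant single-domain peak plus
tandem-domain and fusion-length minorities.

Annotations: a fraction `annotation_coverage` (default 0.25) of sequences
get their family's canonical-class-style label (Greek-letter names assigned
per family) — high enough that desk-scale nodes acquire majority labels;
taxonomy lineages are sampled from a bacteria-dominant category mix;
`reaction_evidence_rate` (default 0.05) of sequences get one reaction type
with a random evidence source. Structure chains are exact copies of selected
member sequences (optionally duplicated, giving ID95 deduplication a known
truth), and the structure-score table places within-group pairs at
cutoff + separation and cross-group pairs at cutoff − separation plus
optional Gaussian noise, so zero-noise thresholding recovers the groups
exactly.

What the generator does *not* model — and hence what passing tests do not
establish about real data: insertions/deletions (indels are off by default,
so alignment lengths are unrealistically uniform), site-rate heterogeneity
and realistic phylogenies (only the two-level root hierarchy), domain
architecture (length minorities are plain longer random roots, not actual
fused domains), biased residue composition, and annotation errors.
Identical config + seed reproduces sequences, annotations, and score tables
byte-identically.

## Desk-scale study conditions and calibration

The validation dataset is 3 groups × 3 families × 15 members (135 sequences,
9,045 alignments, ~30 s on one CPU) at single-domain lengths (225–235), with
the default substitution rates. At this scale planted groups carry 45
members, so subgroup designation uses `min_members = 10`; the ≥50 rule's
49/50 boundary is exercised separately at the unit level. The level 1 cutoff
is the standard 1×10⁻¹³. The family-separation window moves from dataset to
dataset (group-root length and stochastic divergence shift the worst
spanning-pair E-values), so the level 2 cutoff is taken from the package's
own objective scan over candidates 10⁻¹³…10⁻⁸⁵ — using the method's own
threshold-selection machinery as its calibration, exactly as it would be used
on real data. Under these conditions the pipeline recovers the planted
level 1 partition at ARI 1.0 and the family partition at ARI 1.0 (the
acceptance script recomputes both), and the scan picks a cutoff inside the
separation window in all 20 seeded replicates.

## Known limitations

* The internal aligner is O(n²) optimal alignment — right for thousands of
  sequences, not for genome-scale inputs; at scale, ingest an external
  search tool's tabular output instead.
* E-value calibration inherits fixed λ, K; no composition-based statistics
  or low-complexity masking (masking was deliberately off in the motivating
  study).
* The combined threshold-selection score weights its two agreement terms
  equally; with very sparse class annotation the class term rests on few
  nodes and the MCL term dominates.
* Level 1 subgroup names are positional (G1, G2, …) unless curated labels
  are supplied; biological naming is out of scope.
* MCL is dense-matrix; representative networks of more than a few thousand
  nodes would need a sparse implementation.
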