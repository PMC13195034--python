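# Methods

## Models and procedures

### Reliable absence and Dollo loss mapping

A gene family's observed states across species are `present`, `absent`, or
`missing` (`1/0/?` on disk). Because genome assemblies and annotations
fail unevenly, a raw absence is promoted to a *reliable* loss only when
every species in the same group lacks the gene; otherwise it is recoded as
missing information. The group is defined by a configurable leaf-tag level
(default `genus`; `min_group_size` can demand larger groups). At taxon
resolution — one leaf per family-level taxon, as in the packaged fixture —
each leaf is its own group and the rule is the identity.

Loss mapping assumes Dollo evolution: a single gain, any number of losses,
no regain. The origin is the most recent common ancestor of the present
leaves. One loss event is charged to the stem of every maximal subtree
(within the origin's subtree) that contains no present leaf and at least
one absent leaf. Missing leaves are uninformative: an all-missing subtree
generates no loss, and ambiguous internal states resolve toward presence,
deferring losses tipward. Both choices make the count a minimum — the
"lost at least N times" reading — and the test suite verifies equality
with an exhaustive brute-force minimum over all single-gain edge-labelings
on hundreds of random trees. Per-clade counts attribute a loss edge to a
named clade only when the edge lies strictly inside it; nested clade
arguments would double-count and are not used.

Known limitation: when an entire child subtree of the root is lost, Dollo
parsimony instead narrows the origin, so losses on root-adjacent edges are
invisible. This is inherent to the lower-bound semantics, not a defect of
the implementation.

### Ancestral orthogroup content

Species map to major taxa; named nodes of a small taxon tree define the
ancestors of interest. An orthogroup (OG) is in the content of node N when
every major taxon below N contributes at least one gene (the coverage
rule). Content at a taxon leaf requires only representation in that taxon;
content at a species is direct membership. Gains and losses are set
differences along the chain of named ancestors, so
size(child) = size(parent) + gain − loss holds by construction, and
internal contents nest along the chain.

An OG whose represented taxa are not exactly the taxon set of one named
node (e.g. Enoplida + Rhabditina only) is *patchy*: it receives no origin
node and is listed per taxon in the report. We deliberately keep patchy
OGs inside the plain coverage contents rather than excluding them from
multi-taxon ancestors: exclusion would make content non-monotone in OG
membership (adding an Enoplida gene to a Tylenchina+Rhabditina OG could
remove the OG from their ancestor's content), which we consider
unacceptable for a reconstruction that advertises lower-bound semantics.

### Homolog screening

Reciprocal one-to-one top hits: a pair (q, s) is accepted when s is q's
best forward hit with e-value strictly below the forward threshold
(default 1e-20) and q is s's best reverse hit strictly below the
reciprocal threshold (default 1e-10). Best-hit ties break by higher
bitscore, then lexicographic subject ID, keeping results deterministic.
Both thresholds are strict inequalities and are independent knobs because
the procedure uses them asymmetrically across rounds.

Iterative screening uses the genes accepted in round r−1 as queries
against every species with no accepted gene yet, and stops when a round
adds nothing or after `max_rounds` (default 3) — whichever comes first.
Hit tables are precomputed inputs; no sequence search runs in-process.
Clade validation accepts a candidate when it descends from the smallest
gene-tree node containing all reference members and that node's bootstrap
support reaches `min_support` (default 70 — "high support" is not a
standardized number, so it is configurable). When the reference members
only join at the root, validation proceeds accept-all but logs a
low-confidence warning.

### Expression screening

Preprocessing: replicate columns at one stage collapse to their arithmetic
mean; split gene models are summed per time point under a new ID;
overlapping windows of three time points are averaged, the window mean
representing the central time point (endpoints drop, length shrinks by
two). Smoothing damps per-time-point developmental jitter while keeping
peak positions.

Clustering is standard fuzzy c-means (fuzzifier m = 2, tolerance 1e-6,
at most 500 iterations, random membership initialization from the seed).
Profiles are z-scored per gene by default so clustering captures shape
rather than absolute abundance — the selection step is about shape. A
point coincident with a center takes membership 1 there. The objective
J = Σ u^m d² is non-increasing across iterations and memberships sum to 1;
both are asserted in tests.

Cluster selection is algorithmic rather than visual: a cluster is selected
when its z-scored center has a local maximum with z ≥ 1 inside
(molt − δ·preceding-intermolt, molt] for strictly more than a `majority`
fraction of molt events (defaults δ = 0.25, majority = 0.5). The z ≥ 1
prominence floor exists because z-scoring a near-flat center amplifies
noise wiggles into spurious peaks everywhere; a genuinely molt-locked
center peaks well above one standard deviation. Candidate genes are those
whose maximum-membership cluster is selected. Cluster count is a
per-dataset choice in the 5–7 range (default 6).

### Regulator intersection and NR counting

An orthogroup survives the cross-species screen only if every species
contributes at least one expression-screen candidate to it — one empty
candidate set annihilates the result (and warns). The representative
species' gene list is the sorted, de-duplicated union over surviving OGs.
The transcription-factor filter keeps genes with at least one hit below
1e-5 against a fixed panel of 34 Pfam TF domains; accession version
suffixes are ignored on both sides. Nuclear receptors are genes (isoforms
collapsed by an explicit map, or by stripping a trailing `.digit`/letter
variant suffix) with a Hormone_recep (PF00104) hit below the same
threshold.

### Structure comparison

Chains are CA traces; LBDs of 150 residues or fewer are discarded
(`min_len = 151`) to focus on complete domains. Superposition is the
Kabsch least-squares rigid fit with the reflection excluded (det +1
always); degenerate (collinear) configurations raise. TM-score uses the
standard functional form and d0 = 1.24(L−15)^⅓ − 1.8 clamped at 0.5
(active for L ≤ 21), maximized over superpositions by iterative re-fitting
on close pairs. Alignment is a deliberately simple heuristic: every
gapless sliding offset is scored by one superposition, the best three
seeds plus a leading-fragment (length ≤ 40) seed then iterate
superpose → score pairs by 1/(1+(d/d0)²) → dynamic programming with
gap-open 0.6, free gap extension and free end gaps → re-superpose until
the correspondence is stable (≤ 20 iterations). Everything is
deterministic. Exact numeric agreement with the TM-align binary is not
promised; the contract is rank agreement (same-fold beats different-fold),
which the tests enforce 100/100 at 0.5 Å noise on controlled folds.
Normalization defaults to the reference chain length; query normalization
is a flag, as the appropriate convention depends on the comparison's
direction. Classification is the per-query argmax over references, ties
broken lexicographically and flagged; histograms use fixed 0.02-wide bins.

## Synthetic data: what it emulates and what it does not

* `gen_presence_matrix` — single-gain/multiple-loss evolution with
  per-edge loss probability and missing-data corruption of absences. It
  does not model lineage-specific rates, gene gain, or correlated
  assembly failure across related species.
* `gen_orthogroups` — planted origin nodes drawn from a user distribution,
  1–2 genes per species, within-taxon thinning; "clean" OGs keep every
  descendant taxon represented so the planted origin stays
  reconstructible. No paralogy structure or annotation noise.
* `gen_expression_timecourse` — Gaussian bumps of amplitude 10 over
  baseline 2 centred 1 h before each molt (hourly grid over 0–38 h, molts
  every 8 h, matching the few-hour anticipation of molt-locked genes on
  the time grids of public molting time courses), 30% planted fraction,
  additive noise of sd 0.1× amplitude, background genes flat or peaking at
  a random phase away from the pre-molt window. Bumps were chosen over
  sinusoids because molt-locked genes show sharp pre-ecdysis peaks, not
  symmetric oscillation. Real data add count noise, trends and missing
  stages that the generator does not emulate — passing tests demonstrate
  correct inference under the stated model, not robustness to every real
  artifact.
* `gen_hit_tables` — a planted ortholog bijection with reciprocal best
  e-values below 1e-25 and decoys at ≥ factor × the query's true e-value.
  With that bound decoys can never displace a true best hit, so recall
  degradation is probed through an explicit lognormal jitter knob instead.
* `gen_structure_pair` — rigid copies of two idealized CA folds (a
  three-helix bundle and a four-strand meander, 160 residues) with
  isotropic coordinate noise. No loops, packing or secondary-structure
  realism; sufficient for rank-based classification contracts.

All generators are deterministic given (parameters, seed) and their
outputs validate against the consuming stage's type invariants.

## Numerical choices and degenerate inputs

* FCM: zero-distance membership convention as above; convergence on
  absolute objective change < 1e-6.
* Dollo: families with no present leaf raise (`family never observed`)
  rather than guessing an origin.
* Kabsch: the second singular value must exceed 1e-9× the largest, else a
  conditioning error; fewer than 3 pairs is a size error.
* Alignment DP runs in a numba-compiled kernel; scores are plain float64
  and the traceback re-derives pointers, keeping memory at two (L+1)²
  matrices.
* Newick: numeric internal labels are bootstrap supports and must lie in
  [0, 100]; non-numeric labels are clade names; duplicate labels are
  validation errors; unbalanced parentheses report the character offset.
* PDB reading: one record per residue from the CA atom; residues without
  CA are skipped with a warning; disordered-atom selection follows
  Biopython's default (highest occupancy, first on tie).

## Problem sizes in the shipped checks

The test-suite property checks run at deliberately modest sizes chosen to
make the statistics decisive while keeping the suite quick: 500 random
trees of ≤ 12 leaves against the exhaustive oracle, 10 expression seeds of
150 genes on a 39-point grid, 100 reciprocal-best-hit replicates of 12
orthologs with 24 decoys, and 100 structure trials per fold at 160
residues. The acceptance script's worked example is the 14-taxon fixture
and is exact.

## Known limitations

* The coverage rule cannot distinguish an OG truly born at an ancestor
  from independent gains in all descendant taxa; with single-gain
  orthology semantics this is the intended reading.
* The iterative homolog screen inherits any bias in the offline search
  outputs; it cannot rescue a species whose hit tables are absent (these
  are reported as uncoverable, not fatal).
* Pre-molt selection assumes molt events are annotated on the same time
  axis as the expression columns; ordinal stage labels must be mapped to
  a numeric axis upstream.
* The structural aligner is not TM-align: it has no fragment library or
  secondary-structure seeding, and its absolute scores on hard (low
  similarity) pairs are less converged than its ranks.
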