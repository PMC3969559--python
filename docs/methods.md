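# Methods

## Problem and data model

The unit of analysis is a gene family: one unrooted maximum-likelihood (ML)
tree over eukaryotic and prokaryotic protein sequences, plus N bootstrap
replicate trees over the same leaves (N = 100 by default), read through a
taxonomy table mapping each sequence to its species, taxonomic group (phylum,
or class for Proteobacteria and Firmicutes), domain and — for eukaryotes —
supergroup (Unikonts, Plantae, Chromalveolates, Kinetoplastids,
OtherEukaryote).

Because gene trees are unrooted, "monophyletic" is formalized as the *clan*:
a leaf set forming one side of some bipartition (single leaves and the full
leaf set are trivial clans). All structural queries — clan membership, the
sister group of a clan, the tripartition around the node at the base of a
clan's stem — are implemented on an adjacency representation with a canonical
traversal rooted at the lexicographically smallest leaf label, which makes
every tie-break deterministic across runs and platforms. Newick parsing and
writing are delegated to dendropy; bootstrap values are read from internal
node labels, with a fallback to bracketed branch comments (`)[90]:0.1`),
both of which occur in ML program output. Missing branch lengths default to
1.0 with a logged warning (only root placement and pruning depend on lengths,
never supports). Degree-2 nodes left over from rooted Newick strings are
collapsed, their lengths summed.

## LECA clades

Eukaryotic clades are the maximal clans of exclusively eukaryotic leaves;
they are pairwise disjoint and cover all eukaryotic leaves. A clade is traced
back to LECA when its *species* counts (never sequence counts — in-paralogs
must not inflate ancestrality) satisfy at least one of:

* R1 — ≥ 2 Unikont species and ≥ 2 Plantae species;
* R2 — ≥ 2 Unikont and ≥ 2 Chromalveolate species;
* R3 — ≥ 2 Plantae, ≥ 2 Chromalveolate and ≥ 1 Kinetoplastid species.

Each rule demands two distant supergroups, so lineage-specific expansions
(e.g. an opisthokont-only family) never qualify. Kinetoplastids are treated
as a supergroup label disjoint from Chromalveolates. Multiple LECA clades in
one family are analyzed as independent units.

Recent eukaryote-to-prokaryote transfers can make the eukaryotes appear
paraphyletic: a small prokaryotic clan nested among diverse eukaryotes splits
what is really one clade. Instead of manual tree inspection, `flag_intruders`
flags every maximal prokaryotic clan of ≤ 2 leaves (configurable) whose
removal merges ≥ 2 eukaryotic clades jointly spanning ≥ 2 supergroups; the
pipeline prunes flagged leaves when auto-pruning is enabled and logs every
pruning. Two deliberate consequences of the clan formalization: a single
prokaryote in a tree can never split the eukaryotes (its complement is a
clan), so it is never flagged; and a small prokaryotic *outgroup* clan
positioned between eukaryote blocks is a legitimate candidate — as a
safeguard, pruning is skipped whenever it would leave the tree without any
prokaryote. This heuristic is a declared approximation of an inherently
judgment-based step; its parameters ("isolated" = clan size ≤ 2, "diverse" =
≥ 2 supergroups) are configurable, and all flags are reported even when
pruning is off.

## Representative sampling

Large clades are reduced to k = 10 representatives (configurable). The clade
subtree is rooted by the least-squares criterion: the root is the point on
any edge minimizing Σ (d(root, leaf) − mean depth)². For a candidate edge the
criterion is a convex quadratic in the offset, solved in closed form per edge
(two-pass dynamic program over directed-edge distance moments: count, sum,
sum of squares); the global optimum is an exhaustive scan over edges. An
all-zero-length tree is rooted at an arbitrary edge midpoint with a warning.

Pruning then repeats: compute each leaf's node-wise depth (edge count from
the root); among the maxima take the largest path-length depth; residual ties
remove the lexicographically greatest label. After each removal unary nodes
are suppressed with lengths summed and depths are recomputed — suppression
changes node-wise depths, and recomputing is what makes the selection nested
(the k−1 selection is always a subset of the k selection). The unary root is
kept: it marks the least-squares root position. This rooting is the standard
minimal-variance reading of "least-squares rooting"; the guide-tree inference
and manual curation that can accompany this step in practice are out of
scope — the sampler consumes whatever clade tree it is given.

## Configurations

A LECA clade's configuration in one tree is decided as follows. If the
clade's (representative) leaves are not a clan: **paraphyletic**. Otherwise,
for every group X and then every prokaryotic domain D, find the *largest*
clan containing the clade whose prokaryotic members all belong to X (or D) —
qualifying clans for a fixed taxon are nested, so the largest is well defined
and carries the most species. Eukaryotic leaves inside the clan are ignored
for species counting. The taxon is eligible when

1. the clade is *embedded* in the clan: at the node at the base of the
   clade's stem, at least two of the other subtrees intersect the clan; and
2. the clan's distinct-species count reaches the taxon's threshold
   (per-group table below; 10 for a domain).

The embedding condition is what distinguishes "branching inside a clade of X"
from merely being adjacent to one. It is load-bearing: in a perfect
three-domain topology the complement of the archaeal clan is a pure-bacterial
clan containing the eukaryotes (and vice versa), so without embedding every
three-domain tree would be mis-labeled domain-related — or group-related
whenever a domain happens to be represented by one group — and the
three-domain configuration would be unreachable on binary trees.

The decision order is: the most specific eligible group (**group-related**;
smallest qualifying clan wins ties, then alphabetical order, logged); else a
uniquely eligible domain (**bacterial-** / **archaeal-domain-related**; if
both domains are eligible, a residual three-domain signature, the decision
falls through); else **three-domain** when Eukarya, Bacteria and Archaea are
each clans and both prokaryotic domains have ≥ 10 species in the tree; else
**unclear**.

Group thresholds default to the reference prokaryote sampling: per group the
number of sampled species and a minimum (an integer, or HALF = half the
sampled species rounded up — e.g. 8 of 15 for Actinobacteria — or NEVER for
groups sampled too thinly to ever be assigned, e.g. Fusobacteria with one
genome). Species-count comparisons use ≥, the reading under which the HALF
example is attainable. The table is overridable from YAML.

`classify_naive` implements the sister-clade-identity criterion for contrast:
the lowest-rank taxon shared by all members of the clade's sister group
(group, else domain, else "mixed"). It is deliberately over-confident — a
single transferred sequence as sister names its own group — which is exactly
the failure mode configurations are designed to resist.

`bootstrap_configuration_profile` classifies the clade in every replicate and
reports per-label frequencies (summing to 1, paraphyletic included), the
per-group association fractions, and the modal label. Modal ties break by
specificity: group-related, three-domain, domain-related, unclear,
paraphyletic; alphabetical within a level; ties are logged.

## Support measures

Classical branch support cannot describe a clade's attachment point, which
involves a node rather than a single branch. Two statistics are computed at
the node at the base of the eukaryote stem:

* **NBS** — the percentage of replicates containing the ML tree's base
  tripartition, i.e. in which its three adjacent bipartitions co-occur.
  Replicates where the clade is not a clan contribute 0. Exact tripartition
  occurrence is required, not approximate sister overlap.
* **SGS** — with G_i the sister group (the smaller of the two prokaryotic
  subtrees at the clade's base; equal sizes break to the lexicographically
  smaller label tuple) in replicate i:

  SGS = 2/(N(N−1)) · Σ_{i<j} s(G_i, G_j),   s = Jaccard = |∩| / |∪|,

  with s = 0 whenever the clade is paraphyletic or its base multifurcating in
  either replicate. SGS is 0 under complete disjunction of sister groups and
  1 under absolute stability. The pairwise similarity is pluggable
  (`sgs(..., similarity=...)`) so alternative readings (overlap coefficient,
  comparison to the ML sister group) can be swapped without touching callers.
  Identical sister sets are collapsed to multiplicities before the pair sum,
  so the usual near-stable ensembles cost far less than N²/2 set operations.

SGS is the more permissive measure, but not pointwise ≥ NBS/100 under the
pairwise-Jaccard definition: replicates that agree with the ML tripartition
have identical sister sets, which yields the bound
SGS ≥ p(pN−1)/(N−1) with p = NBS/100 — "at least as high as the NBS" holds up
to O(1/N) slack, and the test suite asserts exactly this bound rather than
the loose claim.

Replicates must share the ML tree's leaf set; a mismatch is a hard error
rather than a silent renormalization.

`monophyly_support` (percentage of replicates in which a taxon's leaves form
a clan) serves the domain-level questions; the near-universal filter keeps
families with representatives for ≥ 90% of the sampled species of *both*
prokaryotic domains (count rounded up — with the default design, 36 of 39
archaea and 130 of 144 bacteria), since only widely present, vertically
inherited genes are informative about the relationship between domains.

`calibrate_sgs_threshold` takes reference clades of known expected origin
(e.g. families whose genes are organelle-encoded in a deeply sampled
mitochondrial genome) with their SGS values and assigned groups, and returns
the smallest threshold t such that every reference with SGS > t is correctly
assigned — operationally, the largest SGS among incorrect references, 0 if
none. When no reference lies above t the result is flagged unusable.

## Pipeline

`run_pipeline` consumes a directory of `<family>.ml.nwk` + `<family>.boot.nwk`
files and one taxonomy TSV. Per family: detect clades (intruder pruning on),
sample k = 10 representatives, restrict every tree to the representatives
plus all non-clade leaves — the study design this emulates re-infers trees
from representatives, and the restriction is the tree-level analogue —
then discard clades whose representative-set monophyly support is ≤ 50%
(strict: exactly 50 is discarded; configurable), classify the ML tree and the
replicate ensemble, and compute NBS/SGS plus per-domain monophyly supports
and the near-universal flag. Families without a replicate file produce
ML-only rows with blank supports and a warning; taxonomy gaps are a hard
error naming the leaves. Every family lands in exactly one of: report rows,
the no-LECA log, or the ambiguous log. Rows are sorted by configuration class
(group-related, bacterial-domain, three-domain, archaeal-domain, unclear,
paraphyletic) and decreasing NBS; the summary table counts clades per
configuration under both the ML-tree and the modal-bootstrap criterion. The
pipeline is a pure function of its inputs: reruns are identical.

## The simulator

The generator emulates the statistical structure of the study inputs, not
sequence evolution. The species design defaults to the reference sampling
(31 prokaryotic groups, 39 archaeal + 144 bacterial species) plus a
19-species eukaryote panel spanning the supergroups (6 Unikonts, 5 Plantae,
5 Chromalveolates, 2 Kinetoplastids, 1 other). The species tree has
monophyletic groups, domains and supergroups, topology
((Archaea, Eukarya), Bacteria), random within-group topologies and
exponential branch lengths (mean 0.2 substitutions/site — typical of
single-protein ML trees and sufficient to exercise rooting and pruning).

A gene family applies, in order: per-species gene loss (default 0; a core of
two Unikont and two Plantae species is never lost, because the generator
models the population of families that *passed* LECA detection — families
that would fail were discarded upstream in any real screen); Poisson(hgt_rate)
replacing transfers (the recipient leaf is re-attached on a donor leaf's
terminal edge, donor drawn from a different group); and the origin scenario
for the eukaryote clade — `EGT_FROM(g)`: attached on an edge strictly inside
donor group g's clan; `VERTICAL_ARCHAEAL`: attached on the inter-group
backbone of Archaea (never inside a single group, which would legitimately
classify as group-related); `LUCA_THREE_DOMAIN`: attached between the two
prokaryotic domains; `UNCLEAR_MIX`: domains interleaved by forced
cross-domain transfers before a uniform attachment. Every loss and transfer
is logged and replays to the emitted topology.

Bootstrap ensembles are emulated topologically rather than by resampling
alignment columns: the pipeline consumes trees only, and topological
perturbation gives analytic control of the expected supports. Each replicate
copies the family tree; with probability q the eukaryote clan is detached and
re-attached to a backbone edge drawn from a distance-decaying kernel
(weight ∝ decay^distance, decay 0.5, the true edge excluded — so a replicate
retains the base tripartition with probability exactly 1 − q and
E[NBS] = 100(1 − q)); with probability r one random internal edge is
NNI-perturbed. A constructed confound generator places a single transferred
sequence as the eukaryote sister (the classic recent-HGT trap for the naive
criterion). Everything is deterministic under the configured seed; datasets
written twice are byte-identical.

What passing the simulation-based tests does *not* show: robustness to
alignment error, long-branch attraction, model misspecification, rate
heterogeneity across lineages, or paralogy beyond single-copy families —
none of which the generator emulates. Results on real data depend on those
factors; the tests establish the correctness and calibration of the
*inference machinery* given trees.

## Numerical and degenerate-case choices

* Sister-group size ties: lexicographically smaller sorted label tuple.
* Multifurcating base at the eukaryote attachment: NBS contribution 0 for
  that replicate; SGS similarity 0 (same treatment as paraphyly).
* A clade whose complement is a single leaf has that leaf as sister but no
  base tripartition (NBS undefined → error at the caller's level).
* Least-squares root: per-edge closed form with clamping to the edge; global
  scan keeps the first strict improvement (> 1e-12) in a fixed edge order.
* Species thresholds compare with ≥; HALF = ceil(sampled/2).
* Frequencies in profiles are exact rational counts over N; reported floats.
* All randomness flows from one integer seed through numpy Generators; no
  global random state is touched.

## Known limitations

* The intruder heuristic approximates a judgment call; it can flag small
  outgroup clans in depauperate trees (see safeguard above) and cannot
  recognize intruders larger than its size bound.
* Domain-level labels require ≥ 10 species by default; scaled-down designs
  must scale `domain_min` and the group table accordingly (the simulator's
  default design needs no adjustment).
* The pipeline classifies on trees restricted to representatives rather than
  re-inferring trees from representative sequences; with ≤ 10-sequence clades
  (as in all simulated designs) the two coincide.
* SGS compares sister *sets* only; branch lengths and supports inside the
  sister group are ignored by design.
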