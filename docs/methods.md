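# Methods

`paleophylo` implements the analysis workflow used to confront a
morphologically intermediate fossil with a molecular phylogeny: distance
networks over categorical (anatomical) characters with bootstrap and
posterior support overlays, exhaustive parsimony and likelihood placement
of query taxa into a fixed backbone, and partition-wise outgroup
root-placement scans with gene jackknifing.  This note records the models,
the numerical choices, and what the synthetic data generator does and does
not emulate.

## Character matrices and distances

A `DataMatrix` stores each cell as a *set* of states over the character's
alphabet, which covers fixed states, polymorphisms (`{12}`), IUPAC
ambiguity codes, and missing entries uniformly.  Missing cells (`?`, and
gap `-` by default — configurable, since gap handling in morphological
matrices is a matter of convention) carry the full alphabet for parsimony
and likelihood and are excluded ("pairwise deletion") from distances and
patterns.  `N`/`X` in nucleotide data are treated as missing: a
full-ambiguity code carries no information.

The **mean character distance** between two taxa is the fraction of
characters scored in both whose state sets are *disjoint*; overlapping
sets (e.g. `{0,1}` vs `{1}`) count as matches.  This is the common
convention of splits-graph software for polymorphic cells; a fractional
overlap rule would down-weight polymorphisms instead, and the disjointness
rule is the documented default.  Distances are a premetric on [0, 1]
(symmetric, zero diagonal); the triangle inequality is *not* guaranteed
under pairwise deletion and is not asserted.  Pairs with no shared scored
characters get NaN and deliberately abort the neighbour-net rather than
being imputed — for the fossil-rich matrices this targets, imputation
would silently fabricate signal.

**Pattern accounting.**  Two columns share a pattern iff their full
taxon-state vectors (including missingness) are identical.  The
pattern-share statistic of a partition subset is the percentage of the
concatenated matrix's distinct patterns that occur within the subset's
columns.

## Neighbour-net

The neighbour-net generalizes neighbor joining: agglomeration produces a
*circular ordering* of taxa, and non-negative least squares fits weights
to the n(n−1)/2 ordering-compatible splits so that split-path distances
approximate the input.  The agglomeration keeps clusters of one or two
active nodes (chain ends): cluster pairs are selected by the NJ adjusted
distance on cluster-mean distances; the joining node pair is selected by
the same criterion with the two clusters' end nodes promoted to
singletons; chains longer than two nodes are reduced end-inward with the
standard 2/3–1/3 mixture and the averaged internal distance.  Ties break
to the lowest index pair, making results platform-deterministic.  The
implementation was cross-checked against the independent implementation
in the R package phangorn (identical orderings on generic random
matrices; one test keeps this comparison in the suite) and satisfies the
defining exactness property: any distance matrix that *is* a non-negative
combination of one circular ordering's splits is reproduced with residual
< 1e-6.

Weights come from `scipy.optimize.nnls` on the dense pair-by-split
incidence system.  Splits with weight ≤ 1e-8 (configurable) are dropped
as numerical noise from the active-set solver; the threshold is declared
rather than matched to any particular viewer's undocumented filtering.
Support values (bootstrap percentages, posterior probabilities) are
frequencies of each split in replicate/posterior tree samples, computed
on unrooted topologies; splits present in samples but absent from the
network are reported separately rather than dropped.

## Parsimony

Generalized Fitch counting: polymorphic leaf cells enter as their state
set, missing cells as the full alphabet; characters are unordered (no
step matrices), matching how Lewis-model software treats the same data.
Multifurcations are folded pairwise, which equals scoring an arbitrary
binary resolution and is exact for the binary trees used here.  Fitch
scores depend only on the unrooted topology — asserted on random
re-rootings — which is why alternative rooting scenarios of one backbone
always optimize to the same tree length.

`min_steps` counts the states that must appear (observed in scored,
non-polymorphic cells) minus one; the consistency index is
`min_steps / observed_steps` with CI = 1 for characters needing no steps.
The insertion scan attaches a query to every branch (pendants included),
re-scores, and reports the full ranking; ties are reported, never broken,
because tied most-parsimonious placements are themselves a result.

## Likelihood

Felsenstein pruning with per-pattern rescaling.  Models:

* **Mk** — Lewis' k-state symmetric model (uniform frequencies, equal
  exchangeabilities), with the closed form
  `P_same(t) = 1/k + ((k−1)/k) e^{−kt/(k−1)}` under the global
  normalization of one expected substitution per unit branch length.
* **multistate-GTR** — equal exchangeabilities with empirical per-character
  state frequencies (+1 smoothing).  This is a deliberate, documented
  reconstruction of "GTR for multistate characters": full exchangeability
  estimation for small categorical alphabets is not identifiable at these
  data sizes and is not implemented.
* **DNA-GTR** — general time-reversible with optional discrete-gamma rate
  variation (4 equal-probability categories, category means).

Categorical characters use a per-character alphabet: the states observed
for that character, minimum two (`alphabet="declared"` keeps the full
declared alphabet, used by the exhaustive-summation oracle tests).
Transition matrices come from the eigendecomposition of the symmetrized
rate matrix; likelihood evaluation groups characters by state count with
stacked spectra so that one vectorized pruning pass serves each group.
The evaluator caches this workspace per matrix object; matrices are
treated as immutable once they enter likelihood code.

**Ascertainment.**  The variable-only (Mkv) correction divides each
character's likelihood by 1 − P(constant) on the same tree.  It is off by
default — the original analyses cite Lewis' model without stating the
conditioning — and exposed behind a flag.  Note the correction *raises*
the log-likelihood of variable characters (conditioning re-normalizes
onto observable patterns).

**Branch lengths** are optimized coordinate-wise under bounds
[1e-8, 100] with tolerance 1e-6 and at most 20 sweeps (scans use fewer;
see below).  Each one-dimensional problem is first bracketed on a fixed
log-spaced grid and then refined by bounded Brent — likelihood surfaces
in a branch length are extremely flat at the long-branch plateau, and a
naive bounded search over the full range can converge there.  Moves are
accepted only if the log-likelihood does not decrease, so the score is
monotone across sweeps.  The gamma shape, when optimized, uses the same
scalar routine with bounds [0.05, 50].

## Tree inference and resampling

* **BioNJ**: standard NJ selection with variance-weighted reduction
  (variances initialized to the distances); negative length estimates are
  clamped to zero.
* **NNI hill climbing**: sweeps over internal edges, both alternatives
  per edge, accepting strict improvements; ML moves re-optimize branch
  lengths (short sweeps per evaluation).  Strict-improvement NNI has
  genuine plateau-locked local optima even on five taxa — the two
  antipodal double-swap topologies of any target tree — so the search is
  an exact hill climber, not a global optimizer; the test suite verifies
  both the climbs and the locked endpoints.
* **Bootstrap**: characters resampled with replacement, with per-character
  weights as sampling multiplicities; each replicate re-infers by NJ, MP
  or ML, with MP/ML starting from the replicate's BioNJ tree (the
  fast-bootstrap economy).  Default 1,000 replicates (the original study
  used 10,000; a flag restores that) keeps desk-scale runs fast.  Rare
  replicates with undefined distance pairs impute the maximum observed
  distance — a bootstrap-only concession, never applied to primary
  distances.
* **Mk MCMC**: single-chain Metropolis–Hastings over (topology, branch
  lengths); proposals are a random NNI (p = 0.5) or a single-branch
  log-uniform multiplier in [e^−0.5, e^0.5] (p = 0.5, Hastings ratio =
  the factor); priors are uniform on unrooted binary topologies and iid
  Exponential(mean 0.1) lengths.  Posterior probabilities are post-burn-in
  thinned split frequencies.  The sampler passes the standard prior
  recovery check (constant data leave the topology posterior
  exchangeable, so every 2-vs-3 split on five taxa has PP 3/15).  No
  heated chains; the sampler targets matrices of a few dozen taxa.

All stochastic routines take integer seeds and reproduce bit-for-bit.

## Evolutionary placement and character weighting

Queries are placed on every branch of a fixed backbone.  ML placement
attaches at the branch midpoint and optimizes the pendant branch only
(full re-optimization behind a flag), then reports softmax likelihood
weights over branches — the placement-probability semantics of the
evolutionary placement algorithm.  MP placement scores weighted step
increases via the insertion scan and reports ranks (inverse-rank weights
are listed for convenience but are not probabilities).

The three character-weighting schemes are declared reconstructions of the
original analysis' calibration step, which the source work does not
specify numerically: **MP** weights characters by their consistency index
on the backbone (floored at 1e-3 so no character is silenced); **ML_MK**
and **ML_GTR** weight by `exp(ℓ_c − max ℓ)` from per-character backbone
log-likelihoods under the respective model, rescaled to mean one.
Position swaps — queries whose best branch differs across schemes — are
exactly what the swap report records, since morphologically intermediate
(ancestral-grade) taxa are the ones expected to move.

Placement operates on the molecular backbone *topology* with
morphological scoring by default; scoring a concatenated matrix instead
is a caller decision (pass the concatenation), not a separate mode.

## Root-placement scans and gene jackknifing

Root hypotheses are defined by ingroup clades (plain taxon lists, so the
machinery is not tied to any particular family): a branch realizes a
hypothesis iff it separates exactly that clade.  Per partition, ingroup
branch lengths (and gamma shape) are re-optimized on the partition's
columns — partitions differ strongly in rate — each outgroup taxon is
placed as an ML query, per-branch likelihood weights are averaged over
outgroups (attachment of a pre-resolved outgroup subtree is the
generator's concern; the scan places taxa one at a time), and weights are
pooled by hypothesis.  Per-subset supports plus "other" sum to one;
"other" pools every unclassified branch, so a diffuse scan correctly
reports "other" on uninformative data.  Partitions with fewer than four
variable columns are flagged low-information but still reported.

Gene jackknifing runs the same scan on the concatenation, each partition
alone, and each leave-one-out concatenation (1 + P + P subsets;
leave-one-out is skipped when P = 1, where it would be empty).  The
focal-split bootstrap table reports BS percentages for named splits per
subset.

## Synthetic data

The generators produce the statistical structure the analyses assume, at
the scale of the motivating study: a ~30-taxon × 23-character multistate
matrix (states 2–4, ~15 % missing cells) on a Yule tree rescaled to unit
mean depth, and a partitioned alignment (two "coding" partitions of 300
columns, two "spacer" partitions of 250) with an engineered rooting
conflict: coding partitions are simulated with the outgroup attached at
one ingroup branch, spacers at another.  Conflict by generating-branch
assignment is simpler than simulating convergence and is sufficient to
exercise the scan; the `outgroup_stem` length (default 0.5) emulates the
long-branch risk of distant outgroups, and recovery experiments use a
short stem (0.1) so that the engineered signal, not stem-length artefacts,
is what is being recovered.

Fossil queries evolve from a point partway down a recorded branch on a
short pendant, so the true attachment is ground truth; mosaic mode
instead mixes two clades' consensus states at a set ratio, emulating an
ancestral-grade character suite with no single true branch.

What the generator does *not* emulate: correlated characters, ordered
character states, heterotachy, indel structure, alignment uncertainty,
and fossilized birth–death sampling.  Passing recovery tests therefore
show that the machinery extracts engineered signal at realistic scale,
not that real fossils are placed with those accuracies.

## Problem sizes used in the test and acceptance runs

Oracle and closed-form checks run at n ≤ 8 taxa where exhaustive
enumeration is feasible.  Recovery experiments use the study-scale
generator defaults: placement recovery on a 10-taxon backbone with 30
characters and pendant 0.1 over 50 replicates; conflict recovery over 20
seeds of the 4-partition conflict dataset; one jackknife flip experiment.
Bootstrap experiments use 200 replicates and the MCMC prior-recovery
check a 30,000-step chain — sizes chosen so a full run completes on a
single CPU in minutes while keeping Monte-Carlo error well inside the
asserted margins.

## Known limitations

* NNI-only tree search (no SPR/TBR); heuristic, as documented above.
* Multistate exchangeabilities are not estimated; "GTR" for morphology
  means empirical frequencies only.
* The MCMC is single-chain with two proposal types; convergence
  diagnostics beyond acceptance rate and split-frequency stability are
  out of scope.
* Branch-length optimization is coordinate-wise; no analytic derivatives.
* The splits-NEXUS writer targets SplitsTree-compatible viewers;
  drawing/layout is delegated entirely.
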