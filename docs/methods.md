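# Methods

`glowtree` implements a comparative pipeline for asking, on a time-calibrated
phylogeny, (i) how many times a binary trait — here, bioluminescence in
ray-finned fishes — arose independently, and (ii) whether the clades carrying
it are more species-rich than a constant-rate birth–death process predicts.
This note documents the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## 1. Trait model and ancestral states

The trait follows a two-state continuous-time Markov (Mk) model with gain
rate `q01` and loss rate `q10` (events/Ma).  The transition matrix is used in
closed form,

    P00(t) = (q10 + q01·e^{-(q01+q10)t}) / (q01+q10),

with the identity returned when both rates are zero.  Tip data enter
Felsenstein's pruning algorithm as partial likelihoods; a missing state
contributes (1, 1), i.e. it is marginalised rather than imputed.  Partial
likelihoods are rescaled per node (threshold 1e-240) with accumulated log
scalers, so trees of hundreds of tips with extreme rates do not underflow.
Polytomies are handled natively by pruning over all children.

Marginal ancestral states combine the inside (downward) partials with outside
partials computed on a preorder pass; each node's two probabilities are
normalised exactly, so they sum to one by construction.

The root prior defaults to uniform (0.5, 0.5) and can be set to the
stationary distribution `(q10, q01)/(q01+q10)`.  Uniform is the default
because the reconstruction should not presuppose how common the trait was at
the root of the radiation; the choice matters only when the rates are large
or the data nearly uninformative.

### MCMC over rates and trees

Rather than conditioning on one tree, the sampler integrates over a posterior
sample of time trees: every Metropolis–Hastings iteration draws one tree
uniformly from the sample jointly with a log-multiplier update (half-width
1.0 on the log scale) of one randomly chosen rate.  Because the tree proposal
is symmetric, the acceptance ratio only carries the multiplier Hastings term.
Retained (post burn-in, thinned) iterations contribute a marginal
reconstruction of the *current* tree, so per-tree node probabilities are
averages over rate draws; trees never visited after burn-in (possible with
short chains) are reconstructed once at the posterior-mean rates.

Rate priors default to independent exponentials with mean `1/(tree height)`
— about one event per root-to-tip path a priori — configurable to
uniform(0, 100/height).  Chain defaults (1,010,000 iterations, 10% burn-in,
thinning 1,000) follow common practice for this class of sampler; every test
and script in this repository uses much shorter, explicitly stated chains
(12,000 iterations, 25% burn-in, thinning 18 for the ~300-tip analyses),
which our convergence summaries (effective sample sizes, prior-recovery KS
checks) show to be adequate at these data sizes.  All chains are
deterministic given the seed.

## 2. Origin counting

Reconstructions are binarized at a threshold (default 0.5; a node is
"present" only if P(1) strictly exceeds it, so ties resolve to absence — the
conservative direction for counting origins).  Observed tip states override
reconstructed tip marginals.  Every edge whose parent is absent and child
present is one gain; each gain is one independent origin.  Losses are counted
and reported but never folded into origin counts.  A built-in threshold sweep
(0.5–0.95) reports the sensitivity of the headline count.

The cross-tree distribution of per-tree gain counts is summarised by its
minimum, mode (ties to the smaller value), median and central 95% interval.
The minimum is always printed because "at least N origins" is the defensible
reading when reconstructions differ across trees.  Mechanism and species
tallies are computed on a reference tree: the lowest-index tree achieving the
modal count.

Each gain is classified by the mechanism annotations (intrinsic / bacterial /
unknown) of the present-state tips it subtends: a unique informative
annotation wins, several give "mixed", none give "unknown" (with a warning if
the gain subtends no present tips at all, which can happen under
reconstruction noise).  Species totals per mechanism sum the described
richness of the smallest named clade containing each gain, de-duplicated per
clade.

An optional cross-check estimator samples full character histories
(joint node states by backward sampling, within-branch histories by
endpoint-conditioned uniformization) and reports the expected number of
gains; it is off by default in the pipeline.

## 3. Clade richness under birth–death

For net diversification `r = λ − μ > 0`, relative extinction `ε = μ/λ < 1`
and crown age `t`, with `β = (e^{rt} − 1)/(e^{rt} − ε)`, the number of
extant species of a crown clade whose two basal lineages both survive is

    P(N = n) = (n − 1)(1 − β)² β^{n−2},   n ≥ 2,

i.e. `N − 2` is negative binomial.  The pmf is truncated adaptively at
cumulative mass 1 − 1e-9.  Expected-richness envelopes are equal-tail
quantiles at the requested coverage (default 95%).  A clade is flagged
*exceptionally rich* only when its described species count strictly exceeds
the upper bound; clades below the lower bound are reported separately as
depauperate, and a clade sitting exactly on a bound is neither.  Crown ages
are taken from the tree's node heights unless the richness table supplies
one.

## 4. Rate-shift search

The piecewise birth–death likelihood is edge-additive.  Within a piece under
(λ, μ):

* an internal edge from age `s` down to age `u` contributes the
  no-observed-split probability `−[r(s−u) + ln((λ − μe^{−rs})/(λ − μe^{−ru}))]`,
* the split at its child node an observed-branching factor
  `ln λ(1 − p0(u))` with `p0` the extinction probability,
* a terminal with `m` described species and stem age `s` the taxonomic
  (geometric) likelihood `ln (1 − β_s)β_s^{m−1}` with `β_s` evaluated at the
  stem age.

Constants independent of the parameters are dropped; they cancel in every
likelihood-ratio and AICc comparison.  With `μ = 0` and all terminal richness
1 this reduces exactly to the product-of-exponentials pure-birth likelihood,
which the test suite verifies against an independent implementation.
Additivity across pieces holds by construction, which is what makes the
stepwise search cheap: accepting a shift refits only the carved subtree and
its donor piece.

The search fits a single (r, ε) model (L-BFGS-B on (log r, ε), ε bounded to
[0, 0.99], multi-start at ε ∈ {0, 0.5, 0.9}; refits warm-start at the donor's
parameters), then repeatedly proposes a shift on every eligible stem edge
(edges subtending an internal node, so a candidate piece has at least three
edges), accepting the best candidate only if AICc improves by at least 4.0
(configurable).  AICc counts 2 parameters per piece plus 1 per shift
location, with `n` = number of edges.  Shift placement is stem-based: the
new rate applies to the stem edge and its whole subtree.  Candidate fits that
fail to converge are skipped with a warning.  The search is deterministic
given the tree; ties break toward the lower edge index.

Envelope rates default to the background (root) piece of the shift search on
the MCC tree, coupling the two analyses; the user can override (r, ε)
directly.  In simulation this configuration accepts spurious shifts on
homogeneous 100-tip pure-birth trees in ≲5% of replicates while recovering a
planted 10× clade in ~98% (see `tests/test_acceptance.py`).

## 5. Tree handling

Input trees must be rooted, with finite non-negative branch lengths in Ma,
unique tips, and root-to-tip depths equal within a relative tolerance of
1e-6 (dating software produces exactly ultrametric trees; the tolerance only
absorbs round-tripping error).  Non-ultrametric trees are rejected unless the
check is explicitly disabled.  Newick and NEXUS (TREES/TRANSLATE) I/O go
through dendropy; quoted labels and bracketed comments are preserved, and
internal labels are treated as labels.

The maximum clade credibility tree is the member tree maximising the product
of clade frequencies in the sample (ties to the lowest index), with node
heights replaced by the mean (or median) height of the matching clade across
the trees containing it.  Because different nodes are averaged over different
conditioning sets, a parent can in principle end up younger than a child;
such branches are clamped to zero length, as summary-tree tools convention-
ally do.

Subsampling a tree sample is either deterministic ("even": every
⌊len/n⌋-th tree) or uniform without replacement under a seed; both are
provided because dating workflows differ and neither is canonical.

## 6. The synthetic fish-like dataset

`make_fish_fixture` generates the dataset every end-to-end test runs on:

* **Tree**: a pure-birth topology simulated to 301 tips and rescaled to a
  150 Ma crown age, so simulated origins span the window from the Early
  Cretaceous to the present.  Tip counts, depth and all rates below are
  configurable.
* **Tree sample**: 500 branch-length-only replicates; node ages are jittered
  by applying lognormal noise (σ = 0.1 on the log scale) to parent/child age
  ratios, which keeps every replicate ultrametric with the same topology.
  This stands in for posterior height uncertainty; it does *not* emulate
  topological uncertainty.
* **Trait**: gain rate set to (target gains)/(total tree length), loss rate a
  fifth of that ("rare trait, rarer reversal"); trait histories are
  resampled until the realised painting has exactly 27 gains, no losses, and
  every pair of gains is *identifiable*: no two gains on sister edges, and no
  third gain inside the only side branch separating a pair.  Sister gains are
  indistinguishable from a single parental gain for any reconstruction
  method, and chain configurations collapse under one reconstructed loss, so
  excluding them is what makes "the truth is 27" a well-posed statement.
  The realised painting *is* the truth block; nothing downstream sees it.
* **Mechanisms**: 8 intrinsic, 17 bacterial, 2 unknown, painted largest-first
  (intrinsic lineages are the most species-rich ones in the real system,
  unknowns the smallest).
* **Richness**: one named clade per gain (singleton gains take their smallest
  ancestral clade with ≥2 tips); described species are drawn from the
  crown-size distribution at the clade's age under the background rate, with
  six clades planted at 3× the background net diversification (two-thirds
  intrinsic, one-third bacterial), yielding counts spanning orders of
  magnitude and a known set of truly exceptional clades.

Because the generator writes the same Newick/NEXUS/TSV formats the readers
consume, every fixture also exercises the I/O layer, and the truth block is
invariant under a disk round trip.

What passing the end-to-end tests shows: on data whose generating process
matches the model (correct Mk likelihood, ultrametric trees, identifiable
gain configurations), the pipeline recovers the planted origin count, the
mechanism split and the planted exceptional clades.  What it does not show:
robustness to model violations present in real data — topological error,
rate heterogeneity across lineages or time, ascertainment in taxon sampling,
or misassigned tip states.

## 7. Problem sizes and determinism

All simulations and chains used by the tests and by
`scripts/acceptance.py` are sized for a single CPU: 12,000-iteration chains
for the 301-tip, 500-tree analyses; 16,000 iterations for 200-tip rate
recovery; 10⁵ replicates for the clade-size distribution check; 50
replicates each for the shift-search error-rate studies.  Every random
quantity flows from one seed through `numpy.random.SeedSequence` spawning,
so all outputs are bit-reproducible given the seed, and pipeline reruns with
the same config are byte-identical.
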