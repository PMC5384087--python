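# Methods

This note records the models, conventions and numerical choices behind the
package, and what its synthetic-data tests do and do not demonstrate.

## Trees

A chronogram is a rooted ultrametric tree with branch lengths in millions
of years (my). Ultrametricity is validated on load with a relative
tolerance of 1e-6 of total depth (configurable) — dating software emits
floating-point branch lengths that never agree exactly — and tip ages are
snapped to zero afterwards. Newick parsing is delegated to dendropy;
branch lengths are mandatory except on the root edge, quoted labels are
supported, internal labels are preserved but unused. Polytomies are
tolerated by the tree model but rejected where the math requires binary
cladogenesis (branching times, DEC pruning, trait pruning).

Pagel's δ is defined on depths-from-root: `x → (x/T)^δ · T` with T the
crown depth. The `T^{1−δ}` normalization is a package convention chosen so
the transform preserves total depth, which keeps ages in my comparable
before and after rescaling for ancestral reconstruction; other tools leave
the normalization implicit. Pagel's λ is applied at the covariance level
(off-diagonals × λ) rather than by editing branches, which is exact and
cannot create negative tip branches.

## DEC biogeography

Range states are subsets of the area set, capped at `max_range_size` = 4
(the widest range any extant species occupies), ordered by size then
bitmask; the empty range exists only as an internal absorbing state.
Anagenesis follows the standard dispersal/extirpation generator; the
timeline is split into epochs (default boundaries 11, 8, 5, 0 my before
present) each with its own multiplier matrix, and a branch crossing a
boundary is propagated segment-by-segment, oldest first. Ages older than
the oldest boundary extend the oldest epoch rather than erroring, since
simulated or re-dated trees routinely overshoot.

Cladogenesis: a single-area range is copied to both daughters. A
widespread range S splits through 2|S| scenarios — for each occupied area
i, vicariance ({i} vs S∖{i}) or subset sympatry ({i} vs S) — each with
weight 1/(2|S|), and each scenario contributes both daughter orderings at
full scenario weight. This enumeration weights vicariant splits of a
two-area range at 1/4 each (the classical uniform-over-ordered-pairs
convention would give 1/6); the pruning implementation and the exhaustive
enumeration oracle in the tests share this definition, and all likelihoods
and ancestral probabilities are internally consistent under it.

The root carries a flat prior over observable states and no survival
conditioning (both switchable), matching common DEC defaults. Matrix
exponentials use scipy's Padé scaling-and-squaring for state spaces up to
64 states; the 256-state nine-area system instead propagates conditional
vectors with the Al-Mohy–Higham `expm_multiply` action, which avoids ever
forming a dense 256×256 exponential per branch. ML over (d, e) is a
bounded L-BFGS-B search in log space on [1e-8, 10]², five seeded starts by
default. "Most-probable state" ties break toward the lowest canonical
state index for determinism.

Event summaries operate on most-probable states: an internal node is an
in-situ speciation for a focal area set when its range and both daughter
ranges are subsets of the focal set (denominator: all internal nodes); a
colonization of area X is a branch whose parent range excludes X and whose
child range includes X. Both rules are deliberately simple and
deterministic; probability-weighted variants would be straightforward but
are not what the reported fractions mean here.

Multi-tree ("statistical") DEC is approximated by independent per-tree
fits plus frequency summaries over shared clades; exact posterior
averaging is out of scope.

The packaged three-class dispersal schedule (adjacent 1.0, one-barrier
0.5, long-distance 0.01, Central America isolated before 5 Ma) is a
reproducible default, not a transcription of any published matrix; real
analyses should supply their own YAML schedule.

## Trait evolution

The likelihood is the multivariate normal with mean `root·1` and
covariance `σ² C(λ, δ)`. For fixed (λ, δ), the root state and σ² have
closed-form GLS/ML profiles, so fitting reduces to a bounded search over
λ ∈ [0, 1] and δ ∈ [1e-5, 3]. The δ upper bound of 3 is the default
because boundary estimates near 3 are a recognizable signature of the
standard tools' box constraint; it is configurable. The search seeds a
5×5 grid, refines the three best cells with L-BFGS-B, and — because a
nested model must never out-score its superset — re-polishes the free fit
from any constrained optimum that beats it. LRTs use χ² with 1 df per
fixed parameter, without boundary-mixture corrections: the plain χ²₁ tail
is what reproduces the printed p-values this workflow reports
(e.g. LRT 5.16 → p 0.023).

Ancestral reconstruction first applies the fitted scalings — by default
only when the corresponding LRT is significant at 0.05, on the argument
that a non-significant scaling is noise — then computes each node's
conditional normal given the tips with a flat prior on the root state. The
root mean therefore equals the GLS root estimate and carries variance
σ²/(1'C⁻¹1). Note that conditional variances are not monotone along every
root-to-tip path: a node on a long, data-poor branch can be more uncertain
than its parent if the parent sits next to an informative sister clade.
Tips are pinned to their observations with zero variance.

An independent Felsenstein-pruning evaluation of the same likelihood (with
λ realized as a tree transform) exists purely as a cross-check; the tests
require the two routes to agree to 1e-8.

## Diversification

With t backward from the present, λ(t) = λ₀e^{αt} and μ(t) = μ₀e^{βt}, so
α > 0 means faster speciation in the past. Writing r = λ − μ,
R(t) = ∫₀ᵗ r and F(t) = 1/f + ∫₀ᵗ λ e^R, the crown-conditioned
log-likelihood of branching times t₁ > t₂ ≥ … (crown first, its own
speciation factor excluded) is

    logL = Σ_{i≥2} [log λ(tᵢ) + R(tᵢ) − 2 log F(tᵢ)]
           + 2R(t₁) − 4 log F(t₁) − n log f .

For μ = 0 this collapses exactly to the closed-form pure-birth expression
`(n−2) log λ − λ·TL`, which the tests assert; survival conditioning
(subtract 2·[R(t₁) − log F(t₁)]) is off by default and switchable. R(t) is
closed-form for exponential rates; F(t) is closed-form when μ₀ = 0 and
otherwise integrated by 24-point composite Gauss–Legendre between
consecutive node times, vectorized over all segments (the integrand is
smooth, and an adaptive-quadrature route with absolute tolerance 1e-8 is
kept as the verification path — the two agree to 1e-7 in the tests).

Model selection uses AIC with k = 1, 2, 2, 3, 3, 4 free parameters for
BCST, BVAR, BCST-DCST, BVAR-DCST, BCST-DVAR, BVAR-DVAR; "supported" means
every rival sits more than 2 AIC units behind. Fits use bounded L-BFGS-B
(λ₀ ∈ [1e-4, 10], μ₀ ∈ [0, 10], α, β ∈ [−2, 2]) from one
method-of-moments start plus seeded random starts (8 by default); ranking
ties break by lower k then lower λ₀.

The shift scan fits, per tree, a homogeneous constant-rate birth–death
model, then greedily accepts the internal node (clade of ≥ 4 tips) whose
own (λ, μ) regime improves AICc by at least the threshold (default 4),
iterating until no acceptance. The two-regime likelihood factorizes over
a branch partition: each regime's constant-rate branch and event factors
use survival-to-present probabilities under that regime's own rates — an
approximation for ancestors of the shift (their descendants' regime
changes mid-history), in the same spirit as the classical stepwise AICc
scanners. The shifted clade owns its crown event; its stem branch stays
with the background. Across trees, shift locations are matched by
descendant-tip-set Jaccard ≥ 0.9 and declared significant only at
frequency ≥ 5% of trees. At the default threshold the per-tree
false-positive probability on homogeneous 50-tip trees is close to 10%,
so single-tree hits should never be interpreted without the frequency
rule.

AIC (not AICc) is used for the six-model table, AICc for the scan, because
the two analyses play different roles: one compares a fixed small ladder of
nested models on one tree, the other searches dozens of candidate shift
points where the small-sample penalty matters.

## Synthetic data

All generators hang off one integer seed that spawns independent
substreams per stage (tree, trait, ranges, table), so stage outputs are
reproducible and order-independent. The tree simulator runs a forward
Gillespie process from a crown pair with thinning for time-varying rates
(exponential rates are monotone, so the thinning bound is an endpoint
evaluation); extinct lineages are pruned and whole-clade extinction
triggers resimulation (up to 1000 attempts — this conditions the output on
survival, a bias that is intrinsic to fixed-crown-age simulation). A
separate exact-n pure-birth sampler serves the tests that need a given tip
count. Trait values are drawn from the λ/δ-scaled covariance by Cholesky;
range histories are simulated by per-branch Gillespie within epochs plus
scenario sampling at nodes, under the same cladogenesis law as the
likelihood.

The default generator settings are the study's own scale: crown 10.6 my,
λ₀ = 0.161 /lineage/my, α = 0.110 /my, no extinction; σ² = 4·10⁴ m²/my
around a 1500 m root (chosen to reproduce the order of magnitude of
elevational spread across the checklist, roughly 250–2100 m); d = 0.05 and
e = 0.01 events/my, which yield the observed mix of single-area and
multi-area extant ranges. The synthetic species table emulates the
checklist schema exactly (the packaged checklist itself ships as a
fixture, checksum-guarded).

What passing the synthetic tests shows: the likelihoods are correct
(oracle equivalences), the optimizers find their optima (nesting and
determinism contracts), and each estimator recovers its generating
parameter at realistic sizes. What they do not show: robustness to the
features real data add — topological and dating uncertainty beyond
independent replicate trees, range assignments from noisy occurrence
records, elevational intervals estimated from very few records, or model
misspecification (non-exponential rate histories, founder-event jumps,
OU-like traits). Extirpation rates in particular are weakly identified
from extant ranges alone and routinely collapse to the lower bound.

## Known limitations

* DEC lacks the founder-event (jump) parameter; no Bayesian variants.
* The cladogenesis weighting is the package convention documented above;
  absolute log-likelihoods are not comparable with tools using the
  uniform-over-ordered-pairs convention, though ML estimates of (d, e)
  are in practice very close.
* The shift scan's two-regime likelihood is an approximation (see above)
  and its default threshold leaves a ~10% single-tree false-positive
  rate by design; the cross-tree frequency rule is the significance
  filter.
* Statistical selection between constant and slowly-varying speciation at
  small tree sizes (a few dozen tips) has limited power; simulation
  studies at exactly the study scale sit near 50% selection probability
  for the true time-varying model under AIC.
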