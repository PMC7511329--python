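# Methods

This note documents the models and procedures `playnet` implements, the
choices made where the design was genuinely open, and what the synthetic
study generator does and does not emulate.

## Networks from event logs

An event log has one row per scored play-fight initiation (pen, observation
day, initiator, recipient, reciprocated flag).  A reciprocated bout appears
once, credited to its initiator — never once per participant — so summed
undirected weights divided by two equal the reciprocated bout count exactly.
Only reciprocated bouts form edges: an ignored initiation is not a social
tie.  Networks aggregate all observation days; per-day dynamics are out of
scope.  The node set is always the full pen roster, because per-pen
normalisation (below) is defined over everyone present, including animals
that never played.

## Centrality

* **Degree / strength.**  Binary degree counts distinct partners; weighted
  degree sums incident bout counts.  In-/out- variants split receipt from
  initiation on the directed network.  Normalised values divide by the
  observed pen maximum of the same quantity (not n − 1), so the most
  connected animal in each pen scores 1; the unnormalised scores are kept
  available because Freeman centralisation needs them.  Whether the pen
  maximum includes the focal animal is immaterial under this convention
  (it always does).
* **Eigenvector.**  Leading eigenvector of the adjacency (weighted or
  binarised), computed by power iteration on A + I (the identity shift makes
  the iteration aperiodic, so near-bipartite pens still converge), tolerance
  1e-10, at most 10,000 iterations, deterministic uniform start, rescaled to
  max 1.  Tests require agreement with a dense eigendecomposition to 1e-8.
  On disconnected pens the components not attaining the leading eigenvalue
  decay to zero — the dominant-component convention — and results carry a
  `disconnected` flag when isolated animals are present.  For directed
  networks the right eigenvector of the initiator→recipient adjacency is
  used, so prestige accrues by *receiving* play from well-connected animals;
  a `transpose` flag flips the orientation.  The orientation convention is a
  package choice: either is defensible and nothing downstream depends on it.
* **Betweenness and clustering** are computed on the undirected binary
  variant only (weighted versions are not analysed), via networkx (Brandes
  accumulation and triangle counting); tests pin them to exhaustive
  shortest-path enumeration and partner-pair counting oracles on all graphs
  up to 8 nodes.

## Pen-level structure

Freeman centralisation divides the observed sum of centrality shortfalls
Σ(c_max − c_i) by the theoretical maximum of that sum on any network of the
same size.  Rather than carrying a closed form per metric, the maximum is
evaluated numerically on the n-node star graph — the canonical maximiser —
choosing, for directed metrics, the star orientation (in-, out- or mutual)
that maximises the shortfall sum.  Closed forms for degree ((n−1)(n−2)) and
betweenness ((n−1)²(n−2)/2) serve as cross-checks in tests.  Weighted scores
are divided by the *binary* star maximum, so weighted centralisations can
exceed 1; that is intentional and matches how such tables are reported.

Edge density is dyads-with-any-bout / C(n, 2) (binary) or total bouts /
C(n, 2) (weighted; exceeds 1 when dyads play repeatedly).  The pen-level
clustering coefficient defaults to transitivity (closed triads over
connected triples); an `all_triples` flag scores against C(n, 3) instead.
Transitivity is the default because observed pen values in this literature
span 0.4–0.95, consistent with the connected-triple denominator.

Treatment comparisons use the Wilcoxon rank-sum test with W reported as the
rank sum of the socialised group (the convention of the field's tables; the
Mann–Whitney U is returned alongside).  p is exact when there are no ties,
otherwise a tie-corrected normal approximation.  Medians and quartiles are
linear-interpolation (Tukey) quantiles.

## Littermate assortment

Newman's discrete assortativity is computed from the weight-normalised
litter mixing matrix; undirected dyads are counted once and symmetrised.  It
is invariant to global weight rescaling, and the binary and weighted values
coincide when all positive weights are 1.  A single-litter pen has no
defined coefficient (NaN).

**Null model.**  Litter labels are permuted over the pen roster, preserving
topology and weights exactly.  This is the standard node-label null for
discrete assortativity; an edge-rewiring null would answer a different
question (whether the *topology* is unusual) and is not what a littermate-
preference test needs.  Per-pen random streams derive deterministically from
(seed, pen id), so results are bit-reproducible and independent of pen
order.

**p-value rules.**  `paper_exact` reproduces the literal arithmetic used in
the source literature: q = #{r_obs > r_perm}/n_perm, reported as 1 − q for
nonnegative observed values and q for negative ones.  The default `add_one`
rule uses the (b + 1)/(m + 1) estimator, which cannot return p = 0.  Both
conventions choose the tested tail *after* seeing the observed sign; under a
direction-free null that inflates the rejection rate to roughly twice
nominal (measured ≈ 9% at α = 5%).  When calibration matters — simulation
studies, planned one-sided hypotheses — pass `alternative="greater"` (or
`"less"`), which is exactly calibrated under label exchangeability.  The
sign-adaptive default is retained as the descriptive reporting convention.

Note the coefficient itself is biased slightly negative in finite samples
(like a Pearson correlation over clustered observations; ≈ −0.07 on a
22-animal pen at the default bout rates).  The permutation null has the same
bias, so the test is unaffected; raw r values near zero should be read
against the permutation distribution, not against 0.

**Population preference.**  The total littermate bout count is tested
against a binomial null whose proportion is the probability that a random
within-pen dyad is a littermate pair, Σ_litters k(k−1) / (n(n−1)), averaged
over socialised pens weighted by their bout counts (a user p₀ overrides).
The test is one-sided (preference *for* littermates) and is accompanied by
the median per-animal littermate initiation proportion.  Bout counts are
clustered by dyad rather than independent, so the binomial p is approximate;
under the generator's no-preference setting it stays non-significant in
≈ 99% of replicates.

## Lesion outcomes and mixed models

Responses: contest lesion gain (post − pre), 24 h mixing gain (24 h −
pre-mix), and the 3-week fresh-lesion count transformed as log(x + 1) by
default — zero counts occur, so the plain log (available via flag) would
drop animals.  Animals missing a required count are excluded with a warning.
Attack latency is missing when an animal attacked in neither
resident-intruder test; models are complete-case on the terms they use (a
300 s ceiling imputation is a documented alternative the user can apply
upstream).

Mixed models are Gaussian with random intercepts.  Fitting goes through
statsmodels MixedLM: when one random factor contains the others nested
inside it (the study's structure — pen, contest dyad and mixing pen all sit
within farrowing batch) it becomes the MixedLM grouping with the rest as
variance components; fully crossed structures fall back to a single constant
group with every factor as a variance component.  Because variance
components at the boundary (≈ 0) can stall the MixedLM optimizer, every fit
is validated by probing the profile likelihood around the reported optimum;
if a clearly better point exists, or the fit errors, the same REML/ML
criterion is re-optimised directly by bounded L-BFGS.  REML is used for
coefficient reporting, ML for AIC and likelihood-ratio tests.

**Degrees of freedom.**  t-tests use a Satterthwaite approximation computed
from the REML profile: df = 2·(c′C(θ̂)c)² / (g′Ag), with C(θ) the
fixed-effect covariance at variance estimates θ, g its finite-difference
gradient and A the inverse observed information of the restricted
likelihood (finite-difference Hessian).  Components pinned at zero are held
fixed; df is clipped to [1, n − p] and falls back to the residual df when
the information matrix is degenerate.  Agreement with lmerTest (estimates,
SEs, df, p) is covered by a test.  All reported model p-values are
two-sided.

**Staged selection** mirrors the field's workflow: (1) backward elimination
of systematic fixed effects (sex, treatment, attack latency, plus the
context's covariates) at p ≥ 0.1, never removing a main effect that
participates in a retained interaction; (2) pruning of network traits
correlated at |r| > 0.8 — greedy over pairs by descending |r|, dropping the
later-listed trait, deterministic given column order; (3) bidirectional
stepwise AIC search over the surviving traits on the fixed-effects (OLS)
model, on a common complete-case row set, with perfectly collinear
candidates excluded first and VIF > 10 flagged; (4) a final REML mixed model
with the selected traits and their treatment interactions (interactions may
be eliminated at p ≥ 0.1, the traits themselves are protected); and (5) a
log-likelihood ratio test between ML fits with and without the trait block
on identical rows.

## The synthetic study generator

The generator emulates the experimental design, not the biology: 10 control
pens (one litter) and 6 socialised pens (two litters) over two farrowing
batches, litter sizes drawn from N(10.8, 1.65²) (minimum 3).  Per-dyad
initiation counts are Poisson with log-rate combining

* a baseline of 0.55 expected reciprocated bouts per dyad in a
  reference-size pen, chosen so simulated pen edge densities (binary ≈ 0.5,
  weighted ≈ 0.7–1.2 bouts/dyad) sit in the range reported for pre-weaning
  pigs;
* a pen-size scaling (litter_size_mean − 1)/(n − 1), encoding the observed
  ceiling on per-animal play: giving piglets twice as many potential
  partners does not double their interactions, which is what makes
  two-litter pens sparser;
* lognormal per-animal sociability frailties (sd 0.6) that generate
  overdispersion and tunable degree centralisation;
* a littermate affinity multiplier (default 2.0) active only in socialised
  pens, yielding a clear population-level littermate preference of the kind
  reported, while remaining tunable to 1 (no preference) for null
  simulations;
* a per-male multiplier (default 1.5) reproducing sex-biased play.

The initiator of each bout is drawn by relative sociability; reciprocation
is Bernoulli (default 0.7).  Attack latencies are lognormal (median 60 s,
σ = 0.9), right-censored at the 300 s test ceiling into missing values.
Lesion counts are negative-binomial (size 3) with log-means tied to the
animal's *true* network traits: normalised in-degree for the contest
response (default coefficient −1 per unit), degree × socialisation for the
3-week response (+0.75), attack latency for the 24 h response (−0.002/s);
intercepts put typical counts near 40 (contest), 70 (24 h) and 20 (3 weeks).
A truth record stores every latent quantity for recovery tests.

Deliberately not emulated: diurnal observation windows, bout durations,
partner choice by weight or sex, litter-specific affinity heterogeneity, and
observation error in scoring.  Passing tests therefore demonstrate that the
pipeline recovers structure *of this kind* from data *of this shape*; they
do not validate the behavioural scoring itself, and effects whose detection
hinges on features the generator lacks (e.g. pen-specific assortment
heterogeneity) are outside what the simulations can show.

## Numerical and reproducibility notes

* All randomness flows from explicit integer seeds (numpy Generator);
  identical seeds give byte-identical event logs and permutation traces.
* Power iteration: tolerance 1e-10, cap 10,000 iterations; ties across
  disconnected components resolve to the limit of the uniform start.
* The pipeline writes a manifest with a config hash and SHA-256 checksums of
  every CSV artefact; deterministic stages reproduce identical checksums on
  re-run, and changing only the permutation seed changes only the assortment
  outputs.
* Degenerate inputs: pens of < 2 animals have no edge density, < 3 no
  clustering or centralisation; edgeless networks return zero degree (with a
  warning under normalisation) and refuse eigenvector centrality and
  assortment; single-litter pens have undefined assortment.

## Known limitations

* Satterthwaite df relies on finite differences of the REML profile; with
  variance components near the boundary the df can snap to the residual df.
* The AIC stepwise search is greedy (single add/drop moves) and, like all
  stepwise selection, does not control selection inference; the final
  p-values are conditional on the selected model.
* Lesion counts are modelled as Gaussian after differencing/log transform,
  following the field's practice, not as counts; a count-family GLMM is out
  of scope.
* The binomial littermate test ignores dyad-level clustering of bouts (see
  above); its p-values are mildly anti-conservative in principle, though
  calibration holds under the generator's null.
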