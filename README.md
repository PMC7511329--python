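# playnet

Social-network analysis of play fighting in piglet litters, and of whether a
central play-fighting network position predicts the injuries (skin lesions)
an animal later receives from real aggression.

Juvenile pigs play fight in ways that closely mimic adult fighting, so early
play experience is a natural candidate predictor of later contest outcomes.
`playnet` implements the full analysis chain for a study design in which
litters are either kept intact ("control" pens, one litter) or socialised
pre-weaning with a neighbouring litter ("socialised" pens, two litters), play
fight initiations are scored from video, and skin lesions are counted after a
staged dyadic contest and after mixing into new social groups.  It is aimed
at behavioural ecologists and applied ethologists who want the whole pipeline
— networks, centrality, assortment, permutation inference and outcome mixed
models — reproducible from a single event log.

## What it computes

**Networks.** One network per pen from *reciprocated* play-fight bouts only,
in four variants: directed (initiator → recipient) or undirected, crossed
with weighted (bout counts) or binary.  Animals that never played stay in the
network as isolated nodes.

**Individual centrality** (per Table-style definitions used in pig social
network work): degree / in- / out-degree (binary = distinct partners,
weighted = "strength", normalised by the observed pen maximum), eigenvector
centrality (leading eigenvector of the adjacency, power iteration, max = 1),
betweenness and the local clustering coefficient (undirected binary only).

**Pen-level structure.** Edge density (realised dyads, or bouts per possible
dyad when weighted), the global clustering coefficient, and Freeman's
centralisation of each centrality metric,

```
C = Σ_i (c_max − c_i) / max_network Σ_i (c_max − c_i),
```

where the theoretical maximum is evaluated numerically on the n-node star
graph; binary centralisations lie in [0, 1], weighted ones (scored against
the binary star) may exceed 1.  Socialised and control pens are compared
with exact Wilcoxon rank-sum tests (W = rank sum of the socialised group).

**Littermate assortment.** Newman's discrete assortativity on the
litter-label mixing matrix e,

```
r = (Σ_i e_ii − Σ_i a_i b_i) / (1 − Σ_i a_i b_i),
```

with a permutation null that shuffles litter labels over the pen roster
(5,000 permutations by default), plus per-animal littermate proportions and
a population-level binomial test of littermate preference.

**Outcome models.** Three Gaussian responses — contest lesion gain
(post − pre), 24 h mixing lesion gain, and log-transformed 3-week fresh
lesions — fitted with linear mixed models (random intercepts for pen nested
in farrowing batch, plus contest dyad or mixing pen), with the staged
selection used in this literature: backward elimination of systematic fixed
effects at p ≥ 0.1, pruning of network traits correlated at |r| > 0.8,
bidirectional AIC stepwise selection of traits with VIF collinearity checks,
and a log-likelihood ratio test of the trait block.  Coefficient t-tests use
Satterthwaite-approximated degrees of freedom.

**Synthetic studies.** `playnet.generate` draws a full synthetic study with
the design's structure (22 litters, two batches, 10 control + 6 socialised
pens, litter size ~ N(10.8, 1.65²)), tunable littermate affinity, sex-biased
play, sociability-driven centralisation and lesion counts with known
dependence on the true network traits, so every stage is testable end to end.

## Worked example

```python
from playnet import (SyntheticConfig, generate, build_all_networks,
                     NetworkVariant, permutation_test, pen_metrics,
                     treatment_comparison)

events, animals, truth = generate(SyntheticConfig(seed=7))
print(f"{len(animals)} piglets, {len(events)} scored initiations")

table2 = treatment_comparison(pen_metrics(events, animals),
                              {a.pen_id: a.treatment for a in animals})
row = table2.set_index(["metric", "variant"]).loc[("eigenvector", "binary")]
print("eigenvector centralisation:",
      f"socialised {row.socialised_median_iqr}, control {row.control_median_iqr},",
      f"W={row.W:.0f}, p={row.p:.3f}")

nets = build_all_networks(events, animals, NetworkVariant(directed=False, weighted=True))
labels = {a.id: a.litter_id for a in animals}
res = permutation_test(nets["pen12"], labels, n_perm=5000, seed=42)
print(f"pen12 littermate assortment r={res.r_obs:.3f}, permutation p={res.p:.4f}")
```

prints

```
231 piglets, 2154 scored initiations
eigenvector centralisation: socialised 0.57 (0.51-0.66), control 0.48 (0.43-0.61), W=62, p=0.263
pen12 littermate assortment r=0.294, permutation p=0.0002
```

The first line is the simulated population; the second compares pen-level
eigenvector centralisation between treatments (medians with quartiles, the
socialised-group rank sum W and its exact p); the third tests whether piglets
in one socialised pen play-fought with littermates more than label shuffling
would predict (here they clearly do: the default generator plants a 2×
littermate rate preference).

The same stages are scriptable from the shell:

```bash
playnet simulate --seed 7 --out simdata/
playnet build --events simdata/events.csv --animals simdata/animals.csv \
              --variant directed,weighted --out nets/
playnet penstats --events simdata/events.csv --animals simdata/animals.csv --out table2.csv
playnet assort --events simdata/events.csv --animals simdata/animals.csv \
               --n-perm 5000 --seed 42 --out assort.csv
playnet run --config study.yaml      # full pipeline + reproducibility manifest
```

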