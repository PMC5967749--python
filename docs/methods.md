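# Methods

This note documents the statistical procedures `littoralhdm` implements,
the assumptions behind its synthetic-coast generator, and the numerical
and design choices that were genuinely open.

## Data model

The unit of analysis is an ordered 1-D chain of coastline points at ~10 m
spacing. Each point carries projected planar coordinates (meters; no
geodesy is attempted), three continuous predictors — mean sea-surface
temperature (°C), mean and minimum wave height (m) — and three categorical
predictors: slope class (ordinal 1–5, treated as categorical), geology
(metamorphic / mineral / plutonic / sedimentary / artificial) and substrate
type (natural / artificial). Habitat layers are binary presence/absence
columns. Indices are 0-based; train/test splits are index sets over
0..n−1. The loader drops rows with any missing predictor (logged count);
a chain-consistency check flags consecutive steps longer than 5× the
median step, and `order_chain` can rebuild a nearest-neighbour chain from
the northernmost point when a table arrives in arbitrary row order
(duplicate coordinates tie-break by original row order).

## Habitat model

Each habitat is a binomial GLM with logit link over main effects only
(interactions are deliberately out of scope). Fitting is by IRLS:

* convergence when the deviance changes by < 1e−8, at most 50 sweeps;
* a ridge of 1e−8 on the normal-equation diagonal keeps the solve
  well-posed under quasi-separation (common for rare habitats in small
  training stretches); such fits are flagged (`separation_flag`: any
  standardized non-intercept coefficient exceeding 15 in absolute value)
  rather than refused;
* the linear predictor is clipped at ±30 before the logistic transform,
  and predicted probabilities are clipped into (1e−12, 1−1e−12) so a
  prediction is never exactly 0 or 1;
* an all-presence or all-absence training response raises
  `DegenerateSampleError`, which the orchestration layer records as a
  scenario with status `degenerate` instead of a failure.

AIC = residual deviance + 2 × (number of coefficients, intercept and every
dummy column included); for 0/1 data the deviance is −2 × log-likelihood,
so this is the ordinary AIC. Model selection enumerates every subset of
the candidate terms (categoricals as whole blocks; at most 12 candidates,
i.e. ≤ 4096 fits) and keeps the minimum-AIC fit, breaking ties toward
fewer terms and then lexicographic term order. Following the study
protocol, selection runs once on the complete dataset and the selected
subset is then refitted inside each training sample
(`selection_mode="full"`); per-sample re-selection is available
(`"per_sample"`). Dummy coding uses the most frequent level in the
training split as the reference by default — this stabilises fits when a
rare level barely occurs in a stretch — and references can be pinned
explicitly (the generator pins slope 1 / metamorphic / natural so that
coefficient recovery is well-defined). A categorical level unseen at
training maps to the reference at prediction time, with a warning.
Explained deviance D² = (null − residual)/null × 100.

## Validation

Predictions on the held-out points are scored by

* **AUC**, computed by the rank (Mann–Whitney) formulation; tied
  probabilities contribute 1/2 per tied presence–absence pair. Bands:
  ≤ 0.5 no power, < 0.7 poor, 0.7–0.9 useful, > 0.9 highly accurate.
* **threshold**: the classification rule is presence when probability ≥ t.
  Candidate cut-offs are the midpoints between consecutive distinct
  predicted probabilities plus the two boundary candidates (below the
  minimum, above the maximum); these realise every achievable confusion
  matrix regardless of scan order. The returned threshold maximises
  sensitivity + specificity; exact ties resolve to the smallest such
  threshold, which favours sensitivity (detecting presences). By default
  the threshold is optimised on the test predictions; optimising on the
  training split is available (`threshold_on="train"`).
* **sensitivity / specificity** from the confusion matrix at that
  threshold.

Null models train on uniform random subsets of the same size, replicated
10× with consecutive seeds; metrics are reported as replicate mean and
sample SD (ddof = 1). Degenerate replicates are excluded and counted.

## Synthetic coastline generator

The generator produces data with exactly the structure the analysis
assumes, which makes it both a test harness and the substrate for the
design-comparison experiments.

* **Continuous fields.** SST is a linear north→south gradient spanning
  16.8–18.7 °C (index 0 is the northernmost point; temperature rises
  southward) plus AR(1) noise with sd 0.15 × range, clipped to the range.
  Wave heights are AR(1) fields min–max rescaled into 0.02–0.9 m (mean)
  and 0.01–0.07 m (minimum); the minimum is correlated with the mean
  (weight 0.7) and capped at it pointwise. The AR(1) lag-1 coefficient
  defaults to 0.995 — a correlation length of ~200 points (~2 km),
  mimicking slowly varying coastal fields with a single spatial-scale
  knob.
* **Categorical fields** are first-order Markov chains realised as
  geometric run lengths with expected run 200 points, echoing geological
  patchiness at the kilometre scale.
* **Coordinates** follow a gently curving southward chain (heading
  −π/2 ± 0.5 rad, AR(1)-smoothed) with 10 m spacing, so the chain starts
  at its own northernmost point and is strictly ordered.
* **Habitat layers** are Bernoulli draws from the logistic model itself:
  logit pᵢ = β₀ + xᵢᵀβ + zonal offset. The linear predictor is centred to
  mean zero (the grand mean moves into the intercept) and β₀ is then
  found by bisection over [−20, 20] so that the mean probability hits the
  target prevalence; the bracket check reports the achievable range when
  a target is unreachable. 80 bisection steps leave the achieved mean
  within ~1e−15 of the target (the contract allows 2e−3).
* **Distribution patterns.** `localized_north` adds the pattern strength
  to the logit for indices < n/2 and subtracts it beyond (mirrored for
  `localized_south`); the half-coast boundary is a deliberate
  simplification, since the contrast of interest is north vs south.
  `rare_scattered` shrinks β by a factor 0.25 so the few occurrences
  spread along the whole coast rather than clustering on a predictor
  gradient. The six default habitat recipes mirror the study system's
  mix: prevalences 0.479, 0.349, 0.072, 0.028, 0.007, 0.284 with
  northern-localized, southern-localized, scattered-rare and widespread
  patterns, and coefficient signs chosen on ecological grounds (exposure-
  loving northern habitats load positively on wave height and negatively
  on SST; the calm-water southern habitat the reverse; the infralittoral
  alga avoids artificial substrate). Zonal strengths default to 2–2.5
  logits for localized habitats and 0 for widespread/scattered ones.

What the generator does *not* emulate: 2-D coastline geometry (bays,
capes, islands), measurement error in the predictors, spatial dependence
in habitat occupancy beyond what the smooth predictors and the zonal
offset induce (no residual clustering, no dispersal), and interactions
among predictors. Passing tests therefore demonstrate correctness of the
pipeline and the direction of design effects under a known
data-generating process — not that any particular real coastline will
yield the same metric values.

## Design scenarios

Sample sizes are round(fraction × n), half away from zero. The default
19-scenario grid per habitat is: interspaced (k = 5 stretches, the design
minimum) at 10–50 %, aggregated case 1 at 10–50 %, aggregated cases 2–4
at 20–40 %. The four aggregated placements are pinned to block starts at
0 / 25 / 50 / 75 % of the chain (clipped to fit) so that an experiment
whose original placements were chosen by hand in a GIS becomes exactly
reproducible; the grid is configurable (JSON/YAML) for re-pinning.
Interspaced stretch j starts at round(j·n/k) with lengths equal to within
one point (longer stretches first); at 50 % sampling with k dividing n/2
this degenerates to selected and unselected runs of identical length.
Overlapping stretches (fraction too high for the chosen k) are refused
with a suggestion to lower k.

## Replicate-world experiments

Design comparisons are run over 20 synthetic worlds (seeds form a fixed
ladder; every random draw descends from the experiment seed) at the study
scale of n = 16,098. In each world the predictor subset is AIC-selected
on the full coast, then each design's model is trained and scored on its
own held-out complement; null models use 10 random replicates per world.
Reported values are means across worlds. With the default generator this
experiment shows: interspaced 20 % sampling beats a spatially biased
aggregated stretch by a wide margin for a localized habitat; increasing
the interspaced fraction from 20 % to 50 % changes mean AUC only
marginally for a widespread habitat; and interspaced sampling trails the
random-sampling ceiling by several hundredths of AUC — the cost of
covering an unmodelled ±2-logit zonal contrast with only five stretches
under strong spatial autocorrelation. How close "close to the null" is
depends directly on how much zonal structure the environmental predictors
leave unexplained.

## Known limitations

* The logistic model ignores residual spatial autocorrelation; standard
  errors on real, strongly autocorrelated coastline data are optimistic
  (the generator's draws are independent given the predictors, so its
  recovery checks are exact).
* Exhaustive AIC search is limited to 12 candidate terms by design.
* The AUC implementation is O(n log n) but the threshold scan enumerates
  all distinct probabilities; both are exact, not approximate.
* `order_chain` is a greedy nearest-neighbour heuristic — adequate for
  lightly shuffled tables, not a travelling-salesman solver for genuinely
  scrambled point clouds.
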