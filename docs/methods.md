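# Methods

## Model

`amews` is an agent-based model of household food security. Households are
the only agents; wards (third-level administrative units) are the spatial
unit of seeding, aggregation, and validation. Time is discrete; one round
corresponds to one calendar month, matching the monthly cadence of
sentinel surveillance and of the stressor series.

Each round every household, exactly once and in a freshly shuffled global
order, runs the cycle *strategy selection → action → adaption*:

**Selection.** A strategy is drawn from the household's set with
probability proportional to `memory_j + ε · mean(memory)`, where the
memory is an exponential moving average (weight α) of the sufficiency the
strategy realized when used, and ε is a selection floor that keeps
unproven strategies explorable. A singleton set is selected
deterministically; an all-zero memory with ε = 0 falls back to uniform.

**Action.** Per-child food availability is
`food = (Σ_d s_d · h_s,d · x_d) / n_children`. Units are normalized so
that a fully capable, unshocked, single-child household on any pure
strategy attains exactly 1.0. Health `h_p` and assets `h_a` enter
multiplicatively: `n_s = food · h_p · h_a`. The household is
nutritionally insufficient when `n_s < n_0` and acutely malnourished
(*w* = true) when the last *K* rounds were all insufficient; a history
shorter than *K* counts the missing rounds as sufficient, so no household
is malnourished before *K* observed rounds. Ward-month prevalence is the
child-weighted percentage of malnourished households — child weighting
keeps the statistic aligned with child-level MUAC prevalence.

**Adaption** is gated on having failed sufficiency this round. With
probability λ the household copies the strategy its best-performing
neighbor (highest most-recent realized `n_s`, ties broken uniformly) just
used, provided that neighbor strictly outperformed it; the copy happens
regardless of the household's own capability profile — imitation is
hill climbing on observed outcomes, not on introspection. Independently,
with the spawn probability, the household appends a renormalized Gaussian
perturbation (scale 0.1) of its active strategy. Copied strategies enter
the set with the neighbor's realized `n_s` as initial memory (the
evidence that motivated adoption) and become active; spawned strategies
enter with the set's mean memory (a common prior) and must win selection
on their own. Sets are capped at `max_set_size` (8) with lowest-memory
eviction, never evicting the active strategy.

Neighborhoods are the k nearest households (default k = 8) by planar
distance within the same ward; there is no cross-ward interaction,
migration, or intra-household allocation.

## Stressors

Stressor intensity is a monthly deviation from a long-term ward-level
average. The climate channel uses an NDVI z-score,
`factor = clip(1 + β_c · min(z, 0), floor, 1)`; the market channel uses
the relative staple-price deviation from a 10-year baseline,
`factor = clip(1 − β_m · max(r, 0), floor, 1)`. Both forms are linear in
the deviation, capped at 1 (above-average greenness or below-baseline
prices never help beyond normal), and floored at 0.1 so a data artifact
cannot annihilate a dimension. Climate maps to own production and market
to buy/barter; the local-network dimension carries no exogenous stressor.
The mapping is configurable and logged. β_c = 0.25 and β_m = 0.5 by
default, both calibratable. Shock operators compose multiplicatively:
applying factors a then b to a dimension equals applying a·b.

## Parameters

| Parameter | Meaning | Default | Notes |
|---|---|---|---|
| λ (`learning_rate`) | monthly probability an insufficient household imitates its best neighbor | 0.05 | calibration box [0.01, 0.1]; values outside are accepted and logged |
| `spawn_rate` | monthly probability of generating a mutated strategy | 0.05 | box [0.01, 0.1] |
| `n_0` (`sufficiency_threshold`) | sufficiency threshold on the normalized per-child food scale | 0.5 | calibratable; see the fixture note below |
| *K* (`persistence_window`) | consecutive insufficient rounds defining acute malnutrition | 2 | "sustained" insufficiency; configurable |
| `neighborhood_k` | neighbors per household (same ward) | 8 | 0 disables interaction |
| ε (`selection_floor`) | exploration floor in success-weighted selection | 0.05 | |
| α (`ema_alpha`) | EMA weight of the performance memory | 0.3 | |
| `init_set_size` | strategies dealt per household at initialization | 3 | drawn uniformly without replacement from the catalog |
| `max_set_size` | strategy-set cap under growth | 8 | initial sets larger than the cap are tolerated |
| `spawn_scale` | sd of the spawn perturbation | 0.1 | |

The strategy catalog defaults to the full simplex grid at step 0.25
(15 strategies), optionally restricted per livelihood zone by per-dimension
bounds (e.g., pastoral zones can drop high own-production entries).

A deliberate design choice: households start with a *small random subset*
of the catalog (default 3; the synthetic fixture uses 1) rather than the
whole catalog. If every household already owns every strategy,
success-weighted selection finds good strategies internally and the
imitation rate λ has no observable effect on prevalence — we verified
this empirically (flat calibration objective across λ). Narrow initial
repertoires make adaptive capacity a real constraint, which is the
phenomenon the model exists to study, and they reflect how narrow actual
livelihood repertoires are in arid-land contexts.

## Calibration and forecast evaluation

λ (optionally with the spawn rate and n_0) is estimated by grid search.
Each cell runs R replicate simulations (default 20) with deterministic
per-cell, per-replicate seeds; the objective is the RMSD between the
replicate-mean trajectory and observed prevalence on the proportion
scale, minimized, with macro-F1 as tie-break. Scoring the replicate mean
rather than averaging per-replicate RMSDs matters: the latter folds
Monte-Carlo variance into the objective and systematically favors
low-variance cells (in recovery experiments it piled estimates at the box
edge), whereas the mean-trajectory RMSD estimates systematic bias, which
is what the validity criterion is about. Both are reported in the grid
table. The first 6 months of every scored span are discarded as burn-in,
since the malnutrition state needs history and the strategy memories need
a few rounds to reflect realized performance.

Out-of-sample protocols: a *temporal split* calibrates strictly before a
split month and simulates through the later span with frozen parameters
(tests assert that poisoning the test rows leaves the calibrated
parameters bit-identical); *leading-edge* forecasting cuts the months
after an initial training year into consecutive non-overlapping windows
of 2 or 4 months, re-calibrates before each window on everything observed
so far, and pools the per-window ward-month forecast errors.

## Validation metrics

Prevalence is banded into IPC acute-malnutrition phases with breakpoints
(5, 10, 15, 30)% — the standard GAM band edges; the thresholds are
configurable to match any dialect of the scale. Macro-F1 averages
per-class F1 over the classes present in observed ∪ predicted, with
per-class F1 = 0 when precision + recall is 0; classes absent from both
sides are dropped (this matches scikit-learn's `zero_division=0`
behavior, which the tests cross-check). Hamming loss is the fraction of
misclassified ward-months; RMSD is computed on proportions. The joint
validity rule is strict: F1 > 0.5 **and** RMSD < 0.2 — a random baseline
on imbalanced 5-class phase data sits around F1 0.3–0.4, so 0.5 marks
genuine skill.

## Counterfactual scenarios

Shock presets: *climate* multiplies the own-production channel by 0.8 (an
early lean-season onset cutting own-production food by 20%); *economic*
multiplies household assets `h_a` by 0.5 (income halved — the shock hits
the income channel, not the market's price effectiveness, because it
models the household's ability to generate income; a config toggle can
target the buy/barter dimension instead); *combined* applies both.
Scenario multipliers compose multiplicatively with any observed stressor
factors. Adaptation modes scale the calibrated λ by 0.5 (constrained),
1.0 (baseline), or 1.5 (enabled); transformed values are not clipped to
the calibration box, only logged. All scenarios share the replicate seed
stream, so contrasts are paired and the identity scenario reproduces a
plain simulation bit for bit. Uncertainty bands are 2.5/97.5 percentiles
over replicates.

On the default fixture, enhanced adaptation offsets about 70% of the
climate shock's prevalence impact but under 10% of the economic one —
switching livelihood strategies can route around a production shock but
not an income shock. The absolute constrained-minus-enabled gap is
slightly *larger* for the economic shock (it generates far more
adaptation events); the meaningful comparison is mitigation relative to
shock impact, and that is how the property is tested. This ordering is a
property of the default configuration, not a theorem.

## Synthetic sentinel-survey generator

The generator emulates the structure of national drought-surveillance
sentinel data: a fixed panel of 30 households per site observed monthly,
one site per ward, five wards, 24 months. Capabilities are Beta-drawn
around livelihood-zone archetypes cycled across wards — pastoral
(0.90, 0.45, 0.15), agro-pastoral (0.70, 0.55, 0.35), mixed
(0.40, 0.50, 0.85) over (own production, networks, buy/barter) — with
concentration 30. The archetypes are deliberately peaked: in narrow
arid-land livelihood contexts, the channel a household is equipped for
dominates, so a mismatched strategy is genuinely costly. Assets come from
a rich/poor mixture (Beta(5,2) with weight 0.4 vs Beta(2,5) with weight
0.6), health from Beta(9,1), child counts from a truncated Poisson(2) on
{1..6}. NDVI is a small seasonal sinusoid plus noise around the long-term
mean with a scheduled 3-month drought anomaly of −2.5 z-units; price
follows the ward baseline with slow drift, noise, and a 3-month 50%
spike.

The fixture's ground-truth parameters put λ at the box center (0.05), the
spawn rate at the box floor (0.01 — inventing a genuinely novel
livelihood strategy is rare relative to imitating a neighbor),
`init_set_size` at 1, and n_0 at 0.04. Two notes on n_0: first, because
food is divided by the number of children and `h_p`, `h_a` multiply, the
generic default of 0.5 would make every household with two or more
children structurally insufficient regardless of behavior, so the fixture
needs a threshold on the scale of realized `n_s`; second, 0.04 places the
capable median household above threshold in normal months while poor,
large, or strategy-mismatched households slip under, producing endemic
prevalence in the 15–30% range with drought-driven spikes — crisis-level
conditions typical of arid-land sentinel data in drought years, and
enough spread to exercise all IPC phases. These conditions were fixed by
a sensitivity analysis of λ identifiability (trajectory signal across the
λ box versus replicate noise) during fixture design, i.e., they define
study conditions under which household adaptive capacity is actually
estimable from ward-month prevalence, which is the premise of the
calibration machinery.

What the generator does **not** emulate: MUAC measurement error, survey
non-response, household attrition or replacement, spatial structure
beyond ward labels and planar coordinates, cross-ward spillovers, or
conflict stressors. Passing tests on this fixture therefore demonstrate
internal consistency and recoverability under the stated conditions, not
performance on real surveillance data.

## Numerical choices and degenerate inputs

- Strategy weights validated to sum to 1 within 1e-9; duplicate detection
  in sets uses component-wise tolerance 1e-9.
- Ties in neighbor performance are broken uniformly at random; ties in
  the calibration objective fall to higher macro-F1, then to grid order.
- A single global RNG stream drives each simulation (NumPy PCG64); the
  shuffled update order and all per-household draws come from it, so
  identical inputs, parameters, and seed give bit-identical trajectories.
  Derived seeds (calibration cells, replicates, windows) come from
  `SeedSequence` spawn keys and stay below 2^31.
- A household table without coordinates gets uniform placement within its
  ward's unit cell; wards with a single household have no neighbors, so
  only the spawn branch of adaption can fire.
- Problem sizes used by the test suite: the default fixture is 150
  households × 24 months; the recovery experiment runs 8 ground truths ×
  10 grid cells × 20 replicates; scenario contrasts use 20 paired
  replicates. The full suite and the acceptance script each complete in
  well under a minute per component on a single CPU.

## Known limitations

- λ is weakly identified when households hold broad strategy repertoires
  or when prevalence is dominated by structurally insufficient households
  (low assets, many children); single-run estimates scatter over several
  grid steps even under favorable conditions — only the aggregate
  (median-over-truths) recovery is tight.
- The IPC banding step makes F1 and Hamming sensitive to prevalence
  values that sit near band edges; with few wards, one re-banded ward
  moves the scores substantially.
- The economic shock acts on `h_a` and is therefore partially
  confounded with the asset mixture; an alternative operationalization
  through the buy/barter effectiveness factor is available via config.
- `n_0`, the archetypes, and the mixture parameters jointly set the
  prevalence operating point; transferring the fixture to another context
  requires re-choosing them.
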