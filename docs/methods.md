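# Methods

## Model

Each foraging trip is reduced to a bivariate observation series on an
exact 5-minute grid: step length `l_t` (distance from fix *t* to
*t+1*, so the value at *t* summarizes the interval forward of *t*) and
turning angle `phi_t` (signed heading change at *t*, counter-clockwise
positive, wrapped to (−π, π]). A latent behavioural state
`s_t ∈ {rest, forage, travel}` follows a first-order Markov chain with
3×3 transition matrix Γ; given the state,

* `l_t ~ Gamma(mean_i, sd_i)` — parameterized by mean and standard
  deviation, internally shape `(mean/sd)²` and scale `sd²/mean`;
* `phi_t ~ vonMises(0, kappa_i)` — the angle mean is fixed at zero for
  all states, so only the concentration differs: directed movement has
  large κ, tortuous search small κ.

Each gap-delimited segment is an independent realization of the chain
started from the stationary distribution of Γ. The stationary choice
(rather than a separately estimated initial distribution) removes two
parameters and is the natural default when segments are arbitrary cuts
of a long behavioural process. Total parameter count: 9 emission + 6
free transition entries = 15; AIC = −2·loglik + 2·15.

State indices carry no meaning until fitted; they are mapped to
biology a posteriori by step-length ordering — smallest mean step =
rest, largest = travel, middle = forage — with a diagnostic if the
forage state does not also have the most dispersed angles. Exact ties
in step mean (a degenerate corner) are broken by angle concentration:
the most dispersed tied state takes the forage slot, the most
concentrated takes rest.

## Semi-supervision

A fix whose behavioural state *k* is known from auxiliary sensors
contributes an emission row in which all states other than *k* have
density zero. This is the standard known-states construction: the
constraint propagates through the forward recursion, so labelled fixes
pull the emission and transition estimates of unlabelled fixes rather
than merely overwriting decoded output. Consequences that the tests
assert: the constrained maximized likelihood can never exceed the
unconstrained one; the Viterbi path and the smoothed posterior agree
exactly with the label at every supervised fix (posterior of the label
is 1).

## Track preparation

Raw GPS fixes arrive irregularly (target interval 5 min, with dropouts
of 6–20 min at roughly 1.5% of positions and > 20 min at roughly 0.4%).
Coordinates are linearly interpolated onto a grid anchored at each
trip's first timestamp. Gaps ≤ 20 min (`max_gap_s = 1200`) are filled;
anything longer splits the trip into segments with no interpolation
across the gap — the model treats the pieces discretely. Interpolated
fixes are flagged but otherwise carry the same status as observed
fixes; users who want to exclude them from validation can filter on the
flag. Planar-meter coordinates are the default (and what the simulator
produces); lon/lat mode computes haversine steps and great-circle
bearings instead.

## Sensor fusion

Sensor records are matched forward: the summary attached to the fix at
*t* aggregates the stream over \[t, t+1), consistent with the forward
step/angle convention. Proportions (wet, on-water, flapping) are
time-weighted means of piecewise-constant samples; dives are event
counts, a dive belonging to the interval containing its start time.
The rules:

1. **Forage** — at least one dive in the accelerometer or TDR stream.
2. **Rest** — interval 100% wet, or > 50% on-water; no dive detected in
   any *available* dive stream.
3. **Travel** — interval 0% wet, or 100% flapping; same no-dive
   condition.

Rule 1 dominates (the rest/travel rules are explicitly conditioned on
no dives). If both dive streams are missing, rules 2–3 may still fire
on immersion/activity evidence alone — birds carrying only a wet–dry
logger contribute known rest and travel but never forage. Evidence for
both rest and travel at once is incoherent; the fix stays unknown with
a conflict flag. The 100%/0% comparisons are exact by default, with a
configurable epsilon for float-safe input.

## Fitting

Maximum likelihood by L-BFGS-B on unconstrained working parameters
(log step means, log step sds, log concentrations, row-wise multinomial
logits of Γ), gradients by finite differences, gradient tolerance 1e-8,
bounded to keep the parameters in physically sane ranges (κ ≤ 500).
The forward recursion is computed with per-fix scaling plus a max-shift
of the log densities, so likelihoods stay finite for observations
arbitrarily far into distribution tails.

Starting values come from k-means (k = 3) on **log** step lengths —
on the raw scale the travel state's variance dominates the
squared-distance objective and k-means merges rest with forage while
splitting travel, a local optimum restarts rarely escape; the log scale
respects the orders-of-magnitude separation of gamma states. Clusters
are ordered by ascending step mean; each cluster's starting κ comes
from the mean resultant length of its angles (Best–Fisher
approximation, κ = 0 when fewer than 3 angles). The fit is rerun from
`n_restarts` (default 10) starts: the k-means values plus perturbed
copies under multiplicative log-normal jitter (sd 0.25) on the positive
parameters and on the transition rows (renormalized) — the jitter is a
deterministic function of the seed and is exactly the identity at
scale 0. The best converged restart is returned with full per-restart
metadata; with fixed structure the highest likelihood and the lowest
AIC coincide.

Numerical details: exact zero steps (possible after interpolation) are
floored to `interval_s × 1e-6` distance units before density
evaluation, since the gamma density is undefined at zero, and the
adjacent angles are set missing (heading undefined); no zero-inflation
component is used. A missing step or angle contributes a unit factor at
that fix while the fix remains in the chain, preserving transitions.
Viterbi ties break toward the lowest state index. Randomness is
confined to k-means and restart perturbation, both seeded.

## Validation design

Hold-outs are 10 independent random samples of 10% of the known-state
fixes (repeated random sub-sampling, not a partition — folds may
overlap). For each supervision fraction and fold, the model is refitted
with a random subset of the fold's training pool supervised and scored
on the fold's test fixes only, after mapping fitted states to labels.
The supervision fraction is measured against **all** fixes in the
modelled dataset, not against the known fixes — this is why a dataset
where ~10% of fixes are known has a feasible ceiling near 9% after
setting aside the test sample, and a fully sensor-covered dataset tops
out near 75%. Leakage (a supervised test fix) is a hard error.

Metrics come from the 3×3 confusion matrix (rows = reference labels,
columns = predictions): global accuracy = trace/total; per class,
sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP).
Zero-denominator metrics are reported as NA and excluded from mean ± sd
aggregation. Threshold filtering retains fixes whose maximum smoothed
state probability is at least the threshold (default 0.9) and is
applied to test fixes only, keeping metrics comparable across
threshold settings.

## Synthetic data

The generator emulates the deployment that motivates the method:
5-minute fixes; Markov switching with self-transition defaults
(0.82, 0.59, 0.76) for (rest, forage, travel) and off-diagonal mass
split evenly; movement presets at zero overlap of step mean/sd
(30/20, 600/400, 2500/800) meters and κ (1, 0.5, 15) — invented
numbers chosen to respect the qualitative short/mid/long and
tortuous-forage orderings, all overridable. `overlap_level` linearly
interpolates the forage step mean and sd toward travel's (angles are
left alone), reaching identical distributions at 1 — the opportunistic
forager's regime. Sensors: coverage is assigned per trip by default
(mirroring a double-tagged subset; per-fix mode available), default
14% of trips; covered rest intervals read fully wet and ~90% on-water,
covered travel intervals dry and fully flapping, with `wet_noise`
(default 0.05) knocking a random subset off the exact endpoints so the
strict rules stay silent there; covered forage intervals carry Poisson
dive counts (rate 1.2/interval) thinned by a detection probability
(default 0.8); a small conflict rate (default 0.002 of covered fixes)
injects contradictory rest+travel evidence. GPS gaps delete runs of
fixes so that short (6–20 min) and long (> 20 min) gap incidence among
retained positions hits 1.5% and 0.4% at `gap_rate = 1`; the start
probabilities are pre-corrected by the expected retained fraction so
the realized incidence matches the target.

What the generator does **not** emulate: GPS position error, central-
place trip geometry, diel or environmental covariates on switching,
serially correlated sensor noise, behaviours shorter than the fix
interval, and the imbalance structure of real colonies. Tests passing
on this generator therefore demonstrate correctness of the machinery
and the direction of the supervision effect, not field-data
performance levels.

## Experiment and test problem sizes

The replicated supervision-benefit experiment defaults to 10 replicates
of 36 trips × 70 fixes at overlap 0.7 with 10% per-fix sensor coverage,
2 hold-out folds and 2 optimizer restarts per fit — sizes chosen so the
full experiment runs in minutes on one CPU while leaving the
supervised-vs-unsupervised contrast far larger than its replicate
noise. Parameter-recovery checks use 200 trips × 100 fixes at overlap
0, where the generating step means are recovered within ~1% and
transitions within ~0.01. Exactness checks (forward likelihood,
Viterbi, posteriors) compare against brute-force enumeration of all
3^T paths for segments up to T = 8.

With every fix supervised, the transition part of the likelihood is a
Markov-chain likelihood plus the stationary initial terms; its
maximizer differs from the bare empirical transition frequencies by
order (number of segments)/(number of transitions), ~1e-3 at the sizes
above. The test oracle therefore maximizes the supervised chain
likelihood directly (a 6-parameter problem solved independently of the
package's optimizer) and additionally checks the empirical frequencies
at the correspondingly looser tolerance.

## Known limitations

* Three states, no transition covariates, discrete time: trips with
  strong diel structure or more behavioural modes need a different
  model class.
* The known-state construction trusts the fusion rules absolutely; a
  mislabelled sensor interval is enforced, not down-weighted.
* Finite-difference gradients make fitting robust but not fast; very
  large datasets would benefit from analytic gradients.
* At high overlap the unsupervised model's states need not map onto
  biology at all — the step-ordering label map can then be arbitrary,
  which is precisely the failure mode supervision repairs; posterior
  thresholding cannot fix a label swap.
* Interpolated fixes are treated like observed ones throughout;
  whether that flatters validation metrics on real data is untested
  here (they are flagged so users can check).
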