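# sshmm — semi-supervised movement HMMs for behavioural classification

Hidden Markov models are the workhorse for classifying animal GPS tracks
into behavioural states (resting, foraging, travelling) from step
lengths and turning angles. For species with distinct commuting trips
this works well; for opportunistic foragers that feed "on the go"
across homogeneous environments — tropical seabirds being the canonical
case — the foraging and travelling movement distributions overlap and
unsupervised HMMs misclassify badly, contaminating any downstream
habitat or time-budget analysis.

`sshmm` implements the remedy: **semi-supervision from auxiliary
biologging sensors**. A subset of fixes whose behaviour is known from
immersion (wet–dry) loggers, accelerometers and time-depth recorders is
fixed inside the likelihood, informing the fit of every other fix. The
package provides the full pipeline:

* **Track preparation** — linear interpolation of irregular GPS fixes
  onto an exact 5-minute grid, with gaps over 20 minutes splitting the
  track into segments the HMM treats discretely.
* **Sensor fusion** — forward matching of sensor streams onto fix
  intervals \[t, t+1) and rule-based known states: ≥ 1 dive ⇒ foraging;
  100% wet or > 50% on-water (and no dives) ⇒ resting; 0% wet or 100%
  flapping (and no dives) ⇒ travelling; contradictory evidence stays
  unknown.
* **The HMM** — 3 states, gamma step lengths, zero-mean von Mises
  turning angles, stationary initial distribution per segment. For a
  fix with known state *k* the emission densities of all other states
  are zeroed in the forward recursion, so labels shape the estimated
  parameters rather than being pasted on afterwards. Fitting is direct
  numerical maximum likelihood (quasi-Newton on working scales) from
  k-means starting values with randomized restarts; decoding is Viterbi
  and forward–backward state probabilities.
* **Validation** — repeated random 10% hold-outs of the known states,
  supervision-fraction sweeps, 3×3 confusion matrices with global
  accuracy and class-wise sensitivity / specificity / precision, and
  filtering by a state-probability threshold (default 0.9).
* **Synthetic data** — a generator with controllable forage/travel
  overlap, sensor coverage, detection error, conflicts and realistic
  GPS gap incidence, so the absolute benefit of supervision can be
  measured against known truth.

The model: observations per fix are step length
`l_t ~ Gamma(mean_s, sd_s)` and turning angle
`phi_t ~ vonMises(0, kappa_s)` given state `s`, states follow a Markov
chain with transition matrix `Γ`, and the supervised likelihood per
segment is `δ' B(y_1) Γ B(y_2) … Γ B(y_T) 1` where `B` is diagonal in
the state-wise emission densities with rows zeroed at known fixes and
`δ` is the stationary distribution of `Γ`.

## Worked example

```python
import numpy as np
from sshmm import (SimConfig, simulate_dataset, prepare_dataset, fit,
                   label_states, LABEL_NAMES, hmm)

sim = simulate_dataset(SimConfig(n_trips=8, fixes_per_trip=80, overlap_level=0.7,
                                 sensor_coverage=0.3, seed=42))
prep = prepare_dataset(sim.tracks, sim.sensors, sim.truth)
print(f"{prep.n_fixes} fixes, {len(prep.known_idx)} with sensor-known states "
      f"({100 * len(prep.known_idx) / prep.n_fixes:.0f}%)")

res = fit(prep.obs, n_restarts=3, seed=0)     # known states constrain the fit
mapping = label_states(res)
for i in range(3):
    print(f"state {i} -> {LABEL_NAMES[mapping[i]]:7s} "
          f"step mean {res.emissions.step_mean[i]:7.1f} m, "
          f"kappa {res.emissions.kappa[i]:5.2f}")
print(f"loglik {res.loglik:.1f}, AIC {res.aic:.1f}")

states = hmm.map_states(hmm.viterbi(res.emissions, res.gamma_mat, prep.obs), mapping)
acc = (states == prep.true_state)[prep.true_state >= 0].mean()
print(f"Viterbi vs simulated truth: {acc:.1%} of fixes correct")
```

prints

```
640 fixes, 76 with sensor-known states (12%)
state 0 -> REST    step mean    31.3 m, kappa  1.01
state 1 -> FORAGE  step mean  1930.2 m, kappa  0.33
state 2 -> TRAVEL  step mean  2477.0 m, kappa 16.69
loglik -5146.8, AIC 10323.7
Viterbi vs simulated truth: 93.4% of fixes correct
```

The three fitted states order by step length into rest / forage /
travel; the foraging state's low concentration (κ = 0.33, tortuous
turning) against travelling's κ = 16.7 (directed flight) is what the
labels anchor even though the two step distributions largely overlap at
`overlap_level=0.7`.

There is also a CLI (`sshmm simulate | prepare | fuse | fit | decode |
sweep`), and `analysis/01…04` run the two experiment series end to end
at desk scale: a supervision sweep from 0 to the feasible ceiling on a
fully sensor-covered dataset, the 0-vs-maximum comparison on a dataset
where only ~14% of trips carry sensors, and a replicated absolute
measurement of the supervision benefit under distribution overlap.

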