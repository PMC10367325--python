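"""Independent reference implementations used only by the tests.

These deliberately avoid the package's recursive algorithms: likelihoods
and decodings are computed by brute-force enumeration of all 3^T state
paths, fusion labels by a literal transcription of the rule text, and
confusion metrics by a second reading of their definitions.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import gamma as gamma_dist
from scipy.stats import vonmises as vonmises_dist


def stationary(g: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(g.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _emission_density(step, angle, mean, sd, kappa):
    d = 1.0
    if not np.isnan(step):
        a = (mean / sd) ** 2
        d *= gamma_dist.pdf(step, a, scale=sd**2 / mean)
    if not np.isnan(angle):
        d *= vonmises_dist.pdf(angle, kappa)
    return d


def path_table(params, g, steps, angles, known):
    """(paths, prob) over every admissible state path of one segment."""
    t = len(steps)
    delta = stationary(g)
    paths, probs = [], []
    for path in itertools.product(range(3), repeat=t):
        if any(k >= 0 and s != k for s, k in zip(path, known)):
            continue
        p = delta[path[0]]
        for a, b in zip(path[:-1], path[1:]):
            p *= g[a, b]
        for s, st, an in zip(path, steps, angles):
            p *= _emission_density(
                st, an, params.step_mean[s], params.step_sd[s], params.kappa[s]
            )
        paths.append(path)
        probs.append(p)
    return paths, np.array(probs)


def brute_loglik(params, g, steps, angles, known):
    _, probs = path_table(params, g, steps, angles, known)
    total = probs.sum()
    return math.log(total) if total > 0 else -math.inf


def brute_viterbi(params, g, steps, angles, known):
    paths, probs = path_table(params, g, steps, angles, known)
    # first maximum in lexicographic path order = lowest-index tie-break
    return np.array(paths[int(np.argmax(probs))])


def brute_posteriors(params, g, steps, angles, known):
    paths, probs = path_table(params, g, steps, angles, known)
    t = len(steps)
    post = np.zeros((t, 3))
    for path, p in zip(paths, probs):
        for i, s in enumerate(path):
            post[i, s] += p
    return post / post.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------


def fusion_rule_oracle(
    prop_wet, prop_on_water, prop_flapping, dives_acc, dives_tdr
):
    """Literal transcription of the known-state rules; None = missing.

    Returns (label_name, conflict).
    """
    dive_streams = [d for d in (dives_acc, dives_tdr) if d is not None]
    if any(d >= 1 for d in dive_streams):
        return "FORAGE", False
    rest = (prop_wet is not None and prop_wet == 1.0) or (
        prop_on_water is not None and prop_on_water > 0.5
    )
    travel = (prop_wet is not None and prop_wet == 0.0) or (
        prop_flapping is not None and prop_flapping == 1.0
    )
    if rest and travel:
        return "UNKNOWN", True
    if rest:
        return "REST", False
    if travel:
        return "TRAVEL", False
    return "UNKNOWN", False


def metrics_oracle(cm: np.ndarray) -> dict:
    """Second implementation of the confusion-matrix metric definitions."""
    cm = np.asarray(cm, dtype=float)
    out = {"accuracy": np.trace(cm) / cm.sum()}
    for c in range(3):
        tp = cm[c, c]
        fn = sum(cm[c, p] for p in range(3) if p != c)
        fp = sum(cm[r, c] for r in range(3) if r != c)
        tn = sum(cm[r, p] for r in range(3) for p in range(3) if r != c and p != c)
        out[f"sens_{c}"] = tp / (tp + fn) if tp + fn else np.nan
        out[f"spec_{c}"] = tn / (tn + fp) if tn + fp else np.nan
        out[f"prec_{c}"] = tp / (tp + fp) if tp + fp else np.nan
    return out


def random_hmm_params(rng):
    from sshmm.hmm import EmissionParams

    mean = np.sort(np.exp(rng.uniform(1.0, 8.0, size=3)))
    sd = mean * rng.uniform(0.3, 1.2, size=3)
    kappa = rng.uniform(0.0, 8.0, size=3)
    g = rng.dirichlet(np.ones(3) * 2.0, size=3)
    return EmissionParams(mean, sd, kappa), g


def random_segment(rng, t, params, missing_frac=0.15, known_frac=0.3):
    """Random observations loosely matched to the parameter scales."""
    states = rng.integers(0, 3, size=t)
    steps = rng.gamma(params.gamma_shape[states], params.gamma_scale[states])
    angles = rng.vonmises(0.0, np.maximum(params.kappa[states], 1e-6))
    steps[rng.random(t) < missing_frac] = np.nan
    angles[rng.random(t) < missing_frac] = np.nan
    known = np.full(t, -1)
    sup = rng.random(t) < known_frac
    known[sup] = states[sup]
    return steps, angles, known
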