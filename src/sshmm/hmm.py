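"""Three-state movement HMM with partial state supervision.

The observation model is the standard movement-ecology pairing: step
lengths follow a state-dependent gamma distribution and turning angles a
zero-mean von Mises. Latent states switch by a first-order Markov chain
whose initial distribution is the stationary distribution of the
transition matrix, applied independently to every gap-delimited track
segment.

Semi-supervision uses the known-states construction: at a fix whose
behavioural state k is known from auxiliary sensors, the emission
densities of all states other than k are set to zero inside the forward
recursion. Labelled fixes therefore inform both the decoded path *and*
the fitted parameters of unlabelled fixes, rather than being overwritten
post hoc.

Parameters are estimated by direct numerical maximum likelihood on
unconstrained working scales (log means/sds/concentrations, row-wise
multinomial logits of the transition matrix) with a quasi-Newton
optimizer, started from k-means clusters of the step lengths plus
randomized restarts to reduce the risk of local maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, i0e
from sklearn.cluster import KMeans

from .sensor_fusion import FORAGE, REST, TRAVEL
from .track_prep import MoveSeries

__all__ = [
    "EmissionParams",
    "Observations",
    "HMMFit",
    "FitError",
    "stationary_distribution",
    "gamma_logpdf",
    "vonmises_logpdf",
    "forward_loglik",
    "viterbi",
    "state_probabilities",
    "kmeans_init",
    "perturb_start",
    "fit",
    "label_states",
]

N_STATES = 3
# 3 x (step mean, step sd, kappa) emissions + 3 x 2 free transition entries
N_PARAMS = 15

KAPPA_FLOOR = 1e-6


@dataclass
class EmissionParams:
    """State-dependent emission parameters (states indexed 0..2).

    The gamma distribution is parameterized by mean and standard
    deviation (shape = (mean/sd)^2, scale = sd^2/mean); the von Mises
    angle distribution has its mean fixed at zero so only the
    concentration ``kappa`` varies by state.
    """

    step_mean: np.ndarray
    step_sd: np.ndarray
    kappa: np.ndarray

    def __post_init__(self) -> None:
        self.step_mean = np.asarray(self.step_mean, dtype=float)
        self.step_sd = np.asarray(self.step_sd, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if np.any(self.step_mean <= 0) or np.any(self.step_sd <= 0):
            raise ValueError("step mean/sd must be positive")
        if np.any(self.kappa < 0):
            raise ValueError("kappa must be non-negative")

    @property
    def gamma_shape(self) -> np.ndarray:
        return (self.step_mean / self.step_sd) ** 2

    @property
    def gamma_scale(self) -> np.ndarray:
        return self.step_sd**2 / self.step_mean

    def copy(self) -> "EmissionParams":
        return EmissionParams(
            self.step_mean.copy(), self.step_sd.copy(), self.kappa.copy()
        )


class FitError(RuntimeError):
    """No optimizer restart converged; carries per-restart diagnostics."""

    def __init__(self, message: str, restarts=None):
        super().__init__(message)
        self.restarts = restarts or []


def gamma_logpdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    a = (mean / sd) ** 2
    scale = sd**2 / mean
    return (a - 1.0) * np.log(x) - x / scale - gammaln(a) - a * np.log(scale)


def vonmises_logpdf(x: np.ndarray, kappa: float) -> np.ndarray:
    # log I0(k) = log i0e(k) + k keeps large concentrations finite
    return kappa * np.cos(x) - np.log(2.0 * np.pi) - (np.log(i0e(kappa)) + kappa)


def stationary_distribution(gamma_mat: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix."""
    n = gamma_mat.shape[0]
    a = np.vstack([(gamma_mat.T - np.eye(n))[:-1], np.ones(n)])
    b = np.zeros(n)
    b[-1] = 1.0
    try:
        pi = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        # reducible chain (e.g. identity): stationary set is not unique
        return np.full(n, 1.0 / n)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


@dataclass
class Observations:
    """Padded per-segment arrays of steps, angles and known states.

    Segments are padded to a common length with NaN observations and
    ``known = -1``; a padded fix has unit emission density for every
    state and so contributes nothing to the likelihood. Exact zero steps
    are replaced by ``step_floor`` (the gamma density is undefined at 0).
    """

    steps: np.ndarray  # (S, Tmax), NaN = missing or pad
    angles: np.ndarray  # (S, Tmax)
    known: np.ndarray  # (S, Tmax) int, -1 = unsupervised or pad
    lengths: np.ndarray  # (S,)

    @property
    def n_segments(self) -> int:
        return len(self.lengths)

    @property
    def n_fixes(self) -> int:
        return int(self.lengths.sum())

    @classmethod
    def from_segments(
        cls,
        segments: list[tuple[np.ndarray, np.ndarray]],
        known: list[np.ndarray] | None = None,
        step_floor: float = 3e-4,
    ) -> "Observations":
        if not segments:
            raise ValueError("no segments")
        lengths = np.array([len(s) for s, _ in segments])
        tmax = int(lengths.max())
        s_arr = np.full((len(segments), tmax), np.nan)
        a_arr = np.full((len(segments), tmax), np.nan)
        k_arr = np.full((len(segments), tmax), -1, dtype=int)
        n_floored = 0
        for i, (st, an) in enumerate(segments):
            st = np.asarray(st, dtype=float).copy()
            zero = st == 0.0
            n_floored += int(np.nansum(zero))
            st[zero] = step_floor
            s_arr[i, : len(st)] = st
            a_arr[i, : len(an)] = an
            if known is not None and known[i] is not None:
                k_arr[i, : len(known[i])] = known[i]
        if n_floored:
            warnings.warn(f"floored {n_floored} zero steps to {step_floor}")
        return cls(s_arr, a_arr, k_arr, lengths)

    @classmethod
    def from_move_series(
        cls,
        moves: list[MoveSeries],
        known_flat: np.ndarray | None = None,
        step_floor: float = 3e-4,
    ) -> "Observations":
        """Build from per-trip movement series; ``known_flat`` is a state
        code per fix across all trips/segments in order (-1 unknown)."""
        segs, ks = [], []
        pos = 0
        for mv in moves:
            for st, an in mv.per_segment():
                segs.append((st, an))
                n = len(st)
                if known_flat is not None:
                    ks.append(np.asarray(known_flat[pos : pos + n], dtype=int))
                else:
                    ks.append(None)
                pos += n
        if known_flat is not None and pos != len(known_flat):
            raise ValueError("known_flat length does not match total fixes")
        return cls.from_segments(segs, ks if known_flat is not None else None, step_floor)

    def with_known(self, known_flat: np.ndarray) -> "Observations":
        """Same observations with a different supervision vector (flat order)."""
        k_arr = np.full_like(self.known, -1)
        pos = 0
        for i, n in enumerate(self.lengths):
            k_arr[i, :n] = known_flat[pos : pos + n]
            pos += n
        return Observations(self.steps, self.angles, k_arr, self.lengths)

    def flatten(self, padded: np.ndarray) -> np.ndarray:
        """Concatenate per-segment rows of a padded array, dropping pads."""
        parts = [padded[i, : self.lengths[i]] for i in range(self.n_segments)]
        return np.concatenate(parts, axis=0)

    def flat_known(self) -> np.ndarray:
        return self.flatten(self.known)


def _log_emissions(
    params: EmissionParams, obs: Observations, supervised: bool = True
) -> np.ndarray:
    """(S, Tmax, 3) log emission densities with supervision constraints.

    Missing components contribute log-density 0; at a fix with known
    state k, states != k are assigned -inf (zero density).
    """
    s, t = obs.steps.shape
    lb = np.zeros((s, t, N_STATES))
    sv = ~np.isnan(obs.steps)
    av = ~np.isnan(obs.angles)
    steps, angles = obs.steps[sv], obs.angles[av]
    for i in range(N_STATES):
        lb[sv, i] += gamma_logpdf(steps, params.step_mean[i], params.step_sd[i])
        lb[av, i] += vonmises_logpdf(angles, params.kappa[i])
    if supervised:
        k = obs.known
        has = k >= 0
        if has.any():
            mask = np.zeros((s, t, N_STATES), dtype=bool)
            idx = np.broadcast_to(np.arange(N_STATES), (s, t, N_STATES))
            mask[has] = idx[has] != k[has, None]
            lb[mask] = -np.inf
    return lb


def forward_loglik(
    params: EmissionParams, gamma_mat: np.ndarray, obs: Observations
) -> float:
    """Log-likelihood by the scaled forward recursion, summed over segments.

    Each segment starts from the stationary distribution of the
    transition matrix. A per-fix max-shift keeps the recursion finite for
    arbitrarily small densities; a fix where every permitted state has
    zero density yields -inf.
    """
    lb = _log_emissions(params, obs)
    delta = stationary_distribution(gamma_mat)
    s, tmax, _ = lb.shape
    m = np.max(lb, axis=2)  # (S, Tmax)
    m_fin = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(invalid="ignore"):
        b = np.exp(lb - m_fin[:, :, None])
    b[~np.isfinite(lb)] = 0.0

    ll = np.zeros(s)
    alpha = delta[None, :] * b[:, 0, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        c = alpha.sum(axis=1)
        ll += np.log(c) + m_fin[:, 0]
        alpha = np.where(c[:, None] > 0, alpha / c[:, None], 0.0)
        for t in range(1, tmax):
            active = obs.lengths > t
            alpha = (alpha @ gamma_mat) * b[:, t, :]
            c = alpha.sum(axis=1)
            ll += np.where(active, np.log(c) + m_fin[:, t], 0.0)
            alpha = np.where(c[:, None] > 0, alpha / c[:, None], 0.0)
    # dead segments (zero-density permitted path) are -inf, not NaN
    ll[np.isnan(ll)] = -np.inf
    return float(ll.sum())


def viterbi(
    params: EmissionParams, gamma_mat: np.ndarray, obs: Observations
) -> np.ndarray:
    """Most probable state path per segment, flat-concatenated.

    Supervision forces the decoded state at known fixes. Ties break
    toward the lowest state index.
    """
    lb = _log_emissions(params, obs)
    with np.errstate(divide="ignore"):
        ld = np.log(stationary_distribution(gamma_mat))
        lg = np.log(gamma_mat)
    out = []
    for i in range(obs.n_segments):
        n = int(obs.lengths[i])
        seg_lb = lb[i, :n]
        phi = ld + seg_lb[0]
        bp = np.zeros((n, N_STATES), dtype=int)
        for t in range(1, n):
            cand = phi[:, None] + lg  # (prev, next)
            bp[t] = np.argmax(cand, axis=0)  # first max -> lowest index
            phi = cand[bp[t], np.arange(N_STATES)] + seg_lb[t]
        if not np.isfinite(phi.max()):
            raise FitError(f"segment {i}: no admissible state path (contradictory known states)")
        path = np.zeros(n, dtype=int)
        path[-1] = int(np.argmax(phi))
        for t in range(n - 1, 0, -1):
            path[t - 1] = bp[t, path[t]]
        out.append(path)
    return np.concatenate(out)


def state_probabilities(
    params: EmissionParams, gamma_mat: np.ndarray, obs: Observations
) -> np.ndarray:
    """Forward-backward smoothed state posteriors, flat (n_fixes, 3).

    Computed under the same supervision-constrained likelihood as
    fitting, so a known fix has posterior 1 on its label.
    """
    lb = _log_emissions(params, obs)
    delta = stationary_distribution(gamma_mat)
    out = []
    for i in range(obs.n_segments):
        n = int(obs.lengths[i])
        seg = lb[i, :n]
        m = np.max(seg, axis=1)
        m_fin = np.where(np.isfinite(m), m, 0.0)
        b = np.exp(seg - m_fin[:, None])
        b[~np.isfinite(seg)] = 0.0
        alpha = np.zeros((n, N_STATES))
        c = np.zeros(n)
        a = delta * b[0]
        c[0] = a.sum()
        if c[0] <= 0:
            raise FitError(f"segment {i}: zero forward mass (contradictory known states)")
        alpha[0] = a / c[0]
        for t in range(1, n):
            a = (alpha[t - 1] @ gamma_mat) * b[t]
            c[t] = a.sum()
            if c[t] <= 0:
                raise FitError(f"segment {i}: zero forward mass at t={t}")
            alpha[t] = a / c[t]
        beta = np.zeros((n, N_STATES))
        beta[-1] = 1.0
        for t in range(n - 2, -1, -1):
            beta[t] = (gamma_mat @ (b[t + 1] * beta[t + 1])) / c[t + 1]
        post = alpha * beta
        post /= post.sum(axis=1, keepdims=True)
        out.append(post)
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# starting values


def _kappa_from_resultant(r: float) -> float:
    """Best-Fisher approximation of the von Mises concentration MLE."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return min(1.0 / (r**3 - 4 * r**2 + 3 * r), 500.0)


def kmeans_init(obs: Observations, seed: int, k: int = N_STATES) -> EmissionParams:
    """Starting emission values from k-means clusters of the step lengths.

    Clusters are ordered by ascending step mean (so the short-step rest
    state is index 0); each cluster's angle sample sets the starting
    concentration through its mean resultant length.
    """
    steps_flat = obs.flatten(obs.steps)
    angles_flat = obs.flatten(obs.angles)
    sv = ~np.isnan(steps_flat)
    steps = steps_flat[sv]
    if len(steps) < k:
        raise ValueError(f"need at least {k} non-missing steps")
    if len(np.unique(steps)) < k:
        warnings.warn("fewer than k distinct steps: jittered quantile fallback")
        rng = np.random.default_rng(seed)
        q = np.quantile(steps, [0.1, 0.5, 0.9])
        q = q * np.exp(0.01 * rng.standard_normal(k))
        order = np.argsort(q)
        mean = np.maximum(q[order], 1e-6)
        return EmissionParams(mean, np.maximum(0.5 * mean, 1e-6), np.ones(k))

    # cluster on the log scale: gamma step distributions differ by orders
    # of magnitude between states and the largest state's variance would
    # otherwise dominate the squared-distance objective
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(np.log(steps).reshape(-1, 1))
    means = np.array([steps[assign == j].mean() for j in range(k)])
    order = np.argsort(means)
    step_mean = np.empty(k)
    step_sd = np.empty(k)
    kappa = np.empty(k)
    angles_of_valid = angles_flat[sv]
    for new, j in enumerate(order):
        grp = steps[assign == j]
        step_mean[new] = grp.mean()
        sd = grp.std(ddof=1) if len(grp) > 1 else 0.0
        step_sd[new] = max(sd, 1e-3 * step_mean[new], 1e-9)
        ang = angles_of_valid[assign == j]
        ang = ang[~np.isnan(ang)]
        if len(ang) < 3:
            kappa[new] = 0.0
        else:
            r = float(np.hypot(np.cos(ang).mean(), np.sin(ang).mean()))
            kappa[new] = _kappa_from_resultant(r)
    return EmissionParams(step_mean, step_sd, np.maximum(kappa, KAPPA_FLOOR))


def perturb_start(
    params: EmissionParams,
    gamma_mat: np.ndarray,
    seed: int,
    scale: float = 0.25,
) -> tuple[EmissionParams, np.ndarray]:
    """Randomized restart: multiplicative log-normal jitter (sd = scale) on
    the positive emission parameters and on the transition rows, which are
    then renormalized. ``scale = 0`` returns the input unchanged."""
    rng = np.random.default_rng(seed)
    p = EmissionParams(
        params.step_mean * np.exp(scale * rng.standard_normal(N_STATES)),
        params.step_sd * np.exp(scale * rng.standard_normal(N_STATES)),
        np.maximum(
            params.kappa * np.exp(scale * rng.standard_normal(N_STATES)),
            KAPPA_FLOOR,
        ),
    )
    g = gamma_mat * np.exp(scale * rng.standard_normal((N_STATES, N_STATES)))
    g = g / g.sum(axis=1, keepdims=True)
    return p, g


# ---------------------------------------------------------------------------
# working-scale packing and fitting

_OFF_DIAG = [(i, j) for i in range(N_STATES) for j in range(N_STATES) if i != j]


def _pack(params: EmissionParams, gamma_mat: np.ndarray) -> np.ndarray:
    logits = [np.log(gamma_mat[i, j] / gamma_mat[i, i]) for i, j in _OFF_DIAG]
    return np.concatenate(
        [
            np.log(params.step_mean),
            np.log(params.step_sd),
            np.log(np.maximum(params.kappa, KAPPA_FLOOR)),
            logits,
        ]
    )


def _unpack(theta: np.ndarray) -> tuple[EmissionParams, np.ndarray]:
    p = EmissionParams(
        np.exp(theta[0:3]), np.exp(theta[3:6]), np.exp(theta[6:9])
    )
    g = np.eye(N_STATES)
    for (i, j), logit in zip(_OFF_DIAG, theta[9:15]):
        g[i, j] = np.exp(logit)
    g = g / g.sum(axis=1, keepdims=True)
    return p, g


_BOUNDS = [(-20.0, 30.0)] * 6 + [(np.log(KAPPA_FLOOR), np.log(500.0))] * 3 + [
    (-15.0, 15.0)
] * 6


@dataclass
class HMMFit:
    emissions: EmissionParams
    gamma_mat: np.ndarray
    loglik: float
    aic: float
    n_params: int
    restarts: list[dict] = field(default_factory=list)
    best_restart: int = 0
    initial_mode: str = "stationary"

    def to_dict(self) -> dict:
        return {
            "emissions": {
                "step_mean": self.emissions.step_mean.tolist(),
                "step_sd": self.emissions.step_sd.tolist(),
                "kappa": self.emissions.kappa.tolist(),
            },
            "gamma": self.gamma_mat.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "initial_mode": self.initial_mode,
            "best_restart": self.best_restart,
            "restarts": self.restarts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMFit":
        em = d["emissions"]
        return cls(
            EmissionParams(
                np.array(em["step_mean"]),
                np.array(em["step_sd"]),
                np.array(em["kappa"]),
            ),
            np.array(d["gamma"]),
            d["loglik"],
            d["aic"],
            d["n_params"],
            d.get("restarts", []),
            d.get("best_restart", 0),
            d.get("initial_mode", "stationary"),
        )


def fit(
    obs: Observations,
    n_restarts: int = 10,
    seed: int = 0,
    perturb_scale: float = 0.25,
    gamma0_diag: float = 0.8,
    maxiter: int = 300,
    gtol: float = 1e-8,
) -> HMMFit:
    """Maximum-likelihood fit with k-means start plus randomized restarts.

    The first restart starts from the k-means values; the remaining
    ``n_restarts - 1`` perturb them. The best converged restart (highest
    log-likelihood, equivalently lowest AIC at fixed structure) is
    returned with full restart metadata.
    """
    if obs.n_fixes < 2:
        raise ValueError("need at least one segment with >= 2 fixes")
    base = kmeans_init(obs, seed)
    gamma0 = np.full((N_STATES, N_STATES), (1.0 - gamma0_diag) / (N_STATES - 1))
    np.fill_diagonal(gamma0, gamma0_diag)
    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=max(n_restarts - 1, 0))

    def neg_ll(theta: np.ndarray) -> float:
        p, g = _unpack(theta)
        ll = forward_loglik(p, g, obs)
        return 1e12 if not np.isfinite(ll) else -ll

    restarts: list[dict] = []
    results = []
    for r in range(n_restarts):
        if r == 0:
            p0, g0 = base.copy(), gamma0
            rseed = seed
        else:
            rseed = int(restart_seeds[r - 1])
            p0, g0 = perturb_start(base, gamma0, rseed, perturb_scale)
        theta0 = _pack(p0, g0)
        res = minimize(
            neg_ll,
            theta0,
            method="L-BFGS-B",
            bounds=_BOUNDS,
            options={"maxiter": maxiter, "gtol": gtol, "maxfun": 10 * maxiter * N_PARAMS},
        )
        ll = -float(res.fun)
        restarts.append(
            {
                "seed": rseed,
                "start": theta0.tolist(),
                "converged": bool(res.success),
                "loglik": ll,
            }
        )
        results.append((res, ll))

    converged = [i for i, rec in enumerate(restarts) if rec["converged"]]
    if not converged:
        raise FitError("no restart converged", restarts)
    best = max(converged, key=lambda i: restarts[i]["loglik"])
    p, g = _unpack(results[best][0].x)
    ll = restarts[best]["loglik"]
    return HMMFit(
        emissions=p,
        gamma_mat=g,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * N_PARAMS,
        n_params=N_PARAMS,
        restarts=restarts,
        best_restart=best,
    )


def label_states(fit_result: HMMFit | EmissionParams) -> dict[int, int]:
    """Map fitted state indices to behavioural labels by step length.

    REST is the state with the smallest mean step, TRAVEL the largest,
    FORAGE the middle one — the a-posteriori interpretation step of
    movement HMMs. Exact ties break by ascending concentration. A
    diagnostic warns when the FORAGE state's angles are not the most
    dispersed (largest kappa would contradict tortuous search).
    """
    em = fit_result.emissions if isinstance(fit_result, HMMFit) else fit_result
    order = np.lexsort((em.kappa, em.step_mean))
    if len(np.unique(em.step_mean)) < N_STATES:
        # exact ties: the most dispersed (lowest kappa) member of the tied
        # group takes the FORAGE slot, the most concentrated takes REST
        warnings.warn("tied step means: breaking ties by angle concentration")
        order = list(order)
        for mean in np.unique(em.step_mean):
            members = [s for s in range(N_STATES) if em.step_mean[s] == mean]
            if len(members) < 2:
                continue
            slots = sorted(order.index(s) for s in members)
            by_kappa = sorted(members, key=lambda s: em.kappa[s])
            assign: dict[int, int] = {}
            if 1 in slots:  # FORAGE slot inside the tie
                assign[1] = by_kappa.pop(0)
            for slot in slots:
                if slot not in assign:
                    assign[slot] = by_kappa.pop() if slot == 0 else by_kappa.pop(0)
            for slot, s in assign.items():
                order[slot] = s
        order = np.array(order)
    mapping = {int(order[0]): REST, int(order[1]): FORAGE, int(order[2]): TRAVEL}
    forage_state = int(order[1])
    if em.kappa[forage_state] != em.kappa.min():
        warnings.warn(
            f"state labelled FORAGE (kappa={em.kappa[forage_state]:.3g}) does not "
            "have the most dispersed angles"
        )
    return mapping


def map_states(states: np.ndarray, mapping: dict[int, int]) -> np.ndarray:
    """Apply a label_states mapping to a decoded state-index sequence."""
    lut = np.empty(N_STATES, dtype=int)
    for k, v in mapping.items():
        lut[k] = v
    return lut[states]
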