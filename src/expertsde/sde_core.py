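"""Noisy evidence accumulators and first-passage decisions.

Three families of stochastic differential equation are covered by a single
accumulator specification

    dx = (mu + lambda * x) dt + sigma dW,

where ``mu`` is the mean evidence (drift) rate, ``sigma`` the diffusion
scale (evidence per square-root unit time) and ``lambda`` an optional
linear state gain.  ``lambda = 0`` gives the constant-drift
drift-diffusion model; ``lambda < 0`` the mean-reverting
Ornstein-Uhlenbeck process.  Several accumulators advanced in lockstep
with independent noise form a race model: the first to reach its own
upper boundary wins the decision.

Time and evidence are dimensionless model units.  Integration is
fixed-step Euler-Maruyama; for constant drift the Gaussian increments are
exact in distribution, so the only discretization effect is that boundary
crossings are monitored at step endpoints.  An optional Brownian-bridge
crossing test (``detect="bridge"``) accounts for excursions between
endpoints and removes the O(sqrt(dt)) monitoring bias of the endpoint
rule.

Randomness contract: every public simulator takes one master ``seed``.
Substreams are derived with ``numpy.random.SeedSequence(seed,
spawn_key=...)`` where the spawn key encodes the accumulator index (and,
for batch runs, the batch role), so adding an accumulator to a race never
perturbs the draws of the existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, NoStationaryDistributionError

__all__ = [
    "AccumulatorSpec",
    "DriftComponents",
    "Trajectory",
    "FirstPassageResult",
    "BatchFirstPassage",
    "simulate_path",
    "first_passage",
    "batch_first_passage",
    "coupled_refinement_fractions",
    "simulate_race",
    "batch_race",
    "compose_drift",
    "ou_stationary_moments",
]

#: Default integration step, in model time units.
DEFAULT_DT = 1e-3


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if math.isnan(value):
        raise InvalidParameterError(f"{name} is NaN")
    return value


@dataclass(frozen=True)
class AccumulatorSpec:
    """One noisy evidence variable with absorbing decision boundaries.

    Parameters
    ----------
    drift
        Mean evidence rate mu (may be a composite net drift).
    diffusion
        Noise scale sigma >= 0.
    state_gain
        Linear gain lambda on the current state; 0 recovers the
        constant-drift model, negative values give mean reversion.
    upper_boundary, lower_boundary
        Absorbing decision boundaries Z1 > initial_state > Z2.  Either
        may be infinite (a one-sided accumulator).
    initial_state
        Starting evidence level, default 0.
    label
        Optional identifier used in race results and file output.
    """

    drift: float
    diffusion: float
    state_gain: float = 0.0
    upper_boundary: float = 1.0
    lower_boundary: float = -1.0
    initial_state: float = 0.0
    label: str | None = None

    def __post_init__(self):
        for name in ("drift", "diffusion", "state_gain", "upper_boundary",
                     "lower_boundary", "initial_state"):
            object.__setattr__(self, name, _check_finite(name, getattr(self, name)))
        if self.diffusion < 0:
            raise InvalidParameterError(f"diffusion must be >= 0, got {self.diffusion}")
        if not (self.lower_boundary < self.initial_state < self.upper_boundary):
            raise InvalidParameterError(
                "boundaries must satisfy lower_boundary < initial_state < "
                f"upper_boundary, got ({self.lower_boundary}, "
                f"{self.initial_state}, {self.upper_boundary})"
            )


@dataclass(frozen=True)
class DriftComponents:
    """A net drift split into labelled signed components.

    The composite drift mu* = mu_1 - mu_2 + mu_3 - ... stays constant as
    long as each part is constant, so evidence sources with distinct
    interpretations (perceptual, mnemonic, inhibitory ...) can be
    book-kept separately and summed exactly.
    """

    components: tuple[tuple[str, float, int], ...] = ()

    def __post_init__(self):
        canon = []
        for label, value, sign in self.components:
            if sign not in (+1, -1):
                raise InvalidParameterError(f"sign must be +1 or -1, got {sign!r}")
            canon.append((str(label), _check_finite(f"component {label!r}", value), int(sign)))
        object.__setattr__(self, "components", tuple(canon))


def compose_drift(components: DriftComponents) -> float:
    """Signed sum of drift components (empty list -> 0).

    Uses exact floating summation so the result is independent of the
    ordering of components within each sign group.
    """
    return math.fsum(sign * value for _, value, sign in components.components)


@dataclass(frozen=True)
class Trajectory:
    """A discrete sample path (or lockstep bundle of paths).

    ``states`` has shape (n_steps + 1,) for a single accumulator or
    (n_steps + 1, k) for k accumulators; ``times[0] == 0`` and the
    spacing is constant ``dt``.
    """

    times: np.ndarray
    states: np.ndarray
    seed: int
    dt: float
    labels: tuple[str, ...] = ()

    def to_frame(self):
        """Trajectory as a pandas DataFrame with a ``t`` column."""
        import pandas as pd

        states = np.atleast_2d(self.states.T).T
        cols = self.labels or tuple(f"x_{i}" for i in range(states.shape[1]))
        frame = pd.DataFrame(states, columns=list(cols))
        frame.insert(0, "t", self.times)
        return frame


@dataclass(frozen=True)
class FirstPassageResult:
    """Outcome of a threshold decision.

    ``winner`` names the absorbing boundary ("upper"/"lower") for a single
    accumulator, or the winning accumulator's label/index for a race.
    ``censored`` is True when the horizon elapsed with no crossing; the
    crossing_time then equals the horizon and ``winner`` is None.
    """

    winner: str | int | None
    crossing_time: float
    crossed_value: float
    censored: bool


@dataclass(frozen=True)
class BatchFirstPassage:
    """Vectorized first-passage outcomes over many independent trials."""

    winners: np.ndarray        # int codes; -1 = censored
    crossing_times: np.ndarray
    censored: np.ndarray       # bool
    winner_labels: tuple[str, ...] = ("lower", "upper")

    @property
    def n_trials(self) -> int:
        return self.winners.shape[0]

    def fraction(self, label: str) -> float:
        """Fraction of non-censored trials won by ``label``."""
        code = self.winner_labels.index(label)
        n_decided = int((~self.censored).sum())
        if n_decided == 0:
            return math.nan
        return float((self.winners == code).sum() / n_decided)

    def to_frame(self):
        import pandas as pd

        labels = [self.winner_labels[w] if w >= 0 else "" for w in self.winners]
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "winner": labels,
                "crossing_time": self.crossing_times,
                "censored": self.censored.astype(int),
            }
        )


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=spawn_key))


def _check_grid(dt: float, horizon: float) -> int:
    dt = _check_finite("dt", dt)
    horizon = _check_finite("horizon", horizon)
    if dt <= 0 or horizon <= 0:
        raise InvalidParameterError(f"dt and horizon must be positive, got {dt}, {horizon}")
    if dt >= horizon:
        raise InvalidParameterError(f"dt must be smaller than horizon ({dt} >= {horizon})")
    return int(round(horizon / dt))


def simulate_path(spec: AccumulatorSpec, dt: float = DEFAULT_DT,
                  horizon: float = 1.0, seed: int = 0) -> Trajectory:
    """Euler-Maruyama sample path of one accumulator, without absorption.

    Boundaries in ``spec`` are ignored here: the path is the raw
    unbounded solution of dx = (mu + lambda x) dt + sigma dW.  With
    ``diffusion == 0`` and ``state_gain == 0`` the path is exactly
    x(t) = x0 + mu t.
    """
    n_steps = _check_grid(dt, horizon)
    times = np.arange(n_steps + 1) * dt
    rng = _rng(seed, 0)
    if spec.diffusion > 0:
        noise = spec.diffusion * math.sqrt(dt) * rng.standard_normal(n_steps)
    else:
        noise = np.zeros(n_steps)
    if spec.state_gain == 0.0:
        # Constant drift: closed-form deterministic part keeps the
        # noise-free path exact to the last bit.
        states = spec.initial_state + spec.drift * times
        states[1:] += np.cumsum(noise)
    else:
        states = np.empty(n_steps + 1)
        states[0] = x = spec.initial_state
        growth = 1.0 + spec.state_gain * dt
        mu_dt = spec.drift * dt
        for i in range(n_steps):
            x = x * growth + mu_dt + noise[i]
            states[i + 1] = x
    return Trajectory(times=times, states=states, seed=int(seed), dt=float(dt),
                      labels=(spec.label,) if spec.label else ())


def ou_stationary_moments(spec: AccumulatorSpec) -> tuple[float, float]:
    """Stationary mean and variance of a mean-reverting accumulator.

    For dx = (mu + lambda x) dt + sigma dW with lambda < 0 the stationary
    law is Gaussian with mean -mu/lambda and variance sigma^2 / (2 |lambda|).
    """
    if spec.state_gain >= 0:
        raise NoStationaryDistributionError(
            f"state_gain must be negative for a stationary law, got {spec.state_gain}"
        )
    mean = -spec.drift / spec.state_gain
    variance = spec.diffusion**2 / (2.0 * abs(spec.state_gain))
    return mean, variance


def _bridge_crossing(x0: np.ndarray, x1: np.ndarray, boundary: float,
                     sig2dt: float, above: bool) -> np.ndarray:
    """P(Brownian bridge between endpoints touched ``boundary``).

    Both endpoints are assumed on the interior side; the standard
    reflection result gives exp(-2 d0 d1 / (sigma^2 dt)) with d the
    endpoint distances to the boundary.
    """
    if above:
        d0, d1 = boundary - x0, boundary - x1
    else:
        d0, d1 = x0 - boundary, x1 - boundary
    return np.exp(-2.0 * d0 * d1 / sig2dt)


def batch_first_passage(spec: AccumulatorSpec, dt: float = DEFAULT_DT,
                        horizon: float = 10.0, n_trials: int = 1,
                        seed: int = 0, detect: str = "endpoint") -> BatchFirstPassage:
    """First boundary crossing for ``n_trials`` independent replicas.

    ``detect="endpoint"`` declares a crossing when the state at a step
    endpoint lies at or beyond a boundary (the default semantics of the
    discrete accumulator).  ``detect="bridge"`` additionally samples
    whether the continuous path crossed in the interior of a step using
    the Brownian-bridge crossing probability, which for constant drift
    makes the simulated crossing statistics exact up to the (negligible)
    chance of hitting both boundaries within one step.

    Trials that never cross within ``horizon`` are censored with
    ``crossing_time = horizon``.
    """
    if detect not in ("endpoint", "bridge"):
        raise InvalidParameterError(f"unknown detection mode {detect!r}")
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    if detect == "bridge" and spec.state_gain != 0.0:
        raise InvalidParameterError("bridge detection requires state_gain == 0")
    n_steps = _check_grid(dt, horizon)
    rng = _rng(seed, 0)

    winners = np.full(n_trials, -1, dtype=np.int64)
    times = np.full(n_trials, float(n_steps * dt))
    censored = np.ones(n_trials, dtype=bool)

    x = np.full(n_trials, spec.initial_state)
    active = np.arange(n_trials)
    sqdt = math.sqrt(dt)
    sig2dt = spec.diffusion**2 * dt
    up, lo = spec.upper_boundary, spec.lower_boundary
    use_bridge = detect == "bridge" and spec.diffusion > 0

    for step in range(1, n_steps + 1):
        if active.size == 0:
            break
        drift = spec.drift + spec.state_gain * x
        if spec.diffusion > 0:
            x_new = x + drift * dt + spec.diffusion * sqdt * rng.standard_normal(active.size)
        else:
            x_new = x + drift * dt
        hit_up = x_new >= up
        hit_lo = x_new <= lo
        if use_bridge:
            interior = ~(hit_up | hit_lo)
            if interior.any():
                p_up = np.zeros(active.size)
                p_lo = np.zeros(active.size)
                if np.isfinite(up):
                    p_up[interior] = _bridge_crossing(x[interior], x_new[interior],
                                                      up, sig2dt, above=True)
                if np.isfinite(lo):
                    p_lo[interior] = _bridge_crossing(x[interior], x_new[interior],
                                                      lo, sig2dt, above=False)
                u = rng.random(active.size)
                bridge_up = interior & (u < p_up)
                bridge_lo = interior & ~bridge_up & (u < p_up + p_lo)
                hit_up = hit_up | bridge_up
                hit_lo = hit_lo | bridge_lo
        hit = hit_up | hit_lo
        if hit.any():
            idx = active[hit]
            winners[idx] = np.where(hit_up[hit], 1, 0)
            times[idx] = step * dt
            censored[idx] = False
            keep = ~hit
            active = active[keep]
            x = x_new[keep]
        else:
            x = x_new

    return BatchFirstPassage(winners=winners, crossing_times=times,
                             censored=censored, winner_labels=("lower", "upper"))


def coupled_refinement_fractions(spec: AccumulatorSpec, dt_coarse: float,
                                 n_levels: int = 3, horizon: float = 10.0,
                                 n_trials: int = 1, seed: int = 0) -> list[float]:
    """Upper-boundary fractions under nested endpoint monitoring.

    One set of Brownian paths is simulated at the finest step
    ``dt_coarse / 2**(n_levels-1)`` and boundary crossings are monitored
    (endpoint rule) at every level's stride simultaneously.  Because all
    levels share the same paths, differences between the returned
    fractions isolate the monitoring-discretization effect from
    Monte-Carlo noise.  Returns fractions ordered coarse to fine,
    computed over each level's decided trials.

    Only the constant-drift model is supported (``state_gain == 0``).
    """
    if spec.state_gain != 0.0:
        raise InvalidParameterError("refinement experiment requires state_gain == 0")
    if n_levels < 2:
        raise InvalidParameterError("n_levels must be >= 2")
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    strides = [2 ** (n_levels - 1 - l) for l in range(n_levels)]  # coarse..fine
    dt = float(dt_coarse) / strides[0]
    n_steps = _check_grid(dt, horizon)
    n_steps -= n_steps % strides[0]  # horizon commensurate with every stride
    rng = _rng(seed, 0)
    sqdt = math.sqrt(dt)
    up, lo = spec.upper_boundary, spec.lower_boundary

    x = np.full(n_trials, spec.initial_state)
    alive = np.arange(n_trials)  # trials not yet absorbed at every level
    # per-level outcome: -1 pending, 0 lower, 1 upper
    outcome = np.full((n_levels, n_trials), -1, dtype=np.int8)

    for step in range(1, n_steps + 1):
        if alive.size == 0:
            break
        x = x + spec.drift * dt + spec.diffusion * sqdt * rng.standard_normal(alive.size)
        for level, stride in enumerate(strides):
            if step % stride:
                continue
            pending = outcome[level, alive] == -1
            hit_up = pending & (x >= up)
            hit_lo = pending & (x <= lo)
            outcome[level, alive[hit_up]] = 1
            outcome[level, alive[hit_lo]] = 0
        done = (outcome[:, alive] != -1).all(axis=0)
        if done.any():
            keep = ~done
            alive = alive[keep]
            x = x[keep]

    fractions = []
    for level in range(n_levels):
        decided = outcome[level] != -1
        n_dec = int(decided.sum())
        fractions.append(float((outcome[level] == 1).sum() / n_dec) if n_dec else math.nan)
    return fractions


def first_passage(spec: AccumulatorSpec, dt: float = DEFAULT_DT,
                  horizon: float = 10.0, seed: int = 0,
                  detect: str = "endpoint") -> FirstPassageResult:
    """First crossing of either decision boundary for a single replica.

    The state is not clipped before detection, so ``crossed_value`` may
    overshoot the boundary.  If the horizon elapses without a crossing
    the result is censored rather than raising: zero-drift processes have
    heavy-tailed passage times and censoring is an expected outcome.
    """
    n_steps = _check_grid(dt, horizon)
    rng = _rng(seed, 0)
    sqdt = math.sqrt(dt)
    sig2dt = spec.diffusion**2 * dt
    x = spec.initial_state
    up, lo = spec.upper_boundary, spec.lower_boundary
    use_bridge = detect == "bridge" and spec.diffusion > 0
    if detect not in ("endpoint", "bridge"):
        raise InvalidParameterError(f"unknown detection mode {detect!r}")
    for step in range(1, n_steps + 1):
        drift = spec.drift + spec.state_gain * x
        x_new = x + drift * dt
        if spec.diffusion > 0:
            x_new += spec.diffusion * sqdt * rng.standard_normal()
        if x_new >= up:
            return FirstPassageResult("upper", step * dt, float(x_new), False)
        if x_new <= lo:
            return FirstPassageResult("lower", step * dt, float(x_new), False)
        if use_bridge:
            p_up = _bridge_crossing(np.asarray(x), np.asarray(x_new), up, sig2dt, True) if np.isfinite(up) else 0.0
            p_lo = _bridge_crossing(np.asarray(x), np.asarray(x_new), lo, sig2dt, False) if np.isfinite(lo) else 0.0
            u = rng.random()
            if u < p_up:
                return FirstPassageResult("upper", step * dt, float(up), False)
            if u < p_up + p_lo:
                return FirstPassageResult("lower", step * dt, float(lo), False)
        x = x_new
    return FirstPassageResult(None, n_steps * dt, float(x), True)


def _race_labels(specs: list[AccumulatorSpec]) -> tuple[str, ...]:
    return tuple(s.label if s.label is not None else str(i) for i, s in enumerate(specs))


def batch_race(specs: list[AccumulatorSpec], dt: float = DEFAULT_DT,
               horizon: float = 10.0, n_trials: int = 1,
               seed: int = 0) -> BatchFirstPassage:
    """Independent-accumulator race, vectorized over trials.

    All accumulators advance in lockstep with statistically independent
    noise; the winner of a trial is the first accumulator to reach its
    own *upper* boundary.  An accumulator that falls through its lower
    boundary is eliminated (absorbed without winning).  If two cross in
    the same step the one with the larger overshoot relative to its
    boundary magnitude wins; exact ties go to the lowest index.  A trial
    with no winner by the horizon (or with every accumulator eliminated)
    is censored.

    Noise streams are keyed per accumulator index, so appending an
    accumulator leaves the draws of the others untouched.
    """
    if len(specs) < 2:
        raise InvalidParameterError("a race needs at least 2 accumulators")
    n_steps = _check_grid(dt, horizon)
    k = len(specs)
    rngs = [_rng(seed, j) for j in range(k)]
    sqdt = math.sqrt(dt)

    drift = np.array([s.drift for s in specs])
    gain = np.array([s.state_gain for s in specs])
    sigma = np.array([s.diffusion for s in specs])
    up = np.array([s.upper_boundary for s in specs])
    lo = np.array([s.lower_boundary for s in specs])
    x0 = np.array([s.initial_state for s in specs])
    up_scale = np.where(np.isfinite(up) & (np.abs(up) > 0), np.abs(up), 1.0)

    winners = np.full(n_trials, -1, dtype=np.int64)
    times = np.full(n_trials, float(n_steps * dt))
    censored = np.ones(n_trials, dtype=bool)

    x = np.tile(x0, (n_trials, 1))
    eliminated = np.zeros((n_trials, k), dtype=bool)
    active = np.arange(n_trials)

    for step in range(1, n_steps + 1):
        if active.size == 0:
            break
        n_act = active.size
        dx = (drift + gain * x) * dt
        for j in range(k):
            if sigma[j] > 0:
                dx[:, j] += sigma[j] * sqdt * rngs[j].standard_normal(n_act)
        x = x + dx
        crossed = (x >= up) & ~eliminated
        eliminated |= x <= lo
        won = crossed.any(axis=1)
        dead = eliminated.all(axis=1) & ~won
        if won.any():
            overshoot = np.where(crossed, (x - up) / up_scale, -np.inf)
            # argmax returns the lowest index among exact ties
            champ = np.argmax(overshoot, axis=1)
            idx = active[won]
            winners[idx] = champ[won]
            times[idx] = step * dt
            censored[idx] = False
        if won.any() or dead.any():
            keep = ~(won | dead)
            active = active[keep]
            x = x[keep]
            eliminated = eliminated[keep]

    return BatchFirstPassage(winners=winners, crossing_times=times,
                             censored=censored, winner_labels=_race_labels(specs))


def simulate_race(specs: list[AccumulatorSpec], dt: float = DEFAULT_DT,
                  horizon: float = 10.0, seed: int = 0) -> FirstPassageResult:
    """Single-trial race; see :func:`batch_race` for the semantics."""
    batch = batch_race(specs, dt=dt, horizon=horizon, n_trials=1, seed=seed)
    if batch.censored[0]:
        return FirstPassageResult(None, float(batch.crossing_times[0]), math.nan, True)
    code = int(batch.winners[0])
    label = batch.winner_labels[code]
    return FirstPassageResult(label, float(batch.crossing_times[0]),
                              float(specs[code].upper_boundary), False)
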