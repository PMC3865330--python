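"""Expert perceptual categorization from competing cell assemblies.

A high-level category neuron C_i accumulates noisy evidence whose mean
rate (net drift) is the summed firing of the assemblies that excite it
minus the summed firing of those that inhibit it:

    mu*_i = (E_i + E_iE_j + E_iI_j) - (I_i + I_iE_j + I_iI_j),

where intersections such as E_iI_j are cell groups that excite category i
while inhibiting category j.  Each of k competing categories races its
evidence toward a shared symmetric recognition threshold z with common
noise sigma, and the probability that category j is recognized first
follows the softmax (boundary-crossing) law

    p(Z_j crossed) = exp(beta mu*_j) / sum_k exp(beta mu*_k),
    beta = 2 z / sigma^2.

The law is exact for two categories (it is the classic crossing
probability of the difference process between symmetric boundaries); for
k > 2 independent accumulators it is the model's defining analytic
choice rule, and :func:`simulate_categorization` exposes the race
simulation so the two can be compared.  k may run into the thousands —
an expert's learned template repertoire.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import softmax as _softmax

from . import sde_core
from .errors import InvalidParameterError

__all__ = [
    "AssemblyRates",
    "CategoryEnsemble",
    "ChoiceDistribution",
    "CategorizationSimulation",
    "net_drift",
    "beta_from_threshold",
    "category_probabilities",
    "simulate_categorization",
    "build_ensemble_from_assemblies",
]

# exp() underflows irrecoverably past ~ +-745; shifted logits below this
# are clamped (they are indistinguishable from -inf at double precision).
_LOGIT_CLAMP = 700.0


@dataclass(frozen=True)
class AssemblyRates:
    """Mean signal rates of the six cell groups feeding one category neuron.

    The first three rates excite the neuron, the last three inhibit it;
    ``*_shared_with_other_*`` groups are intersections that also project
    (with the stated polarity) onto the rival category.  All rates are
    nonnegative mean firing rates in arbitrary evidence units.
    """

    e_own: float
    e_shared_with_other_excite: float
    e_shared_with_other_inhibit: float
    i_own: float
    i_shared_with_other_excite: float
    i_shared_with_other_inhibit: float

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            value = float(getattr(self, name))
            if math.isnan(value) or value < 0:
                raise InvalidParameterError(f"{name} must be a nonnegative rate, got {value}")
            object.__setattr__(self, name, value)

    @property
    def excitatory(self) -> tuple[float, float, float]:
        return (self.e_own, self.e_shared_with_other_excite, self.e_shared_with_other_inhibit)

    @property
    def inhibitory(self) -> tuple[float, float, float]:
        return (self.i_own, self.i_shared_with_other_excite, self.i_shared_with_other_inhibit)

    def swapped(self) -> "AssemblyRates":
        """Rates with the excitatory and inhibitory triples exchanged."""
        return AssemblyRates(*self.inhibitory, *self.excitatory)


def net_drift(rates: AssemblyRates) -> float:
    """Net drift mu* = sum(excitatory rates) - sum(inhibitory rates)."""
    return math.fsum(rates.excitatory) - math.fsum(rates.inhibitory)


def beta_from_threshold(z: float, sigma: float) -> float:
    """Noise-sensitivity parameter beta = 2 z / sigma^2."""
    z, sigma = float(z), float(sigma)
    if not (z > 0) or not (sigma > 0):
        raise InvalidParameterError(f"z and sigma must be positive, got z={z}, sigma={sigma}")
    return 2.0 * z / sigma**2


@dataclass(frozen=True)
class ChoiceDistribution:
    """Normalized probabilities over a labelled option set."""

    labels: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        probs = np.asarray(self.probabilities, dtype=float)
        if probs.ndim != 1 or len(labels) != probs.size:
            raise InvalidParameterError("labels and probabilities must have equal length")
        if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
            raise InvalidParameterError("probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise InvalidParameterError(f"probabilities sum to {probs.sum()!r}, not 1")
        object.__setattr__(self, "labels", labels)
        probs = probs.copy()
        probs.flags.writeable = False
        object.__setattr__(self, "probabilities", probs)

    def __getitem__(self, label: str) -> float:
        return float(self.probabilities[self.labels.index(label)])

    def as_dict(self) -> dict[str, float]:
        return {l: float(p) for l, p in zip(self.labels, self.probabilities)}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"label": self.labels, "probability": self.probabilities})


@dataclass(frozen=True)
class CategoryEnsemble:
    """k >= 2 category accumulators sharing one threshold and noise scale."""

    labels: tuple[str, ...]
    net_drifts: np.ndarray
    threshold: float = 1.0
    diffusion: float = 1.0

    def __post_init__(self):
        labels = tuple(str(l) for l in self.labels)
        drifts = np.asarray(self.net_drifts, dtype=float)
        if len(labels) < 2:
            raise InvalidParameterError("an ensemble needs at least 2 categories")
        if len(set(labels)) != len(labels):
            raise InvalidParameterError("category labels must be unique")
        if drifts.shape != (len(labels),):
            raise InvalidParameterError("net_drifts must match labels in length")
        if not np.all(np.isfinite(drifts)):
            raise InvalidParameterError("net drifts must be finite")
        if not (float(self.threshold) > 0) or not (float(self.diffusion) > 0):
            raise InvalidParameterError("threshold and diffusion must be positive")
        object.__setattr__(self, "labels", labels)
        drifts = drifts.copy()
        drifts.flags.writeable = False
        object.__setattr__(self, "net_drifts", drifts)
        object.__setattr__(self, "threshold", float(self.threshold))
        object.__setattr__(self, "diffusion", float(self.diffusion))

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def beta(self) -> float:
        return beta_from_threshold(self.threshold, self.diffusion)


def _stable_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max()
    if np.any(shifted < -_LOGIT_CLAMP):
        warnings.warn(
            "softmax logits span more than 700 after shifting; "
            "smallest probabilities underflow to 0",
            RuntimeWarning,
            stacklevel=3,
        )
        shifted = np.maximum(shifted, -_LOGIT_CLAMP)
    p = _softmax(shifted)
    return p / p.sum()  # exact renormalization


def category_probabilities(ensemble: CategoryEnsemble) -> ChoiceDistribution:
    """Recognition probabilities p_j = softmax(beta * mu*_j).

    Computed with max-subtraction so the result is invariant (to within
    1e-12) under adding any constant to all net drifts, and normalized
    exactly.
    """
    logits = ensemble.beta * ensemble.net_drifts
    return ChoiceDistribution(ensemble.labels, _stable_softmax(logits))


@dataclass(frozen=True)
class CategorizationSimulation:
    """Empirical recognition frequencies from a race simulation.

    Frequencies are computed over decided trials only; ``n_censored``
    counts trials whose horizon elapsed with no category reaching
    threshold.
    """

    distribution: ChoiceDistribution
    n_censored: int
    n_trials: int


def simulate_categorization(ensemble: CategoryEnsemble, dt: float = sde_core.DEFAULT_DT,
                            horizon: float = 10.0, n_trials: int = 1000,
                            seed: int = 0) -> CategorizationSimulation:
    """Race the k category accumulators and return win frequencies.

    Each category runs an accumulator with drift mu*_j, the shared
    diffusion sigma, an upper (recognition) boundary at z and no lower
    boundary: recognition is reaching z, never rejection.
    """
    if n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    specs = [
        sde_core.AccumulatorSpec(
            drift=float(mu), diffusion=ensemble.diffusion,
            upper_boundary=ensemble.threshold, lower_boundary=-math.inf,
            label=label,
        )
        for label, mu in zip(ensemble.labels, ensemble.net_drifts)
    ]
    batch = sde_core.batch_race(specs, dt=dt, horizon=horizon,
                                n_trials=n_trials, seed=seed)
    decided = ~batch.censored
    n_decided = int(decided.sum())
    counts = np.bincount(batch.winners[decided], minlength=ensemble.k)
    if n_decided == 0:
        raise InvalidParameterError(
            "all trials censored; increase horizon or lower the threshold")
    freqs = counts / n_decided
    return CategorizationSimulation(
        distribution=ChoiceDistribution(ensemble.labels, freqs),
        n_censored=n_trials - n_decided,
        n_trials=n_trials,
    )


def build_ensemble_from_assemblies(pair: tuple[AssemblyRates, AssemblyRates],
                                   z: float, sigma: float,
                                   labels: tuple[str, str] = ("C1", "C2")) -> CategoryEnsemble:
    """Binary ensemble whose net drifts come from two mirrored rate sets."""
    if len(pair) != 2:
        raise InvalidParameterError("exactly two assembly rate sets are required")
    drifts = [net_drift(r) for r in pair]
    return CategoryEnsemble(labels=labels, net_drifts=np.array(drifts),
                            threshold=z, diffusion=sigma)
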