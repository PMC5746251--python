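"""Optimal present/absent search observer with Gaussian measurement noise.

The observer sees a display of ``N`` oriented elements. On target-present
trials one element has the target orientation ``s_T`` and the remaining
``N-1`` have the distractor orientation ``s_D``; on target-absent trials all
``N`` are distractors. Each element yields a noisy orientation measurement
``x_i ~ Normal(s_i, sigma_i^2)`` where the measurement noise depends on the
element's identity (target vs distractor). The optimal decision variable is
the global log-likelihood ratio

    d = log[(1/N) * sum_i exp(d_i)]

where each local log-likelihood ratio has the closed form

    d_i = (1/2) log(sigma_D^2 / sigma_T^2)
          - (1/2) [(x_i - s_T)^2 / sigma_T^2 - (x_i - s_D)^2 / sigma_D^2]

and the observer reports "present" whenever d exceeds the decision
threshold (0 is optimal at 50% prevalence).

Orientations are treated on a linear degree scale: the measurement
distributions are linear Gaussians and the 30-degree target/distractor
separation used throughout is far from circular wrap-around effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, ndtri

__all__ = [
    "SearchConfig",
    "ReliabilityPair",
    "DisplayMeasurements",
    "DecisionVariables",
    "ResponseCounts",
    "simulate_display",
    "local_llr",
    "global_decision",
    "decision_variables",
    "decide",
    "simulate_experiment",
    "sensitivity_and_bias",
]


@dataclass(frozen=True)
class SearchConfig:
    """Display geometry and stimulus orientations entering the decision rule.

    Defaults follow the study design this package emulates: a 5x5 array of
    candidate target locations (N=25), near-cardinal orientation 80 degrees,
    oblique orientation 50 degrees, equal prevalence, optimal threshold 0.
    """

    n_locations: int = 25
    s_target: float = 80.0
    s_distractor: float = 50.0
    decision_threshold: float = 0.0
    present_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n_locations < 1:
            raise ValueError("n_locations must be >= 1")
        if self.s_target == self.s_distractor:
            raise ValueError("s_target must differ from s_distractor")
        if not 0.0 < self.present_prob < 1.0:
            raise ValueError("present_prob must lie strictly in (0, 1)")


@dataclass(frozen=True)
class ReliabilityPair:
    """Orientation uncertainty (inverse reliability) of targets/distractors."""

    sigma_target: float
    sigma_distractor: float

    def __post_init__(self) -> None:
        for name in ("sigma_target", "sigma_distractor"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0.0):
                raise ValueError(f"{name} must be strictly positive and finite")


@dataclass(frozen=True)
class DisplayMeasurements:
    """Noisy orientation measurements for one display."""

    measurements: np.ndarray
    target_present: bool
    target_location: int | None

    def __post_init__(self) -> None:
        if self.target_present == (self.target_location is None):
            raise ValueError("target_location must be set iff target_present")


@dataclass(frozen=True)
class DecisionVariables:
    """Local log-likelihood ratios and their pooled global value."""

    local: np.ndarray
    global_llr: float


@dataclass(frozen=True)
class ResponseCounts:
    """Present/absent response counts of one simulated (or real) experiment."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_present(self) -> int:
        return self.hits + self.misses

    @property
    def n_absent(self) -> int:
        return self.false_alarms + self.correct_rejections

    @property
    def n_trials(self) -> int:
        return self.n_present + self.n_absent


def simulate_display(
    target_present: bool,
    config: SearchConfig,
    rel: ReliabilityPair,
    rng: np.random.Generator,
) -> DisplayMeasurements:
    """Draw one display's orientation measurements.

    Every location receives an independent Gaussian measurement centred on
    its element's orientation; on present trials the target occupies a
    uniformly chosen location.
    """
    n = config.n_locations
    x = rng.normal(config.s_distractor, rel.sigma_distractor, size=n)
    loc: int | None = None
    if target_present:
        loc = int(rng.integers(n))
        x[loc] = rng.normal(config.s_target, rel.sigma_target)
    return DisplayMeasurements(measurements=x, target_present=target_present, target_location=loc)


def local_llr(x, config: SearchConfig, rel: ReliabilityPair):
    """Local log-likelihood ratio d_i of target vs distractor at one location.

    Vectorised over ``x``. Equals the log ratio of the two Gaussian
    measurement densities, in closed form.
    """
    x = np.asarray(x, dtype=float)
    st, sd = config.s_target, config.s_distractor
    vt = rel.sigma_target**2
    vd = rel.sigma_distractor**2
    return 0.5 * math.log(vd / vt) - 0.5 * ((x - st) ** 2 / vt - (x - sd) ** 2 / vd)


def global_decision(locals_: np.ndarray, n_locations: int) -> float:
    """Pool local LLRs into the global LLR: log of the mean of exp(d_i).

    Overflow-safe (log-sum-exp). The vector length must equal the number of
    display locations, since the 1/N prior over target position is what makes
    the mean the correct pooling rule.
    """
    locals_ = np.asarray(locals_, dtype=float)
    if locals_.size == 0:
        raise ValueError("locals vector must be non-empty")
    if locals_.size != n_locations:
        raise ValueError(f"expected {n_locations} local values, got {locals_.size}")
    return float(logsumexp(locals_) - math.log(n_locations))


def decision_variables(
    display: DisplayMeasurements, config: SearchConfig, rel: ReliabilityPair
) -> DecisionVariables:
    """Local and global decision variables for one display."""
    loc = local_llr(display.measurements, config, rel)
    return DecisionVariables(local=loc, global_llr=global_decision(loc, config.n_locations))


def decide(d: float, threshold: float = 0.0) -> bool:
    """Report target present iff d strictly exceeds the threshold.

    The tie d == threshold maps to "absent" — a measure-zero event, fixed
    for determinism.
    """
    if not np.isfinite(d):
        raise ValueError("decision variable must be finite")
    return bool(d > threshold)


def _experiment_responses(
    z: np.ndarray,
    present: np.ndarray,
    target_cols: np.ndarray,
    config: SearchConfig,
    rel: ReliabilityPair,
) -> np.ndarray:
    """Present/absent responses for a block of trials from standard-normal draws.

    ``z`` has shape (n_trials, N); ``present`` is a boolean mask over trials;
    ``target_cols`` gives the target location for each present trial (in
    order). Reusing a fixed ``z`` across parameter candidates implements
    common random numbers for the stochastic fitting objective.
    """
    x = config.s_distractor + rel.sigma_distractor * z
    rows = np.flatnonzero(present)
    x[rows, target_cols] = config.s_target + rel.sigma_target * z[rows, target_cols]
    d_local = local_llr(x, config, rel)
    # max-shifted log-mean-exp per trial; faster than scipy's general routine
    # on this (n_trials, N) layout and equally overflow-safe
    m = d_local.max(axis=1)
    d_global = m + np.log(np.exp(d_local - m[:, None]).mean(axis=1))
    return d_global > config.decision_threshold


def _counts_from_responses(responses: np.ndarray, present: np.ndarray) -> ResponseCounts:
    hits = int(np.count_nonzero(responses & present))
    fas = int(np.count_nonzero(responses & ~present))
    return ResponseCounts(
        hits=hits,
        misses=int(np.count_nonzero(present)) - hits,
        false_alarms=fas,
        correct_rejections=int(np.count_nonzero(~present)) - fas,
    )


def simulate_experiment(
    config: SearchConfig,
    rel: ReliabilityPair,
    n_trials: int,
    rng: np.random.Generator,
) -> ResponseCounts:
    """Simulate a full present/absent experiment and tally responses.

    The number of present trials is round(present_prob * n_trials); each
    trial runs the display simulation, the local/global LLR computation and
    the threshold decision (vectorised across trials).
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    n_present = int(round(config.present_prob * n_trials))
    present = np.zeros(n_trials, dtype=bool)
    present[:n_present] = True
    z = rng.standard_normal((n_trials, config.n_locations))
    target_cols = rng.integers(config.n_locations, size=n_present)
    responses = _experiment_responses(z, present, target_cols, config, rel)
    return _counts_from_responses(responses, present)


def _corrected_rates(counts: ResponseCounts, correction: str) -> tuple[float, float]:
    if correction == "loglinear":
        h = (counts.hits + 0.5) / (counts.n_present + 1.0)
        f = (counts.false_alarms + 0.5) / (counts.n_absent + 1.0)
    elif correction == "none":
        h = counts.hits / counts.n_present
        f = counts.false_alarms / counts.n_absent
    else:
        raise ValueError(f"unknown correction rule: {correction!r}")
    return h, f


def sensitivity_and_bias(
    counts: ResponseCounts, correction: str = "loglinear"
) -> tuple[float, float]:
    """Sensitivity d' = z(H) - z(F) and criterion c = -(z(H) + z(F)) / 2.

    The log-linear correction (default) adds 0.5 to each response cell and 1
    to each trial count before taking rates, keeping d' finite when the hit
    or false-alarm rate is 0 or 1. Pass ``correction="none"`` for the raw
    rates.
    """
    if counts.n_present == 0 or counts.n_absent == 0:
        raise ValueError("need at least one present and one absent trial")
    h, f = _corrected_rates(counts, correction)
    zh, zf = ndtri(h), ndtri(f)
    return float(zh - zf), float(-(zh + zf) / 2.0)
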