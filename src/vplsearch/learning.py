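"""Reliability learning curves and the group/session -> (sigma_T, sigma_D) map.

Perceptual learning is modelled as an exponential decrease of orientation
uncertainty over training sessions:

    sigma(t) = sigma0 * (1 + exp(-tau * t))

so uncertainty starts at 2*sigma0 on day 1 (t = 0) and decays toward the
asymptote sigma0. Four model variants differ in which uncertainties and
learning rates are free:

- R   (Reliability): separate initial uncertainties for the near-cardinal and
      oblique orientations, one shared learning rate. 3 parameters.
- L   (Learning): one shared initial uncertainty, separate learning rates for
      the target and distractor roles. 3 parameters.
- RL  (Reliability-and-Learning): separate initial uncertainties and separate
      target/distractor learning rates. 4 parameters.
- RLG (Reliability-Learning-Group): separate initial uncertainties, and
      target/distractor learning rates that are independent per group.
      6 parameters.

One group trains with the near-cardinal target among oblique distractors,
the other with the roles of the two orientations reversed; in the
orientation-transfer test each group is probed with the *untrained* target,
i.e. the two orientations swap task roles while keeping the uncertainty each
acquired during training (frozen at the end-of-training state).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .observer import ReliabilityPair

__all__ = [
    "CARDINAL_ORIENTATION",
    "OBLIQUE_ORIENTATION",
    "GROUPS",
    "VARIANTS",
    "PARAM_COUNTS",
    "RATE_KEYS",
    "LearningCurveParams",
    "VariantParams",
    "GroupPhase",
    "uncertainty_at",
    "role_mapping",
    "orientation_values",
    "session_reliabilities",
    "pack_params",
    "unpack_params",
    "param_names",
]

# Stimulus orientations in degrees counterclockwise from vertical.
CARDINAL_ORIENTATION = 80.0
OBLIQUE_ORIENTATION = 50.0

GROUPS = ("near_cardinal", "oblique")
VARIANTS = ("R", "L", "RL", "RLG")
PARAM_COUNTS = {"R": 3, "L": 3, "RL": 4, "RLG": 6}

# Learning-rate keys per variant, in packing order.
RATE_KEYS = {
    "R": ("tau",),
    "L": ("tau_target", "tau_distractor"),
    "RL": ("tau_target", "tau_distractor"),
    "RLG": (
        "tau_target_near_cardinal",
        "tau_distractor_near_cardinal",
        "tau_target_oblique",
        "tau_distractor_oblique",
    ),
}


@dataclass(frozen=True)
class LearningCurveParams:
    """One exponential uncertainty curve: asymptote sigma0 and rate tau."""

    sigma0: float
    tau: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma0) and self.sigma0 > 0):
            raise ValueError("sigma0 must be strictly positive and finite")
        if not (np.isfinite(self.tau) and self.tau >= 0):
            raise ValueError("tau must be nonnegative and finite")


@dataclass(frozen=True)
class VariantParams:
    """Free parameters of one model variant.

    ``rates`` maps the variant's learning-rate keys (see ``RATE_KEYS``) to
    per-session rates. Under L the two orientations share one initial
    uncertainty, so ``sigma_cardinal == sigma_oblique`` is enforced.
    """

    variant: str
    sigma_cardinal: float
    sigma_oblique: float
    rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant: {self.variant!r}")
        for name in ("sigma_cardinal", "sigma_oblique"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive and finite")
        if self.variant == "L" and self.sigma_cardinal != self.sigma_oblique:
            raise ValueError("L variant requires sigma_cardinal == sigma_oblique")
        expected = RATE_KEYS[self.variant]
        if tuple(self.rates.keys()) != expected:
            if set(self.rates.keys()) != set(expected):
                raise ValueError(
                    f"{self.variant} variant requires rates {expected}, got {tuple(self.rates)}"
                )
            object.__setattr__(self, "rates", {k: self.rates[k] for k in expected})
        for k, v in self.rates.items():
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"rate {k} must be nonnegative and finite")

    @property
    def k(self) -> int:
        """Number of free parameters (3/3/4/6 for R/L/RL/RLG)."""
        return PARAM_COUNTS[self.variant]


@dataclass(frozen=True)
class GroupPhase:
    """A (group, session, phase) coordinate in the study design."""

    group: str
    phase: str = "training"
    session_index: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group: {self.group!r}")
        if self.phase not in ("training", "orientation_test"):
            raise ValueError(f"unknown phase: {self.phase!r}")
        if self.phase == "training":
            if self.session_index is None or self.session_index < 1:
                raise ValueError("training phase requires session_index >= 1")
        elif self.session_index is not None:
            raise ValueError("orientation_test carries no session_index")


def uncertainty_at(params: LearningCurveParams, t: float) -> float:
    """Uncertainty sigma0 * (1 + exp(-tau * t)) after t elapsed sessions."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return params.sigma0 * (1.0 + np.exp(-params.tau * t))


def role_mapping(group: str) -> tuple[str, str]:
    """Orientations holding the (target, distractor) roles during training."""
    if group == "near_cardinal":
        return ("cardinal", "oblique")
    if group == "oblique":
        return ("oblique", "cardinal")
    raise ValueError(f"unknown group: {group!r}")


def orientation_values(gp: GroupPhase) -> tuple[float, float]:
    """(s_T, s_D) in degrees for a group and phase.

    During training the group's trained orientation is the target; in the
    orientation test the two orientations swap roles.
    """
    tgt, _ = role_mapping(gp.group)
    if gp.phase == "orientation_test":
        tgt = "oblique" if tgt == "cardinal" else "cardinal"
    if tgt == "cardinal":
        return CARDINAL_ORIENTATION, OBLIQUE_ORIENTATION
    return OBLIQUE_ORIENTATION, CARDINAL_ORIENTATION


def _training_rates(params: VariantParams, group: str) -> dict[str, float]:
    """Learning rate per orientation ("cardinal"/"oblique") for one group.

    Rates attach to the role an orientation holds during *training*: under L
    and RL the training target's orientation learns at tau_target and the
    training distractor's at tau_distractor; under RLG the same attachment
    uses the group-specific pair; under R both orientations share one rate.
    """
    tgt_orient, dist_orient = role_mapping(group)
    r = params.rates
    if params.variant == "R":
        return {"cardinal": r["tau"], "oblique": r["tau"]}
    if params.variant in ("L", "RL"):
        return {tgt_orient: r["tau_target"], dist_orient: r["tau_distractor"]}
    suffix = "near_cardinal" if group == "near_cardinal" else "oblique"
    return {
        tgt_orient: r[f"tau_target_{suffix}"],
        dist_orient: r[f"tau_distractor_{suffix}"],
    }


def _sigma0(params: VariantParams, orientation: str) -> float:
    return params.sigma_cardinal if orientation == "cardinal" else params.sigma_oblique


def session_reliabilities(
    params: VariantParams, gp: GroupPhase, n_training_sessions: int = 6
) -> ReliabilityPair:
    """The (sigma_T, sigma_D) pair the observer model uses on one session.

    Training day ``i`` evaluates each orientation's curve at t = i - 1. The
    orientation test freezes both curves at the end-of-training state
    (t = n_training_sessions - 1) and swaps the target/distractor roles; the
    test is a read-out of the learned state, not a further training step.
    """
    rates = _training_rates(params, gp.group)
    tgt_orient, dist_orient = role_mapping(gp.group)
    if gp.phase == "training":
        if gp.session_index > n_training_sessions:
            raise ValueError(
                f"session_index {gp.session_index} exceeds {n_training_sessions} training sessions"
            )
        t = float(gp.session_index - 1)
    else:
        t = float(n_training_sessions - 1)
        tgt_orient, dist_orient = dist_orient, tgt_orient
    sig = {
        o: uncertainty_at(LearningCurveParams(_sigma0(params, o), rates[o]), t)
        for o in ("cardinal", "oblique")
    }
    return ReliabilityPair(sigma_target=sig[tgt_orient], sigma_distractor=sig[dist_orient])


def param_names(variant: str) -> tuple[str, ...]:
    """Ordered names of the packed parameter vector for one variant."""
    if variant == "L":
        return ("sigma",) + RATE_KEYS["L"]
    if variant in VARIANTS:
        return ("sigma_cardinal", "sigma_oblique") + RATE_KEYS[variant]
    raise ValueError(f"unknown variant: {variant!r}")


def pack_params(params: VariantParams) -> np.ndarray:
    """Flatten VariantParams to the variant's ordered vector (length k)."""
    if params.variant == "L":
        head = [params.sigma_cardinal]
    else:
        head = [params.sigma_cardinal, params.sigma_oblique]
    return np.array(head + [params.rates[k] for k in RATE_KEYS[params.variant]], dtype=float)


def unpack_params(vector, variant: str) -> VariantParams:
    """Inverse of :func:`pack_params`; validates the vector length."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant: {variant!r}")
    vector = np.asarray(vector, dtype=float)
    k = PARAM_COUNTS[variant]
    if vector.shape != (k,):
        raise ValueError(f"{variant} variant expects a length-{k} vector, got shape {vector.shape}")
    if variant == "L":
        sig_c = sig_o = vector[0]
        tail = vector[1:]
    else:
        sig_c, sig_o = vector[0], vector[1]
        tail = vector[2:]
    rates = dict(zip(RATE_KEYS[variant], tail.tolist()))
    return VariantParams(
        variant=variant, sigma_cardinal=float(sig_c), sigma_oblique=float(sig_o), rates=rates
    )
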