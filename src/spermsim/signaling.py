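"""Receptor-level signaling: chemoattractant binding, cGMP production,
the turn trigger, and desensitization.

The chemoattractant receptor is a membrane guanylyl cyclase (GC).  Binding
follows a negatively cooperative Hill curve (K1/2 = 0.65 nM, h = 0.49).
Because binding equilibrates slowly (on the order of two minutes), only a
fraction 1/2000 of the equilibrium occupancy binds per 60 ms frame.  Each
bound GC produces cGMP at a stochastic rate of 4.3 +/- 1.7 molecules per
frame; cGMP lives for a single frame and the sperm enters a turn when the
per-frame cGMP total reaches a threshold of 100 molecules.

Two desensitization schemes are modeled:

``continuous`` (sea urchin)
    Bound GC autodephosphorylates after ~160 ms: a binding cohort produces
    cGMP for three frames and is then permanently removed from the
    signal-competent pool.

``turn_triggered`` (starfish)
    GC dephosphorylation is coupled to the Ca2+ influx that initiates a
    turn: the whole bound pool is removed at the instant a turn begins.

A "frozen" control disables the desensitization subtraction altogether:
nothing ever removes receptors from the bound pool, which therefore
accumulates monotonically and keeps producing cGMP.  The signal-competent
population (active + bound) never shrinks, the per-frame cGMP signal
saturates far above threshold, and turning degenerates into a
concentration-insensitive fixed cycle — the control that demonstrates why
desensitization is essential for chemotaxis.

This module holds the scalar reference semantics, written for clarity and
used directly by the unit tests; :mod:`spermsim.engine` applies the same
update rules vectorized across a cohort of agents.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np

__all__ = [
    "BindingParams",
    "ReceptorState",
    "hill_fraction",
    "bind_step",
    "cgmp_production",
    "check_turn_trigger",
    "desensitize_continuous",
    "desensitize_on_turn",
    "equilibrium_bound",
]

CONTINUOUS = "continuous"
TURN_TRIGGERED = "turn_triggered"


@dataclass(frozen=True)
class BindingParams:
    """Receptor and second-messenger parameters.

    Units: ``k_half`` in nM; cGMP rates in molecules per bound GC per 60 ms
    frame; ``cgmp_threshold`` in molecules per frame; ``bound_lifetime_frames``
    in frames (continuous scheme only).
    """

    k_half: float = 0.65
    hill_coefficient: float = 0.49
    binding_divisor: float = 2000.0
    cgmp_rate_mean: float = 4.3
    cgmp_rate_sd: float = 1.7
    cgmp_threshold: float = 100.0
    initial_gc: int = 300_000
    bound_lifetime_frames: int = 3
    #: one N(mean, sd) draw per sperm per frame ("per_frame", default) or a
    #: central-limit equivalent of one draw per bound receptor ("per_receptor").
    draw_mode: str = "per_frame"
    #: integer rounding of the per-frame binding increment: "stochastic"
    #: (floor + Bernoulli on the fractional part, default), "floor" or "round".
    rounding: str = "stochastic"

    def __post_init__(self) -> None:
        if not self.k_half > 0:
            raise ValueError("k_half must be positive")
        if not 0 < self.hill_coefficient <= 1:
            raise ValueError("hill_coefficient must lie in (0, 1]")
        if self.binding_divisor < 1:
            raise ValueError("binding_divisor must be >= 1")
        if not self.cgmp_threshold > 0:
            raise ValueError("cgmp_threshold must be positive")
        if not self.initial_gc > 0:
            raise ValueError("initial_gc must be positive")
        if self.draw_mode not in ("per_frame", "per_receptor"):
            raise ValueError(f"unknown draw_mode {self.draw_mode!r}")
        if self.rounding not in ("stochastic", "floor", "round"):
            raise ValueError(f"unknown rounding {self.rounding!r}")


@dataclass
class ReceptorState:
    """Bookkeeping of one sperm's GC pools.

    ``active_gc`` counts phosphorylated, unbound, signal-competent receptors;
    ``bound_cohorts`` holds (birth_frame, count) pairs of currently bound GC;
    ``desensitized_gc`` accumulates permanently removed receptors.  The three
    pools always sum to the initial receptor count.
    """

    active_gc: int
    bound_cohorts: List[Tuple[int, int]] = field(default_factory=list)
    desensitized_gc: int = 0
    species_scheme: str = CONTINUOUS

    @classmethod
    def initial(cls, params: BindingParams, scheme: str = CONTINUOUS) -> "ReceptorState":
        if scheme not in (CONTINUOUS, TURN_TRIGGERED):
            raise ValueError(f"unknown scheme {scheme!r}")
        return cls(active_gc=params.initial_gc, species_scheme=scheme)

    @property
    def total_bound(self) -> int:
        return sum(count for _, count in self.bound_cohorts)

    def total(self) -> int:
        return self.active_gc + self.total_bound + self.desensitized_gc


def hill_fraction(concentration, params: BindingParams):
    """Equilibrium occupancy fraction C^h / (K1/2^h + C^h), in [0, 1].

    Accepts scalars or arrays (nM).  Zero at zero concentration, 1/2 at
    ``k_half``, approaching 1 at saturation.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    ch = np.power(c, params.hill_coefficient)
    frac = ch / (params.k_half**params.hill_coefficient + ch)
    return frac if frac.ndim else float(frac)


def _round_count(raw: float, rounding: str, u: float) -> int:
    if rounding == "floor":
        return int(np.floor(raw))
    if rounding == "round":
        return int(np.rint(raw))
    lo = int(np.floor(raw))
    return lo + (u < raw - lo)


def bind_step(
    state: ReceptorState,
    concentration: float,
    params: BindingParams,
    frame: int,
    rng: np.random.Generator,
) -> int:
    """One frame of GC-chemoattractant binding.

    Moves ``active_gc * hill_fraction(C) / binding_divisor`` receptors
    (rounded to an integer per ``params.rounding``) from the active pool into
    a new cohort stamped with ``frame``.  Returns the number newly bound.
    """
    raw = state.active_gc * hill_fraction(concentration, params) / params.binding_divisor
    u = rng.uniform() if params.rounding == "stochastic" else 0.0
    new = min(_round_count(raw, params.rounding, u), state.active_gc)
    if new > 0:
        state.active_gc -= new
        state.bound_cohorts.append((frame, new))
    return new


def cgmp_production(
    state: ReceptorState, params: BindingParams, rng: np.random.Generator
) -> float:
    """cGMP molecules produced this frame by the currently bound pool.

    One normal rate draw per frame (``per_frame``) multiplied by the bound
    count, or a CLT-equivalent of independent per-receptor draws
    (``per_receptor``); either way the draw is clamped at zero, since
    production cannot be negative.  The returned amount exists for this frame
    only — cGMP does not accumulate across frames.
    """
    b = state.total_bound
    if b == 0:
        # burn a draw so the stream position does not depend on state
        rng.normal()
        return 0.0
    if params.draw_mode == "per_frame":
        rate = max(0.0, params.cgmp_rate_mean + params.cgmp_rate_sd * rng.normal())
        return b * rate
    total = b * params.cgmp_rate_mean + params.cgmp_rate_sd * np.sqrt(b) * rng.normal()
    return max(0.0, total)


def check_turn_trigger(cgmp_this_frame: float, params: BindingParams) -> bool:
    """True when the per-frame cGMP reaches the turn threshold (inclusive)."""
    if cgmp_this_frame < 0:
        raise ValueError("cGMP amount must be non-negative")
    return cgmp_this_frame >= params.cgmp_threshold


def desensitize_continuous(
    state: ReceptorState, params: BindingParams, frame: int, frozen: bool = False
) -> ReceptorState:
    """Expire binding cohorts that have reached their three-frame lifetime.

    Expired receptors move to the desensitized pool.  Under the frozen
    control the subtraction is skipped entirely — cohorts stay bound and
    keep producing.  Mutates and returns ``state``.
    """
    if state.species_scheme != CONTINUOUS:
        raise ValueError("continuous desensitization requires the continuous scheme")
    if frozen:
        return state
    keep: List[Tuple[int, int]] = []
    for birth, count in state.bound_cohorts:
        if frame - birth >= params.bound_lifetime_frames:
            state.desensitized_gc += count
        else:
            keep.append((birth, count))
    state.bound_cohorts = keep
    return state


def desensitize_on_turn(state: ReceptorState, frozen: bool = False) -> ReceptorState:
    """Remove the whole bound pool at turn onset (starfish scheme).

    Called exactly once per entry into turn mode.  The bound pool moves to
    the desensitized pool; under the frozen control the subtraction is
    skipped and the pool persists.  Mutates and returns ``state``.
    """
    if state.species_scheme != TURN_TRIGGERED:
        raise ValueError("turn-triggered desensitization requires the turn_triggered scheme")
    if frozen:
        return state
    state.desensitized_gc += state.total_bound
    state.bound_cohorts = []
    return state


def equilibrium_bound(active_gc, concentration, params: BindingParams):
    """Equilibrium bound-GC count: active pool times the Hill fraction.

    The slow-binding divisor does not appear here — it sets the rate of
    approach to equilibrium, not the equilibrium itself.  This is the
    steady-state quantity behind the observation that desensitization tunes
    the bound-receptor count to a near-constant value across the gradient.
    """
    active = np.asarray(active_gc, dtype=float)
    if np.any(active < 0):
        raise ValueError("active_gc must be non-negative")
    out = active * hill_fraction(concentration, params)
    return out if out.ndim else float(out)
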