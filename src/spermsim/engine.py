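"""Cohort simulation engine.

Advances a cohort of independent sperm agents through the full model loop.
Each 60 ms frame, per agent:

1. evaluate the chemoattractant concentration at the sperm position,
   relative to the (possibly oscillating) egg center;
2. bind receptors: ``active_gc x Hill(C) / 2000`` new bindings, integer
   rounded;
3. age binding cohorts / continuous desensitization (sea urchin);
4. draw the stochastic cGMP production of the bound pool;
5. trigger a turn when per-frame cGMP reaches the threshold, applying
   turn-triggered desensitization at that instant (starfish);
6. advance the kinematics one exact circular arc;
7. test arrival: within the egg radius ends the run as success.

Agents are embarrassingly parallel.  Every random draw comes from a
counter-based RNG — a vectorized splitmix64 hash of (master seed, agent
index, frame, draw slot), with normal deviates via the inverse CDF — so an
agent's entire random stream is a pure function of ``(seed, agent_index)``.
Cohort results are therefore bit-identical across runs, independent of
execution order or batching, and :func:`run_sperm` reproduces exactly the
agent that :func:`run_cohort` simulates at the same index.

The whole cohort is stepped synchronously with numpy array operations;
agents that reach the egg are flagged on first crossing (arrival is
absorbing for the statistics) and the loop exits early once every agent
has arrived.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .config import DisturbanceParams, SimulationConfig
from .signaling import TURN_TRIGGERED

__all__ = ["CohortResult", "run_cohort", "run_sperm", "egg_position", "CounterRNG"]

# mode codes in the vectorized state
_CIRCULAR, _TURN, _REFRACTORY = 0, 1, 2
_MODE_NAMES = {_CIRCULAR: "circular", _TURN: "turn", _REFRACTORY: "refractory"}

# draw slots within a frame
SLOT_BINDING = 0   # uniform for stochastic rounding of the binding increment
SLOT_RATE = 1      # uniform behind the normal cGMP-rate draw
SLOT_INIT = 2      # uniform for the initial circle phase (frame 0 only)

_CHECK_EVERY = 512  # frames between all-arrived early-exit checks


# ---------------------------------------------------------------------------
# counter-based RNG
# ---------------------------------------------------------------------------

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_FRAME_C = np.uint64(0xD1B54A32D192ED03)
_SLOT_C = np.uint64(0x8CB92BA72F3D8DD7)


def _mix(x):
    """splitmix64 finalizer; operates elementwise on uint64."""
    x = np.asarray(x, dtype=np.uint64).copy()
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


class CounterRNG:
    """Random-access uniforms indexed by (agent, frame, slot).

    ``uniform(frame, slot)`` returns one deviate in (0, 1) per agent key;
    the value depends only on (master_seed, agent_index, frame, slot).
    """

    def __init__(self, master_seed: int, agent_indices) -> None:
        idx = np.asarray(agent_indices, dtype=np.uint64)
        base = (int(master_seed) * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
        self.keys = _mix(np.uint64(base) + (idx + np.uint64(1)) * _FRAME_C)

    def uniform(self, frame: int, slot: int) -> np.ndarray:
        # frame key in Python ints (arbitrary precision), reduced mod 2^64
        fk = _mix(
            np.uint64(
                (frame * 0x9E3779B97F4A7C15 + slot * 0x8CB92BA72F3D8DD7
                 + 0x632BE59BD9B4E019) & 0xFFFFFFFFFFFFFFFF
            )
        )
        u = _mix(self.keys ^ fk)
        return ((u >> np.uint64(11)).astype(np.float64) + 0.5) * 2.0**-53

    def normal(self, frame: int, slot: int) -> np.ndarray:
        return ndtri(self.uniform(frame, slot))


# ---------------------------------------------------------------------------
# egg motion
# ---------------------------------------------------------------------------

def egg_position(t: float, disturbance: DisturbanceParams | None = None):
    """Egg center at time ``t`` (s): ``(0, A sin(2π f t))`` when the
    positional disturbance is enabled, the origin otherwise."""
    if disturbance is None or not disturbance.enabled:
        return np.array([0.0, 0.0])
    return np.array(
        [0.0, disturbance.amplitude * np.sin(2.0 * np.pi * disturbance.frequency * t)]
    )


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Outcome of one cohort run.

    ``arrival_times`` holds the arrival frame of each successful agent (in
    agent order); ``arrival_rate`` is a fraction (NaN for an empty cohort).
    """

    species: str
    n_sperm: int
    n_arrived: int
    arrival_rate: float
    arrival_times: np.ndarray
    seed: int
    config: dict

    @property
    def arrival_rate_percent(self) -> float:
        return 100.0 * self.arrival_rate

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "n_sperm": self.n_sperm,
            "n_arrived": self.n_arrived,
            "arrival_rate": None if np.isnan(self.arrival_rate) else self.arrival_rate,
            "arrival_times": [int(v) for v in self.arrival_times],
            "seed": self.seed,
            "config": self.config,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# the simulation loop
# ---------------------------------------------------------------------------

def _initial_pose(config: SimulationConfig, rng: CounterRNG, n: int):
    """Start pose: position exactly at (start_distance, 0), heading
    tangential to the agent's swimming circle, whose center lies at a
    uniform-random (or fixed) bearing from the start point."""
    if config.fixed_phase:
        phi = np.zeros(n)
    else:
        phi = 2.0 * np.pi * rng.uniform(0, SLOT_INIT)
    x = np.full(n, float(config.start_distance))
    y = np.zeros(n)
    # bearing of the agent about its circle center is phi + pi; heading is
    # tangential, rotated -90 deg (clockwise) or +90 deg (counterclockwise)
    if config.clockwise:
        heading = phi + 0.5 * np.pi
    else:
        heading = phi + 1.5 * np.pi
    return x, y, heading


def _simulate(config: SimulationConfig, agent_indices, record: int = 0):
    """Run the frame loop for the given agent indices.

    Returns ``(arrived, arrival_frame, trajectories)`` where ``trajectories``
    is a list of per-agent DataFrames for the first ``record`` agents (empty
    list when ``record`` is 0).
    """
    idx = np.asarray(agent_indices, dtype=np.int64)
    n = idx.size
    bp = config.binding
    starfish_scheme = config.scheme == TURN_TRIGGERED
    frozen = config.freeze_desensitization
    prof = config.turn_profile.as_array()
    n_prof = len(prof)
    refr = config.turn_profile.refractory_frames
    v, dt = config.speed, config.dt
    kappa0 = config.baseline_curvature
    fld = config.field.solve()
    r_egg, r_edge, c_surf = fld.egg_radius, fld.field_radius, fld.surface_concentration
    log_ratio = np.log(r_edge / r_egg)
    h = bp.hill_coefficient
    kh = bp.k_half**h
    dist = config.disturbance if config.disturbance.enabled else None

    rng = CounterRNG(config.seed, idx)
    x, y, heading = _initial_pose(config, rng, n)

    mode = np.zeros(n, dtype=np.int8)
    mode_frame = np.zeros(n, dtype=np.int32)
    active = np.full(n, float(bp.initial_gc))
    desens = np.zeros(n)
    # under the frozen control the desensitization subtraction is skipped
    # entirely: bound GC stays bound (and producing) for either species,
    # so a single accumulating pool suffices
    if starfish_scheme or frozen:
        bound_pool = np.zeros(n)
    else:
        c0 = np.zeros(n)
        c1 = np.zeros(n)
        c2 = np.zeros(n)

    ex, ey = egg_position(0.0, dist)
    arrived = np.hypot(x - ex, y - ey) <= r_egg
    arrival_frame = np.where(arrived, 0, -1).astype(np.int64)

    rec = min(record, n)
    if rec:
        cols = ("frame", "t", "x", "y", "heading", "mode", "cgmp",
                "active_gc", "bound_gc", "desensitized_gc")
        buf = {c: [] for c in cols}

    stochastic_round = bp.rounding == "stochastic"
    per_frame_draw = bp.draw_mode == "per_frame"

    for f in range(config.duration_frames):
        t = f * dt
        ex, ey = egg_position(t, dist)

        # 1. local chemoattractant concentration
        r = np.hypot(x - ex, y - ey)
        c = c_surf * np.log(r_edge / np.clip(r, r_egg, r_edge)) / log_ratio
        ch = np.power(c, h)
        frac = ch / (kh + ch)

        # 2. binding
        raw = active * frac / bp.binding_divisor
        if stochastic_round:
            lo = np.floor(raw)
            new = lo + (rng.uniform(f, SLOT_BINDING) < raw - lo)
        elif bp.rounding == "floor":
            new = np.floor(raw)
        else:
            new = np.rint(raw)
        np.minimum(new, active, out=new)
        active -= new

        # 3. cohort aging (continuous scheme; skipped when frozen)
        if starfish_scheme or frozen:
            bound_pool += new
            bound = bound_pool
        else:
            desens += c2
            c2, c1, c0 = c1, c0, new
            bound = c0 + c1 + c2

        # 4. stochastic cGMP production (one-frame lifetime)
        z = rng.normal(f, SLOT_RATE)
        if per_frame_draw:
            rate = np.maximum(bp.cgmp_rate_mean + bp.cgmp_rate_sd * z, 0.0)
            cgmp = bound * rate
        else:
            cgmp = np.maximum(
                bound * bp.cgmp_rate_mean + bp.cgmp_rate_sd * np.sqrt(bound) * z, 0.0
            )

        # 5. turn trigger (blocked during turn and refractory); the
        # turn-time subtraction is skipped when frozen
        trig = (cgmp >= bp.cgmp_threshold) & (mode == _CIRCULAR)
        if starfish_scheme and not frozen and trig.any():
            desens[trig] += bound_pool[trig]
            bound_pool[trig] = 0.0
        mode[trig] = _TURN
        mode_frame[trig] = 0

        # 6. kinematic step (exact circular arc)
        in_turn = mode == _TURN
        mult = np.ones(n)
        mult[in_turn] = prof[mode_frame[in_turn]]
        dtheta = v * kappa0 * dt * mult
        chord = v * dt * np.sinc(dtheta / (2.0 * np.pi))
        mid = heading + 0.5 * dtheta
        x += chord * np.cos(mid)
        y += chord * np.sin(mid)
        heading += dtheta

        in_refr = mode == _REFRACTORY
        mode_frame[in_turn] += 1
        mode_frame[in_refr] += 1
        done_turn = in_turn & (mode_frame >= n_prof)
        mode[done_turn] = _REFRACTORY if refr > 0 else _CIRCULAR
        mode_frame[done_turn] = 0
        done_refr = in_refr & (mode_frame >= refr)
        mode[done_refr] = _CIRCULAR
        mode_frame[done_refr] = 0

        # 7. arrival test
        newly = ~arrived & (np.hypot(x - ex, y - ey) <= r_egg)
        arrival_frame[newly] = f + 1
        arrived |= newly

        if rec:
            buf["frame"].append(f + 1)
            buf["t"].append((f + 1) * dt)
            buf["x"].append(x[:rec].copy())
            buf["y"].append(y[:rec].copy())
            buf["heading"].append(heading[:rec].copy())
            buf["mode"].append(mode[:rec].copy())
            buf["cgmp"].append(cgmp[:rec].copy())
            buf["active_gc"].append(active[:rec].copy())
            buf["bound_gc"].append(np.asarray(bound)[:rec].copy())
            buf["desensitized_gc"].append(desens[:rec].copy())

        if f % _CHECK_EVERY == 0 and arrived.all():
            break

    trajectories = []
    if rec:
        nf = len(buf["frame"])
        for a in range(rec):
            trajectories.append(
                pd.DataFrame(
                    {
                        "frame": buf["frame"],
                        "t": buf["t"],
                        "x": [buf["x"][i][a] for i in range(nf)],
                        "y": [buf["y"][i][a] for i in range(nf)],
                        "heading": [buf["heading"][i][a] for i in range(nf)],
                        "mode": [_MODE_NAMES[buf["mode"][i][a]] for i in range(nf)],
                        "cgmp": [buf["cgmp"][i][a] for i in range(nf)],
                        "active_gc": [buf["active_gc"][i][a] for i in range(nf)],
                        "bound_gc": [buf["bound_gc"][i][a] for i in range(nf)],
                        "desensitized_gc": [buf["desensitized_gc"][i][a] for i in range(nf)],
                    }
                )
            )
    return arrived, arrival_frame, trajectories


def run_sperm(config: SimulationConfig, agent_index: int = 0,
              record_trajectory: bool = False):
    """Simulate a single agent.

    Returns ``(arrived, arrival_frame_or_None, trajectory_or_None)``.  The
    agent is identified by its index within the cohort of ``config.seed``;
    its outcome is bit-identical to the same index in :func:`run_cohort`.
    """
    arrived, frames, trajs = _simulate(
        config, [agent_index], record=1 if record_trajectory else 0
    )
    arrival = int(frames[0]) if arrived[0] else None
    return bool(arrived[0]), arrival, (trajs[0] if record_trajectory else None)


def run_cohort(config: SimulationConfig, dump_trajectories: int = 0):
    """Simulate the full cohort of ``config.n_sperm`` independent agents.

    Returns a :class:`CohortResult`; with ``dump_trajectories = k`` also
    returns the per-frame trajectories of the first ``k`` agents as
    ``(result, [DataFrame, ...])``.
    """
    n = config.n_sperm
    if n == 0:
        result = CohortResult(
            species=config.species, n_sperm=0, n_arrived=0,
            arrival_rate=float("nan"), arrival_times=np.empty(0, dtype=np.int64),
            seed=config.seed, config=config.to_dict(),
        )
        return (result, []) if dump_trajectories else result
    arrived, frames, trajs = _simulate(config, np.arange(n), record=dump_trajectories)
    n_arr = int(arrived.sum())
    result = CohortResult(
        species=config.species,
        n_sperm=n,
        n_arrived=n_arr,
        arrival_rate=n_arr / n,
        arrival_times=frames[arrived],
        seed=config.seed,
        config=config.to_dict(),
    )
    return (result, trajs) if dump_trajectories else result
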