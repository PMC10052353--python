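"""EDS reference-state Hamiltonian and state-sampling diagnostics.

The enveloping reference potential at smoothing parameter ``s`` with
per-state energy offsets ``E_i`` is

    V_R(x) = -(beta*s)^-1 * ln sum_i exp[-beta*s*(V_i(x) - E_i)]

which lies below ``min_i(V_i - E_i)`` everywhere and within
``(beta*s)^-1 ln N`` of it, so every end-state basin is enveloped. All
log-sum evaluations are shifted by the extreme exponent and are safe for
kJ/mol-scale energy gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.special import logsumexp

from .toy_model import EndStateSystem

__all__ = [
    "EDSParameters",
    "StateWeights",
    "SamplingStats",
    "reference_energy_from_states",
    "reference_potential",
    "state_weights",
    "sampling_fractions",
]


@dataclass(frozen=True)
class EDSParameters:
    """The s-ladder and per-state energy offsets defining the reference state."""

    s_ladder: tuple
    offsets: tuple

    def __init__(self, s_ladder: Sequence[float], offsets: Sequence[float]) -> None:
        s = tuple(float(v) for v in s_ladder)
        if not s or abs(s[0] - 1.0) > 1e-12:
            raise ValueError("s-ladder must start at 1.0")
        if any(v <= 0 for v in s):
            raise ValueError("all s values must be > 0")
        if any(b >= a for a, b in zip(s, s[1:])):
            raise ValueError("s-ladder must be strictly decreasing")
        object.__setattr__(self, "s_ladder", s)
        object.__setattr__(self, "offsets", tuple(float(v) for v in offsets))

    @property
    def n_replicas(self) -> int:
        return len(self.s_ladder)

    @property
    def n_states(self) -> int:
        return len(self.offsets)

    def with_offsets(self, offsets: Sequence[float]) -> "EDSParameters":
        return EDSParameters(self.s_ladder, offsets)


@dataclass(frozen=True)
class StateWeights:
    """Normalized Boltzmann weights of the end states at one configuration."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-12 or (w < 0).any():
            raise ValueError("weights must be nonnegative and sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def dominant_state(self) -> int:
        return int(np.argmax(self.weights))


@dataclass(frozen=True)
class SamplingStats:
    """Per-state sampling fractions of one trajectory and the deviation
    from ideal (equal) sampling, max_i |f_i - 1/N|."""

    fractions: np.ndarray
    deviation_from_ideal: float
    frames_counted: int

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if abs(f.sum() - 1.0) > 1e-12 or (f < 0).any():
            raise ValueError("fractions must be nonnegative and sum to 1")
        if self.deviation_from_ideal < 0:
            raise ValueError("deviation must be >= 0")
        object.__setattr__(self, "fractions", f)

    @property
    def deviation_percent(self) -> float:
        return 100.0 * self.deviation_from_ideal


def reference_energy_from_states(
    v_states: np.ndarray, s: float, offsets: Sequence[float], beta: float
) -> np.ndarray:
    """V_R from end-state energies; vectorized over leading axes.

    ``v_states`` has the state axis last.
    """
    v = np.asarray(v_states, dtype=float)
    E = np.asarray(offsets, dtype=float)
    if v.shape[-1] == 0:
        raise ValueError("empty state list")
    if v.shape[-1] != E.shape[0]:
        raise ValueError(f"{v.shape[-1]} states vs {E.shape[0]} offsets")
    return -logsumexp(-beta * s * (v - E), axis=-1) / (beta * s)


def reference_potential(
    system: EndStateSystem, s: float, offsets: Sequence[float], x: np.ndarray
) -> float:
    """Enveloping reference potential V_R at one configuration (kJ/mol)."""
    if s <= 0:
        raise ValueError("s must be > 0")
    v = system.energies(np.asarray(x, dtype=float))
    return float(reference_energy_from_states(v, s, offsets, system.conditions.beta))


def _log_weights(v_states: np.ndarray, s: float, offsets, beta: float) -> np.ndarray:
    a = -beta * s * (np.asarray(v_states, dtype=float) - np.asarray(offsets, dtype=float))
    return a - logsumexp(a, axis=-1, keepdims=True)


def state_weights(
    system: EndStateSystem, s: float, offsets: Sequence[float], x: np.ndarray
) -> StateWeights:
    """Softmax decomposition of the reference state at one configuration."""
    if s <= 0:
        raise ValueError("s must be > 0")
    v = system.energies(np.asarray(x, dtype=float))
    if v.size == 0:
        raise ValueError("empty state list")
    return StateWeights(np.exp(_log_weights(v, s, offsets, system.conditions.beta)))


def sampling_fractions(traj, params, s: float | None = None) -> SamplingStats:
    """Dominant-state sampling fractions of a trajectory.

    Each frame is assigned to its maximal-weight state (ties break to the
    lowest state index); the deviation from ideal sampling is the maximum
    absolute departure of any fraction from 1/N, the scalar stop criterion
    used by offset rebalancing.

    Parameters
    ----------
    traj
        :class:`~reedsnet.sampler.EnergyTrajectory` (or anything exposing
        ``v_states`` (n_frames, n_states) and ``beta``).
    params
        :class:`EDSParameters`; the physical ``s`` defaults to the value
        recorded on the trajectory.
    """
    v = np.asarray(traj.v_states, dtype=float)
    if v.shape[0] == 0:
        raise ValueError("empty trajectory")
    s_eff = float(s) if s is not None else float(np.atleast_1d(traj.s)[0])
    lw = _log_weights(v, s_eff, params.offsets, traj.beta)
    assigned = np.argmax(lw, axis=-1)  # argmax keeps the lowest index on ties
    n_states = v.shape[-1]
    counts = np.bincount(assigned, minlength=n_states)
    f = counts / counts.sum()
    return SamplingStats(f, float(np.abs(f - 1.0 / n_states).max()), int(v.shape[0]))
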