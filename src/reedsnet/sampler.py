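"""Metropolis sampling of the EDS reference state and replica exchange in s.

Sampling is a derivative-free Metropolis random walk on the reference
potential: single-site Gaussian proposals accepted with probability
``min(1, exp(-beta dV_R))``, which has the exact reference-state Boltzmann
distribution as its stationary law (no integrator timestep bias, so the
quadrature oracles apply without correction terms). Replicas sit at fixed
rungs of the s-ladder; exchanges swap configurations between adjacent rungs
with the usual Hamiltonian replica-exchange criterion. Free energies are
always estimated from the physical s = 1 replica.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .eds_core import EDSParameters, reference_energy_from_states
from .toy_model import EndStateSystem

__all__ = [
    "ReplicaState",
    "ExchangeRecord",
    "EnergyTrajectory",
    "default_proposal_width",
    "propagate",
    "attempt_exchange",
    "run_re_eds",
    "roundtrip_stats",
    "trajectory_to_csv",
    "trajectory_from_csv",
]


@dataclass
class EnergyTrajectory:
    """Per-frame end-state and reference energies from one replica.

    This is the estimator's sole input: every stored ``v_ref`` is exactly
    reproducible from the stored ``v_states`` and the EDS parameters.
    """

    v_states: np.ndarray  # (n_frames, n_states)
    v_ref: np.ndarray  # (n_frames,)
    s: np.ndarray  # (n_frames,) s of origin
    frame_index: np.ndarray  # (n_frames,)
    labels: List[str]
    beta: float

    def __post_init__(self) -> None:
        self.v_states = np.asarray(self.v_states, dtype=float)
        self.v_ref = np.asarray(self.v_ref, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        self.frame_index = np.asarray(self.frame_index, dtype=int)

    @property
    def n_frames(self) -> int:
        return self.v_states.shape[0]

    def prefix(self, n: int) -> "EnergyTrajectory":
        return EnergyTrajectory(
            self.v_states[:n], self.v_ref[:n], self.s[:n], self.frame_index[:n],
            self.labels, self.beta,
        )

    def permuted(self, order: np.ndarray) -> "EnergyTrajectory":
        return EnergyTrajectory(
            self.v_states[order], self.v_ref[order], self.s[order],
            self.frame_index[order], self.labels, self.beta,
        )


@dataclass
class ReplicaState:
    """One replica: its rung on the s-ladder, configuration and RNG stream."""

    replica_id: int
    s: float
    x: np.ndarray
    v_states: np.ndarray  # end-state energies at x
    v_ref: float
    rng: np.random.Generator

    def refresh_energies(self, system: EndStateSystem, offsets: Sequence[float]) -> None:
        self.v_states = system.energies(self.x)
        self.v_ref = float(
            reference_energy_from_states(self.v_states, self.s, offsets, system.conditions.beta)
        )


@dataclass
class ExchangeRecord:
    """Log of exchange attempts and per-walker ladder-position history.

    ``rung_history[p, w]`` is the ladder rung occupied by walker
    (configuration lineage) ``w`` after exchange phase ``p``; row 0 is the
    initial assignment.
    """

    attempts: List[Tuple[int, Tuple[int, int], bool]] = field(default_factory=list)
    rung_history: np.ndarray | None = None

    @property
    def n_phases(self) -> int:
        return 0 if self.rung_history is None else self.rung_history.shape[0] - 1

    def acceptance_rate(self) -> float:
        if not self.attempts:
            return float("nan")
        return sum(1 for *_, acc in self.attempts if acc) / len(self.attempts)


def default_proposal_width(system: EndStateSystem) -> float:
    """0.5 * sqrt(kT / k_max) over all effective (well + restraint) stiffnesses."""
    k_max = max(
        system.effective_harmonics(m)[0].max() for m in range(system.n_states)
    )
    return 0.5 * math.sqrt(system.conditions.kt / k_max)


def _new_replica(
    replica_id: int, s: float, system: EndStateSystem, offsets, rng: np.random.Generator
) -> ReplicaState:
    x = np.array([site.restraint.center for site in system.sites], dtype=float)
    r = ReplicaState(replica_id, s, x, np.empty(system.n_states), 0.0, rng)
    r.refresh_energies(system, offsets)
    return r


def propagate(
    replica: ReplicaState,
    system: EndStateSystem,
    offsets: Sequence[float],
    n_steps: int,
    proposal_width: float,
    stride: int = 1,
    seed: int | None = None,
) -> Tuple[ReplicaState, EnergyTrajectory]:
    """Metropolis random walk on V_R at the replica's s value.

    One frame (all end-state energies plus V_R) is recorded every ``stride``
    steps. Bitwise reproducible from the replica's RNG stream (or ``seed``
    if given, which reseeds the stream).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if proposal_width <= 0:
        raise ValueError("proposal_width must be > 0")
    if seed is not None:
        replica.rng = np.random.default_rng(seed)
    rng = replica.rng
    beta = system.conditions.beta
    E = np.asarray(offsets, dtype=float)
    n_sites = system.n_sites
    bs = beta * replica.s

    def _vr(v: np.ndarray) -> float:
        a = -bs * (v - E)
        m = a.max()
        return float(-(m + math.log(np.exp(a - m).sum())) / bs)

    x = replica.x.copy()
    v_states = system.energies(x)
    v_ref = _vr(v_states)

    n_rec = n_steps // stride
    rec_v = np.empty((n_rec, system.n_states))
    rec_r = np.empty(n_rec)
    rec = 0
    sites = rng.integers(0, n_sites, size=n_steps)
    deltas = rng.normal(0.0, proposal_width, size=n_steps)
    log_us = np.log(rng.random(size=n_steps))
    for step in range(n_steps):
        i = sites[step]
        old = x[i]
        x[i] = old + deltas[step]
        v_new = system.energies(x)
        if not np.all(np.isfinite(v_new)):
            raise FloatingPointError(f"non-finite energy at configuration {x!r}")
        vr_new = _vr(v_new)
        if log_us[step] < -beta * (vr_new - v_ref):
            v_states, v_ref = v_new, vr_new
        else:
            x[i] = old
        if (step + 1) % stride == 0:
            rec_v[rec] = v_states
            rec_r[rec] = v_ref
            rec += 1
    replica.x = x
    replica.v_states = v_states
    replica.v_ref = v_ref
    traj = EnergyTrajectory(
        rec_v[:rec],
        rec_r[:rec],
        np.full(rec, replica.s),
        np.arange(rec),
        system.labels,
        beta,
    )
    return replica, traj


def attempt_exchange(
    r_m: ReplicaState,
    r_n: ReplicaState,
    system: EndStateSystem,
    params: EDSParameters,
    rng: np.random.Generator,
) -> bool:
    """Metropolis exchange of configurations between adjacent s-rungs.

    Acceptance probability
    ``min{1, exp(-beta [V_R(s_m;x_n)+V_R(s_n;x_m)-V_R(s_m;x_m)-V_R(s_n;x_n)])}``.
    One uniform variate is consumed whether or not the swap is accepted.
    """
    ladder = params.s_ladder
    i_m, i_n = ladder.index(r_m.s), ladder.index(r_n.s)
    if abs(i_m - i_n) != 1:
        raise ValueError(f"replicas at rungs {i_m} and {i_n} are not adjacent")
    beta = system.conditions.beta
    E = params.offsets
    cross_mn = reference_energy_from_states(r_n.v_states, r_m.s, E, beta)
    cross_nm = reference_energy_from_states(r_m.v_states, r_n.s, E, beta)
    exponent = beta * (cross_mn + cross_nm - r_m.v_ref - r_n.v_ref)
    accept = math.log(rng.random()) < -exponent
    if accept:
        r_m.x, r_n.x = r_n.x, r_m.x
        r_m.v_states, r_n.v_states = r_n.v_states, r_m.v_states
        r_m.v_ref, r_n.v_ref = float(cross_mn), float(cross_nm)
    return accept


def run_re_eds(
    system: EndStateSystem,
    params: EDSParameters,
    n_phases: int,
    steps_per_phase: int,
    stride: int = 1,
    seed: int = 0,
    proposal_width: float | None = None,
) -> Tuple[Dict[float, EnergyTrajectory], ExchangeRecord]:
    """Alternate Metropolis propagation and neighbor-exchange sweeps.

    Even phases attempt the even neighbor pairs (0-1, 2-3, ...), odd phases
    the odd pairs, the standard deterministic ergodic schedule. Returns one
    trajectory per s-rung, keyed by s; the s = 1.0 entry is the estimation
    ensemble.
    """
    if n_phases < 1 or steps_per_phase < 1 or stride < 1:
        raise ValueError("schedule values must be positive")
    if proposal_width is None:
        proposal_width = default_proposal_width(system)
    n_rep = params.n_replicas
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(n_rep + 1)
    exch_rng = np.random.default_rng(streams[-1])
    replicas = [
        _new_replica(r, params.s_ladder[r], system, params.offsets,
                     np.random.default_rng(streams[r]))
        for r in range(n_rep)
    ]
    # walker w starts on rung w; swapping configurations moves walkers
    walker_of_rung = np.arange(n_rep)
    rung_history = np.empty((n_phases + 1, n_rep), dtype=int)
    rung_history[0] = np.arange(n_rep)

    parts: List[List[EnergyTrajectory]] = [[] for _ in range(n_rep)]
    record = ExchangeRecord()
    for phase in range(n_phases):
        for r, rep in enumerate(replicas):
            try:
                _, traj = propagate(rep, system, params.offsets, steps_per_phase,
                                    proposal_width, stride)
            except Exception as exc:  # annotate with replica context
                raise RuntimeError(
                    f"replica {r} (s={rep.s:g}) failed in phase {phase}"
                ) from exc
            parts[r].append(traj)
        if n_rep > 1:
            start = 0 if phase % 2 == 0 else 1
            for lo in range(start, n_rep - 1, 2):
                accepted = attempt_exchange(replicas[lo], replicas[lo + 1], system,
                                            params, exch_rng)
                record.attempts.append((phase, (lo, lo + 1), accepted))
                if accepted:
                    walker_of_rung[[lo, lo + 1]] = walker_of_rung[[lo + 1, lo]]
        for rung in range(n_rep):
            rung_history[phase + 1, walker_of_rung[rung]] = rung
    record.rung_history = rung_history

    out: Dict[float, EnergyTrajectory] = {}
    for r in range(n_rep):
        chunks = parts[r]
        out[params.s_ladder[r]] = EnergyTrajectory(
            np.concatenate([c.v_states for c in chunks]),
            np.concatenate([c.v_ref for c in chunks]),
            np.concatenate([c.s for c in chunks]),
            np.arange(sum(c.n_frames for c in chunks)),
            system.labels,
            system.conditions.beta,
        )
    return out, record


def roundtrip_stats(record: ExchangeRecord) -> Tuple[np.ndarray, float]:
    """Completed s-ladder roundtrips per walker and the mean roundtrip time.

    A roundtrip is a walker's traversal from one end of the ladder to the
    other and back (top-bottom-top or bottom-top-bottom), measured in
    exchange phases. With zero completed trips the mean is NaN.
    """
    if record.rung_history is None:
        raise ValueError("record holds no ladder-position history")
    hist = record.rung_history
    n_phases, n_walkers = hist.shape[0] - 1, hist.shape[1]
    top, bottom = 0, int(hist.max())
    counts = np.zeros(n_walkers, dtype=int)
    durations: List[int] = []
    for w in range(n_walkers):
        series = hist[:, w]
        # times at which the walker reaches the extreme opposite to the one
        # last visited; two consecutive alternations close one roundtrip,
        # disjoint trips sharing their endpoint (additive under history
        # concatenation)
        last_extreme = None
        alternation_times: List[int] = []
        for t, rung in enumerate(series):
            if rung not in (top, bottom) or (top == bottom):
                continue
            if last_extreme is None:
                alternation_times.append(t)
                last_extreme = rung
            elif rung != last_extreme:
                alternation_times.append(t)
                last_extreme = rung
        for k in range(2, len(alternation_times), 2):
            counts[w] += 1
            durations.append(alternation_times[k] - alternation_times[k - 2])
    mean_time = float(np.mean(durations)) if durations else float("nan")
    return counts, mean_time


# ---------------------------------------------------------------------------
# CSV round-trip (the re-analysis entry point)
# ---------------------------------------------------------------------------


def trajectory_to_csv(traj: EnergyTrajectory, path: str, seed: int | None = None) -> None:
    """Write ``frame, s, V_R, V_state_<label>...`` with a units header line."""
    df = pd.DataFrame({"frame": traj.frame_index, "s": traj.s, "V_R": traj.v_ref})
    for j, lab in enumerate(traj.labels):
        df[f"V_state_{lab}"] = traj.v_states[:, j]
    with open(path, "w") as fh:
        meta = f"# units: kJ/mol; beta: {traj.beta!r} mol/kJ"
        if seed is not None:
            meta += f"; seed: {seed}"
        fh.write(meta + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def trajectory_from_csv(path: str) -> EnergyTrajectory:
    """Read a trajectory written by :func:`trajectory_to_csv`."""
    beta = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "beta:" in first:
        beta = float(first.split("beta:")[1].split(";")[0].split()[0])
    df = pd.read_csv(path, comment="#")
    required = {"frame", "s", "V_R"}
    state_cols = [c for c in df.columns if c.startswith("V_state_")]
    missing = sorted(required - set(df.columns))
    if missing or not state_cols:
        raise ValueError(
            f"trajectory CSV schema mismatch; missing columns: {missing or ['V_state_*']}"
        )
    labels = [c[len("V_state_"):] for c in state_cols]
    if beta is None:
        raise ValueError("trajectory CSV lacks the beta metadata header")
    return EnergyTrajectory(
        df[state_cols].to_numpy(float),
        df["V_R"].to_numpy(float),
        df["s"].to_numpy(float),
        df["frame"].to_numpy(int),
        labels,
        beta,
    )
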