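"""Free-energy estimation from the physical s = 1 ensemble, with oracles.

The multistate estimate applies Zwanzig's perturbation formula twice: once
from the reference state to each end state,

    g_i = -kT ln < exp(-beta (V_i - V_R)) >_R,

and then between end states, dG_ji = g_j - g_i. Because every matrix entry
derives from the per-state scalars g_i, antisymmetry and cycle closure hold
exactly by construction. Uncertainties on a single trajectory come from a
circular block bootstrap whose block length tracks the integrated
autocorrelation time of the reference-energy series; replicate spread is
summarized separately.

A deterministic thermodynamic-integration oracle (linear mixing, trapezoid
over an even lambda grid, configurational averages by quadrature) provides
an independent route to the same differences on small systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .eds_core import EDSParameters
from .sampler import EnergyTrajectory
from .states import NetworkState
from .toy_model import EndStateSystem, _quad_grid

__all__ = [
    "FreeEnergyMatrix",
    "ReplicateSummary",
    "EstimationError",
    "zwanzig_twice",
    "ti_reference",
    "convergence_series",
    "combine_replicates",
    "combine_matrices",
    "propagate_error",
]


class EstimationError(RuntimeError):
    pass


@dataclass
class FreeEnergyMatrix:
    """Pairwise dG_ji (kJ/mol) over all end states of one environment.

    Built from per-state free energies ``g`` so that ``dG_ji = -dG_ij`` and
    ``dG_ki = dG_kj + dG_ji`` hold exactly.
    """

    labels: List[str]
    g: np.ndarray  # per-state free energies, arbitrary common origin
    sd: np.ndarray  # (n, n) per-pair standard deviation
    environment_tag: str = "pocket"
    n_frames: int = 0

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        n = len(self.labels)
        if self.g.shape != (n,) or self.sd.shape != (n, n):
            raise ValueError("inconsistent matrix dimensions")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    @property
    def delta(self) -> np.ndarray:
        """Matrix with entry [j, i] = dG_ji = g_j - g_i."""
        return self.g[:, None] - self.g[None, :]

    def _idx(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"state {label!r} not in matrix") from None

    def dg(self, from_label: str, to_label: str) -> float:
        """dG of transforming ``from_label`` into ``to_label``."""
        return float(self.g[self._idx(to_label)] - self.g[self._idx(from_label)])

    def dg_sd(self, from_label: str, to_label: str) -> float:
        return float(self.sd[self._idx(to_label), self._idx(from_label)])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, li in enumerate(self.labels):
            for j, lj in enumerate(self.labels):
                if i == j:
                    continue
                rows.append(
                    {
                        "state_from": li,
                        "state_to": lj,
                        "dG": self.g[j] - self.g[i],
                        "sd": self.sd[j, i],
                        "n_frames": self.n_frames,
                        "environment": self.environment_tag,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str, seed: int | None = None) -> None:
        with open(path, "w") as fh:
            meta = "# units: kJ/mol"
            if seed is not None:
                meta += f"; seed: {seed}"
            fh.write(meta + "\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str) -> "FreeEnergyMatrix":
        """Rebuild a matrix from the long-format CSV written by :meth:`to_csv`."""
        df = pd.read_csv(path, comment="#")
        required = {"state_from", "state_to", "dG", "sd", "n_frames", "environment"}
        missing = sorted(required - set(df.columns))
        if missing:
            raise ValueError(f"matrix CSV schema mismatch; missing columns: {missing}")
        labels = list(dict.fromkeys(df["state_from"]))
        n = len(labels)
        idx = {lab: k for k, lab in enumerate(labels)}
        g = np.zeros(n)
        sd = np.zeros((n, n))
        origin = labels[0]
        for row in df.itertuples(index=False):
            j, i = idx[row.state_to], idx[row.state_from]
            sd[j, i] = row.sd
            if row.state_from == origin:
                g[j] = row.dG
        return cls(labels, g, sd, str(df["environment"].iloc[0]), int(df["n_frames"].iloc[0]))


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean and sample standard deviation over replicate runs."""

    values: Tuple[float, ...]
    mean: float
    sd: float
    degenerate: bool  # single replicate: sd is 0 by convention


def propagate_error(sd_pocket: float, sd_bulk: float) -> float:
    """Quadrature combination sqrt(sd_pocket^2 + sd_bulk^2)."""
    if sd_pocket < 0 or sd_bulk < 0:
        raise ValueError("standard deviations must be >= 0")
    return math.hypot(sd_pocket, sd_bulk)


def combine_replicates(values: Sequence[float]) -> ReplicateSummary:
    """Arithmetic mean and n-1 standard deviation of replicate values."""
    vals = tuple(float(v) for v in values)
    if not vals:
        raise ValueError("need at least one replicate value")
    mean = float(np.mean(vals))
    if len(vals) == 1:
        return ReplicateSummary(vals, mean, 0.0, True)
    return ReplicateSummary(vals, mean, float(np.std(vals, ddof=1)), False)


# ---------------------------------------------------------------------------
# Zwanzig twice
# ---------------------------------------------------------------------------


def _log_mean_exp(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return logsumexp(a, axis=axis) - math.log(a.shape[axis])


def _g_from_frames(v_states: np.ndarray, v_ref: np.ndarray, beta: float) -> np.ndarray:
    expo = -beta * (v_states - v_ref[:, None])
    return -_log_mean_exp(expo, axis=0) / beta


def _autocorr_time(series: np.ndarray, max_lag: int | None = None) -> float:
    """Integrated autocorrelation time with a standard adaptive cutoff."""
    x = np.asarray(series, float)
    n = x.size
    if n < 8 or np.allclose(x, x[0]):
        return 1.0
    x = x - x.mean()
    if max_lag is None:
        max_lag = min(n // 4, 1000)
    var = float(np.dot(x, x) / n)
    tau = 1.0
    for lag in range(1, max_lag):
        c = float(np.dot(x[:-lag], x[lag:]) / n) / var
        if c < 0.05:
            break
        tau += 2.0 * c
    return max(tau, 1.0)


def zwanzig_twice(
    traj: EnergyTrajectory,
    params: EDSParameters,
    environment_tag: str = "pocket",
    n_boot: int = 200,
    boot_seed: int = 2024,
) -> FreeEnergyMatrix:
    """Double-Zwanzig free-energy matrix from an s = 1 trajectory.

    Frames from s < 1 rungs are rejected: only the physical replica defines
    the estimation ensemble. Raises :class:`EstimationError` when an end
    state never contributes to the reference average (its exponent
    underflows on every frame), which indicates the offsets need
    rebalancing.
    """
    if traj.n_frames == 0:
        raise EstimationError("empty trajectory")
    if not np.allclose(traj.s, 1.0):
        raise EstimationError("estimation requires frames from the physical s = 1 replica")
    beta = traj.beta
    expo = -beta * (traj.v_states - traj.v_ref[:, None])
    max_expo = expo.max(axis=0)
    dead = np.where(max_expo < -700.0)[0]
    if dead.size:
        names = ", ".join(traj.labels[k] for k in dead)
        raise EstimationError(
            f"state(s) {names} never contribute to the reference ensemble "
            "(exponent underflow on every frame); rebalance the energy offsets"
        )
    g = _g_from_frames(traj.v_states, traj.v_ref, beta)

    # circular block bootstrap over frames
    n = traj.n_frames
    block = max(1, math.ceil(2.0 * _autocorr_time(traj.v_ref)))
    n_blocks = math.ceil(n / block)
    rng = np.random.default_rng(boot_seed)
    n_states = len(traj.labels)
    g_boot = np.empty((n_boot, n_states))
    idx_base = np.arange(block)
    for b in range(n_boot):
        starts = rng.integers(0, n, size=n_blocks)
        idx = (starts[:, None] + idx_base[None, :]).ravel()[:n] % n
        g_boot[b] = _g_from_frames(traj.v_states[idx], traj.v_ref[idx], beta)
    sd = np.empty((n_states, n_states))
    for i in range(n_states):
        for j in range(n_states):
            sd[j, i] = np.std(g_boot[:, j] - g_boot[:, i], ddof=1) if i != j else 0.0
    return FreeEnergyMatrix(list(traj.labels), g, sd, environment_tag, n)


def convergence_series(
    traj: EnergyTrajectory, params: EDSParameters, n_blocks: int, **kwargs
) -> List[Tuple[int, FreeEnergyMatrix]]:
    """Estimates on growing trajectory prefixes (1/n, 2/n, ..., all frames).

    The final entry is the full-trajectory estimate computed by the
    identical code path.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    n = traj.n_frames
    out = []
    for b in range(1, n_blocks + 1):
        m = (n * b) // n_blocks
        if m == 0:
            raise EstimationError(f"prefix {b}/{n_blocks} contains zero frames")
        out.append((m, zwanzig_twice(traj.prefix(m), params, **kwargs)))
    return out


def combine_matrices(matrices: Sequence[FreeEnergyMatrix]) -> FreeEnergyMatrix:
    """Replicate-combined matrix: mean per-state g, per-pair n-1 sd of dG.

    Averaging the per-state scalars preserves exact antisymmetry and cycle
    closure of the combined matrix.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels:
            raise ValueError("replicate matrices must share state labels")
    g_stack = np.stack([m.g - m.g[0] for m in matrices])  # common origin
    g_mean = g_stack.mean(axis=0)
    n = len(labels)
    sd = np.zeros((n, n))
    if len(matrices) > 1:
        for i in range(n):
            for j in range(n):
                if i != j:
                    sd[j, i] = np.std(g_stack[:, j] - g_stack[:, i], ddof=1)
    return FreeEnergyMatrix(
        list(labels), g_mean, sd, matrices[0].environment_tag,
        sum(m.n_frames for m in matrices),
    )


# ---------------------------------------------------------------------------
# TI oracle
# ---------------------------------------------------------------------------


def ti_reference(
    system: EndStateSystem,
    state_i: NetworkState,
    state_j: NetworkState,
    n_lambda: int = 11,
    n_nodes: int = 40,
) -> float:
    """Thermodynamic-integration oracle dG_ji (kJ/mol).

    Mixes the end states linearly, V_lambda = (1-lambda) V_i + lambda V_j
    (no soft-core: the toy potentials are bounded), and integrates the
    quadrature average < V_j - V_i >_lambda over an even lambda grid by the
    trapezoid rule. Discretization error shrinks with ``n_lambda``.
    """
    if system.n_sites > 4:
        raise ValueError("quadrature supports at most 4 sites")
    if n_lambda < 2:
        raise ValueError("need at least 2 lambda windows")
    beta = system.conditions.beta
    mi, mj = system.state_index(state_i), system.state_index(state_j)
    ki, ci, _ = system.effective_harmonics(mi)
    kj, cj, _ = system.effective_harmonics(mj)
    lambdas = np.linspace(0.0, 1.0, n_lambda)
    dvdl = np.empty(n_lambda)
    for w, lam in enumerate(lambdas):
        k_mix = (1 - lam) * ki + lam * kj
        c_mix = ((1 - lam) * ki * ci + lam * kj * cj) / k_mix
        X, lw = _quad_grid(system, k_mix, c_mix, n_nodes)
        v_all = system.energies(X)
        vi_full, vj_full = v_all[:, mi], v_all[:, mj]
        # residual beyond the Gaussian base: mixed quadratic remainder + couplings
        harm_i = vi_full - system.coupling_energy(X, mi)
        harm_j = vj_full - system.coupling_energy(X, mj)
        harm_mix = (1 - lam) * harm_i + lam * harm_j
        base = (0.5 * k_mix * (X - c_mix) ** 2).sum(axis=1)
        w_coup = (1 - lam) * system.coupling_energy(X, mi) + lam * system.coupling_energy(X, mj)
        log_wt = lw - beta * (harm_mix - base + w_coup)
        log_norm = logsumexp(log_wt)
        wt = np.exp(log_wt - log_norm)
        dvdl[w] = float(np.dot(wt, vj_full - vi_full))
    return float(np.trapezoid(dvdl, lambdas))
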