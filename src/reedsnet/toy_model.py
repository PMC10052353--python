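"""Desk-scale alchemical site-network systems with exact free-energy references.

Each hydration site is a one-dimensional coordinate in a harmonic well whose
parameters depend on the site's character (water or apolar probe) in the
current end state, plus a character-independent position restraint. Pairs of
sites may interact through bounded Gaussian coupling wells, the stand-in for
the hydrogen-bond-network stabilization whose thermodynamic signature the
replacement free energies probe. Because every potential is a sum of
quadratics and bounded smooth terms, partition functions are computable to
high accuracy by Gauss-Hermite quadrature for up to four sites, giving an
exact oracle against which the stochastic RE-EDS machinery is validated.

Units: kJ/mol for energies, nm for lengths, K for temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import yaml
from numpy.polynomial.hermite import hermgauss
from scipy.special import logsumexp

from .states import NetworkState, enumerate_states

KB = 0.008314462618  # kJ/mol/K

__all__ = [
    "KB",
    "Well",
    "SiteSpec",
    "CouplingSpec",
    "ThermoConditions",
    "EndStateSystem",
    "state_potential",
    "exact_free_energy",
    "make_benchmark_suite",
    "BenchmarkPair",
    "load_system",
    "save_system",
    "QuadratureError",
]


class QuadratureError(RuntimeError):
    """Raised when the partition-function quadrature fails its self-check."""


@dataclass(frozen=True)
class Well:
    """Harmonic well ``0.5 * k * (x - center)**2``."""

    center: float
    force_constant: float

    def __post_init__(self) -> None:
        if self.force_constant <= 0:
            raise ValueError("force constant must be > 0")

    def energy(self, x: np.ndarray | float) -> np.ndarray | float:
        return 0.5 * self.force_constant * (np.asarray(x) - self.center) ** 2


@dataclass(frozen=True)
class SiteSpec:
    """One hydration site: water well, probe well, and position restraint.

    The probe differs from the water only through its well (center and/or
    force constant); it carries no charge term, mimicking a single uncharged
    particle standing in for a methyl substituent.
    """

    site_id: int
    water_well: Well
    probe_well: Well
    restraint: Well

    def __post_init__(self) -> None:
        if self.site_id < 1:
            raise ValueError("site_id must be >= 1")


@dataclass(frozen=True)
class CouplingSpec:
    """Gaussian coupling well between two sites.

    ``-strength * exp(-(x_a - x_b)**2 / (2 width**2))`` is added whenever
    both sites host the character the channel names (water-water by default;
    water-probe applies for either orientation).
    """

    site_pair: Tuple[int, int]
    water_water: Tuple[float, float] = (0.0, 1.0)  # (strength, width)
    water_probe: Tuple[float, float] = (0.0, 1.0)
    probe_probe: Tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        a, b = self.site_pair
        if a == b:
            raise ValueError("coupling pair members must be distinct")
        object.__setattr__(self, "site_pair", (min(a, b), max(a, b)))
        for name in ("water_water", "water_probe", "probe_probe"):
            strength, width = getattr(self, name)
            if width <= 0:
                raise ValueError(f"{name} width must be > 0")


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature and the derived inverse thermal energy beta = 1/(kB*T)."""

    temperature: float = 298.15
    boltzmann_constant: float = KB

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def kt(self) -> float:
        return self.boltzmann_constant * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kt


class EndStateSystem:
    """A site network with its full set of end states and evaluable potentials.

    Parameters
    ----------
    sites
        Site specifications; ids must be unique.
    couplings
        At most one :class:`CouplingSpec` per site pair.
    conditions
        Thermodynamic conditions (temperature).
    environment_tag
        ``"pocket"`` or ``"bulk"``. By convention the bulk partner of a
        pocket system has identical sites and zero couplings, so that the
        thermodynamic cycle isolates the pocket's network-correlation
        effects and the (identical) restraints cancel.
    states
        End states to consider; defaults to all 2**n combinations in
        canonical order.
    """

    def __init__(
        self,
        sites: Sequence[SiteSpec],
        couplings: Sequence[CouplingSpec] = (),
        conditions: ThermoConditions = ThermoConditions(),
        environment_tag: str = "pocket",
        states: Sequence[NetworkState] | None = None,
        name: str = "system",
    ) -> None:
        ids = [s.site_id for s in sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site ids must be unique")
        if environment_tag not in ("pocket", "bulk"):
            raise ValueError("environment_tag must be 'pocket' or 'bulk'")
        pairs = [c.site_pair for c in couplings]
        if len(set(pairs)) != len(pairs):
            raise ValueError("at most one coupling spec per site pair")
        id_set = set(ids)
        for c in couplings:
            if not set(c.site_pair) <= id_set:
                raise ValueError(f"coupling pair {c.site_pair} references unknown site")
        self.sites: List[SiteSpec] = sorted(sites, key=lambda s: s.site_id)
        self.couplings: List[CouplingSpec] = list(couplings)
        self.conditions = conditions
        self.environment_tag = environment_tag
        self.name = name
        if states is None:
            states = enumerate_states(len(ids), site_ids=ids)
        for st in states:
            if not st.probe_sites <= id_set:
                raise ValueError(f"state {st.label} references sites outside the system")
        self.states: List[NetworkState] = list(states)
        self._build_tables()

    # -- internal precomputation -------------------------------------------------

    def _build_tables(self) -> None:
        n_states, n_sites = len(self.states), len(self.sites)
        site_index = {s.site_id: i for i, s in enumerate(self.sites)}
        self._site_index = site_index
        # character wells per (state, site)
        K = np.empty((n_states, n_sites))
        C = np.empty((n_states, n_sites))
        for m, st in enumerate(self.states):
            for i, s in enumerate(self.sites):
                well = s.probe_well if st.has_probe(s.site_id) else s.water_well
                K[m, i] = well.force_constant
                C[m, i] = well.center
        self._k_char, self._c_char = K, C
        self._k_restr = np.array([s.restraint.force_constant for s in self.sites])
        self._c_restr = np.array([s.restraint.center for s in self.sites])
        # couplings: per state, per coupling, the active (strength, 2*width^2)
        n_coup = len(self.couplings)
        eps = np.zeros((n_states, n_coup))
        two_sig2 = np.ones((n_states, n_coup))
        pair_i = np.zeros(n_coup, dtype=int)
        pair_j = np.zeros(n_coup, dtype=int)
        for c_idx, coup in enumerate(self.couplings):
            a, b = coup.site_pair
            pair_i[c_idx], pair_j[c_idx] = site_index[a], site_index[b]
            for m, st in enumerate(self.states):
                pa, pb = st.has_probe(a), st.has_probe(b)
                if not pa and not pb:
                    strength, width = coup.water_water
                elif pa and pb:
                    strength, width = coup.probe_probe
                else:
                    strength, width = coup.water_probe
                eps[m, c_idx] = strength
                two_sig2[m, c_idx] = 2.0 * width * width
        self._eps, self._two_sig2 = eps, two_sig2
        self._pair_i, self._pair_j = pair_i, pair_j

    # -- public surface ----------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> List[str]:
        return [st.label for st in self.states]

    def state_index(self, state: NetworkState) -> int:
        for m, st in enumerate(self.states):
            if st.probe_sites == state.probe_sites:
                return m
        raise KeyError(f"state {state.label} not in system")

    def energies(self, x: np.ndarray) -> np.ndarray:
        """End-state potential energies at one or many configurations.

        ``x`` of shape ``(n_sites,)`` returns ``(n_states,)``; shape
        ``(m, n_sites)`` returns ``(m, n_states)``.
        """
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] != self.n_sites:
            raise ValueError(
                f"configuration has {X.shape[1]} coordinates, expected {self.n_sites}"
            )
        harm = 0.5 * (self._k_char[None, :, :] * (X[:, None, :] - self._c_char[None, :, :]) ** 2).sum(
            axis=2
        )
        restr = (0.5 * self._k_restr * (X - self._c_restr) ** 2).sum(axis=1)
        V = harm + restr[:, None]
        if self.couplings:
            d2 = (X[:, self._pair_i] - X[:, self._pair_j]) ** 2  # (m, n_coup)
            V -= (self._eps[None, :, :] * np.exp(-d2[:, None, :] / self._two_sig2[None, :, :])).sum(
                axis=2
            )
        return V[0] if single else V

    def coupling_energy(self, X: np.ndarray, state_index: int) -> np.ndarray:
        """Coupling part of one state's potential at many configurations."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not self.couplings:
            return np.zeros(X.shape[0])
        d2 = (X[:, self._pair_i] - X[:, self._pair_j]) ** 2
        return -(self._eps[state_index] * np.exp(-d2 / self._two_sig2[state_index])).sum(axis=1)

    def effective_harmonics(self, state_index: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-site (k_eff, c_eff, const) combining character well + restraint.

        ``0.5*k_w*(x-c_w)^2 + 0.5*k_r*(x-c_r)^2 = 0.5*k_eff*(x-c_eff)^2 + const``.
        """
        kw = self._k_char[state_index]
        cw = self._c_char[state_index]
        kr, cr = self._k_restr, self._c_restr
        k_eff = kw + kr
        c_eff = (kw * cw + kr * cr) / k_eff
        const = 0.5 * (kw * cw**2 + kr * cr**2) - 0.5 * k_eff * c_eff**2
        return k_eff, c_eff, const

    def bulk_partner(self) -> "EndStateSystem":
        """Same sites and states, zero couplings, tagged bulk."""
        return EndStateSystem(
            sites=self.sites,
            couplings=(),
            conditions=self.conditions,
            environment_tag="bulk",
            states=self.states,
            name=self.name + "-bulk",
        )


def state_potential(system: EndStateSystem, state: NetworkState, x: np.ndarray) -> float:
    """Potential energy of one end state at configuration ``x`` (kJ/mol)."""
    m = system.state_index(state)
    x = np.asarray(x, dtype=float)
    if x.shape != (system.n_sites,):
        raise ValueError(
            f"configuration has shape {x.shape}, expected ({system.n_sites},)"
        )
    return float(system.energies(x)[m])


# ---------------------------------------------------------------------------
# Exact references by Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

_MAX_QUAD_SITES = 4


def _quad_grid(system: EndStateSystem, k_eff: np.ndarray, c_eff: np.ndarray, n_nodes: int):
    """Tensor-product Gauss-Hermite nodes/log-weights for a Gaussian base."""
    beta = system.conditions.beta
    nodes_1d, w_1d = hermgauss(n_nodes)
    axes, logw = [], []
    for i in range(system.n_sites):
        a = 0.5 * beta * k_eff[i]  # exp(-a (x-c)^2)
        axes.append(c_eff[i] + nodes_1d / math.sqrt(a))
        logw.append(np.log(w_1d) - 0.5 * math.log(a))
    mesh = np.meshgrid(*axes, indexing="ij")
    X = np.stack([m.ravel() for m in mesh], axis=1)
    lw = np.zeros(X.shape[0])
    meshw = np.meshgrid(*logw, indexing="ij")
    for mw in meshw:
        lw += mw.ravel()
    return X, lw


def log_partition(system: EndStateSystem, state: NetworkState, n_nodes: int = 40) -> float:
    """ln Z of one end state by Gauss-Hermite quadrature (sites <= 4)."""
    if system.n_sites > _MAX_QUAD_SITES:
        raise ValueError(
            f"quadrature supports at most {_MAX_QUAD_SITES} sites, system has {system.n_sites}"
        )
    beta = system.conditions.beta
    m = system.state_index(state)
    k_eff, c_eff, const = system.effective_harmonics(m)
    X, lw = _quad_grid(system, k_eff, c_eff, n_nodes)
    w_coup = -beta * system.coupling_energy(X, m)
    return float(logsumexp(lw + w_coup) - beta * const.sum())


def exact_free_energy(
    system: EndStateSystem,
    state_i: NetworkState,
    state_j: NetworkState,
    n_nodes: int = 40,
    check_tol: float = 1e-7,
) -> float:
    """Exact ΔG_ji = -kT ln(Z_j/Z_i) by deterministic quadrature (kJ/mol).

    Self-checks convergence by recomputing on a denser node set; for fully
    uncoupled systems this reduces to the closed-form harmonic ratio
    ``0.5*kT*sum(ln(k_eff,j/k_eff,i))`` plus well-offset terms.
    """
    kt = system.conditions.kt
    lz_i = log_partition(system, state_i, n_nodes)
    lz_j = log_partition(system, state_j, n_nodes)
    dg = -kt * (lz_j - lz_i)
    if system.couplings:
        lz_i2 = log_partition(system, state_i, n_nodes + 16)
        lz_j2 = log_partition(system, state_j, n_nodes + 16)
        dg2 = -kt * (lz_j2 - lz_i2)
        if abs(dg2 - dg) > check_tol * max(1.0, abs(dg)):
            raise QuadratureError(
                f"quadrature not converged: {dg:.9f} vs {dg2:.9f} kJ/mol at "
                f"{n_nodes}/{n_nodes + 16} nodes"
            )
        dg = dg2
    return dg


# ---------------------------------------------------------------------------
# Benchmark suite
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkPair:
    """A pocket system together with its coupling-free bulk partner."""

    name: str
    pocket: EndStateSystem
    bulk: EndStateSystem
    seed: int = 0


# Fixed benchmark conditions (kJ/mol, nm): water well k=25 at 0, probe well
# k=100 at 0.3 nm, restraint k=10 at 0; coupled benchmark implants one
# water-water Gaussian well eps=4.0, sigma=0.3 between sites 1-2. The probe
# well is displaced enough that end-state basins are distinct (dominance
# cells track basins, keeping offset rebalancing contractive) yet close
# enough that the s=1 reference still mixes.
_WATER = Well(0.0, 25.0)
_PROBE = Well(0.3, 100.0)
_RESTRAINT = Well(0.0, 10.0)
COUPLED_EPS = 4.0
COUPLED_SIGMA = 0.3


def _uniform_sites(n: int) -> List[SiteSpec]:
    return [SiteSpec(i, _WATER, _PROBE, _RESTRAINT) for i in range(1, n + 1)]


def make_benchmark_suite(seed: int = 0) -> List[BenchmarkPair]:
    """The named benchmark systems used throughout the test battery.

    Returns pocket/bulk pairs for: ``uncoupled-3site`` (symmetric, zero
    expected correlation), ``coupled-3site`` (one implanted water-water
    coupling, known nonadditivity), ``chain-5site`` (32 states, scale
    tests). Parameters are fixed study conditions; ``seed`` is recorded on
    each pair for provenance.
    """
    cond = ThermoConditions()
    out: List[BenchmarkPair] = []

    pocket_a = EndStateSystem(_uniform_sites(3), (), cond, "pocket", name="uncoupled-3site")
    out.append(BenchmarkPair("uncoupled-3site", pocket_a, pocket_a.bulk_partner(), seed))

    coup_b = CouplingSpec((1, 2), water_water=(COUPLED_EPS, COUPLED_SIGMA))
    pocket_b = EndStateSystem(_uniform_sites(3), (coup_b,), cond, "pocket", name="coupled-3site")
    out.append(BenchmarkPair("coupled-3site", pocket_b, pocket_b.bulk_partner(), seed))

    chain = [
        CouplingSpec((i, i + 1), water_water=(2.0, COUPLED_SIGMA)) for i in range(1, 5)
    ]
    pocket_c = EndStateSystem(_uniform_sites(5), chain, cond, "pocket", name="chain-5site")
    out.append(BenchmarkPair("chain-5site", pocket_c, pocket_c.bulk_partner(), seed))
    return out


def get_benchmark(name: str, seed: int = 0) -> BenchmarkPair:
    for pair in make_benchmark_suite(seed):
        if pair.name == name:
            return pair
    raise KeyError(f"unknown benchmark {name!r}")


# ---------------------------------------------------------------------------
# YAML system specification
# ---------------------------------------------------------------------------


def _well_to_dict(w: Well) -> Dict[str, float]:
    return {"center": float(w.center), "force_constant": float(w.force_constant)}


def save_system(system: EndStateSystem, path: str) -> None:
    """Write a system specification file (YAML)."""
    doc: Dict = {
        "name": system.name,
        "environment": system.environment_tag,
        "temperature": float(system.conditions.temperature),
        "sites": [
            {
                "id": s.site_id,
                "water": _well_to_dict(s.water_well),
                "probe": _well_to_dict(s.probe_well),
                "restraint": _well_to_dict(s.restraint),
            }
            for s in system.sites
        ],
        "couplings": [
            {
                "pair": list(c.site_pair),
                "water_water": {"strength": c.water_water[0], "width": c.water_water[1]},
                "water_probe": {"strength": c.water_probe[0], "width": c.water_probe[1]},
                "probe_probe": {"strength": c.probe_probe[0], "width": c.probe_probe[1]},
            }
            for c in system.couplings
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _well_from_dict(d: Dict) -> Well:
    return Well(float(d["center"]), float(d["force_constant"]))


def load_system(path: str) -> EndStateSystem:
    """Read a system specification file (YAML schema of :func:`save_system`)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    sites = [
        SiteSpec(
            int(s["id"]),
            _well_from_dict(s["water"]),
            _well_from_dict(s["probe"]),
            _well_from_dict(s["restraint"]),
        )
        for s in doc["sites"]
    ]
    couplings = []
    for c in doc.get("couplings") or []:
        kwargs = {}
        for chan in ("water_water", "water_probe", "probe_probe"):
            if chan in c:
                kwargs[chan] = (float(c[chan]["strength"]), float(c[chan]["width"]))
        couplings.append(CouplingSpec(tuple(int(v) for v in c["pair"]), **kwargs))
    return EndStateSystem(
        sites,
        couplings,
        ThermoConditions(float(doc.get("temperature", 298.15))),
        doc.get("environment", "pocket"),
        name=doc.get("name", "system"),
    )
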