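"""Thermodynamic-cycle combination and water-network analyses.

Combining the pocket and bulk free-energy matrices through the
thermodynamic cycle gives the replacement free energy of each perturbation,

    ddG_replacement(j,i) = dG_ji(pocket) - dG_ji(bulk),

the binding free energy of the apolar probe(s) to the perturbed hydration
sites. On top of the replacement matrix this module computes the headline
network analyses: conditional (environment-dependent) replacements,
additivity gaps between summed single-site and simultaneous multi-site
replacements, the solvation-correlation graph whose edges carry
dddG_replacement, Spearman rank comparison of replacement profiles, and
the pairwise simulation-cost accounting model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimators import FreeEnergyMatrix, propagate_error
from .states import NetworkState, count_unique_pairs, enumerate_states, parse_label

__all__ = [
    "NetworkState",
    "enumerate_states",
    "count_unique_pairs",
    "parse_label",
    "ReplacementMatrix",
    "CorrelationEdge",
    "CostProtocol",
    "replacement_matrix",
    "conditional_replacement",
    "additivity_gap",
    "gap_from_totals",
    "correlation_graph",
    "correlation_to_networkx",
    "rank_by_spearman",
    "cost_model",
    "cumulative_time",
    "CONFIDENCE_LIMIT",
]

# Entries whose replicate standard deviation exceeds this are flagged
# low-confidence in outputs (kJ/mol).
CONFIDENCE_LIMIT = 2.5


@dataclass
class ReplacementMatrix:
    """Antisymmetric ddG_replacement over all ordered state pairs (kJ/mol)."""

    labels: List[str]
    ddg: np.ndarray  # [j, i] = ddG of i -> j
    sd: np.ndarray
    pocket_id: str = "pocket"
    bulk_id: str = "bulk"
    confidence_limit: float = CONFIDENCE_LIMIT

    def __post_init__(self) -> None:
        self.ddg = np.asarray(self.ddg, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        n = len(self.labels)
        if self.ddg.shape != (n, n) or self.sd.shape != (n, n):
            raise ValueError("inconsistent matrix dimensions")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def _idx(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"state {label!r} not in matrix") from None

    def value(self, from_label: str, to_label: str) -> float:
        return float(self.ddg[self._idx(to_label), self._idx(from_label)])

    def value_sd(self, from_label: str, to_label: str) -> float:
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
                        "ddG": self.ddg[j, i],
                        "sd": self.sd[j, i],
                        "low_confidence": bool(self.sd[j, i] > self.confidence_limit),
                        "pocket": self.pocket_id,
                        "bulk": self.bulk_id,
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


@dataclass(frozen=True)
class CorrelationEdge:
    """Solvation-correlation edge between two hydration sites.

    ``delta_ab`` is the change in ddG of replacing site a caused by site b
    already being replaced (and ``delta_ba`` the reverse); ``delta`` is the
    symmetrized mean. Negative delta means prior replacement of one site
    makes replacing the other more favorable: positive solvation
    correlation (the blue edges of the correlation graph); positive delta
    is a negative correlation.
    """

    site_pair: Tuple[int, int]
    delta_ab: float
    delta_ba: float
    sd_ab: float = 0.0
    sd_ba: float = 0.0

    @property
    def delta(self) -> float:
        return 0.5 * (self.delta_ab + self.delta_ba)

    @property
    def sd(self) -> float:
        return 0.5 * math.hypot(self.sd_ab, self.sd_ba)

    @property
    def sign_class(self) -> str:
        if self.delta < 0:
            return "positive-cooperative"
        if self.delta > 0:
            return "negative-cooperative"
        return "neutral"

    def significant(self, n_sigma: float = 3.0) -> bool:
        return self.sd > 0 and abs(self.delta) > n_sigma * self.sd


@dataclass(frozen=True)
class CostProtocol:
    """Accounting inputs for the pairwise (TI-style) simulation-cost model."""

    n_states: int
    n_lambda_windows: int
    protein_ns_per_window: float
    solution_ns_per_window: float
    pairwise_mode: str = "minimal"  # minimal (N-1) or all-pairs

    def __post_init__(self) -> None:
        if self.n_states < 1 or self.n_lambda_windows < 1:
            raise ValueError("n_states and n_lambda_windows must be positive")
        if self.protein_ns_per_window <= 0 or self.solution_ns_per_window <= 0:
            raise ValueError("per-window times must be positive")
        if self.pairwise_mode not in ("minimal", "all-pairs"):
            raise ValueError("pairwise_mode must be 'minimal' or 'all-pairs'")


def replacement_matrix(pocket: FreeEnergyMatrix, bulk: FreeEnergyMatrix) -> ReplacementMatrix:
    """Thermodynamic-cycle combination of pocket and bulk matrices."""
    if pocket.labels != bulk.labels:
        diff = sorted(set(pocket.labels) ^ set(bulk.labels))
        raise ValueError(f"pocket/bulk state sets differ: {diff}")
    n = pocket.n_states
    sd = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                sd[j, i] = propagate_error(pocket.sd[j, i], bulk.sd[j, i])
    return ReplacementMatrix(
        list(pocket.labels),
        pocket.delta - bulk.delta,
        sd,
        pocket.environment_tag,
        bulk.environment_tag,
    )


def _label(context: Iterable[int]) -> str:
    return NetworkState(frozenset(context)).label


def conditional_replacement(
    matrix: ReplacementMatrix, site: int, context: Set[int] | Iterable[int] = ()
) -> Tuple[float, float]:
    """ddG (and sd) of replacing ``site`` given ``context`` already replaced."""
    context = set(context)
    if site in context:
        raise ValueError(f"site {site} already replaced in context {sorted(context)}")
    frm, to = _label(context), _label(context | {site})
    return matrix.value(frm, to), matrix.value_sd(frm, to)


def additivity_gap(
    matrix: ReplacementMatrix, subset: Set[int] | Iterable[int]
) -> Tuple[Tuple[float, float], Tuple[float, float], Tuple[float, float]]:
    """Sum-of-singles vs concomitant replacement of ``subset``.

    Returns ``((sum_of_singles, sd), (concomitant, sd), (gap, sd))`` with
    gap = sum_of_singles - concomitant; a positive gap means simultaneous
    replacement is cheaper than the additive estimate from the apo pocket,
    the signature of cooperative solvation.
    """
    subset = sorted(set(subset))
    if len(subset) < 2:
        raise ValueError("subset must contain at least two sites")
    singles = [conditional_replacement(matrix, s, set()) for s in subset]
    sum_singles = float(sum(v for v, _ in singles))
    sd_sum = math.sqrt(sum(sd**2 for _, sd in singles))
    concomitant = matrix.value("apo", _label(subset))
    sd_con = matrix.value_sd("apo", _label(subset))
    gap = sum_singles - concomitant
    return (sum_singles, sd_sum), (concomitant, sd_con), (gap, math.hypot(sd_sum, sd_con))


def gap_from_totals(
    sum_of_singles: float, sd_sum: float, concomitant: float, sd_concomitant: float
) -> Tuple[float, float]:
    """Additivity gap from tabulated totals (e.g. published summary tables)."""
    return sum_of_singles - concomitant, propagate_error(sd_sum, sd_concomitant)


def correlation_graph(matrix: ReplacementMatrix, site_ids: Sequence[int] | None = None
                      ) -> List[CorrelationEdge]:
    """Pairwise solvation-correlation edges dddG_replacement.

    For each ordered site pair (a, b):
    ``delta(a|b) = conditional(a, {b}) - conditional(a, {})``; the edge for
    the unordered pair keeps both directional values plus their mean.
    """
    if site_ids is None:
        all_state = max((parse_label(l) for l in matrix.labels), key=lambda s: s.n_probes)
        site_ids = sorted(all_state.probe_sites)
    edges = []
    for k, a in enumerate(site_ids):
        for b in site_ids[k + 1:]:
            v_a0, sd_a0 = conditional_replacement(matrix, a, set())
            v_ab, sd_ab = conditional_replacement(matrix, a, {b})
            v_b0, sd_b0 = conditional_replacement(matrix, b, set())
            v_ba, sd_ba = conditional_replacement(matrix, b, {a})
            edges.append(
                CorrelationEdge(
                    (a, b),
                    v_ab - v_a0,
                    v_ba - v_b0,
                    math.hypot(sd_ab, sd_a0),
                    math.hypot(sd_ba, sd_b0),
                )
            )
    return edges


def correlation_to_networkx(edges: Sequence[CorrelationEdge]) -> nx.Graph:
    """Graph with site-id nodes and dddG edge attributes (GraphML-ready)."""
    g = nx.Graph()
    for e in edges:
        a, b = e.site_pair
        g.add_node(a)
        g.add_node(b)
        g.add_edge(
            a, b,
            delta_ab=e.delta_ab,
            delta_ba=e.delta_ba,
            delta_mean=e.delta,
            sd=e.sd,
            sign_class=e.sign_class,
        )
    return g


def write_correlation_graph(edges: Sequence[CorrelationEdge], graphml_path: str | None = None,
                            json_path: str | None = None) -> None:
    g = correlation_to_networkx(edges)
    if graphml_path:
        nx.write_graphml(g, graphml_path)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(nx.node_link_data(g, edges="links"), fh, indent=1, sort_keys=True)


def rank_by_spearman(
    profile_a: Sequence[float],
    profile_b: Sequence[float],
    n_permutations: int = 5000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Spearman rank correlation of two replacement profiles with a
    two-sided permutation-test p-value (average ranks on ties)."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profiles differ in length: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError("profiles must have length >= 3")
    rho = float(sps.spearmanr(a, b).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(b)
        if abs(float(sps.spearmanr(a, perm).statistic)) >= abs(rho) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return rho, p


def cost_model(protocol: CostProtocol) -> Tuple[float, float, float]:
    """(solution_ns, protein_ns, total_ns) of the pairwise protocol.

    ``minimal`` mode uses the spanning N-1 perturbations, ``all-pairs``
    uses n(n-1)/2; each perturbation costs (windows x ns-per-window) in
    both environments, equilibration disregarded.
    """
    n = protocol.n_states
    pairwise = n - 1 if protocol.pairwise_mode == "minimal" else count_unique_pairs(n)
    solution = pairwise * protocol.n_lambda_windows * protocol.solution_ns_per_window
    protein = pairwise * protocol.n_lambda_windows * protocol.protein_ns_per_window
    return solution, protein, solution + protein


def cumulative_time(stage_ns: Dict[str, float] | Sequence[float]) -> float:
    """Cumulative simulation time over protocol stages (ns)."""
    values = list(stage_ns.values()) if isinstance(stage_ns, dict) else list(stage_ns)
    if any(v < 0 for v in values):
        raise ValueError("stage times must be >= 0")
    return float(sum(values))
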