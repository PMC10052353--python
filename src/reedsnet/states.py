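"""Water/probe network end states and their canonical enumeration.

An end state of the alchemical network is the subset of hydration sites
occupied by an apolar probe; all remaining sites hold a water. States are
labelled ``apo`` (no probes) or ``(i,j,...)`` with ascending site ids, the
convention used throughout figures and output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import FrozenSet, Iterable, List

__all__ = [
    "NetworkState",
    "enumerate_states",
    "count_unique_pairs",
    "parse_label",
]


@dataclass(frozen=True, order=False)
class NetworkState:
    """One composition of the water network.

    Parameters
    ----------
    probe_sites
        Site ids occupied by an apolar probe; the complement of the
        system's site set holds waters.
    """

    probe_sites: FrozenSet[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_sites", frozenset(int(s) for s in self.probe_sites))
        if any(s < 1 for s in self.probe_sites):
            raise ValueError("site ids must be >= 1")

    @property
    def label(self) -> str:
        if not self.probe_sites:
            return "apo"
        return "(" + ",".join(str(s) for s in sorted(self.probe_sites)) + ")"

    @property
    def n_probes(self) -> int:
        return len(self.probe_sites)

    def has_probe(self, site_id: int) -> bool:
        return site_id in self.probe_sites

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"NetworkState({self.label})"


def parse_label(label: str) -> NetworkState:
    """Inverse of :attr:`NetworkState.label`."""
    label = label.strip()
    if label == "apo":
        return NetworkState(frozenset())
    if not (label.startswith("(") and label.endswith(")")):
        raise ValueError(f"unrecognized state label: {label!r}")
    inner = label[1:-1].strip()
    if not inner:
        raise ValueError(f"empty probe list in label: {label!r}")
    return NetworkState(frozenset(int(tok) for tok in inner.split(",")))


def enumerate_states(n_sites: int, site_ids: Iterable[int] | None = None) -> List[NetworkState]:
    """All 2**n probe/water combinations in canonical order.

    Canonical order is by number of probes ascending, then lexicographic in
    the sorted site-id tuple: apo first, then singles, pairs, ..., all-probe.
    """
    if not (0 <= n_sites <= 12):
        raise ValueError(f"n_sites must be in [0, 12], got {n_sites}")
    ids = sorted(site_ids) if site_ids is not None else list(range(1, n_sites + 1))
    if len(ids) != n_sites:
        raise ValueError("site_ids length must equal n_sites")
    states: List[NetworkState] = []
    for size in range(n_sites + 1):
        for combo in combinations(ids, size):
            states.append(NetworkState(frozenset(combo)))
    return states


def count_unique_pairs(n_states: int) -> int:
    """Number of unique unordered state pairs, n(n-1)/2."""
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    return n_states * (n_states - 1) // 2
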