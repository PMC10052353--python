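"""Configuration, the end-to-end dual-environment study, and re-analysis.

A study configuration names a pocket and a bulk system (file path or a
``builtin:<name>`` benchmark), the EDS settings, the rebalancing settings,
the sampling schedules, the number of replicates and the master seed. The
full study runs, for each environment and replicate, the rebalancing
pipeline followed by production RE-EDS sampling and double-Zwanzig
estimation; replicates are combined, the thermodynamic cycle is closed,
and the network analyses plus a human-readable report are written to the
output directory. All randomness derives deterministically from the master
seed, so repeated runs produce byte-identical artifacts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import network_analysis as na
from .eds_core import EDSParameters
from .estimators import FreeEnergyMatrix, combine_matrices, convergence_series, zwanzig_twice
from .pipeline import (
    DEFAULT_INTENSITIES,
    PipelineResult,
    RebalanceSettings,
    choose_s_ladder,
    harmonic_offset_increment,
    initial_offsets,
    rebalancing_loop,
)
from .sampler import run_re_eds, trajectory_from_csv, trajectory_to_csv
from .toy_model import EndStateSystem, get_benchmark, load_system

__all__ = ["RunConfig", "load_config", "save_config", "run_full_study", "reanalyze", "StudyResult"]


@dataclass
class Schedule:
    n_phases: int
    steps_per_phase: int
    stride: int = 1


@dataclass
class RunConfig:
    """Validated study configuration with defaults filled in."""

    pocket_system: str
    bulk_system: str
    n_replicas: int = 4
    s_min: float = 0.05
    per_probe_increment: float | None = None  # None: closed-form harmonic guess
    intensities: Tuple[float, ...] = DEFAULT_INTENSITIES
    floor_fraction: float | None = None
    stop_threshold: float = 0.05
    max_iterations: int = 15
    pipeline_schedule: Schedule = field(default_factory=lambda: Schedule(30, 800, 2))
    production_schedule: Schedule = field(default_factory=lambda: Schedule(30, 600, 1))
    n_replicates: int = 3
    seed: int = 1
    outdir: str = "results"

    def settings_for(self, replicate: int) -> RebalanceSettings:
        intensity = self.intensities[replicate % len(self.intensities)]
        return RebalanceSettings(
            intensity=intensity,
            floor_fraction=self.floor_fraction,
            stop_threshold=self.stop_threshold,
            max_iterations=self.max_iterations,
        )


_SCHEMA = {
    "pocket_system": str,
    "bulk_system": str,
    "n_replicas": int,
    "s_min": float,
    "per_probe_increment": float,
    "intensities": list,
    "floor_fraction": float,
    "stop_threshold": float,
    "max_iterations": int,
    "pipeline_schedule": dict,
    "production_schedule": dict,
    "n_replicates": int,
    "seed": int,
    "outdir": str,
}
_SCHEDULE_KEYS = {"n_phases": int, "steps_per_phase": int, "stride": int}
_OPTIONAL_NONE = {"per_probe_increment", "floor_fraction"}


def _check_schedule(name: str, d: dict) -> Schedule:
    unknown = sorted(set(d) - set(_SCHEDULE_KEYS))
    if unknown:
        raise ValueError(f"unknown key {unknown[0]!r} in {name}")
    vals = {}
    for k, t in _SCHEDULE_KEYS.items():
        if k in d:
            if not isinstance(d[k], int) or isinstance(d[k], bool):
                raise ValueError(f"{name}.{k} must be an integer")
            vals[k] = d[k]
    return Schedule(**{**{"n_phases": 10, "steps_per_phase": 400, "stride": 1}, **vals})


def load_config(path: str) -> RunConfig:
    """Read and schema-validate a study configuration (YAML).

    Unknown keys are rejected by name; omitted keys take their documented
    defaults. Referenced system files must exist.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError("configuration must be a mapping")
    unknown = sorted(set(doc) - set(_SCHEMA))
    if unknown:
        raise ValueError(f"unknown configuration key {unknown[0]!r}")
    for key in ("pocket_system", "bulk_system"):
        if key not in doc:
            raise ValueError(f"missing required key {key!r} (expected str)")
    kwargs: Dict = {}
    for key, typ in _SCHEMA.items():
        if key not in doc:
            continue
        val = doc[key]
        if val is None and key in _OPTIONAL_NONE:
            kwargs[key] = None
            continue
        if typ is float and isinstance(val, int) and not isinstance(val, bool):
            val = float(val)
        if not isinstance(val, typ) or isinstance(val, bool):
            raise ValueError(f"key {key!r} must be of type {typ.__name__}")
        kwargs[key] = val
    if "pipeline_schedule" in kwargs:
        kwargs["pipeline_schedule"] = _check_schedule("pipeline_schedule", kwargs["pipeline_schedule"])
    if "production_schedule" in kwargs:
        kwargs["production_schedule"] = _check_schedule(
            "production_schedule", kwargs["production_schedule"]
        )
    if "intensities" in kwargs:
        kwargs["intensities"] = tuple(float(v) for v in kwargs["intensities"])
    cfg = RunConfig(**kwargs)
    for ref in (cfg.pocket_system, cfg.bulk_system):
        if not ref.startswith("builtin:") and not os.path.exists(ref):
            raise FileNotFoundError(f"referenced system file does not exist: {ref}")
    return cfg


def save_config(cfg: RunConfig, path: str) -> None:
    doc = asdict(cfg)
    doc["intensities"] = list(cfg.intensities)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _resolve_system(ref: str, environment: str) -> EndStateSystem:
    if ref.startswith("builtin:"):
        pair = get_benchmark(ref.split(":", 1)[1])
        return pair.pocket if environment == "pocket" else pair.bulk
    system = load_system(ref)
    if system.environment_tag != environment:
        raise ValueError(
            f"system {ref} is tagged {system.environment_tag!r}, expected {environment!r}"
        )
    return system


@dataclass
class StudyResult:
    config: RunConfig
    pocket_matrix: FreeEnergyMatrix
    bulk_matrix: FreeEnergyMatrix
    replacement: na.ReplacementMatrix
    gaps: pd.DataFrame
    edges: List[na.CorrelationEdge]
    pipeline_results: Dict[Tuple[str, int], PipelineResult]
    replicate_matrices: Dict[Tuple[str, int], FreeEnergyMatrix]
    cost_table: pd.DataFrame
    artifacts: List[str] = field(default_factory=list)


def _run_environment(
    system: EndStateSystem, cfg: RunConfig, env_idx: int, outdir: str | None
) -> Tuple[FreeEnergyMatrix, Dict[int, PipelineResult], Dict[int, FreeEnergyMatrix], List[str]]:
    env = system.environment_tag
    increment = (
        cfg.per_probe_increment
        if cfg.per_probe_increment is not None
        else harmonic_offset_increment(system)
    )
    ladder = choose_s_ladder(cfg.n_replicas, cfg.s_min)
    artifacts: List[str] = []
    pipeline_results: Dict[int, PipelineResult] = {}
    matrices: Dict[int, FreeEnergyMatrix] = {}
    for r in range(cfg.n_replicates):
        base = cfg.seed * 10000 + env_idx * 1000 + r * 10
        params0 = EDSParameters(ladder, initial_offsets(system.states, increment))
        pr = rebalancing_loop(
            system,
            params0,
            cfg.settings_for(r),
            n_phases=cfg.pipeline_schedule.n_phases,
            steps_per_phase=cfg.pipeline_schedule.steps_per_phase,
            stride=cfg.pipeline_schedule.stride,
            seed=base,
        )
        pipeline_results[r] = pr
        trajs, record = run_re_eds(
            system,
            pr.params,
            cfg.production_schedule.n_phases,
            cfg.production_schedule.steps_per_phase,
            cfg.production_schedule.stride,
            seed=base + 5,
        )
        mat = zwanzig_twice(trajs[1.0], pr.params, env, boot_seed=base + 7)
        matrices[r] = mat
        if outdir:
            log_path = os.path.join(outdir, f"pipeline_{env}_rep{r}.csv")
            with open(log_path, "w") as fh:
                fh.write("# units: kJ/mol\n")
                pr.log_frame().to_csv(fh, index=False, float_format="%.10g")
            artifacts.append(log_path)
            if r == 0:
                conv = convergence_series(trajs[1.0], pr.params, n_blocks=5, boot_seed=base + 7)
                rows = [
                    {
                        "n_frames": m,
                        "dG_apo_to_all": mat_b.dg("apo", mat_b.labels[-1]),
                    }
                    for m, mat_b in conv
                ]
                conv_path = os.path.join(outdir, f"convergence_{env}.csv")
                with open(conv_path, "w") as fh:
                    fh.write("# units: kJ/mol\n")
                    pd.DataFrame(rows).to_csv(fh, index=False, float_format="%.10g")
                artifacts.append(conv_path)
            traj_path = os.path.join(outdir, f"energies_{env}_rep{r}.csv")
            trajectory_to_csv(trajs[1.0], traj_path, seed=base + 5)
            artifacts.append(traj_path)
    combined = combine_matrices([matrices[r] for r in range(cfg.n_replicates)])
    return combined, pipeline_results, matrices, artifacts


def _gap_table(repl: na.ReplacementMatrix, site_ids: Sequence[int]) -> pd.DataFrame:
    from itertools import combinations

    rows = []
    for size in range(2, len(site_ids) + 1):
        for subset in combinations(site_ids, size):
            (s, s_sd), (c, c_sd), (g, g_sd) = na.additivity_gap(repl, set(subset))
            rows.append(
                {
                    "subset": na.NetworkState(frozenset(subset)).label,
                    "sum_of_singles": s,
                    "sum_sd": s_sd,
                    "concomitant": c,
                    "concomitant_sd": c_sd,
                    "gap": g,
                    "gap_sd": g_sd,
                }
            )
    return pd.DataFrame(rows)


def run_full_study(cfg: RunConfig, outdir: str | None = "auto") -> StudyResult:
    """The complete dual-environment workflow.

    For each environment and replicate: rebalancing pipeline, production
    RE-EDS sampling, double-Zwanzig estimation. Replicates are combined,
    the replacement matrix, additivity gaps, correlation graph and cost
    accounting computed, and (unless ``outdir`` is None) all artifacts
    written.
    """
    if outdir == "auto":
        outdir = cfg.outdir
    if outdir:
        os.makedirs(outdir, exist_ok=True)
    pocket = _resolve_system(cfg.pocket_system, "pocket")
    bulk = _resolve_system(cfg.bulk_system, "bulk")
    if pocket.labels != bulk.labels:
        raise ValueError("pocket and bulk systems must share the same end states")

    artifacts: List[str] = []
    pocket_mat, pr_p, mats_p, art_p = _run_environment(pocket, cfg, 0, outdir)
    bulk_mat, pr_b, mats_b, art_b = _run_environment(bulk, cfg, 1, outdir)
    artifacts += art_p + art_b
    repl = na.replacement_matrix(pocket_mat, bulk_mat)
    site_ids = [s.site_id for s in pocket.sites]
    gaps = _gap_table(repl, site_ids)
    edges = na.correlation_graph(repl, site_ids)
    reti = na.CostProtocol(pocket.n_states, 11, 5.0, 0.5, "minimal")
    sol, prot, tot = na.cost_model(reti)
    cost_table = pd.DataFrame(
        [
            {"protocol": "RE-TI lower limit (minimal pairs, 11 windows)",
             "solution_ns": sol, "protein_ns": prot, "total_ns": tot},
        ]
    )
    pipeline_results = {("pocket", r): v for r, v in pr_p.items()}
    pipeline_results.update({("bulk", r): v for r, v in pr_b.items()})
    replicate_matrices = {("pocket", r): v for r, v in mats_p.items()}
    replicate_matrices.update({("bulk", r): v for r, v in mats_b.items()})
    result = StudyResult(
        cfg, pocket_mat, bulk_mat, repl, gaps, edges,
        pipeline_results, replicate_matrices, cost_table, artifacts,
    )
    if outdir:
        _write_artifacts(result, outdir)
    return result


def _write_artifacts(res: StudyResult, outdir: str) -> None:
    cfg = res.config
    paths = {
        "pocket": os.path.join(outdir, "pocket_matrix.csv"),
        "bulk": os.path.join(outdir, "bulk_matrix.csv"),
        "repl": os.path.join(outdir, "replacement_matrix.csv"),
        "gaps": os.path.join(outdir, "additivity_gaps.csv"),
        "graphml": os.path.join(outdir, "correlation_graph.graphml"),
        "json": os.path.join(outdir, "correlation_graph.json"),
        "cost": os.path.join(outdir, "cost_model.csv"),
        "config": os.path.join(outdir, "config_echo.yaml"),
        "report": os.path.join(outdir, "report.md"),
    }
    res.pocket_matrix.to_csv(paths["pocket"], seed=cfg.seed)
    res.bulk_matrix.to_csv(paths["bulk"], seed=cfg.seed)
    res.replacement.to_csv(paths["repl"], seed=cfg.seed)
    with open(paths["gaps"], "w") as fh:
        fh.write("# units: kJ/mol\n")
        res.gaps.to_csv(fh, index=False, float_format="%.10g")
    na.write_correlation_graph(res.edges, paths["graphml"], paths["json"])
    with open(paths["cost"], "w") as fh:
        fh.write("# units: ns\n")
        res.cost_table.to_csv(fh, index=False, float_format="%.10g")
    save_config(cfg, paths["config"])
    _write_report(res, paths["report"])
    res.artifacts.extend(paths.values())


def _write_report(res: StudyResult, path: str) -> None:
    cfg = res.config
    lines = [
        "# RE-EDS water-network replacement study",
        "",
        f"- master seed: {cfg.seed}",
        f"- replicates per environment: {cfg.n_replicates} "
        f"(rebalancing intensities {list(cfg.intensities)})",
        f"- s-ladder: {cfg.n_replicas} replicas, log-uniform down to {cfg.s_min}",
        f"- systems: pocket={cfg.pocket_system}, bulk={cfg.bulk_system}",
        "",
        "## Rebalancing",
        "",
    ]
    for (env, r), pr in sorted(res.pipeline_results.items()):
        dev = pr.history[-1].deviation_from_ideal if pr.history else float("nan")
        lines.append(
            f"- {env} replicate {r}: converged={pr.converged} in {pr.iterations_used} "
            f"iteration(s), final deviation from ideal sampling {dev:.3f}"
        )
    lines += ["", "## Replacement free energies (kJ/mol)", ""]
    singles = [lab for lab in res.replacement.labels if lab.startswith("(") and "," not in lab]
    for lab in singles:
        v = res.replacement.value("apo", lab)
        sd = res.replacement.value_sd("apo", lab)
        lines.append(f"- apo -> {lab}: {v:+.2f} +/- {sd:.2f}")
    all_lab = res.replacement.labels[-1]
    lines.append(
        f"- apo -> {all_lab} (full network): "
        f"{res.replacement.value('apo', all_lab):+.2f} +/- "
        f"{res.replacement.value_sd('apo', all_lab):.2f}"
    )
    lines += ["", "## Additivity gaps (sum of singles minus concomitant, kJ/mol)", ""]
    for row in res.gaps.itertuples(index=False):
        lines.append(
            f"- {row.subset}: gap {row.gap:+.2f} +/- {row.gap_sd:.2f} "
            f"(sum {row.sum_of_singles:+.2f}, concomitant {row.concomitant:+.2f})"
        )
    lines += ["", "## Solvation-correlation edges (dddG, kJ/mol)", ""]
    significant = [e for e in res.edges if e.significant()]
    for e in res.edges:
        flag = " [significant]" if e.significant() else ""
        lines.append(
            f"- sites {e.site_pair[0]}-{e.site_pair[1]}: delta {e.delta:+.2f} "
            f"+/- {e.sd:.2f} ({e.sign_class}){flag}"
        )
    lines.append("")
    lines.append(
        f"{len(significant)} significant edge(s) at the 3-sigma level out of {len(res.edges)}."
    )
    lines += ["", "## Pairwise-protocol cost accounting (ns)", ""]
    for row in res.cost_table.itertuples(index=False):
        lines.append(
            f"- {row.protocol}: solution {row.solution_ns:g}, protein {row.protein_ns:g}, "
            f"total {row.total_ns:g}"
        )
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def reanalyze(
    trajectories: Dict[str, Sequence[str]],
    params: EDSParameters,
    boot_seed: int = 2024,
) -> Dict[str, object]:
    """Estimation and network analyses from stored energy CSVs (no sampling).

    ``trajectories`` maps environment tag (``pocket``/``bulk``) to one CSV
    path per replicate. Returns the per-environment combined matrices and,
    when both environments are present, the replacement matrix, additivity
    gaps and correlation edges.
    """
    out: Dict[str, object] = {}
    combined: Dict[str, FreeEnergyMatrix] = {}
    for env, paths in trajectories.items():
        mats = []
        for k, p in enumerate(paths):
            traj = trajectory_from_csv(p)
            mats.append(zwanzig_twice(traj, params, env, boot_seed=boot_seed + k))
        combined[env] = combine_matrices(mats)
        out[f"{env}_matrix"] = combined[env]
        out[f"{env}_replicates"] = mats
    if "pocket" in combined and "bulk" in combined:
        repl = na.replacement_matrix(combined["pocket"], combined["bulk"])
        out["replacement"] = repl
        all_state = max((na.parse_label(l) for l in repl.labels), key=lambda s: s.n_probes)
        site_ids = sorted(all_state.probe_sites)
        out["gaps"] = _gap_table(repl, site_ids)
        out["edges"] = na.correlation_graph(repl, site_ids)
    return out
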