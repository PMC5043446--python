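"""End-to-end design runs: enumerate candidate structures, estimate
parameters per structure with GDE3, rank by HVUPF + complexity, and
write reports with full provenance.

Per-structure optimization seeds are derived by hashing (master seed,
structure id), so adding or removing structures does not perturb the
results of the others; stochastic objective evaluations draw a fresh
seeded substream per evaluation.  Identical config + seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .casestudies import DesignTask
from .enumerator import CandidateStructure, enumerate_candidates
from .network import ReactionNetwork, flatten
from .objectives import (
    OscillatorSpec,
    SwitchSpec,
    oscillator_objectives,
    switch_objectives,
)
from .optimize import OptimizerBudget, ParetoFront, gde3_minimize
from .rank import ScoreProfile, median_ranks, rank_profile
from .simulate import Trajectory, simulate_ode, simulate_ssa

__all__ = [
    "RunConfig",
    "RunReport",
    "stable_seed",
    "make_evaluator",
    "optimize_structure",
    "run_design",
    "run_task_grid",
    "simulate_selected",
]

log = logging.getLogger("procdesign")

WORST = 1.0  # objective value assigned to failed evaluations


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary string/int parts."""
    h = hashlib.sha256("\x1f".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass
class RunConfig:
    task: DesignTask
    budget: OptimizerBudget = field(default_factory=OptimizerBudget)
    master_seed: int = 0
    outdir: Path | None = None

    def provenance(self) -> dict:
        obj = self.task.objective
        return {
            "version": __version__,
            "task": self.task.name,
            "interpretation": self.task.interpretation,
            "objective": {k: (list(v) if isinstance(v, tuple) else v) for k, v in obj.__dict__.items()},
            "n_realizations": self.task.n_realizations,
            "alpha": self.task.alpha,
            "budget": self.budget.__dict__ | {},
            "master_seed": self.master_seed,
        }


@dataclass
class RunReport:
    config: RunConfig
    candidates: list[CandidateStructure]
    networks: dict[str, ReactionNetwork]
    fronts: dict[str, ParetoFront]
    profile: ScoreProfile
    outdir: Path | None = None


def make_evaluator(task: DesignTask, net: ReactionNetwork, eval_seed: int):
    """Build the total objective callback for one candidate network.

    Deterministic tasks integrate the ODE system; stochastic tasks run
    the SSA ensemble with a fresh per-evaluation substream.  Any
    simulation failure maps to the worst objective vector.
    """
    cn = net.compile()
    free = net.free_parameters
    fixed = {name: spec.fixed for name, spec in net.parameters.items() if spec.is_fixed}

    def evaluate(x: np.ndarray) -> np.ndarray:
        params = dict(zip((n for n, _ in free), x)) | fixed
        pvec = cn.param_vector(params)
        if task.interpretation == "deterministic":
            traj = simulate_ode(cn, pvec, task.grid, events=task.events or None)
            return oscillator_objectives(traj, task.objective)
        # common random numbers: every evaluation in this optimization
        # run shares one realization substream, so comparisons between
        # parameter vectors are consistent and archived points are not
        # lucky draws of the simulation noise
        traj = simulate_ssa(
            cn,
            pvec,
            task.grid,
            n_real=task.n_realizations,
            seed=eval_seed,
            events=task.events or None,
            max_total=200_000,
            max_events=2_000_000,
            on_failure="flag",
        )
        if traj.n_failed:
            return np.array([WORST, WORST])
        return switch_objectives(traj, task.objective)

    return evaluate


def optimize_structure(
    task: DesignTask,
    cand: CandidateStructure,
    budget: OptimizerBudget,
    master_seed: int,
) -> tuple[ReactionNetwork, ParetoFront]:
    net = flatten(cand, task.library, task.model)
    seed = stable_seed(master_seed, cand.id)
    evaluate = make_evaluator(task, net, eval_seed=seed)
    box = [rng for _, rng in net.free_parameters]
    if not box:  # fully determined structure: single evaluation
        obj = evaluate(np.empty(0))
        front = ParetoFront(np.empty((1, 0)), np.atleast_2d(obj))
    else:
        b = OptimizerBudget(
            population=budget.population,
            generations=budget.generations,
            F=budget.F,
            CR=budget.CR,
            seed=seed,
        )
        front = gde3_minimize(evaluate, box, b)
    front.provenance = dict(front.provenance) | {
        "structure": cand.id,
        "task": task.name,
        "master_seed": master_seed,
    }
    return net, front


def run_design(config: RunConfig) -> RunReport:
    """Full design run for one task; any per-structure failure is
    logged, scored worst, and the run continues."""
    from .rank import hvupf

    task = config.task
    handler = None
    if config.outdir is not None:
        Path(config.outdir).mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(Path(config.outdir) / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    candidates = enumerate_candidates(task.model, task.library)
    networks: dict[str, ReactionNetwork] = {}
    fronts: dict[str, ParetoFront] = {}
    rows = []
    for cand in candidates:
        t0 = time.perf_counter()
        try:
            net, front = optimize_structure(task, cand, config.budget, config.master_seed)
            networks[cand.id] = net
            fronts[cand.id] = front
            hv = hvupf(front)
        except Exception:  # partial-failure tolerance
            log.exception("structure %s failed; scored worst", cand.id)
            hv = 1.0
        rows.append((cand.id, hv, cand.complexity))
        log.info(
            "structure %s: hvupf=%.4g complexity=%d (%.1fs)",
            cand.id, rows[-1][1], cand.complexity, time.perf_counter() - t0,
        )
    profile = rank_profile(rows, alpha=task.alpha, task=task.name)
    report = RunReport(config, candidates, networks, fronts, profile, outdir=config.outdir)
    if config.outdir is not None:
        _write_report(report)
    if handler is not None:
        log.removeHandler(handler)
        handler.close()
    return report


def run_task_grid(
    tasks: list[DesignTask],
    budget: OptimizerBudget,
    master_seed: int,
    outdir: Path | None = None,
) -> tuple[list[RunReport], dict[str, float]]:
    """Run several tasks over the same structure space and summarize
    with per-structure median ranks."""
    reports = []
    for task in tasks:
        cfg = RunConfig(task=task, budget=budget, master_seed=master_seed,
                        outdir=(Path(outdir) / _safe(task.name)) if outdir else None)
        reports.append(run_design(cfg))
    med = median_ranks([r.profile for r in reports])
    if outdir is not None:
        import pandas as pd

        pd.DataFrame(sorted(med.items()), columns=["id", "median_rank"]).to_csv(
            Path(outdir) / "medians.csv", index=False
        )
    return reports, med


def simulate_selected(
    report: RunReport, structure_id: str, point_index: int
) -> Trajectory:
    """Re-simulate a chosen design at a chosen Pareto-front point."""
    if structure_id not in report.fronts:
        raise KeyError(f"unknown structure id {structure_id!r}")
    front = report.fronts[structure_id]
    if not 0 <= point_index < len(front):
        raise IndexError(f"front point index {point_index} out of range")
    net = report.networks[structure_id]
    task = report.config.task
    x = front.params[point_index]
    free = net.free_parameters
    params = dict(zip((n for n, _ in free), x)) | {
        name: spec.fixed for name, spec in net.parameters.items() if spec.is_fixed
    }
    if task.interpretation == "deterministic":
        return simulate_ode(net, params, task.grid, events=task.events or None)
    return simulate_ssa(
        net,
        params,
        task.grid,
        n_real=task.n_realizations,
        seed=stable_seed(report.config.master_seed, structure_id, "selected", point_index),
        events=task.events or None,
        on_failure="flag",
    )


# ---------------------------------------------------------------------------
# report files


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in name)


def _write_report(report: RunReport) -> None:
    import pandas as pd

    out = Path(report.outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"id": c.id, "complexity": c.complexity,
             **{point: choice for point, choice in c.decisions}}
            for c in report.candidates
        ]
    ).to_csv(out / "structures.csv", index=False)
    report.profile.to_frame().to_csv(out / "profile.csv", index=False)
    fronts_dir = out / "fronts"
    fronts_dir.mkdir(exist_ok=True)
    for sid, front in report.fronts.items():
        net = report.networks[sid]
        pcols = [n for n, _ in net.free_parameters]
        df = pd.DataFrame(front.params, columns=pcols)
        for m in range(front.objectives.shape[1]):
            df[f"objective_{m + 1}"] = front.objectives[:, m]
        df.insert(0, "structure", sid)
        df.to_csv(fronts_dir / f"{_safe(sid)}.csv", index=False)
    (out / "run.json").write_text(json.dumps(report.config.provenance(), indent=2))
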