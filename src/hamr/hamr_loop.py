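"""The HAMR loop: a torsion-driving genetic algorithm over conformers,
scored by molecular replacement.

One run proceeds as follows.  Every conformer of the input ensemble is
phased by MR and the solutions ranked (step "seed").  Torsions are then
ordered by impact — the mean heavy-atom displacement over a full 360°
scan (ΔRMSD), largest first — and optimized one per cycle: each population
member is driven through all settings of the current torsion, the settings
are pre-filtered by the cheap inherited-pose R factor (the modified
conformer is scored in the parent's position in the lattice before any new
MR is spent on it), near-duplicates of already-phased conformers are
discarded, and the survivors are re-phased by MR.  Selection is elitist:
parents compete with children, so the best score never decreases.  When a
full pass over the agenda still improves the score (typical at low
resolution), the agenda is repeated up to ``max_cycles`` passes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Callable, Optional, Sequence

import numpy as np

from hamr.chem_model import (
    Conformer,
    TorsionDef,
    find_torsions,
    rank_torsions,
    set_torsion,
    Lineage,
)
from hamr.crystal_model import ReflectionSet, calc_structure_factors, fit_scale, r_factor
from hamr.mr_engine import MRConfig, MRSolution, Pose, run_mr

logger = logging.getLogger(__name__)


@dataclass
class HamrConfig:
    """Run configuration; serialized into every results bundle."""

    scan_step: float = 10.0
    prefilter_fraction: float = 0.2   # 1.0 disables the R-factor filter
    dedup_rmsd: float = 0.02
    n_top_carry: int = 3
    rank_metric: str = "llg"          # "llg" or "r_factor"
    # passes over the torsion agenda; None = one pass per rotatable torsion
    # (with early stop once a full pass no longer improves the best score)
    max_cycles: Optional[int] = None
    visits_per_torsion: int = 1
    dedup_superpose: bool = False
    agenda_ascending: bool = False
    seed: int = 0
    # Packing tolerance is relaxed during the loop: unrefined trial
    # conformers mid-optimization necessarily show short symmetry contacts,
    # and rejecting them would starve the population.  The strict test
    # belongs to standalone MR of final models.  tfz is evaluated lazily
    # inside the loop (the llg gate decides) and recomputed for the final
    # best solution.
    mr: MRConfig = field(
        default_factory=lambda: MRConfig(clash_dist=0.8, lazy_tfz=True)
    )

    def __post_init__(self):
        if not 0.0 < self.prefilter_fraction <= 1.0:
            raise ValueError("prefilter_fraction must be in (0, 1]")
        if self.rank_metric not in ("llg", "r_factor"):
            raise ValueError("rank_metric must be 'llg' or 'r_factor'")
        if self.n_top_carry < 1:
            raise ValueError("n_top_carry must be >= 1")
        if self.dedup_rmsd < 0:
            raise ValueError("dedup_rmsd must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _metric_key(metric: str) -> Callable[[MRSolution], float]:
    if metric == "llg":
        return lambda s: -s.llg_like
    return lambda s: s.r_work


@dataclass
class HamrState:
    """GA bookkeeping: population, dedup registry, agenda, audit log."""

    config: HamrConfig
    data: ReflectionSet
    cycle: int = 0
    population: list[MRSolution] = field(default_factory=list)
    registry: list[np.ndarray] = field(default_factory=list)
    agenda: list[TorsionDef] = field(default_factory=list)
    optimized: list[bool] = field(default_factory=list)
    best: Optional[MRSolution] = None
    n_mr_calls: int = 0
    n_prefiltered: int = 0
    n_dedup_skipped: int = 0
    log: list[dict] = field(default_factory=list)

    def register(self, sol: MRSolution) -> None:
        """Add a phased conformer to the dedup registry, keeping the
        registry's pairwise separation >= dedup_rmsd."""
        coords = sol.posed_coords(self.data.cell)
        if not self.is_duplicate(coords, sol.conformer):
            self.registry.append(coords)

    def is_duplicate(self, posed_coords: np.ndarray, conf: Conformer) -> bool:
        """Crystal-frame RMSD (no superposition by default) vs registry."""
        heavy = conf.parent.heavy_indices
        x = posed_coords[heavy]
        for reg in self.registry:
            y = reg[heavy]
            if self.config.dedup_superpose:
                from hamr.chem_model import _rmsd_arrays
                val = _rmsd_arrays(x, y, superpose=True)
            else:
                val = float(np.sqrt(((x - y) ** 2).sum(axis=1).mean()))
            if val < self.config.dedup_rmsd:
                return True
        return False

    def best_metric(self) -> float:
        key = _metric_key(self.config.rank_metric)
        return key(self.best) if self.best is not None else np.inf


def _update_best(state: HamrState) -> None:
    key = _metric_key(state.config.rank_metric)
    for sol in state.population:
        if state.best is None or key(sol) < key(state.best):
            state.best = sol


def seed_population(
    ensemble: Sequence[Conformer],
    data: ReflectionSet,
    config: HamrConfig,
) -> HamrState:
    """Phase every input conformer by MR and keep the top n_top_carry."""
    if not ensemble:
        raise ValueError("empty conformer ensemble")
    state = HamrState(config=config, data=data)
    solutions: list[MRSolution] = []
    for i, conf in enumerate(ensemble):
        if conf.cid is None:
            conf = conf.copy(cid=f"seed-{i:04d}")
        mr_cfg = replace(config.mr, seed=config.seed)
        sol = run_mr(conf, data, mr_cfg)
        state.n_mr_calls += 1
        if sol is not None:
            solutions.append(sol)
    if not solutions:
        raise RuntimeError("no viable starting conformer: all MR attempts failed")
    key = _metric_key(config.rank_metric)
    solutions.sort(key=key)
    state.population = solutions[: config.n_top_carry]
    for sol in state.population:
        state.register(sol)
    _update_best(state)
    # fix the torsion agenda from the best conformer
    torsions = [
        t for t in find_torsions(state.best.conformer.parent) if t.rotatable
    ]
    ranked = rank_torsions(
        state.best.conformer, torsions, step_deg=config.scan_step
    )
    if config.agenda_ascending:
        ranked = ranked[::-1]
    state.agenda = ranked
    state.optimized = [False] * len(ranked)
    state.log.append(
        {
            "event": "seed",
            "n_input": len(ensemble),
            "n_phased": len(solutions),
            "best": _scores_of(state.best),
            "agenda": [t.bond for t in state.agenda],
            "delta_rmsd": [t.delta_rmsd for t in state.agenda],
        }
    )
    return state


def _scores_of(sol: MRSolution) -> dict:
    return {
        "id": sol.conformer_id,
        "llg_like": sol.llg_like,
        "tfz_like": sol.tfz_like,
        "r_work": sol.r_work,
        "cc": sol.cc,
    }


def scan_torsion(
    state: HamrState,
    torsion: TorsionDef,
    data: ReflectionSet,
    config: HamrConfig,
) -> list[MRSolution]:
    """Drive one torsion through all settings for every population member.

    Settings are scored cheaply with the parent's pose (inherited-position
    R factor), the best ``prefilter_fraction`` go on, registry duplicates
    are dropped without spending MR, and the survivors are re-phased.
    """
    nstep = int(round(360.0 / config.scan_step))
    settings = [k * config.scan_step for k in range(nstep)]
    candidates: list[tuple[float, Conformer, Pose]] = []
    for member in state.population:
        parent_conf = member.conformer
        scored = []
        for ang in settings:
            child = set_torsion(parent_conf, torsion, ang)
            child.lineage = Lineage(
                generation=state.cycle + 1,
                parent_id=member.conformer_id,
                torsion_id=torsion.bond,
                angles_deg=(float(ang),),
            )
            child.cid = f"c{state.cycle + 1}-{member.conformer_id}-{torsion.b}_{torsion.c}-{int(ang)}"
            fc = np.abs(
                calc_structure_factors(
                    child, member.pose, data.cell, data.spacegroup,
                    data.hkl, b_iso=config.mr.b_iso,
                )
            )
            scaling = fit_scale(data, fc)
            r = r_factor(data, fc, scaling, subset="work")
            scored.append((r, child))
        scored.sort(key=lambda x: x[0])
        n_keep = int(np.ceil(config.prefilter_fraction * len(scored)))
        state.n_prefiltered += len(scored) - n_keep
        for r, child in scored[:n_keep]:
            candidates.append((r, child, member.pose))

    new_solutions: list[MRSolution] = []
    for r, child, pose in sorted(candidates, key=lambda x: x[0]):
        posed = pose.apply(child.coords, data.cell)
        if state.is_duplicate(posed, child):
            state.n_dedup_skipped += 1
            continue
        # register the candidate itself as well as (below) its phased
        # result, so revisiting the same grid point later costs no MR
        state.registry.append(posed)
        mr_cfg = replace(config.mr, seed=config.seed)
        sol = run_mr(child, data, mr_cfg, start_pose=pose)
        state.n_mr_calls += 1
        if sol is None:
            continue
        state.register(sol)
        new_solutions.append(sol)
    return new_solutions


def advance_cycle(
    state: HamrState,
    data: ReflectionSet,
    config: HamrConfig,
) -> HamrState:
    """Scan the next torsion in agenda order; elitist selection."""
    pending = [i for i, done in enumerate(state.optimized) if not done]
    if not pending:
        return state
    idx = pending[0]
    torsion = state.agenda[idx]
    new = scan_torsion(state, torsion, data, config)
    key = _metric_key(config.rank_metric)
    merged = sorted(state.population + new, key=key)
    state.population = merged[: config.n_top_carry]
    state.optimized[idx] = True
    state.cycle += 1
    _update_best(state)
    state.log.append(
        {
            "event": "cycle",
            "cycle": state.cycle,
            "torsion": torsion.bond,
            "n_candidates": len(new),
            "n_mr_calls": state.n_mr_calls,
            "n_prefiltered": state.n_prefiltered,
            "n_dedup_skipped": state.n_dedup_skipped,
            "best": _scores_of(state.best),
            "population": [_scores_of(s) for s in state.population],
        }
    )
    return state


@dataclass
class HamrResult:
    """Results bundle: best solution, audit log, provenance."""

    best: Optional[MRSolution]
    state: HamrState
    config: HamrConfig
    log: list[dict]

    def write(self, outdir) -> None:
        from pathlib import Path
        import yaml
        from hamr.io_formats import write_solution_cif

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "solutions.jsonl", "w") as fh:
            for entry in self.log:
                fh.write(json.dumps(entry, default=_json_default) + "\n")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh)
        with open(out / "run.log", "w") as fh:
            fh.write(
                f"{'cycle':>5} {'torsion':>9} {'cand':>5} {'mr':>5} "
                f"{'dedup':>6} {'best_llg':>10} {'best_r':>8}\n"
            )
            for e in self.log:
                if e["event"] != "cycle":
                    continue
                fh.write(
                    f"{e['cycle']:>5} {str(tuple(e['torsion'])):>9} "
                    f"{e['n_candidates']:>5} {e['n_mr_calls']:>5} "
                    f"{e['n_dedup_skipped']:>6} "
                    f"{e['best']['llg_like']:>10.1f} "
                    f"{e['best']['r_work']:>8.4f}\n"
                )
        if self.best is not None:
            write_solution_cif(
                out / "best.cif", self.best, self.state.data
            )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def run_hamr(
    ensemble: Sequence[Conformer],
    data: ReflectionSet,
    config: Optional[HamrConfig] = None,
) -> HamrResult:
    """Run the full loop: seed, then optimize torsions until the agenda is
    exhausted; repeat the agenda while it still improves the score, up to
    ``max_cycles`` passes (useful at low resolution)."""
    if config is None:
        config = HamrConfig()
    state = seed_population(ensemble, data, config)
    max_passes = (
        config.max_cycles if config.max_cycles is not None
        else max(len(state.agenda), 1)
    )
    if max_passes == 0:
        return HamrResult(best=state.best, state=state, config=config,
                          log=state.log)
    for pass_i in range(max_passes):
        metric_before = state.best_metric()
        visits = max(config.visits_per_torsion, 1)
        if pass_i > 0:
            # agenda re-ranked by impact on the current best conformer
            ranked = rank_torsions(
                state.best.conformer, state.agenda, step_deg=config.scan_step
            )
            state.agenda = ranked[::-1] if config.agenda_ascending else ranked
        for _ in range(visits):
            state.optimized = [False] * len(state.agenda)
            while not all(state.optimized):
                advance_cycle(state, data, config)
        metric_after = state.best_metric()
        rel = abs(metric_before - metric_after) / max(abs(metric_before), 1e-12)
        state.log.append(
            {"event": "pass", "pass": pass_i + 1, "rel_improvement": rel}
        )
        if rel < 1e-3:
            break
    if state.best is not None and config.mr.lazy_tfz:
        from hamr.mr_engine import recompute_tfz

        recompute_tfz(state.best, data, b_iso=config.mr.b_iso)
    return HamrResult(best=state.best, state=state, config=config,
                      log=state.log)
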