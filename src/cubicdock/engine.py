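"""Memetic docking optimizer over the six cubic rigid-body parameters.

Each generation runs differential evolution (rand/1/bin), axis sliding,
a Monte-Carlo local search, pairwise selection against the parent, and
occasional backbone trials from the ensemble.  Selection is on the
interface score (Iscore); the square-well bounds penalty keeps the
subsystem representation valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import geometry as geo
from . import symmetry as sym
from .ccs import CCSConfig
from .energy import AssemblyScorer, EnergyConfig
from .structure_io import Assembly, ChainModel
from .symmetry import (
    BoundsSpec,
    RigidBodyParams,
    SymmetryDefinition,
    square_well_penalty,
)

MODES = ("recapitulate", "local", "global")


class EngineError(Exception):
    pass


@dataclass
class DEConfig:
    population_size: int = 100
    generations: int = 50
    mutation_rate: float = 0.1
    recombination_rate: float = 0.7
    bb_trial_probability: float = 0.3
    mc_subroutine_moves: int = 10
    metropolis_temperature: float = 1.0
    seed: int = 0
    slide_step: float = 0.3
    slide_max_steps: int = 100
    packmin_deltas: tuple[float, ...] = (2.0, 0.5)
    packmin_sweeps: int = 2
    final_refine_deltas: tuple[float, ...] = (0.5, 0.125, 0.03)
    final_refine_sweeps: int = 6
    mc_sigma_angles: float = 8.0  # degrees, CCS subroutine proposal width
    mc_sigma_trans: float = 1.0  # A
    global_z_start: float = 80.0

    def __post_init__(self):
        for r in (self.mutation_rate, self.recombination_rate, self.bb_trial_probability):
            if not 0.0 <= r <= 1.0:
                raise EngineError(f"rate {r} outside [0, 1]")


@dataclass
class Individual:
    backbone_id: int
    params: RigidBodyParams
    flipped: bool = False
    iscore: float = math.inf
    ccs_total: float = math.inf


@dataclass
class DockingContext:
    """Shared immutable state for one docking run."""

    sd: SymmetryDefinition
    bounds: BoundsSpec
    cfg: DEConfig
    scorers: dict[int, AssemblyScorer]
    ensemble: list[ChainModel]
    mode: str = "recapitulate"

    def scorer(self, backbone_id: int) -> AssemblyScorer:
        return self.scorers[backbone_id]

    def penalized_iscore(self, ind: Individual) -> float:
        pen = square_well_penalty(ind.params, self.bounds)
        if pen > 0:
            return pen
        return self.scorer(ind.backbone_id).iscore(ind.params, flipped=ind.flipped)

    def evaluate(self, ind: Individual) -> Individual:
        ind.iscore = self.penalized_iscore(ind)
        return ind

    def ccs_total(self, ind: Individual) -> float:
        return self.scorer(ind.backbone_id).ccs_breakdown(
            ind.params, flipped=ind.flipped
        ).total


def make_context(
    ensemble: list[ChainModel],
    sd: SymmetryDefinition,
    mode: str,
    cfg: DEConfig,
    center: RigidBodyParams | None = None,
    ccs_cfg: CCSConfig | None = None,
    energy_cfg: EnergyConfig | None = None,
) -> DockingContext:
    if mode not in MODES:
        raise EngineError(f"unknown mode {mode!r}")
    if not ensemble:
        raise EngineError("empty backbone ensemble")
    center = center or sd.params
    bounds_mode = "global" if mode == "global" else "local"
    bounds = sym.make_bounds(sd, bounds_mode, center=center)
    scorers = {
        i: AssemblyScorer(bb, sd, ccs_cfg=ccs_cfg, cfg=energy_cfg)
        for i, bb in enumerate(ensemble)
    }
    ctx = DockingContext(
        sd=sd, bounds=bounds, cfg=cfg, scorers=scorers, ensemble=ensemble, mode=mode
    )
    # fix the subsystem from a reference placement so every evaluation sees
    # the same interaction partners (integrity is enforced by the bounds)
    ref = center
    if mode == "global":
        ref = replace(center, z=_slide_in_z(ctx, center))
    idx = scorers[0].subsystem_from_params(ref)
    for s in scorers.values():
        s.set_subsystem(idx)
    sd.subsystem_chain_indices = idx
    return ctx


# -- pose/parameter conversion ------------------------------------------------


def _pose_of(params: RigidBodyParams, flipped: bool):
    return sym.placement_transform(params, flipped=flipped)


def _params_from_pose(q: np.ndarray, c: np.ndarray, flipped: bool) -> RigidBodyParams:
    z = float(c[2])
    x = float(math.hypot(c[0], c[1]))
    lam = float(math.degrees(math.atan2(c[1], c[0]))) if x > 1e-9 else 0.0
    e = geo.rot_z(-lam) @ q
    if flipped:
        e = geo.rot_x(180.0) @ e
    psi, theta, phi = geo.matrix_to_euler(e)
    return RigidBodyParams(psi=psi, theta=theta, phi=phi, z=z, x=x, lam=lam)


# -- population ---------------------------------------------------------------


def initialize_population(
    ctx: DockingContext, rng: np.random.Generator
) -> list[Individual]:
    """Uniform parameters within bounds, uniform backbones; in global mode
    z comes from slide-away/slide-in and half the population is flipped."""
    cfg = ctx.cfg
    pop = []
    for i in range(cfg.population_size):
        params = ctx.bounds.sample(rng)
        backbone_id = int(rng.integers(len(ctx.ensemble)))
        flipped = ctx.mode == "global" and i % 2 == 1
        ind = Individual(backbone_id=backbone_id, params=params, flipped=flipped)
        if ctx.mode == "global":
            ind.params = replace(
                params, z=_slide_in_z(ctx, ind.params, ind.flipped, ind.backbone_id)
            )
        pop.append(ctx.evaluate(ind))
    return pop


def _slide_in_z(
    ctx: DockingContext,
    params: RigidBodyParams,
    flipped: bool = False,
    backbone_id: int = 0,
) -> float:
    """Slide away along the setup axis, then back in until first clash."""
    scorer = ctx.scorer(backbone_id)
    step = ctx.cfg.slide_step
    z = ctx.cfg.global_z_start
    while z > step:
        trial = replace(params, z=z - step)
        if scorer.n_clashes(trial, flipped=flipped) > 0:
            break
        z -= step
    return float(z)


# -- differential evolution ---------------------------------------------------


def de_step(
    population: list[Individual], cfg: DEConfig, rng: np.random.Generator
) -> list[Individual]:
    """DE/rand/1/bin trial vector per individual (unevaluated).

    The trial inherits the target's backbone and the base donor's flip
    orientation; at least one parameter always comes from the donor vector.
    """
    if len(population) < 4:
        raise EngineError("differential evolution needs a population of >= 4")
    n = len(population)
    trials = []
    for i, target in enumerate(population):
        others = [j for j in range(n) if j != i]
        a, b, c = rng.choice(others, size=3, replace=False)
        va = population[a].params.as_array()
        vb = population[b].params.as_array()
        vc = population[c].params.as_array()
        donor = va + cfg.mutation_rate * (vb - vc)
        tv = target.params.as_array().copy()
        jrand = int(rng.integers(6))
        for j in range(6):
            if j == jrand or rng.random() < cfg.recombination_rate:
                tv[j] = donor[j]
        trials.append(
            Individual(
                backbone_id=target.backbone_id,
                params=RigidBodyParams.from_array(tv),
                flipped=population[a].flipped,
            )
        )
    return trials


def select(parent: Individual, trial: Individual) -> Individual:
    """Lower Iscore wins; ties keep the parent."""
    return trial if trial.iscore < parent.iscore else parent


# -- sliding ------------------------------------------------------------------


def slide(
    ind: Individual,
    ctx: DockingContext,
    max_steps: int | None = None,
    folds: tuple[int, ...] | None = None,
) -> tuple[Individual, dict[int, int]]:
    """Slide along the symmetric folds from the highest to the lowest.

    For each fold order the nearest fold axis to the main subunit is used;
    the subunit translates toward the assembly center in fixed steps so the
    fold's own ring moves rigidly (its interface stays fixed) while contacts
    to the other interfaces improve.  Sliding along one axis ends at the
    first CCS clash or after the step budget; leaving the parameter bounds
    reverts that axis move.  Returns the slid individual and the number of
    steps attempted per fold.
    """
    cfg = ctx.cfg
    max_steps = cfg.slide_max_steps if max_steps is None else max_steps
    scorer = ctx.scorer(ind.backbone_id)
    steps_taken: dict[int, int] = {}
    params = ind.params
    fold_orders = folds if folds is not None else sym.FOLDS[ctx.sd.kind]
    for fold in sorted(fold_orders, reverse=True):
        axes = sym.setup_fold_axes(ctx.sd.kind, ctx.sd.setup_fold, fold)
        q, c = _pose_of(params, ind.flipped)
        if np.linalg.norm(c) < 1e-9:
            continue
        cn = c / np.linalg.norm(c)
        # nearest axis line, oriented toward the subunit side
        best_axis = max(
            (s * a for a in axes for s in (1.0, -1.0)),
            key=lambda v: float(np.dot(v, cn)),
        )
        start = params
        attempted = 0
        while attempted < max_steps:
            attempted += 1
            c_new = c - cfg.slide_step * best_axis
            p_new = _params_from_pose(q, c_new, ind.flipped)
            if not ctx.bounds.contains(p_new):
                params = start  # revert the whole axis move
                break
            if scorer.n_clashes(p_new, flipped=ind.flipped) > 0:
                break
            c = c_new
            params = p_new
        steps_taken[fold] = attempted
    out = replace(ind, params=params)
    return ctx.evaluate(out), steps_taken


# -- local search -------------------------------------------------------------

_STEP_SCALE = np.array([1.0, 1.0, 1.0, 0.25, 0.25, 0.5])


def _packmin(ind: Individual, ctx: DockingContext) -> Individual:
    """Surrogate packing-minimization: coordinate descent on the Iscore."""
    arr = ind.params.as_array()
    best = ind.iscore
    for delta in ctx.cfg.packmin_deltas:
        steps = delta * _STEP_SCALE
        for _ in range(ctx.cfg.packmin_sweeps):
            improved = False
            for j in range(6):
                for sgn in (1.0, -1.0):
                    cand = arr.copy()
                    cand[j] += sgn * steps[j]
                    trial = replace(
                        ind, params=RigidBodyParams.from_array(cand), iscore=math.inf
                    )
                    s = ctx.penalized_iscore(trial)
                    if s < best - 1e-12:
                        best, arr = s, cand
                        improved = True
                        break
            if not improved:
                break
    return replace(ind, params=RigidBodyParams.from_array(arr), iscore=best)


def _metropolis(delta: float, temperature: float, rng: np.random.Generator) -> bool:
    if delta <= 0:
        return True
    return rng.random() < math.exp(-delta / max(temperature, 1e-9))


def local_search(
    ind: Individual, ctx: DockingContext, rng: np.random.Generator
) -> Individual:
    """Pack-min, then the 10-move CCS-guided rigid-body subroutine, then a
    final pack-min; returns the best-accepted state by Iscore."""
    cfg = ctx.cfg
    if not math.isfinite(ind.iscore):
        ind = ctx.evaluate(ind)
    best = ind
    state = _packmin(ind, ctx)
    if ind.iscore - state.iscore >= ctx.scorer(ind.backbone_id).cfg.improvement_threshold:
        state = _packmin(state, ctx)
    if state.iscore < best.iscore:
        best = state

    scorer = ctx.scorer(ind.backbone_id)
    state.ccs_total = ctx.ccs_total(state)
    for _ in range(cfg.mc_subroutine_moves):
        sa, st = cfg.mc_sigma_angles, cfg.mc_sigma_trans
        perturb = rng.normal(0.0, 1.0, 6) * np.array([sa, sa, sa, st, st, sa / 2.0])
        cand_params = RigidBodyParams.from_array(state.params.as_array() + perturb)
        if not ctx.bounds.contains(cand_params):
            continue
        cand_ccs = scorer.ccs_breakdown(cand_params, flipped=state.flipped).total
        if _metropolis(cand_ccs - state.ccs_total, cfg.metropolis_temperature, rng):
            state = replace(state, params=cand_params, ccs_total=cand_ccs, iscore=math.inf)

    if not math.isfinite(state.iscore):
        state = ctx.evaluate(state)
    state = _packmin(state, ctx)
    if state.iscore < best.iscore:
        best = state
    return best


# -- backbone trials ----------------------------------------------------------


def bb_trial(
    ind: Individual,
    ctx: DockingContext,
    rng: np.random.Generator,
    probability: float | None = None,
) -> Individual:
    """Occasionally swap in another ensemble backbone; keep only on
    Iscore improvement after slide + local search."""
    p = ctx.cfg.bb_trial_probability if probability is None else probability
    if len(ctx.ensemble) < 2 or rng.random() >= p:
        return ind
    choices = [i for i in range(len(ctx.ensemble)) if i != ind.backbone_id]
    new_bb = int(rng.choice(choices))
    cand = replace(ind, backbone_id=new_bb, iscore=math.inf)
    cand = ctx.evaluate(cand)
    cand, _ = slide(cand, ctx)
    cand = local_search(cand, ctx, rng)
    return select(ind, cand)


def perturb_params(
    center: RigidBodyParams,
    ranges,
    rng: np.random.Generator,
    bounds: BoundsSpec | None = None,
) -> RigidBodyParams:
    """Uniform draw in center +- range per parameter, clipped to bounds."""
    ranges = np.asarray(ranges, float)
    arr = center.as_array() + rng.uniform(-ranges, ranges)
    if bounds is not None:
        arr = bounds.clip(arr)
    return RigidBodyParams.from_array(arr)


# -- main loop ----------------------------------------------------------------


@dataclass
class GenerationLog:
    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    @property
    def best_iscores(self) -> list[float]:
        return [r["best_iscore"] for r in self.records]


@dataclass
class DockingResult:
    population: list[Individual]
    archive: list[dict]
    log: GenerationLog

    def best(self) -> Individual:
        return min(self.population, key=lambda ind: ind.iscore)


def run_docking(
    ensemble: list[ChainModel],
    sd: SymmetryDefinition,
    mode: str,
    cfg: DEConfig,
    center: RigidBodyParams | None = None,
    reference: Assembly | None = None,
    run_id: int = 0,
    ccs_cfg: CCSConfig | None = None,
    energy_cfg: EnergyConfig | None = None,
) -> DockingResult:
    """Run the full memetic loop; reproducible for a fixed cfg.seed."""
    ctx = make_context(
        ensemble, sd, mode, cfg, center=center, ccs_cfg=ccs_cfg, energy_cfg=energy_cfg
    )
    rng = np.random.default_rng(cfg.seed)
    pop = initialize_population(ctx, rng)
    for i, ind in enumerate(pop):
        slid, _ = slide(ind, ctx)
        pop[i] = local_search(slid, ctx, rng)
    log = GenerationLog()
    archive: list[dict] = []

    def record(gen: int, individuals: list[Individual]):
        for ind in individuals:
            archive.append(
                {
                    "run_id": run_id,
                    "generation": gen,
                    "backbone_id": ind.backbone_id,
                    "flipped": ind.flipped,
                    "iscore": ind.iscore,
                    "ccs_total": ind.ccs_total,
                    **{
                        name: getattr(ind.params, name)
                        for name in sym.PARAM_NAMES
                    },
                }
            )

    def log_gen(gen: int, accepted: int):
        scores = np.array([ind.iscore for ind in pop])
        entry = {
            "generation": gen,
            "best_iscore": float(scores.min()),
            "mean_iscore": float(scores.mean()),
            "acceptance_rate": accepted / max(len(pop), 1),
        }
        if reference is not None:
            from .evaluation import symmetric_rmsd

            best = pop[int(np.argmin(scores))]
            model = sym.place_and_expand(
                ensemble[best.backbone_id], best.params, sd, flipped=best.flipped
            )
            entry["best_rmsd"] = symmetric_rmsd(
                model, reference, sd.kind, sd.setup_fold
            )
        log.records.append(entry)

    record(0, pop)
    log_gen(0, 0)
    for gen in range(1, cfg.generations + 1):
        trials = de_step(pop, cfg, rng)
        accepted = 0
        for i, trial in enumerate(trials):
            trial = ctx.evaluate(trial)
            trial, _ = slide(trial, ctx)
            trial = local_search(trial, ctx, rng)
            winner = select(pop[i], trial)
            if winner is trial:
                accepted += 1
            winner = bb_trial(winner, ctx, rng)
            pop[i] = winner
        record(gen, pop)
        log_gen(gen, accepted)
    # terminal refinement: fine coordinate descent of the best individual,
    # standing in for the all-atom refinement of the final output model
    best_i = int(np.argmin([ind.iscore for ind in pop]))
    fine = replace(
        cfg,
        packmin_deltas=cfg.final_refine_deltas,
        packmin_sweeps=cfg.final_refine_sweeps,
    )
    fine_ctx = replace(ctx, cfg=fine)
    pop[best_i] = _packmin(pop[best_i], fine_ctx)
    record(cfg.generations + 1, [pop[best_i]])
    log_gen(cfg.generations + 1, 0)
    return DockingResult(population=pop, archive=archive, log=log)
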