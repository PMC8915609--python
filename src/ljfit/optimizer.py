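"""Derivative-free fitting: Nelder-Mead simplex with oriented restarts and
the sequential atom-type adaptation scheduler.

Atom types are never adjusted simultaneously: an :class:`AdaptationSchedule`
orders :class:`FitTask` entries so that each task's data subset only involves
atom types that are already optimized (or declared fixed). Before each task
the evaluator is re-run with the current parameter set to obtain the "ref"
RMSD normalizers of the objective; fitted coefficients are frozen afterwards.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import ParameterSet
from .objective import ObjectiveSpec, objective_Z

logger = logging.getLogger(__name__)

__all__ = [
    "NelderMeadResult",
    "nelder_mead",
    "multi_start",
    "FitTask",
    "AdaptationSchedule",
    "SchedulingError",
    "sequential_fit",
    "gaff_adaptation_order",
    "build_gaff_schedule",
]


class SchedulingError(ValueError):
    pass


@dataclass
class NelderMeadResult:
    x_best: np.ndarray
    f_best: float
    n_eval: int
    n_iter: int
    converged: bool
    trace: list[tuple[int, float]] = field(default_factory=list)


def _project(x: np.ndarray, bounds) -> np.ndarray:
    if bounds is None:
        return x
    lo = np.asarray([b[0] for b in bounds], dtype=float)
    hi = np.asarray([b[1] for b in bounds], dtype=float)
    return np.clip(x, lo, hi)


def nelder_mead(
    f,
    x0,
    initial_scale: float = 0.1,
    orientation=None,
    tol: float = 1e-3,
    diameter_tol: float = 1e-4,
    max_iter: int = 2000,
    bounds=None,
    seed: int | None = None,
) -> NelderMeadResult:
    """Downhill simplex minimization (reflection 1, expansion 2,
    contraction 0.5, shrink 0.5).

    The initial simplex offsets each coordinate by ``initial_scale *
    max(|x0_i|, 1) * orientation_i``; ``orientation`` is a vector of +-1
    signs. Bounds are enforced by projection onto the box. Convergence:
    f-spread below ``tol * (1 + |f_best|)`` and simplex diameter (in
    coordinates scaled by the initial point) below ``diameter_tol``.
    Deterministic for fixed inputs; ``seed`` is accepted for interface
    symmetry but unused.
    """
    x0 = np.asarray(x0, dtype=float)
    dim = len(x0)
    if dim < 1:
        raise ValueError("dimension must be >= 1")
    orient = (
        np.ones(dim) if orientation is None else np.asarray(orientation, dtype=float)
    )
    scale_ref = np.maximum(np.abs(x0), 1.0)

    simplex = [_project(x0.copy(), bounds)]
    for i in range(dim):
        x = x0.copy()
        x[i] += initial_scale * scale_ref[i] * orient[i]
        simplex.append(_project(x, bounds))
    simplex = np.asarray(simplex)
    n_eval = 0

    def call(x):
        nonlocal n_eval
        n_eval += 1
        return float(f(x))

    fvals = np.asarray([call(x) for x in simplex])
    trace: list[tuple[int, float]] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        order = np.argsort(fvals, kind="stable")
        simplex, fvals = simplex[order], fvals[order]
        trace.append((n_eval, float(fvals[0])))
        spread = fvals[-1] - fvals[0]
        diam = np.max(
            np.abs(simplex - simplex[0]) / scale_ref[np.newaxis, :]
        )
        if spread < tol * (1.0 + abs(fvals[0])) and diam < diameter_tol:
            converged = True
            break
        centroid = simplex[:-1].mean(axis=0)
        worst = simplex[-1]
        xr = _project(centroid + 1.0 * (centroid - worst), bounds)
        fr = call(xr)
        if fr < fvals[0]:
            xe = _project(centroid + 2.0 * (centroid - worst), bounds)
            fe = call(xe)
            if fe < fr:
                simplex[-1], fvals[-1] = xe, fe
            else:
                simplex[-1], fvals[-1] = xr, fr
        elif fr < fvals[-2]:
            simplex[-1], fvals[-1] = xr, fr
        else:
            xc = _project(centroid + 0.5 * (worst - centroid), bounds)
            fc = call(xc)
            if fc < fvals[-1]:
                simplex[-1], fvals[-1] = xc, fc
            else:  # shrink toward the best vertex
                for i in range(1, dim + 1):
                    simplex[i] = _project(
                        simplex[0] + 0.5 * (simplex[i] - simplex[0]), bounds
                    )
                    fvals[i] = call(simplex[i])
    order = np.argsort(fvals, kind="stable")
    return NelderMeadResult(
        x_best=simplex[order[0]].copy(),
        f_best=float(fvals[order[0]]),
        n_eval=n_eval,
        n_iter=it,
        converged=converged,
        trace=trace,
    )


def _default_orientations(dim: int, n: int, seed: int) -> list[np.ndarray]:
    """Deterministic sequence of sign vectors: sign-pattern enumeration first,
    random +-1 vectors beyond 2^dim."""
    out: list[np.ndarray] = []
    for signs in itertools.product((1.0, -1.0), repeat=dim):
        out.append(np.asarray(signs))
        if len(out) >= n:
            return out
    rng = np.random.default_rng(seed)
    while len(out) < n:
        out.append(rng.choice([-1.0, 1.0], size=dim))
    return out


def multi_start(
    f,
    x0,
    n_restarts: int = 4,
    orientations=None,
    seed: int = 0,
    **nm_kwargs,
) -> NelderMeadResult:
    """Run Nelder-Mead from differently oriented initial simplices; return
    the best result over all restarts."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    x0 = np.asarray(x0, dtype=float)
    if orientations is None:
        orientations = _default_orientations(len(x0), n_restarts, seed)
    best: NelderMeadResult | None = None
    for orient in orientations[:n_restarts]:
        res = nelder_mead(f, x0, orientation=orient, **nm_kwargs)
        if best is None or res.f_best < best.f_best:
            best = res
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# fit tasks and the sequential scheduler
# ---------------------------------------------------------------------------


@dataclass
class FitTask:
    """One optimization step: adapt one atom type's coefficients.

    ``kind`` selects the coefficient pair: ``"self"`` fits (epsilon, sigma)
    of ``target_type``; ``"water-interaction"`` fits the (xi, zeta) override
    of ``target_type`` against ``water_type``. ``subset_ids`` selects the
    reference systems entering the objective; ``requires`` lists atom types
    that must already be optimized or fixed.
    """

    name: str
    target_type: str
    kind: str = "self"
    water_type: str | None = None
    subset_ids: tuple[str, ...] = ()
    requires: tuple[str, ...] = ()
    x0: tuple[float, ...] | None = None
    bounds: tuple[tuple[float, float], ...] | None = None
    w_dG: float = 1.0
    w_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("self", "water-interaction"):
            raise ValueError(f"unknown task kind {self.kind!r}")
        if self.kind == "water-interaction" and not self.water_type:
            raise ValueError("water-interaction tasks need a water_type")
        if self.bounds is not None:
            for lo, hi in self.bounds:
                if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                    raise ValueError("bounds must be finite with lower < upper")


def default_self_bounds(eps0: float, sig0: float):
    """+-50 % of the initial epsilon, +-20 % of the initial sigma."""
    return (
        (0.5 * eps0, 1.5 * eps0),
        (0.8 * sig0, 1.2 * sig0),
    )


XI_ZETA_BOUNDS = ((-0.5, 0.5), (-0.5, 0.5))


@dataclass
class AdaptationSchedule:
    """Ordered fit tasks with prerequisite validation."""

    tasks: list[FitTask]
    fixed_types: tuple[str, ...] = ()

    def validate(self) -> None:
        """Every task may only require types fitted earlier or fixed."""
        done = set(self.fixed_types)
        for task in self.tasks:
            missing = set(task.requires) - done
            if missing:
                raise SchedulingError(
                    f"task {task.name!r} requires unoptimized, unfixed types: "
                    f"{sorted(missing)}"
                )
            done.add(task.target_type)

    @property
    def target_types(self) -> list[str]:
        """Distinct target atom types in first-appearance order."""
        seen: list[str] = []
        for task in self.tasks:
            if task.target_type not in seen:
                seen.append(task.target_type)
        return seen


def sequential_fit(
    schedule: AdaptationSchedule,
    evaluator,
    params0: ParameterSet,
    n_restarts: int = 4,
    seed: int = 0,
    halt_on_error: bool = True,
    nm_kwargs: dict | None = None,
):
    """Execute the schedule task by task, freezing parameters as fitted.

    ``evaluator(params, subset_ids) -> (rmsd_dG, rmsd_rho)`` supplies the
    objective ingredients (either may be None when its weight is zero). Each
    task first re-evaluates the reference RMSDs with the current parameter
    set, then minimizes the RMSD-ratio objective over the task's two
    coefficients. Returns ``(fitted ParameterSet, per-task report list)``.
    """
    schedule.validate()
    nm_kwargs = dict(nm_kwargs or {})
    params = params0.with_updates(label=f"{params0.label}+fit")
    reports: list[dict] = []
    for ti, task in enumerate(schedule.tasks):
        try:
            ref_dg, ref_rho = evaluator(params, task.subset_ids)
            spec = ObjectiveSpec(
                w_dG=task.w_dG,
                w_rho=task.w_rho,
                rmsd_dG_ref=ref_dg if ref_dg else 1.0,
                rmsd_rho_ref=ref_rho if ref_rho else 1.0,
            )

            if task.kind == "self":
                t = params.get_type(task.target_type)
                x0 = np.asarray(task.x0 or (t.epsilon, t.sigma), dtype=float)
                bounds = task.bounds or default_self_bounds(*x0)

                def apply(x, _task=task):
                    return params.with_updates(
                        type_updates={_task.target_type: (x[0], x[1])}
                    )

            else:
                o = params.get_override(task.target_type, task.water_type)
                x0 = np.asarray(
                    task.x0 or ((o.xi, o.zeta) if o else (0.0, 0.0)), dtype=float
                )
                bounds = task.bounds or XI_ZETA_BOUNDS

                def apply(x, _task=task):
                    return params.with_updates(
                        override_updates={
                            (_task.target_type, _task.water_type): (x[0], x[1])
                        }
                    )

            def objective(x):
                rmsd_dg, rmsd_rho = evaluator(apply(x), task.subset_ids)
                return objective_Z(rmsd_dg, rmsd_rho, spec)

            result = multi_start(
                objective,
                x0,
                n_restarts=n_restarts,
                seed=seed + ti,
                bounds=bounds,
                **nm_kwargs,
            )
            params = apply(result.x_best)
            reports.append(
                {
                    "task": task.name,
                    "target_type": task.target_type,
                    "kind": task.kind,
                    "x0": list(map(float, x0)),
                    "x_best": [float(v) for v in result.x_best],
                    "Z_ref": objective_Z(
                        ref_dg if task.w_dG else None,
                        ref_rho if task.w_rho else None,
                        spec,
                    ),
                    "Z_best": result.f_best,
                    "n_eval": result.n_eval,
                    "converged": result.converged,
                    "status": "ok",
                }
            )
            logger.info(
                "task %s: Z %.4g -> %.4g (%d evals)",
                task.name,
                reports[-1]["Z_ref"],
                result.f_best,
                result.n_eval,
            )
        except Exception as exc:  # noqa: BLE001 - task isolation by contract
            reports.append({"task": task.name, "status": "error", "error": str(exc)})
            logger.error("task %s failed: %s", task.name, exc)
            if halt_on_error:
                raise
    return params, reports


# ---------------------------------------------------------------------------
# the published adaptation order
# ---------------------------------------------------------------------------

#: Adaptation order of the 21 refitted atom types: sp3 ring carbon first,
#: then acyclic sp3 carbon, aromatic carbon with the alcohol oxygen, the
#: phenol-oxygen split (ohP), the chain/end-carbon split (c3 / c3E), ethers
#: and chlorine, aromatic and heteroaromatic nitrogens, carbonyl chemistry
#: with the ester-oxygen split (osE), amides and nitriles, bromine, amines,
#: and finally fluorine and iodine.
GAFF_ADAPTATION_ORDER: tuple[str, ...] = (
    "c3R",
    "c3",
    "ca",
    "oh",
    "ohP",
    "c3E",
    "os",
    "cl",
    "nb",
    "c2",
    "c",
    "na",
    "o",
    "osE",
    "n",
    "n1",
    "c1",
    "br",
    "nh",
    "f",
    "i",
)

#: GAFF equivalence classes folded onto one canonical type each.
GAFF_ALIASES: dict[str, str] = {
    "cc": "ca",
    "cd": "ca",
    "ce": "ca",
    "cg": "c1",
    "n2": "nb",
    "n3": "nh",
}


def gaff_adaptation_order() -> tuple[str, ...]:
    """The sequential adaptation order of the refitted atom types."""
    return GAFF_ADAPTATION_ORDER


def build_gaff_schedule(
    water_types: tuple[str, ...] = ("OW_tip3p", "OW_tip4p2005"),
    include_water_tasks: bool = True,
) -> AdaptationSchedule:
    """Schedule skeleton following the published adaptation order.

    Each atom type gets a self-parameter task plus, when enabled, one
    (xi, zeta) water-interaction task per water model; prerequisites chain
    each type to all previously adapted ones.
    """
    tasks: list[FitTask] = []
    done: list[str] = []
    for name in GAFF_ADAPTATION_ORDER:
        tasks.append(
            FitTask(
                name=f"self:{name}",
                target_type=name,
                kind="self",
                requires=tuple(done),
            )
        )
        if include_water_tasks:
            for wt in water_types:
                tasks.append(
                    FitTask(
                        name=f"water:{name}:{wt}",
                        target_type=name,
                        kind="water-interaction",
                        water_type=wt,
                        requires=tuple(done),
                        w_dG=1.0,
                        w_rho=0.0,
                    )
                )
        done.append(name)
    schedule = AdaptationSchedule(tasks=tasks, fixed_types=tuple(water_types))
    schedule.validate()
    return schedule
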