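"""Seeded synthetic libraries: toy molecules, systems and reference datasets
with known ground-truth parameters.

The generated library supports the full fit-evaluate loop offline:

* a roster of target atom types with truth parameters drawn from documented
  ranges (epsilon in [0.2, 1.2] kJ/mol, sigma in [0.25, 0.45] nm) plus fixed
  solvent types including a designated water-like solvent (``watO``) so
  (xi, zeta) water-interaction tasks are exercisable,
* solvation systems (solute in solvent) probing each target type in at least
  two distinct solvent environments, plus diatomic "chain" molecules that
  couple consecutive types and exercise the scheduler's prerequisite logic,
* pure-liquid density systems over >= 3 temperatures,
* a deterministic reference engine whose solvation free energies come from
  Widom insertion into cached solvent-only trajectories (the solvent
  trajectory is independent of solute parameters, so the objective surface
  is smooth and noise-free) and whose densities come from NPT runs.

``synthesize_reference`` evaluates everything at the truth parameters and
adds homoscedastic Gaussian noise per :class:`NoiseSpec`; with zero noise a
re-run at truth reproduces the reference exactly (same derived seeds).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .forcefield import (
    AtomTypeDef,
    InteractionOverride,
    MoleculeSpec,
    ParameterSet,
    SiteSpec,
    SystemSpec,
)
from .objective import ReferenceDataset, error_stats
from .optimizer import AdaptationSchedule, FitTask
from .toysim import SimSettings, TrajectoryStats, run_nvt, run_npt_density, widom_mu_excess

__all__ = [
    "NoiseSpec",
    "ToyLibrary",
    "build_toy_library",
    "ToyReferenceEngine",
    "synthesize_reference",
    "make_evaluator",
    "default_engine_settings",
]

GROUP_CYCLE = ("alkane", "alcohol", "ether", "halogen", "amine", "arene")

#: fixed (never fitted) solvent types: name -> (epsilon, sigma, molar mass).
#: Well depths keep every solvent state point supercritical (T* ~ 1.4-1.5),
#: well away from the LJ two-phase region where free-energy estimators
#: converge poorly at toy scale.
SOLVENT_TYPES = {
    "solvA": (1.70, 0.340, 40.0),
    "solvB": (1.55, 0.300, 32.0),
    "watO": (1.80, 0.316, 18.0),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Homoscedastic Gaussian noise added to synthetic reference values."""

    sd_dG: float = 0.0
    sd_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_dG < 0 or self.sd_rho < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class ToyLibrary:
    """Atom types with truth parameters, molecules, systems and fit tasks."""

    truth: ParameterSet
    start: ParameterSet
    molecules: dict[str, MoleculeSpec]
    systems: dict[str, SystemSpec]
    system_properties: dict[str, str]  # system id -> "dGsolv" | "density"
    schedule: AdaptationSchedule
    target_types: list[str]
    seed: int

    def validate(self) -> None:
        for mol in self.molecules.values():
            for site in mol.sites:
                if self.truth.resolve(site.type_name) not in self.truth.types:
                    raise ValueError(
                        f"molecule {mol.name} uses undefined type {site.type_name}"
                    )
        for task in self.schedule.tasks:
            if not task.subset_ids:
                raise ValueError(f"fit task {task.name} has an empty subset")
        self.schedule.validate()
        temps = {
            s.temperature
            for sid, s in self.systems.items()
            if self.system_properties[sid] == "density"
        }
        if len(temps) < 3:
            raise ValueError("density systems must span at least 3 temperatures")


def _stable_seed(*parts) -> int:
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "little")


def _liquid_box(sigma: float, n: int, reduced_density: float = 0.62) -> float:
    return (n * sigma**3 / reduced_density) ** (1.0 / 3.0)


def default_engine_settings(seed: int = 0) -> SimSettings:
    """Desk-scale protocol: short equilibration, ~120 stored frames."""
    return SimSettings(
        n_steps=10500,
        equil_steps=3300,
        r_cut=1.2,
        tail_correction=False,
        max_displacement=0.09,
        sample_interval=60,
        seed=seed,
        n_blocks=5,
    )


def build_toy_library(n_types: int = 3, seed: int = 0) -> ToyLibrary:
    """Deterministic toy library with ``n_types`` fit targets.

    Every target type gets: a monatomic solute molecule, solvation systems in
    two ordinary solvents plus two water-like state points, and a self fit
    task followed by a water-interaction task. Types beyond the first also
    appear in a diatomic chain molecule whose systems enter the next type's
    subset, creating real scheduler prerequisites.
    """
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA11B)))

    truth = ParameterSet(label=f"toy-truth-seed{seed}")
    for name, (eps, sig, _mass) in SOLVENT_TYPES.items():
        truth.add_type(AtomTypeDef(name, eps, sig, "fixed solvent type"))
    target_types = []
    for i in range(n_types):
        name = f"t{i}"
        eps = float(rng.uniform(0.2, 1.2))
        sig = float(rng.uniform(0.25, 0.45))
        truth.add_type(AtomTypeDef(name, eps, sig, f"toy target type {i}"))
        target_types.append(name)
    # truth water-interaction modifiers for each target type
    for i, name in enumerate(target_types):
        xi = float(rng.uniform(-0.15, 0.15))
        zeta = float(rng.uniform(-0.05, 0.05))
        truth.add_override(InteractionOverride(name, "watO", xi, zeta))

    # perturbed starting parameters: +20 % epsilon, +5 % sigma, zero overrides
    start = ParameterSet(label=f"toy-start-seed{seed}", aliases=dict(truth.aliases))
    for name, t in truth.types.items():
        if name in SOLVENT_TYPES:
            start.add_type(t)
        else:
            start.add_type(replace(t, epsilon=1.2 * t.epsilon, sigma=1.05 * t.sigma))
    for name in target_types:
        start.add_override(InteractionOverride(name, "watO", 0.0, 0.0))

    molecules: dict[str, MoleculeSpec] = {}
    for name, (_eps, sig, mass) in SOLVENT_TYPES.items():
        molecules[name] = MoleculeSpec(
            name=name,
            sites=(SiteSpec(name),),
            group_tags=("water",) if name == "watO" else ("solvent",),
            molar_mass=mass,
        )
    for i, name in enumerate(target_types):
        molecules[f"mono_{name}"] = MoleculeSpec(
            name=f"mono_{name}",
            sites=(SiteSpec(name),),
            group_tags=(GROUP_CYCLE[i % len(GROUP_CYCLE)],),
            molar_mass=30.0 + 5.0 * i,
        )
        if i >= 1:
            prev = target_types[i - 1]
            bond = 0.55 * (truth.types[prev].sigma + truth.types[name].sigma)
            molecules[f"chain_{prev}_{name}"] = MoleculeSpec(
                name=f"chain_{prev}_{name}",
                sites=(SiteSpec(prev), SiteSpec(name)),
                group_tags=("chain",),
                geometry=((0.0, 0.0, 0.0), (bond, 0.0, 0.0)),
                molar_mass=55.0 + 5.0 * i,
            )

    n_solvent = 60
    systems: dict[str, SystemSpec] = {}
    props: dict[str, str] = {}

    def add_solvation(sid, solute_mol, solvent_name, temperature):
        solvent = molecules[solvent_name]
        sig = truth.types[solvent_name].sigma
        systems[sid] = SystemSpec(
            name=sid,
            molecules=(
                (solute_mol, 1, "solute"),
                (solvent, n_solvent, "solvent"),
            ),
            temperature=temperature,
            box_edge=_liquid_box(sig, n_solvent),
        )
        props[sid] = "dGsolv"

    tasks: list[FitTask] = []
    done: list[str] = []
    for i, name in enumerate(target_types):
        mono = molecules[f"mono_{name}"]
        self_subset = [f"dg:{name}:solvA", f"dg:{name}:solvB"]
        add_solvation(f"dg:{name}:solvA", mono, "solvA", 300.0)
        add_solvation(f"dg:{name}:solvB", mono, "solvB", 280.0)
        requires: list[str] = []
        if i >= 1:
            prev = target_types[i - 1]
            chain = molecules[f"chain_{prev}_{name}"]
            sid = f"dg:chain_{prev}_{name}:solvA"
            add_solvation(sid, chain, "solvA", 310.0)
            self_subset.append(sid)
            requires.append(prev)
        tasks.append(
            FitTask(
                name=f"self:{name}",
                target_type=name,
                kind="self",
                subset_ids=tuple(self_subset),
                requires=tuple(requires),
                w_dG=1.0,
                w_rho=0.0,
            )
        )
        water_subset = [f"dg:{name}:watO300", f"dg:{name}:watO330"]
        add_solvation(f"dg:{name}:watO300", mono, "watO", 300.0)
        add_solvation(f"dg:{name}:watO330", mono, "watO", 330.0)
        tasks.append(
            FitTask(
                name=f"water:{name}",
                target_type=name,
                kind="water-interaction",
                water_type="watO",
                subset_ids=tuple(water_subset),
                requires=tuple(requires) + (name,),
                w_dG=1.0,
                w_rho=0.0,
            )
        )
        done.append(name)

    for solvent_name, temps in (
        ("solvA", (280.0, 300.0, 320.0)),
        ("solvB", (260.0, 280.0, 300.0)),
    ):
        sig = truth.types[solvent_name].sigma
        for temp in temps:
            sid = f"rho:{solvent_name}:{int(temp)}"
            systems[sid] = SystemSpec(
                name=sid,
                molecules=((molecules[solvent_name], n_solvent, "solvent"),),
                temperature=temp,
                pressure=200.0,  # bar; keeps the toy liquid bound
                box_edge=_liquid_box(sig, n_solvent),
            )
            props[sid] = "density"

    schedule = AdaptationSchedule(
        tasks=tasks, fixed_types=tuple(SOLVENT_TYPES)
    )
    library = ToyLibrary(
        truth=truth,
        start=start,
        molecules=molecules,
        systems=systems,
        system_properties=props,
        schedule=schedule,
        target_types=target_types,
        seed=seed,
    )
    library.validate()
    return library


class ToyReferenceEngine:
    """Deterministic property engine over a toy library.

    Solvation free energies: Widom insertion into cached solvent-only NVT
    trajectories; the cache key ignores solute parameters, so re-evaluating
    a system under candidate parameters reuses identical configurations and
    insertion points — the parameter -> objective map is smooth and exactly
    zero-residual at the truth parameters.

    Densities: seeded NPT runs (these do depend on the parameters used).
    """

    def __init__(
        self,
        library: ToyLibrary,
        settings: SimSettings | None = None,
        n_insertions: int = 144,
    ) -> None:
        self.library = library
        self.settings = settings or default_engine_settings(seed=library.seed)
        self.n_insertions = n_insertions
        self._solvent_cache: dict[tuple, TrajectoryStats] = {}

    def _solvent_stats(self, system: SystemSpec) -> TrajectoryStats:
        (solvent, count), = system.solvents
        key = (solvent.name, count, round(system.temperature, 6), system.box_edge)
        if key not in self._solvent_cache:
            solvent_only = SystemSpec(
                name=f"solvent:{solvent.name}",
                molecules=((solvent, count, "solvent"),),
                temperature=system.temperature,
                box_edge=system.box_edge,
            )
            settings = replace(
                self.settings, seed=_stable_seed(self.settings.seed, *key)
            )
            # solvent types are fixed: truth vs start parameters coincide here
            self._solvent_cache[key] = run_nvt(
                solvent_only, self.library.truth, settings
            )
        return self._solvent_cache[key]

    def dg_solv(self, system_id: str, params: ParameterSet) -> float:
        system = self.library.systems[system_id]
        if system.solute is None:
            raise ValueError(f"{system_id} is not a solvation system")
        stats = self._solvent_stats(system)
        return widom_mu_excess(
            stats,
            system.solute,
            params,
            self.settings,
            n_insertions=self.n_insertions,
            seed=_stable_seed(self.settings.seed, "widom", system_id),
        )

    def density(self, system_id: str, params: ParameterSet) -> float:
        system = self.library.systems[system_id]
        settings = replace(
            self.settings,
            seed=_stable_seed(self.settings.seed, "rho", system_id),
            tail_correction=True,
        )
        rho, _sem, _stats = run_npt_density(system, params, settings)
        return rho

    def evaluate(self, system_id: str, params: ParameterSet) -> float:
        if self.library.system_properties[system_id] == "dGsolv":
            return self.dg_solv(system_id, params)
        return self.density(system_id, params)


def synthesize_reference(
    library: ToyLibrary,
    settings: SimSettings | None = None,
    noise: NoiseSpec = NoiseSpec(),
    engine: ToyReferenceEngine | None = None,
    system_ids=None,
) -> ReferenceDataset:
    """Run the engine at truth parameters and record noisy "experimental" rows."""
    engine = engine or ToyReferenceEngine(library, settings)
    rng = np.random.default_rng(np.random.SeedSequence((noise.seed, 0x5EF)))
    rows = []
    ids = list(system_ids) if system_ids is not None else list(library.systems)
    for sid in ids:
        system = library.systems[sid]
        prop = library.system_properties[sid]
        try:
            value = engine.evaluate(sid, library.truth)
        except Exception as exc:
            raise RuntimeError(f"engine failure for system {sid}") from exc
        sd = noise.sd_dG if prop == "dGsolv" else noise.sd_rho
        noisy = value + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        solute = system.solute
        rows.append(
            {
                "system_id": sid,
                "property": prop,
                "experimental": noisy,
                "simulated": np.nan,
                "solute_group": solute.group_tags[0] if solute else "none",
                "solvent_group": system.solvents[0][0].group_tags[0],
                "temperature": system.temperature,
            }
        )
    return ReferenceDataset(pd.DataFrame(rows))


def make_evaluator(engine: ToyReferenceEngine, reference: ReferenceDataset):
    """Adapter: ``evaluator(params, subset_ids) -> (rmsd_dG, rmsd_rho)``.

    Either RMSD is None when the subset has no entries for that property.
    """
    exp_by_id = dict(
        zip(reference.frame["system_id"], reference.frame["experimental"])
    )

    def evaluator(params: ParameterSet, subset_ids):
        ids = list(subset_ids) if subset_ids else list(exp_by_id)
        diffs: dict[str, list[tuple[float, float]]] = {"dGsolv": [], "density": []}
        for sid in ids:
            prop = engine.library.system_properties[sid]
            diffs[prop].append((engine.evaluate(sid, params), exp_by_id[sid]))
        out = []
        for prop in ("dGsolv", "density"):
            if diffs[prop]:
                sim, exp = zip(*diffs[prop])
                out.append(error_stats(sim, exp)[0])
            else:
                out.append(None)
        return tuple(out)

    return evaluator
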