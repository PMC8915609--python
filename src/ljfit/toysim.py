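"""Desk-scale Metropolis Monte Carlo engine for rigid LJ / point-charge fluids.

The engine stands in for a production MD code at toy system sizes: it samples
NVT and NPT ensembles of rigid molecules in periodic cubic boxes, with
truncated Lennard-Jones interactions (optional analytic tail correction) and
truncated-and-shifted Coulomb electrostatics (no Ewald — the default test
systems are neutral, so the electrostatic approximation never drives any
quantitative check).

Conventions
-----------
* one "step" = one attempted Monte Carlo move (molecule displacement /
  rotation, or a volume move in ln V for NPT),
* energies kJ/mol, lengths nm, pressure bar, density kg/m^3,
* fixed seed => bit-identical trajectory.

A pluggable ``solute_pair_fn`` hook lets the alchemy layer replace the
solute-solvent LJ interaction with a softcore form without this module
knowing anything about coupling schedules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import BAR_NM3_TO_KJ_PER_MOL, COULOMB_K, N_AVOGADRO, R_GAS
from .forcefield import MoleculeSpec, ParameterSet, SystemSpec

__all__ = [
    "Configuration",
    "SimSettings",
    "TrajectoryStats",
    "ParticleSystem",
    "build_particle_system",
    "total_energy",
    "run_nvt",
    "run_npt_density",
    "widom_mu_excess",
    "metropolis_accept",
    "effective_r_cut",
]


class GeometryError(ValueError):
    """Cutoff / box incompatibility."""


class EstimationError(RuntimeError):
    """No samples available for the requested estimate."""


@dataclass
class Configuration:
    """A snapshot: site positions (n_sites, 3) in nm plus the box edge."""

    positions: np.ndarray
    box_edge: float

    def wrapped(self) -> "Configuration":
        return Configuration(np.mod(self.positions, self.box_edge), self.box_edge)


@dataclass
class SimSettings:
    """Monte Carlo protocol settings.

    ``temperature`` / ``pressure`` override the system's values when set.
    ``r_cut`` is clamped at run time to ``0.495 * box_edge`` (the scaled-down
    analogue of the production 1.2 nm cutoff for small toy boxes).
    """

    n_steps: int = 20000
    equil_steps: int = 4000
    r_cut: float = 1.2
    tail_correction: bool = True
    max_displacement: float = 0.08
    max_rotation: float = 0.5
    volume_move_scale: float = 0.04
    volume_move_freq: float | None = None
    sample_interval: int = 50
    seed: int = 0
    n_blocks: int = 5
    temperature: float | None = None
    pressure: float | None = None

    def __post_init__(self) -> None:
        if not self.n_steps > self.equil_steps >= 0:
            raise ValueError("need n_steps > equil_steps >= 0")
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")


@dataclass
class TrajectoryStats:
    """Recorded production-phase samples and acceptance bookkeeping."""

    energies: np.ndarray
    volumes: np.ndarray
    densities: np.ndarray
    acceptance: dict[str, float]
    configurations: list[Configuration]
    site_type_names: list[str]
    site_charges: np.ndarray
    temperature: float
    total_mass_g: float
    sample_interval: int

    @property
    def n_samples(self) -> int:
        return len(self.energies)


def effective_r_cut(r_cut: float, box_edge: float) -> float:
    """Clamp the cutoff to just under half the box edge."""
    return min(r_cut, 0.495 * box_edge)


def metropolis_accept(delta_w: float, beta: float, rng: np.random.Generator) -> bool:
    """Standard Metropolis rule min(1, exp(-beta * delta_w))."""
    if delta_w <= 0.0:
        return True
    return rng.random() < math.exp(-beta * delta_w)


# ---------------------------------------------------------------------------
# flattened particle system
# ---------------------------------------------------------------------------


@dataclass
class ParticleSystem:
    """Flattened site arrays for one SystemSpec under one ParameterSet."""

    spec: SystemSpec
    type_names: list[str]
    eps_table: np.ndarray  # (n_types, n_types) combined epsilon
    sig_table: np.ndarray  # (n_types, n_types) combined sigma
    site_type: np.ndarray  # (n_sites,) int
    site_charge: np.ndarray  # (n_sites,)
    site_mol: np.ndarray  # (n_sites,) int
    mol_slices: list[slice]
    mol_geometry: list[np.ndarray | None]
    solute_mol: int | None
    total_mass_g: float
    site_type_labels: list[str] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.site_type)

    @property
    def n_mol(self) -> int:
        return len(self.mol_slices)

    @property
    def has_charges(self) -> bool:
        return bool(np.any(self.site_charge != 0.0))


def build_particle_system(system: SystemSpec, params: ParameterSet) -> ParticleSystem:
    """Expand a SystemSpec into flat site arrays plus combined pair tables."""
    type_names: list[str] = []
    for mol, _, _ in system.molecules:
        for site in mol.sites:
            cname = params.resolve(site.type_name)
            if cname not in type_names:
                type_names.append(cname)
    n_t = len(type_names)
    eps_table = np.zeros((n_t, n_t))
    sig_table = np.ones((n_t, n_t))
    for a in range(n_t):
        for b in range(n_t):
            eps_table[a, b], sig_table[a, b] = params.pair_parameters(
                type_names[a], type_names[b]
            )

    site_type: list[int] = []
    site_charge: list[float] = []
    site_mol: list[int] = []
    mol_slices: list[slice] = []
    mol_geometry: list[np.ndarray | None] = []
    solute_mol: int | None = None
    total_mass = 0.0
    labels: list[str] = []
    mol_idx = 0
    for mol, count, role in system.molecules:
        for _ in range(count):
            start = len(site_type)
            for site in mol.sites:
                site_type.append(type_names.index(params.resolve(site.type_name)))
                site_charge.append(site.charge)
                site_mol.append(mol_idx)
                labels.append(params.resolve(site.type_name))
            mol_slices.append(slice(start, len(site_type)))
            geo = (
                np.asarray(mol.geometry, dtype=float)
                if mol.geometry is not None
                else None
            )
            mol_geometry.append(geo)
            if role == "solute":
                solute_mol = mol_idx
            total_mass += mol.molar_mass
            mol_idx += 1

    return ParticleSystem(
        spec=system,
        type_names=type_names,
        eps_table=eps_table,
        sig_table=sig_table,
        site_type=np.asarray(site_type, dtype=np.intp),
        site_charge=np.asarray(site_charge, dtype=float),
        site_mol=np.asarray(site_mol, dtype=np.intp),
        mol_slices=mol_slices,
        mol_geometry=mol_geometry,
        solute_mol=solute_mol,
        total_mass_g=total_mass,
        site_type_labels=labels,
    )


# ---------------------------------------------------------------------------
# energy evaluation
# ---------------------------------------------------------------------------


def _minimum_image(delta: np.ndarray, box: float) -> np.ndarray:
    return delta - box * np.round(delta / box)


def _lj_sum(eps: np.ndarray, sig: np.ndarray, r2: np.ndarray, rc2: float) -> float:
    mask = r2 < rc2
    if not np.any(mask):
        return 0.0
    sr6 = (sig[mask] ** 2 / r2[mask]) ** 3
    return float(np.sum(4.0 * eps[mask] * (sr6 * sr6 - sr6)))


def _coulomb_sum(
    qq: np.ndarray, r2: np.ndarray, rc: float
) -> float:
    """Truncated-and-shifted Coulomb: k q_i q_j (1/r - 1/rc) inside rc."""
    mask = (r2 < rc * rc) & (qq != 0.0)
    if not np.any(mask):
        return 0.0
    r = np.sqrt(r2[mask])
    return float(COULOMB_K * np.sum(qq[mask] * (1.0 / r - 1.0 / rc)))


def _tail_coeff(psys: ParticleSystem, r_cut: float, exclude_solute: bool) -> float:
    """C such that U_tail = C / V; U_tail = (8 pi / 3 V) sum_ab N_a N_b eps sig^3
    [ (1/3)(sig/rc)^9 - (sig/rc)^3 ]."""
    if exclude_solute and psys.solute_mol is not None:
        mask = psys.site_mol != psys.solute_mol
    else:
        mask = np.ones(psys.n_sites, dtype=bool)
    counts = np.bincount(
        psys.site_type[mask], minlength=len(psys.type_names)
    ).astype(float)
    coeff = 0.0
    for a in range(len(psys.type_names)):
        for b in range(len(psys.type_names)):
            eps = psys.eps_table[a, b]
            if eps == 0.0:
                continue
            sig = psys.sig_table[a, b]
            sr3 = (sig / r_cut) ** 3
            coeff += counts[a] * counts[b] * eps * sig**3 * (sr3**3 / 3.0 - sr3)
    return (8.0 * math.pi / 3.0) * coeff


class MCEngine:
    """Metropolis sampler over rigid-molecule configurations.

    ``solute_pair_fn(eps, sig, r2) -> energies`` replaces the LJ interaction
    for solute-solvent pairs when set (used for alchemical coupling);
    ``solute_charge_scale`` scales solute-solvent Coulomb terms.
    """

    def __init__(
        self,
        psys: ParticleSystem,
        box_edge: float,
        settings: SimSettings,
        rng: np.random.Generator,
        npt: bool = False,
        solute_pair_fn=None,
        solute_charge_scale: float = 1.0,
    ) -> None:
        self.psys = psys
        self.box = float(box_edge)
        self.settings = settings
        self.rng = rng
        self.npt = npt
        self.solute_pair_fn = solute_pair_fn
        self.solute_charge_scale = solute_charge_scale
        self.temperature = (
            settings.temperature
            if settings.temperature is not None
            else psys.spec.temperature
        )
        self.pressure = (
            settings.pressure
            if settings.pressure is not None
            else psys.spec.pressure
        )
        self.beta = 1.0 / (R_GAS * self.temperature)
        self.positions = self._initial_positions()
        # zero-interaction shortcut (ideal gas): every energy is exactly 0
        self._inert = (
            not np.any(psys.eps_table)
            and not psys.has_charges
            and solute_pair_fn is None
        )
        self._tail_c = _tail_coeff(
            psys, effective_r_cut(settings.r_cut, self.box),
            exclude_solute=solute_pair_fn is not None,
        )
        self.energy = self.full_energy()
        self.n_att = {"move": 0, "volume": 0}
        self.n_acc = {"move": 0, "volume": 0}

    # -- geometry ----------------------------------------------------------

    def _initial_positions(self) -> np.ndarray:
        psys = self.psys
        n_mol = psys.n_mol
        n_cells = math.ceil(n_mol ** (1.0 / 3.0))
        spacing = self.box / n_cells
        pos = np.zeros((psys.n_sites, 3))
        m = 0
        for ix in range(n_cells):
            for iy in range(n_cells):
                for iz in range(n_cells):
                    if m >= n_mol:
                        break
                    com = (np.array([ix, iy, iz]) + 0.5) * spacing
                    geo = psys.mol_geometry[m]
                    sl = psys.mol_slices[m]
                    if geo is None:
                        pos[sl] = com
                    else:
                        rot = _random_rotation(self.rng)
                        pos[sl] = com + (geo - geo.mean(axis=0)) @ rot.T
                    m += 1
        return pos

    @property
    def r_cut(self) -> float:
        return effective_r_cut(self.settings.r_cut, self.box)

    # -- energies ----------------------------------------------------------

    def _pair_block(
        self,
        pos_a: np.ndarray,
        types_a: np.ndarray,
        charges_a: np.ndarray,
        involves_solute: np.ndarray,
        pos_b: np.ndarray,
        types_b: np.ndarray,
        charges_b: np.ndarray,
    ) -> float:
        """Energy of every site in block a against every site in block b.

        ``involves_solute`` flags, per b-site, whether the (a, b) pair crosses
        the solute boundary (a is assumed homogeneous in that respect).
        """
        rc = self.r_cut
        total = 0.0
        for k in range(len(pos_a)):
            delta = _minimum_image(pos_b - pos_a[k], self.box)
            r2 = np.einsum("ij,ij->i", delta, delta)
            eps = self.psys.eps_table[types_a[k], types_b]
            sig = self.psys.sig_table[types_a[k], types_b]
            if self.solute_pair_fn is not None and np.any(involves_solute):
                sol = involves_solute
                reg = ~sol
                total += _lj_sum(eps[reg], sig[reg], r2[reg], rc * rc)
                in_rc = sol & (r2 < rc * rc)
                if np.any(in_rc):
                    total += float(
                        np.sum(
                            self.solute_pair_fn(eps[in_rc], sig[in_rc], r2[in_rc])
                        )
                    )
            else:
                total += _lj_sum(eps, sig, r2, rc * rc)
            if self.psys.has_charges:
                qq = charges_a[k] * charges_b
                if self.solute_pair_fn is not None or self.solute_charge_scale != 1.0:
                    qq = np.where(
                        involves_solute, qq * self.solute_charge_scale, qq
                    )
                total += _coulomb_sum(qq, r2, rc)
        return total

    def mol_external_energy(self, m: int, pos_override: np.ndarray | None = None) -> float:
        """Interaction energy of molecule ``m`` with all other molecules."""
        psys = self.psys
        if self._inert:
            return 0.0
        sl = psys.mol_slices[m]
        pos_m = self.positions[sl] if pos_override is None else pos_override
        others = psys.site_mol != m
        pos_o = self.positions[others]
        types_o = psys.site_type[others]
        charges_o = psys.site_charge[others]
        if psys.solute_mol is None:
            involves = np.zeros(len(pos_o), dtype=bool)
        elif m == psys.solute_mol:
            involves = np.ones(len(pos_o), dtype=bool)
        else:
            involves = psys.site_mol[others] == psys.solute_mol
        return self._pair_block(
            pos_m,
            psys.site_type[sl],
            psys.site_charge[sl],
            involves,
            pos_o,
            types_o,
            charges_o,
        )

    def full_energy(self, positions: np.ndarray | None = None) -> float:
        """Full O(N^2) pairwise energy plus tail correction."""
        if self.r_cut > self.box / 2.0 + 1e-12:
            raise GeometryError(
                f"r_cut {self.r_cut} exceeds half the box edge {self.box / 2}"
            )
        if self._inert:
            return 0.0
        saved = None
        if positions is not None:
            saved, self.positions = self.positions, positions
        try:
            total = 0.0
            for m in range(self.psys.n_mol):
                total += self.mol_external_energy(m)
            total *= 0.5
            if self.settings.tail_correction:
                total += self._tail_c / self.box**3
            return total
        finally:
            if saved is not None:
                self.positions = saved

    # -- moves -------------------------------------------------------------

    def attempt_move(self) -> None:
        psys = self.psys
        m = int(self.rng.integers(psys.n_mol))
        sl = psys.mol_slices[m]
        old = self.positions[sl].copy()
        disp = (self.rng.random(3) - 0.5) * 2.0 * self.settings.max_displacement
        new = old + disp
        if psys.mol_geometry[m] is not None and len(old) > 1:
            angle = (self.rng.random() - 0.5) * 2.0 * self.settings.max_rotation
            axis = _random_unit(self.rng)
            com = new.mean(axis=0)
            new = com + (new - com) @ _rotation_matrix(axis, angle).T
        e_old = self.mol_external_energy(m)
        e_new = self.mol_external_energy(m, pos_override=new)
        self.n_att["move"] += 1
        if metropolis_accept(e_new - e_old, self.beta, self.rng):
            self.positions[sl] = new
            self.energy += e_new - e_old
            self.n_acc["move"] += 1

    def attempt_volume_move(self) -> None:
        """ln V move with the (N_mol + 1) Jacobian weight."""
        v_old = self.box**3
        ln_v_new = math.log(v_old) + (self.rng.random() - 0.5) * 2.0 * (
            self.settings.volume_move_scale
        )
        v_new = math.exp(ln_v_new)
        s = (v_new / v_old) ** (1.0 / 3.0)
        psys = self.psys
        new_pos = np.empty_like(self.positions)
        for m in range(psys.n_mol):
            sl = psys.mol_slices[m]
            com = self.positions[sl].mean(axis=0)
            new_pos[sl] = com * s + (self.positions[sl] - com)
        old_box, old_energy = self.box, self.energy
        self.box = v_new ** (1.0 / 3.0)
        try:
            e_new = self.full_energy(positions=new_pos)
        except GeometryError:
            self.box = old_box
            self.n_att["volume"] += 1
            return
        work = (
            (e_new - old_energy)
            + self.pressure * (v_new - v_old) * BAR_NM3_TO_KJ_PER_MOL
            - (psys.n_mol + 1) * R_GAS * self.temperature * math.log(v_new / v_old)
        )
        self.n_att["volume"] += 1
        if metropolis_accept(work, self.beta, self.rng):
            self.positions = new_pos
            self.energy = e_new
            self.n_acc["volume"] += 1
        else:
            self.box = old_box
            self.energy = old_energy

    # -- driver ------------------------------------------------------------

    def run(self) -> TrajectoryStats:
        st = self.settings
        p_vol = (
            st.volume_move_freq
            if st.volume_move_freq is not None
            else 1.0 / (self.psys.n_mol + 1)
        )
        energies: list[float] = []
        volumes: list[float] = []
        configs: list[Configuration] = []
        for step in range(st.n_steps):
            if self.npt and self.rng.random() < p_vol:
                self.attempt_volume_move()
            else:
                self.attempt_move()
            if step >= st.equil_steps and (step - st.equil_steps) % st.sample_interval == 0:
                energies.append(self.energy)
                volumes.append(self.box**3)
                configs.append(
                    Configuration(np.mod(self.positions, self.box), self.box)
                )
        if not energies:
            raise EstimationError("no production samples recorded")
        volumes_arr = np.asarray(volumes)
        mass_kg = self.psys.total_mass_g / N_AVOGADRO / 1000.0
        densities = mass_kg / (volumes_arr * 1e-27)
        acceptance = {
            key: (self.n_acc[key] / self.n_att[key]) if self.n_att[key] else 0.0
            for key in self.n_att
        }
        return TrajectoryStats(
            energies=np.asarray(energies),
            volumes=volumes_arr,
            densities=densities,
            acceptance=acceptance,
            configurations=configs,
            site_type_names=list(self.psys.site_type_labels),
            site_charges=self.psys.site_charge.copy(),
            temperature=self.temperature,
            total_mass_g=self.psys.total_mass_g,
            sample_interval=st.sample_interval,
        )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    return _rotation_matrix(_random_unit(rng), rng.random() * 2.0 * math.pi)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def _resolve_box(system: SystemSpec, settings: SimSettings) -> float:
    if system.box_edge is not None:
        return system.box_edge
    # ideal-gas estimate for NPT starts without an explicit box
    n_mol = sum(count for _, count, _ in system.molecules)
    t = settings.temperature if settings.temperature is not None else system.temperature
    p = settings.pressure if settings.pressure is not None else system.pressure
    v = (n_mol + 1) * R_GAS * t / (p * BAR_NM3_TO_KJ_PER_MOL)
    return v ** (1.0 / 3.0)


def total_energy(
    config: Configuration,
    system: SystemSpec,
    params: ParameterSet,
    settings: SimSettings,
    solute_pair_fn=None,
    solute_charge_scale: float = 1.0,
) -> float:
    """Total potential energy of one configuration (kJ/mol).

    Raises :class:`GeometryError` if the requested cutoff exceeds half the
    box edge (minimum image would be invalid).
    """
    if settings.r_cut > config.box_edge / 2.0 + 1e-12:
        raise GeometryError(
            f"r_cut {settings.r_cut} > box_edge/2 = {config.box_edge / 2}"
        )
    psys = build_particle_system(system, params)
    rng = np.random.default_rng(0)
    engine = MCEngine(
        psys,
        config.box_edge,
        settings,
        rng,
        solute_pair_fn=solute_pair_fn,
        solute_charge_scale=solute_charge_scale,
    )
    return engine.full_energy(positions=np.asarray(config.positions, dtype=float))


def run_nvt(
    system: SystemSpec,
    params: ParameterSet,
    settings: SimSettings,
    solute_pair_fn=None,
    solute_charge_scale: float = 1.0,
) -> TrajectoryStats:
    """Sample the NVT ensemble; returns recorded production statistics."""
    psys = build_particle_system(system, params)
    rng = np.random.default_rng(settings.seed)
    engine = MCEngine(
        psys,
        _resolve_box(system, settings),
        settings,
        rng,
        npt=False,
        solute_pair_fn=solute_pair_fn,
        solute_charge_scale=solute_charge_scale,
    )
    return engine.run()


def block_sem(samples: np.ndarray, n_blocks: int) -> float:
    """Standard error of the mean from ``n_blocks`` equal contiguous blocks."""
    n = len(samples) - len(samples) % n_blocks
    if n < n_blocks:
        raise EstimationError("too few samples for block averaging")
    blocks = np.asarray(samples[:n]).reshape(n_blocks, -1).mean(axis=1)
    return float(np.std(blocks, ddof=1) / math.sqrt(n_blocks))


def run_npt_density(
    system: SystemSpec,
    params: ParameterSet,
    settings: SimSettings,
) -> tuple[float, float, TrajectoryStats]:
    """NPT sampling; returns (density, block SEM, stats) with density in kg/m^3.

    The density is total mass over the production-average volume; its
    uncertainty is the standard error of the mean over ``n_blocks`` equal
    blocks of the density series.
    """
    p = settings.pressure if settings.pressure is not None else system.pressure
    if p <= 0:
        raise ValueError("pressure must be positive for NPT")
    psys = build_particle_system(system, params)
    rng = np.random.default_rng(settings.seed)
    engine = MCEngine(
        psys, _resolve_box(system, settings), settings, rng, npt=True
    )
    stats = engine.run()
    mass_kg = psys.total_mass_g / N_AVOGADRO / 1000.0
    density = mass_kg / (float(np.mean(stats.volumes)) * 1e-27)
    sem = block_sem(stats.densities, settings.n_blocks)
    return density, sem, stats


def widom_mu_excess(
    stats: TrajectoryStats,
    solute: MoleculeSpec,
    params: ParameterSet,
    settings: SimSettings,
    n_insertions: int = 200,
    seed: int | None = None,
    full_output: bool = False,
):
    """Excess chemical potential by Widom test-particle insertion (kJ/mol).

    Inserts the (rigid) solute at random positions/orientations into each
    stored configuration and returns ``-RT ln < exp(-beta dU) >``. Tail
    corrections are never applied to the inserted particle, matching the
    plain-truncated solute-solvent convention of the alchemical route.
    """
    if not stats.configurations:
        raise EstimationError("no stored configurations for Widom insertion")
    rng = np.random.default_rng(settings.seed if seed is None else seed)
    beta = 1.0 / (R_GAS * stats.temperature)

    # combined pair parameters: solute site type x solvent site type
    solv_types = stats.site_type_names
    unique_solv = sorted(set(solv_types))
    solv_idx = np.asarray([unique_solv.index(t) for t in solv_types], dtype=np.intp)
    eps_tab = np.zeros((len(solute.sites), len(unique_solv)))
    sig_tab = np.ones_like(eps_tab)
    for a, site in enumerate(solute.sites):
        for b, tname in enumerate(unique_solv):
            eps_tab[a, b], sig_tab[a, b] = params.pair_parameters(
                site.type_name, tname
            )
    geo = (
        np.asarray(solute.geometry, dtype=float)
        if solute.geometry is not None
        else np.zeros((1, 3))
    )
    geo = geo - geo.mean(axis=0)

    per_config = np.empty(len(stats.configurations))
    for ci, config in enumerate(stats.configurations):
        box = config.box_edge
        rc = effective_r_cut(settings.r_cut, box)
        coms = rng.random((n_insertions, 3)) * box
        if len(geo) > 1:
            rots = np.stack([_random_rotation(rng) for _ in range(n_insertions)])
            # site positions per insertion: (n_ins, n_sites, 3)
            site_pos = coms[:, None, :] + np.einsum("tij,aj->tai", rots, geo)
        else:
            site_pos = coms[:, None, :]
        du = np.zeros(n_insertions)
        for a in range(site_pos.shape[1]):
            delta = _minimum_image(
                config.positions[None, :, :] - site_pos[:, a, None, :], box
            )
            r2 = np.einsum("tij,tij->ti", delta, delta)
            eps = eps_tab[a, solv_idx][None, :]
            sig = sig_tab[a, solv_idx][None, :]
            mask = r2 < rc * rc
            sr6 = np.where(mask, (sig**2 / np.maximum(r2, 1e-12)) ** 3, 0.0)
            du += np.sum(4.0 * eps * (sr6 * sr6 - sr6), axis=1)
        # cap huge overlap energies to avoid exp underflow warnings
        per_config[ci] = float(np.mean(np.exp(-beta * np.minimum(du, 700.0 / beta))))
    mean_b = float(np.mean(per_config))
    if mean_b <= 0.0:
        raise EstimationError("all Widom insertions overlapped; increase sampling")
    mu = -math.log(mean_b) / beta
    if not full_output:
        return mu
    nb = min(settings.n_blocks, len(per_config))
    sem_b = block_sem(per_config, nb)
    # delta-method propagation through -RT ln(x)
    sem_mu = sem_b / mean_b / beta
    return mu, sem_mu
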