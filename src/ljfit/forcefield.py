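"""Force-field parameter model: atom types, pair combination rules, file I/O.

The central object is :class:`ParameterSet`, a mapping of atom-type names to
Lennard-Jones ``(epsilon, sigma)`` pairs plus optional pairwise overrides
``(xi, zeta)`` that modify the Lorentz-Berthelot combination for specific
type pairs (in practice: solute type against a water-oxygen type).

Combination convention (multiplicative, reduces to plain Lorentz-Berthelot
for ``xi = zeta = 0``)::

    epsilon_ij = (1 + xi_ij)  * sqrt(epsilon_i * epsilon_j)
    sigma_ij   = (1 + zeta_ij) * (sigma_i + sigma_j) / 2

The convention is isolated in :func:`combine_pair`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "AtomTypeDef",
    "InteractionOverride",
    "ParameterSet",
    "SiteSpec",
    "MoleculeSpec",
    "SystemSpec",
    "lj_energy",
    "combine_pair",
    "read_parameter_file",
    "write_parameter_file",
    "export_gromacs_nonbond_params",
]


class ParameterFormatError(ValueError):
    """Raised for malformed or inconsistent parameter files."""


@dataclass(frozen=True)
class AtomTypeDef:
    """One atom type with its self Lennard-Jones parameters.

    Parameters
    ----------
    name : str
        Short unique identifier, e.g. ``"c3R"`` or ``"ohP"``.
    epsilon : float
        Well depth in kJ/mol, must be >= 0 (0 for non-interacting sites
        such as water hydrogens).
    sigma : float
        Size parameter in nm, must be > 0.
    description : str
        Free-text description.
    """

    name: str
    epsilon: float
    sigma: float
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom type name must be nonempty")
        if self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class InteractionOverride:
    """Pairwise modifiers applied inside the combination rule.

    ``xi`` scales the combined epsilon, ``zeta`` the combined sigma; both are
    dimensionless and zero means plain Lorentz-Berthelot. Overrides are
    symmetric in ``(type_i, type_j)``.
    """

    type_i: str
    type_j: str
    xi: float = 0.0
    zeta: float = 0.0

    @property
    def key(self) -> frozenset:
        return frozenset((self.type_i, self.type_j))


@dataclass
class ParameterSet:
    """A named collection of atom types plus pairwise overrides."""

    types: dict[str, AtomTypeDef] = field(default_factory=dict)
    overrides: dict[frozenset, InteractionOverride] = field(default_factory=dict)
    label: str = "default"
    #: alias -> canonical name, for GAFF-style equivalence classes
    #: (e.g. cc/cd/ce all mapping to ca).
    aliases: dict[str, str] = field(default_factory=dict)

    def resolve(self, name: str) -> str:
        """Return the canonical type name for ``name`` (follows aliases)."""
        return self.aliases.get(name, name)

    def add_type(self, t: AtomTypeDef) -> None:
        if t.name in self.types:
            raise ParameterFormatError(f"duplicate atom type {t.name!r}")
        self.types[t.name] = t

    def add_override(self, o: InteractionOverride) -> None:
        for n in (o.type_i, o.type_j):
            if self.resolve(n) not in self.types:
                raise ParameterFormatError(
                    f"override references undefined atom type {n!r}"
                )
        self.overrides[o.key] = o

    def get_type(self, name: str) -> AtomTypeDef:
        return self.types[self.resolve(name)]

    def get_override(self, name_i: str, name_j: str) -> InteractionOverride | None:
        key = frozenset((self.resolve(name_i), self.resolve(name_j)))
        return self.overrides.get(key)

    def pair_parameters(self, name_i: str, name_j: str) -> tuple[float, float]:
        """Combined ``(epsilon_ij, sigma_ij)`` for two type names."""
        return combine_pair(
            self.get_type(name_i),
            self.get_type(name_j),
            self.get_override(name_i, name_j),
        )

    def with_updates(
        self,
        label: str | None = None,
        type_updates: dict[str, tuple[float, float]] | None = None,
        override_updates: dict[tuple[str, str], tuple[float, float]] | None = None,
    ) -> "ParameterSet":
        """Return a copy with selected (epsilon, sigma) or (xi, zeta) replaced."""
        new = ParameterSet(
            types=dict(self.types),
            overrides=dict(self.overrides),
            label=label if label is not None else self.label,
            aliases=dict(self.aliases),
        )
        for name, (eps, sig) in (type_updates or {}).items():
            cname = new.resolve(name)
            if cname not in new.types:
                raise KeyError(f"unknown atom type {name!r}")
            new.types[cname] = replace(new.types[cname], epsilon=eps, sigma=sig)
        for (ni, nj), (xi, zeta) in (override_updates or {}).items():
            o = InteractionOverride(new.resolve(ni), new.resolve(nj), xi, zeta)
            new.add_override(o)
        return new

    def validate(self) -> None:
        """Check internal consistency; raises ParameterFormatError on failure."""
        for key in self.overrides:
            for n in key:
                if self.resolve(n) not in self.types:
                    raise ParameterFormatError(
                        f"override references undefined atom type {n!r}"
                    )
        for alias, target in self.aliases.items():
            if target not in self.types:
                raise ParameterFormatError(
                    f"alias {alias!r} points at undefined type {target!r}"
                )


@dataclass(frozen=True)
class SiteSpec:
    """One interaction site of a molecule: an atom type plus a partial charge (e)."""

    type_name: str
    charge: float = 0.0


@dataclass(frozen=True)
class MoleculeSpec:
    """A rigid molecule: named, with sites and substance-group tags.

    ``geometry`` gives site positions (nm) in the molecular frame; ``None``
    for monatomic species.
    """

    name: str
    sites: tuple[SiteSpec, ...]
    group_tags: tuple[str, ...] = ()
    geometry: tuple[tuple[float, float, float], ...] | None = None
    molar_mass: float = 40.0  # g/mol, toy default

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("molecule must have at least one site")
        if self.geometry is not None and len(self.geometry) != len(self.sites):
            raise ValueError("geometry length must match site count")
        if len(self.sites) > 1 and self.geometry is None:
            raise ValueError("multi-site molecules require a geometry")

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class SystemSpec:
    """A simulated system: molecule counts, box or pressure, T and p.

    Each entry of ``molecules`` is ``(molecule, count, role)`` with role
    ``"solvent"`` or ``"solute"``. At most one solute entry is allowed and
    its count must be 1 for solvation systems.
    """

    name: str
    molecules: tuple[tuple[MoleculeSpec, int, str], ...]
    temperature: float
    pressure: float = 1.01325
    box_edge: float | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        n_solute = sum(1 for _, _, role in self.molecules if role == "solute")
        if n_solute > 1:
            raise ValueError("at most one solute role per system")
        for mol, count, role in self.molecules:
            if count < 1:
                raise ValueError(f"count for {mol.name} must be >= 1")

    @property
    def solute(self) -> MoleculeSpec | None:
        for mol, _, role in self.molecules:
            if role == "solute":
                return mol
        return None

    @property
    def solvents(self) -> tuple[tuple[MoleculeSpec, int], ...]:
        return tuple(
            (mol, count) for mol, count, role in self.molecules if role == "solvent"
        )


def lj_energy(epsilon: float, sigma: float, r: float):
    """Lennard-Jones pair energy ``4 eps [(sigma/r)^12 - (sigma/r)^6]``.

    Accepts scalar or ndarray ``r``; energies in kJ/mol, distances in nm.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    import numpy as np

    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("r must be > 0")
    sr6 = (sigma / r_arr) ** 6
    out = 4.0 * epsilon * (sr6 * sr6 - sr6)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def combine_pair(
    i: AtomTypeDef,
    j: AtomTypeDef,
    override: InteractionOverride | None = None,
) -> tuple[float, float]:
    """Combined pair parameters ``(epsilon_ij, sigma_ij)``.

    Plain Lorentz-Berthelot (geometric epsilon, arithmetic sigma) modified by
    the multiplicative ``(1 + xi)`` / ``(1 + zeta)`` factors of the override,
    if present. Symmetric in ``i`` and ``j``.
    """
    eps = math.sqrt(i.epsilon * j.epsilon)
    sig = 0.5 * (i.sigma + j.sigma)
    if override is not None:
        if override.key != frozenset((i.name, j.name)):
            raise ValueError(
                f"override {override.type_i}-{override.type_j} does not match "
                f"pair {i.name}-{j.name}"
            )
        eps *= 1.0 + override.xi
        sig *= 1.0 + override.zeta
    return eps, sig


# ---------------------------------------------------------------------------
# parameter file I/O
#
# Line-oriented plain text with two sections:
#
#   [types]
#   # name  epsilon  sigma  [description...]
#   c3R  0.457730  0.339967  sp3 ring carbon
#   [aliases]
#   cc  ca
#   [overrides]
#   # type_i  type_j  xi  zeta
#   c3R  OW  0.012000  -0.003000
#
# Values are written with 6 significant digits.
# ---------------------------------------------------------------------------


def write_parameter_file(params: ParameterSet, path) -> None:
    """Serialize ``params`` to the documented plain-text format."""
    lines = [f"# ljfit parameter set: {params.label}", "[types]"]
    for t in params.types.values():
        desc = f"  {t.description}" if t.description else ""
        lines.append(f"{t.name}  {t.epsilon:.6g}  {t.sigma:.6g}{desc}")
    if params.aliases:
        lines.append("[aliases]")
        for alias, target in params.aliases.items():
            lines.append(f"{alias}  {target}")
    if params.overrides:
        lines.append("[overrides]")
        for o in params.overrides.values():
            lines.append(f"{o.type_i}  {o.type_j}  {o.xi:.6g}  {o.zeta:.6g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_parameter_file(path) -> ParameterSet:
    """Parse a parameter file written by :func:`write_parameter_file`."""
    params = ParameterSet(label="default")
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if raw.startswith("# ljfit parameter set:"):
                params.label = raw.split(":", 1)[1].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[]").lower()
                if section not in ("types", "aliases", "overrides"):
                    raise ParameterFormatError(
                        f"{path}:{lineno}: unknown section [{section}]"
                    )
                continue
            fields = line.split()
            try:
                if section == "types":
                    name, eps, sig = fields[0], float(fields[1]), float(fields[2])
                    desc = " ".join(fields[3:])
                    params.add_type(AtomTypeDef(name, eps, sig, desc))
                elif section == "aliases":
                    params.aliases[fields[0]] = fields[1]
                elif section == "overrides":
                    params.add_override(
                        InteractionOverride(
                            fields[0], fields[1], float(fields[2]), float(fields[3])
                        )
                    )
                else:
                    raise ParameterFormatError(
                        f"{path}:{lineno}: data before any section header"
                    )
            except (IndexError, ValueError) as exc:
                if isinstance(exc, ParameterFormatError):
                    raise
                raise ParameterFormatError(f"{path}:{lineno}: {exc}") from exc
    params.validate()
    return params


def export_gromacs_nonbond_params(params: ParameterSet, path) -> None:
    """Write explicitly combined pairs as a GROMACS-style [nonbond_params] block.

    Interoperability helper; round-trip exactness is not promised.
    """
    names = list(params.types)
    lines = ["[ nonbond_params ]", "; i  j  func  sigma(nm)  epsilon(kJ/mol)"]
    for a in range(len(names)):
        for b in range(a, len(names)):
            eps, sig = params.pair_parameters(names[a], names[b])
            lines.append(f"{names[a]:>6s} {names[b]:>6s}  1  {sig:.6e}  {eps:.6e}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
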