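"""Partial-charge handling: vacuum/continuum averaging and mixture interpolation.

Charge sets are inputs (tabular files); no quantum chemistry happens here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChargeSet",
    "ipolq_mod_average",
    "mixture_charges",
    "read_charge_table",
    "write_charge_table",
]

NET_CHARGE_TOL = 1e-6


class ChargeConsistencyError(ValueError):
    pass


@dataclass(frozen=True)
class ChargeSet:
    """Ordered per-site partial charges for one molecule in one environment.

    ``environment`` is a label such as ``"vacuum"``, ``"continuum:water"``,
    ``"ipolq-mod:water"`` or ``"mixture:..."``.
    """

    molecule: str
    environment: str
    charges: tuple[float, ...]

    @property
    def net_charge(self) -> float:
        return float(sum(self.charges))

    def __len__(self) -> int:
        return len(self.charges)


def _check_compatible(a: ChargeSet, b: ChargeSet) -> None:
    if a.molecule != b.molecule:
        raise ChargeConsistencyError(
            f"molecule mismatch: {a.molecule!r} vs {b.molecule!r}"
        )
    if len(a) != len(b):
        raise ChargeConsistencyError(
            f"site count mismatch for {a.molecule}: {len(a)} vs {len(b)}"
        )
    if abs(a.net_charge - b.net_charge) > NET_CHARGE_TOL:
        raise ChargeConsistencyError(
            f"net charge mismatch for {a.molecule}: "
            f"{a.net_charge:.8f} vs {b.net_charge:.8f}"
        )


def ipolq_mod_average(q_vacuum: ChargeSet, q_continuum: ChargeSet) -> ChargeSet:
    """Per-site arithmetic mean of a vacuum and a continuum charge set.

    Approximates polarization on transfer into the solvent implicitly. The
    continuum set's environment label must be ``"continuum:<solvent>"``; the
    result is labelled ``"ipolq-mod:<solvent>"``.
    """
    _check_compatible(q_vacuum, q_continuum)
    solvent = (
        q_continuum.environment.split(":", 1)[1]
        if ":" in q_continuum.environment
        else q_continuum.environment
    )
    averaged = tuple(
        0.5 * (qa + qb) for qa, qb in zip(q_vacuum.charges, q_continuum.charges)
    )
    return ChargeSet(q_vacuum.molecule, f"ipolq-mod:{solvent}", averaged)


def mixture_charges(qAA: ChargeSet, qAB: ChargeSet, xA: float) -> ChargeSet:
    """Mole-fraction interpolation of two continuum charge sets.

    For compound A in a binary A/B mixture at mole fraction ``xA``, the
    per-site charge is ``xA * q^{A,A} + (1 - xA) * q^{A,B}``.
    """
    if not 0.0 <= xA <= 1.0:
        raise ValueError(f"mole fraction must be in [0, 1], got {xA}")
    _check_compatible(qAA, qAB)
    mixed = tuple(
        xA * qa + (1.0 - xA) * qb for qa, qb in zip(qAA.charges, qAB.charges)
    )
    return ChargeSet(qAA.molecule, f"mixture:xA={xA:g}", mixed)


def write_charge_table(cs: ChargeSet, path) -> None:
    """Write a charge set as delimited text with a descriptive header."""
    lines = [
        f"# molecule: {cs.molecule}",
        f"# environment: {cs.environment}",
        f"# net_charge: {cs.net_charge:.8f}",
        "site_index\tcharge",
    ]
    for i, q in enumerate(cs.charges):
        lines.append(f"{i}\t{q:.8f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_charge_table(path) -> ChargeSet:
    molecule = environment = None
    recorded_net = None
    charges: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("# molecule:"):
                molecule = line.split(":", 1)[1].strip()
            elif line.startswith("# environment:"):
                environment = line.split(":", 1)[1].strip()
            elif line.startswith("# net_charge:"):
                recorded_net = float(line.split(":", 1)[1])
            elif not line or line.startswith("#") or line.startswith("site_index"):
                continue
            else:
                charges.append(float(line.split()[1]))
    if molecule is None or environment is None:
        raise ChargeConsistencyError(f"{path}: missing molecule/environment header")
    cs = ChargeSet(molecule, environment, tuple(charges))
    if recorded_net is not None and abs(cs.net_charge - recorded_net) > NET_CHARGE_TOL:
        raise ChargeConsistencyError(
            f"{path}: recorded net charge {recorded_net} disagrees with "
            f"sum {cs.net_charge}"
        )
    return cs
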