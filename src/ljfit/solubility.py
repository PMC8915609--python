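"""Relative solubilities from solvation free energy differences.

For a solute S in solvents A and B at the same temperature::

    ln(c_A / c_B) = -beta * (dG_A - dG_B),    beta = 1 / (R T)

so the more negative solvation free energy predicts the higher solubility.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .constants import R_GAS

__all__ = [
    "SolvationRecord",
    "RelativeSolubility",
    "relative_solubility",
    "enumerate_pairs",
    "records_from_frame",
    "pairs_to_frame",
]


class RecordMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class SolvationRecord:
    """One computed solvation free energy (kJ/mol) with its uncertainty."""

    solute: str
    solvent: str
    dG: float
    uncertainty: float = 0.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class RelativeSolubility:
    """Predicted concentration ratio of one solute between two solvents."""

    solute: str
    solvent_a: str
    solvent_b: str
    ln_ratio: float
    uncertainty: float
    temperature: float

    @property
    def ratio(self) -> float:
        return math.exp(self.ln_ratio)


def relative_solubility(
    rec_a: SolvationRecord, rec_b: SolvationRecord
) -> RelativeSolubility:
    """Relative solubility of the common solute in solvent A vs solvent B."""
    if rec_a.solute != rec_b.solute:
        raise RecordMismatchError(
            f"solute mismatch: {rec_a.solute!r} vs {rec_b.solute!r}"
        )
    if rec_a.temperature != rec_b.temperature:
        raise RecordMismatchError(
            f"temperature mismatch: {rec_a.temperature} vs {rec_b.temperature}"
        )
    beta = 1.0 / (R_GAS * rec_a.temperature)
    ln_ratio = -beta * (rec_a.dG - rec_b.dG)
    unc = beta * math.sqrt(rec_a.uncertainty**2 + rec_b.uncertainty**2)
    return RelativeSolubility(
        solute=rec_a.solute,
        solvent_a=rec_a.solvent,
        solvent_b=rec_b.solvent,
        ln_ratio=ln_ratio,
        uncertainty=unc,
        temperature=rec_a.temperature,
    )


def enumerate_pairs(records) -> list[RelativeSolubility]:
    """All unordered solvent pairs per solute, canonically oriented.

    Each solute with n solvents contributes n (n - 1) / 2 entries; the pair
    is oriented so ``solvent_a < solvent_b`` lexicographically. Solutes with
    fewer than two solvents contribute nothing.
    """
    by_solute: dict[str, list[SolvationRecord]] = defaultdict(list)
    for rec in records:
        by_solute[rec.solute].append(rec)
    out: list[RelativeSolubility] = []
    for solute in sorted(by_solute):
        recs = sorted(by_solute[solute], key=lambda r: r.solvent)
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                out.append(relative_solubility(recs[i], recs[j]))
    return out


def records_from_frame(frame: pd.DataFrame) -> list[SolvationRecord]:
    """Build records from a table with columns solute, solvent, dG,
    [uncertainty], [temperature]."""
    recs = []
    for _, row in frame.iterrows():
        recs.append(
            SolvationRecord(
                solute=str(row["solute"]),
                solvent=str(row["solvent"]),
                dG=float(row["dG"]),
                uncertainty=float(row.get("uncertainty", 0.0) or 0.0),
                temperature=float(row.get("temperature", 298.15) or 298.15),
            )
        )
    return recs


def pairs_to_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "solute": [p.solute for p in pairs],
            "solvent_a": [p.solvent_a for p in pairs],
            "solvent_b": [p.solvent_b for p in pairs],
            "ln_ratio": [p.ln_ratio for p in pairs],
            "ratio": [p.ratio for p in pairs],
            "uncertainty": [p.uncertainty for p in pairs],
            "temperature": [p.temperature for p in pairs],
        }
    )
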