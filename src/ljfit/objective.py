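"""Evaluation statistics and the refitting objective function.

Provides RMSD / MAE, regression diagnostics (through-origin slope, Pearson
correlation), substance-group and temperature-bin aggregation, percentage
reductions, and the weighted RMSD-ratio objective used by the optimizer::

    Z = w_dG * rmsd_dG / rmsd_dG_ref  +  w_rho * rmsd_rho / rmsd_rho_ref

where the "ref" normalizers come from an evaluation with unaltered
parameters at the start of each fitting step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceDataset",
    "ObjectiveSpec",
    "EvaluationReport",
    "error_stats",
    "regression_stats",
    "grouped_rmsd",
    "objective_Z",
    "percent_reduction",
    "evaluate_dataset",
    "temperature_bin_labels",
]

#: required columns of a reference dataset table
DATASET_COLUMNS = [
    "system_id",
    "property",
    "experimental",
    "simulated",
    "solute_group",
    "solvent_group",
    "temperature",
]

VALID_PROPERTIES = {"dGsolv", "density"}


class DegenerateInputError(ValueError):
    pass


@dataclass
class ReferenceDataset:
    """Experimental (and optionally simulated) values with group tags.

    Thin wrapper around a pandas DataFrame with the columns of
    ``DATASET_COLUMNS``; units are kJ/mol for ``dGsolv`` and kg/m^3 for
    ``density`` entries.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if self.frame["system_id"].duplicated().any():
            dupes = self.frame.loc[
                self.frame["system_id"].duplicated(), "system_id"
            ].tolist()
            raise ValueError(f"duplicate system ids: {dupes}")
        bad = set(self.frame["property"]) - VALID_PROPERTIES
        if bad:
            raise ValueError(f"unknown properties: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)

    def subset(
        self,
        property: str | None = None,
        system_ids=None,
        exclude_groups=None,
    ) -> "ReferenceDataset":
        df = self.frame
        if property is not None:
            df = df[df["property"] == property]
        if system_ids is not None:
            df = df[df["system_id"].isin(set(system_ids))]
        if exclude_groups:
            excl = set(exclude_groups)
            df = df[
                ~df["solute_group"].isin(excl) & ~df["solvent_group"].isin(excl)
            ]
        return ReferenceDataset(df.reset_index(drop=True))

    def pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """(simulated, experimental) arrays, dropping rows without simulation."""
        df = self.frame.dropna(subset=["simulated"])
        return df["simulated"].to_numpy(float), df["experimental"].to_numpy(float)

    def with_simulated(self, values: dict[str, float]) -> "ReferenceDataset":
        df = self.frame.copy()
        df["simulated"] = df["system_id"].map(values).astype(float)
        return ReferenceDataset(df)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceDataset":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class ObjectiveSpec:
    """Weights and reference normalizers for the RMSD-ratio objective."""

    w_dG: float = 1.0
    w_rho: float = 1.0
    rmsd_dG_ref: float = 1.0
    rmsd_rho_ref: float = 1.0

    def __post_init__(self) -> None:
        if self.w_dG < 0 or self.w_rho < 0:
            raise ValueError("weights must be >= 0")
        if self.w_dG == 0 and self.w_rho == 0:
            raise ValueError("at least one weight must be positive")
        if (self.w_dG > 0 and self.rmsd_dG_ref <= 0) or (
            self.w_rho > 0 and self.rmsd_rho_ref <= 0
        ):
            raise ValueError("reference RMSDs must be positive")


@dataclass
class EvaluationReport:
    """Overall and grouped accuracy statistics for one dataset."""

    rmsd: float
    mae: float
    slope: float
    pearson_r: float
    n: int
    by_solute_group: dict[str, float] = field(default_factory=dict)
    by_solvent_group: dict[str, float] = field(default_factory=dict)
    by_temperature_bin: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "rmsd": self.rmsd,
            "mae": self.mae,
            "slope": self.slope,
            "pearson_r": self.pearson_r,
            "n": self.n,
            "by_solute_group": self.by_solute_group,
            "by_solvent_group": self.by_solvent_group,
            "by_temperature_bin": self.by_temperature_bin,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def render_table(self) -> str:
        """Plain-text summary table (overall stats plus grouped RMSDs)."""
        lines = [
            f"{'n':>12s}  {self.n:d}",
            f"{'RMSD':>12s}  {self.rmsd:.4g}",
            f"{'MAE':>12s}  {self.mae:.4g}",
            f"{'slope m':>12s}  {self.slope:.4f}",
            f"{'Pearson R':>12s}  {self.pearson_r:.4f}",
        ]
        for title, table in (
            ("by solute group", self.by_solute_group),
            ("by solvent group", self.by_solvent_group),
            ("by temperature bin", self.by_temperature_bin),
        ):
            if table:
                lines.append(f"-- RMSD {title} --")
                for key, val in table.items():
                    lines.append(f"{key:>20s}  {val:.4g}")
        return "\n".join(lines)


def error_stats(simulated, experimental) -> tuple[float, float]:
    """Root-mean-square deviation and mean absolute error of paired values."""
    sim = np.asarray(simulated, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if sim.size == 0 or sim.shape != exp.shape:
        raise ValueError("need at least one pair of equal-length arrays")
    diff = sim - exp
    return float(np.sqrt(np.mean(diff**2))), float(np.mean(np.abs(diff)))


def regression_stats(simulated, experimental) -> tuple[float, float]:
    """Least-squares slope through the origin plus Pearson correlation.

    The slope is ``sum(x*y) / sum(x^2)`` with x = experimental; the Pearson
    coefficient is computed on the raw (centered) pairs.
    """
    sim = np.asarray(simulated, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if sim.size < 2:
        raise DegenerateInputError("need at least 2 pairs")
    if np.allclose(exp.var(), 0.0) or np.allclose(sim.var(), 0.0):
        raise DegenerateInputError("zero variance input")
    slope = float(np.sum(exp * sim) / np.sum(exp * exp))
    pearson = float(np.corrcoef(exp, sim)[0, 1])
    return slope, pearson


def temperature_bin_labels(temperatures, edges_celsius=(-10, 0, 20, 40, 60, 80)):
    """Half-open temperature bins, lower-exclusive / upper-inclusive.

    ``edges_celsius`` are interior edges in deg C; temperatures (K) are
    binned as ``edge_low < theta <= edge_high``.
    """
    theta = np.asarray(temperatures, dtype=float) - 273.15
    edges = list(edges_celsius)
    labels = []
    for t in theta:
        if t <= edges[0]:
            labels.append(f"theta <= {edges[0]} C")
            continue
        assigned = None
        for lo, hi in zip(edges, edges[1:]):
            if lo < t <= hi:
                assigned = f"{lo} C < theta <= {hi} C"
                break
        labels.append(assigned or f"theta > {edges[-1]} C")
    return labels


def grouped_rmsd(
    dataset: ReferenceDataset,
    group_key: str,
    edges_celsius=(-10, 0, 20, 40, 60, 80),
) -> dict[str, float]:
    """RMSD per group plus the overall value under key ``"overall"``.

    ``group_key`` is ``"solute_group"``, ``"solvent_group"`` or
    ``"temperature"`` (binned). Groups left empty after dropping rows
    without simulated values are omitted with a logged note.
    """
    df = dataset.frame.dropna(subset=["simulated"])
    if df.empty:
        raise ValueError("no simulated values to aggregate")
    if group_key == "temperature":
        keys = temperature_bin_labels(df["temperature"], edges_celsius)
    elif group_key in ("solute_group", "solvent_group"):
        keys = df[group_key].tolist()
    else:
        raise ValueError(f"unknown group key {group_key!r}")
    out: dict[str, float] = {}
    frame = df.assign(_key=keys)
    for key, sub in frame.groupby("_key", sort=True):
        if sub.empty:  # pragma: no cover - groupby never yields empty groups
            logger.info("group %s empty after filtering; omitted", key)
            continue
        out[str(key)] = error_stats(sub["simulated"], sub["experimental"])[0]
    out["overall"] = error_stats(df["simulated"], df["experimental"])[0]
    return out


def objective_Z(rmsd_dG: float | None, rmsd_rho: float | None, spec: ObjectiveSpec) -> float:
    """Weighted sum of RMSD ratios; the quantity minimized during refitting."""
    z = 0.0
    if spec.w_dG > 0:
        if rmsd_dG is None:
            raise ValueError("rmsd_dG required when w_dG > 0")
        z += spec.w_dG * rmsd_dG / spec.rmsd_dG_ref
    if spec.w_rho > 0:
        if rmsd_rho is None:
            raise ValueError("rmsd_rho required when w_rho > 0")
        z += spec.w_rho * rmsd_rho / spec.rmsd_rho_ref
    return z


def percent_reduction(rmsd_baseline: float, rmsd_new: float) -> float:
    """Percentage reduction 100 * (1 - new / baseline)."""
    if rmsd_baseline <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (1.0 - rmsd_new / rmsd_baseline)


def evaluate_dataset(
    dataset: ReferenceDataset,
    exclude_groups=None,
    edges_celsius=(-10, 0, 20, 40, 60, 80),
) -> EvaluationReport:
    """Full evaluation: overall stats plus all three grouped RMSD tables."""
    ds = dataset.subset(exclude_groups=exclude_groups) if exclude_groups else dataset
    sim, exp = ds.pairs()
    rmsd, mae = error_stats(sim, exp)
    try:
        slope, pearson = regression_stats(sim, exp)
    except DegenerateInputError:
        slope, pearson = float("nan"), float("nan")
    return EvaluationReport(
        rmsd=rmsd,
        mae=mae,
        slope=slope,
        pearson_r=pearson,
        n=len(sim),
        by_solute_group=grouped_rmsd(ds, "solute_group"),
        by_solvent_group=grouped_rmsd(ds, "solvent_group"),
        by_temperature_bin=grouped_rmsd(ds, "temperature", edges_celsius),
        meta={"excluded_groups": sorted(exclude_groups) if exclude_groups else []},
    )
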