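"""Minimal plot exports (parity scatter, grouped-RMSD bars).

Deliberately unstyled; matplotlib is imported lazily so headless use of the
rest of the toolkit never touches a plotting backend.
"""

from __future__ import annotations

from .objective import EvaluationReport, ReferenceDataset


def parity_scatter(dataset: ReferenceDataset, path, property: str | None = None):
    """Simulated-vs-experimental scatter with the y = x diagonal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ds = dataset.subset(property=property) if property else dataset
    sim, exp = ds.pairs()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(exp, sim, s=12)
    lo = min(exp.min(), sim.min())
    hi = max(exp.max(), sim.max())
    ax.plot([lo, hi], [lo, hi], "k-", lw=0.8)
    ax.set_xlabel("experimental")
    ax.set_ylabel("simulated")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def grouped_rmsd_bars(report: EvaluationReport, path, which: str = "by_solute_group"):
    """Bar chart of grouped RMSDs with the overall value as a horizontal line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = dict(getattr(report, which))
    overall = table.pop("overall", report.rmsd)
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(table)), 3))
    ax.bar(range(len(table)), list(table.values()))
    ax.axhline(overall, color="k", lw=1.2)
    ax.set_xticks(range(len(table)))
    ax.set_xticklabels(list(table), rotation=45, ha="right", fontsize=7)
    ax.set_ylabel("RMSD")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
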