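"""Report and figure emission: metrics tables, isometric-size boxplots and
two-variable scatterplots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .descriptive import isize_boxplot_table
from .filters import select_matrix
from .indices import build_scatter
from .io import SpecimenRecord
from .mosimann import size_shape_features
from .pipeline import EvalReport
from .registry import Element, Registry, default_registry

__all__ = ["write_report", "format_report_table", "isize_boxplot_figure", "scatter_figure"]

_GROUP_COLORS = {
    "dom_castrate": "tab:olive",
    "dom_male": "tab:blue",
    "dom_female": "tab:cyan",
    "wild_male": "tab:red",
    "wild_female": "tab:orange",
    "fen_male": "tab:green",
    "fen_female": "tab:purple",
}


def format_report_table(report: EvalReport) -> str:
    """Human-readable metrics table (element, variable set, partition,
    accuracy, balanced accuracy, F1-measure in percent, macro-averaged)."""
    lines = [
        f"{'Element':<12} {'Variable set':<17} {'Partition':<9} "
        f"{'Accuracy':>8} {'Bal.acc':>8} {'F1':>8}"
    ]
    for _, r in report.frame.iterrows():
        lines.append(
            f"{r.element:<12} {r.subset_id:<17} {r.partition:<9} "
            f"{r.accuracy:8.1f} {r.balanced_accuracy:8.1f} {r.macro_f1:8.1f}"
        )
    lines.append(f"(F1 averaging: {report.f1_averaging})")
    return "\n".join(lines)


def isize_boxplot_figure(
    records: Sequence[SpecimenRecord],
    element: Element,
    registry: Registry | None = None,
    subset_id: str = "all",
    path: str | Path | None = None,
):
    """Boxplot of per-specimen isometric size per group for one element."""
    registry = registry or default_registry()
    matrix, _ = select_matrix(records, element, subset_id, registry)
    _, feats = size_shape_features(matrix)
    by_group: dict[str, list[float]] = {}
    for g, row in zip(feats.groups, feats.X):
        by_group.setdefault(g.key, []).append(row[0])
    groups = sorted(by_group)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot([by_group[g] for g in groups], tick_labels=groups, whis=1.5)
    ax.set_ylabel("isometric size (log units)")
    ax.set_title(f"{element.value} ({subset_id} variables)")
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return isize_boxplot_table({g: np.array(v) for g, v in by_group.items()})


def scatter_figure(
    records: Sequence[SpecimenRecord],
    element: Element,
    x_spec: str,
    y_spec: str,
    unit: str = "mm",
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Index-vs-variable or variable-vs-variable scatter, colored by group."""
    points = build_scatter([r for r in records if r.element is element], x_spec, y_spec, unit=unit)
    fig, ax = plt.subplots(figsize=(6, 5))
    for group, sub in points.groupby("group"):
        ax.scatter(sub.x, sub.y, s=18, label=group,
                   color=_GROUP_COLORS.get(group), alpha=0.8)
    suffix = "" if x_spec in ("ME1", "ME3") else f" ({unit})"
    ax.set_xlabel(f"{x_spec}{suffix}")
    suffix = "" if y_spec in ("ME1", "ME3") else f" ({unit})"
    ax.set_ylabel(f"{y_spec}{suffix}")
    ax.set_title(element.value)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return points


def write_report(
    report: EvalReport,
    outdir: str | Path,
    records: Sequence[SpecimenRecord] | None = None,
    registry: Registry | None = None,
    figures: bool = True,
    scatter_specs: Sequence[tuple[Element, str, str]] = (),
    fmt: str = "csv",
) -> list[Path]:
    """Write the metrics table (CSV/XLSX + text) and optional figures.

    Returns the list of files written.  When ``records`` is given and
    ``figures`` is true, one isometric-size boxplot per reported element and
    any requested scatterplots are emitted as PNG.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    table_path = outdir / f"classification_report.{fmt}"
    if fmt == "csv":
        report.frame.to_csv(table_path, index=False)
    elif fmt == "xlsx":
        report.frame.to_excel(table_path, index=False)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    written.append(table_path)

    text_path = outdir / "classification_report.txt"
    text_path.write_text(format_report_table(report) + "\n")
    written.append(text_path)

    if figures and records is not None:
        registry = registry or default_registry()
        for element_name in report.frame.element.unique():
            element = Element(element_name)
            fig_path = outdir / f"isize_boxplot_{element_name}.png"
            table = isize_boxplot_figure(records, element, registry, path=fig_path)
            csv_path = outdir / f"isize_boxplot_{element_name}.csv"
            table.to_csv(csv_path, index=False)
            written.extend([fig_path, csv_path])
        for element, x_spec, y_spec in scatter_specs:
            fig_path = outdir / f"scatter_{element.value}_{x_spec}_x_{y_spec}.png"
            points = scatter_figure(records, element, x_spec, y_spec, path=fig_path)
            csv_path = outdir / f"scatter_{element.value}_{x_spec}_x_{y_spec}.csv"
            points.to_csv(csv_path, index=False)
            written.extend([fig_path, csv_path])
    return written
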