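"""Plot helpers for benchmark reports.

All functions build figures with the object-oriented matplotlib API (no
pyplot, no global state) and write straight to file, so they are safe in
headless pipelines.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .metrics import MetricReport
from .summaries import CoverageProfile

__all__ = ["plot_metric_report", "plot_coverage", "plot_relatedness"]

_METRIC_PANELS = (
    "accuracy",
    "length_accuracy",
    "length_discrepancy_cm",
    "recall",
    "power",
    "accumulative_power",
)


def _save(fig: Figure, path) -> None:
    FigureCanvasAgg(fig)
    fig.savefig(str(path), dpi=110)


def plot_metric_report(report: MetricReport, path, title: str = "") -> None:
    """Six-panel figure, one panel per metric, length bins on the x axis."""
    labels = [lab for lab in report.labels if lab != "all"]
    fig = Figure(figsize=(11, 6.5))
    axes = fig.subplots(2, 3).ravel()
    x = np.arange(len(labels))
    for ax, metric in zip(axes, _METRIC_PANELS):
        vals = [getattr(report[lab], metric) for lab in labels]
        ax.bar(x, [0.0 if (isinstance(v, float) and math.isnan(v)) else v for v in vals],
               color="#4878d0")
        ax.set_xticks(x)
        ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
        ax.set_title(metric.replace("_", " "), fontsize=10)
        if metric != "length_discrepancy_cm":
            ax.set_ylim(0, 1.05)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    _save(fig, path)


def plot_coverage(profiles: Sequence[tuple[str, CoverageProfile]], path) -> None:
    """Per-site IBD coverage along the chromosome, one line per call set."""
    fig = Figure(figsize=(9, 4))
    ax = fig.subplots()
    for name, prof in profiles:
        ax.plot(prof.positions / 1e6, prof.counts, label=name, linewidth=0.9)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("segments covering site")
    ax.legend(fontsize=8)
    fig.tight_layout()
    _save(fig, path)


def plot_relatedness(table, path) -> None:
    """Grouped bars: pairs per relatedness degree, truth vs reported."""
    fig = Figure(figsize=(7, 4))
    ax = fig.subplots()
    x = np.arange(len(table))
    width = 0.38
    ax.bar(x - width / 2, table["n_truth"], width, label="truth")
    ax.bar(x + width / 2, table["n_reported"], width, label="reported")
    ax.set_xticks(x)
    ax.set_xticklabels(table["degree"], fontsize=9)
    ax.set_xlabel("degree of relatedness")
    ax.set_ylabel("individual pairs")
    ax.legend(fontsize=8)
    fig.tight_layout()
    _save(fig, path)
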