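"""Diagnostic figures: sweep curves, validation boxplot, GA trace."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .ga import OptimizationResult
from .selection import SweepResult, ValidationReport


def plot_sweep(sweep: SweepResult, path: str | Path) -> None:
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax1.errorbar(sweep.grid, sweep.r2_mean, yerr=sweep.r2_std, fmt="-o", ms=3)
    ax1.axvline(sweep.chosen_count, ls="--", c="gray")
    ax1.set_xlabel("descriptor count")
    ax1.set_ylabel(r"test $R^2$")
    ax2.errorbar(sweep.grid, sweep.mse_mean, yerr=sweep.mse_std, fmt="-o", ms=3)
    ax2.set_xlabel("descriptor count")
    ax2.set_ylabel("test MSE")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_validation(report: ValidationReport, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.boxplot([report.r2[g] for g in report.groups], tick_labels=report.groups)
    ax.set_ylabel(r"test $R^2$")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ga_trace(result: OptimizationResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(result.best_trace)
    ax.set_xlabel("generation")
    ax.set_ylabel("best fitness")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
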