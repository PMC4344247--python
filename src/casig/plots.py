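"""Optional figure output: trace gallery, dose response, feature scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .discriminant import DiscriminantModel
from .pipeline import ExperimentReport


def plot_dose_response(report: ExperimentReport, path: str | Path) -> None:
    """First-peak amplitude vs concentration, per genotype and stimulus."""
    fig, ax = plt.subplots(figsize=(6, 4))
    markers = {"col0_like": "s", "c24_like": "^"}
    styles = {"nacl": "-", "sorbitol": "--"}
    for (geno, stim), grp in report.dose_response.groupby(["genotype", "stimulus"]):
        grp = grp.sort_values("concentration_mM")
        ax.plot(
            grp["concentration_mM"], grp["amp1_nM"],
            marker=markers.get(geno, "o"), linestyle=styles.get(stim, "-"),
            label=f"{geno} / {stim}",
        )
    ax.set_xlabel("concentration (mM, NaCl scale for sorbitol x0.5)")
    ax.set_ylabel("first-peak amplitude (nM)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_feature_scatter(report: ExperimentReport, path: str | Path) -> None:
    """log10 amp2 vs log10 amp1 of the NaCl rows with the LDA decision line."""
    feat = report.feature_table
    nacl = feat[feat["stimulus"] == "nacl"]
    fig, ax = plt.subplots(figsize=(5, 5))
    for geno, grp in nacl.groupby("genotype"):
        ax.scatter(grp["log_amp1"], grp["log_amp2"], label=geno, s=25)
    _draw_decision_line(ax, report.model)
    ax.set_xlabel("log10 first amplitude (nM)")
    ax.set_ylabel("log10 second amplitude (nM)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _draw_decision_line(ax, model: DiscriminantModel) -> None:
    # D(x) = w.x + b = 0 with w = S^-1 (m1 - m2)
    w = np.linalg.solve(model.pooled_cov, model.means[0] - model.means[1])
    mid = 0.5 * (model.means[0] + model.means[1])
    b = -w @ mid + np.log(model.priors[0] / model.priors[1])
    xs = np.array(ax.get_xlim())
    if abs(w[1]) > 1e-12:
        ax.plot(xs, -(w[0] * xs + b) / w[1], "k:", lw=1, label="decision line")
    else:
        ax.axvline(-b / w[0], color="k", ls=":", lw=1)


def plot_report(report: ExperimentReport, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = [out_dir / "dose_response.png", out_dir / "feature_scatter.png"]
    plot_dose_response(report, paths[0])
    plot_feature_scatter(report, paths[1])
    return paths
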