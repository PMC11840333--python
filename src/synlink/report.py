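"""Human-readable rendering of an AnalysisReport: markdown summary + figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pipeline import AnalysisReport
from .pls import pls_canonical_fit, pls_regression

__all__ = ["render_report"]


def _score_scatter(report: AnalysisReport, path: Path) -> None:
    ca = pls_canonical_fit(
        report.pet, report.fmri_pe, n_components=len(report.plsca["components"])
    )
    k = ca.n_components
    fig, axes = plt.subplots(1, k, figsize=(4.2 * k, 3.6), squeeze=False)
    for i in range(k):
        ax = axes[0, i]
        t, u = ca.x_scores[:, i], ca.y_scores[:, i]
        ax.scatter(t, u, s=18, color="tab:blue")
        b = np.polyfit(t, u, 1)
        xs = np.linspace(t.min(), t.max(), 50)
        ax.plot(xs, np.polyval(b, xs), color="tab:red", lw=1.2)
        comp = report.plsca["components"][i]
        ax.set_title(f"component {i + 1}: r={comp['r']:.2f}, p={comp['p']:.3f}")
        ax.set_xlabel("PET scores")
        ax.set_ylabel("fMRI scores")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _pred_vs_obs(report: AnalysisReport, path: Path) -> None:
    outcome = report.behaviour.iloc[:, 0]
    fit = pls_regression(
        report.pet, outcome, n_components=len(report.plsr["pet_weights"])
    )
    fig, ax = plt.subplots(figsize=(4.2, 3.8))
    ax.scatter(outcome, fit.predictions, s=18, color="tab:blue")
    b = np.polyfit(outcome, fit.predictions, 1)
    xs = np.linspace(outcome.min(), outcome.max(), 50)
    ax.plot(xs, np.polyval(b, xs), color="tab:red", lw=1.2)
    ax.set_xlabel(f"observed {report.plsr['outcome']}")
    ax.set_ylabel("predicted")
    ax.set_title(
        f"PLS-R: R²={report.plsr['r_squared']:.2f}, "
        f"RMSE={report.plsr['rmse']:.3f}, p={report.plsr['p']:.3f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def render_report(report: AnalysisReport, outdir) -> Path:
    """Write summary.md plus score-scatter and predicted-vs-observed figures."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _score_scatter(report, out / "plsca_scores.png")
    _pred_vs_obs(report, out / "plsr_pred_vs_obs.png")

    lines = ["# Multimodal analysis summary", ""]
    lines.append(f"Subjects included: {report.pet.shape[0]}")
    excluded = report.exclusions[~report.exclusions["included"]]
    if len(excluded):
        def _fmt(reasons):
            return reasons if isinstance(reasons, str) else "/".join(reasons)

        lines.append("Excluded: " + ", ".join(
            f"{s} ({_fmt(excluded.loc[s, 'reasons'])})" for s in excluded.index
        ))
    else:
        lines.append("Excluded: none")
    lines += ["", "## PLS canonical analysis (PET vs fMRI)", "",
              "| component | r | Cov | p |", "|---|---|---|---|"]
    for comp in report.plsca["components"]:
        lines.append(
            f"| {comp['component']} | {comp['r']:.3f} | {comp['cov']:.3f} | {comp['p']:.3f} |"
        )
    lines += ["", "### Weights", ""]
    for comp in report.plsca["components"]:
        lines.append(f"Component {comp['component']} PET weights: "
                     + ", ".join(f"{r}={w:.3f}" for r, w in comp["pet_weights"].items()))
        lines.append(f"Component {comp['component']} fMRI weights: "
                     + ", ".join(f"{r}={w:.3f}" for r, w in comp["fmri_weights"].items()))
    lines += ["", "## PLS regression (PET vs behaviour)", "",
              f"Outcome: {report.plsr['outcome']}; "
              f"R² = {report.plsr['r_squared']:.3f}, RMSE = {report.plsr['rmse']:.4f}, "
              f"p = {report.plsr['p']:.3f}", ""]
    lines += ["## Exploratory per-ROI Pearson correlations", ""]
    if len(report.exploratory) == 0:
        lines.append("no results")
    else:
        lines += ["| roi | pair | r | p (uncorrected) |", "|---|---|---|---|"]
        for _, row in report.exploratory.iterrows():
            lines.append(
                f"| {row['roi']} | {row['pair']} | {row['r']:.3f} | {row['p_uncorrected']:.3f} |"
            )
    lines += ["", "## Regional PET variability", "",
              "| roi | variance | CV |", "|---|---|---|"]
    for roi, row in report.variability.iterrows():
        lines.append(f"| {roi} | {row['variance']:.4f} | {row['cv']:.4f} |")
    lines.append("")
    (out / "summary.md").write_text("\n".join(lines))
    return out
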