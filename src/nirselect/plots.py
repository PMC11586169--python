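"""Diagnostic plots: spectra, outlier map, RMSECV trace, predicted-vs-measured."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .containers import SpectrumSet  # noqa: E402

__all__ = ["plot_spectra", "plot_outlier_map", "plot_rmsecv_trace",
           "plot_pred_vs_measured", "run_diagnostics"]


def plot_spectra(sset: SpectrumSet, path: str | Path, title: str = "Spectra") -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(sset.wavelengths, sset.intensities.T, lw=0.4, alpha=0.6)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel("intensity")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_outlier_map(report, path: str | Path) -> None:
    """Mean vs STD of per-sample prediction errors, flagged samples annotated."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    flagged = set(report.flagged_ids)
    for sid, m, s in zip(report.sample_ids, report.mean_error, report.std_error):
        if sid in flagged:
            ax.scatter(m, s, color="crimson", zorder=3)
            ax.annotate(sid, (m, s), fontsize=7)
        else:
            ax.scatter(m, s, color="steelblue", s=12, alpha=0.7)
    ax.set_xlabel("mean |prediction error| (% SSC)")
    ax.set_ylabel("STD of prediction error (% SSC)")
    ax.set_title("Monte-Carlo outlier map")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rmsecv_trace(trace, path: str | Path, title: str = "BVS-PLS iterations") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(range(len(trace)), trace, marker="o", ms=3)
    ax.set_xlabel("iteration")
    ax.set_ylabel("RMSECV (% SSC)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pred_vs_measured(y, y_hat, path: str | Path, label: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4.8, 4.8))
    ax.scatter(y, y_hat, s=18, alpha=0.8)
    lo, hi = min(y.min(), y_hat.min()), max(y.max(), y_hat.max())
    ax.plot([lo, hi], [lo, hi], "k--", lw=0.8)
    ax.set_xlabel("measured SSC (%)")
    ax.set_ylabel("predicted SSC (%)")
    ax.set_title(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_diagnostics(report, out_dir: str | Path) -> None:
    """Write the standard plot set for a pipeline RunReport with artifacts."""
    out = Path(out_dir)
    art = report.artifacts
    if "calibration" in art:
        plot_spectra(art["calibration"], out / "calibration_spectra.png",
                     "Preprocessed calibration spectra")
    if "outlier_report" in art:
        plot_outlier_map(art["outlier_report"], out / "outlier_map.png")
    if "combined" in art:
        plot_rmsecv_trace(art["combined"].bvs.rmsecv_trace, out / "bvs_trace.png")
    if "selected_model" in art and "prediction" in art:
        from . import pls, selection
        model = art["selected_model"]
        bins = art["combined"].selected_bins
        Xp = selection.bin_matrix(art["prediction"].intensities,
                                  art["combined"].grouping.n)[:, bins]
        plot_pred_vs_measured(art["prediction_ref"].ssc, pls.predict(model, Xp),
                              out / "pred_vs_measured.png", "Selected-wavelength model")
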