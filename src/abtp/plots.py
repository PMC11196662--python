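"""Figure export: LASSO path, fitted sigmoids with TT50, triage chart."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .effective import EffectiveIndexModel, iso_probability_contour  # noqa: E402
from .lasso import LassoPath  # noqa: E402
from .models import ModelFit, predict  # noqa: E402
from .thi import TriageBands  # noqa: E402

__all__ = ["plot_lasso_path", "plot_sigmoids", "plot_triage_chart"]


def plot_lasso_path(path: LassoPath, out_file) -> None:
    """Coefficient trajectories against the (log) penalty."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for j, name in enumerate(path.feature_names):
        ax.plot(np.log10(path.lambdas), path.coefs[j], label=name)
    if path.selected_lambda is not None:
        ax.axvline(np.log10(path.selected_lambda), ls="--", c="grey", lw=0.8)
    ax.set_xlabel(r"$\log_{10}\lambda$")
    ax.set_ylabel("standardized coefficient")
    ax.invert_xaxis()
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_file, dpi=150)
    plt.close(fig)


def plot_sigmoids(fits: dict[str, ModelFit], thi_range=(55.0, 95.0), out_file=None):
    """Overlay the fitted ABTP curves with their TT50 markers."""
    grid = np.linspace(*thi_range, 400)
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, fit in fits.items():
        ax.plot(grid, predict(fit.params, grid),
                label=f"{name} (TT50={fit.params.tn50:.2f})")
        ax.axvline(fit.params.tn50, ls=":", lw=0.6, c="grey")
    ax.axhline(0.5, ls="--", lw=0.6, c="grey")
    ax.set_xlabel("THI")
    ax.set_ylabel("abnormal body temperature probability")
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    if out_file is not None:
        fig.savefig(out_file, dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_triage_chart(model: EffectiveIndexModel, bands: TriageBands, out_file,
                      temp_range=(36.5, 41.0), qs=(0.2, 0.5)) -> None:
    """Two-region management chart: triage temperatures, THI alert, contours."""
    temps = np.linspace(*temp_range, 60)
    fig, ax = plt.subplots(figsize=(6, 4))
    for q in qs:
        t, thi, ok = iso_probability_contour(model, q, temps)
        ax.plot(thi[ok], t[ok], label=f"ABTP = {int(q * 100)}%")
    ax.axhspan(temp_range[0], bands.normal_below, color="tab:green", alpha=0.15)
    ax.axhspan(bands.normal_below, bands.observe_upper, color="tab:orange", alpha=0.15)
    ax.axhspan(bands.observe_upper, temp_range[1], color="tab:red", alpha=0.15)
    ax.axhline(bands.normal_below, c="tab:orange", lw=0.8)
    ax.axhline(bands.observe_upper, c="tab:red", lw=0.8)
    ax.axvline(bands.thi_alert, c="tab:red", ls="--", lw=0.8,
               label=f"THI alert > {bands.thi_alert:g}")
    ax.set_xlabel("THI")
    ax.set_ylabel("body temperature (°C)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_file, dpi=150)
    plt.close(fig)
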