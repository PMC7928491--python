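"""Static QC figures: dwell-time histograms and stability plots.

Display only — nothing here feeds back into fitting.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .dwell import ExponentialMixtureResults, dwell_histogram  # noqa: E402

__all__ = ["plot_dwell_histogram", "plot_stability"]


def plot_dwell_histogram(
    dwells,
    fit: ExponentialMixtureResults | None = None,
    bins_per_decade: int = 10,
    ax=None,
    title: str = "",
):
    """Log-binned, square-root-ordinate dwell histogram with fit overlay.

    On these axes each exponential component appears as a peak at its
    time constant.
    """
    if ax is None:
        _, ax = plt.subplots()
    h = dwell_histogram(dwells, bins_per_decade=bins_per_decade)
    edges = h["edges"]
    centers = np.sqrt(edges[:-1] * edges[1:])
    ax.step(centers, h["sqrt_counts"], where="mid", lw=1, color="0.3",
            label=f"n = {len(dwells)}")
    if fit is not None:
        t = np.logspace(np.log10(edges[0]), np.log10(edges[-1]), 400)
        # expected sqrt-counts per log bin: n * t f(t) * ln(10)/bins
        dens = fit.pdf(t) * t * np.log(10.0) / bins_per_decade * len(dwells)
        ax.plot(t, np.sqrt(np.maximum(dens, 0.0)), "r-", lw=1.5,
                label=f"{fit.k}-exponential fit")
        for c in fit.components:
            ax.axvline(c.tau, color="r", ls=":", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("dwell time (ms)")
    ax.set_ylabel("sqrt(count)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_stability(profile, axs=None):
    """Windowed stability statistics with their fitted trends."""
    cols = ["mean_open_amplitude", "mean_open_duration",
            "mean_closed_duration", "event_rate"]
    if axs is None:
        _, axs = plt.subplots(len(cols), 1, sharex=True, figsize=(6, 8))
    trends = profile.attrs.get("trends", {})
    for ax, col in zip(np.atleast_1d(axs), cols):
        ax.plot(profile["t_mid"], profile[col], "o-", ms=3)
        tr = trends.get(col, {})
        if np.isfinite(tr.get("slope", np.nan)):
            t = profile["t_mid"].to_numpy()
            ok = profile[col].notna()
            b = profile.loc[ok, col].mean() - tr["slope"] * t[ok].mean()
            ax.plot(t, tr["slope"] * t + b, "r--", lw=1,
                    label=f"slope p = {tr['p_value']:.3f}")
            ax.legend(frameon=False, fontsize=7)
        ax.set_ylabel(col.replace("_", " "), fontsize=8)
    np.atleast_1d(axs)[-1].set_xlabel("time (s)")
    return axs
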