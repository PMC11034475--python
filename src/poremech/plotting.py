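"""Basic QC figures: force-indentation curves with fit overlays and
ensemble histograms with their Gaussian peaks."""

from __future__ import annotations

import numpy as np

NM = 1e-9
PN = 1e-12


def plot_indentation_fit(delta, force_data, fit_result=None, model=None,
                         ax=None):
    """F-delta scatter with the fitted forward model overlaid.

    ``model`` is the :class:`~poremech.fitting.MembraneIndentationModel`
    used for the fit (needed to evaluate the forward law).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.asarray(delta) / NM, np.asarray(force_data) / PN, ".",
            ms=3, alpha=0.6, label="data")
    if fit_result is not None and model is not None and fit_result.converged:
        dd = np.linspace(0, float(np.max(delta)), 200)
        ff = model.predict(fit_result.E, fit_result.sigma, dd)
        ax.plot(dd / NM, ff / PN, "--", lw=2,
                label=(f"fit: E={fit_result.E_MPa:.0f} MPa, "
                       f"sigma={fit_result.sigma_mN_per_m:.1f} mN/m"))
    ax.set_xlabel("indentation [nm]")
    ax.set_ylabel("force [pN]")
    ax.legend()
    return ax


def plot_peak_histogram(values, peak_fit=None, ax=None, xlabel=""):
    """Histogram of ensemble values with the fitted Gaussian overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    values = np.asarray(values, dtype=float)
    bins = peak_fit.bin_edges if peak_fit is not None else "fd"
    ax.hist(values, bins=bins, alpha=0.6, edgecolor="k")
    if peak_fit is not None:
        x = np.linspace(values.min(), values.max(), 300)
        y = peak_fit.amplitude * np.exp(
            -0.5 * ((x - peak_fit.peak) / peak_fit.width) ** 2)
        ax.plot(x, y, "r-", lw=2,
                label=f"peak = {peak_fit.peak:.1f} +/- {peak_fit.peak_se:.1f}")
        ax.legend()
    ax.set_xlabel(xlabel or getattr(peak_fit, "variable_name", ""))
    ax.set_ylabel("count")
    return ax
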