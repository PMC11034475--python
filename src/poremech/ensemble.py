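"""Per-condition ensemble statistics.

Breakthrough-force and Young's-modulus ensembles are summarised by the
peak of a Gaussian fitted to their histogram (the histograms of membrane
ensembles are unimodal but need not be symmetric, so the histogram-fit
peak is used rather than the sample mean); the pre-stress is summarised as
mean +/- standard error.  The bending rigidity
``kappa = E h^3 / (12 (1 - nu^2))`` and the area-stretching modulus
``E2D = E h`` are derived from the modulus peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DataError

__all__ = [
    "GaussianPeakFit",
    "EnsembleSummary",
    "fit_gaussian_peak",
    "bootstrap_peak_se",
    "summarize_sigma",
    "bending_rigidity",
    "e2d",
    "summarize_condition",
]

MPA = 1e6
MN_PER_M = 1e-3
PN = 1e-12
NM = 1e-9


@dataclass
class GaussianPeakFit:
    """Gaussian fitted to a histogram of ensemble values.

    ``peak`` is the location of the Gaussian maximum in the units of the
    variable, ``peak_se`` its standard error from the fit covariance,
    ``width`` the Gaussian sd.  ``reliable`` is False when the reduced
    Poisson chi-square of the histogram fit is large (e.g. bimodal input),
    in which case the peak should not be reported as a distribution
    summary.
    """

    peak: float
    peak_se: float
    width: float
    amplitude: float
    bin_edges: np.ndarray = field(repr=False)
    n: int
    chi2_red: float
    variable_name: str = ""

    @property
    def reliable(self) -> bool:
        return self.chi2_red < 3.0


def _histogram_fd(values: np.ndarray, min_bins: int = 8):
    """Freedman-Diaconis binning with a floor on the bin count."""
    edges = np.histogram_bin_edges(values, bins="fd")
    if len(edges) - 1 < min_bins:
        edges = np.histogram_bin_edges(values, bins=min_bins)
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges


def fit_gaussian_peak(values, variable_name: str = "",
                      min_bins: int = 8) -> GaussianPeakFit:
    """Least-squares Gaussian (amplitude, peak, width) on histogram counts.

    Requires at least 20 finite values; raises on degenerate (all equal)
    input.  Binning is Freedman-Diaconis with a floor of ``min_bins``
    bins; the peak estimate is insensitive to the binning for unimodal
    samples of realistic size.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 20:
        raise DataError(f"need >= 20 finite values for a Gaussian peak fit, "
                        f"got {values.size}")
    if np.ptp(values) == 0:
        raise DataError("degenerate input: all values equal")

    counts, edges = _histogram_fd(values, min_bins=min_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, mu, w):
        return a * np.exp(-0.5 * ((x - mu) / w) ** 2)

    p0 = [counts.max(), float(np.mean(values)), float(np.std(values))]
    popt, pcov = curve_fit(gauss, centers, counts.astype(float), p0=p0,
                           maxfev=10000)
    a, mu, w = popt
    resid = counts - gauss(centers, *popt)
    dof = max(len(counts) - 3, 1)
    # Poisson-weighted residuals: large for shapes a Gaussian cannot match
    chi2_red = float(np.sum(resid**2 / np.maximum(gauss(centers, *popt), 1.0))
                     / dof)
    return GaussianPeakFit(
        peak=float(mu), peak_se=float(np.sqrt(max(pcov[1, 1], 0.0))),
        width=abs(float(w)), amplitude=float(a), bin_edges=edges,
        n=int(values.size), chi2_red=chi2_red, variable_name=variable_name)


def bootstrap_peak_se(values, n_boot: int = 200, seed: int = 0,
                      min_bins: int = 8) -> float:
    """Bootstrap standard error of the histogram-fit peak.

    Cross-check for the covariance-based ``peak_se`` (which ignores the
    variability of the binning itself): resamples the values with
    replacement and refits the Gaussian each time.
    """
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    peaks = []
    for _ in range(n_boot):
        sample = rng.choice(values, size=values.size, replace=True)
        try:
            peaks.append(fit_gaussian_peak(sample, min_bins=min_bins).peak)
        except (DataError, RuntimeError):
            continue
    if len(peaks) < n_boot // 2:
        raise DataError("bootstrap failed on most resamples")
    return float(np.std(peaks, ddof=1))


def summarize_sigma(results) -> tuple[float, float]:
    """Mean and standard error of per-curve pre-stress [N/m].

    ``results`` is a list of kept fit results (or raw sigma values in
    N/m); at least 3 entries are required.
    """
    sigmas = np.asarray(
        [getattr(r, "sigma", r) for r in results], dtype=float)
    if sigmas.size < 3:
        raise DataError(f"need >= 3 kept results to summarise sigma, "
                        f"got {sigmas.size}")
    mean = float(np.mean(sigmas))
    se = float(np.std(sigmas, ddof=1) / np.sqrt(sigmas.size))
    return mean, se


def bending_rigidity(E: float, h: float, nu: float) -> float:
    """Thin-plate bending rigidity kappa = E h^3 / (12 (1 - nu^2)) [J]."""
    if E <= 0 or h <= 0 or not 0 <= nu < 0.5:
        raise ValueError("require E > 0, h > 0, 0 <= nu < 0.5")
    return E * h**3 / (12.0 * (1.0 - nu**2))


def e2d(E: float, h: float) -> float:
    """Area-stretching (2D) modulus E2D = E * h [N/m]."""
    if E <= 0 or h <= 0:
        raise ValueError("require E > 0 and h > 0")
    return E * h


@dataclass
class EnsembleSummary:
    """Per-condition summary of an analysed curve ensemble."""

    condition: str
    n_curves: int
    n_kept: int
    bf_fit: GaussianPeakFit | None     # pN
    e_fit: GaussianPeakFit | None      # MPa, post-filter values only
    sigma_mean: float | None           # N/m
    sigma_se: float | None             # N/m
    kappa: float | None                # J, from the E peak
    e2d: float | None                  # N/m, from the E peak

    def to_json_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_curves": self.n_curves,
            "n_kept": self.n_kept,
            "bf_peak_pN": None if self.bf_fit is None else self.bf_fit.peak,
            "bf_peak_se": None if self.bf_fit is None else self.bf_fit.peak_se,
            "E_peak_MPa": None if self.e_fit is None else self.e_fit.peak,
            "E_peak_se": None if self.e_fit is None else self.e_fit.peak_se,
            "sigma_mean_mN_m": None if self.sigma_mean is None
            else self.sigma_mean / MN_PER_M,
            "sigma_se": None if self.sigma_se is None
            else self.sigma_se / MN_PER_M,
            "kappa_J": self.kappa,
            "e2d_N_m": self.e2d,
        }


def summarize_condition(condition: str, bf_values_N, fit_results,
                        n_curves: int, h: float, nu: float,
                        threshold: float = 0.03) -> EnsembleSummary:
    """Build the per-condition summary from extracted BFs and fits.

    ``bf_values_N`` are breakthrough forces [N] of all curves with a
    rupture; ``fit_results`` all per-curve fit results of the condition.
    The delta/R inclusion rule applies to the E ensemble only (shallow
    curves carry no modulus information), which additionally keeps only
    fits whose E is identifiable; the pre-stress is summarised over every
    converged fit.  kappa and E2D derive from the E-peak with the
    condition's nominal h and nu.
    """
    bf_fit = None
    if len(bf_values_N) >= 20:
        bf_fit = fit_gaussian_peak(np.asarray(bf_values_N) / PN,
                                   variable_name="BF_pN")
    converged = [r for r in fit_results if r.converged]
    kept = [r for r in converged if r.delta_over_R > threshold]
    e_values = [r.E for r in kept if getattr(r, "e_identifiable", True)]
    e_fit = None
    if len(e_values) >= 20:
        e_fit = fit_gaussian_peak(np.asarray(e_values) / MPA,
                                  variable_name="E_MPa")
    sigma_mean = sigma_se = None
    if len(converged) >= 3:
        sigma_mean, sigma_se = summarize_sigma(converged)
    kappa = kk = None
    if e_fit is not None:
        kappa = bending_rigidity(e_fit.peak * MPA, h, nu)
        kk = e2d(e_fit.peak * MPA, h)
    return EnsembleSummary(
        condition=condition, n_curves=n_curves, n_kept=len(kept),
        bf_fit=bf_fit, e_fit=e_fit, sigma_mean=sigma_mean, sigma_se=sigma_se,
        kappa=kappa, e2d=kk)
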