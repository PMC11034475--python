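"""Estimate (E, sigma) per curve by nonlinear least squares.

The fitting surface follows the model/results idiom: a
:class:`MembraneIndentationModel` is built from the post-contact,
pre-breakthrough (F, delta) data of one curve together with the fixed
geometry (h, R, nu); its :meth:`~MembraneIndentationModel.fit` returns a
:class:`MembraneFitResult` carrying the estimates, their standard errors
from the fit covariance, diagnostics and a ``summary()`` table.

Two details matter for unbiased estimates at realistic noise:

* When the indentation axis was built by the tip-sample separation
  construction ``delta = zeta - (F - F0)/k``, the fit works against the
  piezo coordinate ``zeta`` reconstructed from the data (the
  reconstruction exactly undoes the construction, so ``zeta`` is
  noise-free).  Fitting in (delta, F) would couple the same force-noise
  realisation into both axes and systematically bias E low.
* The contact position is refined as a bounded nuisance parameter ``z0``:
  threshold-based contact detection is systematically late by roughly
  noise/slope because the membrane's early response rises slowly out of
  the noise, and a nanometre of contact error already distorts sigma by
  several percent.  A window of baseline-corrected pre-contact samples
  (force ~ 0) anchors the fit on the far side of the contact point.

The linear (tension) and cubic (stretching) contributions are nearly
degenerate at small indentation, so the optimiser is multi-started: a
physics-based initial point (sigma from the early slope over pi, E from a
constrained linear+cubic polynomial fit) plus perturbed restarts.  Fits
whose E lands on a bound or carries a Wald coefficient of variation above
200% are flagged ``e_identifiable = False``: their sigma is still usable
but their E is not (shallow curves constrain only the tension).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DataError
from .fvk import MembraneSpec, ModelKind, force, q_factor

__all__ = [
    "MembraneIndentationModel",
    "MembraneFitResult",
    "fit_curve",
    "apply_indentation_filter",
    "DEFAULT_DELTA_OVER_R_THRESHOLD",
]

MPA = 1e6
MN_PER_M = 1e-3
PN = 1e-12
NM = 1e-9

#: inclusion threshold on delta_max / R below which E is poorly determined
DEFAULT_DELTA_OVER_R_THRESHOLD = 0.03

_E_BOUNDS_MPA = (1e-3, 1e5)
_SIGMA_BOUNDS_MN_M = (0.0, 500.0)
_Z0_BOUND_NM = 10.0


@dataclass
class MembraneFitResult:
    """Converged (or failed) estimate of one membrane's (E, sigma).

    All stored quantities are SI; ``E_MPa``/``sigma_mN_per_m`` expose the
    reporting units.  ``contact_offset`` is the fitted correction to the
    detected contact position (positive = true contact later than
    detected).  ``passed_filter`` reflects the default delta/R > 0.03
    inclusion rule; :func:`apply_indentation_filter` re-partitions with
    any threshold.  ``e_identifiable`` is False when the curve does not
    constrain E (estimate on a bound or CV > 200%); sigma remains valid.
    """

    E: float                  # Pa
    sigma: float              # N/m
    E_stderr: float           # Pa
    sigma_stderr: float       # N/m
    rss: float                # N^2
    n_points: int
    delta_max: float          # m
    delta_over_R: float
    model_kind: ModelKind
    converged: bool
    contact_offset: float = 0.0   # m
    e_identifiable: bool = True
    message: str = ""

    @property
    def E_MPa(self) -> float:
        return self.E / MPA

    @property
    def sigma_mN_per_m(self) -> float:
        return self.sigma / MN_PER_M

    @property
    def rss_pN2(self) -> float:
        return self.rss / PN**2

    @property
    def passed_filter(self) -> bool:
        return self.converged and self.delta_over_R > DEFAULT_DELTA_OVER_R_THRESHOLD

    def summary(self) -> str:
        lines = [
            "Membrane indentation fit",
            "=" * 46,
            f"model kind        {self.model_kind.value}",
            f"converged         {self.converged}",
            f"n points          {self.n_points}",
            f"E      [MPa]      {self.E_MPa:12.4g} +/- {self.E_stderr / MPA:.3g}",
            f"sigma  [mN/m]     {self.sigma_mN_per_m:12.4g} +/- "
            f"{self.sigma_stderr / MN_PER_M:.3g}",
            f"contact offset    {self.contact_offset / NM:12.3g} nm",
            f"delta_max [nm]    {self.delta_max / NM:12.4g}",
            f"delta_max / R     {self.delta_over_R:12.4g}",
            f"rss    [pN^2]     {self.rss_pN2:12.4g}",
            f"E identifiable    {self.e_identifiable}",
            f"passed filter     {self.passed_filter}",
        ]
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)


class MembraneIndentationModel:
    """Point-load membrane model bound to one curve's data.

    Parameters
    ----------
    force_data, indentation :
        Post-contact force [N] and indentation [m] arrays (equal length),
        as produced by the preprocessing stage.
    h, R, nu :
        Fixed bilayer thickness, hole radius [m] and Poisson ratio.
    model_kind :
        Which forward law to fit (exact FvK by default).
    spring_constant :
        Cantilever stiffness [N/m]; when given, the model reconstructs
        and fits against the noise-free piezo coordinate (see module
        docstring).  ``None`` means the data already live on a true
        indentation axis.
    pre_x, pre_force :
        Optional pre-contact anchor window: abscissa values (negative,
        same coordinate as the fit axis) and baseline-corrected forces.
    fit_contact :
        Fit the contact-offset nuisance z0 (default True).
    weights :
        Optional per-point weights for the post-contact points; default
        uniform (AFM deflection noise is force-independent to first
        order).
    """

    def __init__(self, force_data, indentation, *, h: float, R: float,
                 nu: float = 0.485, model_kind=ModelKind.EXACT,
                 weights=None, min_points: int = 20,
                 delta_max: float | None = None,
                 spring_constant: float | None = None,
                 pre_x=None, pre_force=None, fit_contact: bool = True):
        self.force_data = np.asarray(force_data, dtype=float)
        self.indentation = np.asarray(indentation, dtype=float)
        if self.force_data.shape != self.indentation.shape:
            raise DataError("force and indentation lengths differ")
        if self.force_data.size < min_points:
            raise DataError(
                f"fit region has {self.force_data.size} points; "
                f"needs >= {min_points}")
        self.h, self.R, self.nu = float(h), float(R), float(nu)
        self.model_kind = ModelKind.coerce(model_kind)
        self.spring_constant = spring_constant
        if spring_constant is not None and not spring_constant > 0:
            raise DataError("spring_constant must be > 0")
        self.fit_contact = fit_contact
        self.delta_max = (float(np.max(self.indentation))
                          if delta_max is None else float(delta_max))

        if spring_constant is not None:
            f0 = self.force_data[0]
            x_post = self.indentation + (self.force_data - f0) / spring_constant
        else:
            x_post = self.indentation
        w_post = (np.ones_like(self.force_data) if weights is None
                  else np.asarray(weights, dtype=float))
        if pre_x is not None and len(pre_x) > 0:
            pre_x = np.asarray(pre_x, dtype=float)
            pre_force = np.asarray(pre_force, dtype=float)
            self.x_data = np.concatenate([pre_x, x_post])
            self.y_data = np.concatenate([pre_force, self.force_data])
            self.weights = np.concatenate([np.ones(pre_x.size), w_post])
        else:
            self.x_data = x_post
            self.y_data = self.force_data
            self.weights = w_post

    @classmethod
    def from_curve(cls, force_data, indentation, event=None, *, h, R,
                   nu=0.485, model_kind=ModelKind.EXACT,
                   fit_margin_samples: int = 3, min_points: int = 20,
                   spring_constant: float | None = None,
                   pre_x=None, pre_force=None, fit_contact: bool = True):
        """Build the model from a full post-contact segment.

        When a breakthrough ``event`` is given (indices relative to the
        segment), the fit region ends ``fit_margin_samples`` before the
        event so the rupture transient is excluded, and ``delta_max`` is
        the indentation at rupture.
        """
        force_data = np.asarray(force_data, dtype=float)
        indentation = np.asarray(indentation, dtype=float)
        if event is not None:
            end = max(event.index - fit_margin_samples, 0)
            delta_max = event.delta_at_bf
        else:
            end = force_data.size
            delta_max = float(indentation.max(initial=0.0))
        return cls(force_data[:end], indentation[:end], h=h, R=R, nu=nu,
                   model_kind=model_kind, min_points=min_points,
                   delta_max=delta_max, spring_constant=spring_constant,
                   pre_x=pre_x, pre_force=pre_force, fit_contact=fit_contact)

    # ------------------------------------------------------------------
    def predict(self, E: float, sigma: float, delta=None):
        """Forward force law [N] at the model's geometry."""
        if delta is None:
            delta = self.indentation
        spec = MembraneSpec(E=E, sigma=sigma, h=self.h, R=self.R, nu=self.nu)
        return force(delta, spec, self.model_kind)

    def predict_measured(self, E: float, sigma: float, z0: float = 0.0,
                         x=None):
        """Force at measured abscissa values (piezo or indentation axis).

        On the piezo axis the spring acts in series with the membrane:
        ``delta + F(delta)/k = zeta - z0`` is inverted on a fine grid.
        Abscissae left of the (shifted) contact give zero force.
        """
        if x is None:
            x = self.x_data
        x = np.asarray(x, dtype=float)
        xs = x - z0
        span = float(np.max(xs, initial=0.0))
        if span <= 0:
            return np.zeros_like(xs)
        dgrid = np.linspace(0.0, 1.05 * span, 1500)
        fgrid = self.predict(E, sigma, dgrid)
        if self.spring_constant is not None:
            xgrid = dgrid + fgrid / self.spring_constant
        else:
            xgrid = dgrid
        return np.interp(xs, xgrid, fgrid, left=0.0)

    def _residuals(self, p):
        E, sigma = p[0] * MPA, p[1] * MN_PER_M
        z0 = p[2] * NM if len(p) > 2 else 0.0
        model = self.predict_measured(E, sigma, z0)
        return self.weights * (model - self.y_data) / PN

    def _initial_points(self):
        d, f = self.indentation, self.force_data
        # sigma0 from the early slope of the fit region divided by pi
        k = max(3, d.size // 3)
        slope = np.polyfit(d[:k], f[:k], 1)[0] if d[k - 1] > d[0] else 0.0
        sigma0 = max(slope / math.pi, 1e-2 * MN_PER_M)
        # E0 from the cubic coefficient of a linear+cubic least-squares fit
        A = np.column_stack([d, d**3])
        coef, *_ = np.linalg.lstsq(A, f, rcond=None)
        q3 = q_factor(self.nu) ** 3
        E0 = coef[1] * self.R**2 / q3 / self.h
        if not np.isfinite(E0) or E0 <= 0:
            E0 = 100.0 * MPA
        base = np.array([E0 / MPA, sigma0 / MN_PER_M])
        starts = [np.append(base, 0.0),
                  np.append(base * [5.0, 0.5], -2.0),
                  np.append(base * [0.2, 2.0], 1.0)]
        if not self.fit_contact:
            starts = [s[:2] for s in starts]
        return starts

    def fit(self, restarts: int = 2) -> MembraneFitResult:
        """Weighted least squares with multi-start initialisation.

        ``restarts`` limits how many perturbed starts are tried beyond the
        physics-based one.  The best converged start (lowest residual sum
        of squares) wins; standard errors come from the Gauss-Newton
        covariance ``(J'J)^-1 * rss/dof`` of that solution.
        """
        npar = 3 if self.fit_contact else 2
        lb = [_E_BOUNDS_MPA[0], _SIGMA_BOUNDS_MN_M[0], -_Z0_BOUND_NM][:npar]
        ub = [_E_BOUNDS_MPA[1], _SIGMA_BOUNDS_MN_M[1], _Z0_BOUND_NM][:npar]
        starts = self._initial_points()[:1 + restarts]
        best = None
        msgs = []
        for p0 in starts:
            p0 = np.clip(p0, lb, ub)
            try:
                sol = least_squares(
                    self._residuals, p0, bounds=(lb, ub), method="trf",
                    x_scale=np.maximum(np.abs(p0), [1.0, 0.1, 1.0][:npar]))
            except Exception as exc:  # solver failure on this start
                msgs.append(str(exc))
                continue
            if not sol.success:
                msgs.append(sol.message)
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        n = self.y_data.size
        if best is None:
            return MembraneFitResult(
                E=np.nan, sigma=np.nan, E_stderr=np.nan, sigma_stderr=np.nan,
                rss=np.nan, n_points=n, delta_max=self.delta_max,
                delta_over_R=self.delta_max / self.R,
                model_kind=self.model_kind, converged=False,
                message="; ".join(msgs) or "no start converged")

        E, sigma = best.x[0] * MPA, best.x[1] * MN_PER_M
        z0 = best.x[2] * NM if npar == 3 else 0.0
        rss = 2.0 * best.cost * PN**2  # cost = 0.5 * sum(res^2) in pN^2
        dof = max(n - npar, 1)
        JTJ = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(JTJ) * (2.0 * best.cost / dof)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(npar, np.inf)
        # the fitted contact shift also shifts the maximum indentation
        delta_max = self.delta_max - z0
        # E counts as identified when its Wald uncertainty is below the
        # estimate itself (CV < 100%) and the estimate is off the bounds
        e_ident = (se[0] * MPA < 1.0 * E
                   and E / MPA > 2.0 * _E_BOUNDS_MPA[0]
                   and E / MPA < 0.5 * _E_BOUNDS_MPA[1])
        return MembraneFitResult(
            E=E, sigma=sigma,
            E_stderr=se[0] * MPA, sigma_stderr=se[1] * MN_PER_M,
            rss=rss, n_points=n, delta_max=delta_max,
            delta_over_R=delta_max / self.R,
            model_kind=self.model_kind, converged=True,
            contact_offset=z0, e_identifiable=bool(e_ident))


def fit_curve(force_data, indentation, event=None, *, h, R, nu=0.485,
              model_kind=ModelKind.EXACT, fit_margin_samples: int = 3,
              min_points: int = 20, restarts: int = 2,
              spring_constant: float | None = None,
              pre_x=None, pre_force=None,
              fit_contact: bool = True) -> MembraneFitResult:
    """One-call convenience wrapper around :class:`MembraneIndentationModel`."""
    model = MembraneIndentationModel.from_curve(
        force_data, indentation, event, h=h, R=R, nu=nu,
        model_kind=model_kind, fit_margin_samples=fit_margin_samples,
        min_points=min_points, spring_constant=spring_constant,
        pre_x=pre_x, pre_force=pre_force, fit_contact=fit_contact)
    return model.fit(restarts=restarts)


def apply_indentation_filter(results, threshold: float = DEFAULT_DELTA_OVER_R_THRESHOLD):
    """Partition fit results by the delta/R inclusion rule.

    ``kept`` holds converged results with ``delta_over_R`` strictly above
    the threshold (curves indented deep enough for E to be identifiable);
    ``excluded`` holds (result, reason) pairs.  A result exactly at the
    threshold is excluded.
    """
    kept, excluded = [], []
    for r in results:
        if not r.converged:
            excluded.append((r, "not_converged"))
        elif not r.delta_over_R > threshold:
            excluded.append((r, "delta_over_R_below_threshold"))
        else:
            kept.append(r)
    return kept, excluded
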