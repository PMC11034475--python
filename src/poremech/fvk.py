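"""Forward models for a clamped, pre-stressed circular membrane under a
central point load.

Two force-indentation laws F(delta) are provided for a pore-spanning bilayer
of Young's modulus ``E``, pre-stress ``sigma``, thickness ``h`` spanning a
hole of radius ``R``:

``approx_superposition``
    The widely used linear superposition of the two limiting regimes,

        F = pi * sigma * delta + E2D * q**3 * delta**3 / R**2,

    with ``E2D = E*h`` the area-stretching (2D) modulus and
    ``q = 1/(1.049 - 0.146 nu - 0.158 nu**2)`` the conventional
    Poisson-ratio prefactor of the zero-tension (Schwerin) cubic law.

``exact_fvk``
    The numerical solution of the axisymmetric Foeppl-von-Karman membrane
    boundary-value problem (no bending term): vertical equilibrium
    ``2 pi r N_r w' = -F``, in-plane equilibrium ``d(r N_r)/dr = N_t``,
    linear constitutive relations with modulus ``E2D`` and Poisson ratio
    ``nu``, a clamped edge whose reference state carries the isotropic
    pre-tension ``sigma``, and a Schwerin-type inner asymptote at a small
    cutoff radius regularising the point load.  This law interpolates the
    tension-dominated (quasi-linear) and stretching-dominated (cubic)
    regimes exactly and has no closed form.

Dimensionless structure
-----------------------
With ``x = r/R``, ``G = r N_r / (E2D R)``, ``f = F/(E2D R)``,
``s = sigma/E2D`` and ``t = ln x`` the problem reads

    G_tt - G = -(f**2 / 8 pi**2) * e**t / G**2,      t in [ln x0, 0]
    3 G_t = G                  at t = ln x0   (core asymptote G ~ x**(1/3))
    G_t - nu G = s (1 - nu)    at t = 0       (pre-stressed clamped edge)

and the deflection is ``delta/R = f/(2 pi) * int e**t / G dt`` plus the
analytic core contribution below the cutoff.  Because the inner boundary
condition is homogeneous in G, the solution family obeys the exact scaling
``f(d, s) = s**1.5 * Phi(d/sqrt(s); nu)`` where ``d = delta/R``; at
``s = 0`` it degenerates to the pure cubic ``f = C(nu) * d**3``.  The whole
exact model therefore reduces to one scalar profile ``Phi`` per Poisson
ratio, built once by parameter continuation and cached in-process.
"""

from __future__ import annotations

import enum
import math
import threading
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_bvp
from scipy.interpolate import PchipInterpolator

from .errors import ConfigError, SolverError

__all__ = [
    "MembraneSpec",
    "ModelKind",
    "q_factor",
    "force_approx",
    "force_exact",
    "force",
    "FvkProfile",
    "get_profile",
    "solve_point_load",
]

#: default inner cutoff radius of the point load, as a fraction of R
DEFAULT_INNER_CUTOFF = 1e-4


@dataclass(frozen=True)
class MembraneSpec:
    """Mechanical parameter set of one pore-spanning membrane.

    Parameters
    ----------
    E : float
        Young's modulus [Pa].
    sigma : float
        Pre-stress (in-plane membrane tension) [N/m].
    h : float
        Bilayer thickness [m].
    R : float
        Hole radius [m].
    nu : float
        Poisson ratio (dimensionless), must lie in (0, 0.5).
    """

    E: float
    sigma: float
    h: float
    R: float
    nu: float = 0.485

    def __post_init__(self):
        if not self.E > 0:
            raise ValueError(f"E must be > 0, got {self.E}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not self.h > 0:
            raise ValueError(f"h must be > 0, got {self.h}")
        if not self.R > 0:
            raise ValueError(f"R must be > 0, got {self.R}")
        if not 0 < self.nu < 0.5:
            raise ValueError(f"nu must be in (0, 0.5), got {self.nu}")

    @property
    def e2d(self) -> float:
        """Area-stretching (2D) modulus E2D = E*h [N/m]."""
        return self.E * self.h


class ModelKind(str, enum.Enum):
    """Which force-indentation law to evaluate."""

    APPROX = "approx_superposition"
    EXACT = "exact_fvk"

    @classmethod
    def coerce(cls, kind) -> "ModelKind":
        if isinstance(kind, cls):
            return kind
        try:
            return cls(kind)
        except ValueError:
            raise ConfigError(
                f"unknown model kind {kind!r}; expected one of "
                f"{[k.value for k in cls]}"
            ) from None


def q_factor(nu: float) -> float:
    """Poisson-ratio prefactor of the zero-tension cubic law."""
    return 1.0 / (1.049 - 0.146 * nu - 0.158 * nu**2)


def _check_delta(delta):
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("indentation delta must be >= 0")
    return delta


def force_approx(delta, spec: MembraneSpec):
    """Linear + cubic superposition force law [N].

    ``F = pi*sigma*delta + E2D * q^3 * delta^3 / R^2``.  Valid for small
    indentations (delta up to roughly 0.2 R); larger values are evaluated
    but should be treated with care by the caller.
    """
    delta = _check_delta(delta)
    q3 = q_factor(spec.nu) ** 3
    return math.pi * spec.sigma * delta + spec.e2d * q3 * delta**3 / spec.R**2


# ---------------------------------------------------------------------------
# exact model: dimensionless BVP and cached profile
# ---------------------------------------------------------------------------


def _solve_bvp_once(f: float, s: float, nu: float, t0: float, guess=None,
                    tol: float = 1e-8):
    """Solve the dimensionless membrane BVP for one (f, s, nu)."""
    c = f * f / (8.0 * math.pi**2)

    def rhs(t, y):
        G, Gt = y
        return np.vstack([Gt, G - c * np.exp(t) / (G * G)])

    def bc(ya, yb):
        return np.array([3.0 * ya[1] - ya[0],
                         yb[1] - nu * yb[0] - s * (1.0 - nu)])

    if guess is None:
        t = np.linspace(t0, 0.0, 201)
        # pre-tension background plus Schwerin core of the right amplitude
        a_core = (9.0 * f * f / (64.0 * math.pi**2)) ** (1.0 / 3.0)
        g = s * np.exp(t) + a_core * np.exp(t / 3.0)
        y = np.vstack([g, s * np.exp(t) + (a_core / 3.0) * np.exp(t / 3.0)])
    else:
        t, y = guess
    return solve_bvp(rhs, bc, t, y, tol=tol, max_nodes=50000)


def solve_point_load(f: float, s: float, nu: float,
                     inner_cutoff: float = DEFAULT_INNER_CUTOFF,
                     guess=None) -> tuple[float, object]:
    """Direct BVP solve: dimensionless deflection d = delta/R for load f.

    This is the slow reference path; :func:`force_exact` goes through the
    cached profile instead.  Returns ``(d, solution)`` where ``solution``
    is the scipy BVP result (usable as a warm start).
    """
    t0 = math.log(inner_cutoff)
    sol = _solve_bvp_once(f, s, nu, t0, guess=guess)
    if sol.status != 0:
        raise SolverError("FvK membrane BVP did not converge",
                          {"f": f, "s": s, "nu": nu, "x0": inner_cutoff})
    tt = np.linspace(t0, 0.0, 4001)
    G = sol.sol(tt)[0]
    d = f / (2.0 * math.pi) * np.trapezoid(np.exp(tt) / G, tt)
    # analytic core below the cutoff: G ~ A x^(1/3)
    a_core = sol.sol(t0)[0][()] / inner_cutoff ** (1.0 / 3.0)
    d += 1.5 * f * inner_cutoff ** (2.0 / 3.0) / (2.0 * math.pi * a_core)
    return float(d), sol


@dataclass
class FvkProfile:
    """Cached dimensionless force-deflection law of the exact model.

    ``scaled_force(d, s)`` returns ``f = F/(E2D R)`` for ``d = delta/R``
    and ``s = sigma/E2D``; ``scaled_deflection`` is the inverse in d.
    The profile stores ``Phi`` (log-log monotone interpolant of the s=1
    master curve) and the exact Schwerin constant ``C`` for s = 0.
    """

    nu: float
    inner_cutoff: float
    u: np.ndarray            # master-curve deflections d at s = 1
    fvals: np.ndarray        # corresponding loads f at s = 1
    C: float                 # zero-tension cubic constant f = C d^3
    _phi: PchipInterpolator = field(repr=False, default=None)
    _phi_inv: PchipInterpolator = field(repr=False, default=None)

    def __post_init__(self):
        lu, lf = np.log(self.u), np.log(self.fvals)
        self._phi = PchipInterpolator(lu, lf, extrapolate=False)
        self._phi_inv = PchipInterpolator(lf, lu, extrapolate=False)
        # end slopes for log-log extrapolation
        self._lo_slope = (lf[1] - lf[0]) / (lu[1] - lu[0])
        self._lo = (lu[0], lf[0])
        self._hi = (lu[-1], lf[-1])

    # -- Phi and its inverse with controlled extrapolation ---------------
    def _log_phi(self, lu):
        out = self._phi(lu)
        below = lu < self._lo[0]
        above = lu > self._hi[0]
        if np.any(below):
            out[below] = self._lo[1] + self._lo_slope * (lu[below] - self._lo[0])
        if np.any(above):
            # stretching-dominated tail is exactly cubic in the limit
            out[above] = self._hi[1] + 3.0 * (lu[above] - self._hi[0])
        return out

    def _log_phi_inv(self, lf):
        out = self._phi_inv(lf)
        below = lf < self._lo[1]
        above = lf > self._hi[1]
        if np.any(below):
            out[below] = self._lo[0] + (lf[below] - self._lo[1]) / self._lo_slope
        if np.any(above):
            out[above] = self._hi[0] + (lf[above] - self._hi[1]) / 3.0
        return out

    def scaled_force(self, d, s: float):
        """f = F/(E2D R) for deflection(s) d = delta/R at tension s."""
        d = np.asarray(d, dtype=float)
        scalar = d.ndim == 0
        d = np.atleast_1d(d)
        if np.any(d < 0):
            raise ValueError("scaled deflection d must be >= 0")
        f = np.zeros_like(d)
        pos = d > 0
        if s <= 0:
            f[pos] = self.C * d[pos] ** 3
        else:
            rs = math.sqrt(s)
            f[pos] = s * rs * np.exp(self._log_phi(np.log(d[pos] / rs)))
        return f[0] if scalar else f

    def scaled_deflection(self, f, s: float):
        """Inverse law: d = delta/R producing load f at tension s."""
        f = np.asarray(f, dtype=float)
        scalar = f.ndim == 0
        f = np.atleast_1d(f)
        if np.any(f < 0):
            raise ValueError("scaled force f must be >= 0")
        d = np.zeros_like(f)
        pos = f > 0
        if s <= 0:
            d[pos] = (f[pos] / self.C) ** (1.0 / 3.0)
        else:
            rs = math.sqrt(s)
            d[pos] = rs * np.exp(self._log_phi_inv(np.log(f[pos] / (s * rs))))
        return d[0] if scalar else d


_PROFILE_CACHE: dict[tuple, FvkProfile] = {}
_PROFILE_LOCK = threading.Lock()


def build_profile(nu: float, inner_cutoff: float = DEFAULT_INNER_CUTOFF,
                  f_start: float = 1e-5, ladder: float = 1.5,
                  u_max: float = 1.2e3) -> FvkProfile:
    """Build the dimensionless master curve by continuation in the load.

    Solves the BVP at s = 1 on a geometric ladder of loads, warm-starting
    each solve from the previous mesh, until the scaled deflection exceeds
    ``u_max``; one extra solve at s = 0 yields the exact Schwerin constant.
    Takes well under a second; cached by :func:`get_profile`.
    """
    t0 = math.log(inner_cutoff)
    d0, _ = solve_point_load(1.0, 0.0, nu, inner_cutoff)
    C = 1.0 / d0**3

    us, fs = [], []
    f, guess = f_start, None
    while True:
        sol = _solve_bvp_once(f, 1.0, nu, t0, guess=guess)
        if sol.status != 0:
            raise SolverError("profile continuation failed",
                              {"f": f, "s": 1.0, "nu": nu})
        tt = np.linspace(t0, 0.0, 4001)
        G = sol.sol(tt)[0]
        d = f / (2.0 * math.pi) * np.trapezoid(np.exp(tt) / G, tt)
        a_core = sol.sol(t0)[0][()] / inner_cutoff ** (1.0 / 3.0)
        d += 1.5 * f * inner_cutoff ** (2.0 / 3.0) / (2.0 * math.pi * a_core)
        us.append(d)
        fs.append(f)
        # fresh uniform mesh for the warm start; keeps node counts bounded
        tmesh = np.linspace(t0, 0.0, 401)
        guess = (tmesh, sol.sol(tmesh))
        if d > u_max:
            break
        f *= ladder
    return FvkProfile(nu=nu, inner_cutoff=inner_cutoff,
                      u=np.array(us), fvals=np.array(fs), C=C)


def get_profile(nu: float,
                inner_cutoff: float = DEFAULT_INNER_CUTOFF) -> FvkProfile:
    """Return the cached exact-model profile for (nu, inner_cutoff)."""
    key = (round(float(nu), 6), float(inner_cutoff))
    prof = _PROFILE_CACHE.get(key)
    if prof is None:
        with _PROFILE_LOCK:
            prof = _PROFILE_CACHE.get(key)
            if prof is None:
                prof = build_profile(nu, inner_cutoff)
                _PROFILE_CACHE[key] = prof
    return prof


def force_exact(delta, spec: MembraneSpec,
                inner_cutoff: float = DEFAULT_INNER_CUTOFF):
    """Exact FvK point-load force law [N], via the cached profile."""
    delta = _check_delta(delta)
    prof = get_profile(spec.nu, inner_cutoff)
    e2d = spec.e2d
    return e2d * spec.R * prof.scaled_force(delta / spec.R, spec.sigma / e2d)


def indentation_exact(F, spec: MembraneSpec,
                      inner_cutoff: float = DEFAULT_INNER_CUTOFF):
    """Inverse of :func:`force_exact`: delta [m] producing force F [N]."""
    F = np.asarray(F, dtype=float)
    prof = get_profile(spec.nu, inner_cutoff)
    e2d = spec.e2d
    return spec.R * prof.scaled_deflection(F / (e2d * spec.R), spec.sigma / e2d)


def force(delta, spec: MembraneSpec, kind=ModelKind.EXACT):
    """Dispatch to the requested force law; both share one signature."""
    kind = ModelKind.coerce(kind)
    if kind is ModelKind.APPROX:
        return force_approx(delta, spec)
    return force_exact(delta, spec)
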