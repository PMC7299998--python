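"""Nucleation-elongation kinetics for unseeded amyloid fibril formation.

Implements the combined rate parameters ``lambda`` (primary pathway) and
``kappa`` (secondary pathway), the closed-form fibril mass fraction of the
standard nucleation-elongation master equation, a moment-ODE reference
integrator, and the empirical sigmoidal (logistic) signal model.

Internal units are molar and seconds throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "RateConstants",
    "KineticState",
    "ClosedFormCoefficients",
    "SigmoidalParams",
    "DegenerateModelError",
    "IntegrationError",
    "compute_lambda",
    "compute_kappa",
    "closed_form_coefficients",
    "fibril_mass_fraction",
    "mass_fraction_from_lambda_kappa",
    "model_mass_fraction",
    "integrate_moment_odes",
    "integrate_mass_fraction",
    "sigmoidal_signal",
    "halftime",
]


class DegenerateModelError(ValueError):
    """Raised when the closed form is singular (kappa = 0); use the ODE path."""


class IntegrationError(RuntimeError):
    """Raised when the moment-ODE integrator fails to converge."""


@dataclass(frozen=True)
class RateConstants:
    """Microscopic rate constants of the nucleation-elongation model.

    Parameters
    ----------
    kn : float
        Primary nucleation rate constant, M^(1-nc) s^-1.
    k_plus : float
        Elongation rate constant, M^-1 s^-1.
    k2 : float
        Secondary nucleation rate constant, M^(-n2) s^-1.
    nc : float
        Primary nucleation reaction order (default 2).
    n2 : float
        Secondary nucleation reaction order (default 2).
    """

    kn: float
    k_plus: float
    k2: float
    nc: float = 2.0
    n2: float = 2.0

    def __post_init__(self) -> None:
        if self.kn < 0 or self.k_plus < 0 or self.k2 < 0:
            raise ValueError("rate constants must be non-negative")
        if self.nc < 1 or self.n2 < 1:
            raise ValueError("reaction orders must be >= 1")

    @property
    def sqrt_knkp(self) -> float:
        """Combined primary-pathway constant sqrt(kn * k+), M^-1 s^-1 for nc=2."""
        return math.sqrt(self.kn * self.k_plus)

    @property
    def sqrt_kpk2(self) -> float:
        """Combined secondary-pathway constant sqrt(k+ * k2), M^-3/2 s^-1 for n2=2."""
        return math.sqrt(self.k_plus * self.k2)

    @classmethod
    def from_combined(
        cls,
        sqrt_knkp: float,
        sqrt_kpk2: float,
        nc: float = 2.0,
        n2: float = 2.0,
        k_plus: float = 1.0,
    ) -> "RateConstants":
        """Build rates realising given combined constants.

        Unseeded kinetics determine only the products ``kn*k+`` and ``k2*k+``;
        ``k_plus`` here is an arbitrary gauge choice that leaves every model
        curve unchanged.
        """
        if sqrt_knkp < 0 or sqrt_kpk2 < 0:
            raise ValueError("combined constants must be non-negative")
        if k_plus <= 0:
            raise ValueError("k_plus gauge must be positive")
        return cls(
            kn=sqrt_knkp**2 / k_plus,
            k_plus=k_plus,
            k2=sqrt_kpk2**2 / k_plus,
            nc=nc,
            n2=n2,
        )


@dataclass(frozen=True)
class KineticState:
    """Snapshot of the fibril population at one time point."""

    m0: float
    t: float
    M: float
    P: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.M <= self.m0 * (1 + 1e-9)):
            raise ValueError("fibril mass must lie in [0, m0]")
        if self.P < 0:
            raise ValueError("fibril number concentration must be >= 0")


@dataclass(frozen=True)
class ClosedFormCoefficients:
    """Coefficient set for the closed-form unseeded mass-fraction solution."""

    lam: float
    kap: float
    Bplus: float
    Bminus: float
    Cplus: float
    Cminus: float
    kinf: float
    kinf_tilde: float


@dataclass(frozen=True)
class SigmoidalParams:
    """Parameters of the empirical logistic signal model.

    Signal is ``F0 + A / (1 + exp(r_max * (tau_half - t)))``.
    """

    F0: float
    A: float
    r_max: float
    tau_half: float

    def __post_init__(self) -> None:
        if self.A <= 0 or self.r_max <= 0 or self.tau_half <= 0:
            raise ValueError("A, r_max and tau_half must be positive")


def compute_lambda(rc: RateConstants, m0: float) -> float:
    """Primary-pathway rate parameter lambda = sqrt(2 * k+ * kn * m0^nc)."""
    if m0 <= 0:
        raise ValueError(f"m0 must be positive, got {m0!r}")
    return math.sqrt(2.0 * rc.k_plus * rc.kn * m0**rc.nc)


def compute_kappa(rc: RateConstants, m0: float) -> float:
    """Secondary-pathway rate parameter kappa = sqrt(2 * k+ * k2 * m0^(n2+1))."""
    if m0 <= 0:
        raise ValueError(f"m0 must be positive, got {m0!r}")
    return math.sqrt(2.0 * rc.k_plus * rc.k2 * m0 ** (rc.n2 + 1.0))


def _coefficients_from_lambda_kappa(
    lam: float, kap: float, nc: float, n2: float
) -> ClosedFormCoefficients:
    if kap <= 0:
        raise DegenerateModelError(
            "closed form is singular for kappa = 0; integrate the moment ODEs instead"
        )
    Cplus = lam**2 / (2.0 * kap**2)
    Cminus = -Cplus
    kinf = math.sqrt(2.0 * kap**2 / (n2 * (n2 + 1.0)) + 2.0 * lam**2 / nc)
    kinf_tilde = math.sqrt(kinf**2 - 4.0 * Cplus * Cminus * kap**2)
    Bplus = (kinf + kinf_tilde) / (2.0 * kap)
    Bminus = (kinf - kinf_tilde) / (2.0 * kap)
    return ClosedFormCoefficients(
        lam=lam,
        kap=kap,
        Bplus=Bplus,
        Bminus=Bminus,
        Cplus=Cplus,
        Cminus=Cminus,
        kinf=kinf,
        kinf_tilde=kinf_tilde,
    )


def closed_form_coefficients(rc: RateConstants, m0: float) -> ClosedFormCoefficients:
    """Coefficients of the closed-form unseeded solution at monomer load ``m0``."""
    lam = compute_lambda(rc, m0)
    kap = compute_kappa(rc, m0)
    return _coefficients_from_lambda_kappa(lam, kap, rc.nc, rc.n2)


def _mass_fraction_from_coeffs(
    t: np.ndarray, c: ClosedFormCoefficients
) -> np.ndarray:
    if c.lam == 0:
        # unseeded with no primary nucleation: nothing ever ignites
        return np.zeros_like(t)
    # exp(-kap*t) formulation keeps the bracket finite for large kap*t.
    Einv = np.exp(-c.kap * t)
    bracket = (
        (c.Bplus + c.Cplus)
        / (c.Bplus * Einv + c.Cplus)
        * (c.Bminus * Einv + c.Cplus)
        / (c.Bminus + c.Cplus)
    )
    exponent = c.kinf**2 / (c.kap * c.kinf_tilde)
    frac = 1.0 - np.power(bracket, exponent) * np.exp(-c.kinf * t)
    return np.clip(frac, 0.0, 1.0)


def _check_t_grid(t_grid: np.ndarray) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("t_grid must be a 1-D sequence")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t


def fibril_mass_fraction(
    t_grid: np.ndarray, rc: RateConstants, m0: float
) -> np.ndarray:
    """Closed-form fibril mass fraction M(t)/M(inf) on ``t_grid`` (unseeded).

    Requires an active secondary pathway (kappa > 0); raises
    :class:`DegenerateModelError` otherwise.
    """
    t = _check_t_grid(t_grid)
    coeffs = closed_form_coefficients(rc, m0)
    return _mass_fraction_from_coeffs(t, coeffs)


def mass_fraction_from_lambda_kappa(
    t_grid: np.ndarray, lam: float, kap: float, nc: float = 2.0, n2: float = 2.0
) -> np.ndarray:
    """Closed-form mass fraction parametrised directly by (lambda, kappa).

    The unseeded solution depends on the microscopic rates only through these
    two combined parameters, which is what makes global fitting of the two
    shared combined constants well posed.
    """
    t = _check_t_grid(t_grid)
    coeffs = _coefficients_from_lambda_kappa(lam, kap, nc, n2)
    return _mass_fraction_from_coeffs(t, coeffs)


def integrate_moment_odes(
    t_grid: np.ndarray,
    rc: RateConstants,
    m0: float,
    rtol: float = 1e-9,
    atol: float = 1e-14,
) -> tuple[np.ndarray, np.ndarray]:
    """Reference integration of the moment equations from P = M = 0.

        dP/dt = kn * m^nc + k2 * m^n2 * M
        dM/dt = 2 * k+ * m * P,   m = m0 - M

    Returns (P, M) on ``t_grid``.
    """
    t = _check_t_grid(t_grid)
    if m0 <= 0:
        raise ValueError(f"m0 must be positive, got {m0!r}")

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        P, M = y
        m = max(m0 - M, 0.0)
        return [
            rc.kn * m**rc.nc + rc.k2 * m**rc.n2 * M,
            2.0 * rc.k_plus * m * P,
        ]

    t_eval = t
    t0 = t[0]
    sol = solve_ivp(
        rhs,
        (t0, t[-1]) if t[-1] > t0 else (t0, t0 + 1.0),
        [0.0, 0.0],
        t_eval=t_eval if t[-1] > t0 else None,
        method="LSODA",
        rtol=rtol,
        atol=atol * max(m0, 1e-30),
    )
    if not sol.success:
        raise IntegrationError(f"moment-ODE integration failed: {sol.message}")
    if t[-1] > t0:
        P, M = sol.y
    else:
        P = np.zeros_like(t)
        M = np.zeros_like(t)
    M = np.clip(M, 0.0, m0)
    P = np.maximum(P, 0.0)
    return P, M


def _ode_mass_fraction_lambda_kappa(
    t: np.ndarray, lam: float, kap: float, nc: float, n2: float
) -> np.ndarray:
    # Reduced moment system in mu = M/m0, q = 2*k+*P/m0: depends only on
    # (lambda, kappa, nc, n2), mirroring the closed form's parametrisation.
    def rhs(_t: float, y: np.ndarray) -> list[float]:
        q, mu = y
        mfrac = max(1.0 - mu, 0.0)
        return [
            lam**2 * mfrac**nc + kap**2 * mfrac**n2 * mu,
            mfrac * q,
        ]

    t0 = t[0]
    if t[-1] <= t0:
        return np.zeros_like(t)
    sol = solve_ivp(
        rhs,
        (t0, t[-1]),
        [0.0, 0.0],
        t_eval=t,
        method="LSODA",
        rtol=1e-8,
        atol=1e-12,
    )
    if not sol.success:
        raise IntegrationError(f"moment-ODE integration failed: {sol.message}")
    return np.clip(sol.y[1], 0.0, 1.0)


def model_mass_fraction(
    t_grid: np.ndarray,
    lam: float,
    kap: float,
    nc: float = 2.0,
    n2: float = 2.0,
    closed_form_ratio: float = 10.0,
) -> np.ndarray:
    """Mass fraction with automatic dispatch between closed form and ODE.

    The closed form assumes secondary-pathway dominance; it is used when
    ``kap/lam > closed_form_ratio`` and the reduced moment ODEs otherwise.
    """
    t = _check_t_grid(t_grid)
    if kap > 0 and lam > 0 and kap / lam > closed_form_ratio:
        return _mass_fraction_from_coeffs(
            t, _coefficients_from_lambda_kappa(lam, kap, nc, n2)
        )
    if lam == 0:
        return np.zeros_like(t)
    return _ode_mass_fraction_lambda_kappa(t, lam, kap, nc, n2)


def integrate_mass_fraction(
    t_grid: np.ndarray, rc: RateConstants, m0: float
) -> np.ndarray:
    """M(t)/m0 from the moment-ODE integrator (oracle path)."""
    _, M = integrate_moment_odes(t_grid, rc, m0)
    return M / m0


def sigmoidal_signal(t, p: SigmoidalParams):
    """Logistic signal F0 + A / (1 + exp(r_max * (tau_half - t)))."""
    t = np.asarray(t, dtype=float)
    # clip the exponent to dodge overflow warnings far from the transition
    z = np.clip(p.r_max * (p.tau_half - t), -700.0, 700.0)
    out = p.F0 + p.A / (1.0 + np.exp(z))
    return out if out.ndim else float(out)


def halftime(
    lam: float, kap: float, nc: float = 2.0, n2: float = 2.0
) -> float:
    """Time at which the model mass fraction reaches 1/2 (bisection)."""
    from scipy.optimize import brentq

    rate = max(kap, lam)
    if rate <= 0:
        raise ValueError("need lambda > 0 or kappa > 0")
    lo, hi = 1e-6 / rate, 1.0 / rate
    # expand until the half level is bracketed
    for _ in range(200):
        f = model_mass_fraction(np.array([0.0, hi]), lam, kap, nc, n2)[-1]
        if f > 0.5:
            break
        hi *= 1.6
    else:
        raise IntegrationError("could not bracket the half time")

    def g(t: float) -> float:
        return model_mass_fraction(np.array([0.0, t]), lam, kap, nc, n2)[-1] - 0.5

    while g(lo) > 0:
        lo /= 4.0
    return float(brentq(g, lo, hi, xtol=1e-6 / rate))
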