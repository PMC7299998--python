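"""Model fitting: sigmoidal extraction, global and mechanism-constrained fits.

The unseeded master-equation curve depends on the microscopic rates only
through lambda and kappa, i.e. through the combined constants
``sqrt(kn*k+)`` and ``sqrt(k+*k2)`` at each monomer load. Global fits share
those two constants across monomer concentrations; mechanism fits hold a
zero-inhibitor baseline fixed and let one microscopic rate carry a
per-dose multiplicative factor.

All optimisation is bounded nonlinear least squares on log-transformed
positive parameters, with a Latin-hypercube multi-start (seeded, default
1730) for the global problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar
from scipy.stats import qmc

from .kinetic_model import (
    RateConstants,
    SigmoidalParams,
    compute_kappa,
    compute_lambda,
    model_mass_fraction,
    sigmoidal_signal,
)
from .trace_processing import NormalizedTrace

__all__ = [
    "SigmoidalFitResult",
    "GlobalFitResult",
    "MechanismFitResult",
    "MechanismScan",
    "ScalingResult",
    "InhibitorDependence",
    "HYPOTHESES",
    "DEFAULT_SEED",
    "fit_sigmoidal",
    "fit_lambda_kappa",
    "fit_global",
    "fit_constrained_mechanism",
    "fit_combined_free",
    "fit_halftime_scaling",
    "summarize_inhibitor_dependence",
    "chi_squared",
    "renormalize_to_fitted_plateau",
]

DEFAULT_SEED = 1730
HYPOTHESES = ("kn_free", "kplus_free", "k2_free")


# ---------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class SigmoidalFitResult:
    params: SigmoidalParams
    param_errors: dict[str, float]
    residual_rms: float
    converged: bool
    message: str = ""


@dataclass(frozen=True)
class GlobalFitResult:
    """Shared combined constants from a multi-concentration global fit."""

    sqrt_knkp: float
    sqrt_kpk2: float
    standard_errors: dict[str, float]
    chi2: float
    n_curves: int
    per_curve_residuals: pd.DataFrame
    nc: float = 2.0
    n2: float = 2.0
    converged: bool = True

    def lambda_kappa(self, m0: float) -> tuple[float, float]:
        """(lambda, kappa) implied by the fitted combined constants at m0."""
        lam = math.sqrt(2.0) * self.sqrt_knkp * m0 ** (self.nc / 2.0)
        kap = math.sqrt(2.0) * self.sqrt_kpk2 * m0 ** ((self.n2 + 1.0) / 2.0)
        return lam, kap


@dataclass(frozen=True)
class MechanismFitResult:
    """One single-rate-free hypothesis: per-dose factors and fit quality."""

    hypothesis: str
    dose_factors: dict[float, float]
    chi2: float
    raw_ssr: float


@dataclass(frozen=True)
class MechanismScan:
    results: dict[str, MechanismFitResult]
    ranking: tuple[str, ...]

    @property
    def best(self) -> MechanismFitResult:
        return self.results[self.ranking[0]]


@dataclass(frozen=True)
class ScalingResult:
    gamma: float
    intercept: float
    r_squared: float
    halftimes: pd.DataFrame


@dataclass(frozen=True)
class InhibitorDependence:
    """Half-time linear trend and r_max mono-exponential trend vs dose."""

    tau_slope: float
    tau_intercept: float
    tau_r2: float
    rmax_amplitude: float
    rmax_rate: float
    rmax_asymptote: float
    rmax_r2: float


# ---------------------------------------------------------------------------
# chi squared


def chi_squared(
    model_curves: list[np.ndarray] | np.ndarray,
    data_curves: list[np.ndarray] | np.ndarray,
    n_params: int,
    sigma: float | None = None,
) -> float:
    """Reduced, noise-scaled chi squared over matched model/data curves.

    ``sum(residual^2) / (sigma^2 * (N - n_params))`` where ``sigma`` defaults
    to the residual SD over pre-transition points (model below 10% of its
    range), the region where the signal is flat and residuals are pure noise.
    """
    if isinstance(model_curves, np.ndarray):
        model_curves = [model_curves]
    if isinstance(data_curves, np.ndarray):
        data_curves = [data_curves]
    if len(model_curves) != len(data_curves):
        raise ValueError("model and data curve counts differ")
    res, pre = [], []
    for m, d in zip(model_curves, data_curves):
        m = np.asarray(m, float)
        d = np.asarray(d, float)
        if m.shape != d.shape:
            raise ValueError("model/data grids are not matched")
        r = d - m
        res.append(r)
        lo, hi = float(np.min(m)), float(np.max(m))
        pre.append(r[m < lo + 0.1 * (hi - lo + 1e-300)])
    res = np.concatenate(res)
    n = res.size
    if n <= n_params:
        raise ValueError(f"need more points ({n}) than parameters ({n_params})")
    if sigma is None:
        pre = np.concatenate(pre)
        sigma = float(np.std(pre)) if pre.size >= 10 else float(np.std(res))
        if sigma < 1e-8:
            sigma = 1.0  # (near-)noiseless input: report unscaled reduced SSR
    return float(np.sum(res**2) / (sigma**2 * (n - n_params)))


def estimate_noise_sd(curves: list[np.ndarray]) -> float:
    """Model-free noise SD from first differences (smooth signal cancels).

    ``std(diff(y)) / sqrt(2)`` per curve, pooled by median. Used to put the
    chi-squared values of competing hypotheses on one shared noise scale.
    """
    vals = [float(np.std(np.diff(np.asarray(c, float)))) / math.sqrt(2.0) for c in curves]
    return float(np.median(vals))


# ---------------------------------------------------------------------------
# sigmoidal fit


def _sigmoidal_init(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    f0 = float(np.mean(y[:5]))
    plateau = float(np.mean(y[-10:]))
    a = max(plateau - f0, 1e-12)
    half = f0 + a / 2.0
    above = np.nonzero(y >= half)[0]
    tau = float(t[above[0]]) if above.size else float(t[t.size // 2])
    tau = max(tau, float(t[1]) if t[0] == 0 else float(t[0]))
    slope = float(np.max(np.gradient(y, t)))
    rmax = max(4.0 * slope / a, 1.0 / (t[-1] - t[0]))
    return np.array([f0, a, rmax, tau])


def fit_sigmoidal(
    trace: NormalizedTrace | tuple[np.ndarray, np.ndarray],
) -> SigmoidalFitResult:
    """Least-squares logistic fit, initialized from the data itself."""
    if isinstance(trace, tuple):
        t, y = (np.asarray(v, float) for v in trace)
    else:
        t, y = trace.times, trace.signals

    def residual(p: np.ndarray) -> np.ndarray:
        f0, loga, logr, logtau = p
        sp = SigmoidalParams(f0, math.exp(loga), math.exp(logr), math.exp(logtau))
        return sigmoidal_signal(t, sp) - y

    f0, a, rmax, tau = _sigmoidal_init(t, y)
    p0 = np.array([f0, math.log(a), math.log(rmax), math.log(tau)])
    best = None
    for scale in (1.0, 0.5, 2.0):  # small multi-start on the rate guess
        start = p0.copy()
        start[2] += math.log(scale)
        sol = least_squares(residual, start, xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    f0, loga, logr, logtau = best.x
    params = SigmoidalParams(f0, math.exp(loga), math.exp(logr), math.exp(logtau))
    rms = float(np.sqrt(2.0 * best.cost / t.size))

    errs = _param_errors(best, scale=np.array([1.0, params.A, params.r_max, params.tau_half]))
    converged = bool(best.success) and t[0] <= params.tau_half <= t[-1]
    return SigmoidalFitResult(
        params=params,
        param_errors=dict(zip(("F0", "A", "r_max", "tau_half"), errs)),
        residual_rms=rms,
        converged=converged,
        message=best.message,
    )


def _param_errors(sol, scale: np.ndarray) -> np.ndarray:
    """Asymptotic standard errors from the least-squares jacobian.

    ``scale`` converts errors of log-parameters back to natural units.
    """
    n, p = sol.jac.shape
    dof = max(n - p, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return se * scale


def renormalize_to_fitted_plateau(trace: NormalizedTrace) -> NormalizedTrace:
    """Rescale a window-normalized trace to its fitted F0/plateau.

    Endpoint windows are noisy; the fitted plateau gives a cleaner amplitude
    for kinetic fitting. Falls back to the input when the fit fails.
    """
    fit = fit_sigmoidal(trace)
    if not fit.converged:
        return trace
    p = fit.params
    from dataclasses import replace

    return replace(trace, signals=(trace.signals - p.F0) / p.A)


# ---------------------------------------------------------------------------
# master-equation fits


def _group_traces(
    traces: list[NormalizedTrace], key: str
) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Group traces by a float attribute -> (value, t_grid, data rows)."""
    order: dict[float, list[NormalizedTrace]] = {}
    for tr in traces:
        order.setdefault(round(float(getattr(tr, key)), 12), []).append(tr)
    groups = []
    for value, members in sorted(order.items()):
        t0 = members[0].times
        for m in members[1:]:
            if m.times.shape != t0.shape or not np.allclose(m.times, t0):
                raise ValueError("traces within a group must share one time grid")
        groups.append((value, t0, np.vstack([m.signals for m in members])))
    return groups


def _halftime_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(half-crossing time, max slope) of a roughly normalized curve."""
    ymax = float(np.mean(np.sort(y)[-5:]))
    above = np.nonzero(y >= 0.5 * ymax)[0]
    tau = float(t[above[0]]) if above.size else float(t[-1]) / 2.0
    slope = float(np.max(np.gradient(y, t)))
    return max(tau, t[1] if t[0] == 0 else t[0]), max(slope, 1.0 / t[-1])


def _lambda_kappa_center(groups) -> tuple[float, float]:
    """Data-driven (lambda, kappa) start from the median group's curve shape."""
    value, t, rows = groups[len(groups) // 2]
    tau, slope = _halftime_guess(t, rows.mean(axis=0))
    kap = 4.0 * slope
    # ignition heuristic from the early-time limit (lam^2/kap^2) cosh(kap t)
    lam = kap * math.sqrt(max(1.2 * math.exp(-kap * tau), 1e-12))
    return lam, kap


def _multistart_points(
    center_log: np.ndarray, n_starts: int, seed: int, half_width: float = 2.0
) -> np.ndarray:
    """Latin-hypercube starts (in log space) around a data-driven center."""
    sampler = qmc.LatinHypercube(d=center_log.size, seed=seed)
    unit = sampler.random(n=n_starts)
    lo = center_log - half_width * math.log(10.0)
    hi = center_log + half_width * math.log(10.0)
    pts = qmc.scale(unit, lo, hi)
    return np.vstack([center_log, pts])


def _polish(residual, starts: np.ndarray, keep: int = 3):
    """Evaluate all starts, polish the most promising few, return the best."""
    costs = []
    for p in starts:
        try:
            r = residual(p)
            costs.append(float(np.sum(r**2)))
        except Exception:
            costs.append(np.inf)
    order = np.argsort(costs)[:keep]
    best = None
    for i in order:
        if not np.isfinite(costs[i]):
            continue
        try:
            sol = least_squares(residual, starts[i], xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all multi-start fits failed")
    return best


def fit_lambda_kappa(
    traces: list[NormalizedTrace],
    nc: float = 2.0,
    n2: float = 2.0,
    seed: int = DEFAULT_SEED,
    n_starts: int = 10,
) -> tuple[float, float, float]:
    """Fit (lambda, kappa) to replicate curves at a single condition.

    Returns (lambda, kappa, raw SSR).
    """
    t0 = traces[0].times
    data = np.vstack([tr.signals for tr in traces])
    for tr in traces[1:]:
        if not np.allclose(tr.times, t0):
            raise ValueError("traces must share one time grid")

    def residual(p: np.ndarray) -> np.ndarray:
        lam, kap = np.exp(p)
        curve = model_mass_fraction(t0, lam, kap, nc, n2)
        return (data - curve).ravel()

    lam0, kap0 = _lambda_kappa_center([(0.0, t0, data)])
    starts = _multistart_points(np.log([lam0, kap0]), n_starts, seed)
    best = _polish(residual, starts)
    lam, kap = np.exp(best.x)
    return float(lam), float(kap), float(2.0 * best.cost)


def fit_global(
    traces: list[NormalizedTrace],
    nc: float = 2.0,
    n2: float = 2.0,
    seed: int = DEFAULT_SEED,
    n_starts: int = 10,
    renormalize: bool = False,
) -> GlobalFitResult:
    """Global fit sharing sqrt(kn*k+) and sqrt(k+*k2) across monomer loads."""
    if renormalize:
        traces = [renormalize_to_fitted_plateau(tr) for tr in traces]
    groups = _group_traces(traces, "substrate_conc")
    if len(groups) < 3:
        raise ValueError(
            f"global fit needs >= 3 distinct monomer concentrations, got {len(groups)}"
        )
    m0s = np.array([g[0] for g in groups])

    def residual(p: np.ndarray) -> np.ndarray:
        k1, k2c = np.exp(p)
        out = []
        for m0, t, rows in groups:
            lam = math.sqrt(2.0) * k1 * m0 ** (nc / 2.0)
            kap = math.sqrt(2.0) * k2c * m0 ** ((n2 + 1.0) / 2.0)
            curve = model_mass_fraction(t, lam, kap, nc, n2)
            out.append((rows - curve).ravel())
        return np.concatenate(out)

    # translate the (lambda, kappa) center at the median m0 into combined units
    lam0, kap0 = _lambda_kappa_center(groups)
    m_mid = groups[len(groups) // 2][0]
    k1_0 = lam0 / (math.sqrt(2.0) * m_mid ** (nc / 2.0))
    k2_0 = kap0 / (math.sqrt(2.0) * m_mid ** ((n2 + 1.0) / 2.0))
    starts = _multistart_points(np.log([k1_0, k2_0]), n_starts, seed)
    best = _polish(residual, starts)
    k1, k2c = np.exp(best.x)
    se = _param_errors(best, scale=np.array([k1, k2c]))

    # per-curve residual bookkeeping and chi2
    models, datas, rows_meta = [], [], []
    for m0, t, rows in groups:
        lam = math.sqrt(2.0) * k1 * m0 ** (nc / 2.0)
        kap = math.sqrt(2.0) * k2c * m0 ** ((n2 + 1.0) / 2.0)
        curve = model_mass_fraction(t, lam, kap, nc, n2)
        for row in rows:
            models.append(curve)
            datas.append(row)
            rows_meta.append(
                {"m0": m0, "rms": float(np.sqrt(np.mean((row - curve) ** 2)))}
            )
    chi2 = chi_squared(models, datas, n_params=2)
    return GlobalFitResult(
        sqrt_knkp=float(k1),
        sqrt_kpk2=float(k2c),
        standard_errors={"sqrt_knkp": float(se[0]), "sqrt_kpk2": float(se[1])},
        chi2=chi2,
        n_curves=len(datas),
        per_curve_residuals=pd.DataFrame(rows_meta),
        nc=nc,
        n2=n2,
        converged=bool(best.success),
    )


def _baseline_lambda_kappa(
    traces: list[NormalizedTrace],
    baseline,
    m0: float,
    nc: float,
    n2: float,
    seed: int,
) -> tuple[float, float]:
    if isinstance(baseline, GlobalFitResult):
        return baseline.lambda_kappa(m0)
    if isinstance(baseline, RateConstants):
        return compute_lambda(baseline, m0), compute_kappa(baseline, m0)
    zero = [tr for tr in traces if tr.molar_ratio == 0 and tr.inhibitor_conc == 0]
    if not zero:
        raise ValueError("no zero-inhibitor reference traces and no baseline supplied")
    lam, kap, _ = fit_lambda_kappa(zero, nc=nc, n2=n2, seed=seed)
    return lam, kap


def _dose_lambda_kappa(
    hypothesis: str, lam0: float, kap0: float, factor: float
) -> tuple[float, float]:
    """Apply a multiplicative factor on one microscopic rate to (lambda, kappa).

    lambda^2 ~ kn*k+ and kappa^2 ~ k2*k+, so a factor f on kn scales lambda by
    sqrt(f); on k2 scales kappa by sqrt(f); on k+ scales both by sqrt(f).
    """
    s = math.sqrt(factor)
    if hypothesis == "kn_free":
        return lam0 * s, kap0
    if hypothesis == "k2_free":
        return lam0, kap0 * s
    if hypothesis == "kplus_free":
        return lam0 * s, kap0 * s
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


def fit_constrained_mechanism(
    traces: list[NormalizedTrace],
    baseline: GlobalFitResult | RateConstants | None = None,
    nc: float = 2.0,
    n2: float = 2.0,
    seed: int = DEFAULT_SEED,
    renormalize: bool = False,
) -> MechanismScan:
    """Rank single-rate-free inhibition hypotheses by chi squared.

    Traces share one monomer load and span inhibitor doses (zero dose
    required unless ``baseline`` is supplied). For each hypothesis only the
    named microscopic rate carries a free per-dose factor (1 at zero dose).
    """
    if renormalize:
        traces = [renormalize_to_fitted_plateau(tr) for tr in traces]
    m0s = {round(tr.substrate_conc, 12) for tr in traces}
    if len(m0s) != 1:
        raise ValueError(f"mechanism fit requires one monomer load, got {sorted(m0s)}")
    m0 = next(iter(m0s))
    lam0, kap0 = _baseline_lambda_kappa(traces, baseline, m0, nc, n2, seed)

    dose_groups = _group_traces(traces, "molar_ratio")
    if not any(d == 0 for d, _, _ in dose_groups) and baseline is None:
        raise ValueError("missing zero-inhibitor reference dose")

    # one shared noise scale so chi2 is comparable across hypotheses
    sigma = estimate_noise_sd([tr.signals for tr in traces]) or None

    results = {}
    for hyp in HYPOTHESES:
        factors: dict[float, float] = {}
        models, datas = [], []
        for dose, t, rows in dose_groups:
            if dose == 0:
                factors[dose] = 1.0
                f_opt = 1.0
            else:

                def cost(logf: float) -> float:
                    lam, kap = _dose_lambda_kappa(hyp, lam0, kap0, math.exp(logf))
                    curve = model_mass_fraction(t, lam, kap, nc, n2)
                    return float(np.sum((rows - curve) ** 2))

                sol = minimize_scalar(
                    cost, bounds=(math.log(1e-4), math.log(1e2)), method="bounded",
                    options={"xatol": 1e-10},
                )
                f_opt = float(math.exp(sol.x))
                factors[dose] = f_opt
            lam, kap = _dose_lambda_kappa(hyp, lam0, kap0, f_opt)
            curve = model_mass_fraction(t, lam, kap, nc, n2)
            for row in rows:
                models.append(curve)
                datas.append(row)
        n_free = sum(1 for d in factors if d != 0)
        chi2 = chi_squared(models, datas, n_params=n_free, sigma=sigma)
        ssr = float(sum(np.sum((d - m) ** 2) for m, d in zip(models, datas)))
        results[hyp] = MechanismFitResult(
            hypothesis=hyp, dose_factors=factors, chi2=chi2, raw_ssr=ssr
        )
    ranking = tuple(sorted(results, key=lambda h: results[h].chi2))
    return MechanismScan(results=results, ranking=ranking)


def fit_combined_free(
    traces: list[NormalizedTrace],
    nc: float = 2.0,
    n2: float = 2.0,
    seed: int = DEFAULT_SEED,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Per-dose free fits of both combined constants, relative to zero dose.

    Returns a table with absolute and zero-dose-relative sqrt(kn*k+) and
    sqrt(k+*k2) per inhibitor level.
    """
    if renormalize:
        traces = [renormalize_to_fitted_plateau(tr) for tr in traces]
    m0s = {round(tr.substrate_conc, 12) for tr in traces}
    if len(m0s) != 1:
        raise ValueError(f"combined-free fit requires one monomer load, got {sorted(m0s)}")
    m0 = next(iter(m0s))

    by_dose: dict[float, list[NormalizedTrace]] = {}
    for tr in traces:
        by_dose.setdefault(round(float(tr.molar_ratio), 12), []).append(tr)
    if 0.0 not in by_dose:
        raise ValueError("missing zero-inhibitor reference dose")

    rows = []
    for dose in sorted(by_dose):
        lam, kap, ssr = fit_lambda_kappa(by_dose[dose], nc=nc, n2=n2, seed=seed)
        k1 = lam / (math.sqrt(2.0) * m0 ** (nc / 2.0))
        k2c = kap / (math.sqrt(2.0) * m0 ** ((n2 + 1.0) / 2.0))
        rows.append(
            {"molar_ratio": dose, "sqrt_knkp": k1, "sqrt_kpk2": k2c, "ssr": ssr}
        )
    table = pd.DataFrame(rows)
    ref = table.loc[table["molar_ratio"] == 0].iloc[0]
    table["rel_sqrt_knkp"] = table["sqrt_knkp"] / ref["sqrt_knkp"]
    table["rel_sqrt_kpk2"] = table["sqrt_kpk2"] / ref["sqrt_kpk2"]
    return table


def fit_halftime_scaling(halftimes: pd.DataFrame) -> ScalingResult:
    """OLS of log(tau_half) on log(m0); the slope is the gamma exponent."""
    required = {"m0", "tau_half"}
    if not required <= set(halftimes.columns):
        raise ValueError(f"halftime table needs columns {sorted(required)}")
    tab = halftimes.dropna(subset=["m0", "tau_half"])
    if tab["m0"].nunique() < 3:
        raise ValueError("scaling fit needs >= 3 distinct monomer concentrations")
    if (tab["tau_half"] <= 0).any() or (tab["m0"] <= 0).any():
        raise ValueError("m0 and tau_half must be positive")
    x = np.log(tab["m0"].to_numpy(float))
    y = np.log(tab["tau_half"].to_numpy(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ScalingResult(
        gamma=float(slope), intercept=float(intercept), r_squared=r2,
        halftimes=tab.reset_index(drop=True),
    )


def summarize_inhibitor_dependence(
    sig_fits: pd.DataFrame,
) -> InhibitorDependence:
    """Linear tau-half and mono-exponential r_max trends vs inhibitor dose.

    Input table columns: ``inhibitor_conc``, ``tau_half``, ``r_max``.
    r_max is fitted as ``a * exp(-b * conc) + c``.
    """
    required = {"inhibitor_conc", "tau_half", "r_max"}
    if not required <= set(sig_fits.columns):
        raise ValueError(f"summary table needs columns {sorted(required)}")
    tab = sig_fits.sort_values("inhibitor_conc")
    if tab["inhibitor_conc"].nunique() < 3:
        raise ValueError("need >= 3 distinct doses")
    b_conc = tab["inhibitor_conc"].to_numpy(float)
    tau = tab["tau_half"].to_numpy(float)
    rmax = tab["r_max"].to_numpy(float)

    slope, intercept = np.polyfit(b_conc, tau, 1)
    fit_tau = slope * b_conc + intercept
    ss = float(np.sum((tau - tau.mean()) ** 2))
    tau_r2 = 1.0 - float(np.sum((tau - fit_tau) ** 2)) / ss if ss > 0 else 1.0

    # mono-exponential decay: a*exp(-b*x) + c
    c0 = 0.9 * float(rmax.min())
    a0 = max(float(rmax[0]) - c0, 1e-12)
    span = float(b_conc.max() - b_conc.min())
    with np.errstate(divide="ignore", invalid="ignore"):
        drop = np.log(np.maximum(rmax - c0, 1e-300) / a0)
    b0 = max(-np.polyfit(b_conc, drop, 1)[0], 0.1 / span)

    def residual(p: np.ndarray) -> np.ndarray:
        a, b, c = p
        return a * np.exp(-b * b_conc) + c - rmax

    best = None
    for bscale in (1.0, 0.3, 3.0):
        sol = least_squares(
            residual,
            np.array([a0, b0 * bscale, c0]),
            bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-15, ftol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    a, b, c = best.x
    fit_r = a * np.exp(-b * b_conc) + c
    ss = float(np.sum((rmax - rmax.mean()) ** 2))
    rmax_r2 = 1.0 - float(np.sum((rmax - fit_r) ** 2)) / ss if ss > 0 else 1.0
    return InhibitorDependence(
        tau_slope=float(slope),
        tau_intercept=float(intercept),
        tau_r2=tau_r2,
        rmax_amplitude=float(a),
        rmax_rate=float(b),
        rmax_asymptote=float(c),
        rmax_r2=rmax_r2,
    )
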