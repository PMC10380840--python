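"""Pre-steady-state kinetics of AP-endonuclease DNA incision.

The minimal three-stage mechanism for processing of an abasic (F-site)
substrate S by the enzyme E is

    E + S  <=>[k1][k-1]  ES  -->[kcat]  EP  <=>[Kp]  E + P

a reversible bimolecular binding step (association constant
Ka = k1 / k-1), an irreversible incision step, and reversible dissociation
of the enzyme-product complex characterised by its equilibrium dissociation
constant Kp.  Only the equilibrium of the product step is experimentally
constrained, so EP dissociation is modelled with a fast off-rate
(:data:`EP_KOFF_DEFAULT`) and ``k_on = k_off / Kp``.

The module provides the mass-action simulator, the linear FRET observable
mapping species concentrations to a stopped-flow fluorescence signal, and
the fitting routines used throughout: global fitting of multi-concentration
stopped-flow sets with Ka fixed from thermophoresis, multi-exponential
phase fits F(t) = sum_n A_n exp(-k_n t) + const, the steady-state product
accumulation model [P](t) = A (1 - exp(-k_obs t)) + k_lin t, and the
hyperbolic thermophoresis (MST) binding isotherm
F = F_backgr + F_ampl [E] / (1/Ka + [E]).

Units: time s, concentrations uM, bimolecular rates uM^-1 s^-1,
unimolecular rates s^-1, Kp uM, Ka uM^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize as _opt
from scipy.integrate import solve_ivp

from .errors import FitFailureError, InvalidInputError

__all__ = [
    "Scheme1Params",
    "SpeciesTrajectory",
    "ObservableCoefficients",
    "FretTrace",
    "ExpFitResult",
    "ProductCurveParams",
    "MstModelParams",
    "EP_KOFF_DEFAULT",
    "simulate_scheme1",
    "fret_observable",
    "fit_multiexp",
    "global_fit_scheme1",
    "fit_product_eq6",
    "fit_mst_eq8",
    "default_stopped_flow_grid",
]

#: EP -> E + P off-rate (s^-1); fast relative to kcat so that only the
#: equilibrium constant Kp is kinetically visible.
EP_KOFF_DEFAULT = 50.0


@dataclass(frozen=True)
class Scheme1Params:
    """Rate and equilibrium constants of the three-stage mechanism.

    k1 (uM^-1 s^-1), k_minus1 (s^-1), kcat (s^-1), kp (uM, equilibrium
    dissociation constant of the enzyme-product complex).
    """

    k1: float
    k_minus1: float
    kcat: float
    kp: float

    def __post_init__(self) -> None:
        for name in ("k1", "k_minus1", "kcat", "kp"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")

    @property
    def ka(self) -> float:
        """Association constant Ka = k1 / k-1 (uM^-1)."""
        if self.k_minus1 == 0:
            return np.inf
        return self.k1 / self.k_minus1

    @classmethod
    def from_ka(cls, k1: float, ka: float, kcat: float, kp: float) -> "Scheme1Params":
        """Build with the dissociation rate constrained by k-1 = k1 / Ka."""
        if ka <= 0:
            raise InvalidInputError("Ka must be positive")
        return cls(k1=k1, k_minus1=k1 / ka, kcat=kcat, kp=kp)


@dataclass(frozen=True)
class SpeciesTrajectory:
    """Concentrations of E, S, ES, EP and P (uM) on a shared time grid (s).

    Mass conservation (E + ES + EP = E0 and S + ES + EP + P = S0) holds at
    every point to 1e-6 uM.
    """

    time_s: np.ndarray
    e: np.ndarray
    s: np.ndarray
    es: np.ndarray
    ep: np.ndarray
    p: np.ndarray
    e0: float
    s0: float

    def __post_init__(self) -> None:
        arrs = {}
        for name in ("time_s", "e", "s", "es", "ep", "p"):
            arrs[name] = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arrs[name])
        n = arrs["time_s"].size
        if any(a.shape != (n,) for a in arrs.values()):
            raise InvalidInputError("all trajectory arrays must share one grid")
        if min(a.min() for k, a in arrs.items() if k != "time_s") < -1e-9:
            raise InvalidInputError("concentrations must be non-negative")
        if (
            np.max(np.abs(self.e + self.es + self.ep - self.e0)) > 1e-6
            or np.max(np.abs(self.s + self.es + self.ep + self.p - self.s0)) > 1e-6
        ):
            raise InvalidInputError("mass conservation violated beyond 1e-6 uM")


@dataclass(frozen=True)
class ObservableCoefficients:
    """Per-species fluorescence coefficients of the FRET observable.

    signal(t) = offset + f_s [S] + f_es [ES] + f_ep [EP] + f_p [P].

    Because total DNA is conserved, only differences relative to ``f_s``
    are identifiable from a single substrate concentration; the defaults
    encode the qualitative stopped-flow shape (small quench on complex
    formation, large signal rise on product formation and release).
    """

    f_s: float = 1.0
    f_es: float = 0.8
    f_ep: float = 0.9
    f_p: float = 1.8


@dataclass(frozen=True)
class FretTrace:
    """A stopped-flow FRET time series at one enzyme concentration."""

    time_s: np.ndarray
    signal: np.ndarray
    e0: float
    s0: float
    coefficients: ObservableCoefficients | None = None
    offset: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "signal", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise InvalidInputError("time and signal must be 1-D and equal length")
        if np.any(np.diff(t) <= 0) or t[0] < 0:
            raise InvalidInputError("time must be strictly increasing and >= 0")


@dataclass(frozen=True)
class ExpFitResult:
    """Phases of an exponential-polynomial fit, ordered by descending rate."""

    phases: tuple[tuple[float, float], ...]  # (amplitude, rate s^-1)
    baseline: float
    rss: float

    @property
    def rates(self) -> tuple[float, ...]:
        return tuple(k for _, k in self.phases)

    @property
    def amplitudes(self) -> tuple[float, ...]:
        return tuple(a for a, _ in self.phases)


@dataclass(frozen=True)
class ProductCurveParams:
    """Burst-plus-linear product accumulation parameters.

    amplitude A in %, observed rate k_obs in s^-1, linear accumulation rate
    k_lin in %/s; ``*_err`` are asymptotic standard errors when fitted.
    """

    amplitude: float
    k_obs: float
    k_lin: float = 0.0
    amplitude_err: float | None = None
    k_obs_err: float | None = None
    k_lin_err: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 100.0:
            raise InvalidInputError("amplitude must lie in [0, 100] %")
        if self.k_obs < 0 or self.k_lin < 0:
            raise InvalidInputError("rates must be non-negative")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.amplitude * (1.0 - np.exp(-self.k_obs * t)) + self.k_lin * t


@dataclass(frozen=True)
class MstModelParams:
    """Hyperbolic MST binding isotherm parameters.

    F = F_backgr + F_ampl * [E] / (1/Ka + [E]); Ka in uM^-1.
    """

    f_backgr: float
    f_ampl: float
    ka: float
    ka_err: float | None = None
    at_bound: bool = False

    def __post_init__(self) -> None:
        if not self.ka > 0:
            raise InvalidInputError("Ka must be positive")

    def __call__(self, conc_um):
        c = np.asarray(conc_um, dtype=float)
        return self.f_backgr + self.f_ampl * c / (1.0 / self.ka + c)


def default_stopped_flow_grid(
    t_min_s: float = 1e-3, t_max_s: float = 200.0, n: int = 250
) -> np.ndarray:
    """Log-spaced stopped-flow time grid, 1 ms to 200 s by default."""
    return np.geomspace(t_min_s, t_max_s, n)


def simulate_scheme1(
    params: Scheme1Params,
    e0: float,
    s0: float,
    t_grid,
    ep_koff: float = EP_KOFF_DEFAULT,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SpeciesTrajectory:
    """Integrate the mass-action rate equations of the three-stage scheme.

    Product rebinding is parameterised by ``k_on = ep_koff / Kp`` so that
    the EP <=> E + P equilibrium matches Kp while the off-rate stays fast
    compared with catalysis.  Uses a stiff-capable implicit solver.
    """
    if e0 < 0 or s0 < 0:
        raise InvalidInputError("initial concentrations must be non-negative")
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0) or t[0] < 0:
        raise InvalidInputError("time grid must be 1-D, increasing and >= 0")
    k_on = 0.0 if np.isinf(params.kp) else ep_koff / params.kp if params.kp > 0 else 0.0
    if params.kp == 0 and ep_koff > 0:
        raise InvalidInputError("Kp = 0 with nonzero off-rate is ill-posed")

    def rhs(_t, y):
        e, s, es, ep = y
        p = s0 - s - es - ep
        v_bind = params.k1 * e * s - params.k_minus1 * es
        v_cat = params.kcat * es
        v_rel = ep_koff * ep - k_on * e * p
        return (-v_bind + v_rel, -v_bind, v_bind - v_cat, v_cat - v_rel)

    t_span = (0.0, t[-1] if t[-1] > 0 else 1.0)
    sol = solve_ivp(
        rhs,
        t_span,
        [e0, s0, 0.0, 0.0],
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise FitFailureError(f"ODE solver failed: {sol.message}")
    e, s, es, ep = np.clip(sol.y, 0.0, None)
    p = np.clip(s0 - s - es - ep, 0.0, None)
    return SpeciesTrajectory(
        time_s=t, e=e, s=s, es=es, ep=ep, p=p, e0=e0, s0=s0
    )


def fret_observable(
    traj: SpeciesTrajectory,
    coefficients: ObservableCoefficients,
    offset: float = 0.0,
) -> FretTrace:
    """Map species concentrations to the detected FRET signal."""
    c = coefficients
    sig = (
        offset
        + c.f_s * traj.s
        + c.f_es * traj.es
        + c.f_ep * traj.ep
        + c.f_p * traj.p
    )
    return FretTrace(
        time_s=traj.time_s,
        signal=sig,
        e0=traj.e0,
        s0=traj.s0,
        coefficients=c,
        offset=offset,
    )


# ---------------------------------------------------------------------------
# Exponential-phase fits
# ---------------------------------------------------------------------------


def _exp_design(t, rates):
    return np.column_stack([np.exp(-k * t) for k in rates] + [np.ones_like(t)])


def _exp_varpro_rss(t, y, rates):
    """Best amplitudes + baseline for fixed rates; returns (amps, rss)."""
    design = _exp_design(t, rates)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(np.sum((design @ coef - y) ** 2))
    return coef, rss


def fit_multiexp(trace: FretTrace, n_phases: int, seed: int = 0) -> ExpFitResult:
    """Fit F(t) = sum_n A_n exp(-k_n t) + const by variable projection.

    Rates are optimised by bounded least squares in log space from eight
    multi-start initialisations spanning the resolvable rate window of the
    time grid; amplitudes and baseline are solved linearly at every step.
    Negative amplitudes are permitted (quench phases).  Phases are reported
    by descending rate.
    """
    if not 1 <= n_phases <= 3:
        raise InvalidInputError("n_phases must be between 1 and 3")
    t = trace.time_s
    y = trace.signal
    if t.size < 10 * n_phases:
        raise InvalidInputError("need at least 10 points per phase")

    k_lo = 1.0 / (t[-1] * 10.0)
    k_hi = 2.0 / max(t[t > 0].min(), 1e-12)
    rng = np.random.default_rng(seed)
    starts = []
    for i in range(8):
        base = np.geomspace(k_lo * 10, k_hi / 10, 8)[i]
        ks = base * np.geomspace(1.0, 20.0 ** (n_phases - 1), n_phases)
        starts.append(np.log(ks))
    # one additional randomised start guards against grid-aligned ties
    starts.append(rng.uniform(np.log(k_lo), np.log(k_hi), n_phases))

    def resid(log_k):
        design = _exp_design(t, np.exp(log_k))
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        return design @ coef - y

    best = None
    for x0 in starts:
        try:
            res = _opt.least_squares(
                resid,
                np.clip(x0, np.log(k_lo), np.log(k_hi)),
                bounds=(np.log(k_lo), np.log(k_hi)),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:  # pragma: no cover - solver edge
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, np.exp(res.x))
    if best is None:
        raise FitFailureError("all multi-exponential starts failed")
    rss, rates = best
    coef, rss = _exp_varpro_rss(t, y, rates)
    order = np.argsort(-rates)
    phases = tuple((float(coef[i]), float(rates[i])) for i in order)
    return ExpFitResult(phases=phases, baseline=float(coef[-1]), rss=rss)


# ---------------------------------------------------------------------------
# Global fit of the three-stage scheme
# ---------------------------------------------------------------------------


def _stack_linear_fit(trace_list, trajs):
    """Solve the linear observable layer for fixed rate constants.

    Unknowns: shared differential coefficients (f_es - f_s, f_ep - f_s,
    f_p - f_s) and one baseline per trace (offset + f_s * S0 absorbed).
    Returns (residual vector, coefficient estimates, baselines).
    """
    n_tr = len(trace_list)
    rows = sum(tr.time_s.size for tr in trace_list)
    design = np.zeros((rows, 3 + n_tr))
    y = np.concatenate([tr.signal for tr in trace_list])
    at = 0
    for i, (tr, traj) in enumerate(zip(trace_list, trajs)):
        n = tr.time_s.size
        design[at:at + n, 0] = traj.es
        design[at:at + n, 1] = traj.ep
        design[at:at + n, 2] = traj.p
        design[at:at + n, 3 + i] = 1.0
        at += n
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = design @ coef - y
    return resid, coef[:3], coef[3:]


def global_fit_scheme1(
    traces: list[FretTrace],
    ka_fixed: float,
    ep_koff: float = EP_KOFF_DEFAULT,
    n_starts: int = 8,
    seed: int = 0,
):
    """Globally fit stopped-flow traces at several enzyme concentrations.

    The dissociation rate is constrained by ``k-1 = k1 / Ka`` with Ka
    fixed (from thermophoresis); free nonlinear parameters are k1, kcat
    and Kp, optimised in log space from ``n_starts`` log-spaced
    initialisations.  The observable layer — shared per-species
    coefficients (as differences to the substrate coefficient) and one
    baseline per trace — is profiled out linearly at every step.

    Returns ``(params, info)`` where ``info`` carries the differential
    coefficients, per-trace baselines, residual sum of squares and an
    asymptotic standard-error estimate for (k1, kcat, Kp).
    """
    if len(traces) < 3:
        raise InvalidInputError("global fit needs at least 3 enzyme concentrations")
    if not ka_fixed > 0:
        raise InvalidInputError("Ka must be positive")
    e0s = [tr.e0 for tr in traces]
    if len(set(round(e, 9) for e in e0s)) < 3:
        raise InvalidInputError("need at least 3 distinct enzyme concentrations")

    def trajs_for(k1, kcat, kp):
        p = Scheme1Params.from_ka(k1, ka_fixed, kcat, kp)
        return [
            simulate_scheme1(p, tr.e0, tr.s0, tr.time_s, ep_koff=ep_koff,
                             rtol=1e-7, atol=1e-9)
            for tr in traces
        ]

    def resid(log10_theta):
        k1, kcat, kp = 10.0 ** log10_theta
        try:
            trajs = trajs_for(k1, kcat, kp)
        except FitFailureError:
            return np.full(sum(tr.time_s.size for tr in traces), 1e3)
        r, _, _ = _stack_linear_fit(traces, trajs)
        return r

    lb = np.log10([1e-2, 1e-3, 1e-2])
    ub = np.log10([1e4, 1e3, 1e4])
    starts = [
        np.array([
            np.log10(v)
            for v in (
                np.geomspace(0.5, 200, n_starts)[i],
                np.geomspace(0.1, 100, n_starts)[i],
                np.geomspace(0.5, 100, n_starts)[(i * 3) % n_starts],
            )
        ])
        for i in range(n_starts)
    ]

    best = None
    for x0 in starts:
        try:
            res = _opt.least_squares(
                resid, np.clip(x0, lb, ub), bounds=(lb, ub),
                xtol=1e-10, ftol=1e-10, diff_step=1e-4,
            )
        except Exception:  # pragma: no cover - solver edge
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        raise FitFailureError("every global-fit start failed")
    rss, res = best
    k1, kcat, kp = 10.0 ** res.x
    params = Scheme1Params.from_ka(k1, ka_fixed, kcat, kp)
    trajs = trajs_for(k1, kcat, kp)
    _, coefs, baselines = _stack_linear_fit(traces, trajs)

    # asymptotic covariance of log10(k1, kcat, kp) -> delta-method std errs
    dof = max(sum(tr.time_s.size for tr in traces) - (3 + 3 + len(traces)), 1)
    s2 = rss / dof
    jtj = res.jac.T @ res.jac
    try:
        cov_log = s2 * np.linalg.inv(jtj)
        log_err = np.sqrt(np.clip(np.diag(cov_log), 0.0, None))
        param_err = np.log(10.0) * np.array([k1, kcat, kp]) * log_err
    except np.linalg.LinAlgError:  # pragma: no cover
        param_err = np.full(3, np.nan)

    info = {
        "coef_es_minus_s": float(coefs[0]),
        "coef_ep_minus_s": float(coefs[1]),
        "coef_p_minus_s": float(coefs[2]),
        "baselines": [float(b) for b in baselines],
        "rss": rss,
        "stderr": {
            "k1": float(param_err[0]),
            "kcat": float(param_err[1]),
            "kp": float(param_err[2]),
        },
    }
    return params, info


# ---------------------------------------------------------------------------
# Steady-state product accumulation and MST isotherm
# ---------------------------------------------------------------------------


def fit_product_eq6(t_s, product_pct) -> ProductCurveParams:
    """Fit [Product](t) = A (1 - exp(-k_obs t)) + k_lin t (A in %)."""
    t = np.asarray(t_s, dtype=float)
    y = np.asarray(product_pct, dtype=float)
    if t.size < 6:
        raise InvalidInputError("need at least 6 time points")
    if np.any(y < -1e-9) or np.any(y > 100 + 1e-9):
        raise InvalidInputError("product values must lie in [0, 100] %")

    def model(tt, a, k_obs, k_lin):
        return a * (1.0 - np.exp(-k_obs * tt)) + k_lin * tt

    span = max(y.max() - y.min(), 1e-6)
    t_half = t[np.argmin(np.abs(y - 0.5 * y.max()))] if y.max() > 0 else t[-1]
    p0 = [min(max(span, 1e-3), 100.0), 1.0 / max(t_half, 1e-6), 1e-6]
    try:
        popt, pcov = _opt.curve_fit(
            model, t, y, p0=p0,
            bounds=([0.0, 0.0, 0.0], [100.0, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"product-curve fit did not converge: {exc}") from exc
    err = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return ProductCurveParams(
        amplitude=float(popt[0]),
        k_obs=float(popt[1]),
        k_lin=float(popt[2]),
        amplitude_err=float(err[0]),
        k_obs_err=float(err[1]),
        k_lin_err=float(err[2]),
    )


def fit_mst_eq8(conc_um, signal) -> MstModelParams:
    """Fit the hyperbolic MST isotherm; returns Ka with its standard error.

    Requires at least 6 concentrations spanning at least one decade.  A Ka
    that converges onto the search bounds is flagged ``at_bound``.
    """
    c = np.asarray(conc_um, dtype=float)
    y = np.asarray(signal, dtype=float)
    if c.size < 6:
        raise InvalidInputError("need at least 6 titration points")
    pos = c[c > 0]
    if pos.size == 0 or pos.max() / pos.min() < 10.0 - 1e-9:
        raise InvalidInputError("titration must span at least one decade")

    def model(cc, f0, fa, ka):
        return f0 + fa * cc / (1.0 / ka + cc)

    ka_lo, ka_hi = 1e-4, 1e4
    p0 = [float(y.min()), float(y.max() - y.min()), 1.0 / float(np.median(pos))]
    try:
        popt, pcov = _opt.curve_fit(
            model, c, y, p0=p0,
            bounds=([-np.inf, -np.inf, ka_lo], [np.inf, np.inf, ka_hi]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"MST isotherm fit did not converge: {exc}") from exc
    ka = float(popt[2])
    at_bound = bool(np.isclose(ka, ka_lo) or np.isclose(ka, ka_hi))
    err = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return MstModelParams(
        f_backgr=float(popt[0]),
        f_ampl=float(popt[1]),
        ka=ka,
        ka_err=float(err[2]),
        at_bound=at_bound,
    )
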