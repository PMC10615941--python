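"""Wiener diffusion engine for two-choice response times.

The drift-diffusion model (DDM) describes a decision as a Wiener process with
drift ``v`` and unit diffusion coefficient, started at a fraction ``zr`` of the
boundary separation ``a`` and absorbed at 0 (error) or ``a`` (correct).  The
observed response time is the first-passage (decision) time plus a
non-decision offset ``t0``.  This module provides:

* the defective first-passage-time density at either boundary, evaluated with
  the dual small-time/large-time series representation and an automatic
  crossover rule (Navarro & Fuss, 2009, J. Math. Psychol.);
* trial simulation, by inverse-CDF sampling from that density (default) or by
  Euler–Maruyama integration of the process itself;
* the summed log-likelihood of a trial table and bounded maximum-likelihood
  fitting (Nelder–Mead simplex with EZ-based starting values and jittered
  restarts);
* the EZ-diffusion closed-form estimator (Wagenmakers, van der Maas &
  Grasman, 2007), rescaled to the s = 1 diffusion convention used throughout.

Conventions: the upper boundary codes the *correct* response, the lower
boundary the error (accuracy coding); all times are in seconds; the diffusion
coefficient is fixed at s = 1, so Simulation-style parameter ranges such as
v in [0, 4] and a in [0.5, 2] are used verbatim.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize

__all__ = [
    "DDMParams",
    "FitResult",
    "wiener_fpt_density",
    "absorption_probability",
    "simulate_ddm_trials",
    "ddm_loglik",
    "fit_ddm_ml",
    "fit_ez",
    "ez_summaries",
    "DENSITY_FLOOR",
]

#: Per-trial likelihood floor; keeps the objective finite in misfit regions.
DENSITY_FLOOR = 1e-10

#: Absolute truncation tolerance of the series expansions (normalized scale).
SERIES_TOL = 1e-7

#: Optimizer bounds for the three free parameters.
V_BOUNDS = (-10.0, 10.0)
A_BOUNDS = (0.05, 5.0)


@dataclass(frozen=True)
class DDMParams:
    """Main DDM parameters (zr fixed at 0.5 and s at 1 in all studies)."""

    v: float
    a: float
    t0: float
    zr: float = 0.5
    s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"boundary separation must be positive, got {self.a}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time must be non-negative, got {self.t0}")
        if not (0.0 < self.zr < 1.0):
            raise ValueError(f"relative start point must be in (0, 1), got {self.zr}")
        if not (self.s > 0):
            raise ValueError(f"diffusion coefficient must be positive, got {self.s}")


@dataclass
class FitResult:
    """Best-fitting parameters for one participant (one or two conditions)."""

    params: dict
    loglik: float
    n_free_params: int
    converged: bool
    n_restarts_used: int = 0


# ---------------------------------------------------------------------------
# First-passage-time density
# ---------------------------------------------------------------------------

def _fpt_lower_norm(tau: np.ndarray, w: float, tol: float) -> np.ndarray:
    """Zero-drift defective FPT density at the lower bound on normalized time.

    ``tau`` is decision time divided by a**2; ``w`` the relative start point.
    Uses the small-time expansion when it needs fewer terms than the
    large-time one for the requested absolute tolerance, per element.
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not np.any(pos):
        return out
    t = tau[pos]

    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * tol * np.sqrt(2.0 * np.pi * t)
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(arg_s), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        arg_l = np.pi * t * tol
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(arg_l), 0.0) / (np.pi**2 * t)),
            0.0,
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))

    use_small = ks < kl
    f = np.zeros_like(t)

    if np.any(use_small):
        ts = t[use_small]
        n_terms = int(min(math.ceil(float(ks[use_small].max())), 80))
        kk = np.arange(-(n_terms // 2), n_terms // 2 + 1, dtype=float)
        wk = w + 2.0 * kk[None, :]
        f[use_small] = (
            (wk * np.exp(-(wk**2) / (2.0 * ts[:, None]))).sum(axis=1)
            / np.sqrt(2.0 * np.pi * ts**3)
        )

    if np.any(~use_small):
        tl = t[~use_small]
        n_terms = int(min(math.ceil(float(kl[~use_small].max())), 500))
        kk = np.arange(1.0, n_terms + 1.0)
        f[~use_small] = np.pi * (
            kk[None, :]
            * np.exp(-(kk[None, :] ** 2) * np.pi**2 * tl[:, None] / 2.0)
            * np.sin(kk[None, :] * np.pi * w)
        ).sum(axis=1)

    out[pos] = np.maximum(f, 0.0)
    return out


def _density_arrays(
    t, v: float, a: float, zr: float, s: float, bound: str, tol: float
) -> np.ndarray:
    if bound not in ("upper", "lower"):
        raise ValueError(f"bound must be 'upper' or 'lower', got {bound!r}")
    # rescale to unit diffusion coefficient
    v, a = v / s, a / s
    if bound == "upper":
        v, w = -v, 1.0 - zr
    else:
        w = zr
    t = np.asarray(t, dtype=float)
    tpos = np.maximum(t, 0.0)
    f = _fpt_lower_norm(tpos / a**2, w, tol)
    with np.errstate(over="ignore"):
        pref = np.exp(-v * a * w - (v**2) * tpos / 2.0) / a**2
    return f * pref / s**2 * s**2  # density in 1/s; scaling cancels for time


def wiener_fpt_density(t, params: DDMParams, bound: str = "upper", tol: float = SERIES_TOL):
    """Defective first-passage density at ``bound`` for decision time ``t``.

    Returns 0 for t <= 0.  Integrating the upper plus lower densities over
    (0, inf) gives 1; each branch alone integrates to that response's choice
    probability.
    """
    res = _density_arrays(t, params.v, params.a, params.zr, params.s, bound, tol)
    if np.isscalar(t):
        return float(res)
    return res


def absorption_probability(params: DDMParams, bound: str = "upper") -> float:
    """Closed-form probability of absorption at the given boundary."""
    v, a, zr, s = params.v, params.a, params.zr, params.s
    v, a = v / s, a / s
    z = zr * a
    if abs(v) < 1e-12:
        p_upper = zr
    else:
        p_upper = -math.expm1(-2.0 * v * z) / -math.expm1(-2.0 * v * a)
    if bound == "upper":
        return p_upper
    if bound == "lower":
        return 1.0 - p_upper
    raise ValueError(f"bound must be 'upper' or 'lower', got {bound!r}")


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

def _fpt_grid(params: DDMParams, n_grid: int = 4096, mass_tol: float = 1e-8):
    """Time grid plus cumulative defective CDFs at both bounds (cached).

    The horizon is doubled until the two defective masses jointly account for
    all but ``mass_tol`` of the probability.  Cached on the parameter values:
    in the no-difference designs both conditions share one parameter set, so
    the grid is built once per participant.
    """
    return _fpt_grid_cached(params.v, params.a, params.zr, params.s, n_grid, mass_tol)


@functools.lru_cache(maxsize=16)
def _fpt_grid_cached(v, a, zr, s, n_grid, mass_tol):
    params = DDMParams(v=v, a=a, t0=0.0, zr=zr, s=s)
    a_unit = params.a / params.s
    # the FPT distribution lives on the a^2 time scale (normalized time
    # tau = t / a^2); a fixed floor would let tiny-a spikes fall between
    # grid points, so the horizon must track the natural scale
    horizon = 6.0 * a_unit**2
    for _ in range(16):
        tgrid = np.linspace(0.0, horizon, n_grid)
        f_up = _density_arrays(tgrid, params.v, params.a, params.zr, params.s, "upper", SERIES_TOL)
        f_lo = _density_arrays(tgrid, params.v, params.a, params.zr, params.s, "lower", SERIES_TOL)
        cum_up = cumulative_trapezoid(f_up, tgrid, initial=0.0)
        cum_lo = cumulative_trapezoid(f_lo, tgrid, initial=0.0)
        total = cum_up[-1] + cum_lo[-1]
        if np.isfinite(total) and 1.0 - total < mass_tol:
            return tgrid, cum_up, cum_lo
        horizon *= 2.0
    if not np.isfinite(total) or total <= 0.9:
        raise RuntimeError(
            f"first-passage mass did not converge for v={v}, a={a}, zr={zr}"
        )
    return tgrid, cum_up, cum_lo


def _inverse_cdf_sample(rng, n, tgrid, cum) -> np.ndarray:
    total = cum[-1]
    # strictly increasing copy so interpolation is well defined
    mono = np.maximum.accumulate(cum) + np.arange(cum.size) * 1e-15
    u = rng.random(n) * total
    return np.interp(u, mono, tgrid)


def simulate_ddm_trials(
    params: DDMParams,
    n_trials: int,
    seed=None,
    method: str = "inverse_cdf",
    dt: float = 5e-4,
) -> pd.DataFrame:
    """Simulate two-choice trials; returns columns ``rt`` and ``response``.

    ``response`` is 1 for a correct (upper-bound) response and 0 for an
    error.  ``method='inverse_cdf'`` (default) samples decision times from
    the first-passage density via a per-parameter-set grid inversion;
    ``method='euler'`` integrates the Wiener process with step ``dt``
    (<= 0.5 ms).
    """
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_trials == 0:
        return pd.DataFrame({"rt": np.empty(0), "response": np.empty(0, dtype=int)})

    if method == "inverse_cdf":
        tgrid, cum_up, cum_lo = _fpt_grid(params)
        total = cum_up[-1] + cum_lo[-1]
        p_up = cum_up[-1] / total
        is_correct = rng.random(n_trials) < p_up
        dec = np.empty(n_trials)
        n_up = int(is_correct.sum())
        if n_up:
            dec[is_correct] = _inverse_cdf_sample(rng, n_up, tgrid, cum_up)
        if n_trials - n_up:
            dec[~is_correct] = _inverse_cdf_sample(rng, n_trials - n_up, tgrid, cum_lo)
    elif method == "euler":
        if dt > 5e-4:
            raise ValueError("Euler step must be at most 0.5 ms")
        dec, is_correct = _simulate_euler(params, n_trials, rng, dt)
    else:
        raise ValueError(f"unknown simulation method {method!r}")

    return pd.DataFrame(
        {"rt": dec + params.t0, "response": is_correct.astype(int)}
    )


def _simulate_euler(params: DDMParams, n_trials: int, rng, dt: float):
    v, a, zr, s = params.v, params.a, params.zr, params.s
    x = np.full(n_trials, zr * a)
    dec = np.zeros(n_trials)
    correct = np.zeros(n_trials, dtype=bool)
    active = np.ones(n_trials, dtype=bool)
    sqdt = math.sqrt(dt) * s
    t = 0.0
    while active.any() and t < 120.0:
        idx = np.nonzero(active)[0]
        x[idx] += v * dt + sqdt * rng.standard_normal(idx.size)
        t += dt
        hit_up = x[idx] >= a
        hit_lo = x[idx] <= 0.0
        done = hit_up | hit_lo
        fin = idx[done]
        dec[fin] = t
        correct[fin] = hit_up[done]
        active[fin] = False
    # stragglers (probability ~ exp(-lambda * 120); practically absent)
    if active.any():
        dec[active] = t
        correct[active] = x[active] >= zr * params.a
    return dec, correct


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _loglik_arrays(
    v: float, a: float, t0: float, rt: np.ndarray, correct: np.ndarray,
    zr: float = 0.5, floor: float = DENSITY_FLOOR,
) -> float:
    """Summed log defective density over one condition's trials."""
    if rt.size == 0:
        return 0.0
    td = rt - t0
    dens = np.full(rt.shape, floor)
    ok = td > 0
    up = correct & ok
    lo = ~correct & ok
    if up.any():
        dens[up] = _density_arrays(td[up], v, a, zr, 1.0, "upper", SERIES_TOL)
    if lo.any():
        dens[lo] = _density_arrays(td[lo], v, a, zr, 1.0, "lower", SERIES_TOL)
    return float(np.log(np.maximum(dens, floor)).sum())


def ddm_loglik(params, trials: pd.DataFrame, floor: float = DENSITY_FLOOR) -> float:
    """Summed log-likelihood of a trial table (one participant).

    ``params`` is either a single :class:`DDMParams` (applied to all trials)
    or a mapping ``{condition: DDMParams}``.  Trials whose rt does not exceed
    the relevant t0 contribute the log of the density floor rather than
    raising, so optimizers can recover from bad proposals.
    """
    if trials.empty:
        return 0.0
    rt = trials["rt"].to_numpy(dtype=float)
    correct = trials["response"].to_numpy() == 1
    if isinstance(params, DDMParams):
        return _loglik_arrays(params.v, params.a, params.t0, rt, correct, params.zr, floor)
    total = 0.0
    cond = trials["condition"].to_numpy()
    for label, p in params.items():
        m = cond == label
        total += _loglik_arrays(p.v, p.a, p.t0, rt[m], correct[m], p.zr, floor)
    return total


# ---------------------------------------------------------------------------
# EZ-diffusion closed form
# ---------------------------------------------------------------------------

def ez_summaries(rt: np.ndarray, correct: np.ndarray):
    """(proportion correct, variance of correct RTs, mean of correct RTs)."""
    pc = float(np.mean(correct)) if correct.size else math.nan
    sel = rt[correct] if correct.any() else rt
    mrt = float(np.mean(sel))
    vrt = float(np.var(sel, ddof=1)) if sel.size > 1 else math.nan
    return pc, vrt, mrt


def fit_ez(pc: float, vrt: float, mrt: float, n_trials: int | None = None) -> DDMParams:
    """EZ-diffusion inversion from accuracy and correct-RT moments to (v, a, t0).

    Computed in the published scaling and reported on the s = 1 convention
    (the published equations are scale-covariant, so this amounts to using
    s = 1 directly).  Accuracies of exactly 0, 0.5, or 1 are edge-corrected
    with 1/(2n) before inversion; if ``n_trials`` is unknown a nominal n of
    500 is assumed for the correction.
    """
    if not (vrt > 0):
        raise ValueError(f"RT variance must be positive, got {vrt}")
    n = n_trials if n_trials else 500
    eps = 1.0 / (2.0 * n)
    if pc >= 1.0:
        pc = 1.0 - eps
    elif pc <= 0.0:
        pc = eps
    elif pc == 0.5:
        pc = 0.5 + eps
    logit = math.log(pc / (1.0 - pc))
    x = logit * (logit * pc**2 - logit * pc + pc - 0.5) / vrt
    v = math.copysign(abs(x) ** 0.25, pc - 0.5)
    a = logit / v
    y = -v * a
    mdt = (a / (2.0 * v)) * (1.0 - math.exp(y)) / (1.0 + math.exp(y))
    t0 = mrt - mdt
    return DDMParams(v=v, a=max(a, 1e-6), t0=max(t0, 0.0))


def ez_fit_trials(trials: pd.DataFrame) -> DDMParams:
    """EZ estimate from a single-condition trial table."""
    rt = trials["rt"].to_numpy(dtype=float)
    correct = trials["response"].to_numpy() == 1
    pc, vrt, mrt = ez_summaries(rt, correct)
    return fit_ez(pc, vrt, mrt, n_trials=rt.size)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _ez_start(rt: np.ndarray, correct: np.ndarray, t0_hi: float) -> np.ndarray:
    try:
        ez = ez_fit_trials(pd.DataFrame({"rt": rt, "response": correct.astype(int)}))
        start = np.array([ez.v, ez.a, ez.t0])
    except (ValueError, ZeroDivisionError, OverflowError):
        start = np.array([1.0, 1.0, 0.3 * float(rt.min())])
    lo = np.array([V_BOUNDS[0], A_BOUNDS[0], 1e-4])
    hi = np.array([V_BOUNDS[1], A_BOUNDS[1], t0_hi])
    return np.clip(start, lo + 1e-6, hi - 1e-6)


_NM_OPTS = dict(xatol=1e-3, fatol=1e-3, maxiter=1500, maxfev=2000)


def _fit_condition(rt, correct, n_restarts, rng):
    """Fit (v, a, t0) to one condition's trials by bounded Nelder–Mead."""
    t0_hi = max(float(rt.min()) - 1e-3, 2e-3)
    bounds = [V_BOUNDS, A_BOUNDS, (1e-4, t0_hi)]
    start = _ez_start(rt, correct, t0_hi)

    def nll(theta):
        return -_loglik_arrays(theta[0], theta[1], theta[2], rt, correct)

    best = None
    used = 0
    for i in range(max(n_restarts, 1)):
        x0 = start.copy()
        if i > 0:
            x0 = x0 * (1.0 + 0.1 * rng.standard_normal(3))
            x0 = np.clip(x0, [b[0] + 1e-6 for b in bounds], [b[1] - 1e-6 for b in bounds])
        res = minimize(nll, x0, method="Nelder-Mead", bounds=bounds, options=_NM_OPTS)
        used += 1
        if best is None or res.fun < best.fun:
            best = res
    return best, used, t0_hi


def _pack_layout(vary: tuple, conds: list):
    """Index layout of the free-parameter vector under a sharing constraint."""
    layout = []
    for name, free in zip(("v", "a", "t0"), vary):
        if free:
            layout.append((name, conds))
        else:
            layout.append((name, None))  # shared entry
    return layout


def fit_ddm_ml(
    trials: pd.DataFrame,
    constraint: tuple | None = None,
    n_restarts: int = 3,
    seed=None,
    extra_starts=None,
) -> FitResult:
    """ML fit of one participant's trials, optionally with shared parameters.

    ``constraint`` is a (vary_v, vary_a, vary_t0) triple; ``None`` means all
    three parameters free per condition.  When all parameters vary the joint
    likelihood separates and each condition is fitted independently; under a
    sharing constraint the pooled likelihood is maximized jointly.
    ``extra_starts`` (constrained path only) supplies additional starting
    vectors, e.g. embeddings of a nested model's solution.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if "condition" in trials.columns:
        conds = sorted(trials["condition"].unique())
    else:
        trials = trials.assign(condition="all")
        conds = ["all"]
    for c in conds:
        if (trials["condition"] == c).sum() < 2:
            raise ValueError(f"need at least 2 trials per condition, condition {c!r}")

    if constraint is None:
        constraint = (True, True, True)
    vary = tuple(bool(x) for x in constraint)

    if all(vary) or len(conds) == 1:
        params, ll, ok, used = {}, 0.0, True, 0
        for c in conds:
            sub = trials[trials["condition"] == c]
            rt = sub["rt"].to_numpy(dtype=float)
            correct = sub["response"].to_numpy() == 1
            res, n_used, _ = _fit_condition(rt, correct, n_restarts, rng)
            params[c] = DDMParams(v=res.x[0], a=res.x[1], t0=max(res.x[2], 0.0))
            ll += -res.fun
            ok = ok and bool(res.success)
            used += n_used
        return FitResult(params, ll, 3 * len(conds), ok, used)

    # constrained joint fit over both conditions
    layout = _pack_layout(vary, conds)
    data = {}
    for c in conds:
        sub = trials[trials["condition"] == c]
        data[c] = (
            sub["rt"].to_numpy(dtype=float),
            sub["response"].to_numpy() == 1,
        )
    t0_hi = {c: max(float(data[c][0].min()) - 1e-3, 2e-3) for c in conds}
    t0_hi_shared = min(t0_hi.values())

    bounds, names = [], []
    for name, span in layout:
        if name == "v":
            b = V_BOUNDS
        elif name == "a":
            b = A_BOUNDS
        else:
            b = None
        if span is None:
            bounds.append((1e-4, t0_hi_shared) if name == "t0" else b)
            names.append((name, None))
        else:
            for c in span:
                bounds.append((1e-4, t0_hi[c]) if name == "t0" else b)
                names.append((name, c))

    def unpack(theta):
        per_cond = {c: {} for c in conds}
        for val, (name, c) in zip(theta, names):
            if c is None:
                for cc in conds:
                    per_cond[cc][name] = val
            else:
                per_cond[c][name] = val
        return per_cond

    def nll(theta):
        per_cond = unpack(theta)
        total = 0.0
        for c in conds:
            p = per_cond[c]
            rt, correct = data[c]
            total -= _loglik_arrays(p["v"], p["a"], p["t0"], rt, correct)
        return total

    # EZ start: per-condition estimates, averaged where shared
    ez = {}
    for c in conds:
        ez[c] = _ez_start(data[c][0], data[c][1], t0_hi[c])
    base = []
    for name, c in names:
        i = ("v", "a", "t0").index(name)
        if c is None:
            base.append(float(np.mean([ez[cc][i] for cc in conds])))
        else:
            base.append(float(ez[c][i]))
    starts = [np.asarray(base)]
    if extra_starts is not None:
        starts += [np.asarray(s, dtype=float) for s in extra_starts]

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    best, used = None, 0
    for j, s0 in enumerate(starts):
        for i in range(max(n_restarts, 1) if j == 0 else 1):
            x0 = s0.copy()
            if i > 0:
                x0 = x0 * (1.0 + 0.1 * rng.standard_normal(x0.size))
            x0 = np.clip(x0, lo + 1e-6, hi - 1e-6)
            res = minimize(nll, x0, method="Nelder-Mead", bounds=bounds, options=_NM_OPTS)
            used += 1
            if best is None or res.fun < best.fun:
                best = res
    per_cond = unpack(best.x)
    params = {
        c: DDMParams(v=per_cond[c]["v"], a=per_cond[c]["a"], t0=max(per_cond[c]["t0"], 0.0))
        for c in conds
    }
    n_free = len(bounds)
    return FitResult(params, -best.fun, n_free, bool(best.success), used)
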