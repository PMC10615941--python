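"""Linear Ballistic Accumulator engine: simulation, likelihood, ML fitting.

Two independent linear accumulators race to a threshold ``b``: one for the
correct response with mean drift ``v`` and one for the error response with
mean drift ``1 - v``.  Each trial every accumulator draws a start point
uniformly on [0, A] and a drift from a Normal with the accumulator's mean
and common SD ``s``; the first to reach ``b`` determines the response, and
the observed RT adds the non-decision time ``t0``.  Response caution — the
analogue of DDM boundary separation — is ``b - A/2``, the mean distance from
start to threshold.

The drift SD ``s`` is fixed at 0.3 in both generation and fitting, cohering
with the fitting heuristic that reads a starting drift off the normal
quantile function with SD 0.3.  Trials on which both accumulators draw a
non-positive drift would never finish; the simulator redraws them, and the
likelihood renormalizes by 1 - P(both drifts <= 0) so the two stay mutually
consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

from .ddm import DENSITY_FLOOR, FitResult

__all__ = [
    "LBAParams",
    "LBA_DRIFT_SD",
    "simulate_lba_trials",
    "lba_loglik",
    "fit_lba_ml",
    "lba_start_heuristics",
    "compute_caution",
]

#: Trial-to-trial drift SD, shared by generation and fitting.
LBA_DRIFT_SD = 0.3

_V_BOUNDS = (0.1, 10.0)
_A_BOUNDS = (0.01, 5.0)
_DELTA_BOUNDS = (0.001, 5.0)  # b = A + delta


@dataclass(frozen=True)
class LBAParams:
    """LBA parameters; the error accumulator's mean drift is 1 - v."""

    v: float
    A: float
    b: float
    t0: float
    s: float = LBA_DRIFT_SD

    def __post_init__(self) -> None:
        if not (self.A > 0):
            raise ValueError(f"start-point range A must be positive, got {self.A}")
        if not (self.b > self.A):
            raise ValueError(f"threshold b={self.b} must exceed A={self.A}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time must be non-negative, got {self.t0}")
        if not (self.s > 0):
            raise ValueError(f"drift SD must be positive, got {self.s}")

    @property
    def v_err(self) -> float:
        return 1.0 - self.v

    @property
    def caution(self) -> float:
        return compute_caution(self.A, self.b)


def compute_caution(A: float, b: float) -> float:
    """Response caution b - A/2 (mean start-to-threshold distance)."""
    if not (b > A > 0):
        raise ValueError(f"caution requires b > A > 0, got b={b}, A={A}")
    return b - A / 2.0


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_lba_trials(params: LBAParams, n_trials: int, seed=None) -> pd.DataFrame:
    """Simulate trials; returns columns ``rt`` and ``response`` (1 correct).

    Finishing time of an accumulator is (b - start)/drift when its drift is
    positive and infinite otherwise; trials where both drifts are
    non-positive are redrawn.
    """
    if n_trials < 0:
        raise ValueError("n_trials must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_trials == 0:
        return pd.DataFrame({"rt": np.empty(0), "response": np.empty(0, dtype=int)})

    means = np.array([params.v, 1.0 - params.v])
    d = rng.normal(means, params.s, size=(n_trials, 2))
    stuck = (d <= 0).all(axis=1)
    while stuck.any():
        d[stuck] = rng.normal(means, params.s, size=(int(stuck.sum()), 2))
        stuck = (d <= 0).all(axis=1)
    k = rng.uniform(0.0, params.A, size=(n_trials, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(d > 0, (params.b - k) / d, np.inf)
    winner = np.argmin(t, axis=1)
    dec = t[np.arange(n_trials), winner]
    return pd.DataFrame({"rt": dec + params.t0, "response": (winner == 0).astype(int)})


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _phi(x):
    return np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)


def lba_finishing_cdf(t, drift: float, A: float, b: float, s: float):
    """CDF of one accumulator's threshold-crossing time (Uniform start x
    Normal drift closed form); includes the mass of never finishing."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    ts = t[pos] * s
    x1 = (b - A - t[pos] * drift) / ts
    x2 = (b - t[pos] * drift) / ts
    val = (
        1.0
        + ((b - A - t[pos] * drift) / A) * ndtr(x1)
        - ((b - t[pos] * drift) / A) * ndtr(x2)
        + (ts / A) * _phi(x1)
        - (ts / A) * _phi(x2)
    )
    out[pos] = np.clip(val, 0.0, 1.0)
    return out


def lba_finishing_pdf(t, drift: float, A: float, b: float, s: float):
    """Density of one accumulator's threshold-crossing time."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    ts = t[pos] * s
    x1 = (b - A - t[pos] * drift) / ts
    x2 = (b - t[pos] * drift) / ts
    val = (-drift * ndtr(x1) + s * _phi(x1) + drift * ndtr(x2) - s * _phi(x2)) / A
    out[pos] = np.maximum(val, 0.0)
    return out


def _loglik_arrays(v, A, b, t0, rt, correct, s=LBA_DRIFT_SD, floor=DENSITY_FLOOR):
    if rt.size == 0:
        return 0.0
    td = rt - t0
    dens = np.full(rt.shape, floor)
    ok = td > 0
    drifts = (v, 1.0 - v)
    # renormalize for redrawn never-finishing trials
    p_stuck = float(ndtr(-drifts[0] / s) * ndtr(-drifts[1] / s))
    z = max(1.0 - p_stuck, 1e-12)
    for resp, (win, lose) in ((True, (0, 1)), (False, (1, 0))):
        m = ok & (correct if resp else ~correct)
        if m.any():
            f = lba_finishing_pdf(td[m], drifts[win], A, b, s)
            surv = 1.0 - lba_finishing_cdf(td[m], drifts[lose], A, b, s)
            dens[m] = f * np.clip(surv, 0.0, 1.0) / z
    return float(np.log(np.maximum(dens, floor)).sum())


def lba_loglik(params: LBAParams, trials: pd.DataFrame, floor: float = DENSITY_FLOOR) -> float:
    """Summed log defective density of one participant-condition's trials.

    Defective density of a response = winner's finishing-time pdf times the
    loser's survivor function, renormalized by the probability that at least
    one drift is positive.  Trials with rt <= t0 contribute the floor.
    """
    if trials.empty:
        return 0.0
    rt = trials["rt"].to_numpy(dtype=float)
    correct = trials["response"].to_numpy() == 1
    return _loglik_arrays(params.v, params.A, params.b, params.t0, rt, correct, params.s, floor)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def lba_start_heuristics(rt: np.ndarray, correct: np.ndarray, s: float = LBA_DRIFT_SD):
    """Starting values: t0 at 90% of the fastest response; v from the normal
    quantile of the observed accuracy (SD ``s``); A twice the RT
    inter-quartile range; b at 1.25 A."""
    n = rt.size
    t0 = 0.9 * float(rt.min())
    p = float(np.mean(correct))
    p = min(max(p, 1.0 / (2 * n)), 1.0 - 1.0 / (2 * n))
    v = 0.5 + s * float(ndtri(p))
    q75, q25 = np.percentile(rt, [75.0, 25.0])
    A = 2.0 * float(q75 - q25)
    b = 1.25 * A
    return v, A, b, t0


def fit_lba_ml(
    trials: pd.DataFrame, n_restarts: int = 3, seed=None, s: float = LBA_DRIFT_SD
) -> FitResult:
    """Bounded quasi-Newton (L-BFGS-B) ML fit of one condition's trials.

    The threshold is parameterized as b = A + delta with delta > 0, so b > A
    is guaranteed throughout the search.  The first start uses the standard
    heuristics; on failure the start is jittered (10% multiplicative).  The
    drift SD ``s`` is a fixed scaling constant, not a free parameter.
    """
    if "condition" in trials.columns:
        conds = sorted(trials["condition"].unique())
        if len(conds) > 1:
            params, ll, ok, used = {}, 0.0, True, 0
            for c in conds:
                r = fit_lba_ml(trials[trials["condition"] == c], n_restarts, seed, s)
                params[c] = r.params["all"]
                ll += r.loglik
                ok = ok and r.converged
                used += r.n_restarts_used
            return FitResult(params, ll, 4 * len(conds), ok, used)
    rt = trials["rt"].to_numpy(dtype=float)
    correct = trials["response"].to_numpy() == 1
    if rt.size < 2:
        raise ValueError("need at least 2 trials to fit")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    t0_hi = max(float(rt.min()) - 1e-3, 2e-3)
    v0, A0, b0, t00 = lba_start_heuristics(rt, correct, s=s)
    start = np.array([v0, A0, max(b0 - A0, 0.01), min(t00, t0_hi - 1e-4)])
    bounds = [_V_BOUNDS, _A_BOUNDS, _DELTA_BOUNDS, (1e-4, t0_hi)]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    start = np.clip(start, lo + 1e-6, hi - 1e-6)

    def nll(theta):
        v, A, delta, t0 = theta
        return -_loglik_arrays(v, A, A + delta, t0, rt, correct, s=s)

    best, used = None, 0
    for i in range(max(n_restarts, 1)):
        x0 = start.copy()
        if i > 0:
            x0 = np.clip(x0 * (1.0 + 0.1 * rng.standard_normal(4)), lo + 1e-6, hi - 1e-6)
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        used += 1
        if best is None or res.fun < best.fun:
            best = res
        if best is not None and np.isfinite(best.fun) and best.success:
            break
    v, A, delta, t0 = best.x
    params = {"all": LBAParams(v=v, A=A, b=A + delta, t0=max(t0, 0.0), s=s)}
    return FitResult(params, -best.fun, 4, bool(best.success), used)
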