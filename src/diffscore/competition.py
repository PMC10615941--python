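"""Formal model competition over condition-sharing constraints.

Eight models form the boolean cube over whether drift rate v, boundary
separation a, and non-decision time t0 are free to vary across the easy and
hard conditions.  Model 1 shares everything (3 free parameters per
participant); Model 8 frees everything (6).  Each model is fitted per
participant by maximum likelihood (shared parameters estimated on the pooled
conditions in a single likelihood), and AIC/BIC are summed across
participants; Akaike weights turn the summed criteria into relative evidence
for each model.

Because every model nests inside any model with strictly more free
parameters, the attained log-likelihood must be monotone non-decreasing in
model freedom.  Optimizer noise can violate this, so after fitting, any
super-model that falls below a nested model is repaired by adopting the
nested solution (which is exactly representable in the super-model and has
the identical likelihood).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ddm import fit_ddm_ml

__all__ = [
    "ModelSpec",
    "enumerate_model_family",
    "akaike_weights",
    "fit_model_family",
]


@dataclass(frozen=True)
class ModelSpec:
    """One sharing pattern: which parameters may differ across conditions."""

    vary_v: bool
    vary_a: bool
    vary_t0: bool
    name: str = ""

    @property
    def vary(self) -> tuple:
        return (self.vary_v, self.vary_a, self.vary_t0)

    @property
    def n_free_params(self) -> int:
        return 3 + sum(self.vary)

    def nests_in(self, other: "ModelSpec") -> bool:
        return all(not s or o for s, o in zip(self.vary, other.vary))


def enumerate_model_family() -> list:
    """The 8-model family, ordered from fully shared to fully free."""
    patterns = [
        (False, False, False),
        (True, False, False),
        (False, True, False),
        (False, False, True),
        (False, True, True),
        (True, False, True),
        (True, True, False),
        (True, True, True),
    ]
    return [
        ModelSpec(*p, name=f"Model {i + 1}") for i, p in enumerate(patterns)
    ]


def akaike_weights(ic_values) -> np.ndarray:
    """exp(-delta/2) weights, normalized over the finite entries.

    Non-finite criteria are excluded (weight NaN) with a warning.  The
    weights are invariant to adding a constant to every criterion.
    """
    ic = np.asarray(ic_values, dtype=float)
    out = np.full(ic.shape, np.nan)
    finite = np.isfinite(ic)
    if not finite.any():
        raise ValueError("need at least one finite information criterion")
    if not finite.all():
        warnings.warn(f"excluding {int((~finite).sum())} non-finite criterion value(s)")
    delta = ic[finite] - ic[finite].min()
    w = np.exp(-delta / 2.0)
    out[finite] = w / w.sum()
    return out


def _embed_start(params: dict, names: list, conds: list) -> np.ndarray:
    """Express a fitted parameter set as a start vector for another layout."""
    vec = []
    for name, c in names:
        if c is None:
            vec.append(float(np.mean([getattr(params[cc], name) for cc in conds])))
        else:
            vec.append(float(getattr(params[c], name)))
    return np.asarray(vec)


def _layout_names(vary: tuple, conds: list) -> list:
    names = []
    for name, free in zip(("v", "a", "t0"), vary):
        if free:
            names += [(name, c) for c in conds]
        else:
            names.append((name, None))
    return names


def fit_model_family(
    trials: pd.DataFrame,
    family: list | None = None,
    seed=None,
    n_restarts: int = 3,
) -> pd.DataFrame:
    """Fit all models to every participant and sum the criteria.

    ``trials`` holds two conditions per participant.  Per participant and
    model: joint ML fit under the sharing constraint, AIC = 2k - 2LL and
    BIC = k ln(n) - 2LL with n the participant's pooled trial count.  A
    participant whose fit fails to converge under any model is excluded from
    all models' sums (keeping them balanced) and counted in
    ``result.attrs['n_excluded']``.  Returns the group table (one row per
    model) with summed LL/AIC/BIC, Akaike weights, and winner flags; the
    per-participant criterion table is in ``result.attrs['per_participant']``.
    """
    family = family or enumerate_model_family()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conds = sorted(trials["condition"].unique())
    if len(conds) != 2:
        raise ValueError(f"model family requires exactly 2 conditions, got {conds}")

    full = ModelSpec(True, True, True)
    shared = ModelSpec(False, False, False)
    records = []
    for pid, sub in trials.groupby("participant", sort=True):
        n_tr = len(sub)
        fits = {}
        # anchor fits: fully free (separable) and fully shared
        fits[full.vary] = fit_ddm_ml(sub, full.vary, n_restarts=n_restarts, seed=rng)
        emb_full = fits[full.vary].params
        fits[shared.vary] = fit_ddm_ml(
            sub, shared.vary, n_restarts=1, seed=rng,
            extra_starts=[_embed_start(emb_full, _layout_names(shared.vary, conds), conds)],
        )
        emb_shared = fits[shared.vary].params
        for spec in family:
            if spec.vary in fits:
                continue
            names = _layout_names(spec.vary, conds)
            extra = [
                _embed_start(emb_full, names, conds),
                _embed_start(emb_shared, names, conds),
            ]
            fits[spec.vary] = fit_ddm_ml(
                sub, spec.vary, n_restarts=1, seed=rng, extra_starts=extra
            )
        # nesting repair: a super-model may never score below a nested model
        by_freedom = sorted(family, key=lambda s: sum(s.vary))
        for hi in by_freedom:
            for lo in by_freedom:
                if lo.vary != hi.vary and lo.nests_in(hi):
                    if fits[lo.vary].loglik > fits[hi.vary].loglik:
                        repaired = fits[lo.vary]
                        fits[hi.vary] = type(repaired)(
                            params=dict(repaired.params),
                            loglik=repaired.loglik,
                            n_free_params=hi.n_free_params,
                            converged=repaired.converged,
                            n_restarts_used=fits[hi.vary].n_restarts_used,
                        )
        for spec in family:
            fr = fits[spec.vary]
            k = spec.n_free_params
            records.append(
                {
                    "participant": pid,
                    "model": spec.name,
                    "vary_v": spec.vary_v,
                    "vary_a": spec.vary_a,
                    "vary_t0": spec.vary_t0,
                    "k": k,
                    "n_trials": n_tr,
                    "LL": fr.loglik,
                    "AIC": 2.0 * k - 2.0 * fr.loglik,
                    "BIC": k * math.log(n_tr) - 2.0 * fr.loglik,
                    "converged": fr.converged,
                }
            )

    per = pd.DataFrame.from_records(records)
    bad = per.loc[~per["converged"], "participant"].unique()
    if len(bad):
        warnings.warn(f"excluding {len(bad)} participant(s) with unconverged fits")
    kept = per[~per["participant"].isin(bad)]

    group = (
        kept.groupby(["model", "vary_v", "vary_a", "vary_t0", "k"], sort=False)[
            ["LL", "AIC", "BIC"]
        ]
        .sum()
        .reset_index()
    )
    group["W_AIC"] = akaike_weights(group["AIC"].to_numpy())
    group["W_BIC"] = akaike_weights(group["BIC"].to_numpy())
    group["winner_AIC"] = group["AIC"] == group["AIC"].min()
    group["winner_BIC"] = group["BIC"] == group["BIC"].min()
    group.attrs["per_participant"] = per
    group.attrs["n_excluded"] = len(bad)
    group.attrs["n_participants"] = kept["participant"].nunique()
    return group
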