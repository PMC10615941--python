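"""End-to-end simulation studies: generate -> simulate -> fit -> correlate.

Each study draws a parameter population, simulates two-choice trials per
participant and condition, re-estimates the parameters per participant, and
reports the correlation matrix over condition estimates and hard-minus-easy
difference scores.  Studies:

``sim1``
    No true parameter differences (uniform population, hard == easy);
    fitter ``ml`` (Nelder-Mead maximum likelihood) or ``ez`` (closed form).
``sim2`` / ``sim2_all``
    One parameter (or all three) truly differs across conditions, drawn as a
    correlated bivariate-normal pair at a small/medium/large effect size.
``sim3_equiv``
    Alias of sim1/ML: the cross-implementation replication consists of this
    package being an independent implementation of the same design.
``sim4_lba``
    The LBA analogue of sim1 (response caution b - A/2 plays the role of a).
``sim5``
    Truly correlated (a, t0) difference scores with zero mean differences.
``constrained_v``
    sim1 data fitted with drift shared across conditions (5-parameter model).
``competition``
    sim1 data submitted to the 8-model sharing-pattern competition.

The study defaults mirror the full-scale design (1000 participants x 1000
trials per condition); tests and the acceptance script run reduced sizes
through the same code path.  All randomness flows from the single config
seed; rerunning an identical config byte-reproduces every table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis as _analysis
from . import params as _params
from .competition import fit_model_family
from .ddm import DDMParams, ez_fit_trials, fit_ddm_ml, simulate_ddm_trials
from .lba import LBAParams, fit_lba_ml, simulate_lba_trials

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "run_constrained_v_study",
    "simulate_population_trials",
    "fit_population",
    "load_trial_table",
]

logger = logging.getLogger("diffscore")

STUDIES = (
    "sim1",
    "sim2",
    "sim2_all",
    "sim3_equiv",
    "sim4_lba",
    "sim5",
    "competition",
    "constrained_v",
)


@dataclass
class StudyConfig:
    study: str = "sim1"
    n_participants: int = 1000
    n_trials: int = 1000
    fitter: str = "ml"
    manipulated: str = "v"
    effect_size: str = "small"
    rho_diff: float = -0.7
    seed: int = 1
    out_dir: str | Path | None = None
    save_trials: bool = False

    def __post_init__(self) -> None:
        if self.study not in STUDIES:
            raise ValueError(f"unknown study {self.study!r}; choose from {STUDIES}")
        if self.n_participants <= 0 or self.n_trials <= 0:
            raise ValueError("participant and trial counts must be positive")
        if self.fitter not in ("ml", "ez"):
            raise ValueError(f"fitter must be 'ml' or 'ez', got {self.fitter!r}")

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in dataclasses.asdict(self).items() if k != "out_dir"},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    config: StudyConfig
    generating: pd.DataFrame
    fitted: pd.DataFrame | None = None
    diffs: pd.DataFrame | None = None
    corr: pd.DataFrame | None = None
    model_table: pd.DataFrame | None = None
    trials: pd.DataFrame | None = None
    n_unconverged: int = 0
    paths: dict = dataclasses.field(default_factory=dict)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def _generate(config: StudyConfig) -> pd.DataFrame:
    n, seed = config.n_participants, config.seed
    if config.study in ("sim1", "sim3_equiv", "constrained_v", "competition"):
        return _params.sample_uniform_population(n, seed=seed)
    if config.study == "sim2":
        return _params.sample_manipulated_population(
            n, manipulated=config.manipulated, effect_size=config.effect_size, seed=seed
        )
    if config.study == "sim2_all":
        return _params.sample_manipulated_population(
            n, effect_size=config.effect_size, all_three=True, seed=seed
        )
    if config.study == "sim4_lba":
        return _params.sample_lba_population(n, seed=seed)
    if config.study == "sim5":
        return _params.sample_diffcorr_population(
            n, diff=_params.DiffCorrSpec(rho_diff=config.rho_diff), seed=seed
        )
    raise AssertionError(config.study)


def simulate_population_trials(
    population: pd.DataFrame, n_trials: int, seed: int, model: str = "ddm"
) -> pd.DataFrame:
    """Simulate ``n_trials`` per population row (participant x condition)."""
    frames = []
    for _, row in population.iterrows():
        ci = 0 if row["condition"] == "easy" else 1
        rng = np.random.default_rng([int(seed), 1, int(row["participant"]), ci])
        if model == "ddm":
            p = DDMParams(v=row["v"], a=row["a"], t0=row["t0"])
            tr = simulate_ddm_trials(p, n_trials, seed=rng)
        elif model == "lba":
            p = LBAParams(v=row["v"], A=row["A"], b=row["b"], t0=row["t0"])
            tr = simulate_lba_trials(p, n_trials, seed=rng)
        else:
            raise ValueError(f"unknown model {model!r}")
        tr.insert(0, "participant", row["participant"])
        tr.insert(1, "condition", row["condition"])
        frames.append(tr)
    return pd.concat(frames, ignore_index=True)


def fit_population(
    trials: pd.DataFrame,
    fitter: str = "ml",
    model: str = "ddm",
    seed: int = 0,
    constraint: tuple | None = None,
) -> pd.DataFrame:
    """Fit every participant; returns a long fitted-parameter table."""
    rows = []
    for pid, sub in trials.groupby("participant", sort=True):
        rng = np.random.default_rng([int(seed), 2, int(pid)])
        if model == "lba":
            fit = fit_lba_ml(sub, seed=rng)
            for cond, p in fit.params.items():
                rows.append(
                    {
                        "participant": pid,
                        "condition": cond,
                        "v": p.v,
                        "A": p.A,
                        "b": p.b,
                        "t0": p.t0,
                        "caution": p.caution,
                        "loglik": fit.loglik,
                        "converged": fit.converged,
                    }
                )
            continue
        if fitter == "ez":
            for cond, csub in sub.groupby("condition", sort=True):
                p = ez_fit_trials(csub)
                rows.append(
                    {
                        "participant": pid,
                        "condition": cond,
                        "v": p.v,
                        "a": p.a,
                        "t0": p.t0,
                        "converged": True,
                    }
                )
            continue
        fit = fit_ddm_ml(sub, constraint=constraint, seed=rng)
        for cond, p in fit.params.items():
            rows.append(
                {
                    "participant": pid,
                    "condition": cond,
                    "v": p.v,
                    "a": p.a,
                    "t0": p.t0,
                    "loglik": fit.loglik,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def load_trial_table(path) -> pd.DataFrame:
    """Load an externally supplied trial CSV (participant, condition, rt,
    response), e.g. for applying the pipeline to real data."""
    df = pd.read_csv(path, comment="#")
    missing = {"participant", "condition", "rt", "response"} - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing column(s) {sorted(missing)}")
    if (df["rt"] <= 0).any():
        raise ValueError("all response times must be positive (seconds)")
    return df


# ---------------------------------------------------------------------------
# Study drivers
# ---------------------------------------------------------------------------

def run_study(config: StudyConfig) -> StudyReport:
    """Execute one study end to end; write tables/figures if out_dir is set."""
    if config.study == "constrained_v":
        return run_constrained_v_study(config)

    t_start = time.perf_counter()
    model = "lba" if config.study == "sim4_lba" else "ddm"
    pop = _generate(config)
    logger.info("%s: generated %d participants", config.study, config.n_participants)

    trials = simulate_population_trials(pop, config.n_trials, config.seed, model=model)
    logger.info("%s: simulated %d trials (%.1fs)", config.study, len(trials),
                time.perf_counter() - t_start)

    report = StudyReport(config=config, generating=pop, trials=trials if config.save_trials else None)

    if config.study == "competition":
        t_fit = time.perf_counter()
        report.model_table = fit_model_family(trials, seed=config.seed)
        logger.info("%s: model family fitted (%.1fs)", config.study, time.perf_counter() - t_fit)
    else:
        t_fit = time.perf_counter()
        fitted = fit_population(trials, fitter=config.fitter, model=model, seed=config.seed)
        report.fitted = fitted
        report.n_unconverged = int(
            fitted.loc[~fitted["converged"].astype(bool), "participant"].nunique()
        )
        logger.info(
            "%s: fitted %d participants, %d unconverged (%.1fs)",
            config.study, config.n_participants, report.n_unconverged,
            time.perf_counter() - t_fit,
        )
        order = ("caution", "v", "t0") if model == "lba" else ("a", "v", "t0")
        cols = ["participant", "condition", *order, "converged"]
        report.diffs = _analysis.compute_diff_scores(fitted[cols])
        report.corr = _analysis.correlation_matrix(fitted[cols], order=order)

    _write_outputs(report)
    logger.info("%s: done in %.1fs", config.study, time.perf_counter() - t_start)
    return report


def run_constrained_v_study(config: StudyConfig) -> StudyReport:
    """sim1-style data fitted with drift shared across conditions.

    The 5-parameter model (v, a_easy, a_hard, t0_easy, t0_hard) is fitted on
    the pooled likelihood; the report's correlation matrix covers the seven
    columns a (easy/hard), v, t0 (easy/hard), a diff, t0 diff.
    """
    t_start = time.perf_counter()
    pop = _params.sample_uniform_population(config.n_participants, seed=config.seed)
    trials = simulate_population_trials(pop, config.n_trials, config.seed)
    fitted = fit_population(trials, seed=config.seed, constraint=(False, True, True))
    report = StudyReport(config=config, generating=pop, fitted=fitted,
                         trials=trials if config.save_trials else None)
    report.n_unconverged = int(
        fitted.loc[~fitted["converged"].astype(bool), "participant"].nunique()
    )

    wide = _analysis.to_wide(fitted[["participant", "condition", "v", "a", "t0", "converged"]])
    mat = pd.DataFrame(
        {
            "a (easy)": wide["a_easy"],
            "a (hard)": wide["a_hard"],
            "v": wide["v_easy"],  # shared: easy column == hard column
            "t0 (easy)": wide["t0_easy"],
            "t0 (hard)": wide["t0_hard"],
            "a diff": wide["a_hard"] - wide["a_easy"],
            "t0 diff": wide["t0_hard"] - wide["t0_easy"],
        }
    )
    report.diffs = mat[["a diff", "t0 diff"]].copy()
    corr = mat.corr(method="pearson")
    corr.attrs["n"] = len(mat)
    report.corr = corr

    _write_outputs(report)
    logger.info("constrained_v: done in %.1fs", time.perf_counter() - t_start)
    return report


def _write_outputs(report: StudyReport) -> None:
    config = report.config
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"study={config.study} seed={config.seed} config_hash={config.config_hash()}"
    prefix = config.study

    def save(df, name, index=False):
        path = out / f"{prefix}_{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# {stamp}\n")
            df.to_csv(fh, index=index)
        report.paths[name] = path

    save(report.generating, "generating_parameters")
    if report.fitted is not None:
        save(report.fitted, "fitted_parameters")
    if report.diffs is not None:
        save(report.diffs.reset_index(), "diff_scores")
    if report.corr is not None:
        save(report.corr, "correlation_matrix", index=True)
        fig_path = out / f"{prefix}_correlation_heatmap.png"
        _analysis.plot_correlation_heatmap(
            report.corr, fig_path, title=f"{config.study} (seed {config.seed})"
        )
        report.paths["heatmap"] = fig_path
    if report.model_table is not None:
        save(report.model_table, "model_ic")
        save(report.model_table.attrs["per_participant"], "model_ic_per_participant")
    if report.trials is not None:
        save(report.trials, "trials")

    meta = {
        "study": config.study,
        "seed": config.seed,
        "config": {k: str(v) for k, v in dataclasses.asdict(config).items()},
        "config_hash": config.config_hash(),
        "n_unconverged": report.n_unconverged,
    }
    meta_path = out / f"{prefix}_run_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    report.paths["meta"] = meta_path
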