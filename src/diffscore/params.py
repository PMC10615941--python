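"""Per-participant parameter populations for the simulation studies.

Every study draws a population of participants, each with a (v, a, t0)
triple per condition (or, for the LBA, a (v, A, b, t0) quadruple).  Three
designs are covered:

* **no-difference** populations: parameters drawn from uniform ranges for
  the easy condition and copied bit-identically to the hard condition;
* **manipulated** populations: exactly one parameter (or all three) drawn as
  a correlated bivariate-normal pair across conditions (rho = 0.5) with
  condition-specific means/SDs, the rest copied from uniform draws;
* **correlated-difference** populations: hard-condition a and t0 equal the
  easy values plus a zero-mean bivariate-normal difference with a chosen
  correlation between the two difference scores.

Tables are long-format DataFrames with one row per participant x condition
(`participant, condition, v, a, t0`), conditions labelled ``easy``/``hard``.
A single study seed expands into per-participant child seeds, so growing the
population extends it without reshuffling earlier participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SIM1_RANGES",
    "LBA_RANGES",
    "MANIPULATED_NORMALS",
    "RHO_CONDITIONS",
    "DiffCorrSpec",
    "sample_uniform_population",
    "sample_manipulated_population",
    "sample_diffcorr_population",
    "sample_lba_population",
]

#: Uniform generating ranges of the no-difference DDM population.
SIM1_RANGES: dict = {"v": (0.0, 4.0), "a": (0.5, 2.0), "t0": (0.2, 0.5)}

#: Uniform generating ranges of the no-difference LBA population
#: (b is drawn after A, uniformly on [A + 0.001, 2.0]).
LBA_RANGES: dict = {"v": (1.0, 4.0), "A": (0.5, 2.0), "b_hi": 2.0, "t0": (0.2, 0.5)}

#: Bivariate-normal (mu_easy, sd_easy, mu_hard, sd_hard) per manipulated
#: parameter and effect-size label (Cohen's d 0.3 / 0.5 / 0.8).
MANIPULATED_NORMALS: dict = {
    ("v", "small"): (2.3, 1.0, 2.0, 1.0),
    ("v", "medium"): (2.5, 1.0, 2.0, 1.0),
    ("v", "large"): (2.8, 1.0, 2.0, 1.0),
    ("a", "small"): (1.25, 0.4, 1.37, 0.4),
    ("a", "medium"): (1.25, 0.4, 1.45, 0.4),
    ("a", "large"): (1.25, 0.4, 1.57, 0.4),
    ("t0", "small"): (0.350, 0.1, 0.385, 0.1),
    ("t0", "medium"): (0.350, 0.1, 0.400, 0.1),
    ("t0", "large"): (0.350, 0.1, 0.430, 0.1),
}

#: Between-condition correlation of a manipulated parameter pair.
RHO_CONDITIONS: float = 0.5

#: Cap on rejection-resampling attempts when enforcing positivity.
_MAX_ATTEMPTS = 1000


@dataclass(frozen=True)
class DiffCorrSpec:
    """Correlated-difference-score design: zero-mean bivariate-normal
    (a_diff, t0_diff) with the stated SDs and correlation."""

    sd_a_diff: float = 0.1
    sd_t0_diff: float = 0.05
    rho_diff: float = -0.7

    def __post_init__(self) -> None:
        if not (self.sd_a_diff > 0 and self.sd_t0_diff > 0):
            raise ValueError("difference-score SDs must be positive")
        if not (-1.0 <= self.rho_diff <= 1.0):
            raise ValueError(f"rho_diff must lie in [-1, 1], got {self.rho_diff}")


def _child_rngs(seed, n: int):
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def _check_ranges(ranges: dict) -> None:
    for name, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ValueError(f"invalid uniform range for {name!r}: [{lo}, {hi}]")


def _long_table(rows: list) -> pd.DataFrame:
    cols = ["participant", "condition"] + [
        k for k in (rows[0].keys() if rows else []) if k not in ("participant", "condition")
    ]
    return pd.DataFrame(rows, columns=cols or ["participant", "condition", "v", "a", "t0"])


def sample_uniform_population(
    n_participants: int, ranges: dict | None = None, seed=None
) -> pd.DataFrame:
    """No-difference population: uniform easy-condition draws, hard == easy.

    Each participant's (v, a, t0) is drawn once from the uniform ranges and
    used verbatim in both conditions, so every true difference score is zero.
    """
    if n_participants < 0:
        raise ValueError("n_participants must be non-negative")
    ranges = dict(SIM1_RANGES if ranges is None else ranges)
    _check_ranges(ranges)
    rows = []
    for pid, rng in enumerate(_child_rngs(seed, n_participants)):
        draw = {k: rng.uniform(lo, hi) for k, (lo, hi) in ranges.items()}
        rows.append({"participant": pid, "condition": "easy", **draw})
        rows.append({"participant": pid, "condition": "hard", **draw})
    return _long_table(rows) if rows else pd.DataFrame(
        columns=["participant", "condition", *ranges.keys()]
    )


def _bivariate_pair(rng, mu_e, sd_e, mu_h, sd_h, rho):
    """One (easy, hard) pair, rejection-resampled until both are positive."""
    mean = np.array([mu_e, mu_h])
    cov = np.array(
        [[sd_e**2, rho * sd_e * sd_h], [rho * sd_e * sd_h, sd_h**2]]
    )
    chol = np.linalg.cholesky(cov)
    for _ in range(_MAX_ATTEMPTS):
        pair = mean + chol @ rng.standard_normal(2)
        if pair[0] > 0 and pair[1] > 0:
            return float(pair[0]), float(pair[1])
    raise RuntimeError(
        "could not draw a positive bivariate-normal pair in "
        f"{_MAX_ATTEMPTS} attempts (mu={mean}, sd=({sd_e}, {sd_h}))"
    )


def sample_manipulated_population(
    n_participants: int,
    manipulated: str = "v",
    effect_size: str = "small",
    all_three: bool = False,
    rho: float = RHO_CONDITIONS,
    seed=None,
) -> pd.DataFrame:
    """Population in which one (or all three) parameters truly differ.

    The manipulated parameter is drawn per participant as a correlated
    bivariate-normal (easy, hard) pair with the design's condition means and
    SDs; whole draws with any non-positive component are rejected and
    redrawn, preserving the correlation structure.  Non-manipulated
    parameters are uniform easy-condition draws copied to the hard condition.
    With ``all_three=True`` every parameter is drawn as its own independent
    correlated pair at the given effect size.
    """
    if n_participants < 0:
        raise ValueError("n_participants must be non-negative")
    names = ("v", "a", "t0")
    if all_three:
        targets = names
    else:
        if manipulated not in names:
            raise ValueError(f"manipulated must be one of {names}, got {manipulated!r}")
        targets = (manipulated,)
    for t in targets:
        if (t, effect_size) not in MANIPULATED_NORMALS:
            raise ValueError(f"no sampling design for ({t!r}, {effect_size!r})")

    rows = []
    for pid, rng in enumerate(_child_rngs(seed, n_participants)):
        easy, hard = {}, {}
        for name in names:
            if name in targets:
                mu_e, sd_e, mu_h, sd_h = MANIPULATED_NORMALS[(name, effect_size)]
                easy[name], hard[name] = _bivariate_pair(rng, mu_e, sd_e, mu_h, sd_h, rho)
            else:
                lo, hi = SIM1_RANGES[name]
                easy[name] = hard[name] = rng.uniform(lo, hi)
        rows.append({"participant": pid, "condition": "easy", **easy})
        rows.append({"participant": pid, "condition": "hard", **hard})
    return _long_table(rows) if rows else pd.DataFrame(
        columns=["participant", "condition", *names]
    )


def sample_diffcorr_population(
    n_participants: int,
    diff: DiffCorrSpec | None = None,
    ranges: dict | None = None,
    seed=None,
) -> pd.DataFrame:
    """Population with truly correlated (a, t0) difference scores.

    Easy-condition parameters are uniform (no-difference design); the hard
    condition adds a zero-mean bivariate-normal (a_diff, t0_diff) draw with
    the design's SDs and correlation.  Drift is identical across conditions.
    Difference draws that would make a_hard <= 0 or t0_hard < 0 are redrawn
    as whole pairs (capped), keeping the correlation structure intact.
    """
    if n_participants < 0:
        raise ValueError("n_participants must be non-negative")
    diff = diff or DiffCorrSpec()
    ranges = dict(SIM1_RANGES if ranges is None else ranges)
    _check_ranges(ranges)
    cov = np.array(
        [
            [diff.sd_a_diff**2, diff.rho_diff * diff.sd_a_diff * diff.sd_t0_diff],
            [diff.rho_diff * diff.sd_a_diff * diff.sd_t0_diff, diff.sd_t0_diff**2],
        ]
    )
    chol = np.linalg.cholesky(cov + 1e-18 * np.eye(2))
    rows = []
    for pid, rng in enumerate(_child_rngs(seed, n_participants)):
        easy = {k: rng.uniform(lo, hi) for k, (lo, hi) in ranges.items()}
        for attempt in range(_MAX_ATTEMPTS):
            a_d, t0_d = chol @ rng.standard_normal(2)
            if easy["a"] + a_d > 0 and easy["t0"] + t0_d >= 0:
                break
        else:
            raise RuntimeError(
                f"participant {pid}: could not draw admissible difference scores "
                f"in {_MAX_ATTEMPTS} attempts"
            )
        hard = {"v": easy["v"], "a": easy["a"] + a_d, "t0": easy["t0"] + t0_d}
        rows.append({"participant": pid, "condition": "easy", **easy})
        rows.append({"participant": pid, "condition": "hard", **hard})
    return _long_table(rows) if rows else pd.DataFrame(
        columns=["participant", "condition", "v", "a", "t0"]
    )


def sample_lba_population(
    n_participants: int, ranges: dict | None = None, seed=None
) -> pd.DataFrame:
    """No-difference LBA population (columns v, A, b, t0; hard == easy).

    A is drawn first, then the threshold b uniformly on [A + 0.001, b_hi],
    guaranteeing b > A for every participant.
    """
    if n_participants < 0:
        raise ValueError("n_participants must be non-negative")
    r = dict(LBA_RANGES if ranges is None else ranges)
    rows = []
    for pid, rng in enumerate(_child_rngs(seed, n_participants)):
        v = rng.uniform(*r["v"])
        # the top sliver of the A range leaves no room for b; redraw there
        A = rng.uniform(*r["A"])
        while A + 0.001 >= r["b_hi"]:
            A = rng.uniform(*r["A"])
        b = rng.uniform(A + 0.001, r["b_hi"])
        t0 = rng.uniform(*r["t0"])
        draw = {"v": v, "A": A, "b": b, "t0": t0}
        rows.append({"participant": pid, "condition": "easy", **draw})
        rows.append({"participant": pid, "condition": "hard", **draw})
    return _long_table(rows) if rows else pd.DataFrame(
        columns=["participant", "condition", "v", "A", "b", "t0"]
    )
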