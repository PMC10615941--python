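"""Difference scores, correlation matrices, and outlier-robust correlations.

The statistical readout of every study is the 9 x 9 product-moment
correlation matrix over the fitted parameters {a, v, t0} (or {caution, v,
t0} for the LBA) in the easy condition, the hard condition, and their
hard-minus-easy difference scores.  Correlation coefficients are interpreted
as effect sizes: |r| = 0.1 small, 0.3 medium, 0.5 large.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "EFFECT_SIZE_THRESHOLDS",
    "to_wide",
    "compute_diff_scores",
    "correlation_matrix",
    "outlier_filtered_correlation",
    "plot_correlation_heatmap",
]

EFFECT_SIZE_THRESHOLDS = {"small": 0.1, "medium": 0.3, "large": 0.5}


#: bookkeeping columns that are never treated as model parameters
_META_COLS = ("participant", "condition", "converged", "loglik")


def _param_cols(table: pd.DataFrame) -> list:
    return [c for c in table.columns if c not in _META_COLS]


def to_wide(fitted: pd.DataFrame, require_converged: bool = True) -> pd.DataFrame:
    """Pivot a long fitted table to one row per participant.

    Participants missing either condition — or flagged unconverged in either
    condition when a ``converged`` column is present — are dropped listwise.
    """
    params = _param_cols(fitted)
    conds = sorted(fitted["condition"].unique())
    keep = fitted
    if require_converged and "converged" in fitted.columns:
        bad = fitted.loc[~fitted["converged"].astype(bool), "participant"].unique()
        keep = fitted[~fitted["participant"].isin(bad)]
    wide = keep.pivot_table(
        index="participant", columns="condition", values=params, sort=True
    )
    wide.columns = [f"{p}_{c}" for p, c in wide.columns]
    wide = wide.dropna(axis=0, subset=[f"{p}_{c}" for p in params for c in conds])
    n_dropped = fitted["participant"].nunique() - len(wide)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} participant(s) with missing or unconverged fits")
    return wide


def compute_diff_scores(fitted: pd.DataFrame, require_converged: bool = True) -> pd.DataFrame:
    """Hard-minus-easy difference per parameter, one row per participant."""
    params = _param_cols(fitted)
    wide = to_wide(fitted, require_converged=require_converged)
    out = pd.DataFrame(index=wide.index)
    for p in params:
        out[f"{p}_diff"] = wide[f"{p}_hard"] - wide[f"{p}_easy"]
    return out


def correlation_matrix(
    fitted: pd.DataFrame,
    order: tuple = ("a", "v", "t0"),
    require_converged: bool = True,
) -> pd.DataFrame:
    """9 x 9 Pearson correlation matrix over condition values and diffs.

    Rows/columns follow the conventional layout: a (easy), a (hard),
    v (easy), v (hard), t0 (easy), t0 (hard), a diff, v diff, t0 diff (with
    ``a`` replaced by ``caution`` for LBA fits).  Zero-variance columns yield
    missing (not zero) correlations, with a warning.
    """
    wide = to_wide(fitted, require_converged=require_converged)
    if len(wide) < 3:
        raise ValueError(f"need at least 3 participants, got {len(wide)}")
    diffs = compute_diff_scores(fitted, require_converged=require_converged)
    cols, labels = [], []
    for p in order:
        for c in ("easy", "hard"):
            cols.append(wide[f"{p}_{c}"])
            labels.append(f"{p} ({c})")
    for p in order:
        cols.append(diffs[f"{p}_diff"])
        labels.append(f"{p} diff")
    mat = pd.concat(cols, axis=1)
    mat.columns = labels
    zero_var = [l for l in labels if np.isclose(mat[l].std(ddof=1), 0.0)]
    if zero_var:
        warnings.warn(f"zero-variance column(s) {zero_var}: correlations undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = mat.corr(method="pearson")
    for l in zero_var:
        corr.loc[l, :] = np.nan
        corr.loc[:, l] = np.nan
        corr.loc[l, l] = np.nan
    corr.attrs["n"] = len(mat)
    corr.attrs["effect_size_thresholds"] = dict(EFFECT_SIZE_THRESHOLDS)
    return corr


def outlier_filtered_correlation(x, y, z_threshold: float = 2.5):
    """Pearson correlation after removing |z| > threshold cases.

    Both variables are standardized within the pair; any case exceeding the
    threshold on either variable is excluded before recomputing the
    correlation.  Returns (r, n_removed, n_used).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 cases")
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    keep = (np.abs(zx) <= z_threshold) & (np.abs(zy) <= z_threshold)
    n_removed = int((~keep).sum())
    if keep.sum() < 3:
        raise ValueError("outlier filtering removed too many cases to correlate")
    r = float(np.corrcoef(x[keep], y[keep])[0, 1])
    return r, n_removed, int(keep.sum())


def plot_correlation_heatmap(corr: pd.DataFrame, path=None, title: str | None = None):
    """Heatmap of a correlation matrix with the difference-score block outlined.

    The bottom-right 3 x 3 block (the pairwise correlations among the three
    difference scores) is framed in grey.  Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = corr.shape[0]
    fig, ax = plt.subplots(figsize=(7.5, 6.5))
    im = ax.imshow(corr.to_numpy(), vmin=-1.0, vmax=1.0, cmap="RdBu_r")
    ax.set_xticks(range(n), corr.columns, rotation=45, ha="right")
    ax.set_yticks(range(n), corr.index)
    for i in range(n):
        for j in range(n):
            val = corr.iat[i, j]
            if i != j and np.isfinite(val):
                ax.text(j, i, f"{val:.2f}", ha="center", va="center", fontsize=7)
    n_diff = sum(1 for c in corr.columns if str(c).endswith("diff"))
    if n_diff:
        k = n - n_diff
        rect = plt.Rectangle(
            (k - 0.5, k - 0.5), n_diff, n_diff,
            fill=False, edgecolor="grey", linewidth=2.5,
        )
        ax.add_patch(rect)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Pearson r")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
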