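"""Per-subject linear models linking behaviour to observer variables.

Three ordinary-least-squares models are fitted per subject:

* action — response alpha_t * |delta_t| (the bucket update projected onto
  the error direction) on |delta_t|, CPP*|delta_t|, RU*|delta_t| and
  hit*|delta_t|;
* confidence — response z-scored confidence on the previous trial's
  |delta|, CPP, RU and hit (confidence reflects the immediately preceding
  outcome);
* coupling — absolute action update on absolute confidence update; the
  slope is the action-confidence association strength.

Betas are compared between groups with assumption-routed two-sample tests,
and model fit is summarised by the median R-squared per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .task import circ_diff
from .groupstats import route_two_sample_test, TestResult

__all__ = [
    "RegressionResult",
    "fit_action_model",
    "fit_confidence_model",
    "fit_coupling_model",
    "fit_all_subjects",
    "compare_betas",
    "median_r_squared",
]

MODELS = ("action", "confidence", "coupling")


@dataclass
class RegressionResult:
    """Per-subject OLS fit: betas by predictor name, R^2, trials used."""

    subject_id: str
    model: str
    betas: dict = field(default_factory=dict)
    r_squared: float = np.nan
    n_trials_used: int = 0

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id, "model": self.model,
               "r_squared": self.r_squared, "n_trials_used": self.n_trials_used}
        row.update({f"beta_{k}": v for k, v in self.betas.items()})
        return row


def _ols(subject_id: str, model: str, y: np.ndarray, X: pd.DataFrame) -> RegressionResult:
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # name the offending columns for the caller
        keep: list[str] = []
        collinear = []
        for col in design.columns:
            trial_cols = keep + [col]
            if np.linalg.matrix_rank(design[trial_cols].to_numpy()) == len(trial_cols):
                keep.append(col)
            else:
                collinear.append(col)
        raise ValueError(f"rank-deficient design for {subject_id}/{model}: "
                         f"collinear columns {collinear}")
    fit = sm.OLS(y, design).fit()
    betas = {name: float(fit.params[name]) for name in X.columns}
    betas["intercept"] = float(fit.params["const"])
    return RegressionResult(subject_id=subject_id, model=model, betas=betas,
                            r_squared=float(fit.rsquared), n_trials_used=int(len(y)))


def fit_action_model(derived_one: pd.DataFrame, subject_id: str = "",
                     subset_mask=None) -> RegressionResult:
    """Action model: alpha*|delta| ~ |delta| + CPP*|delta| + RU*|delta| + hit*|delta|.

    Block-final and zero-PE trials are dropped (alpha undefined there);
    percentile-excluded trials are dropped as in the learning-rate analysis.
    Hit is coded 1, miss 0.  ``subset_mask`` (aligned to ``derived_one``)
    optionally restricts the fit, e.g. to the small-PE tertile.
    """
    keep = ~derived_one["excluded"]
    if subset_mask is not None:
        keep &= np.asarray(subset_mask, bool)
    d = derived_one.loc[keep]
    y = (d["alpha"] * d["abs_delta"]).to_numpy()
    absd = d["abs_delta"].to_numpy()
    hit = d["hit"].to_numpy(float)
    X = pd.DataFrame(
        {
            "abs_delta": absd,
            "cpp_x_abs_delta": d["cpp"].to_numpy() * absd,
            "ru_x_abs_delta": d["relative_uncertainty"].to_numpy() * absd,
            "hit_x_abs_delta": hit * absd,
        }
    )
    if np.ptp(hit) == 0:  # single observed hit level: unidentifiable
        X = X.drop(columns="hit_x_abs_delta")
    return _ols(subject_id or _sid(derived_one), "action", y, X)


def fit_confidence_model(derived_one: pd.DataFrame, subject_id: str = "",
                         subset_mask=None) -> RegressionResult:
    """Confidence model: z-confidence_t ~ |delta|, CPP, RU, hit at t-1.

    Confidence is not scaled by |delta|.  Block-first trials are dropped
    (no previous trial); an optional ``subset_mask`` over the *previous*
    trial restricts the fit (small-PE refit).
    """
    d = derived_one.sort_values(["block", "trial"], kind="stable")
    grp = d.groupby("block", sort=False)
    prev = pd.DataFrame(
        {
            "abs_delta_prev": grp["abs_delta"].shift(1),
            "cpp_prev": grp["cpp"].shift(1),
            "ru_prev": grp["relative_uncertainty"].shift(1),
            "hit_prev": grp["hit"].shift(1).astype(float),
        }
    )
    usable = prev.notna().all(axis=1)
    if subset_mask is not None:
        mask = pd.Series(np.asarray(subset_mask, bool), index=derived_one.index).reindex(d.index)
        usable &= grp_shift_bool(d, mask)
    y = d.loc[usable, "z_confidence"].to_numpy()
    X = prev.loc[usable]
    if np.ptp(X["hit_prev"].to_numpy()) == 0:  # single observed hit level
        X = X.drop(columns="hit_prev")
    return _ols(subject_id or _sid(derived_one), "confidence", y, X)


def fit_coupling_model(derived_one: pd.DataFrame, subject_id: str = "",
                       circular: bool = True) -> RegressionResult:
    """Coupling model: |action update| ~ |confidence update| (one predictor).

    The action update is the circular distance between consecutive bucket
    placements within a block; the confidence update is the absolute change
    in z-scored confidence.  The slope is the association strength.
    """
    d = derived_one.sort_values(["block", "trial"], kind="stable")
    rows_y = []
    rows_x = []
    diff = circ_diff if circular else (lambda a, b: np.asarray(a, float) - np.asarray(b, float))
    for _, block_df in d.groupby("block", sort=False):
        b = block_df["bucket"].to_numpy()
        z = block_df["z_confidence"].to_numpy()
        if len(b) < 2:
            continue
        rows_y.append(np.abs(diff(b[1:], b[:-1])))
        rows_x.append(np.abs(np.diff(z)))
    y = np.concatenate(rows_y)
    x = np.concatenate(rows_x)
    if y.size < 3:
        raise ValueError("need at least 3 usable trials for the coupling model")
    if np.ptp(x) == 0:
        raise ValueError("confidence update has zero variance; coupling slope undefined")
    return _ols(subject_id or _sid(derived_one), "coupling", y,
                pd.DataFrame({"abs_conf_update": x}))


def grp_shift_bool(d: pd.DataFrame, mask: pd.Series) -> pd.Series:
    """Shift a boolean series forward one trial within each block."""
    m = mask.to_numpy(dtype=bool)
    blocks = d["block"].to_numpy()
    prev = np.zeros_like(m)
    prev[1:] = m[:-1] & (blocks[1:] == blocks[:-1])
    return pd.Series(prev, index=d.index)


def _sid(df: pd.DataFrame) -> str:
    if "subject_id" in df.columns and len(df):
        return str(df["subject_id"].iloc[0])
    return ""


def fit_all_subjects(derived: pd.DataFrame, small_pe_only: bool = False) -> pd.DataFrame:
    """Fit all three models for every subject; returns a long results table.

    ``small_pe_only`` refits the action and confidence models on the small
    PE-magnitude tertile only (the coupling model is unchanged: consecutive
    confidence differences do not subset cleanly).
    """
    rows = []
    for sid, sub in derived.groupby("subject_id", sort=False):
        mask = sub["pe_bin"].eq("small").fillna(False).astype(bool) if small_pe_only else None
        try:
            rows.append(fit_action_model(sub, sid, subset_mask=mask).to_row())
        except ValueError:
            pass
        try:
            rows.append(fit_confidence_model(sub, sid, subset_mask=mask).to_row())
        except ValueError:
            pass
        if not small_pe_only:
            try:
                rows.append(fit_coupling_model(sub, sid).to_row())
            except ValueError:
                pass
    return pd.DataFrame(rows)


def compare_betas(results: pd.DataFrame, groups: dict | pd.Series, model: str,
                  predictor: str, alpha: float = 0.05) -> TestResult:
    """Compare one beta between two groups with assumption routing.

    Student t by default; Welch t when Levene rejects homogeneity of
    variance; Wilcoxon rank-sum when Shapiro-Wilk rejects normality in
    either group.  The appropriate effect size is attached.
    """
    col = f"beta_{predictor}"
    sub = results.loc[results["model"] == model]
    if col not in sub.columns:
        raise ValueError(f"unknown predictor {predictor!r} for model {model!r}")
    gmap = dict(groups) if not isinstance(groups, pd.Series) else groups.to_dict()
    labels = sub["subject_id"].map(gmap)
    uniq = [g for g in pd.unique(labels) if pd.notna(g)]
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    a = sub.loc[labels == uniq[0], col].dropna().to_numpy()
    b = sub.loc[labels == uniq[1], col].dropna().to_numpy()
    return route_two_sample_test(a, b, alpha=alpha,
                                 label=f"{model}:{predictor} {uniq[0]} vs {uniq[1]}")


def median_r_squared(results: pd.DataFrame, groups: dict | pd.Series, model: str) -> pd.Series:
    """Median R^2 over subjects, per group, for one model."""
    sub = results.loc[results["model"] == model]
    gmap = dict(groups) if not isinstance(groups, pd.Series) else groups.to_dict()
    labels = sub["subject_id"].map(gmap)
    if sub.empty:
        raise ValueError(f"no results for model {model!r}")
    return sub.groupby(labels)["r_squared"].median()
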