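"""Trialwise derived measures: prediction errors, empirical learning rates,
outlier filtering, confidence z-scoring, PE-magnitude tertiles and
peri-change-point profiles.

The empirical learning rate on trial t is the fraction of the prediction
error the subject incorporated into the next bucket placement,

    alpha_t = (b_{t+1} - b_t) / delta_t,      delta_t = X_t - b_t,

with both differences taken on the circle.  Block-final trials (no next
placement) and zero-prediction-error trials are excluded; learning rates
above the group's 95th percentile are treated as non-learning noise and
excluded; confidence is z-scored within subject.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .task import circ_diff

__all__ = [
    "derive_trial_metrics",
    "filter_learning_rates",
    "zscore_confidence",
    "bin_by_pe_magnitude",
    "summarize_subject",
    "summarize_subjects",
    "peri_changepoint_profile",
]

PE_BINS = ("small", "medium", "large")


def derive_trial_metrics(trials: pd.DataFrame, circular: bool = True) -> pd.DataFrame:
    """Compute delta, |delta| and alpha per trial of a trial-log table.

    ``trials`` needs columns subject_id, block, trial, outcome, bucket (and
    is assumed sorted by subject, block, trial).  Returns a copy with added
    columns ``delta``, ``abs_delta``, ``alpha``, ``excluded``,
    ``exclude_reason`` and ``conf_usable`` (False on block-first trials,
    which lack a previous-trial predictor for the confidence analysis).
    Block-final trials get reason ``last_trial``; zero-PE trials ``zero_pe``.
    """
    for col in ("subject_id", "block", "trial", "outcome", "bucket"):
        if col not in trials.columns:
            raise ValueError(f"trial table missing column {col!r}")
    bad = trials[["outcome", "bucket"]].isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0][0])
        raise ValueError(f"missing outcome/bucket at row {row}")

    df = trials.sort_values(["subject_id", "block", "trial"], kind="stable").reset_index(drop=True)
    diff = circ_diff if circular else (lambda a, b: np.asarray(a, float) - np.asarray(b, float))
    delta = diff(df["outcome"].to_numpy(), df["bucket"].to_numpy())

    grp = df.groupby(["subject_id", "block"], sort=False)
    if grp.size().min() < 2:
        raise ValueError("each subject x block needs at least 2 trials")
    next_bucket = grp["bucket"].shift(-1).to_numpy()
    last_trial = np.isnan(next_bucket)
    update = np.where(last_trial, np.nan, diff(np.where(last_trial, 0.0, next_bucket),
                                               df["bucket"].to_numpy()))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = update / delta

    reason = np.full(len(df), "", dtype=object)
    reason[last_trial] = "last_trial"
    zero_pe = (delta == 0) & ~last_trial
    reason[zero_pe] = "zero_pe"
    alpha[delta == 0] = np.nan

    df["delta"] = delta
    df["abs_delta"] = np.abs(delta)
    df["alpha"] = alpha
    df["excluded"] = reason != ""
    df["exclude_reason"] = reason
    df["conf_usable"] = grp.cumcount().to_numpy() > 0  # block-first: no t-1
    return df


def filter_learning_rates(derived: pd.DataFrame, group_assignment: dict | pd.Series) -> pd.DataFrame:
    """Flag learning rates above their group's 95th percentile as excluded.

    The threshold is the linear-interpolation 95th percentile of all pooled
    retained alpha values within each group; trials strictly above it get
    reason ``percentile``.  Only the upper tail is filtered — negative alphas
    are retained.
    """
    df = derived.copy()
    groups = df["subject_id"].map(dict(group_assignment)
                                  if not isinstance(group_assignment, pd.Series)
                                  else group_assignment.to_dict())
    if groups.isna().any():
        missing = df.loc[groups.isna(), "subject_id"].unique()
        raise ValueError(f"subjects without a group: {list(missing)}")
    df["_group"] = groups
    for g, sub in df.groupby("_group", sort=False):
        retained = sub.loc[~sub["excluded"], "alpha"].to_numpy()
        if retained.size == 0:
            raise ValueError(f"group {g!r} has no retained trials")
        threshold = np.percentile(retained, 95)  # linear interpolation
        mask = (~df["excluded"]) & (df["_group"] == g) & (df["alpha"] > threshold)
        df.loc[mask, "excluded"] = True
        df.loc[mask, "exclude_reason"] = "percentile"
    return df.drop(columns="_group")


def zscore_confidence(confidence) -> np.ndarray:
    """Standardise one subject's confidence ratings to mean 0, SD 1 (ddof=1)."""
    c = np.asarray(confidence, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 confidence ratings")
    sd = c.std(ddof=1)
    if sd == 0:
        raise ValueError("constant confidence ratings cannot be z-scored")
    return (c - c.mean()) / sd


def bin_by_pe_magnitude(abs_delta) -> np.ndarray:
    """Assign |delta| values of one subject's retained trials to tertiles.

    Edges are the 1/3 and 2/3 linear-interpolation quantiles of the input;
    values at an edge go to the lower bin.  Returns an array of labels from
    ``("small", "medium", "large")``.
    """
    x = np.asarray(abs_delta, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 retained trials to form tertiles")
    lo, hi = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(x <= lo, "small", np.where(x <= hi, "medium", "large"))
    return labels.astype(object)


def add_derived_columns(derived: pd.DataFrame, pooled_tertiles: bool = False) -> pd.DataFrame:
    """Add z-scored confidence and PE-magnitude bins to a derived table.

    z-scoring is always within subject (over all trials with a confidence
    rating).  Tertile edges are per subject by default; ``pooled_tertiles``
    computes them over all subjects' retained trials instead.
    """
    df = derived.copy()
    df["z_confidence"] = np.nan
    if "confidence" in df.columns:
        for _, idx in df.groupby("subject_id", sort=False).groups.items():
            df.loc[idx, "z_confidence"] = zscore_confidence(df.loc[idx, "confidence"])
    df["pe_bin"] = pd.array([pd.NA] * len(df), dtype="string")
    retained = ~df["excluded"]
    if pooled_tertiles:
        df.loc[retained, "pe_bin"] = bin_by_pe_magnitude(df.loc[retained, "abs_delta"])
    else:
        for _, idx in df.loc[retained].groupby("subject_id", sort=False).groups.items():
            df.loc[idx, "pe_bin"] = bin_by_pe_magnitude(df.loc[idx, "abs_delta"])
    return df


def summarize_subject(derived_one: pd.DataFrame) -> dict:
    """Per-subject summary: mean alpha and z-confidence, overall and by bin."""
    retained = derived_one.loc[~derived_one["excluded"]]
    out = {
        "overall_mean_alpha": retained["alpha"].mean(),
        "mean_z_confidence": derived_one["z_confidence"].mean()
        if "z_confidence" in derived_one else np.nan,
        "proportion_excluded": derived_one["excluded"].mean(),
        "n_retained": len(retained),
    }
    for b in PE_BINS:
        sub = retained.loc[retained["pe_bin"] == b]
        out[f"mean_alpha_{b}"] = sub["alpha"].mean()
        out[f"mean_z_confidence_{b}"] = (sub["z_confidence"].mean()
                                         if "z_confidence" in sub else np.nan)
    return out


def summarize_subjects(derived: pd.DataFrame) -> pd.DataFrame:
    """Subject-level summary table (one row per subject)."""
    rows = []
    for sid, sub in derived.groupby("subject_id", sort=False):
        row = {"subject_id": sid}
        row.update(summarize_subject(sub))
        rows.append(row)
    return pd.DataFrame(rows)


def peri_changepoint_profile(derived: pd.DataFrame, window: int = 4,
                             value_columns: tuple = ("alpha", "z_confidence"),
                             by: str | None = None) -> pd.DataFrame:
    """Average measures at relative positions -window..+window around change
    points (position 0 = the change-point trial itself).

    Only change points whose full window fits inside a block contribute.
    Block-initial forced resets are not counted as change points.  Returns a
    long table with columns position, column, mean, n (plus the ``by`` label
    if grouping is requested); positions with no data are omitted.
    """
    if "changepoint" not in derived.columns:
        raise ValueError("derived table has no changepoint column")
    records = []
    group_iter = derived.groupby(by, sort=False) if by else [(None, derived)]
    for label, part in group_iter:
        frames = []
        for (_, _), block_df in part.groupby(["subject_id", "block"], sort=False):
            block_df = block_df.reset_index(drop=True)
            cps = np.flatnonzero(block_df["changepoint"].to_numpy() & (block_df["trial"].to_numpy() > 0))
            n = len(block_df)
            for cp in cps:
                if cp - window < 0 or cp + window >= n:
                    continue
                seg = block_df.iloc[cp - window: cp + window + 1][list(value_columns)].copy()
                seg["position"] = np.arange(-window, window + 1)
                frames.append(seg)
        if not frames:
            continue
        stacked = pd.concat(frames, ignore_index=True)
        for col in value_columns:
            agg = stacked.groupby("position")[col].agg(["mean", "count"]).reset_index()
            agg = agg.loc[agg["count"] > 0]
            for _, r in agg.iterrows():
                rec = {"position": int(r["position"]), "column": col,
                       "mean": r["mean"], "n": int(r["count"])}
                if by:
                    rec[by] = label
                records.append(rec)
    if not records:
        warnings.warn("no change points found; empty peri-change-point profile")
        return pd.DataFrame(columns=["position", "column", "mean", "n"] + ([by] if by else []))
    return pd.DataFrame(records)
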