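"""Group-comparison statistics for case-control behavioural analyses.

Implements the battery used to compare learning rates and confidence
between groups: tie-corrected Wilcoxon rank-sum with a normal-approximation
Z, Student/Welch t with Shapiro-Wilk/Levene assumption routing, Cohen's d
and Wilcoxon r effect sizes, a mixed (split-plot) ANOVA with Huynh-Feldt
sphericity correction, the heteroscedasticity-robust Welch-James test with
approximate degrees of freedom (Johansen's formulation) for between x
within designs, Kruskal-Wallis with Bonferroni-corrected rank-sum
post-hocs, and Pearson covariate correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

try:  # pingouin imports are slow; only the two helpers are needed
    import pingouin as pg
except ImportError:  # pragma: no cover
    pg = None

__all__ = [
    "TestResult",
    "rank_sum_test",
    "wilcoxon_r",
    "cohen_d_from_t",
    "cohen_d_from_groups",
    "route_two_sample_test",
    "mixed_anova_hf",
    "welch_james_adf",
    "kruskal_wallis_posthoc",
    "correlate_with_covariates",
]


@dataclass
class TestResult:
    """One statistical test: identity, statistic, df, p and effect size."""

    test_name: str
    statistic: float
    df: tuple | float | None
    p_value: float
    effect_size: float | None = None
    effect_size_kind: str = "none"
    correction: str = "none"
    label: str = ""

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")

    def to_row(self) -> dict:
        df = self.df
        if isinstance(df, tuple):
            df = "/".join(f"{v:g}" for v in df)
        return {"label": self.label, "test": self.test_name,
                "statistic": self.statistic, "df": df, "p": self.p_value,
                "effect_size": self.effect_size, "effect_kind": self.effect_size_kind,
                "correction": self.correction}


def rank_sum_test(a, b, label: str = "") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) with tie-corrected normal Z.

    Z is signed by group order: negative when the first group's rank sum
    falls below expectation.  Two-sided p from the normal approximation.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    w = ranks[:n1].sum()
    expect = n1 * (n1 + n2 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n1 * n2 / 12.0 * ((n1 + n2 + 1) - tie_term / ((n1 + n2) * (n1 + n2 - 1.0)))
    if var <= 0:
        raise ValueError("all values tied; rank-sum test undefined")
    diff = w - expect
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)  # continuity-corrected
    p = 2.0 * stats.norm.sf(abs(z))
    r = wilcoxon_r(z, n1 + n2)
    return TestResult("wilcoxon_rank_sum", float(z), None, float(min(p, 1.0)),
                      effect_size=r, effect_size_kind="wilcoxon_r", label=label)


def wilcoxon_r(z_statistic: float, n_total: int) -> float:
    """Rank-test effect size r = |Z| / sqrt(N)."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    return abs(z_statistic) / np.sqrt(n_total)


def cohen_d_from_t(t_statistic: float, n1: int, n2: int) -> float:
    """Cohen's d from a two-sample t statistic: d = |t| * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values")
    return abs(t_statistic) * np.sqrt(1.0 / n1 + 1.0 / n2)


def cohen_d_from_groups(a, b) -> float:
    """Cohen's d from group means and the pooled SD."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    sp = np.sqrt(((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2))
    return abs(a.mean() - b.mean()) / sp


def route_two_sample_test(a, b, alpha: float = 0.05, label: str = "",
                          log: list | None = None) -> TestResult:
    """Two-sample comparison with assumption-based routing.

    Student t by default; Welch t if Levene rejects variance homogeneity;
    Wilcoxon rank-sum if Shapiro-Wilk rejects normality in either group.
    The route taken is recorded in ``test_name`` (and appended to ``log``).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    normal = True
    for g in (a, b):
        if g.size >= 3 and np.ptp(g) > 0 and stats.shapiro(g).pvalue < alpha:
            normal = False
    if not normal:
        res = rank_sum_test(a, b, label=label)
        route = "normality violated -> rank-sum"
    else:
        equal_var = stats.levene(a, b).pvalue >= alpha if (np.ptp(a) > 0 or np.ptp(b) > 0) else True
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        if equal_var:
            df = a.size + b.size - 2
            name = "student_t"
        else:
            v1, v2 = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
            df = (v1 + v2) ** 2 / (v1**2 / (a.size - 1) + v2**2 / (b.size - 1))
            name = "welch_t"
        res = TestResult(name, float(t), float(df), float(p),
                         effect_size=cohen_d_from_t(t, a.size, b.size),
                         effect_size_kind="cohen_d", label=label)
        route = f"normal, {'equal' if equal_var else 'unequal'} variances -> {name}"
    if log is not None:
        log.append(f"{label or 'comparison'}: {route}")
    return res


def _huynh_feldt_p(f: float, df1: float, df2: float, eps: float) -> float:
    return float(stats.f.sf(f, eps * df1, eps * df2))


def mixed_anova_hf(data: pd.DataFrame, dv: str, within: str, subject: str,
                   between: str) -> dict[str, TestResult]:
    """Mixed (split-plot) ANOVA with Huynh-Feldt correction on within terms.

    ``data`` is long-format with one row per subject x within-level;
    the design must be complete (every subject has every level).  Returns
    results for the between effect, the within effect and the interaction;
    the within and interaction dfs are multiplied by the Huynh-Feldt
    epsilon (capped at 1; exactly 1 when the within factor has 2 levels,
    where sphericity is vacuous).
    """
    if pg is None:  # pragma: no cover
        raise ImportError("pingouin is required for mixed_anova_hf")
    wide = data.pivot(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"missing within-factor cells for subjects {missing}")
    k = wide.shape[1]
    eps = 1.0 if k <= 2 else float(min(pg.epsilon(wide, correction="hf"), 1.0))
    aov = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject,
                         between=between, correction=False)
    aov = aov.set_index("Source")
    out: dict[str, TestResult] = {}
    grp = aov.loc[between]
    out["group"] = TestResult("mixed_anova_between", float(grp["F"]),
                              (float(grp["DF1"]), float(grp["DF2"])),
                              float(grp["p_unc"]), label="group")
    for key, src in (("within", within), ("interaction", "Interaction")):
        row = aov.loc[src]
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        p = _huynh_feldt_p(float(row["F"]), df1, df2, eps)
        out[key] = TestResult("mixed_anova_hf", float(row["F"]),
                              (eps * df1, eps * df2), p,
                              correction=f"huynh-feldt eps={eps:.4f}", label=key)
    return out


def _wj_contrasts(g: int, k: int):
    """Johansen contrast matrices for group, within and interaction effects."""
    ones_g = np.ones((1, g)) / g
    ones_k = np.ones((1, k)) / k
    dg = np.hstack([np.eye(g - 1), -np.ones((g - 1, 1))])  # group differences
    dk = np.hstack([np.eye(k - 1), -np.ones((k - 1, 1))])  # within differences
    return {
        "group": np.kron(dg, ones_k),
        "within": np.kron(ones_g, dk),
        "interaction": np.kron(dg, dk),
    }


def welch_james_adf(data: pd.DataFrame, dv: str, within: str, subject: str,
                    between: str) -> dict[str, TestResult]:
    """Welch-James heteroscedasticity-robust test (approximate df).

    Tests the between, within and interaction effects of a groups x
    repeated-measures design without assuming equal covariance matrices
    across groups (Johansen's linear-model formulation; untrimmed means).
    With two groups and one measure the test reduces exactly to Welch's t.
    Returns TestResults with the F-transformed statistic and fractional df.
    """
    wide = data.pivot(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        raise ValueError("incomplete within-factor data")
    subj_group = data.drop_duplicates(subject).set_index(subject)[between]
    groups = pd.unique(subj_group.loc[wide.index])
    g, k = len(groups), wide.shape[1]
    if g < 2:
        raise ValueError("need at least 2 groups")
    mus, covs, ns = [], [], []
    for lab in groups:
        y = wide.loc[subj_group.loc[wide.index] == lab].to_numpy(float)
        n_j = y.shape[0]
        if n_j < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 subjects")
        mus.append(y.mean(axis=0))
        cov = np.cov(y, rowvar=False).reshape(k, k)
        if k > 1 and np.linalg.matrix_rank(cov) < k:
            raise ValueError(f"singular within-group covariance for group {lab!r}")
        covs.append(cov)
        ns.append(n_j)
    mu = np.concatenate(mus)  # length g*k, group-major
    s_blocks = [cov / n for cov, n in zip(covs, ns)]
    s_hat = np.zeros((g * k, g * k))
    for j, blk in enumerate(s_blocks):
        s_hat[j * k:(j + 1) * k, j * k:(j + 1) * k] = blk

    out: dict[str, TestResult] = {}
    for effect, c in _wj_contrasts(g, k).items():
        q = c.shape[0]
        if q == 0:  # single within level: only the group effect exists
            continue
        middle = np.linalg.inv(c @ s_hat @ c.T)
        t_stat = float(mu @ c.T @ middle @ c @ mu)
        r = c.T @ middle @ c
        a = 0.0
        for j in range(g):
            qj = np.zeros((g * k, g * k))
            qj[j * k:(j + 1) * k, j * k:(j + 1) * k] = np.eye(k)
            m = s_hat @ r @ qj
            a += (np.trace(m) ** 2 + np.trace(m @ m)) / (ns[j] - 1)
        a *= 0.5
        cval = q + 2.0 * a - 6.0 * a / (q + 2.0)
        df2 = q * (q + 2.0) / (3.0 * a) if a > 0 else np.inf
        f = t_stat / cval
        p = float(stats.f.sf(f, q, df2))
        out[effect] = TestResult("welch_james_adf", f, (float(q), float(df2)), p,
                                 label=effect)
    return out


def kruskal_wallis_posthoc(values, labels) -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis omnibus over 3 groups + Bonferroni rank-sum post-hocs.

    Pairwise p values are multiplied by the number of comparisons (3) and
    capped at 1.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 3:
        raise ValueError(f"need exactly 3 groups, got {len(uniq)}")
    samples = [values[labels == u] for u in uniq]
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs at least 2 values")
    h, p = stats.kruskal(*samples)
    omnibus = TestResult("kruskal_wallis", float(h), float(len(uniq) - 1), float(p),
                         label=" vs ".join(map(str, uniq)))
    posthocs = []
    m = 3
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            res = rank_sum_test(samples[i], samples[j],
                                label=f"{uniq[i]} vs {uniq[j]}")
            res.p_value = float(min(1.0, m * res.p_value))
            res.correction = f"bonferroni x{m}"
            posthocs.append(res)
    return omnibus, posthocs


def correlate_with_covariates(summaries: pd.DataFrame, covariates: pd.DataFrame,
                              on: str = "subject_id",
                              measures: list | None = None,
                              covariate_cols: list | None = None) -> pd.DataFrame:
    """Pearson correlations between task measures and covariate scores.

    Returns a long table (measure, covariate, n, r, p).  Pairs with zero
    variance raise; pairs with fewer than 3 complete observations raise.
    """
    merged = summaries.merge(covariates, on=on)
    measures = measures or [c for c in summaries.columns if c != on
                            and pd.api.types.is_numeric_dtype(summaries[c])]
    covariate_cols = covariate_cols or [c for c in covariates.columns if c != on
                                        and pd.api.types.is_numeric_dtype(covariates[c])]
    rows = []
    for m in measures:
        for c in covariate_cols:
            sub = merged[[m, c]].dropna()
            if len(sub) < 3:
                raise ValueError(f"fewer than 3 complete observations for ({m}, {c})")
            x, y = sub[m].to_numpy(), sub[c].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(f"zero variance in pair ({m}, {c})")
            r, p = stats.pearsonr(x, y)
            rows.append({"measure": m, "covariate": c, "n": len(sub),
                         "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)
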