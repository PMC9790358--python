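"""End-to-end analysis: model object and results container.

:class:`PredictiveInferenceAnalysis` is built from a trial-log table and a
subject-metadata table (or directly from a simulated cohort); ``fit()``
runs the whole chain — reduced Bayesian observer per subject, trialwise
derived measures with filtering and binning, subject summaries, the three
per-subject regressions, and the group-comparison battery — and returns an
:class:`AnalysisResults` with every table plus a text ``summary()``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, regressions
from .cohort import CohortSpec, simulate_cohort
from .groupstats import (
    TestResult,
    kruskal_wallis_posthoc,
    mixed_anova_hf,
    rank_sum_test,
    route_two_sample_test,
    welch_james_adf,
    correlate_with_covariates,
)
from .observer import ObserverConfig, run_observer

__all__ = ["PredictiveInferenceAnalysis", "AnalysisResults"]

ACTION_PREDICTORS = ["abs_delta", "cpp_x_abs_delta", "ru_x_abs_delta", "hit_x_abs_delta"]
CONFIDENCE_PREDICTORS = ["abs_delta_prev", "cpp_prev", "ru_prev", "hit_prev"]


@dataclass
class AnalysisResults:
    """All tables produced by one analysis run.

    Attributes are pandas DataFrames (or dicts of :class:`TestResult`);
    ``summary()`` renders the headline numbers, ``save(outdir)`` writes
    every table as CSV plus a provenance block.
    """

    derived: pd.DataFrame
    subject_summaries: pd.DataFrame
    group_tests: pd.DataFrame
    regression_results: pd.DataFrame
    beta_comparisons: pd.DataFrame
    median_r2: pd.DataFrame
    peri_changepoint: pd.DataFrame
    correlations: pd.DataFrame | None
    small_pe_regressions: pd.DataFrame | None
    small_pe_beta_comparisons: pd.DataFrame | None
    provenance: dict = field(default_factory=dict)
    routing_log: list = field(default_factory=list)

    def summary(self) -> str:
        buf = _io.StringIO()
        w = buf.write
        w("Predictive-inference task analysis\n")
        w("=" * 50 + "\n\n")
        groups = self.subject_summaries.groupby("group")
        w("Subject summaries (mean (SD) per group)\n")
        for col, name in [("overall_mean_alpha", "Overall LR"),
                          ("mean_alpha_small", "LR (small PE)"),
                          ("mean_alpha_medium", "LR (medium PE)"),
                          ("mean_alpha_large", "LR (large PE)"),
                          ("mean_z_confidence", "z-confidence")]:
            m, s = groups[col].mean(), groups[col].std()
            cells = "  ".join(f"{g}: {m[g]:.3f} ({s[g]:.3f})" for g in m.index)
            w(f"  {name:<16} {cells}\n")
        w("\nGroup tests\n")
        for _, row in self.group_tests.iterrows():
            dfs = f", df={row['df']}" if pd.notna(row["df"]) else ""
            es = (f", {row['effect_kind']}={row['effect_size']:.2f}"
                  if pd.notna(row["effect_size"]) else "")
            w(f"  {row['label']}: {row['test']} stat={row['statistic']:.3f}"
              f"{dfs}, p={row['p']:.4g}{es}\n")
        w("\nMedian R-squared per model and group\n")
        for _, row in self.median_r2.iterrows():
            w(f"  {row['model']:<11} {row['group']}: {row['median_r2']:.3f}\n")
        w("\nSignificant beta comparisons (p < .05)\n")
        sig = self.beta_comparisons.loc[self.beta_comparisons["p"] < 0.05]
        if sig.empty:
            w("  none\n")
        for _, row in sig.iterrows():
            w(f"  {row['label']}: {row['test']} stat={row['statistic']:.3f}, "
              f"p={row['p']:.4g}\n")
        return buf.getvalue()

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "derived_trials.csv": self.derived,
            "subject_summaries.csv": self.subject_summaries,
            "group_tests.csv": self.group_tests,
            "regression_results.csv": self.regression_results,
            "beta_comparisons.csv": self.beta_comparisons,
            "median_r_squared.csv": self.median_r2,
            "peri_changepoint.csv": self.peri_changepoint,
        }
        if self.correlations is not None:
            tables["correlations.csv"] = self.correlations
        if self.small_pe_regressions is not None:
            tables["small_pe_regression_results.csv"] = self.small_pe_regressions
            tables["small_pe_beta_comparisons.csv"] = self.small_pe_beta_comparisons
        for name, df in tables.items():
            df.to_csv(outdir / name, index=False, float_format="%.12g")
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(self.summary())
            fh.write("\nProvenance\n")
            for k, v in self.provenance.items():
                fh.write(f"  {k}: {v}\n")
            fh.write("\nAssumption routing\n")
            for line in self.routing_log:
                fh.write(f"  {line}\n")


class PredictiveInferenceAnalysis:
    """Model object for the full case-control task analysis.

    Parameters
    ----------
    trials : DataFrame
        Canonical trial log (subject_id, block, trial, outcome, bucket,
        confidence, hit, optionally changepoint/latent_mean).
    metadata : DataFrame
        One row per subject with group (and medication) labels plus any
        clinical covariates.
    observer : ObserverConfig, optional
        Generative parameters for the normative observer (defaults: task
        truth, H = 0.125, sigma_N = 12 deg).
    pooled_tertiles, linear_geometry, small_pe_refit, medication_analysis :
        Analysis-variant flags (per-subject tertile edges, circular vs
        linear differences, low-PE-only regression refit, three-group
        medication comparison).
    """

    def __init__(self, trials: pd.DataFrame, metadata: pd.DataFrame,
                 observer: ObserverConfig | None = None, *,
                 pooled_tertiles: bool = False, linear_geometry: bool = False,
                 small_pe_refit: bool = False, medication_analysis: bool = False,
                 seed: int = 0):
        self.trials = trials
        self.metadata = metadata
        self.observer_config = observer or ObserverConfig()
        self.pooled_tertiles = pooled_tertiles
        self.circular = not linear_geometry
        self.small_pe_refit = small_pe_refit
        self.medication_analysis = medication_analysis
        self.seed = seed
        missing = set(trials["subject_id"]) - set(metadata["subject_id"])
        if missing:
            raise ValueError(f"subjects missing from metadata: {sorted(missing)}")

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_csv(cls, trials_path, metadata_path, **kwargs) -> "PredictiveInferenceAnalysis":
        from .io import read_metadata, read_trials
        return cls(read_trials(trials_path), read_metadata(metadata_path), **kwargs)

    @classmethod
    def from_simulation(cls, spec: CohortSpec, **kwargs) -> "PredictiveInferenceAnalysis":
        trials, metadata = simulate_cohort(spec)
        obs = kwargs.pop("observer", None) or spec.observer or ObserverConfig(
            hazard=spec.task.hazard, noise_var=spec.task.noise_sd**2,
            n_positions=spec.task.n_positions)
        return cls(trials, metadata, observer=obs, seed=spec.seed, **kwargs)

    # -- pipeline stages --------------------------------------------------
    def _attach_observer(self) -> pd.DataFrame:
        parts = []
        for sid, sub in self.trials.groupby("subject_id", sort=False):
            sub = sub.sort_values(["block", "trial"], kind="stable").reset_index(drop=True)
            trace = run_observer(sub["outcome"].to_numpy(), self.observer_config,
                                 block=sub["block"].to_numpy())
            tf = trace.to_frame().rename(columns={
                "delta": "model_delta", "learning_rate": "model_learning_rate"})
            parts.append(pd.concat([sub, tf], axis=1))
        return pd.concat(parts, ignore_index=True)

    def fit(self) -> AnalysisResults:
        """Run the full pipeline and return an :class:`AnalysisResults`."""
        group_map = self.metadata.set_index("subject_id")["group"]
        with_trace = self._attach_observer()
        derived = metrics.derive_trial_metrics(with_trace, circular=self.circular)
        derived = metrics.filter_learning_rates(derived, group_map)
        derived = metrics.add_derived_columns(derived, pooled_tertiles=self.pooled_tertiles)

        summaries = metrics.summarize_subjects(derived).merge(
            self.metadata, on="subject_id")

        routing_log: list[str] = []
        tests = self._group_tests(derived, summaries, routing_log)

        reg = regressions.fit_all_subjects(derived)
        beta_cmp = self._beta_comparisons(reg, group_map, routing_log)
        med_r2 = self._median_r2(reg, group_map)

        peri = metrics.peri_changepoint_profile(
            derived, window=4,
            value_columns=tuple(c for c in ("alpha", "z_confidence",
                                            "model_learning_rate", "model_confidence")
                                if c in derived.columns),
            by="group") if "changepoint" in derived.columns else pd.DataFrame()

        correlations = None
        covar_cols = [c for c in self.metadata.columns
                      if c not in ("subject_id", "group", "medication")
                      and pd.api.types.is_numeric_dtype(self.metadata[c])]
        if covar_cols:
            correlations = correlate_with_covariates(
                summaries[["subject_id", "overall_mean_alpha", "mean_alpha_small",
                           "mean_z_confidence"]],
                self.metadata[["subject_id"] + covar_cols])

        small_reg = small_cmp = None
        if self.small_pe_refit:
            small_reg = regressions.fit_all_subjects(derived, small_pe_only=True)
            small_cmp = self._beta_comparisons(small_reg, group_map, routing_log,
                                               models=("action", "confidence"))

        provenance = {
            "seed": self.seed,
            "observer": self.observer_config,
            "n_subjects": summaries.shape[0],
            "pooled_tertiles": self.pooled_tertiles,
            "circular": self.circular,
            "medication_analysis": self.medication_analysis,
        }
        return AnalysisResults(
            derived=derived, subject_summaries=summaries, group_tests=tests,
            regression_results=reg, beta_comparisons=beta_cmp, median_r2=med_r2,
            peri_changepoint=peri, correlations=correlations,
            small_pe_regressions=small_reg, small_pe_beta_comparisons=small_cmp,
            provenance=provenance, routing_log=routing_log)

    # -- helpers ----------------------------------------------------------
    def _two_group_labels(self, summaries: pd.DataFrame) -> list:
        return list(pd.unique(summaries["group"]))

    def _group_tests(self, derived: pd.DataFrame, summaries: pd.DataFrame,
                     log: list) -> pd.DataFrame:
        results: list[TestResult] = []
        labels = self._two_group_labels(summaries)
        by_group = {g: summaries.loc[summaries["group"] == g] for g in labels}

        if len(labels) == 2:
            a, b = (by_group[g] for g in labels)
            results.append(rank_sum_test(a["overall_mean_alpha"], b["overall_mean_alpha"],
                                         label=f"overall LR {labels[0]} vs {labels[1]}"))
            results.append(route_two_sample_test(
                a["mean_z_confidence"], b["mean_z_confidence"],
                label=f"z-confidence {labels[0]} vs {labels[1]}", log=log))
            results.append(route_two_sample_test(
                a["proportion_excluded"], b["proportion_excluded"],
                label="proportion excluded", log=log))
            for bin_label in metrics.PE_BINS:
                col = f"mean_alpha_{bin_label}"
                res = rank_sum_test(a[col], b[col],
                                    label=f"LR ({bin_label} PE) {labels[0]} vs {labels[1]}")
                res.p_value = float(min(1.0, 3 * res.p_value))
                res.correction = "bonferroni x3"
                results.append(res)

        # group x PE-bin factorial tests
        long_alpha = summaries.melt(
            id_vars=["subject_id", "group"],
            value_vars=[f"mean_alpha_{b}" for b in metrics.PE_BINS],
            var_name="pe_bin", value_name="alpha_bin").dropna(subset=["alpha_bin"])
        long_conf = summaries.melt(
            id_vars=["subject_id", "group"],
            value_vars=[f"mean_z_confidence_{b}" for b in metrics.PE_BINS],
            var_name="pe_bin", value_name="conf_bin").dropna(subset=["conf_bin"])
        complete = long_alpha.groupby("subject_id").size() == len(metrics.PE_BINS)
        if complete.all() and len(labels) >= 2:
            wj = welch_james_adf(long_alpha, "alpha_bin", "pe_bin", "subject_id", "group")
            for key, res in wj.items():
                res.label = f"LR welch-james {key}"
                results.append(res)
            aov = mixed_anova_hf(long_conf, "conf_bin", "pe_bin", "subject_id", "group")
            for key, res in aov.items():
                res.label = f"confidence mixed ANOVA {key}"
                results.append(res)

        if self.medication_analysis:
            med = summaries.copy()
            med["med_group"] = np.where(med["medication"].isin(["MED-", "MED+"]),
                                        med["medication"], "CTL")
            if med["med_group"].nunique() == 3:
                for col, nm in [("overall_mean_alpha", "LR"),
                                ("mean_z_confidence", "z-confidence")]:
                    omnibus, posthocs = kruskal_wallis_posthoc(
                        med[col].to_numpy(), med["med_group"].to_numpy())
                    omnibus.label = f"{nm} kruskal-wallis {omnibus.label}"
                    results.append(omnibus)
                    if col == "overall_mean_alpha":
                        results.extend(posthocs)
                wj3 = welch_james_adf(
                    long_alpha.merge(med[["subject_id", "med_group"]], on="subject_id"),
                    "alpha_bin", "pe_bin", "subject_id", "med_group")
                for key, res in wj3.items():
                    res.label = f"LR welch-james 3-group {key}"
                    results.append(res)
        return pd.DataFrame([r.to_row() for r in results])

    def _beta_comparisons(self, reg: pd.DataFrame, group_map: pd.Series,
                          log: list, models=("action", "confidence", "coupling")
                          ) -> pd.DataFrame:
        rows = []
        spec_map = {"action": ACTION_PREDICTORS,
                    "confidence": CONFIDENCE_PREDICTORS,
                    "coupling": ["abs_conf_update"]}
        for model in models:
            if reg.loc[reg["model"] == model].empty:
                continue
            for pred in spec_map[model]:
                try:
                    res = regressions.compare_betas(reg, group_map, model, pred)
                except ValueError:
                    continue
                log.append(f"beta {model}:{pred} -> {res.test_name}")
                rows.append(res.to_row())
        return pd.DataFrame(rows)

    def _median_r2(self, reg: pd.DataFrame, group_map: pd.Series) -> pd.DataFrame:
        rows = []
        for model in ("action", "confidence", "coupling"):
            if reg.loc[reg["model"] == model].empty:
                continue
            med = regressions.median_r_squared(reg, group_map, model)
            for g, v in med.items():
                rows.append({"model": model, "group": g, "median_r2": v})
        return pd.DataFrame(rows)
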