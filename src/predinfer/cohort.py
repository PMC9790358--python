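"""Synthetic agent cohorts for the predictive-inference task.

Agents place the bucket, update it by a policy-dependent fraction of their
own prediction error, and report 1-100 confidence derived from the reduced
Bayesian observer's confidence signal.  Group presets reproduce the
qualitative clinical pattern of interest — elevated learning rates in the
patient group concentrated at small prediction errors, with equivalent
confidence — without targeting any participant's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observer import ObserverConfig, run_observer
from .task import TaskConfig, circ_diff, generate_session, score_trial, wrap_angle

__all__ = [
    "AgentProfile",
    "CohortSpec",
    "simulate_agent",
    "simulate_cohort",
    "default_cohort_spec",
    "PRESET_PROFILES",
]

POLICIES = ("fixed-alpha", "observer-coupled", "smallPE-boosted")

TRIAL_COLUMNS = [
    "subject_id", "group", "medication", "block", "trial", "latent_mean",
    "changepoint", "outcome", "bucket", "confidence", "hit", "points",
]


@dataclass(frozen=True)
class AgentProfile:
    """How a synthetic agent turns observer signals into behaviour.

    ``policy`` selects the effective learning rate: a fixed value
    (``fixed_alpha``), the observer's trialwise alpha scaled by
    ``base_gain``, or the observer alpha plus ``smallpe_boost`` whenever the
    agent's own |prediction error| falls below ``smallpe_threshold`` degrees.
    Bucket placements get signal-dependent Gaussian motor noise with SD
    ``motor_noise_sd * (1 + motor_noise_weber * |intended move|)`` degrees —
    noise grows with movement amplitude, as in human motor control, and
    ``motor_noise_sd = 0`` gives a fully noiseless placement.  Confidence
    reports are ``confidence_gain * model_confidence`` mapped to the 1-100
    scale with Gaussian report noise, rounded and clamped.
    """

    policy: str = "observer-coupled"
    fixed_alpha: float = 0.5
    base_gain: float = 1.0
    smallpe_boost: float = 0.0
    smallpe_threshold: float = 8.0
    motor_noise_sd: float = 0.3
    motor_noise_weber: float = 0.3
    confidence_gain: float = 1.0
    confidence_noise_sd: float = 8.0
    clinical_covariates: dict | None = None

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}; choose from {POLICIES}")
        if self.motor_noise_sd < 0 or self.confidence_noise_sd < 0 \
                or self.motor_noise_weber < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.base_gain < 0:
            raise ValueError("base_gain must be >= 0")


# Group presets: patients (OCD / unmedicated MED-) get a small-PE learning
# boost on top of the normative observer; medicated patients a mild one;
# confidence policy is identical across groups.
PRESET_PROFILES: dict[str, AgentProfile] = {
    "CTL": AgentProfile(policy="observer-coupled", base_gain=0.8),
    "OCD": AgentProfile(policy="smallPE-boosted", base_gain=0.8, smallpe_boost=0.6),
    "MED-": AgentProfile(policy="smallPE-boosted", base_gain=0.8, smallpe_boost=0.6),
    "MED+": AgentProfile(policy="smallPE-boosted", base_gain=0.8, smallpe_boost=0.15),
}


@dataclass(frozen=True)
class CohortSpec:
    """Group sizes and agent profiles for a simulated cohort.

    ``groups`` maps a group label to ``(count, AgentProfile)``; the
    ``medication`` map assigns each label a medication status (CTL groups
    are "none").  One task session is generated per subject from seeds derived
    deterministically from ``seed``.
    """

    groups: dict = field(default_factory=dict)
    task: TaskConfig = field(default_factory=TaskConfig)
    observer: ObserverConfig | None = None
    medication: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n, _ in self.groups.values()):
            raise ValueError("group counts must be >= 0")


def default_cohort_spec(n_ctl: int = 46, n_ocd: int = 27, *, seed: int = 0,
                        task: TaskConfig | None = None,
                        split_medication: bool = False) -> CohortSpec:
    """Preset two-group (CTL/OCD) or three-group (CTL/MED-/MED+) cohort.

    The default sizes mirror a typical adolescent case-control cohort for
    this task (46 controls, 27 patients; 16 unmedicated / 11 medicated when
    split).
    """
    task = task or TaskConfig()
    if split_medication:
        n_unmed = (n_ocd * 16 + 13) // 27  # keep the 16:11 split ratio
        groups = {
            "CTL": (n_ctl, PRESET_PROFILES["CTL"]),
            "MED-": (n_unmed, PRESET_PROFILES["MED-"]),
            "MED+": (n_ocd - n_unmed, PRESET_PROFILES["MED+"]),
        }
        medication = {"CTL": "none", "MED-": "MED-", "MED+": "MED+"}
    else:
        groups = {"CTL": (n_ctl, PRESET_PROFILES["CTL"]),
                  "OCD": (n_ocd, PRESET_PROFILES["OCD"])}
        medication = {"CTL": "none", "OCD": "mixed"}
    return CohortSpec(groups=groups, task=task, medication=medication, seed=seed)


def _effective_alpha(profile: AgentProfile, model_alpha: float, abs_delta: float) -> float:
    if profile.policy == "fixed-alpha":
        alpha = profile.fixed_alpha
    elif profile.policy == "observer-coupled":
        alpha = profile.base_gain * model_alpha
    else:  # smallPE-boosted
        alpha = profile.base_gain * model_alpha
        if abs_delta < profile.smallpe_threshold:
            alpha += profile.smallpe_boost
    return max(alpha, 0.0)


def simulate_agent(profile: AgentProfile, session, seed: int,
                   observer_config: ObserverConfig | None = None) -> pd.DataFrame:
    """Simulate one agent on a session; returns one row per trial.

    The bucket starts at a uniform random position each block and is updated
    by ``alpha_eff * delta + motor noise`` (wrapped), where delta is the
    agent's own circular prediction error.  The observer runs on the same
    outcome sequence to supply the policy's learning-rate and confidence
    signals.
    """
    rng = np.random.default_rng(seed)
    cfg = observer_config or ObserverConfig(
        hazard=session.config.hazard,
        noise_var=session.config.noise_sd**2,
        n_positions=session.config.n_positions,
    )
    trace = run_observer(session.outcome, cfg, block=session.block)

    n = session.n_trials
    bucket = np.empty(n)
    confidence = np.empty(n, dtype=int)
    hit = np.empty(n, dtype=bool)
    points = np.empty(n, dtype=int)
    b = 0.0
    for t in range(n):
        if t == 0 or session.block[t] != session.block[t - 1]:
            b = rng.uniform(0.0, 360.0)
        bucket[t] = b
        delta = circ_diff(session.outcome[t], b)
        alpha = _effective_alpha(profile, trace.learning_rate[t], abs(delta))
        move = alpha * delta
        if profile.motor_noise_sd > 0:
            sd = profile.motor_noise_sd * (1.0 + profile.motor_noise_weber * abs(move))
            noise = rng.normal(0.0, sd)
        else:
            noise = 0.0
        b = wrap_angle(b + move + noise)
        raw_conf = 100.0 * profile.confidence_gain * trace.confidence[t]
        if profile.confidence_noise_sd > 0:
            raw_conf += rng.normal(0.0, profile.confidence_noise_sd)
        confidence[t] = int(np.clip(np.round(raw_conf), 1, 100))
        hit[t], points[t] = score_trial(session.outcome[t], bucket[t], session.config)

    return pd.DataFrame(
        {
            "block": session.block,
            "trial": session.trial,
            "latent_mean": session.latent_mean,
            "changepoint": session.changepoint,
            "outcome": session.outcome,
            "bucket": bucket,
            "confidence": confidence,
            "hit": hit,
            "points": points,
        }
    )


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every agent in a cohort spec.

    Returns ``(trials, metadata)``: the canonical trial-log table (one row
    per subject x trial) and a subject-metadata table with group and
    medication labels plus any clinical covariates.  Per-subject session and
    behaviour seeds are derived from ``spec.seed`` by subject index, so the
    whole cohort is reproducible from the master seed.
    """
    total = sum(n for n, _ in spec.groups.values())
    if total == 0:
        raise ValueError("cohort has zero subjects")
    trial_tables = []
    meta_rows = []
    idx = 0
    for label, (count, profile) in spec.groups.items():
        for _ in range(count):
            subject_id = f"S{idx:03d}"
            session = generate_session(spec.task, seed=int(spec.seed * 1_000_003 + 2 * idx) % (2**31))
            df = simulate_agent(profile, session,
                                seed=int(spec.seed * 1_000_003 + 2 * idx + 1) % (2**31),
                                observer_config=spec.observer)
            df.insert(0, "subject_id", subject_id)
            df.insert(1, "group", label)
            df.insert(2, "medication", spec.medication.get(label, "none"))
            trial_tables.append(df)
            row = {"subject_id": subject_id, "group": label,
                   "medication": spec.medication.get(label, "none")}
            if profile.clinical_covariates:
                # scalar -> fixed value; (mean, sd) -> Gaussian draw per subject
                cov_rng = np.random.default_rng(int(spec.seed * 1_000_003 + 2 * idx + 1) % (2**31) + 7)
                for name, val in profile.clinical_covariates.items():
                    if isinstance(val, (tuple, list)) and len(val) == 2:
                        row[name] = float(cov_rng.normal(val[0], val[1]))
                    else:
                        row[name] = val
            meta_rows.append(row)
            idx += 1
    trials = pd.concat(trial_tables, ignore_index=True)
    metadata = pd.DataFrame(meta_rows)
    return trials, metadata
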