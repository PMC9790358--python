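"""Quasi-optimal (reduced) Bayesian observer for change-point inference.

Instead of maintaining a full posterior over run lengths, the reduced
observer tracks a single belief B_t about the latent mean together with its
uncertainty, and mixes two hypotheses on every trial: "the outcome came from
the current regime" versus "a change point just occurred".  Two normalised
quantities summarise its state:

* change-point probability (CPP, Omega) — posterior probability that the
  current outcome was drawn from a freshly resampled mean, obtained from the
  Bayes ratio of a uniform (change) and Gaussian (no-change) likelihood
  weighted by the hazard H;
* relative uncertainty (RU, tau) — uncertainty about the mean as a fraction
  of total predictive variance, tau = sigma_mu^2 / (sigma_mu^2 + sigma_N^2).

The belief moves toward each outcome by a trialwise learning rate

    alpha_t = Omega_t + (1 - Omega_t) * tau_t,

so learning accelerates both when a change is likely and when the belief is
uncertain.  The observer is normative: it is conditioned on an outcome
sequence with the generative parameters fixed at their true task values, and
has no free parameters fitted to behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import circ_diff, wrap_angle

__all__ = [
    "ObserverConfig",
    "ObserverTrace",
    "change_point_probability",
    "model_learning_rate",
    "update_belief_and_uncertainty",
    "run_observer",
    "model_confidence",
    "CONFIDENCE_VARIANTS",
]

CONFIDENCE_VARIANTS = ("certainty_product", "neg_total_uncertainty", "one_minus_alpha")


@dataclass(frozen=True)
class ObserverConfig:
    """Observer parameters (defaults match the task's generative values).

    ``noise_var`` is the outcome noise variance sigma_N^2 in squared degrees;
    ``initial_uncertainty`` is the belief variance at the start of each block
    (default sigma_N^2, an uninformative start).  ``confidence_map`` selects
    the model-confidence formula; ``circular`` toggles ring geometry (the
    default) versus plain linear differences on the 0-360 scale.
    """

    hazard: float = 0.125
    noise_var: float = 144.0
    n_positions: int = 360
    initial_uncertainty: float | None = None
    confidence_map: str = "certainty_product"
    circular: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError("hazard must be in [0, 1]")
        if self.noise_var <= 0:
            raise ValueError("noise_var must be > 0")
        if self.initial_uncertainty is not None and self.initial_uncertainty < 0:
            raise ValueError("initial_uncertainty must be >= 0")
        if self.confidence_map not in CONFIDENCE_VARIANTS:
            raise ValueError(
                f"unknown confidence_map {self.confidence_map!r}; "
                f"choose from {CONFIDENCE_VARIANTS}"
            )

    @property
    def sigma_mu0(self) -> float:
        return self.noise_var if self.initial_uncertainty is None else self.initial_uncertainty


@dataclass
class ObserverTrace:
    """Per-trial record of the observer's run over one outcome sequence."""

    belief: np.ndarray = field(repr=False)
    delta: np.ndarray = field(repr=False)
    cpp: np.ndarray = field(repr=False)
    relative_uncertainty: np.ndarray = field(repr=False)
    learning_rate: np.ndarray = field(repr=False)
    mean_uncertainty: np.ndarray = field(repr=False)
    confidence: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.belief.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "belief": self.belief,
                "delta": self.delta,
                "cpp": self.cpp,
                "relative_uncertainty": self.relative_uncertainty,
                "learning_rate": self.learning_rate,
                "mean_uncertainty": self.mean_uncertainty,
                "model_confidence": self.confidence,
            }
        )


def change_point_probability(delta, noise_var: float, mean_uncertainty: float,
                             config: ObserverConfig) -> float | np.ndarray:
    """Posterior probability that an outcome came from a resampled mean.

    Omega = H*u / (H*u + (1-H)*g) where u = 1/n_positions is the uniform
    change likelihood and g the Gaussian no-change density of the prediction
    error ``delta`` with predictive variance ``noise_var + mean_uncertainty``.
    Monotonically non-decreasing in |delta|.
    """
    if noise_var <= 0:
        raise ValueError("noise_var must be > 0")
    h = config.hazard
    delta = np.asarray(delta, dtype=float)
    total_var = noise_var + mean_uncertainty
    g = np.exp(-0.5 * delta**2 / total_var) / np.sqrt(2.0 * np.pi * total_var)
    u = 1.0 / config.n_positions
    num = h * u
    den = num + (1.0 - h) * g
    with np.errstate(invalid="ignore"):
        omega = np.where(den > 0.0, num / np.maximum(den, np.finfo(float).tiny), 1.0 if h > 0 else 0.0)
    if h == 0.0:
        omega = np.zeros_like(delta)
    out = np.clip(omega, 0.0, 1.0)
    return out if out.ndim else float(out)


def model_learning_rate(cpp, relative_uncertainty):
    """alpha = Omega + (1 - Omega) * tau."""
    cpp = np.asarray(cpp, dtype=float)
    tau = np.asarray(relative_uncertainty, dtype=float)
    out = cpp + (1.0 - cpp) * tau
    return out if out.ndim else float(out)


def update_belief_and_uncertainty(belief: float, mean_uncertainty: float,
                                  outcome: float, config: ObserverConfig):
    """One observer step: returns (new_belief, new_uncertainty, diagnostics).

    The belief moves by alpha * delta (wrapped).  The belief variance mixes
    the two regimes: after a certain change point it resets to sigma_N^2;
    in the stable regime it shrinks by the Kalman factor tau; regime
    ambiguity adds a term Omega(1-Omega) * (delta(1-tau))^2 reflecting the
    distance between the two candidate beliefs.
    """
    diff = circ_diff if config.circular else (lambda a, b: a - b)
    delta = diff(outcome, belief)
    var_n = config.noise_var
    omega = change_point_probability(delta, var_n, mean_uncertainty, config)
    tau = mean_uncertainty / (mean_uncertainty + var_n)
    alpha = model_learning_rate(omega, tau)
    new_belief = belief + alpha * delta
    if config.circular:
        new_belief = wrap_angle(new_belief)
    new_var = (omega * var_n + (1.0 - omega) * tau * var_n
               + omega * (1.0 - omega) * (delta * (1.0 - tau)) ** 2)
    diagnostics = {"delta": delta, "cpp": omega, "tau": tau, "alpha": alpha}
    return new_belief, new_var, diagnostics


def model_confidence(cpp, relative_uncertainty, mean_uncertainty=None,
                     variant: str = "certainty_product"):
    """Map observer state to a scalar confidence score.

    Variants:

    * ``certainty_product`` (default): (1 - Omega)(1 - tau) in [0, 1] —
      high only when a change is unlikely *and* the mean is well known.
    * ``neg_total_uncertainty``: -(sigma_mu^2 + sigma_N^2) rescaled is not
      available trialwise without sigma; here -(mean_uncertainty), unitless.
    * ``one_minus_alpha``: 1 - alpha.

    All variants decrease in each of Omega and tau.
    """
    cpp = np.asarray(cpp, dtype=float)
    tau = np.asarray(relative_uncertainty, dtype=float)
    if variant == "certainty_product":
        out = (1.0 - cpp) * (1.0 - tau)
    elif variant == "neg_total_uncertainty":
        if mean_uncertainty is None:
            raise ValueError("neg_total_uncertainty variant needs mean_uncertainty")
        out = -np.asarray(mean_uncertainty, dtype=float)
    elif variant == "one_minus_alpha":
        out = 1.0 - model_learning_rate(cpp, tau)
    else:
        raise ValueError(f"unknown confidence variant {variant!r}")
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def run_observer(outcomes, config: ObserverConfig | None = None,
                 block=None) -> ObserverTrace:
    """Run the reduced Bayesian observer over an outcome sequence.

    The belief is initialised to the first outcome of each block with
    uncertainty ``config.sigma_mu0``; blocks (if ``block`` labels are given)
    are filtered independently.  Deterministic: no randomness is involved.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    if outcomes.size == 0:
        raise ValueError("outcome sequence is empty")
    if config is None:
        config = ObserverConfig()
    n = outcomes.size
    block = np.zeros(n, dtype=int) if block is None else np.asarray(block)

    belief = np.empty(n)
    delta = np.empty(n)
    cpp = np.empty(n)
    tau_arr = np.empty(n)
    alpha = np.empty(n)
    var_arr = np.empty(n)

    b = 0.0
    var = 0.0
    for t in range(n):
        if t == 0 or block[t] != block[t - 1]:
            b = outcomes[t]
            var = config.sigma_mu0
        belief[t] = b
        var_arr[t] = var
        b, var, d = update_belief_and_uncertainty(b, var, outcomes[t], config)
        delta[t] = d["delta"]
        cpp[t] = d["cpp"]
        tau_arr[t] = d["tau"]
        alpha[t] = d["alpha"]

    conf = model_confidence(cpp, tau_arr, mean_uncertainty=var_arr,
                            variant=config.confidence_map)
    return ObserverTrace(belief=belief, delta=delta, cpp=cpp,
                         relative_uncertainty=tau_arr, learning_rate=alpha,
                         mean_uncertainty=var_arr, confidence=conf)
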