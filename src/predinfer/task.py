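"""Generative model of the predictive-inference ("coin and bucket") task.

Coins are launched from the centre of a circular ring and land at angular
positions drawn from a Gaussian around a latent mean.  The mean is stable on
most trials but is resampled uniformly over the ring with a fixed per-trial
hazard (a change point), so a learner must distinguish outcome noise from
genuine environmental change.  Catching a coin in the bucket earns points;
missing loses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "SessionData",
    "circ_diff",
    "wrap_angle",
    "generate_session",
    "score_trial",
    "write_session",
    "read_session",
]


def circ_diff(a, b):
    """Signed circular difference ``a - b`` in degrees, mapped to (-180, 180].

    The ring has 360 degrees; the returned value is the shortest signed
    rotation from ``b`` to ``a``, with the antipodal tie resolved to +180.

    Parameters
    ----------
    a, b : float or array_like
        Angles in degrees (any finite real values; reduced mod 360).

    Returns
    -------
    float or ndarray
        ``(a - b) mod 360`` remapped into the half-open interval (-180, 180].
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("circ_diff requires finite angles")
    d = np.mod(a - b, 360.0)
    d = np.where(d > 180.0, d - 360.0, d)
    out = np.asarray(d, dtype=float)
    return out if out.ndim else float(out)


def wrap_angle(a):
    """Wrap angle(s) to [0, 360)."""
    out = np.mod(np.asarray(a, dtype=float), 360.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the task's generative process and scoring rule.

    Attributes
    ----------
    n_blocks, trials_per_block : int
        Session structure; the latent mean is re-drawn at each block start.
    hazard : float
        Per-trial change-point probability H.
    noise_sd : float
        SD (degrees) of the Gaussian outcome noise around the latent mean.
    n_positions : int
        Number of discrete locations the mean can jump to at a change point.
    bucket_halfwidth : float
        Half-width (degrees) of the bucket; hits are inclusive at the edge.
    reward_hit, reward_miss : int
        Points awarded for a catch / lost for a miss.
    min_jump : float
        Optional lower bound (degrees) on the circular distance between the
        old and new mean at a change point (0 = unconstrained, the default).
    """

    n_blocks: int = 4
    trials_per_block: int = 75
    hazard: float = 0.125
    noise_sd: float = 12.0
    n_positions: int = 360
    bucket_halfwidth: float = 20.0
    reward_hit: int = 10
    reward_miss: int = -10
    min_jump: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError(f"hazard must be in [0, 1], got {self.hazard}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if self.trials_per_block < 1 or self.n_blocks < 1:
            raise ValueError("block structure must be positive")
        if self.bucket_halfwidth < 0:
            raise ValueError("bucket_halfwidth must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SessionData:
    """One simulated session: per-block latent means, flags and outcomes."""

    config: TaskConfig
    block: np.ndarray = field(repr=False)  # block index per trial (0-based)
    trial: np.ndarray = field(repr=False)  # trial index within block (0-based)
    latent_mean: np.ndarray = field(repr=False)
    changepoint: np.ndarray = field(repr=False)  # bool: mean resampled this trial
    outcome: np.ndarray = field(repr=False)

    @property
    def n_trials(self) -> int:
        return self.outcome.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": self.block,
                "trial": self.trial,
                "latent_mean": self.latent_mean,
                "changepoint": self.changepoint,
                "outcome": self.outcome,
            }
        )


def _draw_mean(rng: np.random.Generator, config: TaskConfig, previous: float | None) -> float:
    """Uniform draw over the discrete change-point locations, optionally
    constrained to be at least ``min_jump`` degrees from the previous mean."""
    while True:
        mu = float(rng.integers(config.n_positions)) * (360.0 / config.n_positions)
        if previous is None or config.min_jump <= 0:
            return mu
        if abs(circ_diff(mu, previous)) >= config.min_jump:
            return mu


def generate_session(config: TaskConfig, seed: int | None = None) -> SessionData:
    """Simulate one session of the task.

    Each block starts with a fresh uniformly drawn latent mean (flagged as a
    change point).  On every subsequent trial the mean is resampled with
    probability ``config.hazard``; the outcome is the mean plus Gaussian noise,
    wrapped onto [0, 360).  Identical seeds give bit-identical sessions.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.n_blocks * config.trials_per_block
    block = np.repeat(np.arange(config.n_blocks), config.trials_per_block)
    trial = np.tile(np.arange(config.trials_per_block), config.n_blocks)
    latent = np.empty(n)
    flags = np.zeros(n, dtype=bool)
    mu: float | None = None
    for i in range(n):
        if trial[i] == 0:
            mu = _draw_mean(rng, config, None)
            flags[i] = True
        elif rng.random() < config.hazard:
            mu = _draw_mean(rng, config, mu)
            flags[i] = True
        latent[i] = mu
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
    outcome = wrap_angle(latent + noise)
    return SessionData(config=config, block=block, trial=trial,
                       latent_mean=latent, changepoint=flags, outcome=outcome)


def score_trial(outcome: float, bucket: float, config: TaskConfig) -> tuple[bool, int]:
    """Score one trial: hit iff the coin lands within the bucket (inclusive).

    Returns ``(hit, points)`` with points ``reward_hit`` or ``reward_miss``.
    """
    hit = abs(circ_diff(outcome, bucket)) <= config.bucket_halfwidth
    return bool(hit), config.reward_hit if hit else config.reward_miss


_SESSION_COLUMNS = ["block", "trial", "latent_mean", "changepoint", "outcome"]


def write_session(session: SessionData, path) -> None:
    """Write a session to CSV (block, trial, latent_mean, changepoint, outcome)."""
    session.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_session(path, config: TaskConfig | None = None) -> SessionData:
    """Read a session CSV written by :func:`write_session`."""
    df = pd.read_csv(path)
    missing = [c for c in _SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session file {path} missing columns: {missing}")
    return SessionData(
        config=config or TaskConfig(),
        block=df["block"].to_numpy(int),
        trial=df["trial"].to_numpy(int),
        latent_mean=df["latent_mean"].to_numpy(float),
        changepoint=df["changepoint"].to_numpy(bool),
        outcome=df["outcome"].to_numpy(float),
    )
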