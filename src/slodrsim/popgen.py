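"""Synthetic population generator.

Each virtual participant carries a true general-ability score *g* drawn on
the conventional IQ metric (mean 100, SD 15).  A battery of continuous test
scores is built so that test *i* has a specified population correlation
``r_i`` with *g* (a single-common-factor structure).  Optionally, every
participant also carries a multiplicative *disturbance* score ``d`` in
[0, 1] — low motivation, illness, linguistic confusion — that attenuates
all of their observed scores at once: ``observed = d * true``.  The shape
of the disturbance distribution (negatively skewed, symmetric, positively
skewed beta) is the experimental factor of the whole study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "BETA_PARAMS",
    "ConfigError",
    "SimulationConfig",
    "Population",
    "draw_true_g",
    "draw_loadings",
    "generate_true_scores",
    "draw_disturbance",
    "apply_disturbance",
    "simulate_population",
]

#: Beta(alpha, beta) parameters for the three disturbance shapes.
#: "negative" is negatively skewed (most people barely disturbed, a few
#: heavily), "normal" is approximately symmetric, "positive" is positively
#: skewed (most people heavily disturbed).
BETA_PARAMS: Mapping[str, tuple[float, float]] = {
    "negative": (9.0, 1.0),
    "normal": (9.0, 9.0),
    "positive": (1.0, 9.0),
}

DISTURBANCE_SHAPES = ("none", "negative", "normal", "positive")


class ConfigError(ValueError):
    """Raised when a :class:`SimulationConfig` is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters for one simulated population.

    Parameters
    ----------
    n_individuals
        Number of virtual participants per run.
    n_tests
        Number of test scores per participant (at least 3, so a one-factor
        model is identified).  In the traditional subgroup paradigm the
        first test doubles as the selection variable.
    score_mean, score_sd
        Marginal mean and SD of true g and of every undisturbed test score.
    loading_low, loading_high
        Bounds of the uniform distribution the population correlations
        (g-loadings) are drawn from.
    selection_loading
        If set, the first test's loading is fixed to this value instead of
        being drawn; used by the traditional paradigm (0.1 / 0.5 / 0.9).
    disturbance_shape
        One of ``none``, ``negative``, ``normal``, ``positive``.
    beta_params
        Shape → (alpha, beta) map for the disturbance distribution.
    seed
        Seed for the run's random generator.
    """

    n_individuals: int = 10_000
    n_tests: int = 15
    score_mean: float = 100.0
    score_sd: float = 15.0
    loading_low: float = 0.2
    loading_high: float = 0.9
    selection_loading: float | None = None
    disturbance_shape: str = "none"
    beta_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BETA_PARAMS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 2:
            raise ConfigError(f"n_individuals must be >= 2, got {self.n_individuals}")
        if self.n_tests < 3:
            raise ConfigError(
                f"n_tests must be >= 3 for factor-model identification, got {self.n_tests}"
            )
        if self.score_sd <= 0:
            raise ConfigError(f"score_sd must be positive, got {self.score_sd}")
        if not (0 < self.loading_low < self.loading_high < 1):
            raise ConfigError(
                "loading bounds must satisfy 0 < low < high < 1, got "
                f"({self.loading_low}, {self.loading_high})"
            )
        if self.selection_loading is not None and not (0 < self.selection_loading < 1):
            raise ConfigError(
                f"selection_loading must lie in (0, 1), got {self.selection_loading}"
            )
        if self.disturbance_shape not in DISTURBANCE_SHAPES:
            raise ConfigError(
                f"disturbance_shape must be one of {DISTURBANCE_SHAPES}, "
                f"got {self.disturbance_shape!r}"
            )
        if self.disturbance_shape != "none":
            a, b = self.beta_params[self.disturbance_shape]
            if a <= 0 or b <= 0:
                raise ConfigError(f"beta parameters must be positive, got ({a}, {b})")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class Population:
    """One simulated population.

    ``observed_scores`` equals ``true_scores`` row-scaled by ``disturbance``
    when a disturbance shape is active, and equals ``true_scores`` exactly
    otherwise (``disturbance`` is then all ones).
    """

    config: SimulationConfig
    true_g: np.ndarray          # (n,) latent trait on the IQ metric
    loadings: np.ndarray        # (k,) population correlations with g
    true_scores: np.ndarray     # (n, k)
    disturbance: np.ndarray     # (n,) in [0, 1]
    observed_scores: np.ndarray  # (n, k)


def draw_true_g(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw i.i.d. normal true-ability scores (mean 100, SD 15 by default)."""
    config.validate()
    if rng is None:
        rng = config.rng()
    return rng.normal(config.score_mean, config.score_sd, size=config.n_individuals)


def draw_loadings(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw uniform g-loadings; fix the first to ``selection_loading`` if set."""
    config.validate()
    if rng is None:
        rng = config.rng()
    loadings = rng.uniform(config.loading_low, config.loading_high, size=config.n_tests)
    if config.selection_loading is not None:
        loadings[0] = config.selection_loading
    return loadings


def generate_true_scores(
    true_g: np.ndarray,
    loadings: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Build undisturbed test scores with population correlation ``r_i`` to g.

    Column i is ``mean + sd * (r_i * z_g + sqrt(1 - r_i^2) * eps_i)`` with
    ``z_g`` the population-standardized true g and ``eps_i`` i.i.d. standard
    normal, so each column has population mean/SD equal to the configured
    score moments and population correlation exactly ``r_i`` with g.
    """
    if rng is None:
        rng = config.rng()
    true_g = np.asarray(true_g, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    if true_g.shape[0] < 2:
        raise ConfigError("need at least 2 individuals")
    if np.any(np.abs(loadings) >= 1):
        raise ValueError(f"loadings must have |r| < 1, got {loadings}")
    z_g = (true_g - config.score_mean) / config.score_sd
    eps = rng.standard_normal((true_g.shape[0], loadings.shape[0]))
    z = z_g[:, None] * loadings[None, :] + eps * np.sqrt(1.0 - loadings**2)[None, :]
    return config.score_mean + config.score_sd * z


def draw_disturbance(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw i.i.d. Beta disturbance scores in [0, 1] (lower = more disturbed)."""
    config.validate()
    if config.disturbance_shape == "none":
        raise ValueError("disturbance_shape is 'none'; caller must skip disturbance")
    if rng is None:
        rng = config.rng()
    a, b = config.beta_params[config.disturbance_shape]
    return rng.beta(a, b, size=config.n_individuals)


def apply_disturbance(true_scores: np.ndarray, disturbance: np.ndarray) -> np.ndarray:
    """Attenuate each participant's scores by their disturbance factor."""
    true_scores = np.asarray(true_scores, dtype=float)
    disturbance = np.asarray(disturbance, dtype=float)
    if true_scores.shape[0] != disturbance.shape[0]:
        raise ValueError(
            f"row count {true_scores.shape[0]} does not match "
            f"disturbance length {disturbance.shape[0]}"
        )
    if np.any(disturbance < 0) or np.any(disturbance > 1):
        raise ValueError("disturbance values must lie in [0, 1]")
    return true_scores * disturbance[:, None]


def simulate_population(config: SimulationConfig) -> Population:
    """Run the full generative recipe: g, loadings, scores, disturbance.

    All randomness comes from a single generator seeded by ``config.seed``,
    consumed in a fixed order (g, loadings, score noise, disturbance), so a
    given config always reproduces the identical population.
    """
    config.validate()
    rng = config.rng()
    true_g = draw_true_g(config, rng)
    loadings = draw_loadings(config, rng)
    true_scores = generate_true_scores(true_g, loadings, config, rng)
    if config.disturbance_shape == "none":
        disturbance = np.ones(config.n_individuals)
        observed = true_scores.copy()
    else:
        disturbance = draw_disturbance(config, rng)
        observed = apply_disturbance(true_scores, disturbance)
    return Population(
        config=config,
        true_g=true_g,
        loadings=loadings,
        true_scores=true_scores,
        disturbance=disturbance,
        observed_scores=observed,
    )
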