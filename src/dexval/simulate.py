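"""Synthetic data with the hierarchical mixture structure the assessments assume.

Each gene draws a variance from a scaled inverse-chi-square prior
(``sigma_i^2 ~ d0 * s0^2 / chi2(d0)``), is null with probability ``pi0``
(true log-effect ``delta_i = 0``) or differentially expressed with
``delta_i ~ Normal(0, effect_sd^2)``, and emits normal log-scale
replicates.  For paired designs the per-replicate log-ratio
``d_{i,j} ~ Normal(delta_i, sigma_i^2)`` is split cosmetically into two
channels (only the difference matters downstream); for two-group designs
each group has its own mean and, optionally, its own variance draw.

Presets mirror the shapes of the two benchmark studies the assessments
were designed around: a paired dual-channel tomato-ripening experiment
(m = 13440, n = 5 or 6, high null proportion) and the MAQC rat-liver
two-group comparison (m ~ 27000, n = n' = 6, many differentially
expressed genes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .datamodel import GroupedExpression

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate",
    "worked_example_fixture",
    "preset",
    "PRESETS",
]


@dataclass
class SimulationConfig:
    m: int = 1000
    n: int = 6
    n_prime: int = 6
    pi0: float = 0.9
    effect_sd: float = 1.0        # SD of true log-effects (natural-log units)
    var_prior_df: float = 4.0     # d0
    var_prior_scale: float = 0.05  # s0^2
    paired: bool = True
    unequal_group_variances: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must lie in [0, 1]")
        if self.var_prior_df <= 0 or self.var_prior_scale <= 0:
            raise ValueError("variance prior parameters must be positive")
        if self.paired and self.n != self.n_prime:
            raise ValueError("paired designs need n == n'")


@dataclass
class SyntheticTruth:
    is_null: np.ndarray
    delta: np.ndarray
    sigma2: np.ndarray
    sigma2_prime: np.ndarray


def generate(config: SimulationConfig) -> tuple[GroupedExpression, SyntheticTruth]:
    """Draw a fully reproducible dataset and its generating truth."""
    rng = np.random.default_rng(config.seed)
    m = config.m
    d0, s02 = config.var_prior_df, config.var_prior_scale
    sigma2 = d0 * s02 / rng.chisquare(d0, size=m)
    is_null = rng.random(m) < config.pi0
    delta = np.where(is_null, 0.0, rng.normal(0.0, config.effect_sd, size=m))
    gene_ids = [f"g{i + 1}" for i in range(m)]

    if config.paired:
        d = rng.normal(delta[:, None], np.sqrt(sigma2)[:, None], size=(m, config.n))
        baseline = rng.normal(0.0, 0.1, size=(m, config.n))
        data = GroupedExpression(gene_ids, baseline, baseline + d, paired=True)
        return data, SyntheticTruth(is_null, delta, sigma2, sigma2.copy())

    if config.unequal_group_variances:
        sigma2p = d0 * s02 / rng.chisquare(d0, size=m)
    else:
        sigma2p = sigma2
    mu = rng.normal(0.0, 1.0, size=m)
    x = rng.normal(mu[:, None], np.sqrt(sigma2)[:, None], size=(m, config.n))
    xp = rng.normal((mu + delta)[:, None], np.sqrt(sigma2p)[:, None],
                    size=(m, config.n_prime))
    data = GroupedExpression(gene_ids, x, xp, paired=False)
    return data, SyntheticTruth(is_null, delta, sigma2, sigma2p)


def worked_example_fixture() -> GroupedExpression:
    """The single-gene paired illustration: x' = (0, 1, 1), x = (2, 0, -2)."""
    return GroupedExpression(
        ["gene_i"], np.array([[2.0, 0.0, -2.0]]), np.array([[0.0, 1.0, 1.0]]),
        paired=True,
    )


PRESETS = {
    "tomato_paired": SimulationConfig(m=13440, n=6, n_prime=6, pi0=0.9, paired=True),
    "tomato_breaker": SimulationConfig(m=13440, n=5, n_prime=5, pi0=0.9, paired=True),
    "tomato_unpaired": SimulationConfig(m=13440, n=6, n_prime=6, pi0=0.85, paired=False),
    "maqc": SimulationConfig(m=27000, n=6, n_prime=6, pi0=0.6, paired=False),
}


def preset(label: str, **overrides) -> SimulationConfig:
    """A named study-shaped configuration (pure data; no RNG until generate)."""
    try:
        base = PRESETS[label]
    except KeyError:
        raise ValueError(f"unknown preset {label!r}; choose from {sorted(PRESETS)}")
    return replace(base, **overrides)
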