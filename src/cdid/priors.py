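"""Prior specification: empirical-Bayes inverse-gamma moment matching and the
catalogue of remaining priors (with the sensitivity variants).

Clinic-level outcome and age variances get a shared data-informed IG(a, b)
prior: the first two moments of the inverse gamma are matched to the mean and
variance of the observed clinic-level sample variances, giving

    a = E² / V + 2,    b = E · (E² / V + 1),

so that a > 2 always holds and the prior mean b/(a−1) and variance
b²/((a−1)²(a−2)) reproduce (E, V) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np


@dataclass(frozen=True)
class IGHyper:
    """Inverse-gamma hyperparameters (shape a > 2, scale b > 0)."""

    shape: float
    scale: float
    label: str = "outcome"

    def __post_init__(self):
        if not (self.shape > 2):
            raise ValueError(f"shape must exceed 2 for a finite prior variance, got {self.shape}")
        if not (self.scale > 0):
            raise ValueError(f"scale must be positive, got {self.scale}")

    @property
    def mean(self) -> float:
        return self.scale / (self.shape - 1.0)

    @property
    def variance(self) -> float:
        a, b = self.shape, self.scale
        return b * b / ((a - 1.0) ** 2 * (a - 2.0))


@dataclass
class PriorConfig:
    """Prior choices, including the sensitivity-analysis variants.

    * ``variance_prior``: log-uniform π(v) ∝ 1/v on each of τ², λ², ζ², ω²
      (default); ``"inverse_gamma"`` swaps in a proper IG(``variance_ig``)
      prior (conjugate; the log-uniform default is its a0=b0=0 limit).
    * ``proportion_prior``: ``"uniform"`` → Beta(1,1); ``"jeffreys"`` →
      Beta(1/2, 1/2) on the clinic-year proportion parameters.
    * ``ig_variance_multiplier``: scales the plug-in variance before moment
      matching (the quadrupled-variance sensitivity variant uses 4).
    * ``system_effect_prior``: ``"hierarchical_normal"`` keeps ψ_s ~ N(0, ζ²),
      υ_s ~ N(0, ω²); ``"flat"`` gives them improper flat priors.
    * ``coef_prior_precision``: ridge precision on Θ and Θ~ (0 = flat, the
      default non-informative setting).
    """

    variance_prior: Literal["log_uniform", "inverse_gamma"] = "log_uniform"
    variance_ig: tuple[float, float] = (3.0, 2.0)
    proportion_prior: Literal["uniform", "jeffreys"] = "uniform"
    ig_variance_multiplier: float = 1.0
    system_effect_prior: Literal["hierarchical_normal", "flat"] = "hierarchical_normal"
    coef_prior_precision: float = 0.0

    def __post_init__(self):
        if self.ig_variance_multiplier <= 0:
            raise ValueError("ig_variance_multiplier must be positive")
        if self.coef_prior_precision < 0:
            raise ValueError("coef_prior_precision must be >= 0")

    @property
    def beta_prior(self) -> tuple[float, float]:
        return (1.0, 1.0) if self.proportion_prior == "uniform" else (0.5, 0.5)

    @property
    def variance_prior_ab(self) -> tuple[float, float]:
        """(a0, b0) of the conjugate IG prior; (0, 0) encodes log-uniform."""
        return self.variance_ig if self.variance_prior == "inverse_gamma" else (0.0, 0.0)

    def to_dict(self) -> dict:
        return {
            "variance_prior": self.variance_prior,
            "variance_ig": list(self.variance_ig),
            "proportion_prior": self.proportion_prior,
            "ig_variance_multiplier": self.ig_variance_multiplier,
            "system_effect_prior": self.system_effect_prior,
            "coef_prior_precision": self.coef_prior_precision,
        }


def moment_match_inverse_gamma(mean: float, variance: float, label: str = "outcome") -> IGHyper:
    """IG hyperparameters whose first two moments equal (mean, variance)."""
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if variance <= 0:
        raise ValueError(f"variance must be positive, got {variance}")
    ratio = mean * mean / variance
    return IGHyper(shape=ratio + 2.0, scale=mean * (ratio + 1.0), label=label)


def empirical_bayes_from_sample_variances(
    sample_variances: Sequence[float],
    config: PriorConfig | None = None,
    label: str = "outcome",
) -> IGHyper:
    """Empirical-Bayes IG prior from per-clinic sample variances.

    The plug-in moments are the mean of the inputs and their (n−1)-denominator
    variance; ``config.ig_variance_multiplier`` scales the latter before
    matching (sensitivity variant).  All-equal inputs leave the variance zero
    and are rejected: supply an explicit prior instead.
    """
    v = np.asarray(sample_variances, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need sample variances from at least 2 clinics")
    e_hat = float(v.mean())
    var_hat = float(v.var(ddof=1))
    if var_hat <= 0:
        raise ValueError(
            "sample variances are all equal; the moment-matched prior is degenerate — "
            "supply an explicit IGHyper instead"
        )
    if config is not None:
        var_hat *= config.ig_variance_multiplier
    return moment_match_inverse_gamma(e_hat, var_hat, label=label)
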