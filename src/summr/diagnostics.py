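"""Post-hoc power and two-sample overlap diagnostics.

Two design-level sanity checks for a summary-data MR analysis:

* :func:`posthoc_power` — the probability of rejecting the null at level
  ``alpha`` when the true causal effect is ``b`` (standardized units), given
  the outcome-sample size ``n`` and the fraction ``r2`` of exposure variance
  explained by the instrument. Under unit-variance exposure and outcome the
  IV estimate's z-statistic is approximately normal with non-centrality
  ncp = |b| sqrt(n r2), giving
  power = 1 - Phi(z_{1-a/2} - ncp) + Phi(-z_{1-a/2} - ncp).
* :func:`overlap_fraction` — the percentage of the outcome sample that also
  contributed to the exposure GWAS, 100 * overlap * n_exposure / n_outcome;
  small values mean winner's-curse/overlap bias is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .exceptions import ConfigError


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for the post-hoc power calculation.

    alpha: two-sided significance level in (0, 1).
    b: hypothesized causal effect per exposure unit, in outcome SDs.
    n: outcome-sample size.
    r2: instrument variance explained in the exposure, in (0, 1).
    """

    alpha: float
    b: float
    n: int
    r2: float

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha {self.alpha} outside (0, 1)")
        if self.n <= 0:
            raise ConfigError("n must be positive")
        if not (0.0 < self.r2 < 1.0):
            raise ConfigError(f"r2 {self.r2} outside (0, 1)")


@dataclass(frozen=True)
class OverlapSpec:
    """Inputs for the sample-overlap percentage."""

    n_exposure: int
    overlap_proportion: float
    n_outcome: int

    def __post_init__(self):
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ConfigError("sample sizes must be positive")
        if not (0.0 <= self.overlap_proportion <= 1.0):
            raise ConfigError(
                f"overlap_proportion {self.overlap_proportion} outside [0, 1]"
            )


def posthoc_power(spec: PowerSpec) -> float:
    """Two-sided power for the IV test of a standardized effect ``b``.

    Exactly ``alpha`` when b = 0; strictly increasing in |b|, n and r2.
    """
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    ncp = abs(spec.b) * (spec.n * spec.r2) ** 0.5
    return float(stats.norm.sf(z - ncp) + stats.norm.cdf(-z - ncp))


def overlap_fraction(spec: OverlapSpec) -> float:
    """Percentage of the outcome sample shared with the exposure sample."""
    return 100.0 * spec.overlap_proportion * spec.n_exposure / spec.n_outcome
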