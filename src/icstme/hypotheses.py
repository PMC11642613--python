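"""Bootstrap comparison of mechanistic hypotheses via the DSS statistic.

An alternate hypothesis ("TAMs do not exhaust T cells", "melanoma cells do
not exhaust T cells") is encoded by zeroing the corresponding exhaustion
rate, re-fitting the remaining one, and asking whether the alternate model
predicts clinical response as well as the base model.  The test statistic
for a bootstrap resample beta of the slides is the log difference of
success scores,

    DSS_beta = ln score_alt(beta) - ln score_beta(beta),

computed from the *cached* per-slide prediction frequencies (no
re-simulation inside the bootstrap loop), with the same resampled slide
multiset used for both models (paired resampling).  Equality of the models
is rejected at level alpha when the one-sided (1 - alpha) upper confidence
bound for DSS lies below zero; the reported p-value is the fraction of
replicates with DSS_beta >= 0 (alternate at least as good as base).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .calibration import PredictionFrequencies
from .cohort import ValidationError
from .simulator import RateParams

FITTED_EXHAUSTION_RATES = ("bC", "bM")


@dataclass
class DSSDistribution:
    samples: np.ndarray  # DSS_beta, length n_boot
    p_value: float  # fraction of replicates with DSS >= 0
    ci_upper: float  # one-sided (1 - alpha) upper bound for DSS
    alpha: float
    base_label: str = "base"
    alt_label: str = "alt"

    @property
    def n_boot(self) -> int:
        return self.samples.size

    @property
    def reject(self) -> bool:
        """True when the one-sided CI for DSS excludes zero (alt is worse)."""
        return self.ci_upper < 0


def bootstrap_dss(
    f_base: PredictionFrequencies,
    f_alt: PredictionFrequencies,
    b: float = 0.1,
    n_boot: int = 100_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> DSSDistribution:
    """Bootstrap distribution of the log score difference over slides.

    Each replicate draws N slides with replacement from the N slides and
    evaluates both models' scores on that multiset using the cached
    frequencies.
    """
    if list(f_base.slide_ids) != list(f_alt.slide_ids):
        raise ValidationError("base and alternate frequencies index different slides")
    if not 0 <= b < 1:
        raise ValidationError("b must lie in [0, 1)")
    n = f_base.f.size
    if n == 0:
        raise ValidationError("empty frequency vectors")
    log_base = np.log((1 - b) * f_base.f + b / 2)
    log_alt = np.log((1 - b) * f_alt.f + b / 2)
    per_slide = log_alt - log_base
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = per_slide[idx].sum(axis=1)
    p = float(np.mean(samples >= 0))
    ci_upper = float(np.quantile(samples, 1 - alpha))
    return DSSDistribution(
        samples=samples,
        p_value=p,
        ci_upper=ci_upper,
        alpha=alpha,
        base_label=f_base.theta_label or "base",
        alt_label=f_alt.theta_label or "alt",
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: each p-value times the number of tests, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < 1:
        raise ValidationError("number of tests must be >= 1")
    return np.minimum(1.0, m * p)


def make_alternate(params: RateParams, which: str) -> RateParams:
    """Zero one fitted exhaustion rate to encode an alternate hypothesis.

    The caller re-fits the remaining exhaustion rate before testing
    (one-parameter re-estimation).
    """
    if which not in FITTED_EXHAUSTION_RATES:
        raise ValidationError(
            f"unknown exhaustion rate {which!r}; expected one of {FITTED_EXHAUSTION_RATES}"
        )
    return replace(params, **{which: 0.0})
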