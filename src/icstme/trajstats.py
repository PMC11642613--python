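"""Ensemble statistics of stochastic population trajectories.

Late in a simulated treatment course the melanoma population of many
slides grows like a linear pure-birth (Yule) process: trajectories stop
crossing, the ensemble autocorrelation with a late reference time decays
slowly, and the coefficient of variation plateaus.  This module computes
the empirical diagnostics — the ensemble autocorrelation

    A(t, t_i) = (1/N) sum_a [C_a(t_i) - mu(t_i)] [C_a(t) - mu(t)]
                / (sigma(t_i) sigma(t)),

with population (divisor-N) moments, the coefficient of variation
sigma/mu, and the transition time tau* where the mean population is
minimal — and the matching Yule-process closed forms for comparison.

Yule process with birth rate lambda started at n0 cells:

    E[N(t)]   = n0 exp(lambda t)
    Var[N(t)] = n0 exp(lambda t) (exp(lambda t) - 1)
    Corr[N(t_i), N(t)] = exp(lambda (t - t_i) / 2)
                         * sqrt((exp(lambda t_i) - 1) / (exp(lambda t) - 1))

The correlation follows from the branching property
E[N(t) | N(t_i)] = N(t_i) exp(lambda (t - t_i)), which gives
Cov[N(t_i), N(t)] = exp(lambda (t - t_i)) Var[N(t_i)]; for t >> t_i it
approaches the constant sqrt(1 - exp(-lambda t_i)) < 1, the slow late-time
decay characteristic of committed exponential growth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort import Trajectory, ValidationError


@dataclass
class EnsembleTrajectories:
    """Per-sample counts of one cell type on a common time grid."""

    times: np.ndarray  # (n_times,)
    counts: np.ndarray  # (n_samples, n_times)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != self.times.size:
            raise ValidationError("counts must be (n_samples, n_times) matching the grid")
        if self.counts.shape[0] < 1:
            raise ValidationError("need at least one sample")

    @classmethod
    def from_trajectories(
        cls, trajs: Sequence[Trajectory], cell_type: str = "melanoma"
    ) -> "EnsembleTrajectories":
        times = trajs[0].times
        for tr in trajs[1:]:
            if tr.times.shape != times.shape or not np.allclose(tr.times, times):
                raise ValidationError("trajectories must share one recording grid")
        return cls(times, np.stack([tr.count(cell_type) for tr in trajs]))

    @property
    def N(self) -> int:
        return self.counts.shape[0]

    def mu(self) -> np.ndarray:
        """Ensemble mean at each grid time."""
        return self.counts.mean(axis=0)

    def sigma(self) -> np.ndarray:
        """Ensemble standard deviation (population convention, divisor N)."""
        return self.counts.std(axis=0, ddof=0)

    def _index(self, t: float) -> int:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-9 * max(1.0, abs(t)):
            raise ValidationError(f"time {t} not on the recording grid")
        return i


def autocorrelation(ens: EnsembleTrajectories, ti: float, t: float) -> float:
    """Ensemble correlation between the populations at times ``ti`` and ``t``."""
    i = ens._index(ti)
    j = ens._index(t)
    sig = ens.sigma()
    if sig[i] == 0 or sig[j] == 0:
        raise ValidationError("autocorrelation undefined: zero ensemble variance")
    mu = ens.mu()
    dev_i = ens.counts[:, i] - mu[i]
    dev_j = ens.counts[:, j] - mu[j]
    return float((dev_i * dev_j).mean() / (sig[i] * sig[j]))


def autocorrelation_curve(ens: EnsembleTrajectories, ti: float) -> np.ndarray:
    """A(t, ti) at every grid time with nonzero variance (NaN elsewhere)."""
    i = ens._index(ti)
    sig = ens.sigma()
    mu = ens.mu()
    out = np.full(ens.times.size, np.nan)
    if sig[i] == 0:
        return out
    dev_i = ens.counts[:, i] - mu[i]
    ok = sig > 0
    dev = ens.counts[:, ok] - mu[ok]
    out[ok] = (dev_i[:, None] * dev).mean(axis=0) / (sig[i] * sig[ok])
    return out


def coefficient_of_variation(ens: EnsembleTrajectories, t: float) -> float:
    """sigma(t) / mu(t) of the ensemble."""
    j = ens._index(t)
    mu = ens.mu()[j]
    if mu <= 0:
        raise ValidationError("coefficient of variation undefined: mean is zero")
    return float(ens.sigma()[j] / mu)


@dataclass
class TransitionTime:
    tau_star: float  # hours
    index: int
    at_endpoint: bool  # argmin fell on the grid boundary (monotone mean)
    estimator: str = "argmin_mean"


def transition_time(ens: EnsembleTrajectories) -> TransitionTime:
    """Time where the ensemble mean population is minimal (first minimum).

    Marks the crossover from the early mixing stage (trajectories crossing,
    fast-decaying autocorrelation) to the dispersed growth stage; an
    endpoint argmin is flagged since a monotone mean has no interior
    turning point.
    """
    if ens.times.size < 3:
        raise ValidationError("need >= 3 time points")
    mu = ens.mu()
    i = int(np.argmin(mu))  # first minimum under ties
    return TransitionTime(
        tau_star=float(ens.times[i]),
        index=i,
        at_endpoint=i in (0, ens.times.size - 1),
    )


@dataclass
class YuleFit:
    lam: float  # birth rate, h^-1
    n0: float  # effective initial count at window start
    t_start: float
    t_end: float

    def mean(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.n0 * np.exp(self.lam * (np.asarray(t, float) - self.t_start))


def fit_yule(ens: EnsembleTrajectories, window: tuple[float, float]) -> YuleFit:
    """Least-squares exponential fit of the ensemble mean on a time window.

    Fits a line to (t, ln mu(t)) — the Yule mean is exactly exponential, so
    regressing the log of the ensemble mean (not the mean of logs, which is
    biased for branching processes) recovers the birth rate.  ``n0`` is the
    fitted mean extrapolated to the window start.
    """
    t_start, t_end = window
    mask = (ens.times >= t_start - 1e-9) & (ens.times <= t_end + 1e-9)
    if mask.sum() < 2:
        raise ValidationError("fit window must contain at least 2 grid points")
    mu = ens.mu()[mask]
    if (mu <= 0).any():
        raise ValidationError("ensemble mean must be positive throughout the fit window")
    tt = ens.times[mask]
    res = stats.linregress(tt, np.log(mu))
    lam = float(res.slope)
    n0 = float(np.exp(res.intercept + lam * tt[0]))
    return YuleFit(lam=lam, n0=n0, t_start=float(tt[0]), t_end=float(tt[-1]))


def yule_moments(n0: float, lam: float, t: float) -> tuple[float, float]:
    """Mean and variance of a Yule process at time ``t`` started from ``n0``."""
    if n0 < 1 or lam < 0 or t < 0:
        raise ValidationError("require n0 >= 1, lam >= 0, t >= 0")
    g = np.exp(lam * t)
    return float(n0 * g), float(n0 * g * (g - 1.0))


def yule_autocorrelation(n0: float, lam: float, ti: float, t: float) -> float:
    """Closed-form Corr[N(ti), N(t)] of a Yule process (independent of n0).

    Requires 0 < ti <= t and lam > 0; at ti = 0 the variance vanishes and
    the correlation is undefined.
    """
    if lam <= 0:
        raise ValidationError("lam must be > 0")
    if ti <= 0:
        raise ValidationError("autocorrelation undefined at ti = 0 (zero variance)")
    if t < ti:
        raise ValidationError("require ti <= t")
    # exp(lam*(t-ti)/2) * sqrt((e^{lam ti}-1)/(e^{lam t}-1)), written with
    # expm1 for small-exponent accuracy
    return float(
        np.exp(lam * (t - ti) / 2.0) * np.sqrt(np.expm1(lam * ti) / np.expm1(lam * t))
    )
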