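"""Response classification, prediction success frequencies, and rate fitting.

A simulated slide is classified by the fold change of its melanoma
population between t = 0 and the end time T: fold change < 1 predicts a
responder, >= 1 a nonresponder (a fold change of exactly 1 — no net
shrinkage — is read as nonresponse; the tie rule is configurable).  The
*prediction success frequency* ``f_i`` of slide i is the fraction of
independent stochastic simulations whose predicted label matches the
clinical label.  Per-slide frequencies combine into the cohort score

    score(theta) = prod_i [ (1 - b) * f_i(theta) + b / 2 ],

where ``b`` (default 0.1) caps the confidence placed in any one slide: a
1 mm tissue core is an imperfect sample of the tumor, so even a perfect
model can predict a slide no better than ``1 - b/2`` while pure chance
gets ``b/2``.  The two exhaustion rates (bC, bM) are estimated by
maximizing the score over a grid, using common random numbers (the same
per-slide simulation seeds at every grid point) for variance reduction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    NONRESPONDER,
    RESPONDER,
    Cohort,
    LatticeState,
    Slide,
    Trajectory,
    ValidationError,
    slide_to_lattice,
)
from .simulator import RateParams, SimConfig, sim_seeds, simulate


@dataclass
class PredictionFrequencies:
    """Per-slide prediction success frequencies for one parameter set."""

    slide_ids: list[str]
    f: np.ndarray  # values in [0, 1], one per slide
    n_sims: int
    theta_label: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if len(self.slide_ids) != self.f.size:
            raise ValidationError("one frequency per slide required")
        if ((self.f < 0) | (self.f > 1)).any():
            raise ValidationError("frequencies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"slide_id": self.slide_ids, "f": self.f})


@dataclass
class ScoreValue:
    value: float
    b: float
    N: int


@dataclass
class FitResult:
    bC: float
    bM: float
    bc_values: np.ndarray
    bm_values: np.ndarray
    log_scores: np.ndarray  # (len(bc_values), len(bm_values))
    n_sims: int
    seed: int


def fold_change(traj: Trajectory) -> float:
    """Melanoma count at the end time divided by the count at t = 0."""
    m0 = int(traj.melanoma[0])
    if m0 <= 0:
        raise ValidationError("fold change undefined: zero melanoma cells at t = 0")
    return float(traj.melanoma[-1]) / m0


def predict_response(fc: float, tie: str = NONRESPONDER) -> str:
    """Responder iff the melanoma population shrank (fold change < 1)."""
    if not np.isfinite(fc) or fc < 0:
        raise ValidationError(f"invalid fold change {fc!r}")
    if fc < 1:
        return RESPONDER
    if fc > 1:
        return NONRESPONDER
    return tie


def prediction_frequency(
    slide: Slide,
    params: RateParams,
    config: SimConfig = SimConfig(),
    n_sims: int = 100,
    seed: int = 0,
    slide_key: int = 0,
    lattice: LatticeState | None = None,
) -> float:
    """Fraction of ``n_sims`` simulations matching the slide's clinical label.

    Simulation seeds depend only on (seed, slide_key), not on the rate
    parameters, so repeated calls across a parameter grid reuse common
    random numbers.  ``lattice`` may be passed to skip re-rasterization.
    """
    if slide.response is None:
        raise ValidationError(f"slide {slide.slide_id} has no response label")
    if lattice is None:
        lattice = slide_to_lattice(slide, cap=config.cap)
    m0 = lattice.type_counts()["melanoma"]
    if m0 == 0:
        raise ValidationError(f"slide {slide.slide_id}: zero melanoma cells")
    seeds = sim_seeds(seed, slide_key, n_sims)
    hits = 0
    for s in seeds:
        traj = simulate(lattice, params, config, seed=int(s))
        if predict_response(fold_change(traj)) == slide.response:
            hits += 1
    return hits / n_sims


def cohort_frequencies(
    cohort: Cohort,
    params: RateParams,
    config: SimConfig = SimConfig(),
    n_sims: int = 100,
    seed: int = 0,
    theta_label: str = "",
    lattices: Sequence[LatticeState] | None = None,
) -> PredictionFrequencies:
    """Prediction success frequencies for every slide of a labeled cohort."""
    if lattices is None:
        lattices = [slide_to_lattice(s, cap=config.cap) for s in cohort]
    f = [
        prediction_frequency(s, params, config, n_sims, seed, slide_key=i, lattice=lat)
        for i, (s, lat) in enumerate(zip(cohort, lattices))
    ]
    return PredictionFrequencies(
        [s.slide_id for s in cohort], np.array(f), n_sims, theta_label, seed
    )


def score(freqs: PredictionFrequencies | Sequence[float], b: float = 0.1) -> ScoreValue:
    """Cohort prediction success score: prod_i [(1 - b) f_i + b/2]."""
    f = freqs.f if isinstance(freqs, PredictionFrequencies) else np.asarray(freqs, float)
    if f.size == 0:
        raise ValidationError("empty frequency list")
    if not 0 <= b < 1:
        raise ValidationError("b must lie in [0, 1)")
    return ScoreValue(float(np.prod((1 - b) * f + b / 2)), b, int(f.size))


def log_score(f: np.ndarray, b: float = 0.1) -> float:
    """Numerically stable log of the score (sum of per-slide log terms)."""
    return float(np.log((1 - b) * np.asarray(f, float) + b / 2).sum())


def fit_exhaustion_rates(
    cohort: Cohort,
    base_params: RateParams,
    bc_values: Sequence[float],
    bm_values: Sequence[float],
    config: SimConfig = SimConfig(),
    n_sims: int = 100,
    seed: int = 0,
    b: float = 0.1,
) -> FitResult:
    """Grid search for the exhaustion rates (bC, bM) maximizing the score.

    Every slide must carry a response label and at least one melanoma cell.
    The full log-score surface is returned; ties are broken toward the
    smaller (bC, bM) pair in lexicographic order.  A single grid value for
    one axis turns this into the one-parameter re-estimation used when an
    exhaustion mechanism is switched off.
    """
    bc_values = np.asarray(sorted(bc_values), dtype=float)
    bm_values = np.asarray(sorted(bm_values), dtype=float)
    if bc_values.size == 0 or bm_values.size == 0:
        raise ValidationError("empty parameter grid")
    for s in cohort:
        if s.response is None:
            raise ValidationError(f"slide {s.slide_id} has no response label")
    lattices = [slide_to_lattice(s, cap=config.cap) for s in cohort]
    for s, lat in zip(cohort, lattices):
        if lat.type_counts()["melanoma"] == 0:
            raise ValidationError(f"slide {s.slide_id}: zero melanoma cells")
    surface = np.empty((bc_values.size, bm_values.size))
    best = (-np.inf, 0, 0)
    for i, bc in enumerate(bc_values):
        for j, bm in enumerate(bm_values):
            params = base_params.with_(bC=float(bc), bM=float(bm))
            freqs = cohort_frequencies(
                cohort, params, config, n_sims, seed, lattices=lattices
            )
            ls = log_score(freqs.f, b)
            surface[i, j] = ls
            if ls > best[0]:  # strict: first (lexicographically smallest) max wins
                best = (ls, i, j)
    return FitResult(
        bC=float(bc_values[best[1]]),
        bM=float(bm_values[best[2]]),
        bc_values=bc_values,
        bm_values=bm_values,
        log_scores=surface,
        n_sims=n_sims,
        seed=seed,
    )
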