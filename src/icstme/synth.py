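"""Synthetic slide and cohort generators.

Emulates the spatial structure seen in melanoma tissue microarrays — 1 x 1
mm cores holding hundreds to thousands of cells of several phenotypes with
strong patient-to-patient variation in density and clustering — so that
every downstream stage (spatial statistics, simulation, calibration,
hypothesis testing, fencing) can be exercised without any external data.

Three spatial patterns are supported per cell type:

* ``Uniform`` — complete spatial randomness;
* ``Clustered`` — a Thomas-like parent/offspring process (parents uniform,
  offspring isotropic Gaussian around a random parent; out-of-bounds
  offspring are re-drawn so requested counts are exact);
* ``Segregated`` — the type is confined to an axis-aligned band of the
  slide, reproducing the segregated tumor/immune compartments seen in some
  patient cores.

Cohorts can be labeled with fixed responder/nonresponder assignments or by
forward simulation: each slide is evolved under given kinetic rates and
labeled by the majority melanoma fold-change direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    MODEL_TYPES,
    NONRESPONDER,
    RESPONDER,
    Cohort,
    Slide,
    ValidationError,
    slide_to_lattice,
)
from .simulator import RateParams, SimConfig, sim_seeds, simulate


@dataclass(frozen=True)
class Uniform:
    """Homogeneous random points over the whole slide."""

    def sample(self, n: int, width: float, height: float, rng: np.random.Generator) -> np.ndarray:
        pts = np.empty((n, 2))
        pts[:, 0] = rng.uniform(0, width, n)
        pts[:, 1] = rng.uniform(0, height, n)
        return pts


@dataclass(frozen=True)
class Clustered:
    """Thomas-like process: uniform parents, Gaussian offspring."""

    n_parents: int = 5
    offspring_sd: float = 20.0  # um

    def sample(self, n: int, width: float, height: float, rng: np.random.Generator) -> np.ndarray:
        if self.n_parents < 1 or self.offspring_sd <= 0:
            raise ValidationError("Clustered requires n_parents >= 1 and offspring_sd > 0")
        parents = np.column_stack(
            [rng.uniform(0, width, self.n_parents), rng.uniform(0, height, self.n_parents)]
        )
        pts = np.empty((n, 2))
        for i in range(n):
            while True:
                p = parents[rng.integers(self.n_parents)]
                xy = p + rng.normal(0.0, self.offspring_sd, 2)
                if 0 <= xy[0] < width and 0 <= xy[1] < height:
                    pts[i] = xy
                    break
        return pts


@dataclass(frozen=True)
class Segregated:
    """Type confined to the band ``lo <= axis-coordinate < hi``."""

    axis: str = "x"
    lo: float = 0.0
    hi: float = 500.0

    def sample(self, n: int, width: float, height: float, rng: np.random.Generator) -> np.ndarray:
        if self.axis not in ("x", "y"):
            raise ValidationError(f"Segregated axis must be 'x' or 'y', got {self.axis!r}")
        limit = width if self.axis == "x" else height
        lo, hi = max(0.0, self.lo), min(limit, self.hi)
        if not lo < hi:
            raise ValidationError("Segregated band is empty")
        pts = np.empty((n, 2))
        along = rng.uniform(lo, hi, n)
        if self.axis == "x":
            pts[:, 0] = along
            pts[:, 1] = rng.uniform(0, height, n)
        else:
            pts[:, 0] = rng.uniform(0, width, n)
            pts[:, 1] = along
        return pts


Pattern = Uniform | Clustered | Segregated


@dataclass(frozen=True)
class SlideSpec:
    """Recipe for one synthetic slide: per-type counts and spatial patterns."""

    slide_id: str
    counts: Mapping[str, int]
    patterns: Mapping[str, Pattern] = field(default_factory=dict)
    width: float = 1000.0
    height: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for t, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"negative count for {t!r}")


def generate_slide(spec: SlideSpec) -> Slide:
    """Draw a slide with exactly the requested per-type counts."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cell_type in sorted(spec.counts):
        n = int(spec.counts[cell_type])
        if n == 0:
            continue
        pattern = spec.patterns.get(cell_type, Uniform())
        pts = pattern.sample(n, spec.width, spec.height, rng)
        rows.append(
            pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "cell_type": cell_type})
        )
    cells = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["x", "y", "cell_type"])
    )
    return Slide(spec.slide_id, cells, width=spec.width, height=spec.height)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``labels`` is either an explicit sequence of response labels (one per
    slide) or the string ``"simulate"``, in which case each slide is labeled
    by the majority fold-change direction over ``n_sims`` forward
    simulations of the lattice model.
    """

    slide_specs: Sequence[SlideSpec]
    labels: Sequence[str] | str = "simulate"
    n_sims: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.slide_specs) < 1:
            raise ValidationError("cohort needs at least one slide")
        if not isinstance(self.labels, str) and len(self.labels) != len(self.slide_specs):
            raise ValidationError("one label per slide required")


def generate_cohort(
    spec: CohortSpec,
    params: RateParams | None = None,
    config: SimConfig = SimConfig(),
) -> Cohort:
    """Generate slides and attach response labels.

    Forward-simulated labeling is a coarse stand-in for a prediction
    frequency: a slide whose melanoma population shrinks (fold change < 1)
    in the majority of ``n_sims`` runs is a responder, otherwise a
    nonresponder (ties count as nonresponse, consistent with the
    fold-change tie rule).
    """
    slides = [generate_slide(s) for s in spec.slide_specs]
    if isinstance(spec.labels, str):
        if spec.labels != "simulate":
            raise ValidationError(f"unknown labeling rule {spec.labels!r}")
        if params is None:
            raise ValidationError("forward-simulated labeling requires rate parameters")
        for i, slide in enumerate(slides):
            lattice = slide_to_lattice(slide, l0=10.0, cap=config.cap)
            m0 = lattice.type_counts()["melanoma"]
            if m0 == 0:
                raise ValidationError(
                    f"slide {slide.slide_id}: zero melanoma cells, fold change undefined"
                )
            seeds = sim_seeds(spec.seed, 1000 + i, spec.n_sims)
            shrink = 0
            for s in seeds:
                traj = simulate(lattice, params, config, seed=int(s))
                if traj.melanoma[-1] < m0:
                    shrink += 1
            slide.response = RESPONDER if shrink > spec.n_sims / 2 else NONRESPONDER
    else:
        for slide, label in zip(slides, spec.labels):
            if label not in (RESPONDER, NONRESPONDER):
                raise ValidationError(f"unknown response label {label!r}")
            slide.response = label
    return Cohort(slides)


def calibration_cohort_specs(seed: int = 0, width: float = 200.0) -> list[SlideSpec]:
    """Twelve small, well-mixed slides spanning four composition motifs.

    Designed so that forward-simulated outcomes are informative about both
    exhaustion rates: T-cell-poor slides without TAMs progress unless the
    melanoma-driven exhaustion rate bC is small (they anchor bC from
    below), T-cell-rich slides without TAMs regress unless bC is large
    (anchoring bC from above), and the analogous TAM-bearing motifs anchor
    bM.  Slides are deliberately small (default 200 x 200 um) so that the
    thousands of simulations of a grid fit stay cheap; compositions follow
    the same densities per area as a 1 mm core.
    """
    motifs = [
        {"melanoma": 80, "t_active": 20, "tam": 0},  # progresses at moderate bC
        {"melanoma": 80, "t_active": 50, "tam": 0},  # regresses unless bC large
        {"melanoma": 80, "t_active": 50, "tam": 40},  # regresses unless bM large
        {"melanoma": 80, "t_active": 40, "tam": 80},  # progresses unless bM small
    ]
    specs = []
    for m, counts in enumerate(motifs):
        for k in range(3):
            specs.append(
                SlideSpec(
                    slide_id=f"M{m}{chr(ord('a') + k)}",
                    counts=counts,
                    width=width,
                    height=width,
                    seed=seed + 100 * (m + 1) + k,
                )
            )
    return specs


def flip_experiment_slide(seed: int = 5) -> Slide:
    """A strongly segregated slide for the position-randomization experiment.

    Melanoma occupies the left band and active T cells the right band of a
    600 x 600 um slide, separated by a 300 um gap that T cells are unlikely
    to diffuse across within the treatment window; TAMs are uniform.  Under
    lysis-favoring rates the segregated arrangement progresses (T cells
    cannot reach the tumor) while the same cell counts placed uniformly
    regress — the arrangement, not the abundance, sets the outcome.
    """
    return generate_slide(
        SlideSpec(
            "segregated",
            {"melanoma": 180, "t_active": 240, "tam": 60},
            {
                "melanoma": Segregated("x", 0, 150),
                "t_active": Segregated("x", 450, 600),
            },
            width=600.0,
            height=600.0,
            seed=seed,
        )
    )


def flip_experiment_params() -> RateParams:
    """Lysis-favoring rates for the position-randomization experiment."""
    return RateParams(l=0.25, bC=0.03, bM=0.03, r_hop_T=0.6)


def randomize_positions(slide: Slide, cell_type: str, seed: int = 0) -> Slide:
    """Re-place all cells of one type uniformly at random over the slide.

    This is the position-randomization perturbation used to probe how much
    the *initial spatial arrangement* (as opposed to the abundance) of a
    cell type drives the simulated outcome: counts of every type are
    preserved exactly and all other cells keep their positions.
    """
    present = set(slide.cells["cell_type"])
    if cell_type not in present and cell_type not in MODEL_TYPES:
        raise ValidationError(f"unknown cell type {cell_type!r}")
    rng = np.random.default_rng(seed)
    cells = slide.cells.copy()
    mask = (cells["cell_type"] == cell_type).to_numpy()
    n = int(mask.sum())
    if n:
        cells.loc[mask, "x"] = rng.uniform(0, slide.width, n)
        cells.loc[mask, "y"] = rng.uniform(0, slide.height, n)
    return Slide(slide.slide_id, cells, slide.width, slide.height, slide.response)
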