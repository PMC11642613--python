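"""Per-slide densities and the annulus pair-correlation statistic.

The pair correlation ``C(r)`` measures whether *target* cells are enriched
or depleted around *reference* cells relative to a homogeneous random
arrangement.  For each reference cell the local density of target cells in
the annulus ``[r - delta/2, r + delta/2)`` is computed (area-corrected for
the part of the annulus falling outside the slide), averaged over reference
cells, the slide-wide target density is subtracted, and the result is
divided by a normalization constant — conventionally the mean target-cell
count across the cohort's slides — making curves comparable across slides.
``C(r) > 0`` means clustering of targets around references at scale ``r``;
``C(r) < 0`` means avoidance.  The headline evaluation radius in this
analysis is 10.5 um, roughly a nearest-neighbor spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .cohort import Cohort, Slide, ValidationError


@dataclass
class PairCorrelationCurve:
    ref_type: str
    target_type: str
    radii: np.ndarray  # um, strictly increasing
    delta: float  # annulus thickness, um
    values: np.ndarray  # dimensionless (after normalization), same length
    norm_constant: float

    def at(self, r: float) -> float:
        i = int(np.argmin(np.abs(self.radii - r)))
        return float(self.values[i])


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    mean_a: float
    mean_b: float
    method: str


def cell_density(slide: Slide, cell_type: str) -> float:
    """Density of one cell type in cells per mm^2."""
    if slide.area_mm2 <= 0:
        raise ValidationError("slide has non-positive area")
    return slide.count(cell_type) / slide.area_mm2


def density_table(cohort: Cohort, cell_types: Sequence[str]) -> pd.DataFrame:
    """Long-format per-slide densities (cells/mm^2) with response labels."""
    rows = []
    for s in cohort:
        for t in cell_types:
            rows.append(
                {
                    "slide_id": s.slide_id,
                    "response": s.response,
                    "cell_type": t,
                    "density_per_mm2": cell_density(s, t),
                }
            )
    return pd.DataFrame(rows)


def mean_target_count(cohort: Cohort, target_type: str) -> float:
    """Cohort-level normalization constant: mean target-cell count per slide."""
    counts = [s.count(target_type) for s in cohort]
    return float(np.mean(counts)) if counts else float("nan")


def annulus_area(
    x: float,
    y: float,
    r_in: float,
    r_out: float,
    width: float,
    height: float,
    edge_correction: bool = True,
) -> float:
    """Area of the annulus ``[r_in, r_out)`` around (x, y) inside the slide.

    Without edge correction (or when the outer circle lies fully inside the
    slide rectangle) this is simply ``pi * (r_out^2 - r_in^2)``.  Otherwise
    the annulus polygon is intersected with the slide rectangle exactly
    (up to polygonal approximation of the circles).
    """
    full = np.pi * (r_out**2 - r_in**2)
    if not edge_correction:
        return full
    border = min(x, y, width - x, height - y)
    if border >= r_out:
        return full
    from shapely.geometry import Point, box

    disk = Point(x, y).buffer(r_out, quad_segs=64)
    if r_in > 0:
        disk = disk.difference(Point(x, y).buffer(r_in, quad_segs=64))
    return float(disk.intersection(box(0, 0, width, height)).area)


def pair_correlation(
    slide: Slide,
    ref_type: str,
    target_type: str,
    radii: Sequence[float],
    delta: float = 3.0,
    norm_constant: float = 1.0,
    edge_correction: bool = True,
) -> PairCorrelationCurve:
    """Annulus pair correlation of ``target_type`` around ``ref_type``.

    When the two types coincide each reference cell is excluded from its
    own annulus counts (standard for point-pattern autocorrelation).
    Distances land in the half-open bin ``[r - delta/2, r + delta/2)``.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0 or np.any(np.diff(radii) <= 0):
        raise ValidationError("radii must be non-empty and strictly increasing")
    if delta <= 0:
        raise ValidationError("delta must be > 0")
    if norm_constant <= 0:
        raise ValidationError("norm_constant must be > 0")
    refs = slide.positions(ref_type)
    targets = slide.positions(target_type)
    if refs.shape[0] == 0:
        raise ValidationError(f"slide {slide.slide_id}: no {ref_type!r} reference cells")
    same = ref_type == target_type
    slide_density = targets.shape[0] / (slide.width * slide.height)  # per um^2
    tree = cKDTree(targets) if targets.shape[0] else None
    values = np.empty(radii.size)
    for k, R in enumerate(radii):
        r_in = max(0.0, R - delta / 2)
        r_out = R + delta / 2
        local = np.empty(refs.shape[0])
        for i, (x, y) in enumerate(refs):
            if tree is not None:
                idx = tree.query_ball_point([x, y], r_out)
                if same:
                    idx = [j for j in idx if j != i]
                if idx:
                    d = np.sqrt(((targets[idx] - (x, y)) ** 2).sum(axis=1))
                    count = int(np.count_nonzero((d >= r_in) & (d < r_out)))
                else:
                    count = 0
            else:
                count = 0
            area = annulus_area(x, y, r_in, r_out, slide.width, slide.height, edge_correction)
            local[i] = count / area
        values[k] = (local.mean() - slide_density) / norm_constant
    return PairCorrelationCurve(ref_type, target_type, radii, delta, values, norm_constant)


def pair_correlation_table(
    cohort: Cohort,
    pairs: Sequence[tuple[str, str]],
    radii: Sequence[float],
    delta: float = 3.0,
    edge_correction: bool = True,
) -> pd.DataFrame:
    """Long-format C(r) for every slide and requested (ref, target) pair.

    The normalization constant for each pair is the cohort-mean target
    count.  Slides without reference cells get NaN values.
    """
    rows = []
    for ref_type, target_type in pairs:
        norm = mean_target_count(cohort, target_type)
        for s in cohort:
            if s.count(ref_type) == 0 or norm <= 0:
                vals = np.full(len(radii), np.nan)
            else:
                vals = pair_correlation(
                    s, ref_type, target_type, radii, delta, norm, edge_correction
                ).values
            for R, v in zip(radii, vals):
                rows.append(
                    {
                        "slide_id": s.slide_id,
                        "response": s.response,
                        "ref_type": ref_type,
                        "target_type": target_type,
                        "R_um": R,
                        "C": v,
                    }
                )
    return pd.DataFrame(rows)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "welch_t",
    n_perm: int = 10_000,
    seed: int = 0,
) -> GroupComparison:
    """Two-sided test for a difference of group means.

    ``welch_t`` is the unequal-variance t test; ``permutation`` shuffles
    group labels ``n_perm`` times using |mean difference| as the statistic
    (add-one p-value, so two identical groups give exactly p = 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if method == "welch_t":
        if a.size < 2 or b.size < 2:
            raise ValidationError("welch_t needs >= 2 finite values per group")
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparison(
            float(res.statistic), float(res.pvalue), float(a.mean()), float(b.mean()), "welch_t"
        )
    if method == "permutation":
        if a.size < 1 or b.size < 1:
            raise ValidationError("permutation needs >= 1 finite value per group")
        rng = np.random.default_rng(seed)
        obs = a.mean() - b.mean()
        pooled = np.concatenate([a, b])
        tol = 1e-12 * max(1.0, abs(obs))
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            diff = pooled[: a.size].mean() - pooled[a.size :].mean()
            if abs(diff) >= abs(obs) - tol:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        return GroupComparison(float(obs), float(p), float(a.mean()), float(b.mean()), "permutation")
    raise ValidationError(f"unknown method {method!r}")
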