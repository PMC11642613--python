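"""Data model and I/O for spatial single-cell slides, cohorts, and lattices.

A *slide* is a point-cloud snapshot of a tissue microarray (TMA) core:
one row per segmented cell, with a position in micrometres and a phenotype
label.  A *cohort* pairs slides with binary clinical response labels
(responder / nonresponder to checkpoint-inhibitor therapy).  For simulation
the continuous point cloud is rasterized onto a grid of small square
chambers (default 10 x 10 um) with a hard per-chamber occupancy cap that
stands in for cell volume exclusion.

Conventions
-----------
* Coordinates are continuous micrometres with the origin at the slide's
  lower-left corner; the slide occupies the half-open box
  ``[0, width) x [0, height)``.
* Chamber indices are 0-based ``(row, col)``; a cell at ``(x, y)`` belongs
  to chamber ``(floor(y / l0), floor(x / l0))``, so ``x == k * l0`` maps to
  column ``k`` (half-open binning).
* The model's closed phenotype vocabulary is
  ``melanoma, t_active, t_exhausted, tam``; any other label read from a
  cell table is preserved as ``other:<label>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four cell types evolved by the lattice model, in canonical order.
MODEL_TYPES = ("melanoma", "t_active", "t_exhausted", "tam")
TYPE_INDEX = {t: i for i, t in enumerate(MODEL_TYPES)}

RESPONDER = "responder"
NONRESPONDER = "nonresponder"
RESPONSE_LABELS = (RESPONDER, NONRESPONDER)

CELL_COLUMNS = ("slide_id", "x", "y", "cell_type")
TRAJ_COLUMNS = (
    "sample_id",
    "time_h",
    "n_melanoma",
    "n_t_active",
    "n_t_exhausted",
    "n_tam",
)


class FormatError(ValueError):
    """A file does not have the expected columns / layout."""


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class CellRecord(NamedTuple):
    slide_id: str
    x: float
    y: float
    cell_type: str


def normalize_cell_type(label: str) -> str:
    """Map an arbitrary phenotype label into the closed vocabulary.

    Labels already in :data:`MODEL_TYPES` (or already ``other:``-prefixed)
    pass through; anything else becomes ``other:<label>``.
    """
    label = str(label)
    if label in TYPE_INDEX or label.startswith("other:"):
        return label
    return f"other:{label}"


@dataclass
class Slide:
    """One TMA core: a set of phenotyped cell positions plus metadata."""

    slide_id: str
    cells: pd.DataFrame  # columns: x, y, cell_type
    width: float = 1000.0
    height: float = 1000.0
    response: str | None = None

    def __post_init__(self) -> None:
        missing = {"x", "y", "cell_type"} - set(self.cells.columns)
        if missing:
            raise FormatError(f"slide {self.slide_id}: missing cell columns {sorted(missing)}")
        self.cells = self.cells.reset_index(drop=True)
        x = self.cells["x"].to_numpy(dtype=float)
        y = self.cells["y"].to_numpy(dtype=float)
        bad = np.flatnonzero((x < 0) | (x >= self.width) | (y < 0) | (y >= self.height))
        if bad.size:
            i = int(bad[0])
            raise ValidationError(
                f"slide {self.slide_id}: cell row {i} at ({x[i]:g}, {y[i]:g}) outside "
                f"[0, {self.width:g}) x [0, {self.height:g})"
            )
        if self.response is not None and self.response not in RESPONSE_LABELS:
            raise ValidationError(
                f"slide {self.slide_id}: response {self.response!r} not in {RESPONSE_LABELS}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def area_mm2(self) -> float:
        return self.width * self.height / 1e6

    def counts(self) -> dict[str, int]:
        """Number of cells per phenotype label present on the slide."""
        return self.cells["cell_type"].value_counts().to_dict()

    def count(self, cell_type: str) -> int:
        return int((self.cells["cell_type"] == cell_type).sum())

    def positions(self, cell_type: str | None = None) -> np.ndarray:
        """(n, 2) array of cell positions, optionally restricted to one type."""
        df = self.cells if cell_type is None else self.cells[self.cells["cell_type"] == cell_type]
        return df[["x", "y"]].to_numpy(dtype=float)

    def records(self) -> Iterable[CellRecord]:
        for row in self.cells.itertuples(index=False):
            yield CellRecord(self.slide_id, float(row.x), float(row.y), str(row.cell_type))


@dataclass
class Cohort:
    """An ordered collection of slides with unique ids."""

    slides: list[Slide]

    def __post_init__(self) -> None:
        ids = [s.slide_id for s in self.slides]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate slide ids in cohort: {dupes}")

    @property
    def N(self) -> int:
        return len(self.slides)

    def __iter__(self):
        return iter(self.slides)

    def __len__(self) -> int:
        return len(self.slides)

    def get(self, slide_id: str) -> Slide:
        for s in self.slides:
            if s.slide_id == slide_id:
                return s
        raise KeyError(slide_id)

    def labeled(self) -> "Cohort":
        """Sub-cohort of slides that carry a response label."""
        return Cohort([s for s in self.slides if s.response is not None])


@dataclass
class LatticeState:
    """Chamber-grid occupancy of the four model cell types.

    ``counts`` has shape ``(4, n_rows, n_cols)`` indexed by
    :data:`MODEL_TYPES`; the per-chamber total never exceeds ``cap``.
    """

    counts: np.ndarray
    l0: float = 10.0
    cap: int = 4

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 3 or self.counts.shape[0] != len(MODEL_TYPES):
            raise ValidationError(
                f"lattice counts must have shape (4, n_rows, n_cols), got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative chamber occupancy")
        tot = self.counts.sum(axis=0)
        if (tot > self.cap).any():
            r, c = np.unravel_index(int(np.argmax(tot)), tot.shape)
            raise ValidationError(
                f"chamber ({r}, {c}) holds {int(tot[r, c])} cells, exceeding cap={self.cap}"
            )

    @property
    def n_rows(self) -> int:
        return self.counts.shape[1]

    @property
    def n_cols(self) -> int:
        return self.counts.shape[2]

    @property
    def width(self) -> float:
        return self.n_cols * self.l0

    @property
    def height(self) -> float:
        return self.n_rows * self.l0

    def copy(self) -> "LatticeState":
        return LatticeState(self.counts.copy(), self.l0, self.cap)

    def type_counts(self) -> dict[str, int]:
        return {t: int(self.counts[i].sum()) for i, t in enumerate(MODEL_TYPES)}


@dataclass
class Trajectory:
    """Population counts of the four model types on a recording time grid."""

    times: np.ndarray  # hours, first entry 0, non-decreasing
    counts: np.ndarray  # (n_times, 4) integers, MODEL_TYPES order
    sample_id: str = "0"
    seed: int | None = None
    snapshots: dict[float, LatticeState] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.times.ndim != 1 or self.counts.shape != (self.times.size, len(MODEL_TYPES)):
            raise ValidationError(
                f"trajectory shapes inconsistent: times {self.times.shape}, counts {self.counts.shape}"
            )
        if self.times.size == 0:
            raise ValidationError("empty trajectory")
        if self.times[0] != 0:
            raise ValidationError("trajectory must start at t = 0")
        if np.any(np.diff(self.times) < 0):
            raise ValidationError("trajectory times must be non-decreasing")
        if (self.counts < 0).any():
            raise ValidationError("negative population count")

    def count(self, cell_type: str) -> np.ndarray:
        return self.counts[:, TYPE_INDEX[cell_type]]

    @property
    def melanoma(self) -> np.ndarray:
        return self.count("melanoma")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_cell_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    width: float = 1000.0,
    height: float = 1000.0,
) -> list[Slide]:
    """Read a delimited cell table into one :class:`Slide` per slide id.

    Parameters
    ----------
    path
        CSV file with (mappable) columns ``slide_id, x, y, cell_type``.
    dialect
        Optional mapping from the canonical column names to the names used
        in the file, e.g. ``{"x": "X_position"}``.
    width, height
        Slide dimensions in micrometres; every coordinate must lie inside
        ``[0, width) x [0, height)``.
    """
    df = pd.read_csv(path)
    rename = {}
    dialect = dict(dialect or {})
    for canonical in CELL_COLUMNS:
        source = dialect.get(canonical, canonical)
        if source not in df.columns:
            raise FormatError(f"{path}: missing required column {source!r} (for {canonical!r})")
        rename[source] = canonical
    df = df.rename(columns=rename)[list(CELL_COLUMNS)]
    if df.empty:
        return []
    df["cell_type"] = df["cell_type"].map(normalize_cell_type)
    slides = []
    for slide_id, group in df.groupby("slide_id", sort=True):
        try:
            slides.append(
                Slide(
                    slide_id=str(slide_id),
                    cells=group[["x", "y", "cell_type"]].reset_index(drop=True),
                    width=width,
                    height=height,
                )
            )
        except ValidationError as err:
            # re-raise with the file row for easier debugging
            raise ValidationError(f"{path}: {err}") from err
    return slides


def write_cell_table(slides: Sequence[Slide], path: str | Path) -> None:
    frames = []
    for s in slides:
        df = s.cells.copy()
        df.insert(0, "slide_id", s.slide_id)
        frames.append(df)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(CELL_COLUMNS))
    )
    out.to_csv(path, index=False)


def read_cohort(
    cells_path: str | Path,
    manifest_path: str | Path,
    dialect: Mapping[str, str] | None = None,
    width: float = 1000.0,
    height: float = 1000.0,
) -> Cohort:
    """Read cells and a ``slide_id,response`` manifest into a labeled cohort.

    The cohort contains exactly the manifest's slides, in manifest order;
    slides present in the cell table but absent from the manifest are
    dropped with a log message.
    """
    slides = {s.slide_id: s for s in read_cell_table(cells_path, dialect, width, height)}
    manifest = pd.read_csv(manifest_path)
    for col in ("slide_id", "response"):
        if col not in manifest.columns:
            raise FormatError(f"{manifest_path}: missing required column {col!r}")
    missing = [str(i) for i in manifest["slide_id"] if str(i) not in slides]
    if missing:
        raise ValidationError(
            f"{manifest_path}: slides absent from cell table: {sorted(set(missing))}"
        )
    chosen = []
    for row in manifest.itertuples(index=False):
        sid = str(row.slide_id)
        response = str(row.response)
        if response not in RESPONSE_LABELS:
            raise ValidationError(
                f"{manifest_path}: slide {sid}: response {response!r} not in {RESPONSE_LABELS}"
            )
        s = slides[sid]
        s.response = response
        chosen.append(s)
    unused = set(slides) - {s.slide_id for s in chosen}
    if unused:
        logger.info("dropping %d slides not in manifest: %s", len(unused), sorted(unused))
    return Cohort(chosen)


def write_manifest(cohort: Cohort, path: str | Path) -> None:
    pd.DataFrame(
        {"slide_id": [s.slide_id for s in cohort], "response": [s.response for s in cohort]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def default_phenotype_map() -> dict[str, str]:
    """Identity mapping for the four model phenotypes."""
    return {t: t for t in MODEL_TYPES}


def slide_to_lattice(
    slide: Slide,
    l0: float = 10.0,
    cap: int = 4,
    phenotype_map: Mapping[str, str] | None = None,
) -> LatticeState:
    """Rasterize a slide onto the chamber grid.

    Cells whose phenotype is not mapped onto one of the four model types are
    dropped (with a logged count).  When a chamber would exceed ``cap`` the
    surplus cell is relocated to the nearest chamber (by center distance)
    with spare capacity, ties broken in row-major order; relocations are
    logged.  Per-type totals are conserved.
    """
    pmap = dict(phenotype_map) if phenotype_map is not None else default_phenotype_map()
    for target in pmap.values():
        if target not in TYPE_INDEX:
            raise ValidationError(f"phenotype map target {target!r} not a model type")
    n_cols = slide.width / l0
    n_rows = slide.height / l0
    if abs(n_cols - round(n_cols)) > 1e-9 or abs(n_rows - round(n_rows)) > 1e-9:
        raise ValidationError(
            f"l0={l0:g} does not divide slide dimensions {slide.width:g} x {slide.height:g}"
        )
    n_cols, n_rows = int(round(n_cols)), int(round(n_rows))
    counts = np.zeros((len(MODEL_TYPES), n_rows, n_cols), dtype=np.int64)
    total = np.zeros((n_rows, n_cols), dtype=np.int64)

    mapped = slide.cells["cell_type"].map(pmap)
    n_dropped = int(mapped.isna().sum())
    if n_dropped:
        logger.info("slide %s: dropped %d cells with unmapped phenotypes", slide.slide_id, n_dropped)

    rows_grid, cols_grid = np.indices((n_rows, n_cols))
    n_relocated = 0
    keep = mapped.notna().to_numpy()
    xs = slide.cells["x"].to_numpy(float)[keep]
    ys = slide.cells["y"].to_numpy(float)[keep]
    types = mapped.to_numpy()[keep]
    for x, y, tname in zip(xs, ys, types):
        t = TYPE_INDEX[tname]
        r = int(y // l0)
        c = int(x // l0)
        if total[r, c] < cap:
            counts[t, r, c] += 1
            total[r, c] += 1
            continue
        # relocate to nearest chamber with spare capacity (center distance,
        # ties in row-major order)
        free = total < cap
        if not free.any():
            raise ValidationError(
                f"slide {slide.slide_id}: lattice full (cap={cap}), cannot place all cells"
            )
        d2 = (rows_grid - r) ** 2 + (cols_grid - c) ** 2
        d2 = np.where(free, d2, np.iinfo(np.int64).max)
        rr, cc = np.unravel_index(int(np.argmin(d2)), d2.shape)  # argmin is row-major-first
        counts[t, rr, cc] += 1
        total[rr, cc] += 1
        n_relocated += 1
    if n_relocated:
        logger.info(
            "slide %s: relocated %d cells due to chamber capacity cap=%d",
            slide.slide_id,
            n_relocated,
            cap,
        )
    return LatticeState(counts, l0=l0, cap=cap)


# ---------------------------------------------------------------------------
# Trajectory files
# ---------------------------------------------------------------------------

def write_trajectories(trajs: Sequence[Trajectory], path: str | Path) -> None:
    """Write one or more trajectories to a long-format CSV."""
    if not trajs:
        raise ValidationError("no trajectories to write")
    frames = []
    for tr in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": tr.sample_id,
                    "time_h": tr.times,
                    "n_melanoma": tr.counts[:, 0],
                    "n_t_active": tr.counts[:, 1],
                    "n_t_exhausted": tr.counts[:, 2],
                    "n_tam": tr.counts[:, 3],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    write_trajectories([traj], path)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    missing = set(TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing trajectory columns {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_h", kind="stable")
        out.append(
            Trajectory(
                times=grp["time_h"].to_numpy(float),
                counts=grp[["n_melanoma", "n_t_active", "n_t_exhausted", "n_tam"]].to_numpy(
                    np.int64
                ),
                sample_id=str(sid),
            )
        )
    if not out:
        raise FormatError(f"{path}: no trajectory records")
    return out


def read_trajectory(path: str | Path) -> Trajectory:
    trajs = read_trajectories(path)
    if len(trajs) != 1:
        raise FormatError(f"{path}: expected a single sample, found {len(trajs)}")
    return trajs[0]


# ---------------------------------------------------------------------------
# Lattice snapshot files (one integer matrix per type)
# ---------------------------------------------------------------------------

def write_lattice_snapshot(
    state: LatticeState, out_dir: str | Path, slide_id: str, time_h: float
) -> list[Path]:
    """Write per-type chamber-count matrices as ``<slide>_<type>_<time>.txt``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, t in enumerate(MODEL_TYPES):
        p = out_dir / f"{slide_id}_{t}_{time_h:g}.txt"
        np.savetxt(p, state.counts[i], fmt="%d")
        paths.append(p)
    return paths


def read_lattice_snapshot(
    out_dir: str | Path, slide_id: str, time_h: float, l0: float = 10.0, cap: int = 4
) -> LatticeState:
    out_dir = Path(out_dir)
    mats = []
    for t in MODEL_TYPES:
        p = out_dir / f"{slide_id}_{t}_{time_h:g}.txt"
        if not p.exists():
            raise FormatError(f"missing snapshot matrix {p}")
        mats.append(np.loadtxt(p, dtype=np.int64, ndmin=2))
    return LatticeState(np.stack(mats), l0=l0, cap=cap)
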