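"""Stochastic lattice model of tumor-immune dynamics under checkpoint therapy.

Four cell types — melanoma, activated CD8+ T cells, exhausted CD8+ T cells,
and tumor-associated macrophages (TAMs) — occupy 10 um chambers of a 2D
grid with a hard per-chamber capacity.  The model evolves by an exact
kinetic Monte Carlo (Gillespie) scheme over these events:

=====================  =====================================================
event                  rate
=====================  =====================================================
melanoma division      ``r_prolif_mel`` per melanoma cell
lysis                  ``l`` per (active T, melanoma) contact pair
exhaustion (melanoma)  ``bC`` per (active T, melanoma) contact pair
exhaustion (TAM)       ``bM`` per (active T, TAM) same-chamber pair
active-T division      ``r_prolif_T0 + k_prolif * L`` per active T cell
active-T recruitment   ``r_recruit0 + k_recruit * L`` slide-wide
exhausted-T death      ``r_death_ex`` per exhausted T cell
hops                   ``r_hop_T`` per (active or exhausted) T cell,
                       ``r_hop_M`` per TAM
=====================  =====================================================

``L`` is the number of melanoma cells lysed during the most recent
*completed* feedback window of length ``dt_feedback`` (piecewise-constant
feedback, so waiting times stay exponential between window boundaries).
Exhausted T cells neither lyse nor divide; they only hop and die.
Blocked placements (full or off-grid targets) are null events, which gives
reflecting boundaries.  The default rates are documented placeholders of
plausible magnitude, not fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np

from . import _kernel
from .cohort import TYPE_INDEX, LatticeState, Trajectory, ValidationError

NEIGHBORHOODS = ("moore8", "vonneumann4")


@dataclass(frozen=True)
class RateParams:
    """Kinetic rates of the interacting-cell-system model (all h^-1).

    ``bC`` and ``bM`` — the exhaustion rates of activated CD8+ T cells by
    melanoma contact and by TAM co-occupancy — are the two parameters the
    calibration stage estimates from clinical response labels; everything
    else is held fixed.
    """

    r_prolif_mel: float = 0.02
    l: float = 0.1
    bC: float = 0.05
    bM: float = 0.05
    r_death_ex: float = 0.01
    r_hop_T: float = 1.2
    r_hop_M: float = 1.2
    r_prolif_T0: float = 0.005
    k_prolif: float = 1e-4  # per lysed melanoma cell per active T cell
    r_recruit0: float = 0.5  # slide-wide
    k_recruit: float = 1e-2  # slide-wide, per lysed melanoma cell
    dt_feedback: float = 24.0  # h

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValidationError(f"rate {f.name} must be >= 0, got {v}")
        if self.dt_feedback <= 0:
            raise ValidationError("dt_feedback must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in _kernel.RATE_FIELDS], dtype=float)

    def with_(self, **kw) -> "RateParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class SimConfig:
    """Simulation horizon, recording grid, and lattice conventions.

    The default end time of 333 h is about two weeks — a single cycle of
    checkpoint therapy.  Contact defaults to the Moore-8 neighborhood
    (diagonal chamber centers sit ~14 um apart, within cell-contact range);
    hops default to von Neumann-4, the standard lattice diffusion stencil.
    """

    t_end: float = 333.0
    record_every: float = 1.0
    contact_neighborhood: str = "moore8"
    hop_neighborhood: str = "vonneumann4"
    boundary: str = "reflecting"
    cap: int = 4

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValidationError("t_end must be > 0")
        if self.record_every <= 0:
            raise ValidationError("record_every must be > 0")
        if self.contact_neighborhood not in NEIGHBORHOODS:
            raise ValidationError(f"unknown contact neighborhood {self.contact_neighborhood!r}")
        if self.hop_neighborhood not in NEIGHBORHOODS:
            raise ValidationError(f"unknown hop neighborhood {self.hop_neighborhood!r}")
        if self.boundary != "reflecting":
            raise ValidationError("only reflecting boundaries are supported")

    def recording_grid(self) -> np.ndarray:
        n = int(np.floor(self.t_end / self.record_every + 1e-9)) + 1
        times = np.arange(n, dtype=float) * self.record_every
        if times[-1] < self.t_end - 1e-9:
            times = np.append(times, self.t_end)
        return times


def population_counts(state: LatticeState) -> dict[str, int]:
    """Total number of cells of each model type on the lattice."""
    return state.type_counts()


def contact_pairs(
    state: LatticeState, type_a: str, type_b: str, neighborhood: str = "moore8"
) -> int:
    """Number of ordered (type_a, type_b) pairs in contact.

    Two cells are in contact when they share a chamber or occupy chambers
    within the neighborhood (``moore8``, ``vonneumann4``, or ``same`` for
    strictly co-occupying pairs).  Counts are products of occupancies summed
    over chamber pairs; for ``type_a == type_b`` same-chamber self-pairs are
    excluded (``n * (n - 1)`` ordered pairs within a chamber).
    """
    a = state.counts[TYPE_INDEX[type_a]].astype(np.int64)
    b = state.counts[TYPE_INDEX[type_b]].astype(np.int64)
    nb = b.copy()
    if neighborhood != "same":
        shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if neighborhood == "moore8":
            shifts += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
        elif neighborhood != "vonneumann4":
            raise ValidationError(f"unknown neighborhood {neighborhood!r}")
        for dr, dc in shifts:
            nb += _shift(b, dr, dc)
    pairs = int((a * nb).sum())
    if type_a == type_b:
        pairs -= int(a.sum())  # remove each cell paired with itself
    return pairs


def _shift(m: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(m)
    nr, nc = m.shape
    rs = slice(max(dr, 0), nr + min(dr, 0))
    cs = slice(max(dc, 0), nc + min(dc, 0))
    rs0 = slice(max(-dr, 0), nr + min(-dr, 0))
    cs0 = slice(max(-dc, 0), nc + min(-dc, 0))
    out[rs, cs] = m[rs0, cs0]
    return out


def simulate(
    initial: LatticeState,
    params: RateParams,
    config: SimConfig = SimConfig(),
    seed: int = 0,
    snapshot_times: Sequence[float] = (),
    sample_id: str = "0",
) -> Trajectory:
    """Evolve a lattice state to ``config.t_end`` by kinetic Monte Carlo.

    Returns the population trajectory on the recording grid (last state
    carried forward between events) and, optionally, full lattice snapshots
    at the requested times.  A fixed seed yields a bit-identical trajectory.
    """
    if initial.cap != config.cap:
        # the lattice's cap wins; config.cap is for building new lattices
        config = replace(config, cap=initial.cap)
    nr, nc = initial.n_rows, initial.n_cols
    rec_times = config.recording_grid()
    snap_times = np.asarray(sorted(snapshot_times), dtype=float)
    counts0 = np.ascontiguousarray(initial.counts.reshape(4, nr * nc))
    out, snaps, _ = _kernel.run_kmc(
        counts0,
        nr,
        nc,
        initial.cap,
        params.as_array(),
        config.t_end,
        rec_times,
        snap_times,
        config.contact_neighborhood == "moore8",
        config.hop_neighborhood == "moore8",
        np.uint64(seed),
    )
    snapshots = {
        float(t): LatticeState(snaps[i].reshape(4, nr, nc).copy(), l0=initial.l0, cap=initial.cap)
        for i, t in enumerate(snap_times)
    }
    return Trajectory(
        times=rec_times, counts=out, sample_id=sample_id, seed=int(seed), snapshots=snapshots
    )


def simulate_ensemble(
    initial: LatticeState,
    params: RateParams,
    config: SimConfig = SimConfig(),
    n_sims: int = 100,
    seed: int = 0,
    snapshot_times: Sequence[float] = (),
) -> list[Trajectory]:
    """Run ``n_sims`` independent trajectories from one initial state."""
    seeds = sim_seeds(seed, 0, n_sims)
    return [
        simulate(initial, params, config, seed=int(s), snapshot_times=snapshot_times,
                 sample_id=str(i))
        for i, s in enumerate(seeds)
    ]


def sim_seeds(seed: int, stream: int, n: int) -> np.ndarray:
    """Deterministic per-simulation seeds for stream ``stream``.

    Used for common-random-number evaluation across parameter sets: the
    same (seed, stream) always yields the same simulation seeds.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stream),))
    return ss.generate_state(n, dtype=np.uint32) % (2**31 - 1)
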