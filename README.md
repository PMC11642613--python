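# icstme

Spatially resolved **interacting-cell-system (ICS)** modeling of
tumor–immune dynamics in melanoma tissue microarrays.

Multiplexed imaging (IMC, CyCIF) gives a single pretreatment snapshot of a
1 × 1 mm tumor core: every cell's position and phenotype, but no dynamics.
This package asks what that snapshot implies for the course of checkpoint
inhibitor (anti-PD1 / anti-CTLA4) therapy.  It is written for
computational biologists and biophysicists who want to simulate
tumor–immune dynamics from spatial single-cell tables, calibrate the
simulation against binary clinical response labels, and quantify the
spatial structure that drives the outcome.

## The model

Four cell types — melanoma cells, activated CD8⁺ T cells, exhausted CD8⁺
T cells, and tumor-associated macrophages (TAMs) — occupy 10 × 10 μm
chambers of a 2D lattice with a hard per-chamber occupancy cap.  The state
evolves by exact kinetic Monte Carlo over these events (rates per hour):

| event | rate |
|---|---|
| melanoma division | `r_prolif_mel` per melanoma cell |
| lysis of a melanoma cell | `l` per (active T, melanoma) contact pair |
| T-cell exhaustion by melanoma | `bC` per (active T, melanoma) contact pair |
| T-cell exhaustion by a TAM | `bM` per (active T, TAM) same-chamber pair |
| active-T division | `r_prolif_T0 + k_prolif·L` per active T cell |
| active-T recruitment | `r_recruit0 + k_recruit·L` slide-wide |
| exhausted-T death | `r_death_ex` per exhausted T cell |
| diffusive hops | `r_hop_T` per T cell, `r_hop_M` per TAM |

`L` is the number of melanoma cells lysed in the previous feedback window
(default 24 h) — lysing the tumor recruits and expands the T-cell
compartment.  Exhausted T cells neither kill nor divide; they hop, die,
and — crucially — *fence* tumor boundaries, shielding melanoma from still
active T cells.

Around the simulator the package implements the full analysis pipeline:

* **`icstme.cohort`** — cell-table/manifest I/O, rasterization of point
  clouds onto the chamber grid, trajectory and snapshot files.
* **`icstme.synth`** — synthetic slides (uniform / clustered / segregated
  patterns), forward-simulated cohort labeling, and the
  position-randomization perturbation.
* **`icstme.spatial`** — per-slide densities and the annulus pair
  correlation `C(r)` (local target density around reference cells, minus
  the slide density, normalized by the cohort-mean target count), with
  Welch and permutation group tests.
* **`icstme.calibration`** — melanoma fold change over a treatment cycle
  (T = 333 h; fold change < 1 ⇒ responder), per-slide prediction success
  frequencies `f_i(θ)`, the cohort score
  `score(θ) = Π_i [(1−b)·f_i(θ) + b/2]` with `b = 0.1`, and grid
  estimation of the two exhaustion rates `(bC, bM)` with common random
  numbers.
* **`icstme.hypotheses`** — bootstrap comparison of the base model against
  alternates with an exhaustion mechanism removed, via the log score
  difference `DSS_β = ln score_alt(β) − ln score_base(β)` over resampled
  slide sets, plus Bonferroni adjustment.
* **`icstme.fencing`** — connected clusters of exhausted T cells in
  contact with melanoma (lattice or 15 μm point-cloud adjacency), the
  fencing fraction, and its label-permutation null.
* **`icstme.trajstats`** — ensemble autocorrelation
  `A(t, t_i) = ⟨(C_α(t_i)−μ(t_i))(C_α(t)−μ(t))⟩ / (σ(t_i)σ(t))`,
  coefficient of variation, transition time τ*, and Yule (linear pure
  birth) closed forms for late-time growth:
  mean `n₀e^{λt}`, variance `n₀e^{λt}(e^{λt}−1)`, and
  `Corr[N(t_i), N(t)] = e^{λ(t−t_i)/2} √((e^{λt_i}−1)/(e^{λt}−1))`.

## Worked example

Outcome is set by *where* the T cells are, not how many there are.  Build
a segregated slide (tumor on the left, T cells on the right, 300 μm gap),
evolve it through one treatment cycle, then repeat with the same cells
re-seeded uniformly at random:

```python
from icstme import RateParams, SimConfig, simulate, slide_to_lattice
from icstme.synth import SlideSpec, Segregated, generate_slide, randomize_positions
from icstme.calibration import fold_change, predict_response
from icstme.fencing import analyze, permutation_null

slide = generate_slide(
    SlideSpec(
        "demo",
        counts={"melanoma": 180, "t_active": 240, "tam": 60},
        patterns={"melanoma": Segregated("x", 0, 150),
                  "t_active": Segregated("x", 450, 600)},
        width=600, height=600, seed=5,
    )
)
params = RateParams(l=0.25, bC=0.03, bM=0.03, r_hop_T=0.6)
config = SimConfig(t_end=333.0, record_every=333.0)

traj = simulate(slide_to_lattice(slide), params, config, seed=1)
fc = fold_change(traj)
print(f"segregated slide: fold change {fc:.2f} -> {predict_response(fc)}")

shuffled = randomize_positions(slide, "t_active", seed=1)
traj2 = simulate(slide_to_lattice(shuffled), params, config, seed=1,
                 snapshot_times=[72.0])
fc2 = fold_change(traj2)
print(f"randomized T cells: fold change {fc2:.2f} -> {predict_response(fc2)}")

snap = traj2.snapshots[72.0]
fence = analyze(snap)
null = permutation_null(snap, pool="immune", n_perm=200, seed=0)
print(f"fencing fraction at 72 h: {fence.fraction:.2f} "
      f"(permutation null mean {null.mean:.2f})")
```

Output:

```
segregated slide: fold change 19.11 -> nonresponder
randomized T cells: fold change 0.00 -> responder
fencing fraction at 72 h: 0.13 (permutation null mean 0.00)
```

The segregated arrangement grows 19-fold (the T cells never reach the
tumor), while the identical cell counts in a mixed arrangement eliminate
it.  In the mixed run, 13% of exhausted T cells sit in melanoma-touching
clusters of ≥ 3 cells at 72 h — far above the ~0% expected if exhausted
cells were an arbitrary subset of the immune infiltrate, i.e. the
simulation dynamically generates fencing.

A `click` CLI mirrors the library:
`icstme synth | simulate | spatial | fit | predict | test | fencing | trajstats`
(see `icstme --help`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the pipeline end to end on synthetic data (~4 min): it generates a
12-slide cohort, forward-labels it by simulated fold change under known
exhaustion rates, computes spatial statistics and group comparisons,
re-estimates `(bC, bM)` from the labels alone on a log-spaced grid, tests
the "TAMs do not exhaust T cells" alternate by 100,000-replicate
bootstrap with Bonferroni adjustment, measures fencing against its
permutation null on a simulated snapshot, and summarizes ensemble
trajectory statistics, writing its JSON result to `--out`.

## Data formats

* cell table: CSV with `slide_id, x, y, cell_type` (μm; phenotype labels
  outside `melanoma / t_active / t_exhausted / tam` are preserved as
  `other:<label>`), column names remappable via a dialect mapping;
* cohort manifest: CSV with `slide_id, response` (`responder` /
  `nonresponder`);
* trajectories: CSV with
  `sample_id, time_h, n_melanoma, n_t_active, n_t_exhausted, n_tam`;
* lattice snapshots: one integer matrix per cell type,
  `<slide>_<type>_<time>.txt`.

See `docs/methods.md` for model assumptions, parameter defaults and their
rationale, numerical conventions, and known limitations.
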