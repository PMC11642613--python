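"""Slide/cohort I/O, rasterization, and trajectory round trips."""

import numpy as np
import pandas as pd
import pytest

from icstme import (
    FormatError,
    LatticeState,
    Slide,
    Trajectory,
    ValidationError,
    read_cell_table,
    read_cohort,
    read_trajectories,
    read_trajectory,
    slide_to_lattice,
    write_cell_table,
    write_manifest,
    write_trajectories,
    write_trajectory,
)
from icstme.cohort import (
    Cohort,
    normalize_cell_type,
    read_lattice_snapshot,
    write_lattice_snapshot,
)
from icstme.synth import SlideSpec, generate_slide


def write_csv(path, rows, columns=("slide_id", "x", "y", "cell_type")):
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, index=False)
    return path


class TestReadCellTable:
    def test_single_slide(self, tmp_path):
        p = write_csv(tmp_path / "c.csv", [("s1", 1.0, 2.0, "melanoma")] * 3)
        slides = read_cell_table(p)
        assert len(slides) == 1 and slides[0].n_cells == 3

    def test_empty_table(self, tmp_path):
        p = write_csv(tmp_path / "c.csv", [])
        assert read_cell_table(p) == []

    def test_rows_split_by_slide_id(self, tmp_path):
        rows = [("a", i, i, "tam") for i in range(5)] + [("b", i, i, "tam") for i in range(7)]
        slides = read_cell_table(write_csv(tmp_path / "c.csv", rows))
        assert sorted((s.slide_id, s.n_cells) for s in slides) == [("a", 5), ("b", 7)]

    def test_missing_column_is_format_error(self, tmp_path):
        p = write_csv(tmp_path / "c.csv", [("s1", 1.0, 2.0)], columns=("slide_id", "x", "y"))
        with pytest.raises(FormatError, match="cell_type"):
            read_cell_table(p)

    def test_dialect_maps_column_names(self, tmp_path):
        p = write_csv(
            tmp_path / "c.csv",
            [("s1", 10.0, 20.0, "melanoma")],
            columns=("sample", "X_um", "Y_um", "phenotype"),
        )
        slides = read_cell_table(
            p, dialect={"slide_id": "sample", "x": "X_um", "y": "Y_um", "cell_type": "phenotype"}
        )
        assert slides[0].positions("melanoma").tolist() == [[10.0, 20.0]]

    def test_out_of_bounds_names_row(self, tmp_path):
        p = write_csv(tmp_path / "c.csv", [("s1", 5.0, 5.0, "tam"), ("s1", 1000.0, 5.0, "tam")])
        with pytest.raises(ValidationError, match="row 1"):
            read_cell_table(p)

    def test_unknown_phenotypes_preserved_as_other(self, tmp_path):
        p = write_csv(tmp_path / "c.csv", [("s1", 1.0, 1.0, "B cell"), ("s1", 2.0, 2.0, "tam")])
        slides = read_cell_table(p)
        assert set(slides[0].cells["cell_type"]) == {"other:B cell", "tam"}

    def test_normalize_is_idempotent(self):
        assert normalize_cell_type("other:B cell") == "other:B cell"
        assert normalize_cell_type("t_active") == "t_active"


class TestReadCohort:
    def make_pair(self, tmp_path, manifest_rows):
        cells = write_csv(
            tmp_path / "cells.csv",
            [("a", 1, 1, "melanoma"), ("b", 2, 2, "melanoma")],
        )
        manifest = write_csv(
            tmp_path / "manifest.csv", manifest_rows, columns=("slide_id", "response")
        )
        return cells, manifest

    def test_labels_attached(self, tmp_path):
        cells, manifest = self.make_pair(
            tmp_path, [("a", "responder"), ("b", "nonresponder")]
        )
        co = read_cohort(cells, manifest)
        assert co.N == 2
        assert [s.response for s in co] == ["responder", "nonresponder"]

    def test_unknown_slide_in_manifest(self, tmp_path):
        cells, manifest = self.make_pair(tmp_path, [("a", "responder"), ("zz", "responder")])
        with pytest.raises(ValidationError, match="zz"):
            read_cohort(cells, manifest)

    def test_bad_response_label(self, tmp_path):
        cells, manifest = self.make_pair(tmp_path, [("a", "partial")])
        with pytest.raises(ValidationError, match="partial"):
            read_cohort(cells, manifest)

    def test_round_trip_via_writers(self, tmp_path, mixed_slide):
        mixed_slide.response = "responder"
        co = Cohort([mixed_slide])
        write_cell_table(list(co), tmp_path / "c.csv")
        write_manifest(co, tmp_path / "m.csv")
        back = read_cohort(tmp_path / "c.csv", tmp_path / "m.csv", width=200, height=200)
        assert back.N == 1 and back.slides[0].n_cells == mixed_slide.n_cells


class TestSlideToLattice:
    def one_cell_slide(self, x, y):
        cells = pd.DataFrame({"x": [x], "y": [y], "cell_type": ["melanoma"]})
        return Slide("s", cells, width=100, height=100)

    def test_floor_rule(self):
        lat = slide_to_lattice(self.one_cell_slide(5.0, 5.0), l0=10)
        assert lat.counts[0, 0, 0] == 1

    def test_half_open_boundary(self):
        # x = k*l0 belongs to column k, not k-1
        lat = slide_to_lattice(self.one_cell_slide(10.0, 0.0), l0=10)
        assert lat.counts[0, 0, 1] == 1 and lat.counts[0, 0, 0] == 0

    def test_capacity_relocation_conserves_totals(self):
        cells = pd.DataFrame(
            {"x": [5.0] * 3, "y": [5.0] * 3, "cell_type": ["melanoma"] * 3}
        )
        lat = slide_to_lattice(Slide("s", cells, width=100, height=100), l0=10, cap=2)
        assert lat.counts[0, 0, 0] == 2  # chamber holds up to cap
        assert lat.counts[0].sum() == 3  # third cell relocated, not dropped
        # relocated to an adjacent chamber (distance-1 neighbors of (0, 0))
        spill = [tuple(rc) for rc in np.argwhere(lat.counts[0] == 1)]
        assert spill in ([(0, 1)], [(1, 0)], [(1, 1)])

    def test_l0_must_divide_dimensions(self, mixed_slide):
        with pytest.raises(ValidationError, match="divide"):
            slide_to_lattice(mixed_slide, l0=7)

    def test_unmapped_phenotypes_dropped(self):
        cells = pd.DataFrame(
            {"x": [5, 15], "y": [5, 5], "cell_type": ["melanoma", "other:B cell"]}
        )
        lat = slide_to_lattice(Slide("s", cells, width=100, height=100))
        assert lat.counts.sum() == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rasterization_conserves_per_type_totals(self, seed):
        slide = generate_slide(
            SlideSpec(
                "s",
                {"melanoma": 120, "t_active": 60, "tam": 25},
                width=200,
                height=200,
                seed=seed,
            )
        )
        lat = slide_to_lattice(slide, cap=4)
        assert lat.type_counts() == {
            "melanoma": 120,
            "t_active": 60,
            "t_exhausted": 0,
            "tam": 25,
        }
        assert (lat.counts.sum(axis=0) <= lat.cap).all()


class TestLatticeState:
    def test_capacity_invariant_enforced(self):
        counts = np.zeros((4, 2, 2), np.int64)
        counts[0, 0, 0] = 5
        with pytest.raises(ValidationError, match="cap"):
            LatticeState(counts, cap=4)

    def test_geometry(self):
        lat = LatticeState(np.zeros((4, 3, 5), np.int64), l0=10)
        assert (lat.height, lat.width) == (30, 50)


class TestTrajectoryIO:
    def make_traj(self, n=3):
        times = np.arange(n, dtype=float)
        counts = np.column_stack(
            [np.arange(n) + 10, np.arange(n), np.zeros(n, int), np.ones(n, int)]
        )
        return Trajectory(times=times, counts=counts, sample_id="t0")

    def test_round_trip_lossless(self, tmp_path):
        tr = self.make_traj()
        write_trajectory(tr, tmp_path / "t.csv")
        back = read_trajectory(tmp_path / "t.csv")
        assert np.array_equal(back.counts, tr.counts)
        assert np.allclose(back.times, tr.times)

    def test_empty_write_is_error(self, tmp_path):
        with pytest.raises(ValidationError):
            write_trajectories([], tmp_path / "t.csv")
        with pytest.raises(ValidationError):
            Trajectory(times=np.array([]), counts=np.empty((0, 4)))

    def test_three_time_points_three_records(self, tmp_path):
        write_trajectory(self.make_traj(3), tmp_path / "t.csv")
        assert len(pd.read_csv(tmp_path / "t.csv")) == 3

    def test_multi_sample_round_trip(self, tmp_path):
        trs = [self.make_traj(), self.make_traj()]
        trs[1].sample_id = "t1"
        write_trajectories(trs, tmp_path / "t.csv")
        assert [t.sample_id for t in read_trajectories(tmp_path / "t.csv")] == ["t0", "t1"]
        with pytest.raises(FormatError):
            read_trajectory(tmp_path / "t.csv")  # expects one sample

    def test_malformed_file(self, tmp_path):
        (tmp_path / "bad.csv").write_text("a,b\n1,2\n")
        with pytest.raises(FormatError):
            read_trajectories(tmp_path / "bad.csv")


class TestLatticeSnapshotIO:
    def test_round_trip(self, tmp_path, mixed_slide):
        lat = slide_to_lattice(mixed_slide)
        write_lattice_snapshot(lat, tmp_path, "s1", 72.0)
        back = read_lattice_snapshot(tmp_path, "s1", 72.0, l0=lat.l0, cap=lat.cap)
        assert np.array_equal(back.counts, lat.counts)
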