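import numpy as np
import pandas as pd
import pytest

from cardiomech import io, metrics
from cardiomech.engine import ScenarioConfig, run_scenario


# ---------------------------------------------------------------------------
# aspect ratio
# ---------------------------------------------------------------------------

def test_aspect_ratio_formula(params):
    # extents 4:2:2 (after adding the cell diameter) -> AR = sqrt(16/4) = 2
    pos = np.array([[0.0, 0, 0], [60.0, 0, 0],
                    [30.0, 20.0, 0.0], [30.0, 0.0, 20.0]])
    lx, ly, lz = metrics.group_extents_global(pos, 10.0)
    assert (lx, ly, lz) == (80.0, 40.0, 40.0)
    assert metrics.aspect_ratio(pos, 10.0) == pytest.approx(2.0)


def test_aspect_ratio_isotropic_is_one():
    pos = np.array([[0.0, 0, 0], [40.0, 40.0, 40.0]])
    assert metrics.aspect_ratio(pos, 10.0) == pytest.approx(1.0)


def test_aspect_ratio_transverse_symmetry():
    pos = np.array([[0.0, 0, 0], [50.0, 30.0, 10.0]])
    swapped = pos[:, [0, 2, 1]]
    assert metrics.aspect_ratio(pos, 10.0) == \
        pytest.approx(metrics.aspect_ratio(swapped, 10.0))


def test_degenerate_extents_floored_at_cell_diameter():
    pos = np.array([[0.0, 0, 0], [60.0, 0.0, 0.0]])   # collinear
    lx, ly, lz = metrics.group_extents_global(pos, 10.0)
    assert ly == lz == 20.0
    assert metrics.aspect_ratio(pos, 10.0) == pytest.approx(80.0 / 20.0)


# ---------------------------------------------------------------------------
# main group
# ---------------------------------------------------------------------------

def test_main_group_threshold(params):
    labels = np.r_[np.zeros(56, int), np.arange(1, 45)]
    size, members, formed = metrics.main_group_stats(labels, params)
    assert size == 56 and formed                      # 56 of 100 >= 55%
    labels = np.r_[np.zeros(54, int), np.arange(1, 47)]
    size, _, formed = metrics.main_group_stats(labels, params)
    assert size == 54 and not formed


def test_main_group_tie_broken_by_lowest_member(params):
    labels = np.r_[np.full(30, 7), np.full(30, 2)]
    size, members, formed = metrics.main_group_stats(labels, params)
    assert size == 30 and not formed
    assert members.min() == 30                        # label 2 holds cells 30..59


# ---------------------------------------------------------------------------
# arrival times
# ---------------------------------------------------------------------------

def test_cell_seeded_on_fiber_touches_at_time_zero(params):
    ay, az = params.fiber_axis_yz
    reach = params.fiber_outer_radius + params.r_cell
    pos = np.array([[100.0, ay + reach, az]])
    assert metrics.touching_fiber(pos, params).all()


def test_censored_cells_reported_separately():
    out = metrics.summarize_arrival_times({0: 5.0, 2: 7.0}, {0, 1, 2, 3})
    assert out["n_arrived"] == 2 and out["n_censored"] == 2
    assert out["mean_time_to_fiber"] == pytest.approx(6.0)
    empty = metrics.summarize_arrival_times({}, {0, 1})
    assert np.isnan(empty["mean_time_to_fiber"])


# ---------------------------------------------------------------------------
# writers / readers
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_result(small_params):
    cfg = ScenarioConfig.preset("DIFF", params=small_params)
    cfg.steps = 5
    return run_scenario(cfg, seed=3)


def test_result_bundle_round_trips(tmp_path, tiny_result):
    out = io.write_result(tiny_result, tmp_path / "run")
    cells = io.read_cells(out / "cells_final.csv")
    assert list(cells.columns) == io.CELL_COLUMNS
    again = io.cell_table(tiny_result.state)
    pd.testing.assert_frame_equal(cells, again, check_dtype=False)
    manifest = io.read_manifest(out / "manifest.json")
    assert manifest["scenario"] == "DIFF" and manifest["seed"] == 3
    metrics_csv = pd.read_csv(out / "metrics.csv")
    assert len(metrics_csv) == len(tiny_result.metrics)


def test_manifest_missing_calibration_rejected(tmp_path):
    path = tmp_path / "manifest.json"
    path.write_text('{"scenario": "DIFF"}')
    with pytest.raises(io.SchemaError, match="c_sub"):
        io.read_manifest(path)


def test_cell_table_schema_enforced(tmp_path):
    path = tmp_path / "cells.csv"
    pd.DataFrame({"id": [1], "x": [0.0]}).to_csv(path, index=False)
    with pytest.raises(io.SchemaError, match="missing"):
        io.read_cells(path)


def test_vtk_files_written_as_indexed_series(tmp_path, tiny_result):
    st = tiny_result.state
    mesh_path = tmp_path / "ecm.vtk"
    io.write_vtk_mesh(st.ecm.mesh, mesh_path, st.ecm.solution)
    txt = mesh_path.read_text()
    assert txt.startswith("# vtk DataFile")
    assert "DATASET UNSTRUCTURED_GRID" in txt
    assert f"POINTS {st.ecm.mesh.n_nodes}" in txt
    assert "youngs_modulus" in txt and "displacement" in txt

    name0 = io.vtk_series_name("cells", 0)
    name10 = io.vtk_series_name("cells", 10)
    assert name0 == "cells_00000.vtk" and name10 == "cells_00010.vtk"
    cell_path = tmp_path / name0
    io.write_vtk_cells(st, cell_path)
    body = cell_path.read_text()
    assert f"POINTS {len(st.cells)}" in body
    assert "phenotype" in body and "maturation" in body
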