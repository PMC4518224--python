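"""MD-plot data layer: ensemble assembly, brushing, axis operations,
folded layout, scatter projections, and bit-exact export round trips."""

import numpy as np
import pytest

from dynamap.classify import Classification, classify_ensemble
from dynamap.core import ParameterPoint, ParameterSpec
from dynamap.library import get_model
from dynamap.mdplot import (
    Brush,
    brush,
    build_ensemble,
    export,
    filter_by_class,
    folded_layout,
    invert_axis,
    pc_segments,
    read_ensemble,
    reorder_axes,
    scatter_projection,
)
from dynamap.sampling import monte_carlo

SPECS = (
    ParameterSpec("a", 0.0, 10.0),
    ParameterSpec("b", 1e-3, 1.0, scale="log"),
    ParameterSpec("n", 1, 12, scale="linear", integer=True),
)


def _mk(points_and_classes):
    items = [
        Classification(ParameterPoint(dict(p)), [], cls)
        for p, cls in points_and_classes
    ]
    return build_ensemble(items, SPECS, metadata={"model": "toy", "seed": 0,
                                                  "method": "mc"})


@pytest.fixture()
def toy():
    rng = np.random.default_rng(0)
    rows = []
    classes = ["monostable", "oscillatory", "bistable", "monostable",
               "oscillatory", "monostable"]
    for i, cls in enumerate(classes):
        rows.append((
            {"a": float(rng.uniform(0, 10)),
             "b": float(10 ** rng.uniform(-3, 0)),
             "n": float(rng.integers(1, 13))},
            cls,
        ))
    return _mk(rows)


def test_build_single_midpoint_row():
    ens = _mk([({"a": 5.0, "b": 10 ** -1.5, "n": 6.0}, "monostable")])
    np.testing.assert_allclose(ens.unit[0, :2], [0.5, 0.5])
    assert sum(ens.counts().values()) == 1


def test_counts_sum_to_n_points(toy):
    assert sum(toy.counts().values()) == toy.n_points
    assert toy.metadata["counts"] == toy.counts()


def test_unit_matrix_recheckable_from_raw(toy):
    from dynamap.sampling import normalize_matrix

    np.testing.assert_array_equal(toy.unit, normalize_matrix(toy.raw, toy.specs))


def test_filter_identity_and_empty(toy):
    all_classes = set(toy.classes)
    same = filter_by_class(toy, all_classes)
    assert same.n_points == toy.n_points
    none = filter_by_class(toy, {"excitable_or_mixed"})
    assert none.n_points == 0
    assert sum(none.counts().values()) == 0


def test_filter_row_count_matches_metadata(toy):
    osc = filter_by_class(toy, {"oscillatory"})
    assert osc.n_points == toy.counts()["oscillatory"]
    with pytest.raises(ValueError, match="unknown dynamics classes"):
        filter_by_class(toy, {"wobbly"})


def test_brush_empty_keeps_all(toy):
    out = brush(toy, [])
    assert out.keep_mask().all()
    assert not out.highlight_mask().any()


def test_brush_highlight_partitions_rows(toy):
    # highlighting b < 0.1 splits rows into the strong/weak-threshold groups
    out = brush(toy, [Brush("b", (0.0, 0.1), mode="highlight")])
    hl = out.highlight_mask()
    np.testing.assert_array_equal(hl, toy.raw[:, 1] <= 0.1)
    assert out.keep_mask().all()


def test_brush_boundaries_inclusive():
    ens = _mk([({"a": 2.0, "b": 0.1, "n": 3.0}, "monostable")])
    out = brush(ens, [Brush("a", (2.0, 2.0), mode="keep")])
    assert out.keep_mask().all()


def test_disjoint_keep_brushes_empty(toy):
    out = brush(toy, [Brush("a", (0.0, 2.0), mode="keep"),
                      Brush("a", (8.0, 10.0), mode="keep")])
    assert not out.keep_mask().any()


def test_brush_unknown_axis(toy):
    with pytest.raises(ValueError, match="brush axis"):
        brush(toy, [Brush("zzz", (0, 1))])


def test_reorder_identity_and_inverse(toy):
    ident = reorder_axes(toy, ["a", "b", "n"])
    np.testing.assert_array_equal(ident.raw, toy.raw)
    perm = reorder_axes(toy, ["n", "a", "b"])
    back = reorder_axes(perm, ["a", "b", "n"])
    np.testing.assert_array_equal(back.raw, toy.raw)
    np.testing.assert_array_equal(back.unit, toy.unit)
    assert back.axis_names == toy.axis_names


def test_reorder_rejects_non_permutation(toy):
    with pytest.raises(ValueError, match="permutation"):
        reorder_axes(toy, ["a", "a", "b"])


def test_pc_segment_counts(toy):
    lines = pc_segments(toy)
    assert lines.n_polylines == toy.n_points
    assert lines.n_segments == toy.n_points * (len(SPECS) - 1)
    assert lines.vertices.shape == (toy.n_points, 3)


def test_pc_flat_polyline_for_equal_unit_values():
    # comparable rates show up as horizontal lines on the MD plot
    ens = _mk([({"a": 2.5, "b": 10 ** (-3 + 3 * 0.25), "n": 4.0}, "oscillatory")])
    lines = pc_segments(ens)
    row = lines.vertices[0]
    assert np.ptp(row[:2]) < 1e-12  # a and b both at unit value 0.25


def test_pc_respects_keep_and_highlight(toy):
    out = brush(toy, [Brush("a", (0.0, 5.0), mode="keep"),
                      Brush("b", (0.0, 0.1), mode="highlight")])
    lines = pc_segments(out)
    assert lines.n_polylines == int(out.keep_mask().sum())


def test_invert_axis_reflects_at_render_time(toy):
    inv = invert_axis(toy, "a")
    lines = pc_segments(inv)
    np.testing.assert_allclose(lines.vertices[:, 0], 1.0 - toy.unit[:, 0])
    # unit matrix itself untouched, so raw<->unit invariant holds
    np.testing.assert_array_equal(inv.unit, toy.unit)
    again = invert_axis(inv, "a")
    np.testing.assert_allclose(pc_segments(again).vertices, pc_segments(toy).vertices)


def test_folded_layout_panel_counts():
    four = folded_layout(["a", "b", "c", "d"],
                         panels=[("a", "b"), ("a", "c"), ("a", "d"),
                                 ("b", "c"), ("b", "d"), ("c", "d")])
    assert len(four.panels) == four.max_panels == 6
    nine = folded_layout([f"p{i}" for i in range(9)])
    assert nine.max_panels == 36
    # degenerate: two axes is just the standard PC plot
    two = folded_layout(["x", "y"])
    assert len(two.panels) == 1 and two.max_panels == 1


def test_folded_layout_geometry_and_errors():
    lay = folded_layout(["a", "b", "c"], arrangement="polygon")
    radii = np.linalg.norm(lay.axis_positions[:, :2], axis=1)
    np.testing.assert_allclose(radii, 1.0)
    with pytest.raises(ValueError, match="unknown axis"):
        folded_layout(["a", "b"], panels=[("a", "zzz")])
    with pytest.raises(ValueError, match="at least 2"):
        folded_layout(["a"])


def test_scatter_projection_single_row_identity():
    ens = _mk([({"a": 3.0, "b": 0.5, "n": 2.0}, "bistable")])
    proj = scatter_projection(ens, "a", "b")
    assert proj.x[0] == 3.0 and proj.y[0] == 0.5


def test_scatter_projection_expression_and_class_filter(toy):
    proj = scatter_projection(toy, "a/b", "a*n", classes={"oscillatory"})
    assert len(proj.x) == toy.counts()["oscillatory"]
    expected = toy.raw[:, 0] / toy.raw[:, 1]
    mask = np.array([c == "oscillatory" for c in toy.classes])
    np.testing.assert_allclose(proj.x, expected[mask])


def test_scatter_projection_drops_nonfinite():
    ens = _mk([({"a": 0.0, "b": 0.5, "n": 2.0}, "monostable"),
               ({"a": 2.0, "b": 0.5, "n": 2.0}, "monostable")])
    proj = scatter_projection(ens, "b/a", "n")
    assert proj.n_dropped == 1
    assert len(proj.x) == 1


@pytest.mark.parametrize("fmt", ["csv", "json"])
def test_export_import_round_trip_bit_exact(toy, tmp_path, fmt):
    toy2 = brush(toy, [Brush("b", (0.0, 0.1), mode="highlight")])
    path = export(toy2, tmp_path / f"ens.{fmt}")
    back = read_ensemble(path)
    assert back.axis_names == toy2.axis_names
    assert back.raw.tobytes() == toy2.raw.tobytes()
    assert back.unit.tobytes() == toy2.unit.tobytes()
    assert back.classes == toy2.classes
    np.testing.assert_array_equal(back.highlight_mask(), toy2.highlight_mask())
    assert back.metadata["counts"] == toy2.metadata["counts"]


def test_export_empty_ensemble(tmp_path):
    empty = _mk([])
    p = export(empty, tmp_path / "empty.csv")
    back = read_ensemble(p)
    assert back.n_points == 0
    lines = p.read_text().strip().splitlines()
    assert len(lines) == 2  # metadata comment + header only


def test_transform_commutes_with_export(toy, tmp_path):
    # reorder -> export -> import equals export -> import -> reorder
    order = ["n", "a", "b"]
    a = read_ensemble(export(reorder_axes(toy, order), tmp_path / "a.json"))
    b = reorder_axes(read_ensemble(export(toy, tmp_path / "b.json")), order)
    assert a.raw.tobytes() == b.raw.tobytes()
    assert a.classes == b.classes
    assert a.axis_names == b.axis_names


def test_json_counts_match_recomputed_tally(toy, tmp_path):
    import json

    path = export(toy, tmp_path / "ens.json")
    doc = json.loads(path.read_text())
    tally = {}
    for row in doc["rows"]:
        tally[row["class"]] = tally.get(row["class"], 0) + 1
    for cls, n in tally.items():
        assert doc["metadata"]["counts"][cls] == n


def test_pipeline_build_from_real_classification(goodwin_model, tmp_path):
    specs = [goodwin_model.spec_for(x) for x in ("kd1", "kd2")]
    ens = monte_carlo(specs, 15, seed=0)
    res = classify_ensemble(goodwin_model, ens)
    ce = build_ensemble(res, specs, metadata={"model": "goodwin", "seed": 0,
                                              "method": "mc"})
    assert ce.n_points == 15
    np.testing.assert_array_equal(ce.raw, ens.matrix)
    back = read_ensemble(export(ce, tmp_path / "run.csv"))
    assert back.raw.tobytes() == ce.raw.tobytes()
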