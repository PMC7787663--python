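"""Synapse-table QC, dedup, filters, aggregation, motifs, regions."""

import numpy as np
import pandas as pd
import pytest

import persistate as ps
from persistate.connectome import (aggregate_by_type, build_edges,
                                   dedup_detections, filter_edges, io_ratio,
                                   partner_counts, qc_summary, read_swc,
                                   reciprocal_partners, skeleton_centroid,
                                   terminals_by_region,
                                   type_connection_matrix)


def _table(rows):
    out = []
    for i, (pre, post, xyz) in enumerate(rows):
        out.append(dict(id=i, pre_cell=pre, post_cell=post,
                        pre_x_nm=xyz[0], pre_y_nm=xyz[1], pre_z_nm=xyz[2],
                        post_x_nm=xyz[0] + 40, post_y_nm=xyz[1],
                        post_z_nm=xyz[2], source="auto", qc_label="TP",
                        parent_id=-1))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# dedup
# ---------------------------------------------------------------------------


def test_close_pair_collapses_to_one():
    t = _table([("a", "b", (0, 0, 0)), ("a", "b", (100, 0, 0))])
    filt, report = dedup_detections(t)
    assert len(filt) == 1
    assert len(report) == 1


def test_pair_exactly_at_threshold_survives():
    t = _table([("a", "b", (0, 0, 0)), ("a", "b", (150.0, 0, 0))])
    filt, _ = dedup_detections(t)
    assert len(filt) == 2


def test_different_cell_pairs_never_merged():
    t = _table([("a", "b", (0, 0, 0)), ("a", "c", (10, 0, 0))])
    filt, _ = dedup_detections(t)
    assert len(filt) == 2
    filt_global, _ = dedup_detections(t, per_cell_pair=False)
    assert len(filt_global) == 1


def test_qc115_dedup_removes_expected_detections():
    df = ps.qc115_fixture()
    filt, report = dedup_detections(df)
    removed = report["qc_label"].value_counts()
    assert removed["redundant"] == 27
    assert removed["TP"] == 3
    assert len(filt) == 85


def test_dedup_idempotent(rng):
    cfg = ps.ConnectomeSynthConfig(seed=7, duplicate_rate=0.4)
    table = ps.gen_synapse_table(cfg)
    once, _ = dedup_detections(table)
    twice, report2 = dedup_detections(once)
    assert len(report2) == 0
    pd.testing.assert_frame_equal(once, twice)


def _bruteforce_single_linkage(xyz, threshold):
    n = len(xyz)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(xyz[i] - xyz[j]) < threshold:
                parent[find(i)] = find(j)
    return np.array([find(i) for i in range(n)])


@pytest.mark.parametrize("seed", range(20))
def test_dedup_equals_bruteforce_union_find(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 50))
    xyz = rng.uniform(0, 600, (n, 3))
    t = _table([("a", "b", tuple(p)) for p in xyz])
    filt, _ = dedup_detections(t, threshold_nm=150.0)
    comp = _bruteforce_single_linkage(xyz, 150.0)
    # one survivor per connected component, the lexicographic minimum
    expected_ids = []
    for c in np.unique(comp):
        members = np.where(comp == c)[0]
        order = np.lexsort((xyz[members, 2], xyz[members, 1],
                            xyz[members, 0]))
        expected_ids.append(members[order[0]])
    assert sorted(filt["id"]) == sorted(expected_ids)


# ---------------------------------------------------------------------------
# QC summary
# ---------------------------------------------------------------------------


def test_qc_percentages_of_reference_table():
    df = ps.qc115_fixture()
    filt, _ = dedup_detections(df)
    s = qc_summary(df, filt)
    assert s["percent"]["TP"] == 61.7
    assert s["percent"]["redundant"] == 24.3
    assert s["percent"]["FP"] == 13.9
    assert s["removed"] == {"TP": 3, "redundant": 27, "FP": 0}


def test_all_true_positive_table():
    t = _table([("a", "b", (i * 1000, 0, 0)) for i in range(10)])
    s = qc_summary(t)
    assert s["percent"] == {"TP": 100.0, "redundant": 0.0, "FP": 0.0}


def test_unlabeled_rows_excluded_and_counted():
    t = _table([("a", "b", (0, 0, 0)), ("a", "b", (1000, 0, 0))])
    t.loc[1, "qc_label"] = None
    s = qc_summary(t)
    assert s["n_unlabeled"] == 1
    assert s["percent"]["TP"] == 100.0


# ---------------------------------------------------------------------------
# edge filters
# ---------------------------------------------------------------------------


def _edges(counts, focus="F", direction="outputs"):
    rows = []
    for cell, n in counts.items():
        pre, post = (focus, cell) if direction == "outputs" else (cell, focus)
        rows.append({"pre_cell": pre, "post_cell": post, "count": n,
                     "autapse": False})
    return pd.DataFrame(rows)


def test_manual_filter_min3():
    edges = _edges({"A": 2, "B": 3})
    kept, _ = filter_edges(edges, "F", "outputs", "manual_min3")
    assert dict(kept) == {"B": 3}


def test_auto_filter_anchor_rule():
    edges = _edges({"c1": 16, "c2": 7, "c3": 5, "d1": 9})
    ann = pd.DataFrame({"cell": ["c1", "c2", "c3", "d1"],
                        "type": ["X", "X", "X", "Y"]})
    kept, dropped = filter_edges(edges, "F", "outputs",
                                 "auto_min6_anchor15", ann)
    # X anchored by c1 (16 >= 15): keep c1, c2 (>= 6); drop c3 (5) and d1
    # (type Y has no anchor)
    assert dict(kept) == {"c1": 16, "c2": 7}


def test_unannotated_cells_dropped_and_logged():
    edges = _edges({"c1": 20, "mystery": 8})
    ann = pd.DataFrame({"cell": ["c1"], "type": ["X"]})
    kept, dropped = filter_edges(edges, "F", "outputs",
                                 "auto_min6_anchor15", ann)
    assert dropped == ["mystery"]
    assert "mystery" not in kept


@pytest.mark.parametrize("seed", range(20))
def test_filters_equal_bruteforce(seed):
    rng = np.random.default_rng(seed)
    cells = [f"c{i}" for i in range(12)]
    counts = {c: int(rng.integers(1, 20)) for c in cells}
    types = {c: f"T{rng.integers(0, 3)}" for c in cells}
    ann = pd.DataFrame({"cell": cells, "type": [types[c] for c in cells]})
    edges = _edges(counts)
    kept_m, _ = filter_edges(edges, "F", "outputs", "manual_min3")
    assert set(kept_m.index) == {c for c, n in counts.items() if n >= 3}
    kept_a, _ = filter_edges(edges, "F", "outputs", "auto_min6_anchor15", ann)
    anchors = {types[c] for c, n in counts.items() if n >= 15}
    expect = {c for c, n in counts.items()
              if n >= 6 and types[c] in anchors}
    assert set(kept_a.index) == expect
    # auto mode is a subset of manual at min 6 whenever anchors exist
    assert set(kept_a.index) <= {c for c, n in counts.items() if n >= 6}


# ---------------------------------------------------------------------------
# aggregation, ratios, reciprocity
# ---------------------------------------------------------------------------


def test_reference_output_aggregation_cumulative():
    """Top three output types carry 49.4% of 421 output synapses."""
    others = [35, 33, 30, 28, 25, 22, 20, 20]
    assert sum(others) + 131 + 39 + 38 == 421
    counts = {"aIPg-a.0": 131, "aIPg-c.0": 39, "aIPg-b.0": 38}
    ann_rows = [("aIPg-a.0", "aIPg-a"), ("aIPg-c.0", "aIPg-c"),
                ("aIPg-b.0", "aIPg-b")]
    for i, n in enumerate(others):
        counts[f"o{i}.0"] = n
        ann_rows.append((f"o{i}.0", f"other{i}"))
    ann = pd.DataFrame(ann_rows, columns=["cell", "type"])
    agg = aggregate_by_type(pd.Series(counts), ann)
    top3 = agg["cumulative_fraction"].iloc[2]
    assert round(100 * top3, 1) == 49.4


def test_single_type_cumulative_jumps_to_one():
    ann = pd.DataFrame({"cell": ["a"], "type": ["T"]})
    agg = aggregate_by_type(pd.Series({"a": 7}), ann)
    assert agg["cumulative_fraction"].iloc[0] == 1.0


def test_cumulative_curve_is_valid_cdf(rng):
    cells = [f"c{i}" for i in range(15)]
    ann = pd.DataFrame({"cell": cells,
                        "type": [f"T{rng.integers(0, 6)}" for _ in cells]})
    counts = pd.Series({c: int(rng.integers(1, 40)) for c in cells})
    agg = aggregate_by_type(counts, ann)
    cf = agg["cumulative_fraction"].to_numpy()
    assert np.all(np.diff(cf) >= -1e-12)
    assert cf[-1] == pytest.approx(1.0)
    assert np.all(np.diff(agg["count"].to_numpy()) <= 0)


def test_reference_output_input_ratios():
    rows = []
    for cell, out, inp in (("aIPg-a.0", 588, 0), ("aIPg-b.0", 38, 39),
                           ("aIPg-c.0", 39, 14)):
        rows.append({"pre_cell": "pC1d", "post_cell": cell, "count": out,
                     "autapse": False})
        if inp:
            rows.append({"pre_cell": cell, "post_cell": "pC1d", "count": inp,
                         "autapse": False})
    edges = pd.DataFrame(rows)
    assert io_ratio(edges, "pC1d", ["aIPg-c.0"])["ratio"] == 2.8
    assert io_ratio(edges, "pC1d", ["aIPg-b.0"])["ratio"] == 1.0
    assert io_ratio(edges, "pC1d", ["aIPg-a.0"])["ratio"] == "588:0"
    empty = io_ratio(edges, "pC1d", ["nobody"])
    assert empty["ratio"] is None and empty["flag"] == "no_connections"


def test_reciprocal_partner_rules():
    rows = [
        {"pre_cell": "A", "post_cell": "F", "count": 10, "autapse": False},
        {"pre_cell": "F", "post_cell": "A", "count": 7, "autapse": False},
        {"pre_cell": "B", "post_cell": "F", "count": 10, "autapse": False},
        {"pre_cell": "F", "post_cell": "B", "count": 5, "autapse": False},
    ]
    edges = pd.DataFrame(rows)
    assert reciprocal_partners(edges, "F", min_each_way=6) == ["A"]


@pytest.mark.parametrize("seed", range(10))
def test_reciprocity_equals_bruteforce_scan(seed):
    rng = np.random.default_rng(seed)
    cells = [f"c{i}" for i in range(8)]
    rows = []
    for pre in cells:
        for post in cells:
            if pre != post and rng.random() < 0.4:
                rows.append({"pre_cell": pre, "post_cell": post,
                             "count": int(rng.integers(1, 15)),
                             "autapse": False})
    edges = pd.DataFrame(rows)
    got = reciprocal_partners(edges, "c0", min_each_way=6)
    lut = {(r["pre_cell"], r["post_cell"]): r["count"] for r in rows}
    expect = sorted(c for c in cells if c != "c0"
                    and lut.get(("c0", c), 0) >= 6
                    and lut.get((c, "c0"), 0) >= 6)
    assert got == expect


def test_connection_matrix_blocks(rng):
    groups = {f"c{i}": ("g1" if i < 3 else "g2") for i in range(6)}
    rows = []
    for pre in groups:
        for post in groups:
            if pre != post and rng.random() < 0.5:
                rows.append({"pre_cell": pre, "post_cell": post,
                             "count": int(rng.integers(1, 9)),
                             "autapse": False})
    edges = pd.DataFrame(rows)
    mat, block = type_connection_matrix(edges, groups)
    for ga in ("g1", "g2"):
        for gb in ("g1", "g2"):
            oracle = sum(r["count"] for r in rows
                         if groups[r["pre_cell"]] == ga
                         and groups[r["post_cell"]] == gb)
            assert block.loc[ga, gb] == oracle
    empty_mat, empty_block = type_connection_matrix(
        pd.DataFrame(columns=["pre_cell", "post_cell", "count", "autapse"]),
        groups)
    assert (empty_block.to_numpy() == 0).all()


def test_edge_builder_counts_and_autapses():
    det = _table([("a", "b", (0, 0, 0)), ("a", "b", (5000, 0, 0)),
                  ("a", "a", (9000, 0, 0))])
    edges = build_edges(det)
    ab = edges[(edges.pre_cell == "a") & (edges.post_cell == "b")]
    assert int(ab["count"].iloc[0]) == 2
    assert edges[edges.autapse]["pre_cell"].tolist() == ["a"]


# ---------------------------------------------------------------------------
# regions & skeletons
# ---------------------------------------------------------------------------


def test_terminals_all_in_one_region():
    vol = np.ones((4, 4, 4), dtype=int)
    xyz = np.array([[100.0, 100.0, 100.0], [300.0, 300.0, 300.0]])
    df, pct = terminals_by_region(xyz, vol, {1: "R"},
                                  nm_per_voxel=(100, 100, 100),
                                  region_set=["R"])
    assert pct == 100.0
    df2, pct2 = terminals_by_region(xyz, vol, {1: "R"},
                                    nm_per_voxel=(100, 100, 100),
                                    region_set=[])
    assert pct2 == 0.0


def test_out_of_volume_terminals_unassigned(rng):
    vol = np.zeros((3, 3, 3), dtype=int)
    vol[0, 0, 0] = 2
    xyz = np.array([[50.0, 50.0, 50.0], [10_000.0, 0.0, 0.0]])
    df, _ = terminals_by_region(xyz, vol, {2: "R"},
                                nm_per_voxel=(100, 100, 100))
    counts = dict(zip(df.region, df["count"]))
    assert counts == {"R": 1, "unassigned": 1}


def test_random_terminal_tallies_match_bruteforce(rng):
    vol = rng.integers(0, 3, (5, 6, 7))
    names = {0: "bg", 1: "A", 2: "B"}
    xyz = rng.uniform(0, 700, (200, 3))
    df, _ = terminals_by_region(xyz, vol, names, nm_per_voxel=(100, 100, 100))
    got = dict(zip(df.region, df["count"]))
    oracle: dict = {}
    for x, y, z in np.floor(xyz / 100).astype(int):
        name = names[vol[z, y, x]] if (x < 7 and y < 6 and z < 5) \
            else "unassigned"
        oracle[name] = oracle.get(name, 0) + 1
    assert got == oracle


def test_swc_roundtrip_and_centroid(tmp_path):
    swc = tmp_path / "cell.swc"
    swc.write_text("# synthetic test skeleton\n"
                   "1 1 0.0 0.0 0.0 2.0 -1\n"
                   "2 3 10.0 0.0 0.0 1.0 1\n"
                   "3 3 10.0 10.0 0.0 1.0 2\n")
    df = read_swc(swc)
    assert len(df) == 3
    assert df["parent"].tolist() == [-1, 1, 2]
    c = skeleton_centroid(df)
    assert c == pytest.approx(np.array([5.0, 2.5, 0.0]))
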