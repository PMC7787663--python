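"""Synapse-table analytics for EM connectivity of single focus neurons.

Operates on detection-level synapse tables (one row per detected synapse,
with pre/post cell ids and presynaptic coordinates in nm) and cell-type
annotation tables. Implements the quality-control and filtering pipeline
used for automatically detected synapses — distance-based removal of
redundant detections (two coordinates for the same synapse), minimum
synapse-count filters for manual (>= 3) and automatic (>= 6 with a
15-synapse type anchor) detection — plus per-type aggregation,
output:input ratios, reciprocal-partner detection, group connection
matrices and region tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

PRE_XYZ = ["pre_x_nm", "pre_y_nm", "pre_z_nm"]


# ---------------------------------------------------------------------------
# Deduplication & QC
# ---------------------------------------------------------------------------


def _single_linkage_clusters(xyz: np.ndarray, threshold: float) -> np.ndarray:
    """Single-linkage clusters under strict distance < threshold."""
    if len(xyz) == 1:
        return np.zeros(1, dtype=int)
    d = pdist(xyz)
    # fcluster's 'distance' criterion is <=; nudge to make the cut strict
    z = linkage(d, method="single")
    eps = max(threshold * 1e-9, 1e-9)
    return fcluster(z, t=threshold - eps, criterion="distance")


def dedup_detections(
    table: pd.DataFrame,
    threshold_nm: float = 150.0,
    per_cell_pair: bool = True,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse redundant detections by presynaptic-coordinate proximity.

    Within each (pre_cell, post_cell) pair (or globally when
    ``per_cell_pair`` is False), detections whose presynaptic coordinates
    chain together at pairwise distance strictly below ``threshold_nm``
    (single linkage) collapse to one representative — the detection with
    the lexicographically smallest presynaptic coordinate. Detections at
    exactly the threshold are kept apart.

    Returns (filtered table, removal report). The report has one row per
    removed detection with its cluster id and the representative kept.
    """
    if len(table) == 0:
        return table.copy(), pd.DataFrame(
            columns=["id", "cluster", "kept_id", "qc_label"])
    groups = table.groupby(["pre_cell", "post_cell"], sort=False) \
        if per_cell_pair else [((None, None), table)]
    keep_idx: List[int] = []
    removed_rows: List[dict] = []
    cluster_counter = 0
    for _, g in groups:
        xyz = g[PRE_XYZ].to_numpy(dtype=float)
        labels = _single_linkage_clusters(xyz, threshold_nm)
        for c in np.unique(labels):
            sel = np.where(labels == c)[0]
            sub = g.iloc[sel]
            order = np.lexsort((
                sub[PRE_XYZ[2]].to_numpy(), sub[PRE_XYZ[1]].to_numpy(),
                sub[PRE_XYZ[0]].to_numpy()))
            rep_pos = sel[order[0]]
            keep_idx.append(g.index[rep_pos])
            for pos in sel:
                if pos == rep_pos:
                    continue
                row = g.iloc[pos]
                removed_rows.append({
                    "id": row["id"], "cluster": cluster_counter,
                    "kept_id": g.iloc[rep_pos]["id"],
                    "qc_label": row.get("qc_label", None)})
            cluster_counter += 1
    filtered = table.loc[sorted(keep_idx)].reset_index(drop=True)
    report = pd.DataFrame(removed_rows,
                          columns=["id", "cluster", "kept_id", "qc_label"])
    return filtered, report


def qc_summary(
    table: pd.DataFrame, filtered: Optional[pd.DataFrame] = None
) -> dict:
    """Percentages and tallies of QC labels, before and after filtering.

    Percentages are of labeled detections, rounded to 0.1. Unlabeled rows
    are excluded and counted.
    """
    labeled = table[table["qc_label"].isin(["TP", "redundant", "FP"])]
    n = len(labeled)
    out = {
        "n_detections": int(len(table)),
        "n_unlabeled": int(len(table) - n),
        "counts": {k: int((labeled["qc_label"] == k).sum())
                   for k in ("TP", "redundant", "FP")},
    }
    out["percent"] = {k: round(100.0 * v / n, 1) if n else float("nan")
                      for k, v in out["counts"].items()}
    if filtered is not None:
        kept_ids = set(filtered["id"])
        removed = labeled[~labeled["id"].isin(kept_ids)]
        kept = labeled[labeled["id"].isin(kept_ids)]
        out["removed"] = {k: int((removed["qc_label"] == k).sum())
                          for k in ("TP", "redundant", "FP")}
        out["remaining"] = {k: int((kept["qc_label"] == k).sum())
                            for k in ("TP", "redundant", "FP")}
        nk = len(kept)
        out["remaining_percent"] = {
            k: round(100.0 * v / nk, 1) if nk else float("nan")
            for k, v in out["remaining"].items()}
    return out


# ---------------------------------------------------------------------------
# Edge building & filtering
# ---------------------------------------------------------------------------


def build_edges(table: pd.DataFrame) -> pd.DataFrame:
    """Detection table -> directed edge table with synapse counts.

    Autapses (pre_cell == post_cell) are retained but flagged.
    """
    edges = (table.groupby(["pre_cell", "post_cell"], sort=False)
             .size().reset_index(name="count"))
    edges["autapse"] = edges["pre_cell"] == edges["post_cell"]
    return edges


def partner_counts(
    edges: pd.DataFrame, focus: str, direction: str
) -> pd.Series:
    """Synapse count per partner cell of ``focus`` in one direction."""
    if direction == "outputs":
        sel = edges[edges["pre_cell"] == focus]
        return sel.groupby("post_cell")["count"].sum()
    if direction == "inputs":
        sel = edges[edges["post_cell"] == focus]
        return sel.groupby("pre_cell")["count"].sum()
    raise ValueError("direction must be 'inputs' or 'outputs'")


def filter_edges(
    edges: pd.DataFrame,
    focus: str,
    direction: str,
    mode: str,
    annotations: Optional[pd.DataFrame] = None,
) -> Tuple[pd.Series, List[str]]:
    """Apply the per-direction partner filter for one focus cell.

    ``manual_min3`` drops partners connected with fewer than 3 synapses.
    ``auto_min6_anchor15`` keeps a partner iff its count is >= 6 AND its
    annotated type contains at least one cell with >= 15 synapses with the
    focus (counts evaluated within the given direction); unannotated cells
    are dropped and logged. Returns (kept partner counts, dropped-cell log).
    """
    counts = partner_counts(edges, focus, direction)
    dropped: List[str] = []
    if mode == "manual_min3":
        return counts[counts >= 3], dropped
    if mode != "auto_min6_anchor15":
        raise ValueError("mode must be 'manual_min3' or 'auto_min6_anchor15'")
    if annotations is None:
        raise ValueError("auto mode requires annotations")
    type_of = dict(zip(annotations["cell"], annotations["type"]))
    anchor_types = set()
    for cell, n in counts.items():
        if n >= 15 and cell in type_of:
            anchor_types.add(type_of[cell])
    keep = {}
    for cell, n in counts.items():
        if cell not in type_of:
            dropped.append(cell)
            continue
        if n >= 6 and type_of[cell] in anchor_types:
            keep[cell] = n
    return pd.Series(keep, dtype=int).sort_index(), dropped


# ---------------------------------------------------------------------------
# Aggregation, ratios, reciprocity
# ---------------------------------------------------------------------------


def aggregate_by_type(
    counts: pd.Series, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Per-type synapse totals sorted descending, with cumulative fraction.

    Ties in the descending sort are broken alphabetically by type name.
    """
    type_of = dict(zip(annotations["cell"], annotations["type"]))
    totals: Dict[str, int] = {}
    for cell, n in counts.items():
        t = type_of.get(cell, "unannotated")
        totals[t] = totals.get(t, 0) + int(n)
    df = pd.DataFrame(sorted(totals.items(),
                             key=lambda kv: (-kv[1], kv[0])),
                      columns=["type", "count"])
    total = df["count"].sum()
    df["cumulative_fraction"] = df["count"].cumsum() / total if total else 0.0
    return df


def io_ratio(
    edges: pd.DataFrame, focus: str, partner_cells: Sequence[str]
) -> dict:
    """Output:input synapse ratio between a focus cell and a partner set.

    The ratio is outputs/inputs rounded to one decimal; when there are no
    inputs it is reported as the string ``"<outputs>:0"``.
    """
    partner_cells = set(partner_cells)
    outputs = int(edges[(edges["pre_cell"] == focus)
                        & (edges["post_cell"].isin(partner_cells))]["count"].sum())
    inputs = int(edges[(edges["post_cell"] == focus)
                       & (edges["pre_cell"].isin(partner_cells))]["count"].sum())
    out: dict = {"outputs": outputs, "inputs": inputs}
    if outputs == 0 and inputs == 0:
        out["ratio"] = None
        out["flag"] = "no_connections"
    elif inputs == 0:
        out["ratio"] = f"{outputs}:0"
    else:
        out["ratio"] = round(outputs / inputs, 1)
    return out


def reciprocal_partners(
    edges: pd.DataFrame, focus: str, min_each_way: int = 6
) -> List[str]:
    """Partners with at least ``min_each_way`` synapses in both directions."""
    outs = partner_counts(edges, focus, "outputs")
    ins = partner_counts(edges, focus, "inputs")
    return sorted(
        c for c in set(outs.index) & set(ins.index)
        if outs[c] >= min_each_way and ins[c] >= min_each_way)


def type_connection_matrix(
    edges: pd.DataFrame,
    groups: Dict[str, str],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-by-cell synapse matrix plus within/between group block sums.

    ``groups`` maps cell id -> group name; only cells present in the map
    are included. Returns (cell matrix, group block-sum matrix) with rows
    as presynaptic, columns postsynaptic.
    """
    cells = sorted(groups)
    mat = pd.DataFrame(0, index=cells, columns=cells, dtype=int)
    for _, e in edges.iterrows():
        if e["pre_cell"] in groups and e["post_cell"] in groups:
            mat.loc[e["pre_cell"], e["post_cell"]] += int(e["count"])
    gnames = sorted(set(groups.values()))
    block = pd.DataFrame(0, index=gnames, columns=gnames, dtype=int)
    for pre in cells:
        for post in cells:
            block.loc[groups[pre], groups[post]] += mat.loc[pre, post]
    return mat, block


# ---------------------------------------------------------------------------
# Region tallies & skeletons
# ---------------------------------------------------------------------------


def terminals_by_region(
    xyz_nm: np.ndarray,
    label_volume: np.ndarray,
    region_names: Dict[int, str],
    nm_per_voxel: Sequence[float],
    region_set: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, float]:
    """Tally synaptic terminals per labeled region.

    ``label_volume`` is an integer-labeled (z, y, x) volume; coordinates
    are divided by ``nm_per_voxel`` (x, y, z order) to index it.
    Out-of-volume terminals count as "unassigned". Returns (per-region
    counts/percentages, percent of terminals inside ``region_set``).
    """
    xyz = np.asarray(xyz_nm, dtype=float)
    scale = np.asarray(nm_per_voxel, dtype=float)
    vox = np.floor(xyz / scale).astype(int)
    nz, ny, nx = label_volume.shape
    counts: Dict[str, int] = {}
    for x, y, z in vox:
        if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
            name = region_names.get(int(label_volume[z, y, x]), "unassigned")
        else:
            name = "unassigned"
        counts[name] = counts.get(name, 0) + 1
    total = len(vox)
    df = pd.DataFrame(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
                      columns=["region", "count"])
    df["percent"] = 100.0 * df["count"] / total if total else 0.0
    pct = 0.0
    if region_set:
        in_set = sum(counts.get(r, 0) for r in region_set)
        pct = 100.0 * in_set / total if total else 0.0
    return df, pct


def read_swc(path) -> pd.DataFrame:
    """Read an SWC skeleton into a DataFrame (id, type, x, y, z, radius,
    parent)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["id", "type", "x", "y", "z", "radius", "parent"])
    return df


def skeleton_centroid(swc: pd.DataFrame) -> np.ndarray:
    """Radius-weighted centroid of an SWC skeleton's nodes."""
    w = swc["radius"].to_numpy(dtype=float)
    if w.sum() <= 0:
        w = np.ones(len(swc))
    pts = swc[["x", "y", "z"]].to_numpy(dtype=float)
    return (pts * w[:, None]).sum(axis=0) / w.sum()
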