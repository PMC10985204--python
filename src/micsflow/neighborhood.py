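"""Radius-based cellular neighborhood analysis.

For an anchor population (e.g. PD1-high T cells) and a physical radius
(5 µm for touching-distance neighbors, 25 µm for the wider niche), the
analysis finds every cell whose centroid lies within the radius of any
anchor, pools those neighbors, intersects the pool with the annotated
populations, and profiles each population's composition and
immune-checkpoint expression.  Distances are centroid-to-centroid in
micrometers; queries run on a KD-tree but are contractually identical
to brute-force all-pairs evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

#: Immune-modulating markers profiled on neighbor cells by default.
DEFAULT_CHECKPOINT_MARKERS = (
    "CD112", "CD155", "CD276", "CD39", "CD73", "IDO", "PD-L1", "VISTA",
)


@dataclass(frozen=True)
class NeighborhoodQuery:
    anchor_population: str | None = None
    anchor_ids: tuple[int, ...] | None = None
    radius_um: float = 5.0
    distance_mode: str = "centroid"
    include_anchors: bool = False

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")
        if self.distance_mode != "centroid":
            raise NotImplementedError("only centroid distance is implemented")
        if self.anchor_population is None and self.anchor_ids is None:
            raise ValueError("query needs anchor_population or anchor_ids")


@dataclass
class NeighborhoodResult:
    query: NeighborhoodQuery
    per_anchor: dict[int, list[int]]  # anchor cell_id -> sorted neighbor ids
    pooled: list[int]  # union of neighbor ids, sorted
    edges: pd.DataFrame  # anchor_id, neighbor_id, distance_um


def _coords_um(cells: pd.DataFrame) -> np.ndarray:
    if "cy_um" in cells.columns and "cx_um" in cells.columns:
        return cells[["cy_um", "cx_um"]].to_numpy(dtype=np.float64)
    raise ValueError("cell table needs cy_um/cx_um centroid columns")


def _anchor_mask(
    cells: pd.DataFrame, query: NeighborhoodQuery, label_column: str
) -> np.ndarray:
    if query.anchor_ids is not None:
        return cells["cell_id"].isin(query.anchor_ids).to_numpy()
    mask = (cells[label_column] == query.anchor_population).to_numpy()
    if not mask.any():
        raise ValueError(
            f"no anchor cells with label {query.anchor_population!r} in {label_column}"
        )
    return mask


def radius_query(
    cells: pd.DataFrame,
    query: NeighborhoodQuery,
    label_column: str = "label_main_populations",
) -> NeighborhoodResult:
    """Find, per anchor, every cell within the query radius.

    Cell j neighbors anchor i iff the Euclidean centroid distance is
    ≤ radius_um.  Anchors are excluded from neighbor sets unless
    ``include_anchors``; output ordering is sorted by cell id.
    """
    coords = _coords_um(cells)
    ids = cells["cell_id"].to_numpy()
    mask = _anchor_mask(cells, query, label_column)
    anchor_idx = np.flatnonzero(mask)
    anchor_id_set = set(ids[anchor_idx].tolist())

    tree = cKDTree(coords)
    hits = tree.query_ball_point(coords[anchor_idx], r=query.radius_um)
    per_anchor: dict[int, list[int]] = {}
    rows = []
    for ai, neighbor_rows in zip(anchor_idx, hits):
        aid = int(ids[ai])
        neigh = []
        for j in neighbor_rows:
            nid = int(ids[j])
            if j == ai:
                continue
            if not query.include_anchors and nid in anchor_id_set:
                continue
            d = float(np.hypot(*(coords[j] - coords[ai])))
            neigh.append(nid)
            rows.append({"anchor_id": aid, "neighbor_id": nid, "distance_um": d})
        per_anchor[aid] = sorted(neigh)
    pooled = sorted({r["neighbor_id"] for r in rows})
    edges = pd.DataFrame(rows, columns=["anchor_id", "neighbor_id", "distance_um"])
    edges = edges.sort_values(["anchor_id", "neighbor_id"], ignore_index=True)
    return NeighborhoodResult(query=query, per_anchor=per_anchor, pooled=pooled, edges=edges)


def intersect_populations(
    cells: pd.DataFrame,
    pooled_neighbors: list[int],
    label_column: str,
    unassigned_label: str = "unassigned",
) -> pd.DataFrame:
    """Per-population counts and fractions among the pooled neighbors
    (the merge-then-intersect step).  Fractions are over labeled
    neighbors; with an empty neighbor set all fractions are NaN."""
    sub = cells[cells["cell_id"].isin(pooled_neighbors)]
    labels = sorted(cells[label_column].unique())
    counts = sub[label_column].value_counts()
    labeled_total = int(counts.drop(unassigned_label, errors="ignore").sum())
    rows = []
    for lbl in labels:
        c = int(counts.get(lbl, 0))
        if lbl == unassigned_label or labeled_total == 0:
            frac = np.nan
        else:
            frac = c / labeled_total
        rows.append({"label": lbl, "count": c, "fraction": frac})
    return pd.DataFrame(rows)


def neighbor_expression_profile(
    cells: pd.DataFrame,
    pooled_neighbors: list[int],
    label_column: str,
    markers: tuple[str, ...] = DEFAULT_CHECKPOINT_MARKERS,
    compartment: str = "cell",
) -> pd.DataFrame:
    """Median and quartiles of normalized marker expression for each
    population among the neighbor cells."""
    cols = {m: f"{m}__{compartment}__norm" for m in markers}
    missing = [m for m, c in cols.items() if c not in cells.columns]
    if missing:
        raise ValueError(f"markers missing from cell table: {missing}")
    sub = cells[cells["cell_id"].isin(pooled_neighbors)]
    rows = []
    for lbl, grp in sub.groupby(label_column, sort=True):
        for m, c in cols.items():
            v = grp[c].dropna().to_numpy()
            rows.append(
                {
                    "label": lbl,
                    "marker": m,
                    "n": len(v),
                    "median": np.median(v) if len(v) else np.nan,
                    "q25": np.percentile(v, 25) if len(v) else np.nan,
                    "q75": np.percentile(v, 75) if len(v) else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["label", "marker", "n", "median", "q25", "q75"])


def compare_anchor_sets(
    cells: pd.DataFrame,
    query_a: NeighborhoodQuery,
    query_b: NeighborhoodQuery,
    label_column: str,
    markers: tuple[str, ...] | None = DEFAULT_CHECKPOINT_MARKERS,
) -> dict[str, pd.DataFrame]:
    """Side-by-side composition (and optionally expression) profiles of
    two anchor populations at the same radius (e.g. PD1-high vs PD1-low
    T cells)."""
    res_a = radius_query(cells, query_a, label_column)
    res_b = radius_query(cells, query_b, label_column)
    comp_a = intersect_populations(cells, res_a.pooled, label_column)
    comp_b = intersect_populations(cells, res_b.pooled, label_column)
    comp = comp_a.merge(comp_b, on="label", suffixes=("_a", "_b"))
    out = {"composition": comp}
    if markers is not None:
        prof_a = neighbor_expression_profile(cells, res_a.pooled, label_column, markers)
        prof_b = neighbor_expression_profile(cells, res_b.pooled, label_column, markers)
        out["profiles"] = prof_a.merge(
            prof_b, on=["label", "marker"], how="outer", suffixes=("_a", "_b")
        )
    return out


def permutation_enrichment_test(
    cells: pd.DataFrame,
    query: NeighborhoodQuery,
    target_label: str,
    label_column: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Anchor-label shuffling null for within-radius enrichment.

    The statistic is the fraction of pooled neighbors carrying
    ``target_label``.  Anchor status is shuffled over all cells while
    positions and labels stay fixed; the one-sided p-value is the
    proportion of permutations with a statistic at least as large
    (add-one correction).
    """
    coords = _coords_um(cells)
    labels = cells[label_column].to_numpy()
    mask = _anchor_mask(cells, query, label_column)
    n_anchors = int(mask.sum())
    tree = cKDTree(coords)

    def statistic(anchor_rows: np.ndarray) -> float:
        hits = tree.query_ball_point(coords[anchor_rows], r=query.radius_um)
        pooled = set()
        anchor_set = set(anchor_rows.tolist())
        for ai, rowlist in zip(anchor_rows, hits):
            for j in rowlist:
                if j != ai and (query.include_anchors or j not in anchor_set):
                    pooled.add(j)
        if not pooled:
            return np.nan
        pooled = np.fromiter(pooled, dtype=int)
        return float((labels[pooled] == target_label).mean())

    observed = statistic(np.flatnonzero(mask))
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.choice(len(cells), size=n_anchors, replace=False)
        null[i] = statistic(perm)
    valid = null[~np.isnan(null)]
    p = (1 + int((valid >= observed).sum())) / (1 + len(valid))
    return {
        "observed_fraction": observed,
        "null_mean": float(np.nanmean(null)),
        "p_value": float(p),
        "n_permutations": float(len(valid)),
    }
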