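"""Independent reference implementations used to validate the package.

Everything here is deliberately written from first principles — brute
force, closed form, or exhaustive enumeration — and shares no code with
the implementations under test.
"""

from __future__ import annotations

import itertools
import operator

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

_OPS = {">": operator.gt, ">=": operator.ge, "<": operator.lt, "<=": operator.le}


# ---------------------------------------------------------------------------
# neighborhood: brute-force all-pairs radius query


def brute_force_radius_query(
    cells: pd.DataFrame, radius_um: float, anchor_mask: np.ndarray,
    include_anchors: bool = False,
) -> tuple[dict[int, list[int]], list[int]]:
    coords = cells[["cy_um", "cx_um"]].to_numpy(dtype=np.float64)
    ids = cells["cell_id"].to_numpy()
    anchor_ids = set(int(i) for i in ids[anchor_mask])
    per_anchor: dict[int, list[int]] = {}
    for i in np.flatnonzero(anchor_mask):
        neigh = []
        for j in range(len(ids)):
            if j == i:
                continue
            nid = int(ids[j])
            if not include_anchors and nid in anchor_ids:
                continue
            d = float(np.sqrt(((coords[j] - coords[i]) ** 2).sum()))
            if d <= radius_um:
                neigh.append(nid)
        per_anchor[int(ids[i])] = sorted(neigh)
    pooled = sorted(set(itertools.chain.from_iterable(per_anchor.values())))
    return per_anchor, pooled


# ---------------------------------------------------------------------------
# gating: scalar recursive evaluator and exhaustive minterm enumeration


def eval_gate_scalar(gate, pos: dict, vals: dict, pops: dict) -> bool:
    if "marker" in gate:
        m = gate["marker"]
        if "op" in gate:
            return bool(_OPS[gate["op"]](vals[m], gate["value"]))
        return bool(pos[m]) == bool(gate.get("positive", True))
    if "all" in gate:
        return all(eval_gate_scalar(g, pos, vals, pops) for g in gate["all"])
    if "any" in gate:
        return any(eval_gate_scalar(g, pos, vals, pops) for g in gate["any"])
    if "not" in gate:
        return not eval_gate_scalar(gate["not"], pos, vals, pops)
    if "population" in gate:
        return bool(pops[gate["population"]])
    raise ValueError(f"unknown gate node {gate!r}")


def gate_marker_names(gate) -> set[str]:
    if "marker" in gate:
        return {gate["marker"]}
    if "all" in gate or "any" in gate:
        kids = gate.get("all", gate.get("any"))
        out: set[str] = set()
        for g in kids:
            out |= gate_marker_names(g)
        return out
    if "not" in gate:
        return gate_marker_names(gate["not"])
    if "population" in gate:
        return set()
    raise ValueError(f"unknown gate node {gate!r}")


def exhaustive_schema_labels(schema, markers: list[str]):
    """Label every one of the 2^len(markers) boolean phenotypes.

    Per population, satisfaction is determined by enumerating the truth
    table of only the markers its gate mentions (scalar recursion), then
    lifted to the full phenotype index by bitmask comparison.  The final
    label picks the first satisfied population in descending priority
    (np.select), a different formulation from the engine's ascending
    best-so-far loop.  Only valid for schemas without population refs.
    """
    n = len(markers)
    idx = np.arange(1 << n, dtype=np.uint32)
    bit = {m: i for i, m in enumerate(markers)}
    satisfied: dict[str, np.ndarray] = {}
    for p in schema.populations:
        used = sorted(gate_marker_names(p["gate"]))
        used_bits = np.uint32(sum(1 << bit[m] for m in used))
        ok = np.zeros(idx.shape, dtype=bool)
        for assign in itertools.product([False, True], repeat=len(used)):
            pos = dict(zip(used, assign))
            if eval_gate_scalar(p["gate"], pos, pos, {}):
                bits = np.uint32(sum(1 << bit[m] for m, v in pos.items() if v))
                ok |= (idx & used_bits) == bits
        satisfied[p["label"]] = ok
    descending = sorted(schema.populations, key=lambda p: -p["priority"])
    labels = np.select(
        [satisfied[p["label"]] for p in descending],
        [p["label"] for p in descending],
        default=schema.unassigned_label,
    )
    return idx, labels.astype(object)


def phenotype_table_from_bits(idx: np.ndarray, markers: list[str]) -> pd.DataFrame:
    """Cell table whose normalized values are the 0/1 phenotype bits."""
    cols = {"cell_id": np.arange(1, len(idx) + 1)}
    for i, m in enumerate(markers):
        # float32 keeps the 2^20-row enumeration tables small
        cols[f"{m}__cell__norm"] = ((idx >> np.uint32(i)) & 1).astype(np.float32)
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# winsorization caps: inward closest-rank order statistics, closed form


def winsorize_caps(values, lower_pct: float, upper_pct: float):
    """Return (lo, hi) caps under the documented convention: rank
    position p/100*(n-1); lower cap at the ceiling rank, upper cap at
    the floor rank; None when the positions cross (no capping)."""
    v = np.sort(np.asarray(values, dtype=np.float64))
    v = v[~np.isnan(v)]
    n = v.size
    lo_i = int(np.ceil(lower_pct / 100.0 * (n - 1)))
    hi_i = int(np.floor(upper_pct / 100.0 * (n - 1)))
    if lo_i > hi_i:
        return None
    return float(v[lo_i]), float(v[hi_i])


# ---------------------------------------------------------------------------
# donut: per-pixel nearest-nucleus argmin


def brute_force_donut(nucleus: np.ndarray, width_px: float):
    """Assign every pixel within width_px of a nucleus to its nearest
    nucleus by explicit per-label distance transforms.

    Returns (labels, tie_mask); on tie pixels (several labels equally
    near, within 1e-9) any of the tied labels is acceptable, so the
    caller should compare only off-tie pixels and membership on ties.
    """
    labels = np.unique(nucleus)
    labels = labels[labels > 0]
    dists = np.stack([ndi.distance_transform_edt(nucleus != l) for l in labels])
    mind = dists.min(axis=0)
    arg = dists.argmin(axis=0)
    out = np.where(mind <= width_px, labels[arg], 0).astype(np.int32)
    ties = (np.isclose(dists, mind[None], atol=1e-9).sum(axis=0) > 1) & (
        mind <= width_px
    )
    return out, ties, dists, mind


# ---------------------------------------------------------------------------
# builders


def table_from_phenotypes(
    phenotypes: dict[str, set[str]], markers: list[str], n_per: int = 3,
    pos_value: float = 1.0, neg_value: float = 0.0,
) -> pd.DataFrame:
    """Cell table realizing each defining phenotype exactly, n_per cells
    per type; true labels in column 'true_label'."""
    rows = []
    for lbl, pos in phenotypes.items():
        for _ in range(n_per):
            row = {f"{m}__cell__norm": (pos_value if m in pos else neg_value)
                   for m in markers}
            row["true_label"] = lbl
            rows.append(row)
    df = pd.DataFrame(rows)
    df.insert(0, "cell_id", np.arange(1, len(df) + 1))
    return df
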