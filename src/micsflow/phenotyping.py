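"""Hierarchical marker gating and cell-state annotation.

Cells are classified by boolean threshold rules ("gates") on normalized
marker expression, arranged in priority-ordered annotation schemas.
Built-in schemas cover the main immune/stromal populations (16 labels),
a tonsil reference schema (13 labels), and T cell sub-state classifiers:
six differentiation states (naive through terminally differentiated
effector, from CD45RA/CD45RO/CD27/CD95/CD11a combinatorics), activation
tiers (CD69 early, CD25 late, HLA-DR very late), PD1 expression
quartile tiers, and the exhaustion ladder (PD1 single; PD1 plus TIM3 or
LAG3 double; PD1 plus both triple).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from .expression import marker_matrix


class SchemaError(ValueError):
    """Raised when a schema references missing markers or is malformed."""


# ---------------------------------------------------------------------------
# gate predicates

_OPS = {
    ">": np.greater,
    ">=": np.greater_equal,
    "<": np.less,
    "<=": np.less_equal,
}


def gate_markers(gate: Mapping) -> set[str]:
    """All marker names referenced by a gate predicate tree."""
    if "marker" in gate:
        return {gate["marker"]}
    if "all" in gate or "any" in gate:
        children = gate.get("all", gate.get("any"))
        return set().union(*(gate_markers(g) for g in children)) if children else set()
    if "not" in gate:
        return gate_markers(gate["not"])
    if "population" in gate:
        return set()
    raise SchemaError(f"unrecognized gate node: {gate!r}")


def evaluate_gate(
    gate: Mapping,
    positive: pd.DataFrame,
    values: pd.DataFrame,
    populations: Mapping[str, np.ndarray],
) -> np.ndarray:
    """Vectorized evaluation of a gate over all cells.

    ``positive`` is the boolean positivity matrix, ``values`` the
    normalized expression matrix (for explicit threshold atoms), and
    ``populations`` maps previously evaluated population names to masks.
    """
    if "marker" in gate:
        m = gate["marker"]
        if "op" in gate:
            return _OPS[gate["op"]](values[m].to_numpy(), gate["value"])
        want = bool(gate.get("positive", True))
        return positive[m].to_numpy() == want
    if "all" in gate:
        masks = [evaluate_gate(g, positive, values, populations) for g in gate["all"]]
        return np.logical_and.reduce(masks) if masks else np.ones(len(positive), bool)
    if "any" in gate:
        masks = [evaluate_gate(g, positive, values, populations) for g in gate["any"]]
        return np.logical_or.reduce(masks) if masks else np.zeros(len(positive), bool)
    if "not" in gate:
        return ~evaluate_gate(gate["not"], positive, values, populations)
    if "population" in gate:
        name = gate["population"]
        if name not in populations:
            raise SchemaError(f"gate references unknown population {name!r}")
        return populations[name]
    raise SchemaError(f"unrecognized gate node: {gate!r}")


@dataclass
class AnnotationSchema:
    """Priority-ordered list of (label, gate); highest priority wins."""

    name: str
    populations: list[dict]  # {"label", "priority", "gate"}
    unassigned_label: str = "unassigned"

    def __post_init__(self) -> None:
        labels = [p["label"] for p in self.populations]
        if len(set(labels)) != len(labels):
            raise SchemaError(f"{self.name}: duplicate labels")
        prios = [p["priority"] for p in self.populations]
        if len(set(prios)) != len(prios):
            raise SchemaError(f"{self.name}: priorities must be distinct")

    @property
    def labels(self) -> list[str]:
        return [p["label"] for p in self.populations]

    def markers(self) -> set[str]:
        return set().union(*(gate_markers(p["gate"]) for p in self.populations))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnotationSchema":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            name=doc["name"],
            populations=doc["populations"],
            unassigned_label=doc.get("unassigned_label", "unassigned"),
        )


def builtin_schema(name: str) -> AnnotationSchema:
    """Load a packaged schema: 'main_populations', 'tonsil', ..."""
    path = resources.files("micsflow.data") / "schemas" / f"{name}.json"
    return AnnotationSchema.from_json(Path(path))


def estimate_thresholds(
    values: pd.DataFrame, overrides: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Per-marker positivity thresholds on normalized values.

    Default: the midpoint of the largest gap between consecutive sorted
    values — the valley between the negative and positive modes of a
    well-separated bimodal distribution.  Unlike variance-based
    two-class splits, this stays correct when the positive population
    is rare (a handful of cells), at the cost of being conservative for
    strongly overlapping populations, where explicit overrides (expert
    gates) should be supplied.  Degenerate (constant) markers threshold
    above their maximum, i.e. all-negative.
    """
    out: dict[str, float] = {}
    for m in values.columns:
        v = values[m].to_numpy(dtype=np.float64)
        v = np.unique(v[~np.isnan(v)])
        if v.size == 0 or v.size == 1:
            out[m] = float(v.max() if v.size else 0.0) + 1.0
        else:
            gaps = np.diff(v)
            i = int(np.argmax(gaps))
            out[m] = float((v[i] + v[i + 1]) / 2)
    if overrides:
        out.update(overrides)
    return out


def positivity(
    values: pd.DataFrame, thresholds: Mapping[str, float]
) -> pd.DataFrame:
    missing = [m for m in values.columns if m not in thresholds]
    if missing:
        raise SchemaError(f"no thresholds for markers: {missing}")
    return pd.DataFrame(
        {m: values[m].to_numpy() > thresholds[m] for m in values.columns},
        index=values.index,
    )


def apply_schema(
    cells: pd.DataFrame,
    schema: AnnotationSchema,
    thresholds: Mapping[str, float] | None = None,
    compartment: str = "cell",
    column: str | None = None,
) -> pd.DataFrame:
    """Annotate cells: each gets the highest-priority satisfied label,
    else the schema's unassigned label.  Validates marker availability
    before labeling.  Returns a copy with the label column appended.
    """
    values = marker_matrix(cells, compartment=compartment, normalized=True)
    missing = sorted(schema.markers() - set(values.columns))
    if missing:
        raise SchemaError(f"{schema.name}: markers missing from table: {missing}")
    thr = (
        estimate_thresholds(values)
        if thresholds is None
        else {**estimate_thresholds(values), **thresholds}
    )
    pos = positivity(values, thr)

    labels = np.full(len(cells), schema.unassigned_label, dtype=object)
    best = np.full(len(cells), -np.inf)
    pop_masks: dict[str, np.ndarray] = {}
    for p in sorted(schema.populations, key=lambda p: p["priority"]):
        mask = evaluate_gate(p["gate"], pos, values, pop_masks)
        pop_masks[p["label"]] = mask
        take = mask & (p["priority"] > best)
        labels[take] = p["label"]
        best[take] = p["priority"]
    out = cells.copy()
    out[column or f"label_{schema.name}"] = labels
    return out


def merge_populations(
    cells: pd.DataFrame, label_column: str, labels: Sequence[str], merged: str,
    column: str | None = None,
) -> pd.DataFrame:
    """Union of gated populations into one combined label (the 'Merge'
    operation); other labels pass through unchanged."""
    out = cells.copy()
    col = column or label_column
    out[col] = np.where(
        cells[label_column].isin(list(labels)), merged, cells[label_column]
    )
    return out


# ---------------------------------------------------------------------------
# T cell differentiation

#: Boolean phenotype table for the six differentiation states.  Ordered;
#: the first matching row wins.  None = don't care.  CD11a-high is
#: required for every antigen-experienced state.  This is a
#: literature-standard reconstruction shipped as editable configuration.
DEFAULT_DIFFERENTIATION_TABLE: list[tuple[str, dict[str, bool | None]]] = [
    ("TN", {"CD45RA": True, "CD45RO": False, "CD27": True, "CD95": False}),
    ("TSCM", {"CD45RA": True, "CD27": True, "CD95": True, "CD11a": True}),
    ("TCM", {"CD45RA": False, "CD45RO": True, "CD27": True, "CD11a": True}),
    ("TEM", {"CD45RA": False, "CD45RO": True, "CD27": False, "CD11a": True}),
    ("TEMRA", {"CD45RA": True, "CD27": False, "CD95": True, "CD11a": True}),
    ("TTE", {"CD45RA": True, "CD27": False, "CD95": False, "CD11a": True}),
]

DIFFERENTIATION_STATES = [label for label, _ in DEFAULT_DIFFERENTIATION_TABLE]


def validate_differentiation_table(
    table: Sequence[tuple[str, dict[str, bool | None]]]
) -> list[tuple[str, str]]:
    """Return pairs of rows that a single phenotype could satisfy (the
    classifier resolves them first-match, but overlap merits a warning)."""
    overlaps = []
    for i, (la, ra) in enumerate(table):
        for lb, rb in table[i + 1 :]:
            shared = set(ra) & set(rb)
            if all(ra[m] == rb[m] for m in shared):
                overlaps.append((la, lb))
    return overlaps


def t_cell_differentiation(
    cells: pd.DataFrame,
    table: Sequence[tuple[str, dict[str, bool | None]]] | None = None,
    thresholds: Mapping[str, float] | None = None,
    compartment: str = "cell",
    column: str = "label_diff",
    other_label: str = "other T",
) -> pd.DataFrame:
    """Classify (pre-gated) T cells into differentiation states by the
    first matching row of the phenotype table; non-matching cells get
    ``other_label``."""
    table = list(DEFAULT_DIFFERENTIATION_TABLE if table is None else table)
    overlaps = validate_differentiation_table(table)
    if overlaps:
        warnings.warn(f"ambiguous differentiation rows: {overlaps}", stacklevel=2)
    markers = sorted({m for _, req in table for m in req})
    values = marker_matrix(cells, compartment=compartment, normalized=True)
    missing = [m for m in markers if m not in values.columns]
    if missing:
        raise SchemaError(f"differentiation markers missing: {missing}")
    thr = (
        estimate_thresholds(values[markers])
        if thresholds is None
        else {**estimate_thresholds(values[markers]), **thresholds}
    )
    pos = positivity(values[markers], thr)

    labels = np.full(len(cells), other_label, dtype=object)
    unset = np.ones(len(cells), dtype=bool)
    for label, req in table:
        mask = unset.copy()
        for m, want in req.items():
            if want is None:
                continue
            mask &= pos[m].to_numpy() == want
        labels[mask] = label
        unset &= ~mask
    out = cells.copy()
    out[column] = labels
    return out


# ---------------------------------------------------------------------------
# activation / PD1 tiers / exhaustion

ACTIVATION_TIERS = ["none", "early", "late", "very_late"]


def activation_tier(
    cells: pd.DataFrame,
    thresholds: Mapping[str, float] | None = None,
    compartment: str = "cell",
    column: str = "label_activation",
) -> pd.DataFrame:
    """Activation ladder: CD69 early, CD25 late, HLA-DR very late;
    co-positive cells resolve to the latest tier."""
    markers = ["CD69", "CD25", "HLA-DR"]
    values = marker_matrix(cells, compartment=compartment, normalized=True)
    missing = [m for m in markers if m not in values.columns]
    if missing:
        raise SchemaError(f"activation markers missing: {missing}")
    thr = (
        estimate_thresholds(values[markers])
        if thresholds is None
        else {**estimate_thresholds(values[markers]), **thresholds}
    )
    pos = positivity(values[markers], thr)
    labels = np.select(
        [pos["HLA-DR"], pos["CD25"], pos["CD69"]],
        ["very_late", "late", "early"],
        default="none",
    )
    out = cells.copy()
    out[column] = labels
    return out


@dataclass(frozen=True)
class TierSpec:
    """Percentile tiers of one marker over a reference population."""

    marker: str = "PD1"
    cut_percentiles: tuple[float, ...] = (25.0, 75.0)
    tier_labels: tuple[str, ...] = ("low", "intermediate", "high")
    reference_column: str | None = None  # boolean column selecting the reference
    compartment: str = "cell"

    def __post_init__(self) -> None:
        cuts = self.cut_percentiles
        if any(not 0 < c < 100 for c in cuts) or list(cuts) != sorted(set(cuts)):
            raise ValueError("cut_percentiles must be strictly increasing in (0,100)")
        if len(self.tier_labels) != len(cuts) + 1:
            raise ValueError("need one more tier label than cuts")


def percentile_rank(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Percentile rank (0–100) of each value within the reference sample,
    average-rank tie convention: pr = 100 · (avg_rank − 1) / n_ref."""
    reference = np.asarray(reference, dtype=np.float64)
    n = reference.size
    values = np.asarray(values, dtype=np.float64)
    below = np.searchsorted(np.sort(reference), values, side="left")
    equal = np.searchsorted(np.sort(reference), values, side="right") - below
    avg_rank = below + (equal + 1) / 2.0
    return 100.0 * (avg_rank - 1) / n


def pd1_tiers(
    cells: pd.DataFrame, spec: TierSpec = TierSpec(), column: str = "tier_pd1"
) -> pd.DataFrame:
    """Tier cells by the percentile rank of their normalized marker value
    within the reference population (default quartile cuts 25/75 giving
    low / intermediate / high).  A rank exactly at a cut belongs to the
    upper tier."""
    col = f"{spec.marker}__{spec.compartment}__norm"
    if col not in cells.columns:
        raise SchemaError(f"column {col} not in cell table")
    v = cells[col].to_numpy(dtype=np.float64)
    if spec.reference_column is not None:
        ref_mask = cells[spec.reference_column].to_numpy(dtype=bool)
    else:
        ref_mask = np.ones(len(cells), dtype=bool)
    ref = v[ref_mask & ~np.isnan(v)]
    if ref.size == 0:
        raise SchemaError("empty reference population for tiering")
    pr = percentile_rank(v, ref)
    tier_idx = np.searchsorted(np.asarray(spec.cut_percentiles), pr, side="right")
    labels = np.asarray(spec.tier_labels, dtype=object)[tier_idx]
    labels[np.isnan(v)] = "unassigned"
    out = cells.copy()
    out[column] = labels
    return out


EXHAUSTION_CLASSES = ["none", "single", "double", "triple"]


def exhaustion_class(
    cells: pd.DataFrame,
    thresholds: Mapping[str, float] | None = None,
    compartment: str = "cell",
    column: str = "label_exhaustion",
) -> pd.DataFrame:
    """Exhaustion ladder anchored on PD1: single = PD1 only, double = PD1
    plus exactly one of TIM3/LAG3, triple = PD1 plus both.  TIM3 or LAG3
    without PD1 count as none."""
    markers = ["PD1", "TIM3", "LAG3"]
    values = marker_matrix(cells, compartment=compartment, normalized=True)
    missing = [m for m in markers if m not in values.columns]
    if missing:
        raise SchemaError(f"exhaustion markers missing: {missing}")
    thr = (
        estimate_thresholds(values[markers])
        if thresholds is None
        else {**estimate_thresholds(values[markers]), **thresholds}
    )
    pos = positivity(values[markers], thr)
    pd1 = pos["PD1"].to_numpy()
    n_partners = pos["TIM3"].to_numpy().astype(int) + pos["LAG3"].to_numpy().astype(int)
    labels = np.select(
        [pd1 & (n_partners == 2), pd1 & (n_partners == 1), pd1],
        ["triple", "double", "single"],
        default="none",
    )
    out = cells.copy()
    out[column] = labels
    return out


def composition(
    cells: pd.DataFrame, by: str, unassigned_label: str = "unassigned"
) -> pd.DataFrame:
    """Counts and fractions per label.  Fractions are computed over
    labeled cells; the unassigned count is reported with a NaN fraction."""
    if len(cells) == 0:
        return pd.DataFrame(columns=["label", "count", "fraction"])
    counts = cells[by].value_counts()
    labeled = counts.drop(unassigned_label, errors="ignore")
    total = labeled.sum()
    rows = [
        {"label": lbl, "count": int(c), "fraction": c / total if total else np.nan}
        for lbl, c in labeled.items()
    ]
    if unassigned_label in counts:
        rows.append(
            {"label": unassigned_label, "count": int(counts[unassigned_label]),
             "fraction": np.nan}
        )
    return pd.DataFrame(rows).sort_values("label", ignore_index=True)


# ---------------------------------------------------------------------------
# defining phenotypes of the built-in schemas (used by the synthetic
# generator to build consistent scenes, and by the 100%-accuracy tests)

MAIN_POPULATION_PHENOTYPES: dict[str, set[str]] = {
    "T cells": {"CD45", "CD3", "CD8"},
    "B cells": {"CD45", "CD19", "CD20"},
    "Plasma cells": {"CD45", "CD38", "CD138"},
    "NK cells": {"CD45", "CD56"},
    "Monocytes": {"CD45", "CD64", "CD11b", "HLA-DR"},
    "mDC": {"CD45", "CD11c", "HLA-DR"},
    "pDC": {"CD45", "CD123", "HLA-DR"},
    "Granulocytes": {"CD45", "CD15", "CD66b", "CD11b"},
    "Mast cells": {"CD45", "CD117"},
    "MDSC": {"CD45", "CD11b", "S100A8"},
    "Macrophages": {"CD45", "CD163", "CD206", "CD11b", "HLA-DR"},
    "Endothelial": {"CD31", "CD105"},
    "Epithelial": {"EpCAM", "PanCK"},
    "Fibroblasts": {"FSP1"},
    "Platelets": {"CD61"},
    "Erythrocytes": {"CD36"},
}

TONSIL_PHENOTYPES: dict[str, set[str]] = {
    "T cells": {"CD45", "CD3", "CD4"},
    "B cells": {"CD45", "CD19", "CD20"},
    "Plasma cells": {"CD45", "CD38", "CD138"},
    "NK cells": {"CD45", "CD56"},
    "mDC": {"CD45", "CD11c", "HLA-DR"},
    "pDC": {"CD45", "CD123", "HLA-DR"},
    "Granulocytes": {"CD45", "CD15", "CD66b"},
    "Mast cells": {"CD45", "CD117"},
    "Macrophages": {"CD45", "CD163", "CD206", "HLA-DR"},
    "Fibroblasts": {"FSP1"},
    "Blood vessels": {"CD31", "CD105"},
    "Lymphatic vessels": {"Podoplanin"},
    "Squamous epithelium": {"EpCAM", "PanCK"},
}
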