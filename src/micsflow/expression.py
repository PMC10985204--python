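"""Per-cell marker expression extraction and normalization.

Mean marker intensity is measured per cell over three compartments
(nucleus, cytoplasm, whole cell).  Normalization follows the two-step
recipe standard for antibody-intensity data: winsorize each marker at
the 1st/99th percentiles to tame spurious outliers, then apply the
inverse hyperbolic sine (arcsinh) transform, which compresses the
right-skewed positive population while staying defined (and ≈ linear)
near zero.  Winsorization caps at the inward closest-rank order
statistics (ceiling rank for the lower cap, floor rank for the upper),
the convention under which winsorizing twice equals winsorizing once;
empty compartments are recorded as missing, never as zero, and are
excluded from percentile computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .segmentation import SegmentationResult

COMPARTMENTS = ("nucleus", "cytoplasm", "cell")


@dataclass(frozen=True)
class NormalizationParams:
    lower_pct: float = 1.0
    upper_pct: float = 99.0
    arcsinh_cofactor: float = 1.0
    per_marker: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.lower_pct < self.upper_pct <= 100:
            raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
        if self.arcsinh_cofactor <= 0:
            raise ValueError("arcsinh_cofactor must be positive")


def _label_means(grid: np.ndarray, labels: np.ndarray, n: int) -> np.ndarray:
    """Mean of `grid` over each label 1..n; NaN where a label is absent."""
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    sums = ndi.sum_labels(grid, labels, np.arange(1, n + 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means


def extract_expression(
    mosaics: Mapping[str, np.ndarray],
    seg: SegmentationResult,
    geometry: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the raw cell table: one row per segmented cell, one
    ``<marker>__<compartment>__raw`` column per marker and compartment.

    Cytoplasm means for cells with an empty donut are NaN.
    """
    n = seg.n_cells()
    cyto_labels = np.where(seg.nucleus_labels > 0, 0, seg.cell_labels)
    table: dict[str, np.ndarray] = {"cell_id": np.arange(1, n + 1)}
    for marker, grid in mosaics.items():
        grid = np.asarray(grid, dtype=np.float64)
        if grid.shape != seg.cell_labels.shape:
            raise ValueError(
                f"{marker}: mosaic shape {grid.shape} != labels {seg.cell_labels.shape}"
            )
        table[f"{marker}__nucleus__raw"] = _label_means(grid, seg.nucleus_labels, n)
        table[f"{marker}__cytoplasm__raw"] = _label_means(grid, cyto_labels, n)
        table[f"{marker}__cell__raw"] = _label_means(grid, seg.cell_labels, n)
    cells = pd.DataFrame(table)
    if geometry is not None:
        cells = cells.merge(geometry, on="cell_id", how="left")
    return cells


def winsorize(
    values: np.ndarray | pd.Series, lower_pct: float = 1.0, upper_pct: float = 99.0
) -> np.ndarray:
    """Cap values at the given percentiles; NaNs pass through and are
    ignored for the percentile computation.

    Caps are the inward closest-rank order statistics: the lower cap is
    the value at the ceiling of the lower percentile's rank position,
    the upper cap at the floor of the upper's.  Unlike interpolated
    percentiles, these caps are themselves sample values, which makes
    winsorization idempotent.  When the sample is too small to hold
    both caps (rank positions cross), no capping is applied.
    """
    arr = np.asarray(values, dtype=np.float64)
    finite = arr[~np.isnan(arr)]
    if finite.size == 0:
        raise ValueError("winsorize requires at least one non-missing value")
    caps = _rank_caps(finite, lower_pct, upper_pct)
    if caps is None:
        return arr.copy()
    return np.clip(arr, caps[0], caps[1])


def _rank_caps(
    finite: np.ndarray, lower_pct: float, upper_pct: float
) -> tuple[float, float] | None:
    """Inward closest-rank caps at rank position p/100 * (n - 1)."""
    srt = np.sort(finite)
    n = srt.size
    lo_idx = int(np.ceil(lower_pct / 100.0 * (n - 1)))
    hi_idx = int(np.floor(upper_pct / 100.0 * (n - 1)))
    if lo_idx > hi_idx:
        return None
    return float(srt[lo_idx]), float(srt[hi_idx])


def arcsinh_transform(
    values: np.ndarray | pd.Series, cofactor: float = 1.0
) -> np.ndarray:
    """Elementwise arcsinh(x / cofactor) = ln(x/c + sqrt((x/c)² + 1))."""
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.arcsinh(np.asarray(values, dtype=np.float64) / cofactor)


def normalize(
    cells: pd.DataFrame, params: NormalizationParams = NormalizationParams()
) -> pd.DataFrame:
    """Append ``__norm`` columns: arcsinh(winsorize(raw)) per marker and
    compartment, percentiles computed separately for every raw column."""
    out = cells.copy()
    raw_cols = [c for c in cells.columns if c.endswith("__raw")]
    if params.per_marker:
        for col in raw_cols:
            w = winsorize(cells[col], params.lower_pct, params.upper_pct)
            out[col.replace("__raw", "__norm")] = arcsinh_transform(
                w, params.arcsinh_cofactor
            )
    else:
        pooled = cells[raw_cols].to_numpy().ravel()
        finite = pooled[~np.isnan(pooled)]
        caps = _rank_caps(finite, params.lower_pct, params.upper_pct)
        for col in raw_cols:
            w = cells[col].to_numpy(dtype=np.float64)
            if caps is not None:
                w = np.clip(w, caps[0], caps[1])
            out[col.replace("__raw", "__norm")] = arcsinh_transform(
                w, params.arcsinh_cofactor
            )
    return out


def marker_matrix(
    cells: pd.DataFrame, compartment: str = "cell", normalized: bool = True
) -> pd.DataFrame:
    """View of the cell table as cells × markers for one compartment."""
    suffix = f"__{compartment}__{'norm' if normalized else 'raw'}"
    cols = [c for c in cells.columns if c.endswith(suffix)]
    view = cells[cols].copy()
    view.columns = [c[: -len(suffix)] for c in cols]
    view.index = cells["cell_id"].to_numpy()
    return view
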