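"""Synthetic multiplexed-tissue generator with known ground truth.

Every downstream stage (stitching, segmentation, expression extraction,
gating, neighborhood analysis) is validated against scenes produced here:
non-overlapping elliptical nuclei rendered into a DAPI channel, and
marker channels whose per-cell intensities are drawn from type-specific
lognormal mixtures (right-skewed positive populations over a dim negative
background, the regime the arcsinh transform is designed for).  Spatial
layouts cover uniform scatter, follicle-like clusters, and tumor/stroma
compartments.  All randomness flows from a single seed; identical specs
give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from skimage.draw import ellipse
from skimage.segmentation import expand_labels

from .imaging import ImageKey, ImageStack, Tile

DEFAULT_PIXEL_SIZE_UM = 0.106  # µm per pixel (25 µm ≙ 235.85 px)


class GenerationError(RuntimeError):
    """Raised when a scene cannot be packed within the retry budget."""


@dataclass(frozen=True)
class MarkerMixture:
    """Lognormal intensity model of one marker on one cell type.

    ``positive`` selects which component a cell of this type draws its
    true mean photon rate from; rates are in counts per millisecond.
    """

    positive: bool
    pos_log_mean: float = math.log(20.0)
    pos_log_sd: float = 0.35
    neg_log_mean: float = math.log(0.8)
    neg_log_sd: float = 0.5

    def draw(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        mu = self.pos_log_mean if self.positive else self.neg_log_mean
        sd = self.pos_log_sd if self.positive else self.neg_log_sd
        return rng.lognormal(mu, sd, size=n)


@dataclass(frozen=True)
class CellType:
    label: str
    proportion: float
    marker_profile: dict[str, MarkerMixture] = field(default_factory=dict)


def profile(positive: set[str] | frozenset[str], markers: list[str], **kwargs) -> dict:
    """Build a marker profile with the given positive markers."""
    return {m: MarkerMixture(positive=m in positive, **kwargs) for m in markers}


@dataclass(frozen=True)
class Compartment:
    center_xy_px: tuple[float, float]
    radius_px: float
    types: frozenset[str]  # types confined to this compartment


@dataclass(frozen=True)
class TissueSpec:
    width_px: int = 512
    height_px: int = 512
    n_cells: int = 200
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    cell_types: tuple[CellType, ...] = ()
    spatial_layout: Literal["random", "clustered", "compartmental"] = "random"
    cluster_sd_px: float = 40.0
    n_clusters: int = 3
    compartments: tuple[Compartment, ...] = ()
    nucleus_diameter_um: tuple[float, float] = (6.0, 10.0)
    donut_truth_width_um: float = 2.0
    background_level: float = 0.5  # counts/ms
    noise_sd: float = 0.0  # additive Gaussian read noise, counts/ms
    dapi_rate: float = 30.0  # nuclear DAPI photon rate, counts/ms
    bleach_gradient: float | None = None  # linear left→right intensity ramp slope
    exposures_ms: tuple[float, ...] = (10.0,)
    bit_depth: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.cell_types:
            total = sum(t.proportion for t in self.cell_types)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"type proportions sum to {total}, expected 1")
        lo, hi = self.nucleus_diameter_um
        if not (0 < lo <= hi):
            raise ValueError("nucleus diameter range must be positive and ordered")

    @property
    def markers(self) -> list[str]:
        seen: list[str] = []
        for t in self.cell_types:
            for m in t.marker_profile:
                if m not in seen:
                    seen.append(m)
        return seen


@dataclass
class GroundTruth:
    cells: pd.DataFrame  # cell_id, type_label, cy_px, cx_px, nucleus_diameter_px, rate_<marker>
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray


# ---------------------------------------------------------------------------
# placement


def _draw_positions(
    spec: TissueSpec, types: np.ndarray, radii: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample non-overlapping nucleus centers honoring the layout."""
    n = len(types)
    H, W = spec.height_px, spec.width_px
    centers = np.empty((n, 2))
    type_labels = [t.label for t in spec.cell_types]

    cluster_centers = None
    if spec.spatial_layout == "clustered":
        cluster_centers = rng.uniform(
            [0.15 * H, 0.15 * W], [0.85 * H, 0.85 * W], size=(spec.n_clusters, 2)
        )

    comp_by_type: dict[str, Compartment] = {}
    for comp in spec.compartments:
        for t in comp.types:
            comp_by_type[t] = comp

    def candidate(type_idx: int) -> np.ndarray:
        label = type_labels[type_idx] if type_labels else ""
        if spec.spatial_layout == "clustered" and cluster_centers is not None:
            c = cluster_centers[rng.integers(len(cluster_centers))]
            return c + rng.normal(0, spec.cluster_sd_px, size=2)
        if spec.spatial_layout == "compartmental" and label in comp_by_type:
            comp = comp_by_type[label]
            r = comp.radius_px * math.sqrt(rng.uniform())
            theta = rng.uniform(0, 2 * math.pi)
            cx, cy = comp.center_xy_px
            return np.array([cy + r * math.sin(theta), cx + r * math.cos(theta)])
        return rng.uniform([0.0, 0.0], [H, W])

    margin = 2.0  # px gap between nucleus boundaries
    for i in range(n):
        placed = False
        for _ in range(1000):
            c = candidate(int(types[i]))
            r = radii[i]
            if not (r <= c[0] <= H - r and r <= c[1] <= W - r):
                continue
            if i > 0:
                d = np.hypot(*(centers[:i] - c).T)
                if np.any(d < radii[:i] + r + margin):
                    continue
            centers[i] = c
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place cell {i + 1}/{n} after 1000 attempts; "
                "reduce n_cells or enlarge the scene"
            )
    return centers


def _render_labels(
    spec: TissueSpec,
    centers: np.ndarray,
    radii: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Nucleus label grid (ellipses with bounded eccentricity) + cell labels."""
    H, W = spec.height_px, spec.width_px
    nucleus = np.zeros((H, W), dtype=np.int32)
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        ecc = rng.uniform(0.8, 1.0)  # minor/major axis ratio
        theta = rng.uniform(0, math.pi)
        # major semi-axis = placement radius r, so every ellipse stays
        # inside its placement circle: non-overlap and margins hold exactly
        rr, cc = ellipse(cy, cx, r, r * ecc, shape=(H, W), rotation=theta)
        nucleus[rr, cc] = i
    donut_px = spec.donut_truth_width_um / spec.pixel_size_um
    cell = expand_labels(nucleus, distance=donut_px) if donut_px > 0 else nucleus.copy()
    return nucleus, cell


def _quantize(rate: np.ndarray, exposure_ms: float, saturation: int) -> np.ndarray:
    return np.clip(np.round(rate * exposure_ms), 0, saturation).astype(np.uint16)


# ---------------------------------------------------------------------------
# public operations


def sample_cell_table(spec: TissueSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a ground-truth cell table (positions, types, marker rates)
    without rendering images.

    Columns: cell_id, type_label, cy_px, cx_px, cx_um, cy_um and one
    ``rate_<marker>`` column per marker.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if not spec.cell_types:
        raise ValueError("spec.cell_types must be nonempty")
    props = np.array([t.proportion for t in spec.cell_types])
    types = rng.choice(len(spec.cell_types), size=spec.n_cells, p=props)
    lo, hi = spec.nucleus_diameter_um
    radii = rng.uniform(lo, hi, size=spec.n_cells) / 2 / spec.pixel_size_um
    centers = _draw_positions(spec, types, radii, rng)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, spec.n_cells + 1),
            "type_label": [spec.cell_types[t].label for t in types],
            "cy_px": centers[:, 0],
            "cx_px": centers[:, 1],
            "nucleus_diameter_px": radii * 2,
        }
    )
    df["cx_um"] = df["cx_px"] * spec.pixel_size_um
    df["cy_um"] = df["cy_px"] * spec.pixel_size_um
    for m in spec.markers:
        rates = np.empty(spec.n_cells)
        for idx, t in enumerate(spec.cell_types):
            mask = types == idx
            mix = t.marker_profile.get(m)
            if mix is None:
                mix = MarkerMixture(positive=False)
            rates[mask] = mix.draw(rng, int(mask.sum()))
        df[f"rate_{m}"] = rates
    return df


def generate_tissue(spec: TissueSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a full synthetic scene: DAPI plus one channel per marker,
    each with stain and bleach images at the spec's exposure times.

    The marker image is additive: background + per-cell rate over the
    cell's (nucleus + donut) footprint, plus optional Gaussian read noise
    and an optional left-to-right acquisition-bleaching ramp, quantized
    per exposure into 12-bit readings.
    """
    rng = np.random.default_rng(spec.seed)
    cells = sample_cell_table(spec, rng)
    centers = cells[["cy_px", "cx_px"]].to_numpy()
    radii = cells["nucleus_diameter_px"].to_numpy() / 2
    nucleus, cell_lab = _render_labels(spec, centers, radii, rng)
    saturation = (1 << spec.bit_depth) - 1
    H, W = spec.height_px, spec.width_px

    ramp = np.ones((H, W))
    if spec.bleach_gradient is not None:
        ramp += spec.bleach_gradient * (np.arange(W) / max(W - 1, 1))[None, :]

    def noisy(rate: np.ndarray) -> np.ndarray:
        if spec.noise_sd > 0:
            rate = rate + rng.normal(0, spec.noise_sd, rate.shape)
        return np.maximum(rate * ramp, 0)

    images: dict[ImageKey, np.ndarray] = {}
    # DAPI: nuclear rate with mild per-cell variation
    dapi_rate = np.full((H, W), spec.background_level)
    dapi_amp = spec.dapi_rate * rng.lognormal(0, 0.1, len(cells))
    inside = nucleus > 0
    dapi_rate[inside] += dapi_amp[nucleus[inside] - 1]
    for t in spec.exposures_ms:
        images[ImageKey(1, "DAPI", t, "dapi")] = _quantize(
            noisy(dapi_rate), t, saturation
        )

    for ci, m in enumerate(spec.markers, start=1):
        rates = cells[f"rate_{m}"].to_numpy()
        grid = np.full((H, W), spec.background_level)
        fg = cell_lab > 0
        grid[fg] += rates[cell_lab[fg] - 1]
        bleach = np.full((H, W), spec.background_level)
        for t in spec.exposures_ms:
            images[ImageKey(ci, m, t, "stain")] = _quantize(noisy(grid), t, saturation)
            images[ImageKey(ci, m, t, "bleach")] = _quantize(
                noisy(bleach), t, saturation
            )

    tile = Tile("tile_0", (0, 0), images)
    stack = ImageStack([tile], bit_depth=spec.bit_depth, pixel_size_um=spec.pixel_size_um)
    truth = GroundTruth(cells=cells, nucleus_labels=nucleus, cell_labels=cell_lab)
    return stack, truth


def generate_tile_pair(
    spec: TissueSpec,
    overlap_px: int,
    true_shift_px: tuple[int, int] = (0, 0),
    tile_px: int = 256,
) -> tuple[ImageStack, tuple[int, int]]:
    """Cut two horizontally adjacent tiles from one rendered scene.

    Tile B is declared at nominal origin ``(0, tile_px - overlap_px)`` but
    its content is displaced by ``true_shift_px = (dy, dx)``; the recorded
    shift is returned for stitcher validation.
    """
    dy, dx = true_shift_px
    if not (0 < overlap_px < tile_px):
        raise ValueError("overlap must be positive and smaller than the tile")
    pad = max(abs(dy), abs(dx)) + 4
    scene_spec = replace(
        spec,
        width_px=2 * tile_px - overlap_px + 2 * pad,
        height_px=tile_px + 2 * pad,
    )
    stack, _ = generate_tissue(scene_spec)
    scene = {k: g for k, g in stack.tiles[0].images.items()}

    def cut(y0: int, x0: int) -> dict[ImageKey, np.ndarray]:
        return {
            k: g[y0 : y0 + tile_px, x0 : x0 + tile_px].copy()
            for k, g in scene.items()
        }

    b_nominal_x = tile_px - overlap_px
    tiles = [
        Tile("tile_a", (0, 0), cut(pad, pad)),
        Tile("tile_b", (0, b_nominal_x), cut(pad + dy, pad + b_nominal_x + dx)),
    ]
    pair = ImageStack(tiles, bit_depth=spec.bit_depth, pixel_size_um=spec.pixel_size_um)
    return pair, (dy, dx)


def generate_neighborhood_scene(
    anchor_type: str,
    enriched_type: str,
    radius_um: float,
    enrichment: float,
    spec: TissueSpec,
) -> pd.DataFrame:
    """Point scene where ``enriched_type`` cells appear near
    ``anchor_type`` anchors at ``enrichment``-fold the background density.

    Enriched positions are drawn by acceptance thinning: a uniform
    candidate inside the anchor radius is accepted with probability 1, a
    candidate outside with probability 1/enrichment, which yields exactly
    the requested within/outside density ratio.  Other types are uniform.
    Returns a cell table with um and px coordinates.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be ≥ 1")
    rng = np.random.default_rng(spec.seed)
    if not spec.cell_types:
        raise ValueError("spec.cell_types must be nonempty")
    labels = [t.label for t in spec.cell_types]
    if anchor_type not in labels or enriched_type not in labels:
        raise ValueError("anchor_type and enriched_type must be in spec.cell_types")
    H_um = spec.height_px * spec.pixel_size_um
    W_um = spec.width_px * spec.pixel_size_um
    counts = {
        t.label: int(round(t.proportion * spec.n_cells)) for t in spec.cell_types
    }

    anchors = rng.uniform([0, 0], [H_um, W_um], size=(counts.get(anchor_type, 0), 2))

    rows: list[tuple[str, float, float]] = [
        (anchor_type, y, x) for y, x in anchors
    ]

    def near_anchor(p: np.ndarray) -> bool:
        if len(anchors) == 0:
            return False
        return bool(np.any(np.hypot(*(anchors - p).T) <= radius_um))

    n_enriched = counts.get(enriched_type, 0)
    accepted = 0
    attempts = 0
    max_attempts = 1000 * max(n_enriched, 1)
    while accepted < n_enriched and attempts < max_attempts:
        attempts += 1
        p = rng.uniform([0, 0], [H_um, W_um])
        accept_p = 1.0 if near_anchor(p) else 1.0 / enrichment
        if rng.uniform() <= accept_p:
            rows.append((enriched_type, p[0], p[1]))
            accepted += 1
    if accepted < n_enriched:
        raise GenerationError("neighborhood scene placement exceeded retry budget")

    for t in spec.cell_types:
        if t.label in (anchor_type, enriched_type):
            continue
        pts = rng.uniform([0, 0], [H_um, W_um], size=(counts[t.label], 2))
        rows.extend((t.label, y, x) for y, x in pts)

    df = pd.DataFrame(rows, columns=["type_label", "cy_um", "cx_um"])
    df.insert(0, "cell_id", np.arange(1, len(df) + 1))
    df["cy_px"] = df["cy_um"] / spec.pixel_size_um
    df["cx_px"] = df["cx_um"] / spec.pixel_size_um
    return df
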