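"""Raw-to-analysis image pipeline for cyclic immunofluorescence stacks.

Each acquisition cycle yields, per tile (field of view) and fluorescence
channel, a pre-stain *bleach* image and a post-stain image, both captured
at several exposure times, plus a DAPI image used for tile registration.
The processing chain is:

1. exposure fusion — combine the multi-exposure readings into a single
   intensity-per-millisecond image, falling back to shorter exposures
   where the sensor saturates;
2. bleach subtraction — remove residual signal from the previous cycle;
3. stitching — register neighboring tiles on their DAPI overlap and
   compose one mosaic per channel;
4. cropping — trim the stage-motion margin around the DAPI footprint.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import tifffile

log = logging.getLogger(__name__)

SATURATION_12BIT = 4095


@dataclass(frozen=True)
class ImageKey:
    """Index of one grid within a tile: (cycle, channel, exposure, kind)."""

    cycle: int
    channel: str
    exposure_ms: float
    kind: str  # "stain" | "bleach" | "dapi"

    def __post_init__(self) -> None:
        if self.kind not in ("stain", "bleach", "dapi"):
            raise ValueError(f"bad image kind {self.kind!r}")
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")


@dataclass
class Tile:
    tile_id: str
    origin_yx: tuple[int, int]  # nominal placement in mosaic coordinates
    images: dict[ImageKey, np.ndarray] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.images.values()))
        return first.shape

    def validate(self, saturation: float) -> None:
        shapes = {g.shape for g in self.images.values()}
        if len(shapes) > 1:
            raise ValueError(f"tile {self.tile_id}: mixed grid shapes {shapes}")
        for k, g in self.images.items():
            if g.max(initial=0) > saturation:
                raise ValueError(f"tile {self.tile_id} {k}: values exceed saturation")


@dataclass
class ImageStack:
    """Per-ROI collection of tiles with 12-bit data in 16-bit containers."""

    tiles: list[Tile]
    bit_depth: int = 12
    pixel_size_um: float = 0.106

    @property
    def saturation(self) -> int:
        return (1 << self.bit_depth) - 1

    def validate(self) -> None:
        for t in self.tiles:
            t.validate(self.saturation)

    # ---- persistence (multi-page TIFF + JSON sidecar) ----

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index: dict = {
            "bit_depth": self.bit_depth,
            "pixel_size_um": self.pixel_size_um,
            "tiles": [],
        }
        for tile in self.tiles:
            keys = sorted(
                tile.images, key=lambda k: (k.cycle, k.channel, k.kind, k.exposure_ms)
            )
            pages = np.stack([tile.images[k] for k in keys])
            fname = f"{tile.tile_id}.tif"
            tifffile.imwrite(
                directory / fname, pages.astype(np.uint16), photometric="minisblack"
            )
            index["tiles"].append(
                {
                    "tile_id": tile.tile_id,
                    "origin_yx": list(tile.origin_yx),
                    "file": fname,
                    "pages": [
                        [k.cycle, k.channel, k.exposure_ms, k.kind] for k in keys
                    ],
                }
            )
        (directory / "stack_index.json").write_text(json.dumps(index, indent=1))

    @classmethod
    def read(cls, directory: str | Path) -> "ImageStack":
        directory = Path(directory)
        index = json.loads((directory / "stack_index.json").read_text())
        tiles = []
        for rec in index["tiles"]:
            pages = tifffile.imread(directory / rec["file"])
            if pages.ndim == 2:
                pages = pages[None]
            images = {
                ImageKey(cycle, channel, exposure, kind): pages[i]
                for i, (cycle, channel, exposure, kind) in enumerate(rec["pages"])
            }
            tiles.append(
                Tile(rec["tile_id"], tuple(rec["origin_yx"]), images)
            )
        return cls(tiles, index["bit_depth"], index["pixel_size_um"])


@dataclass(frozen=True)
class CropSpec:
    """Fixed margins trimmed from a stitched mosaic (stage-motion border)."""

    top_bottom_px: int = 200
    left_right_px: int = 100

    def __post_init__(self) -> None:
        if self.top_bottom_px < 0 or self.left_right_px < 0:
            raise ValueError("crop margins must be nonnegative")


@dataclass
class FusedImage:
    values: np.ndarray  # intensity per millisecond
    saturated: np.ndarray  # bool mask: saturated at every exposure


def fuse_exposures(
    grids: Mapping[float, np.ndarray], saturation: float = SATURATION_12BIT
) -> FusedImage:
    """Combine multi-exposure readings into intensity per unit time.

    Per pixel, the longest exposure whose reading is below saturation is
    used and its reading divided by the exposure time (linear sensor
    model).  Pixels saturated at every exposure fall back to
    ``saturation / shortest_exposure`` and are flagged.
    """
    if not grids:
        raise ValueError("need at least one exposure")
    exposures = sorted(grids)
    if len(set(exposures)) != len(grids):
        raise ValueError("exposure times must be distinct")
    shapes = {np.asarray(g).shape for g in grids.values()}
    if len(shapes) > 1:
        raise ValueError(f"mismatched grid shapes: {shapes}")

    shape = shapes.pop()
    fused = np.full(shape, saturation / exposures[0], dtype=np.float64)
    saturated = np.ones(shape, dtype=bool)
    # ascending exposure order: longer valid exposures overwrite shorter ones
    for t in exposures:
        g = np.asarray(grids[t], dtype=np.float64)
        ok = g < saturation
        fused[ok] = g[ok] / t
        saturated &= ~ok
    return FusedImage(values=fused, saturated=saturated)


def subtract_bleach(stain: np.ndarray, bleach: np.ndarray) -> np.ndarray:
    """Subtract the pre-stain bleach image, clipping negatives to zero."""
    stain = np.asarray(stain, dtype=np.float64)
    bleach = np.asarray(bleach, dtype=np.float64)
    if stain.shape != bleach.shape:
        raise ValueError(f"shape mismatch: {stain.shape} vs {bleach.shape}")
    return np.maximum(stain - bleach, 0.0)


def apply_flatfield(grid: np.ndarray, flatfield: np.ndarray | None) -> np.ndarray:
    """Divide by a precomputed per-channel flatfield grid; identity if None."""
    if flatfield is None:
        return np.asarray(grid, dtype=np.float64)
    flatfield = np.asarray(flatfield, dtype=np.float64)
    if flatfield.shape != np.asarray(grid).shape:
        raise ValueError("flatfield shape mismatch")
    return np.asarray(grid, dtype=np.float64) / np.where(flatfield == 0, 1.0, flatfield)


def estimate_shift(
    reference: np.ndarray, moving: np.ndarray, max_shift: int = 15
) -> tuple[tuple[int, int], float]:
    """Integer shift of `moving` relative to `reference` by exhaustive
    normalized cross-correlation over a bounded search window.

    Returns ((dy, dx), confidence) such that
    ``moving[y, x] ≈ reference[y + dy, x + dx]`` on the common support;
    confidence is the best normalized correlation in [-1, 1].
    """
    a = np.asarray(reference, dtype=np.float64)
    b = np.asarray(moving, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("estimate_shift requires equal shapes")
    H, W = a.shape
    best_score = -np.inf
    best = (0, 0)
    for dy in range(-max_shift, max_shift + 1):
        y0, y1 = max(dy, 0), H + min(dy, 0)
        if y1 - y0 < 8:
            continue
        for dx in range(-max_shift, max_shift + 1):
            x0, x1 = max(dx, 0), W + min(dx, 0)
            if x1 - x0 < 8:
                continue
            a_sub = a[y0:y1, x0:x1]
            b_sub = b[y0 - dy : y1 - dy, x0 - dx : x1 - dx]
            a_c = a_sub - a_sub.mean()
            b_c = b_sub - b_sub.mean()
            denom = np.sqrt((a_c**2).sum() * (b_c**2).sum())
            if denom == 0:
                score = 1.0 if np.allclose(a_sub, b_sub) else 0.0
            else:
                score = float((a_c * b_c).sum() / denom)
            if score > best_score:
                best_score = score
                best = (dy, dx)
    return best, best_score


@dataclass
class StitchResult:
    mosaics: dict[ImageKey, np.ndarray]
    origins: dict[str, tuple[int, int]]  # refined tile origins
    pairwise_shifts: list[dict]


def _reference_grid(tile: Tile) -> np.ndarray:
    """DAPI grid of the earliest cycle (fused if several exposures exist)."""
    dapi_keys = [k for k in tile.images if k.kind == "dapi"]
    if not dapi_keys:
        raise ValueError(f"tile {tile.tile_id} has no DAPI image")
    cycle = min(k.cycle for k in dapi_keys)
    grids = {k.exposure_ms: tile.images[k] for k in dapi_keys if k.cycle == cycle}
    if len(grids) == 1:
        return np.asarray(next(iter(grids.values())), dtype=np.float64)
    return fuse_exposures(grids).values


def stitch_tiles(
    stack: ImageStack,
    max_shift: int = 15,
    min_confidence: float = 0.3,
    fuse: bool = True,
) -> StitchResult:
    """Register tiles on DAPI overlaps and compose per-channel mosaics.

    Pairwise integer shifts between nominally overlapping tiles are
    estimated by normalized cross-correlation of the overlap strips;
    global positions follow a spanning tree rooted at the first tile.
    A pair whose correlation peak falls below ``min_confidence`` keeps
    its nominal offset (logged).  Overlap pixels are averaged.  When
    ``fuse`` is true, multi-exposure groups are HDR-fused per (cycle,
    channel, kind) before placement.
    """
    if not stack.tiles:
        raise ValueError("empty stack")
    tiles = {t.tile_id: t for t in stack.tiles}
    refs = {t.tile_id: _reference_grid(t) for t in stack.tiles}

    # neighbor pairs: nominal bounding boxes overlap
    pairs: list[tuple[str, str]] = []
    ids = [t.tile_id for t in stack.tiles]
    for i, a_id in enumerate(ids):
        for b_id in ids[i + 1 :]:
            a, b = tiles[a_id], tiles[b_id]
            ah, aw = a.shape
            bh, bw = b.shape
            oy0 = max(a.origin_yx[0], b.origin_yx[0])
            oy1 = min(a.origin_yx[0] + ah, b.origin_yx[0] + bh)
            ox0 = max(a.origin_yx[1], b.origin_yx[1])
            ox1 = min(a.origin_yx[1] + aw, b.origin_yx[1] + bw)
            if oy1 - oy0 > 0 and ox1 - ox0 > 0:
                pairs.append((a_id, b_id))

    # pairwise corrections on DAPI overlap strips
    corrections: dict[tuple[str, str], tuple[int, int]] = {}
    shift_log: list[dict] = []
    for a_id, b_id in pairs:
        a, b = tiles[a_id], tiles[b_id]
        ah, aw = a.shape
        bh, bw = b.shape
        oy0 = max(a.origin_yx[0], b.origin_yx[0])
        oy1 = min(a.origin_yx[0] + ah, b.origin_yx[0] + bh)
        ox0 = max(a.origin_yx[1], b.origin_yx[1])
        ox1 = min(a.origin_yx[1] + aw, b.origin_yx[1] + bw)
        patch_a = refs[a_id][
            oy0 - a.origin_yx[0] : oy1 - a.origin_yx[0],
            ox0 - a.origin_yx[1] : ox1 - a.origin_yx[1],
        ]
        patch_b = refs[b_id][
            oy0 - b.origin_yx[0] : oy1 - b.origin_yx[0],
            ox0 - b.origin_yx[1] : ox1 - b.origin_yx[1],
        ]
        (dy, dx), conf = estimate_shift(patch_a, patch_b, max_shift=max_shift)
        if conf < min_confidence:
            log.warning(
                "stitch %s-%s: correlation %.3f below %.3f, keeping nominal offset",
                a_id, b_id, conf, min_confidence,
            )
            dy, dx = 0, 0
        corrections[(a_id, b_id)] = (dy, dx)
        shift_log.append(
            {"tile_a": a_id, "tile_b": b_id, "dy": dy, "dx": dx, "confidence": conf}
        )

    # spanning tree over the pair graph, rooted at the first tile
    origins: dict[str, tuple[int, int]] = {ids[0]: tiles[ids[0]].origin_yx}
    frontier = [ids[0]]
    adjacency: dict[str, list[tuple[str, int]]] = {i: [] for i in ids}
    for idx, (a_id, b_id) in enumerate(pairs):
        adjacency[a_id].append((b_id, idx))
        adjacency[b_id].append((a_id, idx))
    while frontier:
        cur = frontier.pop(0)
        for other, idx in adjacency[cur]:
            if other in origins:
                continue
            a_id, b_id = pairs[idx]
            dy, dx = corrections[(a_id, b_id)]
            if other == b_id:  # correction moves b relative to its nominal origin
                nominal_delta = (
                    tiles[b_id].origin_yx[0] - tiles[a_id].origin_yx[0],
                    tiles[b_id].origin_yx[1] - tiles[a_id].origin_yx[1],
                )
                origins[other] = (
                    origins[cur][0] + nominal_delta[0] + dy,
                    origins[cur][1] + nominal_delta[1] + dx,
                )
            else:
                nominal_delta = (
                    tiles[a_id].origin_yx[0] - tiles[b_id].origin_yx[0],
                    tiles[a_id].origin_yx[1] - tiles[b_id].origin_yx[1],
                )
                origins[other] = (
                    origins[cur][0] + nominal_delta[0] - dy,
                    origins[cur][1] + nominal_delta[1] - dx,
                )
            frontier.append(other)
    unplaced = set(ids) - set(origins)
    for tid in sorted(unplaced):  # disconnected tiles keep nominal origins
        origins[tid] = tiles[tid].origin_yx
    ymin = min(o[0] for o in origins.values())
    xmin = min(o[1] for o in origins.values())
    origins = {tid: (oy - ymin, ox - xmin) for tid, (oy, ox) in origins.items()}

    # mosaic extent
    H = max(origins[t.tile_id][0] + t.shape[0] for t in stack.tiles)
    W = max(origins[t.tile_id][1] + t.shape[1] for t in stack.tiles)

    # group grids per output key, fusing exposures when requested
    def tile_grids(tile: Tile) -> dict[ImageKey, np.ndarray]:
        if not fuse:
            return {k: np.asarray(g, dtype=np.float64) for k, g in tile.images.items()}
        groups: dict[tuple[int, str, str], dict[float, np.ndarray]] = {}
        for k, g in tile.images.items():
            groups.setdefault((k.cycle, k.channel, k.kind), {})[k.exposure_ms] = g
        out = {}
        for (cycle, channel, kind), grids in groups.items():
            fused = fuse_exposures(grids, stack.saturation)
            out[ImageKey(cycle, channel, 1.0, kind)] = fused.values
        return out

    sums: dict[ImageKey, np.ndarray] = {}
    counts: dict[ImageKey, np.ndarray] = {}
    for tile in stack.tiles:
        oy, ox = origins[tile.tile_id]
        for key, grid in tile_grids(tile).items():
            if key not in sums:
                sums[key] = np.zeros((H, W), dtype=np.float64)
                counts[key] = np.zeros((H, W), dtype=np.int32)
            h, w = grid.shape
            sums[key][oy : oy + h, ox : ox + w] += grid
            counts[key][oy : oy + h, ox : ox + w] += 1
    mosaics = {
        key: np.divide(s, counts[key], out=np.zeros_like(s), where=counts[key] > 0)
        for key, s in sums.items()
    }
    return StitchResult(mosaics=mosaics, origins=origins, pairwise_shifts=shift_log)


def crop_to_dapi(mosaic: np.ndarray, spec: CropSpec = CropSpec()) -> np.ndarray:
    """Trim the fixed stage-motion margin (default 200 px top/bottom,
    100 px left/right) from a stitched mosaic."""
    mosaic = np.asarray(mosaic)
    H, W = mosaic.shape
    if H <= 2 * spec.top_bottom_px or W <= 2 * spec.left_right_px:
        raise ValueError(
            f"mosaic {H}x{W} too small for crop margins "
            f"({spec.top_bottom_px}, {spec.left_right_px})"
        )
    return mosaic[
        spec.top_bottom_px : H - spec.top_bottom_px,
        spec.left_right_px : W - spec.left_right_px,
    ]
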