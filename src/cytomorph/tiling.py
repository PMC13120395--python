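"""Slide tiling, tissue masking, and tile quality control.

A slide raster is partitioned into 256x256 tiles (non-overlapping by
default), a low-resolution tissue mask excludes the near-white,
low-saturation background, and a programmatic QC rule set admits only
tiles containing exactly one intact nucleated epithelial cell — the
rule set rejects acellular fields, multi-cell/overlapping fields,
debris, border-clipped cells and colour-degenerate (low-contrast)
tiles.  The QC replaces visual screening by an expert observer with an
explicit, reproducible rule set enforcing the same exclusion list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .errors import InsufficientTilesError, ParameterError
from .segmentation import CellSegmentation, SegmentationParams, segment_tile

logger = logging.getLogger(__name__)

TILE_SIZE = 256

REJECTION_CODES = ("acellular", "multiple_cells", "border_contact",
                   "debris", "low_contrast")


@dataclass
class Tile:
    """A 256x256 RGB patch with its top-left origin in slide coordinates
    (0-based row, col)."""

    pixels: np.ndarray
    origin: tuple[int, int]
    slide_id: str = "slide"

    def __post_init__(self):
        if self.pixels.shape != (TILE_SIZE, TILE_SIZE, 3):
            raise ParameterError(
                f"tile raster must be {TILE_SIZE}x{TILE_SIZE}x3, "
                f"got {self.pixels.shape}"
            )


@dataclass
class TissueMask:
    """Binary tissue raster at a stated downsample factor."""

    mask: np.ndarray
    downsample: int
    tissue_fraction_threshold: float = 0.05

    def tile_tissue_fraction(self, origin: tuple[int, int],
                             tile_size: int = TILE_SIZE) -> float:
        """Fraction of a tile's footprint covered by tissue."""
        r0 = origin[0] // self.downsample
        c0 = origin[1] // self.downsample
        n = max(1, tile_size // self.downsample)
        window = self.mask[r0:r0 + n, c0:c0 + n]
        return float(window.mean()) if window.size else 0.0

    def tile_in_tissue(self, origin: tuple[int, int],
                       tile_size: int = TILE_SIZE) -> bool:
        return self.tile_tissue_fraction(origin, tile_size) > \
            self.tissue_fraction_threshold


@dataclass
class TileQCReport:
    accepted: bool
    reasons: list[str]
    nucleus_count: int

    def __post_init__(self):
        if self.accepted != (len(self.reasons) == 0):
            raise ParameterError("accepted must equal 'reasons is empty'")


def read_slide(path) -> np.ndarray:
    """Load a slide raster from PNG or (single-resolution/tiled) TIFF.

    Returns an HxWx3 uint8 RGB array; an alpha channel, if present, is
    dropped.
    """
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(p)
    else:
        import imageio.v3 as iio
        arr = iio.imread(p)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] > 3:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def compute_tissue_mask(slide: np.ndarray, downsample: int = 16,
                        threshold_method: str = "otsu", *,
                        fallback_threshold: float = 0.08,
                        tissue_fraction_threshold: float = 0.05
                        ) -> TissueMask:
    """Saturation-based tissue mask at reduced resolution.

    Stained material is chromatic while the smear background is
    near-white and unsaturated, so a global threshold on the HSV
    saturation channel separates the two.  By default the threshold is
    Otsu's; when the saturation histogram is effectively unimodal (an
    empty or uniformly covered slide) a fixed fallback threshold is used
    instead, so an all-background slide maps to an all-zero mask.
    """
    slide = np.asarray(slide)
    if slide.ndim != 3 or slide.shape[2] != 3:
        raise ParameterError("slide must be an RGB raster")
    if downsample < 1 or min(slide.shape[:2]) < downsample:
        raise ParameterError("downsample must be >= 1 and smaller than "
                             "the slide")
    small = slide[::downsample, ::downsample]
    sat = rgb2hsv(small)[..., 1]
    if threshold_method == "otsu":
        if float(sat.max() - sat.min()) < 0.02:
            thr = fallback_threshold  # unimodal: Otsu would split noise
        else:
            thr = max(float(threshold_otsu(sat)), fallback_threshold / 2)
    elif threshold_method == "fixed":
        thr = fallback_threshold
    else:
        raise ParameterError(f"unknown threshold_method {threshold_method!r}")
    return TissueMask(mask=sat > thr, downsample=downsample,
                      tissue_fraction_threshold=tissue_fraction_threshold)


def tile_image(slide: np.ndarray, tile_size: int = TILE_SIZE,
               stride: int = TILE_SIZE, slide_id: str = "slide"
               ) -> list[Tile]:
    """Partition a slide into tiles, row-major, half-open windows.

    Edge regions smaller than ``tile_size`` are discarded; a slide
    smaller than one tile yields an empty list with a logged warning.
    """
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    slide = np.asarray(slide)
    H, W = slide.shape[:2]
    if H < tile_size or W < tile_size:
        logger.warning("slide %s (%dx%d) smaller than one %d-px tile",
                       slide_id, H, W, tile_size)
        return []
    tiles = []
    for r in range(0, H - tile_size + 1, stride):
        for c in range(0, W - tile_size + 1, stride):
            tiles.append(Tile(pixels=slide[r:r + tile_size,
                                           c:c + tile_size].copy(),
                              origin=(r, c), slide_id=slide_id))
    return tiles


def qc_filter_tile(tile: Tile, seg_preview: CellSegmentation, *,
                   contrast_margin: float = 15.0,
                   min_cytoplasm_area: int = 200) -> TileQCReport:
    """Apply the exclusion rule set to a segmented tile.

    Rejection codes: ``acellular`` (no nucleus found), ``debris`` (only
    sub-minimal dark specks, or a nucleus-like object with essentially
    no cytoplasm around it), ``multiple_cells`` (more than one
    admissible nucleus — overlaps and aggregates land here),
    ``border_contact`` (the selected cell touches the tile edge, i.e. an
    incomplete cytoplasmic contour), and ``low_contrast`` (nucleus and
    cytoplasm cluster centres closer than ``contrast_margin`` in CIELAB
    — no reliable colour structure).
    """
    reasons: list[str] = []
    if seg_preview.cluster_separation < contrast_margin:
        # nucleus and cytoplasm clusters are indistinguishable: the tile
        # holds no credibly stained cell, and any connected components
        # are noise artefacts, so component-based codes are skipped
        reasons += ["low_contrast", "acellular"]
    elif seg_preview.nucleus_count == 0:
        reasons.append("debris" if seg_preview.small_nucleus_components
                       else "acellular")
    elif seg_preview.nucleus_count > 1:
        reasons.append("multiple_cells")
    elif seg_preview.a_cytoplasm < min_cytoplasm_area:
        reasons.append("debris")  # bare chromatin clump, not a cell
    if not reasons and seg_preview.border_contact:
        reasons.append("border_contact")
    return TileQCReport(accepted=not reasons, reasons=reasons,
                        nucleus_count=seg_preview.nucleus_count)


def qc_screen(tiles: Sequence[Tile],
              params: Optional[SegmentationParams] = None, *,
              contrast_margin: float = 15.0
              ) -> list[tuple[TileQCReport, CellSegmentation]]:
    """Segment and QC every tile; returns (report, segmentation) pairs."""
    params = params or SegmentationParams()
    out = []
    for t in tiles:
        seg = segment_tile(t.pixels, params)
        out.append((qc_filter_tile(t, seg, contrast_margin=contrast_margin),
                    seg))
    return out


def sample_valid_tiles(tiles: Sequence[Tile], n_required: int,
                       rng_seed: int = 0, *,
                       reports: Optional[Sequence[TileQCReport]] = None,
                       params: Optional[SegmentationParams] = None,
                       return_indices: bool = False):
    """Seeded uniform sample (without replacement) of QC-accepted tiles.

    Returns exactly ``n_required`` accepted tiles (their indices into
    ``tiles`` with ``return_indices=True``), or raises
    :class:`InsufficientTilesError` reporting how many passed QC.  QC
    reports are computed on demand when not supplied.
    """
    if n_required < 1:
        raise ParameterError("n_required must be >= 1")
    if reports is None:
        reports = [r for r, _ in qc_screen(tiles, params)]
    accepted = [i for i, rep in enumerate(reports) if rep.accepted]
    if len(accepted) < n_required:
        raise InsufficientTilesError(len(accepted), n_required)
    rng = np.random.default_rng(rng_seed)
    chosen = rng.choice(len(accepted), size=n_required, replace=False)
    idx = [accepted[i] for i in np.sort(chosen)]
    return idx if return_indices else [tiles[i] for i in idx]


def write_tile_manifest(tiles: Sequence[Tile], path, *,
                        tile_size: int = TILE_SIZE, stride: int = TILE_SIZE,
                        reports: Optional[Sequence[TileQCReport]] = None
                        ) -> None:
    """JSON sidecar recording the tiling convention and QC outcomes:
    0-based row-major origins of half-open windows."""
    import json
    payload = {
        "slide_id": tiles[0].slide_id if tiles else "slide",
        "tile_size": tile_size, "stride": stride,
        "origins": [list(t.origin) for t in tiles],
        "qc": ([{"accepted": r.accepted, "reasons": r.reasons,
                 "nucleus_count": r.nucleus_count} for r in reports]
               if reports is not None else None),
    }
    Path(path).write_text(json.dumps(payload))


def read_tile_manifest(path) -> dict:
    """Inverse of :func:`write_tile_manifest`; origins become tuples."""
    import json
    d = json.loads(Path(path).read_text())
    d["origins"] = [tuple(o) for o in d["origins"]]
    return d
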