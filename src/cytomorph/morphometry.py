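"""Per-cell N/C ratios and case-level aggregation.

The morphometric read-out for one cell is the nucleus-to-cytoplasm area
ratio N/C = A_nucleus / A_cytoplasm in pixels (the micron-per-pixel
factor cancels in the quotient).  The case-level value for one animal is
the median N/C across all quantified cells from its two slides, which is
robust to the occasional mis-segmented cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AggregationError, ParameterError
from .segmentation import CellSegmentation
from .study_data import Cohort

logger = logging.getLogger(__name__)

#: scanner resolution the defaults are calibrated for (reporting only)
MICRONS_PER_PIXEL = 0.14


@dataclass
class CellMorphometry:
    """Areas and N/C ratio of one quantified cell."""

    slide_id: str
    tile_origin: tuple[int, int]
    a_nucleus: int
    a_cytoplasm: int
    nc_ratio_: float = field(init=False)

    def __post_init__(self):
        self.nc_ratio_ = nc_ratio(self.a_nucleus, self.a_cytoplasm)

    @property
    def nc_ratio(self) -> float:
        return self.nc_ratio_

    def area_um2(self, compartment: str = "nucleus",
                 mpp: float = MICRONS_PER_PIXEL) -> float:
        """Compartment area in square microns, for reporting."""
        px = self.a_nucleus if compartment == "nucleus" else self.a_cytoplasm
        return px * mpp * mpp


@dataclass
class CaseMorphometry:
    """All quantified cells of one animal and the case-level median."""

    cat_id: str
    cells: list[CellMorphometry]
    n_wsis: int
    case_nc_ratio: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def nc_ratio(a_nucleus: int, a_cytoplasm: int) -> float:
    """Exact quotient A_nucleus / A_cytoplasm (areas in pixels)."""
    if a_nucleus < 0:
        raise ParameterError("a_nucleus must be >= 0")
    if a_cytoplasm <= 0:
        raise ParameterError(
            "a_cytoplasm must be positive; anucleate/empty segmentations "
            "must be rejected by QC upstream"
        )
    return a_nucleus / a_cytoplasm


def cell_from_segmentation(seg: CellSegmentation, slide_id: str,
                           tile_origin: tuple[int, int]) -> CellMorphometry:
    """Morphometry record for a QC-accepted segmentation."""
    return CellMorphometry(slide_id=slide_id, tile_origin=tile_origin,
                           a_nucleus=seg.a_nucleus,
                           a_cytoplasm=seg.a_cytoplasm)


def aggregate_case(cells: Sequence[CellMorphometry], cat_id: str, *,
                   n_wsis: int = 2, expected_cells_per_wsi: int = 250
                   ) -> CaseMorphometry:
    """Case-level N/C as the median over all cells of the case's slides.

    An even cell count uses the mean of the two central order
    statistics.  A cell count different from the expected
    ``expected_cells_per_wsi * n_wsis`` is logged, not an error.
    """
    if not cells:
        raise AggregationError(f"case {cat_id}: no cells to aggregate")
    expected = expected_cells_per_wsi * n_wsis
    if len(cells) != expected:
        logger.warning("case %s: %d cells (expected %d = %d x %d)",
                       cat_id, len(cells), expected, expected_cells_per_wsi,
                       n_wsis)
    med = float(np.median([c.nc_ratio for c in cells]))
    return CaseMorphometry(cat_id=cat_id, cells=list(cells), n_wsis=n_wsis,
                           case_nc_ratio=med)


def stratify_morphometry(cohort: Cohort, by: str) -> pd.DataFrame:
    """Case-level N/C summarised per stratum of an ordinal covariate.

    ``by`` is one of ``inflammation_score``, ``dysplasia_grade`` or
    ``exposure``.  Returns one row per non-empty stratum with n, median,
    Q1 and Q3 (linear-interpolation quantiles); empty strata are skipped
    with a logged warning.
    """
    if by not in ("inflammation_score", "dysplasia_grade", "exposure"):
        raise ParameterError(f"cannot stratify by {by!r}")
    rows = []
    df = cohort.to_frame()
    if df["case_nc_ratio"].isna().any():
        raise ParameterError("all records need a case_nc_ratio to stratify")
    if df[by].isna().any():
        raise ParameterError(f"stratifying field {by} missing on some records")
    for stratum, grp in df.groupby(by, sort=True):
        vals = grp["case_nc_ratio"].to_numpy(dtype=float)
        if vals.size == 0:
            logger.warning("stratum %s=%r is empty; skipped", by, stratum)
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({by: stratum, "n": int(vals.size), "median": float(med),
                     "q1": float(q1), "q3": float(q3)})
    return pd.DataFrame(rows)


def cells_to_frame(cases: Sequence[CaseMorphometry]) -> pd.DataFrame:
    """One row per quantified cell, across cases."""
    rows = []
    for case in cases:
        for c in case.cells:
            rows.append({"cat_id": case.cat_id, "slide_id": c.slide_id,
                         "tile_row": c.tile_origin[0],
                         "tile_col": c.tile_origin[1],
                         "a_nucleus": c.a_nucleus,
                         "a_cytoplasm": c.a_cytoplasm,
                         "nc_ratio": c.nc_ratio})
    return pd.DataFrame(rows)


def cases_to_frame(cases: Sequence[CaseMorphometry]) -> pd.DataFrame:
    """Case-level summary: cat_id, n_cells, n_wsis, case N/C, quartiles."""
    rows = []
    for case in cases:
        ratios = [c.nc_ratio for c in case.cells]
        q1, q3 = np.percentile(ratios, [25, 75])
        rows.append({"cat_id": case.cat_id, "n_cells": case.n_cells,
                     "n_wsis": case.n_wsis,
                     "case_nc_ratio": case.case_nc_ratio,
                     "q1": float(q1), "q3": float(q3)})
    return pd.DataFrame(rows)
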