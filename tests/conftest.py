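"""Shared fixtures: the bundled study cohort and seeded synthetic batches.

The expensive fixtures (segmented tile batches) are session-scoped so the
segmentation-accuracy and QC-discrimination tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from cytomorph.segmentation import segment_tile
from cytomorph.study_data import load_study_cohort
from cytomorph.synthetic import (CLUTTER_KINDS, generate_cell_tile,
                                 generate_clutter_tile)
from cytomorph.tiling import Tile, qc_filter_tile


@pytest.fixture(scope="session")
def study_cohort():
    return load_study_cohort()


@pytest.fixture(scope="session")
def clean_batch():
    """100 clean single-cell tiles spanning the cohort's N/C range
    (0.2-0.85), each with truth, segmentation and QC report."""
    rng = np.random.default_rng(12345)
    batch = []
    for i in range(100):
        target = float(rng.uniform(0.20, 0.85))
        img, truth = generate_cell_tile(target, rng_seed=10_000 + i)
        seg = segment_tile(img)
        rep = qc_filter_tile(Tile(pixels=img, origin=(0, 0)), seg)
        batch.append((img, truth, seg, rep))
    return batch


@pytest.fixture(scope="session")
def clutter_batches():
    """40 segmented+QC'd tiles per artefact kind."""
    out = {}
    for kind in CLUTTER_KINDS:
        rows = []
        for i in range(40):
            img, truth = generate_clutter_tile(kind, rng_seed=20_000 + i)
            seg = segment_tile(img)
            rep = qc_filter_tile(Tile(pixels=img, origin=(0, 0)), seg)
            rows.append((img, truth, seg, rep))
        out[kind] = rows
    return out
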