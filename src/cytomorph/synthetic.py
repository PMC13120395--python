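"""Synthetic MGG-like smear tiles and cohorts with known ground truth.

Romanowsky-type (May-Gruenwald-Giemsa) oral smears have a characteristic
appearance: dark violet chromatin, pale blue-grey basophilic cytoplasm and
a near-white background, with scattered debris and inflammatory cells.
This module emulates that appearance well enough for colour-clustering
segmentation to be exercised realistically, while keeping exact pixel
ground truth: every generated tile carries its nucleus and cytoplasm
masks, so segmentation accuracy (Dice, N/C error) and tile-QC decisions
can be scored against truth.

At the cohort level the generator reproduces the statistical structure of
the study population: non-exposed cats draw their true case N/C ratio
from a tight band (uniform on [0.215, 0.236]) while exposed cats draw
from a broad right-skewed scaled Beta on [0.24, 0.85]; urinary cotinine
is coupled to the true N/C through a Gaussian copula whose rank
correlation is set directly by ``coupling_strength``, with a heavy-tailed
lognormal marginal in the exposed group (a minority of individuals exceed
200 ng/mL).  Inflammation scores and dysplasia grades are assigned by
thresholding the true N/C with configurable cutpoints, which makes
stratum medians monotone by construction.

All randomness flows from one root seed through ``numpy`` SeedSequence
streams keyed by (stage, cat index, slide index, tile index), so any
tile or cohort can be regenerated bit-for-bit in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy import stats as sps
from skimage.color import rgb2lab
from skimage.draw import ellipse as draw_ellipse

from .errors import ParameterError
from .study_data import EXPOSED, NON_EXPOSED, CatRecord, Cohort

TILE_SIZE = 256

CLUTTER_KINDS = ("acellular", "overlap", "debris", "border_cut",
                 "inflammatory_aggregate")

# stage tags for seed-stream derivation
_STAGE_COHORT = 1
_STAGE_TILE = 2
_STAGE_WSI = 3


def _rng_for(seed: int, *tags: int) -> np.random.Generator:
    """Child generator derived from the root seed and integer path tags."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, tags)]))


@dataclass(frozen=True)
class StainProfile:
    """Mean RGB colour and per-channel spread for the three compartments,
    plus global additive pixel noise.

    The defaults approximate an MGG smear: dark violet nucleus, pale
    blue-grey cytoplasm, near-white background.  Only two properties are
    contractual: the three means must be pairwise separated in CIELAB by
    at least ``min_lab_separation``, and lightness must order
    nucleus < cytoplasm < background.
    """

    nucleus_color: tuple[float, float, float] = (70.0, 40.0, 110.0)
    nucleus_sd: float = 6.0
    cytoplasm_color: tuple[float, float, float] = (180.0, 185.0, 215.0)
    cytoplasm_sd: float = 6.0
    background_color: tuple[float, float, float] = (245.0, 245.0, 248.0)
    background_sd: float = 2.0
    noise_sd: float = 8.0
    min_lab_separation: float = 15.0

    def lab_means(self) -> np.ndarray:
        """CIELAB (D65) coordinates of the three mean colours,
        ordered nucleus, cytoplasm, background."""
        rgb = np.array([self.nucleus_color, self.cytoplasm_color,
                        self.background_color], dtype=float) / 255.0
        return rgb2lab(rgb.reshape(1, 3, 3)).reshape(3, 3)

    def __post_init__(self):
        lab = self.lab_means()
        d = [np.linalg.norm(lab[i] - lab[j])
             for i in range(3) for j in range(i + 1, 3)]
        if min(d) < self.min_lab_separation:
            raise ParameterError(
                f"stain colours too close in CIELAB: min pairwise distance "
                f"{min(d):.1f} < margin {self.min_lab_separation}"
            )
        if not (lab[0, 0] < lab[1, 0] < lab[2, 0]):
            raise ParameterError(
                "stain lightness must order nucleus < cytoplasm < background"
            )


@dataclass
class TileTruth:
    """Ground-truth compartment masks and derived quantities for one tile."""

    nucleus_mask: np.ndarray
    cytoplasm_mask: np.ndarray
    true_nc_ratio: float
    cell_count: int
    kind: str = "cell"  # "cell" or one of CLUTTER_KINDS

    def __post_init__(self):
        if (self.nucleus_mask & self.cytoplasm_mask).any():
            raise ParameterError("truth masks must be disjoint")


def _render(class_map: np.ndarray, stain: StainProfile,
            rng: np.random.Generator) -> np.ndarray:
    """Render a 0/1/2 (background/cytoplasm/nucleus) class map as RGB."""
    means = np.array([stain.background_color, stain.cytoplasm_color,
                      stain.nucleus_color])
    sds = np.array([stain.background_sd, stain.cytoplasm_sd,
                    stain.nucleus_sd])
    img = means[class_map] + rng.standard_normal(class_map.shape + (3,)) * \
        sds[class_map][..., None]
    img += rng.standard_normal(img.shape) * stain.noise_sd
    return np.clip(img, 0, 255).astype(np.uint8)


def _ellipse_mask(center, r_rad, c_rad, rotation, shape=(TILE_SIZE, TILE_SIZE)):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(center[0], center[1], r_rad, c_rad,
                          shape=shape, rotation=rotation)
    mask[rr, cc] = True
    return mask


def _solve_cell_geometry(target_nc: float, rng: np.random.Generator, *,
                         min_axis: float = 20.0, max_axis: float = 58.0,
                         border_margin: int = 6):
    """One ellipse-within-ellipse cell whose realised mask-area N/C is
    within 0.5% of target (pixel quantisation corrected iteratively)."""
    ecc = rng.uniform(1.0, 2.0)
    a = rng.uniform(max(min_axis * ecc, 38.0), max_axis)  # semi-major
    b = a / ecc                                           # semi-minor
    rot = rng.uniform(0, math.pi)
    # bounding half-extent of a rotated ellipse is <= semi-major
    lo = a + border_margin
    hi = TILE_SIZE - 1 - a - border_margin
    center = (rng.uniform(lo, hi), rng.uniform(lo, hi))
    cell = _ellipse_mask(center, a, b, rot)
    a_cell = int(cell.sum())
    # nucleus area so that A_n / (A_cell - A_n) == target_nc
    want = target_nc / (1 + target_nc) * a_cell
    s = math.sqrt(want / (math.pi * a * b))
    # small centre jitter, shrunk to keep the nucleus inside the cell
    jitter = rng.uniform(-1, 1, size=2) * 0.3 * (1 - s) * b
    ncenter = (center[0] + jitter[0], center[1] + jitter[1])
    nucleus = None
    for _ in range(12):
        nucleus = _ellipse_mask(ncenter, a * s, b * s, rot)
        if not (nucleus & ~cell).any():
            realized = nucleus.sum()
            if realized > 0 and abs(realized - want) / want <= 0.005:
                break
            s *= math.sqrt(want / max(realized, 1.0))
        else:  # jittered nucleus crossed the cell boundary: recentre
            ncenter = center
    if nucleus is None or (nucleus & ~cell).any() or nucleus.sum() == 0:
        raise ParameterError(
            f"could not realise target N/C {target_nc} with the configured "
            "cell-size range"
        )
    return cell, nucleus


def generate_cell_tile(target_nc: float, stain: Optional[StainProfile] = None,
                       rng_seed=0) -> tuple[np.ndarray, TileTruth]:
    """One 256x256 tile containing a single intact nucleated cell.

    The realised mask-area N/C ratio is within 3% relative error of
    ``target_nc`` (the geometry solver targets 0.5%); the cell does not
    touch the tile border.  Returns the RGB image and its truth record.
    """
    if not 0 < target_nc < 1:
        raise ParameterError("target_nc must lie in (0, 1)")
    stain = stain or StainProfile()
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    cell, nucleus = _solve_cell_geometry(target_nc, rng)
    cytoplasm = cell & ~nucleus
    class_map = np.zeros((TILE_SIZE, TILE_SIZE), dtype=np.uint8)
    class_map[cytoplasm] = 1
    class_map[nucleus] = 2
    img = _render(class_map, stain, rng)
    truth = TileTruth(nucleus_mask=nucleus, cytoplasm_mask=cytoplasm,
                      true_nc_ratio=float(nucleus.sum() / cytoplasm.sum()),
                      cell_count=1)
    return img, truth


def _spots(rng, n, rad_lo, rad_hi, region=(10, TILE_SIZE - 10)):
    out = []
    for _ in range(n):
        r = rng.uniform(*region)
        c = rng.uniform(*region)
        rad = rng.uniform(rad_lo, rad_hi)
        out.append(((r, c), rad))
    return out


def generate_clutter_tile(kind: str, stain: Optional[StainProfile] = None,
                          rng_seed=0) -> tuple[np.ndarray, TileTruth]:
    """A tile exhibiting one of the artefact classes the tile QC must
    reject: acellular field, overlapping cells, debris, a border-clipped
    cell, or an inflammatory-cell aggregate."""
    if kind not in CLUTTER_KINDS:
        raise ParameterError(f"unknown clutter kind {kind!r}; "
                             f"expected one of {CLUTTER_KINDS}")
    stain = stain or StainProfile()
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    class_map = np.zeros((TILE_SIZE, TILE_SIZE), dtype=np.uint8)
    nucleus = np.zeros((TILE_SIZE, TILE_SIZE), dtype=bool)
    cytoplasm = np.zeros((TILE_SIZE, TILE_SIZE), dtype=bool)
    cell_count = 0

    if kind == "acellular":
        pass  # background only

    elif kind == "debris":
        # dark specks well below any plausible nucleus area
        for (ctr, rad) in _spots(rng, rng.integers(8, 16), 2.0, 4.5):
            nucleus |= _ellipse_mask(ctr, rad, rad, 0.0)
        cell_count = 0

    elif kind == "overlap":
        # two cells with intersecting cytoplasm but separate nuclei
        ecc = rng.uniform(1.0, 1.5)
        a = rng.uniform(42, 52)
        b = a / ecc
        c0 = np.array([rng.uniform(90, 110), rng.uniform(80, 100)])
        offset = np.array([rng.uniform(20, 35), rng.uniform(45, 60)])
        cells, nucs = [], []
        for ctr in (c0, c0 + offset):
            rot = rng.uniform(0, math.pi)
            cell = _ellipse_mask(tuple(ctr), a, b, rot)
            nuc = _ellipse_mask(tuple(ctr), a * 0.45, b * 0.45, rot)
            cells.append(cell)
            nucs.append(nuc)
        assert (nucs[0] & nucs[1]).sum() == 0
        nucleus = nucs[0] | nucs[1]
        cytoplasm = (cells[0] | cells[1]) & ~nucleus
        cell_count = 2

    elif kind == "border_cut":
        # one cell whose contour is clipped by the tile edge
        a = rng.uniform(40, 55)
        b = a / rng.uniform(1.0, 1.6)
        edge = rng.integers(0, 4)
        pos = rng.uniform(60, 196)
        off = rng.uniform(-0.3, 0.3) * b
        coords = {0: (off, pos), 1: (TILE_SIZE - 1 - off, pos),
                  2: (pos, off), 3: (pos, TILE_SIZE - 1 - off)}[int(edge)]
        rot = rng.uniform(0, math.pi)
        cell = _ellipse_mask(coords, a, b, rot)
        nuc = _ellipse_mask(coords, a * 0.45, b * 0.45, rot) & cell
        nucleus = nuc
        cytoplasm = cell & ~nuc
        cell_count = 1

    elif kind == "inflammatory_aggregate":
        # cluster of small round leukocyte-like cells with thin rims
        centre = np.array([rng.uniform(90, 166), rng.uniform(90, 166)])
        n_cells = int(rng.integers(6, 11))
        for _ in range(n_cells):
            ctr = centre + rng.uniform(-45, 45, size=2)
            rad = rng.uniform(7, 10)
            cyt = _ellipse_mask(tuple(ctr), rad + 3, rad + 3, 0.0)
            nuc = _ellipse_mask(tuple(ctr), rad, rad, 0.0)
            nucleus |= nuc
            cytoplasm |= cyt
        cytoplasm &= ~nucleus
        cell_count = n_cells

    class_map[cytoplasm] = 1
    class_map[nucleus] = 2
    img = _render(class_map, stain, rng)
    nc = (float(nucleus.sum() / cytoplasm.sum())
          if cytoplasm.sum() else float("nan"))
    truth = TileTruth(nucleus_mask=nucleus, cytoplasm_mask=cytoplasm,
                      true_nc_ratio=nc, cell_count=cell_count, kind=kind)
    return img, truth


def generate_synthetic_wsi(case_nc_center: float, dispersion: float = 0.02,
                           n_tiles: int = 250,
                           stain: Optional[StainProfile] = None,
                           rng_seed: int = 0, *,
                           clutter_fraction: float = 0.0
                           ) -> tuple[list[tuple[np.ndarray, TileTruth]],
                                      list[float]]:
    """A slide's worth of tiles for one case.

    Per-cell target N/C values are drawn from a normal around
    ``case_nc_center`` (clipped to (0.05, 0.92)); a ``clutter_fraction``
    of tiles is replaced by artefact tiles (kinds cycled, positions
    shuffled).  Returns the (image, truth) list and the realised true
    N/C values of the cell tiles.
    """
    if n_tiles < 1:
        raise ParameterError("n_tiles must be >= 1")
    if not 0 <= clutter_fraction < 1:
        raise ParameterError("clutter_fraction must lie in [0, 1)")
    root = (rng_seed if isinstance(rng_seed, (int, np.integer))
            else 0)
    rng = _rng_for(root, _STAGE_WSI)
    n_clutter = round(clutter_fraction * n_tiles)
    kinds = [CLUTTER_KINDS[i % len(CLUTTER_KINDS)] for i in range(n_clutter)]
    slots = ["cell"] * (n_tiles - n_clutter) + kinds
    rng.shuffle(slots)
    tiles = []
    true_ncs = []
    for i, slot in enumerate(slots):
        trng = _rng_for(root, _STAGE_TILE, i)
        if slot == "cell":
            target = float(np.clip(rng.normal(case_nc_center, dispersion),
                                   0.05, 0.92))
            img, truth = generate_cell_tile(target, stain, trng)
            true_ncs.append(truth.true_nc_ratio)
        else:
            img, truth = generate_clutter_tile(slot, stain, trng)
        tiles.append((img, truth))
    return tiles, true_ncs


def assemble_slide(tiles: Sequence[np.ndarray], n_cols: int,
                   background: tuple[int, int, int] = (245, 245, 248)
                   ) -> np.ndarray:
    """Arrange tiles on a grid into a single slide raster (row-major)."""
    n = len(tiles)
    n_rows = math.ceil(n / n_cols)
    slide = np.empty((n_rows * TILE_SIZE, n_cols * TILE_SIZE, 3),
                     dtype=np.uint8)
    slide[...] = np.array(background, dtype=np.uint8)
    for i, t in enumerate(tiles):
        r, c = divmod(i, n_cols)
        slide[r * TILE_SIZE:(r + 1) * TILE_SIZE,
              c * TILE_SIZE:(c + 1) * TILE_SIZE] = t
    return slide


@dataclass
class SyntheticCohortConfig:
    """Study conditions for synthetic cohort generation.

    The defaults mirror the enrolled population: 20 exposed and 10
    non-exposed indoor cats, two slides per cat with 250 quantified
    tiles each, urinary cotinine available for 13 exposed and 8
    non-exposed animals, and a cotinine-N/C rank coupling of 0.85 in
    the exposed group.
    """

    n_exposed: int = 20
    n_non_exposed: int = 10
    # non-exposed true case N/C: tight uniform band
    nonexposed_nc_range: tuple[float, float] = (0.215, 0.236)
    # exposed true case N/C: right-skewed scaled Beta on [lo, hi]
    exposed_nc_range: tuple[float, float] = (0.24, 0.85)
    exposed_nc_beta: tuple[float, float] = (1.2, 4.0)
    # cotinine marginals (ng/mL)
    cotinine_baseline: float = 1.5       # non-exposed location
    cotinine_baseline_sd: float = 1.0
    exposed_cotinine_median: float = 50.0   # lognormal scale
    exposed_cotinine_sigma: float = 1.2     # heavy right tail
    coupling_strength: float = 0.85   # target Spearman rho, exposed group
    # urine availability: 13/20 exposed, 8/10 non-exposed at the default
    # group sizes; None adapts to smaller groups
    n_exposed_cotinine: Optional[int] = None
    n_non_exposed_cotinine: Optional[int] = None
    # ordinal labels from true N/C
    dysplasia_cutpoints: tuple[float, float, float] = (0.33, 0.50, 0.70)
    inflammation_cutpoints: tuple[float, float, float] = (0.24, 0.45, 0.55)
    tiles_per_wsi: int = 250
    wsis_per_cat: int = 2
    cell_dispersion: float = 0.02     # per-cell spread of target N/C
    clutter_fraction: float = 0.0
    stain: StainProfile = field(default_factory=StainProfile)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_exposed", "n_non_exposed", "tiles_per_wsi",
                     "wsis_per_cat"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        if not 0 <= self.coupling_strength <= 1:
            raise ParameterError("coupling_strength must lie in [0, 1]")
        if self.n_exposed_cotinine is None:
            self.n_exposed_cotinine = min(13, self.n_exposed)
        if self.n_non_exposed_cotinine is None:
            self.n_non_exposed_cotinine = min(8, self.n_non_exposed)
        if self.n_exposed_cotinine > self.n_exposed or \
                self.n_non_exposed_cotinine > self.n_non_exposed:
            raise ParameterError("cotinine subset larger than its group")


def _grade(value: float, cutpoints: Sequence[float]) -> int:
    g = 0
    for c in cutpoints:
        if value >= c:
            g += 1
    return g


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """A synthetic cohort table with true case N/C, cotinine and ordinal
    labels filled in.

    The exposed group's cotinine and true case N/C are drawn from a
    Gaussian copula with correlation ``r = 2 sin(pi * rho_s / 6)`` so the
    population Spearman correlation equals ``coupling_strength``; with
    coupling 1 the coupling is comonotone and the sample rank correlation
    is exactly 1.  Tile imagery is generated separately (and lazily) via
    :func:`generate_case_wsis`, keyed by the same root seed.
    """
    cfg = config
    rng = _rng_for(cfg.seed, _STAGE_COHORT)
    records: list[CatRecord] = []

    # --- exposed group: copula-coupled (N/C, cotinine) --------------------
    rho_s = cfg.coupling_strength
    r = 2 * math.sin(math.pi * rho_s / 6)
    z1 = rng.standard_normal(cfg.n_exposed)
    z2 = r * z1 + math.sqrt(max(0.0, 1 - r * r)) * \
        rng.standard_normal(cfg.n_exposed)
    u_nc = sps.norm.cdf(z1)
    u_cot = sps.norm.cdf(z2)
    lo, hi = cfg.exposed_nc_range
    a, b = cfg.exposed_nc_beta
    nc_exposed = lo + (hi - lo) * sps.beta.ppf(u_nc, a, b)
    cot_exposed = sps.lognorm.ppf(
        u_cot, s=cfg.exposed_cotinine_sigma,
        scale=cfg.exposed_cotinine_median)
    with_cot_e = set(rng.choice(cfg.n_exposed, size=cfg.n_exposed_cotinine,
                                replace=False).tolist())

    ages = rng.choice([1, 2, 3, 4, 5], size=cfg.n_exposed,
                      p=[0.45, 0.15, 0.05, 0.05, 0.30])
    sexes = rng.choice(["M", "F"], size=cfg.n_exposed, p=[0.65, 0.35])
    smokers = rng.choice([1, 2], size=cfg.n_exposed, p=[0.8, 0.2])
    cigs = rng.integers(4, 12, size=cfg.n_exposed)
    for i in range(cfg.n_exposed):
        nc = float(nc_exposed[i])
        records.append(CatRecord(
            cat_id=f"E{i + 1:02d}", exposure=EXPOSED, age=float(ages[i]),
            sex=str(sexes[i]), smoker_owners=int(smokers[i]),
            cigarettes_per_day=float(cigs[i]),
            cotinine_ng_ml=float(cot_exposed[i]) if i in with_cot_e else None,
            inflammation_score=_grade(nc, cfg.inflammation_cutpoints),
            dysplasia_grade=_grade(nc, cfg.dysplasia_cutpoints),
            case_nc_ratio=nc,
        ))

    # --- non-exposed group: tight N/C band, near-baseline cotinine -------
    lo_n, hi_n = cfg.nonexposed_nc_range
    nc_non = rng.uniform(lo_n, hi_n, size=cfg.n_non_exposed)
    cot_non = np.abs(rng.normal(0, cfg.cotinine_baseline_sd,
                                size=cfg.n_non_exposed)) + cfg.cotinine_baseline
    with_cot_n = set(rng.choice(cfg.n_non_exposed,
                                size=cfg.n_non_exposed_cotinine,
                                replace=False).tolist())
    ages_n = rng.choice([1, 2, 3, 4, 5], size=cfg.n_non_exposed,
                        p=[0.15, 0.10, 0.10, 0.20, 0.45])
    sexes_n = rng.choice(["M", "F"], size=cfg.n_non_exposed, p=[0.4, 0.6])
    for i in range(cfg.n_non_exposed):
        nc = float(nc_non[i])
        records.append(CatRecord(
            cat_id=f"N{i + 1:02d}", exposure=NON_EXPOSED,
            age=float(ages_n[i]), sex=str(sexes_n[i]), smoker_owners=0,
            cigarettes_per_day=0.0,
            cotinine_ng_ml=float(cot_non[i]) if i in with_cot_n else None,
            inflammation_score=_grade(nc, cfg.inflammation_cutpoints),
            dysplasia_grade=_grade(nc, cfg.dysplasia_cutpoints),
            case_nc_ratio=nc,
        ))
    return Cohort(records, provenance=f"synthetic cohort (seed {cfg.seed})")


def generate_case_wsis(config: SyntheticCohortConfig, cat_index: int,
                       case_nc: float
                       ) -> Iterator[tuple[int, list, list]]:
    """Yield ``(wsi_index, tiles, true_ncs)`` for one cat's slides.

    The per-slide seed is derived from the cohort root seed and the cat
    and slide indices, so slides can be regenerated independently.
    """
    for w in range(config.wsis_per_cat):
        seed = int(np.random.SeedSequence(
            [config.seed, _STAGE_WSI, cat_index, w]).generate_state(1)[0]
            % (2 ** 31))
        tiles, ncs = generate_synthetic_wsi(
            case_nc, dispersion=config.cell_dispersion,
            n_tiles=config.tiles_per_wsi, stain=config.stain,
            rng_seed=seed, clutter_fraction=config.clutter_fraction)
        yield w, tiles, ncs
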