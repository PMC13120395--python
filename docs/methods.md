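# Methods

## The measurement model

The quantity of interest is the nucleus-to-cytoplasm area ratio
`N/C = A_nucleus / A_cytoplasm` of single exfoliated epithelial cells,
computed in pixels (at a fixed scan resolution — 0.14 µm/px for the
calibration defaults — the µm²/px² factor cancels in the quotient, so no
physical calibration enters the ratio; a conversion helper exists for
reporting areas only). One animal contributes two MGG-stained slides; 250
cells are quantified per slide, one per accepted tile, and the case-level
value is the **median** of all ~500 per-cell ratios. The median is the
deliberate choice of location: it is insensitive to the occasional
mis-segmented cell (a 5% contamination of 10× outliers moves a 500-cell
case median by well under 2%, which is tested empirically).

Key assumptions: cells are measured only on Romanowsky-type (MGG)
staining, where chromatin is dark violet and cytoplasm pale blue-grey, so
colour alone separates compartments; tiles hold at most one intact cell
after QC; and per-cell measurement errors are exchangeable across tiles so
the case median is a consistent estimate of the case's central N/C.

## Segmentation

Per tile: sRGB → CIELAB (D65) → K-means (k = 3) in (L, a, b) →
compartment assignment by lightness ranking (darkest cluster = nucleus,
middle = cytoplasm, lightest = background; exact-L ties broken by chroma,
the more chromatic cluster toward the nucleus) → morphological opening
(disk r = 1) and closing (disk r = 2), nucleus hole-filling, overlap
resolved nucleus-wins → 8-connected components; the largest nucleus
component of ≥ 80 px is the primary cell, and its cytoplasm is the set of
cytoplasm-labelled pixels in the same connected nucleus∪cytoplasm region.

k = 3, not 2: every tile contains background, so a two-class model would
force the background into one of the compartments. Clustering is per
tile; settings are global constants per run, recorded as a config hash in
the run manifest, so identical settings across all slides is checkable.

Two numerical choices matter:

- **Pre-clustering blur.** A channel-wise Gaussian (σ = 1 px) is applied
  before the CIELAB conversion used for clustering. Without it, on tiles
  where one small cell faces ~58k noisy background pixels, the *global*
  K-means optimum can prefer splitting the background's noise distribution
  into two clusters over separating the (far smaller) cytoplasm class —
  verified by comparing within-cluster sums of squares of the two
  solutions. The blur shrinks within-class variance faster than
  between-class distance and removes the pathology; a uniform tile is
  unchanged by it.
- **Subsampled centre fitting.** Centres are fitted (k-means++, 5
  restarts, tol 1e-4, ≤ 300 iterations, fixed seed) on a seeded random
  subsample of 8192 pixels, then every pixel is assigned to its nearest
  centre. For three well-separated colour modes this is statistically
  indistinguishable from a full fit and ~25× faster. Both steps are
  deterministic given the seed.

Colour-degenerate tiles (fewer distinct colours than k) are returned as
empty segmentations with zero cluster separation and fall to QC as
low-contrast.

## Tile quality control

QC replaces the visual screening an expert would do with an explicit rule
set enforcing the same exclusion list — acellular fields, overlaps,
debris, inflammatory aggregates, incomplete cytoplasmic contours:

| code | rule |
|---|---|
| `low_contrast` | CIELAB distance between the nucleus and cytoplasm cluster centres < 15 (the stain-profile separation margin) |
| `acellular` | no admissible nucleus component; also implied by `low_contrast`, since cluster structure is then noise |
| `debris` | only sub-minimal (< 80 px) dark components, or a nucleus-like object with < 200 px of cytoplasm around it |
| `multiple_cells` | more than one nucleus component ≥ 80 px (overlaps and inflammatory aggregates land here) |
| `border_contact` | the selected cell's mask touches the tile edge |

The separation test deliberately uses the nucleus–cytoplasm pair rather
than the minimum over all centre pairs: when a compartment is genuinely
absent, two clusters split the background and an all-pairs minimum would
flag every tile on the slide. 250 accepted tiles per slide are then drawn
by seeded uniform sampling without replacement (order-of-scan mode is the
alternative; the sampling default reflects that candidate tiles come from
anywhere in the tissue-containing region). Fewer accepted tiles than
requested is an error carrying the accepted count, mirroring the
study-design minimum of 250 valid tiles per slide.

Tissue masking is Otsu's threshold on the HSV saturation of a 16×
downsampled slide (stained material is chromatic; smear background is
near-white), with a fixed fallback threshold (0.08) when the saturation
histogram is effectively unimodal — an empty slide must yield an all-zero
mask, which Otsu alone cannot guarantee.

## Statistics

- Median [IQR] with linear-interpolation quantiles throughout (this
  convention reproduces the published IQRs from the individual data
  exactly).
- Mann–Whitney U: two-sided, midrank ties; exact p when both n ≤ 8 with
  no ties, otherwise normal approximation with tie and continuity
  correction (scipy's implementation; the exact branch is verified against
  full rank-split enumeration in tests).
- Cliff's delta computed exactly over all n₁·n₂ pairs; CI by percentile
  bootstrap (default 10 000 replicates, groups resampled independently,
  seeded). With disjoint supports every resample yields δ = 1 and the CI
  degenerates to [1, 1], as it should.
- Fisher's exact test: probability-ordering two-sided p. The OR point
  estimate is the sample cross-product (a·d)/(b·c), not the conditional
  MLE. Two CI flavours: `exact` (conditional, from the noncentral
  hypergeometric likelihood — the default) and `logit` (Woolf normal
  approximation). They differ noticeably at these sample sizes; both are
  exposed because both are in common use under the label "95% CI".
- Spearman: Pearson correlation of midranks, listwise deletion of
  incomplete pairs. Exact permutation p for n ≤ 8 (full enumeration);
  t-approximation above. The cutoff sits at 8 because 9! and 10!
  permutations per call buy no practical accuracy at the sample sizes
  where an exact branch is ever relevant.
- Fisher-z CI for a correlation: `tanh(atanh ρ ± z₀.₉₇₅/√(n−3))`; |ρ| = 1
  returns the degenerate point interval with a flag. Applied to Spearman's
  ρ this interval is approximate; its empirical coverage at n = 30 under a
  Gaussian copula is ~94–95% at moderate ρ, degrading toward strong ρ
  (~93% at ρ = 0.85), which the acceptance checks bound at 95% ± 3%.
- The exposed-cohort correlation matrix uses the listwise-complete subset
  across all five variables (cotinine, case N/C, inflammation score,
  dysplasia grade, age) and refuses fewer than 4 complete cases, naming
  the offending variables.
- No multiple-testing correction is applied anywhere, deliberately; the
  analysis reports raw two-sided p-values (α = 0.05).

## Synthetic data: what it emulates and what it does not

The generator produces 256×256 tiles of ellipse-within-ellipse cells on a
noisy three-class colour model (nucleus ≈ RGB (70, 40, 110), cytoplasm ≈
(180, 185, 215), background ≈ (245, 245, 248); per-class s.d. 6/6/2 plus
global additive noise s.d. 8). Geometry: random eccentricity in [1, 2],
random rotation, nucleus axes solved iteratively so the realised
mask-area ratio lands within 0.5% of target (3% is the contract). Clutter
tiles realise the five QC artefact classes by construction. Exact truth
masks accompany every tile, so Dice, per-cell N/C error and QC confusion
are all measurable without annotation.

Cohort level, defaults = study conditions: 20 exposed / 10 non-exposed,
2 slides × 250 tiles per animal, urine (cotinine) available for 13
exposed and 8 non-exposed. True case N/C: non-exposed uniform on
[0.215, 0.236] (the tight low band observed in unexposed animals);
exposed scaled Beta(1.2, 4) on [0.24, 0.85] (right-skewed, most mass
below 0.5, occasional high-grade values toward 0.8). Cotinine: exposed
lognormal (median 50 ng/mL, σ = 1.2 — heavy-tailed so roughly 1–2 of 13
exceed 200 ng/mL), coupled to true N/C through a Gaussian copula with
correlation r = 2·sin(π·ρₛ/6) so the *population* Spearman correlation
equals `coupling_strength` (default 0.85) exactly; non-exposed cotinine
sits near a 1.5 ng/mL baseline. Inflammation scores and dysplasia grades
are assigned by thresholding true N/C (cutpoints 0.24/0.45/0.55 and
0.33/0.50/0.70), which makes stratum medians monotone by construction.
All randomness flows from one root seed through SeedSequence streams
keyed by (stage, cat, slide, tile), so any object regenerates
bit-for-bit in isolation.

What passing tests therefore show: the pipeline recovers known
compartment geometry and known cohort-level statistical structure under
MGG-like colour statistics. What they do not show: performance on real
smears — the generator has no stain batch variation, no focus blur, no
overlapping chromatin texture, no mucus/protein background, and its cells
are perfect ellipses. Real-slide Dice and error rates will be worse; the
synthetic figures are upper bounds on pipeline health, not estimates of
field performance.

## Problem sizes used in the checks

Segmentation recovery uses 100 clean tiles spanning N/C 0.2–0.85;
QC discrimination 40 tiles per artefact class (30 in the acceptance
script); case-median recovery four cases (two in the script) at the full
2 × 250-cell depth; coupling recovery 100 replicate cohorts at n = 13;
Fisher-z coverage 1500–2000 copula simulations at n = 30. These sizes give
binomial standard errors comfortably inside the asserted margins while
keeping a full run in the minutes range on one CPU.

## Known limitations

- The compartment-assignment rule assumes exactly k = 3 colour classes;
  other k require a custom mapping.
- Per-tile clustering (the default) can assign slightly different cluster
  boundaries across tiles of one slide; a per-slide shared-centres mode is
  a natural extension and is not implemented.
- The QC cannot distinguish a genuine epithelial cell from a large
  isolated leukocyte with visible cytoplasm; on real slides this would
  need a shape or texture feature.
- mrxs and other proprietary scanner formats are out of scope; inputs are
  PNG/TIFF rasters or pre-cut tile directories.
- Dysplasia grading itself is input data (ordinal 0–3); the package does
  not grade Papanicolaou-stained morphology.
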