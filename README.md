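# cytomorph

Whole-slide digital cytomorphometry for stained oral smears, with the
nonparametric statistics used in small exposure cohorts — built around the
question of whether household tobacco-smoke exposure leaves measurable
traces in the oral epithelium of indoor cats.

Oral exfoliative cytology is a minimally invasive way to look for early
epithelial change: a brush smear is stained (May–Grünwald–Giemsa for
morphometry), scanned as a whole-slide image, and the key dysplasia
indicator — the nucleus-to-cytoplasm area ratio of individual epithelial
cells,

```
N/C = A_nucleus / A_cytoplasm
```

— is measured automatically instead of by eye. `cytomorph` implements the
whole measurement chain and its statistical read-out:

1. **Tiling & tissue masking** — the slide is partitioned into 256×256
   tiles; a saturation-threshold (Otsu) mask excludes the near-white
   background.
2. **Tile quality control** — a programmatic rule set admits only tiles
   with exactly one intact nucleated epithelial cell, rejecting acellular
   fields, multi-cell/overlapping fields, debris, border-clipped cells and
   low-contrast tiles.
3. **Segmentation** — tiles are converted to CIELAB and clustered with
   K-means (k = 3); clusters map to nucleus / cytoplasm / background by
   lightness ranking; masks are refined morphologically and
   connected-component analysis isolates the primary cell.
4. **Morphometry** — per-cell N/C ratios; the case-level value for one
   animal is the median across all cells from its two slides
   (2 × 250 cells by default).
5. **Statistics** — median [IQR] summaries with two-sided Mann–Whitney U
   tests and Cliff's delta (bootstrap percentile CI), Fisher's exact test
   with odds ratios for sex, and Spearman rank correlations with
   approximate 95% CIs from Fisher's z-transformation
   (`tanh(atanh ρ ± 1.96/√(n−3))`).

Because raw slides from such studies are rarely deposited, the package
ships a **synthetic generator** (`cytomorph.synthetic`) that produces
MGG-like tiles with exact ground-truth masks and whole cohorts with
controlled statistical structure (group-conditional N/C distributions, a
Gaussian-copula cotinine–N/C coupling with adjustable rank correlation).
Every pipeline stage is therefore testable against known truth.

## Worked example

```python
from cytomorph import load_study_cohort
from cytomorph.reporting import group_comparison_table, sex_odds_ratios
from cytomorph.stats import fisher_z_ci

cohort = load_study_cohort()          # 30 cats: 20 exposed, 10 non-exposed
table = group_comparison_table(cohort, rng_seed=0).set_index("variable")
age = table.loc["age"]
print(f"age: exposed {age.median_exposed:.2f} [{age.iqr_exposed:.2f}] vs "
      f"non-exposed {age.median_non_exposed:.2f} [{age.iqr_non_exposed:.2f}], "
      f"Cliff's d = {age.cliffs_delta:+.2f} "
      f"({age.delta_ci_low:.2f}, {age.delta_ci_high:.2f}), p = {age.p_value:.3f}")
print("female OR =", round(sex_odds_ratios(cohort)["female"].odds_ratio, 3))
print("rho CI =", tuple(round(v, 2) for v in fisher_z_ci(0.85, 13)))
```

prints

```
age: exposed 1.50 [4.00] vs non-exposed 4.50 [2.50], Cliff's d = -0.25 (-0.61, 0.15), p = 0.244
female OR = 0.359
rho CI = (0.56, 0.95)
```

i.e. exposed cats tend to be younger but not significantly so (the delta CI
straddles zero), females are non-significantly under-represented among
exposed animals, and a rank correlation of 0.85 observed in 13 animals
carries a 95% interval of 0.56–0.95.

An end-to-end imaging run on synthetic slides:

```
cytomorph all --out run1 --seed 1 --n-exposed 4 --n-non-exposed 2 --tiles-per-wsi 50
```

writes the simulated cohort, per-tile QC and segmentation results, case
N/C estimates, and the statistics report under `run1/`.

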