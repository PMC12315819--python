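# coagg

Object-based counting of α-synuclein/amylin **co-aggregates** in
dual-channel surface-fluorescence assay images, with the surrounding
machinery needed to run and validate the assay end-to-end.

Protein aggregates captured on a well surface appear as diffraction-limited
bright particles when imaged in a red channel (α-synuclein) and a far-red
channel (amylin). A co-aggregate — an assembly containing both proteins,
of interest as a candidate blood biomarker linking Parkinson's disease and
type-2 diabetes — is counted when a red and a blue detection coincide
spatially. The package provides:

- **`coagg.synth`** — synthetic dual-channel fields with known ground truth
  (Gaussian PSF spots, Poisson/read noise), dilution series, participant
  cohorts, and SPR sensorgrams, so every stage is testable without data
  downloads.
- **`coagg.detection`** — histogram equalization, a contour
  (threshold + connected components) detector and a Hough circle detector,
  merged by distance non-maximum suppression.
- **`coagg.colocalization`** — maximum-cardinality one-to-one red/blue
  matching at a center-distance radius `d_max` and the chance-overlap
  correction `E[chance] = n_red·n_blue·π·d_max²/A` under complete spatial
  randomness, giving a corrected ("confirmed") co-aggregate count and the
  co-localization rate out of red spots.
- **`coagg.assay_qc`** — well-level aggregation to densities per mm²,
  dilution-linearity (log-log slope) checks, and batch pass/fail rules
  (poor standard curve; amylin bleed-through into an α-syn-only standard).
- **`coagg.cohort_stats`** — Student's t-test, one-way ANOVA + Tukey HSD,
  ROC AUC (Mann–Whitney with tie half-credit, stratified bootstrap CI),
  and Spearman rank correlation with exact small-n permutation p-values.
- **`coagg.kinetics`** — 1:1 Langmuir model: `KD = kd/ka` and global
  nonlinear least-squares fitting of (ka, kd, Rmax) to sensorgrams.

## Worked example

```python
from coagg import (SynthFieldParams, generate_field, detect_field,
                   match_spots, coloc_summary, kd_from_rates)

# a 512x512 field with 30 true co-aggregate pairs + 20 singletons/channel
params = SynthFieldParams(lambda_pair=30, lambda_red_only=20,
                          lambda_blue_only=20, seed=3)
field, truth = generate_field(params)
red, blue = detect_field(field)
match = match_spots(red, blue, d_max_px=3.0)
s = coloc_summary(match, len(red), len(blue),
                  area_px2=512 * 512, pixel_size_um=params.pixel_size_um)
print(f"red={s.n_red} blue={s.n_blue} coloc={s.n_coloc} "
      f"chance={s.expected_chance:.2f} corrected={s.corrected_count:.1f} "
      f"rate={s.coloc_rate:.2f}   true fraction={truth.coloc_fraction:.2f}")
print(f"KD = {kd_from_rates(5809, 2.136e-3):.4g} M")
```

prints

```
red=43 blue=34 coloc=20 chance=0.16 corrected=19.8 rate=0.47   true fraction=0.47
KD = 3.677e-07 M
```

43 red and 34 blue particles were detected; 20 red/blue pairs lie within
3 px of each other, of which 0.16 would be expected by chance alone if the
two channels were unrelated, leaving a corrected count of 19.8 — a
co-localization rate of 0.47 of the α-synuclein spots, matching the
generator's true fraction 0.47. The last line is the equilibrium
dissociation constant implied by association rate 5809 M⁻¹s⁻¹ and
dissociation rate 2.136×10⁻³ s⁻¹: 368 nM affinity between the two
proteins.

The same pipeline runs from the shell:

```sh
coagg simulate-field --out fields/ --n-fields 6 --seed 0
coagg assay-summary fields/ --out results/
coagg stats roc cohort.csv --score coagg_count
coagg kinetics kd --ka 5809 --kd 2.136e-3
```

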