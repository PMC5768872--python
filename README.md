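# melanomorph

Morphometric colour inference for fossil feathers.

Melanin-bearing organelles (melanosomes) fossilize as molds or
three-dimensional bodies, and their size and shape correlate with the colour
mechanism of the feather they came from: long narrow rods with black, short
wide ones with brown, tightly regular rods with grey, and flattened
platelet-shaped melanosomes — in living birds — always with iridescence.
`melanomorph` implements the full analysis chain that turns per-sample
length/diameter measurements of such nanostructures into colour inferences:

- **measurements** — validation of measurement tables (body-cavity exclusion,
  axis-swap repair, minimum counts) and the eight per-sample predictors:
  mean, CV and skew of length and diameter, plus mean and skew of the aspect
  ratio.
- **morphospace** — 2D Gaussian-kernel densities of (length, diameter) on a
  shared grid with a pooled-data Silverman bandwidth; the proportional
  overlap statistic ∩(A, B) = Σ min(a, b) over grid nodes of the
  proportion-normalized densities; centroid-distance dispersion comparisons;
  rarefaction of variance.
- **platelet** — the two-criterion platelet call: (i) sample falls outside
  the highest-density region of the non-platelet extant morphospace, and
  (ii) independent image evidence of stacked/flattened structures; ambiguous
  samples are split by a two-component Gaussian mixture on log axes.
- **classify** — backward stepwise variable selection under the partial
  Wilks' Λ F-test (α = 0.05), quadratic discriminant analysis
  δ_k(x) = −½ log|Σ_k| − ½ (x−μ_k)ᵀ Σ_k⁻¹ (x−μ_k) + log π_k,
  six training-set configurations, self-test and leave-one-out validation.
- **taphonomy** — shrinkage scenarios: an assumed fractional decrease d of
  both axes is corrected by ×1/(1−d); dimensionless features are invariant.
- **mantel** — Mantel permutation test relating morphological distance
  between sampling locations to their anatomical proximity on the slab.
- **simulate** — bivariate-lognormal colour-class models, an extant training
  library, and a fossil slab with a spatially correlated morphology field
  and designated platelet-bearing regions, so the whole chain is testable
  without external data.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
packaged synthetic generator (all outputs under `results/`):

```sh
python analysis/01_simulate_data.py
python analysis/03_platelet_id.py
python analysis/07_spatial_autocorrelation.py
```

prints

```
library: 105 samples across 7 colour classes
slab: 53 locations, 21 with platelet image evidence

verdicts: {'platelet': 21, 'non_platelet': 32, 'mixed': 0}
agreement with image-evidence flags: 53/53 locations

Mantel test: r = 0.150, p = 0.002 (999 permutations)
```

i.e. the two-criterion rule recovers every platelet-bearing location of this
slab, and nearby locations are significantly more similar in morphology than
distant ones (one-sided permutation test).  `analysis/04` and `05` then show
the fossil's measurement cloud overlapping the black class most strongly
(∩ = 0.61) and the QDA predicting black for the non-platelet regions, while
`analysis/06` re-runs everything under a 20% taphonomic-shrinkage
correction, which shifts the fossil's overlap toward the large platelet
class (0.47 → 0.53).

The same stages are available as a CLI (`melanomorph simulate | features |
platelet-id | overlap | classify | shrink | sensitivity | mantel | rarefy |
run`); `melanomorph run --out results/run` executes the whole pipeline from
one config with full provenance and byte-reproducible reports.

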