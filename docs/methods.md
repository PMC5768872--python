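# Methods

## The inference problem

Fossil feathers preserve melanosome-like nanostructures whose geometry in
the image plane — long-axis length and short-axis diameter, both in
nanometres — carries a colour signal.  The pipeline answers four questions
about a sampled fossil slab, using an extant training library of samples
with known colour classes:

1. where does the fossil sit in (length, diameter) morphospace relative to
   each extant colour class (proportional overlap)?
2. which sampling locations carry platelet-shaped structures (the
   iridescence-associated morphology)?
3. what colour class does a discriminant model predict for each location?
4. are the conclusions robust to taphonomic shrinkage, sampling effort and
   the spatial layout of the slab?

## Feature definitions

Per sample (a sampling location with ≥ 5 measurements by default): mean,
coefficient of variation (n−1 standard deviation over the mean) and
skewness of length and diameter, plus the mean and skewness of the
per-measurement aspect ratio (length/diameter).  Skewness is the
Fisher–Pearson standardized third moment without small-sample bias
correction; degenerate samples (all measurements identical) get CV = 0 and
skew = 0 with a warning.  The aspect ratio is aggregated as the mean of
per-measurement ratios rather than the ratio of means; the choice is
recorded in output metadata.  Dimensionless features (CVs, skews, aspect
ratio) are exactly invariant under a common rescaling of both axes, which
is what makes the shrinkage sensitivity analysis sharp.

Rows measured near internal organs or the body cavity are excluded before
any analysis (melanosomes from internal organs also fossilize and would
contaminate the plumage signal).  Rows with length < diameter are treated
as axis-assignment slips and swapped with a warning rather than discarded.

## Morphospace and overlap

Densities are Gaussian product-kernel estimates evaluated on a shared
regular grid (default 151 × 151, spanning the pooled range padded by three
bandwidths per side) and converted to proportions by dividing by their sum.
The bandwidth is per-axis Silverman normal-reference,
h = σ̂ (4/((d+2)n))^{1/(d+4)} with d = 2 and σ̂ = min(SD, IQR/1.349),
estimated once from the pooled data of every group *including the fossil*
and reused verbatim for each group, so that overlaps compare distributions
rather than bandwidth choices.  Proportional overlap is the sum over grid
nodes of the pointwise minimum of two proportion densities: 1 for identical
distributions, 0 for disjoint ones.  Densities with points outside the grid
are an error (silent kernel-mass truncation would bias every comparison).
A diagonal bandwidth is the default; a full bandwidth matrix is not
implemented because nothing downstream requires the cross term.

Dispersion between groups is compared by each observation's Euclidean
distance to its own group centroid in per-axis z-scored space (pooled SD,
so the nm-scale length axis does not dominate), followed by a one-way
F-test of distance on group.

Rarefaction of variance subsamples the pooled (length, diameter) cloud
without replacement at increasing sizes (trace of the covariance matrix as
the statistic, n−1 denominator), reporting the mean and 2.5/97.5% band over
replicates; at the full sample size the curve equals the full-sample value
exactly with zero spread.

## Platelet identification

A sample is called platelet-bearing when two independent criteria agree:
(i) its measurements fall outside the extant avian morphospace built from
non-platelet melanosomes, and (ii) electron-microscope images show stacked
mouldic or flattened 3D structures.  Criterion (ii) enters as a boolean
input flag: it is assessed by eye on micrographs and image analysis is out
of scope.  Criterion (i) is operationalized with the highest-density region
(HDR) of the reference KDE: the density threshold is the (1 − p) quantile
of the reference density at the reference points themselves (p = 0.95 by
default), a measurement is outside when its density falls below the
threshold, and the sample flag fires when more than half the measurements
are outside.  The majority rule and the 95% level are package choices — the
procedure's verbal definition fixes neither — and both are configurable and
recorded in outputs.

When the criteria disagree the sample is mixed: a seeded two-component
Gaussian mixture on (log length, log diameter) splits its measurements and
the component whose centroid sits in lower reference density is labelled
platelet.  A non-converged fit falls back to the per-measurement HDR flags
with a warning.  Platelet-flagged measurements are removed from the stream
feeding the colour classifier (platelet shape is an iridescence indicator,
not a colour-class feature).

## Colour classification

Variables are selected by backward stepwise elimination: after a
multicollinearity pre-pass that drops the weaker member (smaller univariate
between-class F) of any pair with |r| > 0.95, the variable with the largest
partial Wilks' Λ F-test p-value exceeding α = 0.05 is removed repeatedly
until all retained variables are significant.  The partial F for removing
one variable from a set of p variables over g classes and n samples is
F = ((n−g−p+1)/(g−1)) (Λ_without/Λ_with − 1) on (g−1, n−g−p+1) df.

The classifier is QDA: per-class Gaussian ML estimates on the retained
variables with a ridge of 1e-8·trace(Σ)/p on the diagonal, equal priors by
default (fossil class frequencies are unknowable; training-frequency priors
by flag).  Validation reports resubstitution (self-test) accuracy and
leave-one-out accuracy; the variable set is selected once on the full
training data and frozen during LOO — re-selecting per fold would be
cleaner against selection optimism but multiplies runtime by the fold
count, and the optimism direction is checked separately (self-test ≥ LOO on
average).  This is a recorded limitation.

Six training-set configurations cover the analysis variants: (1) base
classes black/brown/grey/rod-iridescent plus a single platelet-iridescence
class; (2) hummingbird platelets as their own class; (3) non-hummingbird
platelets merged into rod iridescence; (4) base scheme but classifying only
non-platelet fossil samples; (5) penguin brown-black as a distinct class,
non-platelet fossils only; (6) base scheme with the fossil corrected for
20% shrinkage.  In configurations 1–4 and 6 the penguin brown-black
samples fold into black (their colour), and in 1, 4–6 hummingbird platelets
fold into the common platelet class.

## Taphonomy

The shrinkage scenario assumes both axes decreased by a fraction d during
preservation (default d = 0.20) and corrects fossil measurements by
×1/(1−d) = ×1.25.  The correction is exactly inverse to simulated
shrinkage, rescales only the two mean-size features, and leaves every
dimensionless feature bit-identical.  The sensitivity stage re-runs
overlap and platelet identification under each scenario and itemizes the
sample-level calls that change.

## Spatial autocorrelation

Morphological distance between locations is Euclidean distance between
z-scored feature vectors; anatomical distance is Euclidean millimetre
distance on slab coordinates, or shortest-path hops on a body-region
adjacency graph when coordinates are unavailable.  The Mantel statistic is
the Pearson correlation of strictly-lower triangles; the null comes from
simultaneous row/column permutation of one matrix and the one-sided p-value
is (1 + #{r_perm ≥ r_obs})/(1 + n_perm), 999 permutations by default.  A
test at α = 0.001 therefore needs ≥ 999 permutations.

## Synthetic data: what it emulates and what it does not

Each colour class is a bivariate lognormal over (length, diameter) —
positive, right-skewed, with closed-form mean/CV/skew used as test oracles;
draws violating length ≥ diameter are rejected and redrawn, and a class
whose rejection rate exceeds 99% is refused as degenerate.  Library samples
carry a small lognormal between-sample effect (SD 0.05 on the log scale)
emulating species-level variation within a class.  The default class
parameters are illustrative morphologies in the right size range for avian
melanosomes (rod classes ~650–1100 nm long, platelet classes large and
wide, penguin class near-spherical); nothing in the tests depends on them
matching particular real species.

The fossil slab defaults emulate the study system: 53 sampling locations
on a 200 × 100 mm slab, 21 of them platelet-bearing and spatially
contiguous (nearest locations to a random anchor), ~40 measurements per
location.  Location-level morphology adds a Gaussian-process field
(squared-exponential kernel, correlation length 40 mm) on the log scale.
The field SD of 0.10 was fixed by a simulation sweep so that, at defaults,
the platelet procedure recovers the designated regions with per-replicate
sensitivity and specificity ≥ 0.9 while the Mantel test retains ≥ 0.9 power
when the correlation length is comparable to the slab extent.  Stacking
evidence equals the designated truth, with configurable false-positive/
false-negative rates (default 0).

What the generator does *not* emulate: measurement error from image
digitization, oblique sectioning angles (foreshortened lengths),
within-feather barb/barbule heterogeneity, preservation gradients across
the slab, or hollow-vs-solid interior structure.  Passing tests therefore
demonstrate that the statistical machinery recovers known structure under
the stated model, not that real fossil data satisfy that model.

## Numerical choices

- Proportion densities must sum to 1 within 1e-9; overlap is clipped to
  [0, 1] against floating accumulation.
- KDE evaluation is chunked to bound memory at ~2×10⁷ kernel evaluations
  per block.
- GP covariances get escalating diagonal jitter (from 1e-10·σ²) before a
  positive-definiteness error is raised.
- QDA covariances use the ML (1/n) estimator, making the fit invariant to
  duplicating every training row; Cholesky factorizations are cached.
- All stochastic stages derive their streams from a single integer seed via
  `numpy` `SeedSequence`; permutation tests, mixtures and subsampling are
  bit-reproducible given the seed.
- Reported problem sizes: unit and validation suites use libraries of 15
  samples/class × 30 measurements and slabs of 53 × 40; null calibrations
  use 500–1000 replicates with 199 permutations each — sizes at which every
  binomial check has its stated resolution.

## Known limitations

- The HDR level (0.95) and the >50% majority rule are conventions, not
  estimated quantities; conclusions near those boundaries should be
  examined with the sensitivity tooling.
- LOO does not re-run variable selection per fold (see above).
- The region-adjacency distance treats all adjacent regions as equidistant;
  anatomical distance in millimetres is preferred whenever coordinates
  exist.
- With zero stacking-evidence noise the image criterion is perfect by
  construction; the generator's noise rates exist precisely to stress that
  assumption, and the defaults leave them off.
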