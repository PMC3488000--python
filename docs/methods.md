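# Methods

This note records the models, parameter choices and numerical
conventions behind `lovscreen`, and what the synthetic-data tests do
and do not demonstrate.

## Library coverage statistics

A single-site saturation library is modelled as i.i.d. draws from the
variant distribution of the degenerate codon — uniform over the 32 NNK
codons at codon level, or the translated amino-acid distribution
(renormalised if stops are excluded) at amino-acid level. Codon level
is the default: the "32 possible mutations" arithmetic and the
oversampling factor (180/32 = 5.625, reported as ≈ 6-fold) are codon
level quantities, and stop codons are genuine library members there.

Two different "coverage" notions coexist in screening practice and both
are exposed:

- `coverage_probability(n)` is the *complete-coverage* (coupon
  collector) probability that every variant appears at least once among
  `n` clones. It is computed by inclusion–exclusion: for equal variant
  probabilities the sum collapses to `m + 1` binomial terms
  `Σₖ (−1)ᵏ C(m,k) (1 − k/m)ⁿ`, exact and cheap for any library size
  (this covers NNK); for unequal probabilities the full subset sum is
  evaluated up to 20 variants (2²⁰ terms), and beyond that a seeded
  Monte-Carlo estimate (default 10⁵ replicates, seed 20121024) is
  returned together with its binomial standard error. For the 32-codon
  NNK library, `required_clones(0.95)` = 203.
- `expected_coverage_fraction(n)` is the expected *fraction* of
  variants seen, `mean(1 − (1 − pᵢ)ⁿ)`, the quantity behind the common
  `n = −V ln(1 − F)` rule of thumb; 96 NNK clones reach 95% on this
  measure and 180 clones reach 99.7%. Screening-effort claims of "95%
  coverage" in the saturation-mutagenesis literature usually refer to
  this fraction, which is far less demanding than complete coverage —
  reporting both makes the distinction explicit.

`required_clones` finds the smallest qualifying `n` by doubling and
bisection on the monotone coverage curve; a zero-probability variant is
rejected (its coverage target is unreachable).

## Site selection

Residue–chromophore proximity is the minimum Euclidean distance over
all heavy-atom pairs (hydrogens and deuteriums excluded on both sides);
"distance to the chromophore" without a named atom is read as this
minimum. Coordinates stay in Ångström internally (PDB convention) and
distances are reported in nm. Multi-conformer atoms keep the first
altloc, only the first model of a multi-model file is read, and waters
are dropped. The default shells are 0.3 nm (primary cavity-lining
targets) and 0.4 nm (secondary contacts); the inner shell is a subset
of the outer by construction. Residues selected for other reasons
(e.g. interdomain contacts far from the cofactor) are outside the
scope of a distance criterion — the module annotates distances, it
does not make the final target list.

## Plate screening

Processing per (plate, tier): the background is the pointwise mean of
that plate's background wells (uninduced cells) and is subtracted from
every scan; negative residuals are kept (they are informative noise,
clipped to zero only where a fold denominator needs positivity).
Smoothing is Savitzky–Golay, order 3, window 5, mirror padding at the
edges; the filter is exact on cubic polynomials at interior points,
and edge handling is a convention, so the exactness test covers
interior points only. Peak metrics are the argmax/max of the smoothed
scan over the full 470–600 nm window (a fixed-wavelength readout would
miss shifted variants); ties break to the shorter wavelength.

The wild-type reference of a plate is the peak of the *averaged*
smoothed reference wells, not the average of per-well peaks: the max
of a noisy curve is upward-biased, and taking the peak after averaging
keeps that bias out of the fold denominator.

Classification: beneficial when fold ≥ 2.0 or |peak shift| ≥ 10 nm;
deleterious when fold ≤ 0.5; neutral otherwise. Two conventions are
worth stating. First, the deleterious threshold (emission "greatly
diminished") is set to 0.5 — the log-scale mirror of the twofold
beneficial criterion — and is configurable. Second, the shift
criterion applies only to clones that emit above the deleterious
threshold: the peak position of a collapsed spectrum is the argmax of
noise and carries no information, and treating such clones as
"shifted hits" would misclassify a sizeable fraction of genuinely
deleterious clones at realistic noise levels. Neutral is the residual
band — "indistinguishable from wild type" is a band, not an equality
test. A clone is confirmed beneficial only when beneficial in every
tier it was assayed in; a plate-tier deleterious call is final.

One caveat on threshold-boundary clones: a clone whose *true* fold is
exactly 2.0 sits on the decision boundary, so with any measurement
noise its measured fold falls on either side with roughly even odds —
no estimator can recall such clones perfectly. Recall is exact at the
boundary in the noiseless limit (the criterion is inclusive) and is
complete for true folds comfortably above the boundary (≥ 2.2 at 5%
noise in the recovery tests).

## Photophysics

The quantum yield is relative to the FMN standard (QY 0.27): per-sample
`F/A` values (trapezoidal 470–600 nm emission integral over the 450 nm
absorbance) are averaged within the sample and standard concentration
series, and the estimate is the ratio of the two means scaled by the
standard's quantum yield. Aggregating by mean-of-ratios keeps the
identity `QY(standard, standard) = QY_standard` exact; a
slope-through-origin regression would weight high-concentration points
more but break that identity, so it was not made the default. The
quoted uncertainty is first-order propagation of the two series'
standard errors of the mean; "±" values are standard deviations
throughout. No refractive-index correction is applied — sample and
standard share the same aqueous buffer, so the index ratio is 1.

The holoprotein concentration is `A₄₅₀ / (ε l)` with ε = 12 500
M⁻¹cm⁻¹ (FMN); the apoprotein does not absorb at 450 nm and free FMN
in a purified preparation is assumed negligible, so no free-dye
correction is applied. The fraction `C_holo / C_total` may exceed 1
slightly through measurement error: values up to 1.05 are clamped to 1
with a warning, larger values raise an error (the two concentration
measurements are then mutually inconsistent). Fold enhancements use
the delta method under independence,
`sd = (a/b)·sqrt((sd_a/a)² + (sd_b/b)²)`, with two-significant-figure
rounding applied only at the reporting layer.

## SEC oligomeric state

The calibration is ordinary least squares of log₁₀(mass/kDa) on
elution volume; at least three standards with distinct volumes are
required and the fitted slope must be negative (larger proteins elute
earlier) or the fit is rejected as unphysical. Predictions outside the
standards' volume range are flagged as extrapolations. The oligomeric
state is net mass over the monomer mass (default 16.3 kDa) and the
label is the nearest integer with half-intervals (1.5 ≤ v < 2.5 →
dimer); values below 0.5 still label "monomer" since fractional states
below one are measurement artefacts, not physical species. Whether a
column is calibrated on raw volume or on Kav is column-specific;
log-mass-vs-volume is used here, and a Kav-normalised workflow can be
layered on by transforming the volumes before fitting.

## Synthetic-data generator

The generator emulates the *statistics* of a saturation screen, not
its mutational mechanism: codons are uniform draws from the scheme's
expansion, and the phenotype class and brightness fold are sampled
independently of the codon (a stop-codon clone may be labelled
neutral). This is deliberate — the recovery tests need controlled
class proportions and fold distributions, not a structure–function
model. Defaults mirror a chromophore-sensitive library: proportions
beneficial 0.01 / deleterious 0.40 / neutral 0.59; fold supports
uniform on [2.0, 3.0], [0.05, 0.4] and [0.8, 1.2] respectively, chosen
so every class respects the default thresholds.

Spectra are an asymmetric Gaussian band (blue-side σ 14 nm, red-side
σ 22.4 nm — a broad red tail) centred at 495 nm on the 470–600 nm /
1 nm grid, scaled by fold × a wild-type peak amplitude of 100 a.u.,
plus a flat autofluorescence background (5 a.u.) and additive Gaussian
noise with σ = 3% of the wild-type peak. Only the peak position,
intensity and width drive the analysis, so no vibronic structure is
modelled. Plates follow a 96-well layout with 2 background and 4
wild-type reference wells; a 180-clone library spans two plates.
Photophysics readings carry multiplicative Gaussian noise (1%
relative), chosen so recovery bounds are analytic; SEC elution volumes
carry additive Gaussian noise (σ 0.05 mL) around the calibration
inverse of the target mass. The default SEC calibration places the
four classic standards (670, 158, 44, 17 kDa) exactly on
log₁₀(m) = 4.742 − 0.2128·V, spanning 9–16.5 mL — a realistic
preparative gel-filtration window; real use supplies measured volumes
via CSV.

All randomness flows from one seed through named substreams
(`SeedSequence` spawn keys per stage), so stages regenerate
independently and full datasets are byte-reproducible.

What passing recovery tests show — and what they do not: the pipeline
correctly inverts its own generative model at realistic noise levels
(≈ 99.9% class recovery over 100 seeded 180-clone libraries; QY and
f_holo recovered within ±0.01; SEC state within ±0.05 on average).
Real plate data additionally contain growth-level variation between
wells, autofluorescence with spectral shape, pipetting and edge
effects, and occasional failed wells, none of which are modelled; the
tests validate the analysis logic, not robustness to those artefacts.

## Problem sizes

Recovery experiments use 100 seeded replicates of 180-clone libraries
(screening), 5-point concentration series (photophysics), and
4-standard SEC runs — sizes matching the emulated study design; the
Monte-Carlo coverage checks use 10⁵ replicates, which puts their
standard error near 10⁻³ on a probability scale.
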