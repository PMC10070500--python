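# Methods

This note documents the models, algorithms, default parameters and design
choices of `ramanstains`, and states precisely what the synthetic test bed
does and does not emulate.

## Spectral model and the quantity being estimated

A measured spectrum is modelled as S_org(k) = S_blank(k) + C·S_ref(k),
with k the Raman shift in cm⁻¹. All decompositions operate on
area-normalized spectra (unit trapezoidal integral over the axis), and C
is therefore a *relative spectral weight*: the fraction of the normalized
target reference contained in the normalized mixture. The synthetic
dataset generator composes stains as the convex combination
(1−C)·substrate + C·target so that this definition survives the
re-normalization inside the preprocessing chain; negativity of *estimates*
is allowed throughout, because the absence test needs the null
distribution of restored weights to straddle zero.

## RSC estimator

δf(C̃) = ∫ |d(S_org − C̃·S_ref)/dk| dk is evaluated with central first
differences (one-sided at the axis ends) and trapezoidal integration. The
derivative operator is deliberately independent of the Savitzky–Golay
smoothing stage, so the estimator's definition does not change when the
preprocessing configuration does. δf is convex in C̃ — a weighted sum of
absolute affine functions — which justifies the optimizer: a coarse grid
(step 0.01) over the search interval, then golden-section refinement of
the bracketing cell to |ΔC̃| < 1e−5. The default search interval
[−0.5, 2.0] admits negative estimates and over-subtraction headroom. On a
flat valley (possible when the reference derivative is orthogonal to the
residual's) the candidate with smallest |C̃| is preferred: the toolkit
favours "absent" over an arbitrary nonzero claim. A minimum at a search
boundary sets a warning flag rather than failing.

## MCRAD

The virtual standard-addition series Ŝ_j = S_org + ĉ_j·S_ref (default
levels 0, 0.5, 1.0, 1.5, 2.0, never renormalized inside the series) is
factorized by a two-component non-negative alternating least squares:

- component 1 is initialized to the clipped reference and re-blended
  toward it at weight 0.5 each cycle (a soft anchor: a hard constraint
  would make the additions trivially identifiable and hide the method's
  real fragility; full freedom de-anchors the target);
- component 2 starts from the non-negative residual of the sample after
  projecting out the reference;
- each half-step is an exact two-variable non-negative least squares,
  solved in closed form by enumerating the four KKT active sets with a
  shared 2×2 Gram matrix (vectorized over rows/wavelengths);
- if the re-blend would raise the reconstruction residual in some cycle,
  that cycle is redone as a pure ALS step, so the recorded residual
  history is non-increasing; convergence at relative residual change
  < 1e−8 (or an absolute floor of 1e−13·‖W‖ for exactly factorizable
  data), at most 500 cycles, non-convergence flagged but not fatal.

The target's concentration scores are regressed on the added levels and
extrapolated: c_hat = intercept/slope. Three reliability flags accompany
every estimate: slope ≤ 0, R² < 0.9, and a *blank-drift* diagnostic — the
blank component's score must stay constant across virtual additions
(nothing but target is added), so a relative drift above 5% over the
series means the factorization leaked the target into the blank
(rotational ambiguity) and the extrapolation is untrustworthy. This last
flag is what actually fires in the method's characteristic false-negative
mode, where a rotationally ambiguous solution produces a confident
straight line through zero.

## Preprocessing

Three steps in fixed order, windows configured in cm⁻¹ and converted to
point counts per axis (so files from any instrument work; 182.2 cm⁻¹ ↔
200 points and 41 cm⁻¹ ↔ 45 points on a 0.911 cm⁻¹ axis):

1. **Baseline subtraction** (default window 182.2 cm⁻¹, quantile 10%):
   within each non-overlapping window the data point closest to the
   intensity quantile becomes an anchor; a monotonicity-preserving cubic
   (PCHIP) through the anchors, extended by its end polynomials beyond the
   outermost anchors, is subtracted. Anchoring on actual samples makes the
   construction exact on flat and linear inputs. A trailing window shorter
   than half the nominal width is dropped.
2. **Savitzky–Golay smoothing** (default 41 cm⁻¹, polynomial order 1, odd
   point count enforced): edge points use the polynomial fit on the
   truncated one-sided window — no reflection padding, which would
   fabricate symmetric intensity at the axis limits.
3. **Area normalization** (optional, on by default).

Outlier screening is opt-in: spectra are projected onto the leading
principal components carrying ≥ 95% of the set variance (at most 10) and
scored by a seeded isolation forest; the stated fraction with the worst
scores is removed. The projection exists because a localized spurious peak
occupies a handful of the ~1400 wavelength channels and axis-aligned
random splits on the raw vectors would dilute it.

The SG tuner scores each (window, order) cell by
r = (1/2N)·Σ_j (1/K_j)·Σ_k |S_SG,j − S̄|/|S_SG,j + S̄|, with S̄ the raw
set mean (the replicate average is the best available proxy for the
noiseless spectrum) and K_j the count of points whose denominator exceeds
1e−9 of the set maximum. r is invariant to a global rescaling of the set.

## Similarity diagnostics

The Soergel distance S = Σ|xᵢ−zᵢ|/Σ max(xᵢ,zᵢ) operates on non-negative
vectors; values below zero (possible after baseline subtraction) are
clipped. The block-averaged profile S_l replaces both spectra by averages
over sequential non-overlapping intervals of l points. Block values are
*integral means* (trapezoidal integral over the block / block width): for
two-point blocks this equals the arithmetic mean, and at l = N both
area-normalized spectra collapse to the identical value 1/range, making
the l → N limit of S_l exactly zero — the property that anchors the
profile's interpretation. The proximity factor
r = ½·Σ |S_R,i − S_0,i|/|S_R,i + S_0,i| (denominator guard at 1e−9 of the
pair maximum) is reported both raw and per contributing point; library
classification uses the raw argmin, which the constant does not affect.

## Decision layer

Z = (0 − μ)/σ over the pairwise restored weights, with the two-sided
normal mapping P = 2·(1 − Φ(|Z|)); worked values: Z = 0.03 → P = 0.976,
Z = 0.54 → P = 0.59, Z = 2.7 → P = 0.007, Z = 1.96 → P = 0.05. Absence is
rejected when |Z| exceeds the two-sided critical value at the chosen level
(1.96 at 95%). The reverse-RSC residual extraction estimates the
*substrate* weight inside a stain spectrum (substrate as reference),
subtracts it, and area-normalizes the clipped residual for shape-based
library classification; an exactly vanishing residual yields no normalized
copy. The PCA screen reports the mean silhouette of the stain/pure labels
on the first two principal-component scores; the "separated" flag uses a
documented convention of 0.25 — a number is needed where visual inspection
was used before.

## Synthetic data: what it emulates, and what it does not

Built-in references use published band positions (blood: amide I at
1658 cm⁻¹, phenylalanine 1003, tyrosine doublet 826/856, pyrrole 754,
carbohydrate 960/1032/1127/1208, lipoprotein 1449/~1340, 623/644; denim:
indigo 1573 plus cellulose bands and a broad 1030–1150 envelope; PET bands
for blue polyester; nylon bands for white polyester; cellulose for
cotton). Since only qualitative prominence is published, relative
amplitudes follow a fixed ladder (1.0, 0.8, 0.65, then ×0.85 per rank,
floor 0.2) in the listed order; bands default to Lorentzians of 12 cm⁻¹
FWHM on a 400–1800 cm⁻¹ axis at 1 cm⁻¹ (1401 points). The semen-like
class is a synthetic stand-in from commonly reported dried-semen bands,
present to exercise residual classification only. A `disjoint_control`
substrate, whose bands all sit > 40 cm⁻¹ from any blood band, serves as
the clean null for absence studies.

Replicates emulate mapped measurements with four seeded variability
sources chosen to be realistic for spot-to-spot heterogeneity: log-normal
band-amplitude jitter (SD 0.05), Gaussian band-position jitter (1 cm⁻¹),
log-normal band-width jitter (SD 0.10), and a random non-negative
quadratic fluorescence background (coefficient SD 0.01 ≈ 15× the mean
intensity of a normalized spectrum — fluorescence typically dwarfs the
Raman signal). Without replicate-level variability the restored-weight
distributions collapse to σ ~ 1e−4 and the Z statistic divides tiny
preprocessing artifacts by it, which represents no real measurement.
Additive noise follows the uniform model: ν·(mean reference intensity)·u,
u ~ U[−0.5, 0.5] i.i.d., seeded.

Not emulated: absolute intensities and instrument response, cosmic-ray
spikes (removed by acquisition software in practice), detector
nonlinearity, wavenumber miscalibration beyond the 1 cm⁻¹ jitter, and the
full biochemical diversity of real blood. Passing tests therefore show
that the algorithms behave as specified on spectra with realistic
structure and variability — not that any particular real substrate/stain
combination will reproduce the same numbers.

## Study problem sizes

The test suite and the acceptance script run at desk scale, chosen as the
smallest sizes at which the studied effects are unambiguous: noise
robustness uses 100 replicate pairs per noise amplitude on the 11-point
grid ν ∈ {0, 0.005, …, 0.05} (all ordered pair combinations in the
acceptance script; matched pairs in the quicker test-suite variant); the
RSC/MCRAD comparison uses 10 paired realizations at ν = 0.05; pipeline
parameter-recovery and absence studies use 6 spectra per group over 10
seeds; the SG tuning study uses 40 replicates of a broad-banded
(50 cm⁻¹ FWHM) base at ν = 1.0 — band envelopes and noise of the order
seen in real mapped stain spectra (mean SNR ≈ 11 dB), where the tuning
trade-off between noise removal and band distortion is actually present;
with 12 cm⁻¹ synthetic bands the criterion would simply prefer the
narrowest window.

## Known limitations

- The preprocessing chain is not strictly proportional: the quantile
  baseline rides peak flanks and the SG window widens narrow bands, so
  even noiseless band-structured input is reproduced with correlation
  ~0.95–0.997, and area-shrinkage differences between broad- and
  narrow-banded spectra bias pipeline weight estimates by a few
  hundredths. This is a property of the (standard) chain itself.
- MCRAD's ALS variant is one concrete choice among the family of
  published implementations; its quantitative error magnitudes are
  specific to the soft-anchor weight (0.5), though its qualitative
  fragility relative to RSC is not.
- The Soergel l → N identity holds exactly only with integral-mean block
  averaging of area-normalized spectra, which is how it is implemented.
- JCAMP-DX support covers the two common plain-text data forms only
  (`XYDATA=(X++(Y..Y))`, `XYPOINTS`); compressed (DIFDUP) encodings and
  vendor binary formats are out of scope.
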