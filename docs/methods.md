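# Methods

## Pipeline

The analysis chain is: raw spectra → calibration → band ratios →
cross-validated linear discriminant analysis (LDA).

**Reflectance calibration.** A DRS acquisition is calibrated element-wise
against a white reference and dark background recorded on the same
spectrometer, `R = (S − B) / (Ref − B)`.  All three spectra must share an
identical wavelength grid; no resampling or interpolation is ever
performed, because a grid mismatch between spectra from one instrument
indicates an acquisition fault that silent interpolation would hide.  A
denominator magnitude below a configurable floor (default 1e-9 counts)
is an error naming the wavelength.  Calibrated values outside [0, 1]
(possible through noise, or reflectance genuinely above the standard) are
logged and preserved, never clamped: the band features are linear in the
spectrum and clamping would bias them.

**AF preprocessing.** AF spectra only have their dark background
subtracted; negative residuals are preserved for the same reason.
Mean-normalization (dividing a spectrum by its mean over the full
recorded range) is provided for visual comparison; every band ratio is
mathematically invariant to it, so the feature path operates on
un-normalized calibrated spectra and the choice is immaterial.

**Band features.** A band mean is the arithmetic mean of the samples
whose wavelength lies in the closed interval [lo, hi]; endpoints are
inclusive and a sample is either in or out (no edge interpolation) —
with ~1 nm sampling and bands 10–100 nm wide, sub-sample edge handling
changes ratios at the 1e-3 level while adding ambiguity.  The mean (not
a trapezoidal integral) is used because numerator and denominator share
the grid, so on a uniform grid the two conventions give identical
ratios.  The six default bands live in a named registry
(`drs_vis` 475–575, `drs_nir_norm` 800–900, `drs_lipid_edge` 1100–1120,
`af_bile` 495–505, `af_norm` 550–650, `af_porphyrin` 670–680 nm) and can
be overridden from a YAML/JSON file for other organs without code
changes.  Only the 415 nm AF excitation yields features; 385/450 nm
channels (metabolic fluorophores) are carried through I/O but ignored by
the classifier.

**Classifier.** Two-class LDA: class means, pooled covariance with the
unbiased n−K denominator plus a ridge λ·I, priors from training-fold
class frequencies.  The default λ = 1e-8·trace(Σ)/d guards against
near-collinear ratios without materially moving the boundary; λ=0 is
allowed and turns a singular covariance into an explicit error.  The
discriminant score is δ_k(x) = xᵀΣ⁻¹μ_k − ½μ_kᵀΣ⁻¹μ_k + ln π_k; an exact
tie predicts healthy, the conservative choice for a diagnostic positive
call.  Cross-validation is stratified (per-class shuffled round-robin
assignment, fold class counts differing by at most one), since with ~24
and ~28 samples per class, unstratified fivefold splits risk folds
dominated by one class.  Reported sensitivity/specificity come from the
confusion matrix pooled over all held-out predictions rather than
averaged per fold: with ~10 held-out samples per fold, per-fold rates
are too coarse.  Fold assignment is a pure function of (label order, k,
seed) and is recorded in the report for exact reproducibility.

## Synthetic data generator

The generator emulates the measurement session the pipeline is designed
for: sliced ex-vivo liver segments probed at 24 healthy and 28 tumor
locations (the default study size), each location yielding one DRS
calibration triple (500–1120 nm, 1 nm step) and one 415 nm AF
signal/dark pair (360–830 nm, 1 nm step).

**DRS model.**
`signal = dark + g · L(λ) · a(λ/800)^(−b) · exp(−c_hb·A_hb − c_lc·A_lc) + shot noise`,
where L is a smooth halogen-like lamp shape, g ~ U[0.6, 1.4] a
per-acquisition contact-pressure gain, and a, b the scattering power-law
amplitude and exponent.  A_hb is a qualitative hemoglobin shape
(Soret-like 420 nm band, Q-band-like 542/576 nm peaks, broad visible
pedestal below 600 nm); A_lc a sigmoidal lipid/collagen absorption edge
rising near 1050 nm.  These are parametric stand-ins, not literature
extinction data: the features only consume qualitative band structure.
Healthy tissue draws larger blood fraction (median 1.2 vs 0.4) and
larger lipid/collagen strength (median 1.0 vs 0.3) than tumor, giving
tumor the higher visible reflectance and higher 1100–1120 nm shoulder
seen in such measurements.  With probability 0.08 a tumor measurement
draws a healthy-level blood fraction, modelling surface blood on the
pale tumor slice — the outlier mode that degrades single-modality
classification.

**AF model.**
`signal = dark + g · [bile + porphyrin + red baseline] · exp(−0.5·c_hb·A_hb) · LPF(λ≥458) + shot noise`,
with unit-peak emission templates: a broad bile-like Gaussian at 500 nm
(the in-tissue position of the ~510 nm cuvette peak; the shift is a
configurable parameter because the tissue micro-environment moves
emission bands), a porphyrin double peak at 650/710 nm, a broad red
baseline at 620 nm, and an optional tiny bilirubin band at 560 nm
(default amplitude 0, reflecting its order-of-magnitude weaker
emission).  Tumor draws a stronger bile amplitude (median 2000 vs 600
counts) and weaker porphyrin/red amplitudes; hemoglobin reabsorption
imprints dips in the 540–580 nm region.  The hard long-pass edge zeroes
all emission below 458 nm.

**Noise.** Shot noise is Gaussian with variance proportional to the
count level (large-count Poisson approximation for CMOS spectrometers);
dark spectra get additive Gaussian noise (σ = 2 counts on a 100-count
offset).  The contact-pressure model is a single multiplicative gain per
acquisition — the simplest model the ratio features must, and provably
do, cancel.

**Parameter spread.** Within-class lognormal sigmas (0.45–0.5 for
chromophores, 0.6 for fluorophore amplitudes) were chosen so the
single-modality classifiers make errors at realistic rates (roughly
5–15% at the study size) while the combined model stays above 90%
sensitivity and specificity — the moderately-overlapping regime such
ex-vivo studies report — rather than a trivially separable toy.  The
noiseless class archetypes reproduce the qualitative ordering
ratio1–ratio3 tumor > healthy and ratio4 healthy > tumor exactly, which
the tests verify analytically (the signal construction inverts under
calibration when noise is off).

**What the generator does not model.** No radiative transport or photon
Monte Carlo; no source–detector-separation physics beyond the fixed
effective path absorbed into the templates; no patient-level correlation
between measurements (each location is an independent draw, although
patient ids are assigned for bookkeeping); no wavelength-calibration
drift, stray light, or detector nonlinearity; class-conditional
parameters are spec'd qualitatively, so no numeric agreement with any
particular measured dataset is claimed.  Passing tests therefore
demonstrate the correctness and statistical calibration of the pipeline,
not clinical performance on real tissue.

## Numerical and design choices

- Spectra are serialized at %.17g so write→read round-trips float64
  exactly (`float_precision="round_trip"` on read); datasets regenerate
  byte-identically from (config, seed).
- Duplicate wavelengths in a CSV are an error naming the wavelength, not
  averaged: instrument exports should never contain them.
- A `measurement_id` names a probe location and is shared by the DRS and
  AF records acquired there; (measurement_id, modality, excitation) must
  be unique.  Manifest paths are relative to the manifest file.
- The DRS grid extends to 1120 nm so the 1100–1120 nm band is always
  covered; visible-NIR CMOS spectrometers that end at 1100 nm leave that
  band partially or wholly uncovered, which the band-coverage check then
  reports explicitly.
- Rows missing a modality (e.g. a failed AF acquisition) keep their
  available ratios, are dropped from models that need the missing
  columns, and the drop count is recorded in the CV report.
- Cross-validation at the 52-sample study size is measurement-level;
  leave-one-patient-out grouping is a possible extension, not
  implemented.
- Seeds default to 0 (never wall-clock); every CLI command logs its seed
  and rerunning any command with identical inputs and seed reproduces
  outputs byte-identically.

## Problem sizes used in the checks

The bundled acceptance checks run the study-sized dataset (24+28) and an
n=400 (200 per class) dataset for effect recovery; the null-calibration
check uses 50 seeds × 200 balanced samples of class-independent
features, whose pooled cross-validated accuracy must sit inside the
3σ binomial band around 0.5.  The oracle checks compare band means
against brute-force closed-interval means (200 random spectra/bands) and
LDA predictions against an independent Gaussian-density reference on 50
small datasets, with a scikit-learn cross-check on balanced data where
its covariance convention coincides with ours up to a scale that cancels
in the argmax.
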