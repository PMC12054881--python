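# optibiopsy

Optical-biopsy tissue classification from diffuse reflectance (DRS) and
autofluorescence (AF) spectra.

During a percutaneous liver biopsy, a fiber-optic needle probe can record
two kinds of spectra at the needle tip: broadband diffuse reflectance,
shaped by tissue absorption (hemoglobin, lipid, collagen) and scattering,
and autofluorescence of endogenous fluorophores (bile, bilirubin,
porphyrin derivatives) under narrowband excitation.  Colorectal liver
metastases are pale and bile-rich while healthy liver is blood-rich and
porphyrin-dominated, so both modalities carry diagnostic contrast.  This
package implements the full analysis chain that turns raw spectrometer
counts into a cross-validated tumor/healthy classification, plus a
synthetic spectra generator that emulates such an ex-vivo measurement
session, so the entire pipeline is testable without patient data.

## Method

**Calibration.** Each DRS acquisition comes with a Spectralon white
reference and a dark background from the same spectrometer:

    R(λ) = (Signal(λ) − Background(λ)) / (Reference(λ) − Background(λ))

AF spectra (415 nm excitation, collected behind a 458 nm long-pass
filter) have only their dark background subtracted.

**Features.** Each measurement is reduced to four dimensionless band
ratios (R̄/Ī denote the mean over a closed wavelength band):

| feature | definition | contrast captured |
|---|---|---|
| ratio1 | R̄[475–575] / R̄[800–900] | visible reflectance vs hemoglobin absorption |
| ratio2 | R̄[1100–1120] / R̄[800–900] | lipid/collagen absorption edge |
| ratio3 | Ī[495–505] / Ī[550–650] | bile emission peak |
| ratio4 | Ī[670–680] / Ī[550–650] | porphyrin red emission |

Ratios cancel the per-measurement multiplicative gain caused by variable
probe contact pressure, and reduce each spectrum to two numbers to avoid
overfitting small datasets.

**Classification.** Two-class linear discriminant analysis (shared
pooled covariance, frequency priors, small ridge) with stratified
fivefold cross-validation, evaluated separately on the DRS features, the
AF features, and all four combined.  Performance is reported as
sensitivity (tumor = positive class) and specificity of the confusion
matrix pooled over held-out folds.

## Worked example

```
$ optibiopsy simulate --out liver_sim --seed 42          # 24 healthy + 28 tumor
INFO optibiopsy: wrote 104 records for 52 measurements
$ optibiopsy featurize liver_sim/manifest.json --out features.csv
INFO optibiopsy: featurize: 52 measurements -> features.csv
$ optibiopsy classify features.csv --model-config all --seed 42 --out metrics.json
INFO optibiopsy: classify drs: sensitivity=0.929 specificity=0.958 (seed=42, k=5)
INFO optibiopsy: classify af: sensitivity=0.857 specificity=0.875 (seed=42, k=5)
INFO optibiopsy: classify combined: sensitivity=0.929 specificity=1.000 (seed=42, k=5)
```

The simulated study writes 52 measurement locations (one DRS calibration
triple and one 415 nm AF pair each) as plain CSV spectra plus a JSON
manifest.  `features.csv` holds one row per location:

```
measurement_id,patient_id,tissue_label,ratio1,ratio2,ratio3,ratio4
h001,p01,healthy,0.30755520398546959,0.49545419181302908,1.5417511889663027,1.0456925034952702
```

Healthy tissue shows low visible reflectance (ratio1 ≈ 0.31, hemoglobin
absorption) and a suppressed NIR shoulder (ratio2 ≈ 0.50, lipid/collagen),
with near-unity AF ratios; tumor rows show the opposite pattern.  In
`metrics.json` the DRS-only model misclassifies 3 of 52 held-out
measurements (sensitivity 0.929, specificity 0.958), the AF-only model 7,
and the combined model 2 (sensitivity 0.929, specificity 1.000) — fusing
the two modalities removes the false positives that either alone commits.

The same pipeline is available as a library:

```python
from optibiopsy import GeneratorConfig, generate_feature_frame, cross_validate

table = generate_feature_frame(GeneratorConfig(seed=42))
report = cross_validate(table, "combined", k=5, seed=42)
print(report.sensitivity, report.specificity)
```

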