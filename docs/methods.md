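# Methods

This note records the models, defaults and design choices behind
`fumamap`, and what the synthetic phantoms do and do not establish
about real data.

## Spectral model and units

All processing operates on detector counts over a strictly increasing
wavenumber axis; the default axis spans the fingerprint region,
400–1800 cm⁻¹ sampled at 1 cm⁻¹ (the 532 nm instrument resolution is
~3.6 cm⁻¹, so this oversamples it, matching typical CCD binning).
Integrated band intensities are always divided by the dwell time and
reported in counts·cm⁻¹·s⁻¹, so calibrations transfer between
acquisitions with different integration times.

Bands are Gaussian. The quantitative fumarate band (1401 cm⁻¹ in
solution, σ = 4 cm⁻¹; 1373 cm⁻¹ for the ¹³C₄ isotopologue) is
*calibrated against the integrator*: its rendered area is scaled so
that the flat-baseline trapezoid integral over 1399–1419 cm⁻¹ (baseline
window 1324–1379 cm⁻¹) equals sensitivity × concentration × dwell, with
sensitivity defaulting to 19.2 counts·cm⁻¹·s⁻¹·mM⁻¹. The Gaussian tail
outside the window is absorbed into that scaling, making
generator/integrator round trips exact by construction. The 1277 and
1652 cm⁻¹ companions default to 0.9× and 1.4× the 1401-band area; these
ratios are cosmetic (only the 1401 band is quantitative) and are not
binding.

Noise is additive Gaussian with σ = 7.5 counts at the 0.3 s reference
dwell, scaled as √(dwell/0.3 s) while signal scales linearly with
dwell, so signal-to-noise improves as √dwell. The baseline-subtraction
tolerance of 15 counts equals twice this floor. Cosmic rays are
per-spectrum Bernoulli events (rate 0.01) spiking one channel by
20–100× the local level.

## Preprocessing

**Despiking.** Cosmic rays are flagged by a modified z-score of the
residual against a 5-point running median; a channel is a spike when
the residual exceeds both 8 robust sigmas and an absolute floor of 30
counts (the absolute floor keeps smooth noiseless spectra, where the
MAD collapses, from being flagged). Flagged channels are replaced by
the mean of their nearest clean neighbours; the filter is idempotent.
Despiking is applied to all spectra before any other analysis.

**Iterative polynomial baseline.** A modified-polyfit scheme: fit a
degree-`order` polynomial to a working copy, clip the copy to
min(copy, fit + tolerance), repeat for `iterations` rounds; the final
fit is the baseline. Defaults order 4, 7 iterations, tolerance 15
counts for per-pixel quantification; order 10, 10 iterations for
display averages. The fit is solved by least squares on a [-1, 1]
rescaled axis and vectorised across all pixels of a map.

**Band integral.** Channels belong to a window when lo ≤ ν ≤ hi on the
native grid (no resampling); integration is trapezoidal over member
channels after subtracting the mean count level of the flat-baseline
window. The integral is linear in the spectrum and exactly invariant
to additive constants.

**Known bias.** Two residual systematics partially cancel in the AUC
route: the CH₂-deformation shoulder (1445 cm⁻¹) leaks ≈ 0.2 % of its
area into the 1399–1419 cm⁻¹ window (a few mM-equivalent for
lipid-rich pixels), while the order-4 polynomial drapes across the
1324–1419 cm⁻¹ valley between the lipid bands, biasing every pixel by
roughly −2.5 mM. The net bias is small relative to the mitochondrial
and cytoplasmic concentrations of FH-deficient cells (−7 % at 37 mM)
but large relative to the 2–9 mM entries of the low-concentration
compartments; it also largely cancels when a control table is
subtracted. This is why end-to-end recovery is asserted for the
high-concentration compartments and for the ordering, not per-mM for
the dimmest ones.

**Normalisation and centering.** Fingerprint-AUC normalisation scales
a spectrum to unit area over 500–1800 cm⁻¹. Scan mean-centering (used
before clustering) divides each pixel channel-wise by the scan-average
spectrum and multiplies by the scalar standard deviation of the
pixel's own counts. The antecedent of "its standard deviation" is
ambiguous in the source protocol; the default uses the pixel's SD and
a config switch selects the alternative — the default is not changed
silently. Savitzky–Golay smoothing (11-point window, order 3) exists
for display only and is never applied in the quantification chain,
because smoothing biases extracted concentrations through the window
choice.

## Calibration and limit of detection

Sensitivity and intercept come from ordinary least squares of intensity
on concentration over all replicates (intercept retained; a
through-origin option exists). The LOD formalises "the concentration
above which the series can no longer be fitted with a horizontal
line": scanning prefixes of the sorted dilution series, each prefix
compares the intercept-only model against the straight line by an
extra-sum-of-squares F-test at α = 0.05; the LOD is the smallest
concentration whose prefix rejects. At least two replicates per
concentration are required so residual variance is estimable. With the
default noise floor the Monte-Carlo median LOD is ≈ 10 mM at 0.3 s
dwell and ≈ 4 mM at 5 s, bracketing the instrument's operating point;
the exact printed LOD of a real instrument depends on the AUC noise
magnitude, which is why the suite validates order of magnitude and
monotonicity rather than an exact value. Calibration inversion never
clips negative concentrations, so below-LOD mass stays visible in
histograms (bin edges anchored at 0 mM, width 5 mM, occurrence
normalised by pixel count).

## Phantom geometry and composition

Cell phantoms are parametric so ground truth is exact: an elliptical
cell on a quartz substrate, an offset elliptical nucleus, an annular
membrane rim (~1.5 px), and seeded circular mitochondrial blobs in the
cytoplasm; every pixel carries exactly one label. Default grid 40×40
at 0.5 µm step and 0.3 s dwell. Compartments mix library components
(protein amide I/III, phenylalanine, CH₂ and acyl-twist lipid bands,
DNA 785 cm⁻¹, water bend, quartz) with per-pixel jitter structured as
a small common-mode focal-volume factor (5 % within a cell, 10 %
between cells) times a 2 % independent composition jitter. The
fluorescence baseline is a cubic with a canonical decaying shape shared
within a scan, amplitude 40 counts at the reference dwell, scaled by
the local material content (quartz barely fluoresces) and by the same
focal-volume factor as the bands, so that focal-volume variation is a
pure scale removed by AUC normalisation.

Fumarate enters each pixel at a truncated-normal concentration
(per-compartment mean, SD = 20 % of the mean). The confounding signal
near 1401 cm⁻¹ is rendered as the cytochrome-C oxidised/reduced pair
(weak 1388/1401 cm⁻¹ bands) calibrated in fumarate-equivalent mM, so
apparent concentration = true + confounder by construction; the
resonance cytochrome-C marker bands (748/1127/1585 cm⁻¹) are a
separate, mitochondria-weighted component used for compartment
identification. Cell-line presets encode, per compartment, the
true-fumarate and confounder means whose sums reproduce the reference
apparent-concentration table (WT: confounder only, 2/4/4/6/10 mM;
clone 1: +2/4/4/5/1 mM true; clone 19: +1/5/10/18/27 mM true).

Beyond fumarate, the presets carry clone-specific phenotypes: a
biomass-fraction factor (KO lines are denser, matching their globally
higher Raman intensities), lipid amount and 1301:1445 acyl-twist-to-CH₂
ratio (lipid remodelling/saturation), DNA and phenylalanine content,
and reduced respiratory-chain cytochrome-C in the FH-deficient clones.
These are required for realism of the classification task: cell lines
that differed *only* in fumarate would not be separable per spectrum
at the reported accuracies, because the clone-1 per-compartment
fumarate range is strictly nested inside clone 19's. The magnitudes
(5–30 %) are plausible for clonal metabolic rewiring but are modelling
choices, not measured values.

Tissue phantoms use an irregular (harmonically modulated) tissue
boundary, a protein/lipid matrix with a 1130 cm⁻¹ outline band on
tissue pixels only, and genotype-dependent fumarate: 3 ± 2 mM for
Fh1^fl/fl (majority below the 8 mM LOD) and 25 ± 8 mM for Fh1^−/−
(majority above, reaching ~40 mM). Line-scan datasets emulate scans
through a cell's major axis in 20 steps at 5 s dwell: membrane
endpoints, a central nucleus run (~30 % of points), two mitochondrial
crossings, cytoplasm elsewhere; the composition counts are fixed per
scan (only positions vary) as in standardised acquisitions.

What the phantoms do **not** model: water stretch above 3000 cm⁻¹, Mie
scattering, detector etaloning, realistic organelle morphology,
photodamage, or instrument wavenumber drift. Passing tests on phantoms
therefore demonstrate correctness of the computations and internal
consistency of the pipeline under the stated noise model — not
instrument-level performance on real tissue.

## Segmentation and compartment statistics

k-means uses L1 (Manhattan) point-to-centroid distances with
arithmetic-mean centroid updates (the vendor-style variant; an
L1-consistent median update is available), iterating to label
convergence or 300 iterations, with empty classes re-seeded from the
farthest point. Initialisation defaults to L1 k-means++ seeding with
the best of 4 restarts by total inertia: uniformly random initial
assignment (available as `init="assignment"`) starts every centroid at
the global mean and demonstrably converges to poor local optima
(singleton outlier classes; substrate split while membrane and
cytoplasm merge) whose inertia is distinctly higher than the k-means++
solutions. Runs are deterministic given the seed. Class counts follow
the study design: k = 8 for WT and clone 1, k = 6 for clone 19, chosen
so 4–5 classes remain for the cell after the substrate takes 1–4.

Loadings (class centroids on the original counts scale) are
baseline-corrected and scored on marker bands; classes that are dim
(< 50 % of the brightest class's fingerprint area) *or* carry
essentially no biological marker content are substrate (several may
be; they are merged into one reported row). Among the rest, all
classes within 50 % of the top cytochrome-C score are mitochondria
(FH-deficient scans can legitimately yield two), the top 785 cm⁻¹
score is the nucleus, the top lipid score the membrane, and the
remainder cytoplasm. Compartment tables report mean ± SD over all
pixel concentrations pooled within each (merged) class — pooling over
all pixels rather than per-cell, with the per-cell alternative noted.
Background correction subtracts the control's compartment means and
deliberately carries the uncorrected SDs (no variance propagation — a
documented limitation). One-way ANOVA is computed from the standard
between/within sums of squares.

## Classification

Spectra are fingerprint-AUC normalised, split by removing every fourth
spectrum (1-based positions 4, 8, …) into calibration and validation
sets, and autoscaled (per-channel standardisation — the usual
chemometrics preprocessing; without it the class displacements, which
carry well under 0.1 % of the spectral variance, are invisible to a
7-component model). PLS2 (NIPALS) is fitted on one-hot class targets
with 7 latent variables; venetian-blinds cross-validation uses 10
interleaved folds with preprocessing recomputed inside each fold. The
decision rule defaults to a Gaussian class-conditional (Bayes) model
on the latent scores — the multivariate analogue of the per-class
Bayesian score thresholds used by chemometrics toolboxes; raw argmax
of the predicted class scores is available but is biased against
high-variance classes. VIP scores follow
VIP_j = √(p·Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a) and satisfy
Σ VIP² = p identically. On fumarate-separated classes the VIP spectrum
is led by the isolated 1401 and 1277 cm⁻¹ bands; the 1652 cm⁻¹
companion overlaps amide I and the water bend, so its per-channel
importance is diluted. Both cross-validated and external-validation
sensitivities/specificities are reported, since printed figures of
this kind are often ambiguous between the two.

## Numerical choices and problem sizes

Polynomial fits use pseudo-inverse least squares on a rescaled axis;
the Gaussian peak fit constrains the centre to 1395–1407 cm⁻¹ and σ to
2–12 cm⁻¹ with a linear local background, and returns an undefined
(masked) value on non-convergence rather than zero. Histograms anchor
bin edges at 0 mM so negative values bin reproducibly. Default problem
sizes — 40×40 phantoms, 10-phantom recovery studies, 500-repeat LOD
Monte-Carlo, 2400-spectrum line-scan datasets — were chosen so the
complete validation suite runs in about a minute on one CPU while
keeping Monte-Carlo standard errors well inside the asserted margins.
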