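# Methods

This note records the forward model, the analysis procedures, the default
parameters with their rationale, and the known limitations of the package.

## 1. Study design

Two conditions (hypoxia, normoxia) × three treatment durations (4, 24,
48 h) × 9 biological replicates = 54 samples. Splits for classification
use a stratified 2/3 partition within each time point: 6+6 training,
3+3 testing.

## 2. Forward simulation

### 2.1 Concentrations

Each metabolite m has a fixed baseline level b_m (arbitrary units; sugars,
lactate and osmolytes high, branched-chain amino acids and pyruvate low).
A normoxia sample draws `b_m · ε`, a hypoxia sample `b_m · a_m(t) · ε`,
where ε is lognormal with mean 1 and coefficient of variation 0.10
(`σ = sqrt(log(1+cv²))`, location `−σ²/2`), and a_m(t) is the applied
ratio implied by the signed effect table.

The effect table uses the signed fold-ratio convention: +r means r-fold
higher under hypoxia, −r means r-fold higher under normoxia; |r| ≥ 1
always. The 48 h magnitudes use exact values where known (lactate +1.99,
pyruvate +1.80, myo-inositol −4.29) and range midpoints elsewhere
(+3 for "2–4× higher", +1.75 for "1.5–2× higher", −4 for "2–6× lower",
−1.65 for "1.3–2× lower", taurine −2). Effects at 4 h and 24 h are
attenuated toward 1 on the log2 scale (factors 0.25 and 0.6), reflecting
the gradient in which group differences build up with treatment duration.

`MISSING` cells (pyruvate at 4 h; glucose at 48 h in **both** groups, the
cultures having exhausted it) are rendered as sub-detection trace levels
drawn uniformly from 20–60% of the detection limit, so "undetectable"
means "below the limit", not "absent".

### 2.2 Spectra

A spectrum is rendered on a 10.0 → −0.5 ppm axis (0.001 ppm spacing) as:

- the sum over metabolites of `concentration × template profile`, where a
  template is a set of Lorentzian components at literature chemical shifts
  with relative areas following proton counts (FWHM 0.004 ppm ≈ 2.4 Hz at
  600 MHz) and each profile integrates to 1 per unit concentration;
- a TMSP reference singlet at 0.00 ppm with fixed area 1;
- a broad Gaussian residual-water hump at 4.75 ppm (sd 0.10 ppm);
- smooth baseline drift: a random degree-3 Chebyshev polynomial with
  coefficient scale 20 (raw units);
- additive white Gaussian noise, sd 2.5 raw units per point.

Per-sample nuisance factors: a lognormal receiver gain (sd 0.2 in log
space) multiplying the entire trace, and a rigid calibration shift drawn
uniformly from ±0.004 ppm displacing every feature. All randomness derives
from one `SeedSequence`, so the study is a pure function of
(configuration, seed).

**Noise level rationale.** With TMSP area 1 and FWHM 0.004, the TMSP peak
height is 2/(π·0.004) ≈ 159 raw units. Noise sd 2.5 puts the 3σ peak-height
detection threshold at the concentration detection limit (0.05 units), so
the planted trace levels are genuinely undetectable while panel signals
stay at high signal-to-noise ratio.

## 3. Spectral post-processing

Stage order: **align → scale to TMSP → water excision → baseline
correction → robust-mean normalization → binning.**

- **Alignment**: rigid axis shift placing a reference apex at its nominal
  ppm. Default reference is the α-glucose anomeric doublet (5.223 ppm)
  with fallback to TMSP (0 ppm) when glucose is undetectable (late
  glucose-depleted samples). Peak finding uses the tallest *interior*
  maximum in a ±0.1 ppm window (a window-edge maximum is a neighboring
  feature's slope and is rejected), quadratic three-point interpolation
  for sub-pixel apex position, a first-difference robust noise estimate
  (insensitive to smooth drift), and prominence above the window median at
  ≥5× noise.
- **Scaling**: intensities divided by the TMSP *prominence* (interpolated
  apex height minus window median). Using the raw apex height instead
  would fold the local baseline-drift value into the scale factor — at the
  default drift amplitude up to a ±25% per-sample error shared by all
  metabolites, which propagates directly into group fold-change medians.
- **Water excision**: all points in [4.5, 5.0] ppm removed.
- **Baseline**: Eilers-style asymmetric least squares (smoothness λ=1e7,
  asymmetry p=0.001, 10 reweighting iterations, sparse second-difference
  penalty). Applied only on the pattern-recognition branch (see §5).
- **Normalization**: division by the 5–95% trimmed mean of intensities
  inside the 0.2–4.4 ppm analysis window ("robust mean"). Applied only on
  the pattern-recognition branch.
- **Binning**: intensities summed into 0.01-ppm bins over 0.2–4.4 ppm —
  exactly 420 bins; the bin total equals the in-range total intensity.

## 4. Discriminating-metabolite selection

Mean-centered PCA (exact SVD; component signs fixed so each component's
largest-magnitude loading is positive). Bins are ranked by the loading
distance `sqrt(PC1² + PC2²)`; bins above the 90th percentile are merged
into contiguous regions; each region is integrated per sample and
confirmed with a paired t-test (pairs matched on (time point, replicate);
α = 0.05). Surviving regions are annotated with *every* library metabolite
that has a resonance inside the region padded by one bin width — the
standard ambiguity of 1D-NMR region annotation, under which a crowded
region (e.g. the 3.2–3.6 ppm sugar/osmolyte window, where glucose ring
protons co-resonate with taurine and myo-inositol) is attributed to all
co-resonant candidates. On default synthetic 48 h data the procedure
returns exactly the 17 planted panel metabolites.

## 5. Targeted quantification and fold changes

Concentrations are estimated by non-negative least squares of the
17-template library against the un-binned spectrum on 0.2–4.4 ppm.
Quantification branches off after water excision (TMSP-referenced scale,
**no** separate baseline subtraction and **no** robust-mean
normalization):

- the smooth background is estimated *jointly* in the fit through signed
  Chebyshev nuisance columns (degree 5 > the drift's degree 3). A separate
  asymmetric-least-squares pass would treat part of the summed Lorentzian
  tails as baseline and remove signal in proportion to each sample's total
  content, biasing fold ratios;
- robust-mean normalization would rescale samples content-dependently;
  instead, total-concentration normalization (each row divided by its
  non-missing sum) is available downstream and is used for the SVM.

A fitted component is reported MISSING when its implied peak height falls
below 3× the residual noise (median absolute deviation of the fit
residual). Near-collinear template pairs (cosine > 0.9999 on the fit
window) raise an error naming the pair.

Fold changes are medians: per metabolite and time point, the ratio of the
hypoxia group median to the normoxia group median, reported as +r (r ≥ 1)
or −1/r, with log2 alongside. A group whose samples are >50% below
detection masks the cell (rendered as MISSING, mirroring glucose at 48 h
and pyruvate at 4 h).

## 6. Classification

Per time point: stratified 6+6/3+3 split; features are the total-normalized
concentrations with below-detection values as 0; features standardized with
training-fold statistics only. The linear-kernel SVM cost is tuned by
leave-one-out cross validation on the 12 training samples over the grid
2⁻⁵, 2⁻³, …, 2¹⁵, maximizing balanced accuracy with ties broken toward the
smaller cost. Metrics (hypoxia positive): accuracy (TN+TP)/(TP+FP+FN+TN),
specificity TN/(TN+FP), sensitivity TP/(TP+FN), BAC their mean.

## 7. Pathway network

KGML-subset files are parsed for compound entries, enzyme entries and
reactions (a reaction referencing an undeclared participant is a hard
error). The metabolite panel maps into pathways through KEGG compound IDs;
the up-regulated gene list maps through a static gene→enzyme table
(replacing an online ID-conversion service). The fixture reproduces the
published two-column membership: 14 metabolome pathways, 11 transcriptome
pathways, 4 common. The pathway–pathway graph links two pathways with
weight = |shared mapped compounds| + |shared mapped enzymes| (≥1);
`all_entities=True` counts all KGML entities instead, for global-map-style
analyses. Export formats: GraphML and SIF.

## 8. What the simulator does and does not emulate

Emulated: frequency-domain Lorentzian lineshapes and multiplet-cluster
overlap, TMSP referencing, residual water, smooth baseline drift, receiver
gain and calibration error, lognormal biological variability, censoring at
a detection limit.

Not emulated: time-domain acquisition (pulse sequences, FID apodization,
zero-filling), J-coupling fine structure (multiplets are collapsed to one
Lorentzian per resonance cluster), pH-dependent shift changes, peak-width
heterogeneity, 2D experiments, and spectral artifacts such as phasing
errors. Chemical shifts and relative areas are package fixture constants
adequate for realistic overlap, not a curated shift database.

## 9. Known limitations

- **Early-time separability.** With the default attenuation the 4 h groups
  remain linearly separable and the SVM scores 100% at every time point;
  a real experiment of this kind typically shows weaker early-time
  performance. Reducing the 4 h attenuation factor or raising the
  biological CV reproduces imperfect early classification, but the
  defaults favor the documented 48 h behavior.
- **Region annotation is deliberately greedy.** Attributing a region to
  every co-resonant metabolite is what makes glucose (undetectable at
  48 h) attributable via its ring-proton overlap with taurine and
  myo-inositol; the same greediness can over-annotate crowded regions on
  other panels.
- **Fold-change compression.** NNLS on noisy, overlapping regions slightly
  compresses extreme ratios (single-seed medians for strongly overlapped
  low-abundance metabolites such as pyruvate can deviate ~5–10%); the
  concentration-level estimator is unbiased.
- **Pathway fixture membership is synthetic.** Compound IDs are real KEGG
  accessions and the enzyme placements are mechanistically sensible, but
  membership beyond the published two-column structure (and therefore
  derived connection counts) does not reproduce any specific KEGG release.
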