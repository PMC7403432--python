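# Methods

## Permethylated mass engine

Glycan compositions are expressed in the four residue classes that are
mass-distinct in permethylated MALDI-TOF: HexNAc (GlcNAc), Hex (Man and
Gal pooled — isobaric), dHex (Fuc) and NeuAc. Masses are built from atomic
monoisotopic masses only: each underivatized in-chain residue formula
(monomer minus H₂O) gains one CH₂ per methylation site (3 for Hex and
HexNAc, 2 for dHex, 5 for NeuAc), chain termini restore H₂O plus two
terminal methyls (net C₂H₆O), and the observed ion is [M+Na]⁺ (Na minus
one electron mass). Only singly charged sodiated ions are modeled — the
dominant species for permethylated glycans in reflectron-positive mode.
Tests verify the engine against an independent atom-counting oracle that
sums explicit elemental formulas.

## The 57-species plasma panel

The packaged reference panel holds 57 curated species spanning the
1,500–5,000 Da acquisition window: 5 high-mannose (M5–M9), 4 hybrid,
4 mono-antennary, 24 bi-antennary (12 bisected), 12 tri-antennary and
8 tetra-antennary compositions drawn from the well-characterized human
plasma N-glycome, with per-species baseline abundances that put ~88% of
signal in bi-antennary species (disialylated A2G2S2 dominating), ~6.8% in
tri-antennary, ~7.8% in bisected and ~2% in antenna-fucosylated glycans.
Attributes that composition cannot resolve are curated per species:
a bisected n-antennary glycan is isobaric with an (n+1)-antennary one, so
bisection, fucose placement (core on mono/bi structures, antennal on
tri/tetra) and the Man/Gal split of the pooled Hex count are stored
labels, not inferences. The classification heuristics
(high-mannose iff HexNAc₂Hex₅₊ without Fuc/NeuAc; hybrid iff HexNAc₃Hex₅₊;
otherwise complex with antennae = HexNAc − 2 − bisecting) apply only to
unlabeled compositions. The panel ships as versioned JSON package data;
all panel m/z values are pairwise separated by > 2 Da, twice the default
annotation tolerance.

## Spectrum model and quantification

Synthetic spectra place one Gaussian per species at its theoretical m/z
(default σ = 0.3 Da on a 0.2 Da grid) with area proportional to relative
abundance, plus a flat baseline and white Gaussian noise clipped at zero.
Isotope envelopes, matrix adducts and multiple charging are deliberately
out of scope; the monoisotopic centroid stands for the species, matching
a one-annotated-peak-per-species quantification scheme.

Peak picking thresholds local maxima at baseline + SNR·noise, with the
baseline estimated as the global median and the noise as the upper-side
quantile spread (84.1st percentile minus median — one sigma for Gaussian
noise and robust to a zero-clipped noise floor, where the classic MAD
collapses). Centroids are intensity-weighted means over a ±1.5 Da window
truncated at midpoints between adjacent detected maxima, so a large
neighbor's flank cannot drag a small peak's centroid (the closest panel
pair sits 2.02 Da apart). Peak intensity is the apex height obtained by
log-parabolic interpolation of the three samples around the maximum —
exact for Gaussian peaks, which is what lets the noise-free
synthesize→pick→annotate→normalize round trip reproduce any profile to
10⁻⁶ percent despite grid-phase effects; a raw sample maximum would leave
~0.5% grid-alignment error. Annotation assigns each peak to the nearest
panel m/z within ±0.5 Da (ties to the lower mass; unassigned centroids
reported for QC), and abundances are percent of summed panel intensity.

## Genotype statistics

All group comparisons share one code path: one-way ANOVA (df = groups−1)
followed by two-sided pairwise Welch (unequal-variance) t-tests, with
stars at 0.05/0.01/0.001 and no multiple-testing correction across
glycome features — raw p-values are the convention for this design — plus
a Benjamini–Hochberg column emitted for transparency. Relative-change
matrices vs the reference genotype clip at ±50% (relative) or ±5
percentage points (absolute) for display only; data values are retained.
Monosaccharide contributions weight each glycan's residue-count fractions
by its abundance (count basis by default; a mass basis is available —
which of the two an intensity-normalized assay should use is genuinely
ambiguous, and the choice is a documented switch). Sex-stratified
analyses are an ordinary group-by facet over the cohort metadata.

## Trace elements

MDL = t(0.99, n−1)·SD over n = 7 replicate low-level QC runs — the
standard EPA-style convention, with the multiplier (3.143 at n = 7)
computed from the t-distribution, and a 3·SD alternative available.
Elements whose sample-wide mean does not exceed their MDL are excluded
from inference (strict inequality). Sub-MDL values that survive the
filter are retained as measured; censoring at MDL/2 exists but is off by
default, since near-limit values still carry rank information. Covariate
regressions (element vs age or BMI) are ordinary least squares with a
two-sided slope test.

## Neuroimaging

Ratio volumes are voxel-wise T2w/T1w inside the brain mask; voxels with
zero T1w are dropped. The ratio cancels any per-subject multiplicative
intensity scale (coil loading, body habitus) applied to both images —
the generators exercise exactly this invariance. Voxel-wise genotype
contrasts use Welch t-tests with Benjamini–Hochberg FDR across in-mask
voxels only, two-sided, signed significance at q < 0.05, and no
cluster-extent thresholding. Volumetric morphometry is deliberately
omitted (a negative control in this design).

Dunnett many-to-one post-hoc tests pool the error variance across all
groups and compute adjusted p-values from a seeded Monte-Carlo sample of
the max-|t| null of the many-to-one contrasts (default 200 000 draws;
Monte-Carlo SE near p = 0.05 is ≈ 5·10⁻⁴; the k = 2, df = 20 critical
value reproduces the published 2.38 within that tolerance, and adjusted
p-values agree with an independent exact implementation to ~2·10⁻³).
With a single comparison the procedure reduces to the pooled two-sample
t-test. LDA classification standardizes features, fits a Fisher
discriminant (shrinkage fallback with a warning if the within-class
covariance is singular), sweeps the discriminant score for the ROC and
computes AUC as the normalized Mann–Whitney rank statistic;
leave-one-out scoring is available because resubstitution AUC is
optimistically biased (and leave-one-out mildly pessimistic) at small n.

## Synthetic cohorts: what they emulate, and what not

Generators are bit-reproducible given (config, seed) and return their
ground truth so recovery tests can compare estimates with configured
values. Cohort metadata emulates matched sampling by reusing one base
age/sex/BMI table across genotypes with a small jitter.

*Glycome.* Per-sample profiles are Dirichlet draws around genotype mean
profiles built by scaling the panel's baseline weights inside each
antennarity/class category to configured category means (CC: mono 1.09,
bi 88.0, tri 6.77, tetra 0.574, high-mannose 3.59; carriers shift mass
from tri/tetra toward bi). The hybrid share is not reported for this
design and is set to a plasma-typical 0.35%; the configured vector is
renormalized to exactly 100 (deviations > 1 raise). The default
concentration c = 135 gives a bi-antennary group SD of ≈ 2.8 percentage
points via Var(share) = p(1−p)/(1+c), reproducing the carrier-contrast
significance pattern at group sizes of ~30. A single concentration ties
all category variances to p(1−p), so the tetra-antennary share is
relatively noisier than in real plasma data — its configured downward
shift is therefore not sign-stable per replicate (as in the source
design, where it was not significant). A paired pre/post-Mn CDG profile
pair pins the A2G1S1/A3G3S3/A3FG3S3 anchors to tabulated values within
the category structure.

*Elements.* Concentrations are lognormal with a common CV of 0.225 —
derived from the reported Mn ANOVA (F = 6.47 at means 0.814/0.732/0.669
μg/L, n = 46/46/25 implies pooled SD ≈ 0.17). Only Mn is genotype-graded
by default; seven elements (Be, Cd, Ni, Pt, Te, Tl, W) have means set
below their nominal MDLs and sixteen well above, with margins wide
enough that the QC-run-derived MDLs (χ²-distributed around their
targets) preserve the 16/7 split essentially surely. QC runs are drawn
at 3× the nominal MDL with SD = MDL/3.143.

*Volumes.* A schematic 64³ label map (paired spherical GPi/SN/LPut blobs
in a spherical brain with a white-matter core — toy geometry, not
anatomy) defines tissues with base T2w/T1w levels anchored to reported
ROI means (GPi/SN 0.279, LPut 0.399) and multiplicative genotype effects
(TT: GPi ×0.907, SN ×0.950, LPut ×1.060, WM ×1.02; CT roughly half).
Between-subject variation is a per-tissue lognormal effect with log-SD
0.06, calibrated to the reported post-hoc significance pattern (the
smallest printed contrast, SN at p = 0.0008, implies a within-group SD
of ≈ 0.017 — the separately printed ROI SDs of ≈ 0.03 are not jointly
consistent with those p-values, and the significance pattern is what the
generator is meant to reproduce). White voxel noise (2% of tissue
intensity) enters both images, and a per-subject global scale in
[0.8, 1.2] multiplies both images to exercise the ratio invariance.

Because the generators draw independent samples with known effects, a
passing recovery test demonstrates that the statistics detect what was
injected at the configured noise — not that real biobank data would
reproduce the original cohort values, which depend on unmodeled features
(isotope envelopes, baseline drift, batch effects, registration error,
population structure).

## Problem sizes and numerical choices

Simulation-based tests run at the design's group sizes (33/31/25 glycome,
46/46/25 elements, 45/group MRI) with replicate counts chosen for stable
pass/fail behavior at desk scale: 200 reps for null calibration of the
category tests, 30 for Mn detection, 20 for branching sign recovery and
voxel-FDR null, 5 for the volumetric Dunnett recovery. Monte-Carlo
Dunnett uses 200k draws (400k for critical-value checks). Annotation
tolerance defaults to ±0.5 Da — the panel's minimum spacing is 2.02 Da —
and is configurable. Degenerate inputs fail loudly: empty compositions,
all-zero profiles (an uninterpretable spectrum), groups of fewer than two
samples, constant covariates, empty ROIs and missing metadata joins all
raise with the offending item named.

## Known limitations

- The panel is a curated stand-in constrained by the printed anchors and
  category totals; the original study's exact 57 identities are not
  public, so per-species values are not comparable one-to-one.
- Hex pooling means Man/Gal splits (and therefore terminal-galactose
  counts) rest on curated labels.
- The spectrum model omits isotope clusters, adducts and baseline drift;
  annotation robustness to real instrument artifacts is untested here.
- Dunnett p-values are Monte-Carlo estimates; at extreme significance
  (p < 10⁻⁵) they return 0 at default draw counts.
- The volume generator's geometry is schematic; registration, partial
  voluming and anatomical variability are out of scope.
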