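# Methods

This note records the models implemented in `redflesh`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions that matter for reproducing output bit for
bit.

## Segmentation

A scan is reduced to BT.601 luminance (0.299 R + 0.587 G + 0.114 B) and
thresholded with Otsu's criterion: the integer split point t ∈ [1, 255]
maximising the between-class variance ω₀ω₁(µ₀ − µ₁)² of {v < t} vs
{v ≥ t} over the 256-bin histogram, computed by exhaustive evaluation of
all split points (cumulative-sum form; smallest maximiser wins ties).
Foreground is *darker* than the threshold, matching a white scanner field;
`invert=True` flips the polarity. Components are labelled with
8-connectivity (scikit-image) and components smaller than `min_area`
(default 1% of the image — removes dust and specks) are dropped. Sections
are ordered row-major by bounding-box origin so that the up-to-four
sections of a scan map deterministically to fruit replicates 1–4. Touching
sections are not split: the acquisition protocol spaces fruits on the
glass, and no watershed is attempted (known limitation). The section mask
is the full Otsu foreground; no seed-cavity or peel-ring exclusion is
applied.

## Colorimetry

The conversion is the standard CIE pipeline: inverse sRGB companding
(c ≤ 0.04045 ? c/12.92 : ((c + 0.055)/1.055)^2.4), the sRGB/D65 3×3 matrix
to XYZ, then CIE 1976 L\*a\*b\* with the cube-root function and its linear
segment below (6/29)³. The reference white is taken as the exact image of
RGB (1, 1, 1) under the matrix — numerically (0.95047, 1.0000001, 1.08883)
— so neutral grays give a\* = b\* = 0 identically instead of to ~2·10⁻⁵.
The conversion is implemented in-package with these published constants;
`skimage.color.rgb2lab` (which uses a slightly different matrix precision)
serves as an independent cross-check in the tests, agreeing within 0.05
Lab units.

Descriptors are means and *population* SDs (divide by n) over masked
pixels; at pixel counts ~10⁵ the n vs n−1 distinction is negligible but
fixing it makes outputs bit-reproducible. RGB descriptors are computed on
the raw 0–255 integers with no linearisation, since they describe the
camera-space distribution. Hue and chroma are derived from the *mean*
(a\*, b\*) — not averaged per pixel — and genotype aggregation averages
every descriptor field across fruits, then recomputes hue/chroma from the
aggregated (a\*, b\*) so the angular coordinates stay consistent with the
averaged chromatic position.

Hue convention: the default is the standard CIELCh angle atan2(b\*, a\*)
in degrees mapped to [0, 360) (red ≈ 0°, yellow ≈ 90°), which is
internally consistent with descriptor values ranging red ≈ 0 to yellow
≈ 60 on red-flesh material. The ratio form arctan(a\*/b\*) is available
via `hue_formula="paper"` for comparison with legacy outputs. Whether
degrees or radians were used upstream is ambiguous in the field; degrees
are used throughout because descriptor magnitudes only make sense that
way.

## Biochemical preprocessing

Rule order is fixed and tested: (1) sub-LOD measurements → LOD/2 (values
strictly below the LOD, or flagged/missing ones; a value exactly at the
LOD is kept), (2) mean of the two extraction replicates, (3) class totals
— flavanols = catechin + epicatechin + procyanidins B1 + B2 + C1;
hydroxycinnamic acids = chlorogenic + 4-p-coumaroylquinic;
anthocyanins = cyanidin 3-galactoside; flavonols = quercetin
3-galactoside; dihydrochalcones = phlorizin — and (4) an optional natural
log of named fields (anthocyanins, whose relation to colour saturates).
The log base is a monotone rescale and leaves PLS/VIP rankings unchanged.
Concentrations are carried as µg/g FW; the method's on-column LOD/LOQ
table (ng) is shipped for the substitution rule and validated as
LOD < LOQ. Water content is 1 − DW/FW.

## Heritability

Broad-sense heritability of a descriptor uses the one-way random-effects
model y\_jk = µ + B\_j + ε\_jk and the ANOVA method of moments:
σ²\_ε = MSW, σ²\_B = (MSB − MSW)/n₀ with the Satterthwaite-adjusted mean
group size n₀ = (N − Σn\_j²/N)/(a − 1) for unbalanced designs, and
h² = σ²\_B/(σ²\_B + σ²\_ε) truncated to [0, 1] (negative moment estimates
of σ²\_B are set to 0 first). Replicates are genotype-level values per
harvest year. The estimator's finite-sample bias at 91 genotypes × 2
replicates is about −0.006 at h² = 0.75 (measured by the recovery
simulation), well inside the ±0.03 recovery band. REML was considered and
rejected as the default: the method-of-moments form *is* the intra-class
correlation and is closed-form, dependency-free and exactly testable
against a hand ANOVA.

## PCA

Active variables are centred and reduced by their population SD, so the
decomposition is of the correlation matrix (eigh); loadings are variable–
component correlations (eigenvector × √eigenvalue), cos² their squares,
and observation cos² the squared score share of the row's squared norm.
Component signs are fixed by making the largest-|loading| variable
positive. Supplementary variables are projected as plain correlations
with the scores and never influence the eigendecomposition; a
supplementary copy of an active variable reproduces that variable's
loading exactly (tested). Zero-variance active variables are an error
naming the column.

## Correlations

Pairwise Pearson r with two-sided p from t = r√((n−2)/(1−r²)) on n−2 df,
masked at p < 0.05. p-values are deliberately unadjusted — the matrix is
a descriptive screen, and the mask mirrors that convention. Constant
columns yield NaN, flagged rather than zeroed.

## PLS1, component rule, VIP, validation

NIPALS for a single response on z-scored X and y (SD with n−1, matching
the common chemometrics scalers): per component w = Xᵀy/‖Xᵀy‖, t = Xw,
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflate both blocks. A new component is kept
only while its incremental share of Y dispersion exceeds 1% (strict
inequality); at least one component is always retained, and extraction
also stops at the rank limit. Coefficients are reported in scaled space
(comparable across predictors) with an unscaling layer for prediction.
VIP\_j = √(p · Σ\_h SSY\_h (w\_jh/‖w\_h‖)² / Σ\_h SSY\_h), so Σ VIP² = p;
predictors with VIP ≥ 0.8 are flagged important. Validation refits on a
seeded uniform 80/20 split and reports RMSE on the held-out responses in
original units — the split seed is an explicit, logged parameter, so
hold-out RMSE is reproducible per seed and otherwise a draw from the
split distribution. The default predictor set is the seven class-level
factors (log anthocyanins, flavanols, flavonols, hydroxycinnamic acids,
dihydrochalcones, pH, water content); with one response and one predictor
PLS1 reduces to ordinary least squares (tested closed-form limit).

## Synthetic generators

`generate_scan` renders 1–4 disks on a white field; a target fraction of
each disk is overpainted with seeded random blobs of a second colour.
Colours are specified in Lab, converted to sRGB with an explicit gamut
error (no silent clamping), and quantised to 8 bits *before* the truth is
computed: each section is then an exact two-point mixture of two known
quantised colours, so expected mean (1−f)·base + f·blob and SD
|base − blob|·√(f(1−f)) are exact with f the achieved pixel fraction.
Descriptor recovery through the full segment-and-describe path is
therefore exact to ~10⁻¹¹, and the 0.5/1.0 Lab-unit acceptance bands have
their entire budget available for segmentation effects. What the
generator does not emulate: illumination gradients, specular highlights,
peel rings, seed cavities, continuous pigment gradients and JPEG-like
noise — so passing recovery tests validates the measurement chain, not
robustness to acquisition artefacts.

`generate_panel` draws a latent pigmentation score g ~ N(0, 1) per
genotype. Anthocyanins are log-normal with log-scale mean 3.3 and loading
+1.0 on g (range ≈ 2–300 µg/g across a panel), flavanols log-normal with
loading −0.6 (the pathway-competition anticorrelation, r ≈ −0.77 with
log-anthocyanins), flavonols weakly positive (+0.15), hydroxycinnamic
acids and dihydrochalcones independent log-normals, pH ~ N(3.18, 0.15)
and water content ~ N(0.815, 0.025). The colour responses are linear in
the *analytically* standardised predictors — a\* = 12 + 8·(β\_aᵀz + ε),
b\* = 14 + 3·(β\_bᵀz + ε′), ε ~ N(0, noise\_sd) — so population
correlations and R² follow in closed form from β and the log-normal
moment identities. Defaults β\_a = (0.9, −0.35, 0.20, 0, 0, 0.15, 0) and
noise\_sd = 0.55 give an analytic a\* R² of 0.845 and
corr(log-anthocyanins, a\*) = 0.888, i.e. a panel in the regime where a
single PLS component dominates and anthocyanins top the VIP ranking; an
optional soft saturation cap reproduces the plateau of colour against
anthocyanin content. Hue and chroma are recomputed from the generated
(a\*, b\*) for internal consistency, so hue is only approximately linear
in the predictors. The per-genotype descriptor SD columns are plausible
fillers correlated with pigmentation, not modelled quantities.

## Problem sizes and numerical conventions

The test-suite and acceptance problem sizes are the package's reference
conditions: 50 randomised histograms for threshold optimality, 20
rendered scans for descriptor recovery, 500 simulations of 91 × 2 for
heritability recovery, 200 panels of 91 genotypes for VIP ranking
recovery, and 91-genotype panels for the PLS summaries. Ties in Otsu's
criterion resolve to the smallest threshold; hue at the neutral point is
NaN with chroma 0; a tiny-negative hue angle that rounds to 360° is
mapped to 0; zero-variance predictors are detected with a relative 10⁻¹⁰
tolerance; all generators take one explicit seed and use no global
random state.

## Known limitations

No colour-chart calibration or illumination correction (the shade-box
acquisition is assumed to standardise lighting); touching fruit sections
are not separated; heritability assumes the one-way balanced-ish design
and offers no kinship modelling; the PLS component rule is the 1%
dispersion heuristic, not cross-validated Q²; printed hold-out RMSEs are
split-seed-dependent by construction.
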