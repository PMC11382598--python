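# Methods

This note records the statistical definitions, default parameters, and
numerical choices behind `fmriqc`, and what the synthetic phantom does and
does not emulate.

## Detrending

All "detrended" quantities use ordinary least squares against a Legendre
polynomial basis evaluated on [-1, 1] over each run separately. The
polynomial order for a run of duration D seconds is

    order = 1 + floor(D / 150)

so a 400 s run gets a cubic (4 basis terms including the constant). Legendre
polynomials are used instead of raw monomials purely for conditioning; the
fitted subspace is identical.

## Motion and censoring

- **enorm** is the Euclidean norm of the forward differences of the six
  rigid-body parameters (three rotations in degrees, three translations in
  mm), defined as 0 at the first volume of every run. Degrees and mm are
  summed in quadrature without rescaling; on a human-sized head 1° of
  rotation moves peripheral tissue by roughly 1 mm, which is the usual
  justification for treating the columns as commensurate.
- **Outlier fraction**: per run, each in-mask voxel series is detrended; a
  time point is an outlying sample of that voxel when its absolute deviation
  from the voxel's median residual exceeds q · 1.4826 · MAD, where q is the
  two-sided normal quantile at p = 0.001/T for a run of T volumes (the
  per-run Bonferroni-style adaptation keeps the expected false-positive
  count roughly constant across run lengths). Voxels with zero MAD are
  excluded rather than counted. The per-volume outlier fraction is the share
  of in-mask voxels outlying at that volume.
- **Censoring**: a volume is censored when enorm > 0.3 (default) or outlier
  fraction > 0.05 (default). Because enorm measures a between-pair
  difference, the volume preceding an enorm-censored one (within the same
  run) is censored too ("extend previous"). Both limits are configurable;
  the defaults are the conventional task-fMRI settings.
- **Minimum-outlier volume**: the index of the volume with the smallest
  outlier fraction, a natural registration reference.
- Before/after-censoring distribution summaries are five-number summaries
  (min, q25, median, q75, max) with linear-interpolation quantiles.

## Correlation diagnostics

- **GCOR** is the mean of the full pairwise correlation matrix of in-mask
  series, self-pairs included. It is computed as the squared norm of the
  mean of the unit-normalized series — an algebraic identity that avoids
  forming the N×N matrix.
- **corr_brain** correlates each in-mask residual series with the in-mask
  mean residual. Rendering thresholds |r| = 0.3 (translucency onset) and 0.6
  (color range) are display conventions, not inferential cutoffs.
- **Radial correlation** correlates each voxel with a Gaussian-weighted
  (FWHM 20 mm) average of its in-mask neighborhood. The smoothing is
  zero-padded and mask-renormalized: smoothing data·mask and mask separately
  and dividing makes the neighborhood average exactly a truncated-Gaussian
  weighted mean over in-mask voxels, with no reflection artifacts at mask
  edges. 20 mm is wide enough to capture coil- or motion-induced shells and
  narrow enough to localize them.
- **Seed correlation** maps use seeds given in mm; a seed landing outside
  the mask snaps to the nearest in-mask voxel and the snap is logged.

## TSNR and ROI statistics

TSNR = mean(signal) / sd(noise) voxelwise, at two stages: after volume
registration (noise = detrended residual) and after regression (noise =
regression residual). The per-ROI table reports voxel count (Nvox), count of
exactly-zero TSNR voxels (Nzer — exactly zero, i.e. masked-out or failed,
not near-zero), erosion depth in voxels (Dvox: the number of face-connected
erosions needed to empty the ROI, equivalently the maximum taxicab distance
to the boundary), its location in mm, and TSNR quartiles. Warning levels per
metric use documented heuristic defaults (e.g. Nvox < 20/10/5 →
mild/medium/severe; Nzer/Nvox > 0.1/0.25/0.5; Dvox < 3/2; T75 < 50/30/15;
quartile slope (T75−T25)/Tmed > 0.75/1.0/1.5; Tmed = 0 flags the slope
severe rather than dividing). All are configuration-overridable.

## Regression bookkeeping

- **Ideal responses** convolve stimulus onset trains with a unit-peak
  gamma-variate kernel (peak at 4.5 s, shape exponent 5), a unit block, or
  an identity (impulse) kernel, sampled at the TR.
- **DF accounting** enforces total = censored + regressors + left. A model
  with left < 0 is reported with fraction clamped to 0 and a severe warning
  rather than an exception, since a QC report must still render.
- **Bandpass DF cost**: keeping only [f_lo, f_hi] Hz removes every DFT
  frequency k/(T·TR), k = 1..⌊T/2⌋, outside the band (endpoints kept),
  at 2 DFs per frequency and 1 for the Nyquist bin when T is even. For the
  standard 0.01–0.1 Hz band this consumes 62.5% of DFs at T = 200, TR = 2 s
  and 80.5% at TR = 1 s — the central argument against aggressive bandpass
  plus censoring.
- **Collinearity warnings** grade pairwise design-matrix |r| at 0.4 / 0.6 /
  0.9 (mild / medium / severe) and flag constant columns separately.
- **Per-stimulus censor fractions** report the censored share of each
  stimulus's response support (ideal response > 0); an empty support is
  flagged severe instead of dividing.

## Artifact detectors

- **Flip check**: the blockwise local-Pearson alignment cost
  cost = −Σ_b w_b · sign(r_b) · r_b² / Σ_b w_b over non-overlapping cubes of
  edge 2r+1 (default r = 2) with at least 8 in-mask voxels (w_b = voxel
  count), compared between the EPI as given and the EPI mirrored across the
  left-right axis (the axis whose direction cosine row is dominated by the
  first affine column). The lower cost wins; within a 2% relative margin the
  verdict is UNDECIDED, otherwise NO_FLIP or DO_FLIP (severe).
- **Variance lines**: per in-plane column (i, j), the score is the median
  across slices of the detrended temporal sd of in-mask voxels (columns with
  fewer than half their slices in-mask are excluded). Columns whose score
  exceeds 2.5× the median column score are flagged, and face-adjacent
  flagged columns merge into one cluster reported with its peak location in
  index and mm coordinates.
- **Pre-steady-state volumes**: the longest prefix of volumes whose in-mask
  mean exceeds 1.05× the 10%-trimmed run mean. Only a prefix counts:
  mid-run intensity inflation is a different problem and is left to the
  outlier fraction.
- Warning levels form the total order none < undecided < mild < medium <
  severe with fixed display colors; an aggregate is always the maximum.

## Report and group tables

The HTML report is a single self-contained directory (relative links only)
with ten themed blocks in fixed order: vorig, ve2a, va2t, vstat, mot, mecho
(placeholder unless multi-echo inputs exist), regr, radcor, warns, qsumm.
Statistical overlays fade quadratically below threshold (alpha = (|v|/thr)²)
and outline suprathreshold clusters; the default t-map threshold is the
two-sided p = 0.001 quantile at the model's residual DF. The carpet plot
z-scores each in-mask series, orders rows by decreasing |correlation| with
the first principal component of the in-mask data, and clips the gray scale
at ±3.2905 (two-sided normal p = 0.001). Ratings use the vocabulary good/
bad/other (symbols +, X, ?); a comment on an unrated block forces "other",
and ratings merge into the subject's review dictionary so they can drive
group filtering.

Review dictionaries exist in two equivalent dialects — colon-separated text
and flat JSON — with floats normalized to 6 significant figures (printed
fraction rows use 6 decimals) so the dialects compare equal. Group tables
expand list-valued entries into suffixed columns, keep first-seen column
order, and mark missing entries `NA`. Filter criteria support VARY (differs
from the first subject, numeric comparisons at relative tolerance 1e-9),
EQ, GT, LT, GE, LE, and SHOW; type-mismatched comparisons raise instead of
silently evaluating false. A header scan across datasets (dimensions, voxel
size, TR, volume count, orientation, datum, value range) reports any field
that varies across the group, with unreadable files kept as error rows.

## The synthetic phantom

The phantom is a three-tissue ellipsoid "head" with a deliberately
asymmetric exterior lobe and two interior nodules (so the left-right flip
cost has real contrast to work with), a toy atlas grown by face-connected
BFS from farthest-point seeds, and an EPI series built as

    baseline · (1 + 0.10 · normalized tissue contrast) + drift + networks + noise,

with the in-mask mean of the baseline held exactly at `baseline_mean` so the
no-artifact TSNR expectation is exactly baseline_mean / noise_sd. Injected
artifacts are recorded in a ground-truth record: motion spikes (whole-volume
shift-and-scale perturbations plus matching motion-parameter spikes, whose
censored volume set {t−1, t, t+1} per spike is derived analytically in the
generator, independent of the censor code it validates), variance lines
(noise scale factors on listed columns), network seeds with shared smooth
time courses, per-ROI noise scaling to hit TSNR targets, a left-right flip
toggle, and inflated initial volumes. Defaults: 32×32×20 voxels of
2.5 mm, 200 volumes at TR 2 s, baseline 1000, noise sd 10.

The phantom emulates the *statistical signatures* QC must detect, not MR
physics: there is no k-space model, no slice timing, no spatial
autocorrelation in the thermal noise, no physiological noise spectrum, no
susceptibility dropout, and registration is assumed already done (the
toolkit scores aligned volumes; it does not align them).

## Numerical choices and limitations

- All image math is float64; correlation denominators guard against zero
  variance explicitly rather than relying on floating-point infinities.
- Quantiles use linear interpolation throughout.
- Gaussian smoothing uses zero-padded convolution (see radial correlation).
- The outlier rule's MAD scaling assumes roughly symmetric residual noise;
  heavy skew inflates the fraction.
- The flip check needs genuine left-right contrast; a perfectly symmetric
  brain (or phantom) is reported UNDECIDED by design.
- Warning-level thresholds (ROI metrics, collinearity grades, variance-line
  factor 2.5, presteady factor 1.05) are heuristics chosen to be obvious and
  overridable, not fitted to any dataset.
- Multi-echo combination quality is out of scope; the mecho block emits a
  placeholder note.
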