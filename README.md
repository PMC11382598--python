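# fmriqc

Quality control for single-subject functional MRI, built around the question
every processing pipeline has to answer before group analysis: **is this
subject's data usable, and if not, why not?** `fmriqc` computes the standard
battery of scalar QC quantities and artifact checks from a preprocessed (or
synthetic) 4D EPI series, renders them into a portable static HTML report,
and tabulates them across subjects so that exclusion criteria can be applied
reproducibly instead of by eyeballing.

Everything runs on plain NIfTI volumes plus text sidecars (motion-parameter
matrices, stimulus timing, review dictionaries) and needs no external data:
a synthetic-phantom module generates 4D test data with *known* injected
artifacts — motion spikes, high-variance scanner lines, pre-steady-state
volumes, left-right flips, seeded "networks", per-region TSNR targets — so
every detector can be validated against ground truth.

## What it computes

**Motion and censoring** (`fmriqc.motion`). The Euclidean norm of the
forward differences of the six rigid-body motion parameters,

&nbsp;&nbsp;&nbsp;&nbsp;enorm(t) = ‖Δp(t)‖₂ , p ∈ ℝ⁶ (rotations in degrees, translations in mm),

reset at run boundaries; a robust per-volume outlier fraction (share of
in-mask voxels whose detrended residual exceeds a MAD-based cutoff); and the
censor vector that removes volumes with enorm > 0.3 or outlier fraction
> 0.05, extending enorm censoring to the preceding volume of the pair.

**Correlation diagnostics** (`fmriqc.correlations`). GCOR, the average of
all pairwise correlations of in-mask series, computed via the unit-variance
mean-series identity; corr_brain (each residual's correlation with the mean
residual); radial correlation (correlation with a Gaussian-weighted, FWHM
20 mm, in-mask neighborhood average); seed-based correlation maps with
out-of-mask seeds snapped to the nearest in-mask voxel; mask Dice overlap.

**TSNR and ROI shape statistics** (`fmriqc.tsnr`). Temporal signal-to-noise
TSNR = mean(signal)/sd(noise) at two pipeline stages, plus a per-ROI table of
voxel count, zero-valued count, erosion depth (Dvox, taxicab metric), TSNR
quartiles, and graded warning levels.

**Regression bookkeeping** (`fmriqc.regress`). Ideal stimulus responses
(gamma-variate or block convolution), temporal degrees-of-freedom accounting
(total = censored + regressors + left), the DF cost of a bandpass expressed
as Fourier regressors, per-stimulus censored-response fractions, and
design-matrix collinearity warnings.

**Artifact detectors** (`fmriqc.warns`). A left-right flip check driven by a
blockwise local-Pearson-correlation alignment cost, variance-line detection
(through-slice columns whose temporal sd exceeds 2.5× the median column
score), pre-steady-state volume counting, all reported as warning items on
the ordered severity scale none < undecided < mild < medium < severe.

**Reporting** (`fmriqc.report`, `fmriqc.tables`). A self-contained HTML
report with ten fixed QC blocks (vorig, ve2a, va2t, vstat, mot, mecho, regr,
radcor, warns, qsumm), alpha-faded/boxed statistical overlays, a carpet
(gray) plot ordered by principal-component similarity, edge-overlay
alignment images, and a rating/comment sidecar. Review dictionaries from many
subjects are merged into a group table and filtered with criteria such as
`'censor fraction' GT 0.1` or `'flip guess' EQ DO_FLIP`.

## Worked example

Build the demonstration phantom — 32×32×20 voxels × 200 volumes at TR 2 s,
with two injected motion spikes (magnitudes 1.0 and 0.8 at volumes 60 and
150), one variance line, three seeded networks, four ROI TSNR targets and a
two-class block design — and run the full QC battery on it:

```python
from fmriqc.synthetic import demo_spec
from fmriqc.pipeline import run_phantom_qc

out = run_phantom_qc(demo_spec(rng_seed=1), "qc_demo", subject="sub-001")
for key, val in out["review"].items():
    print(f"{key} : {val}")
```

Printed output (verbatim):

```
QC tool : fmriqc
QC tool version : 0.1.0
subject ID : sub-001
num runs found : 1
num TRs per run : 200
num TRs per run (applied) : 194
fraction censored per run : 0.03
TRs total (uncensored) : 200
TRs total : 194
TRs censored : 6
censor fraction : 0.03
degrees of freedom used : 12
degrees of freedom left : 182
final DF fraction : 0.91
num regs of interest : 2
num TRs per stim (orig) : [63, 63]
num TRs censored per stim : [3, 3]
fraction TRs censored : [0.048, 0.048]
TSNR average : 109.684
global correlation (GCOR) : 0.000224448
anat/EPI mask Dice coef : 1.0
flip guess : NO_FLIP
num variance lines : 1
presteady-state volumes : 0
minimum outlier volume : 0
max motion enorm : 1.00097
max outlier fraction : 0.142568
```

The numbers check out against the injected truth: each of the two motion
spikes censors three volumes (the spiked volume, its successor, and the
extended predecessor), so volumes {59, 60, 61, 149, 150, 151} are censored —
6 of 200, censor fraction 0.03, leaving 194 applied TRs; 12 regressors
(4 polynomial drift terms including the baseline, 6 motion, 2 stimulus)
leave 182 DFs, a final
DF fraction of 0.91; the injected variance line is found; no flip and no
pre-steady-state volumes are reported, matching the generator settings.
`qc_demo/index.html` holds the report; `qc_demo/out.ss_review.sub-001.txt`
holds the same review dictionary in the colon-separated dialect.

Group screening across subjects from the command line (the second subject
was built the same way with `demo_spec(rng_seed=2, motion_spikes=[])`, so it
censors nothing):

```
$ apqc review-table --infiles qc_demo/out.ss_review.sub-001.txt \
      --infiles qc_demo2/out.ss_review.sub-002.txt \
      --report-outliers "'censor fraction' GT 0.02" \
      --report-outliers "'flip guess' EQ DO_FLIP"
subject  censor fraction flip guess
sub-001             0.03         NA
```

Subject `sub-001` trips the censor-fraction criterion (0.03 > 0.02); the
flip-guess column is `NA` for it because that criterion did not fire.

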