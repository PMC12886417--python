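# Methods

`odcdecode` implements a depth-resolved multivariate decoding analysis of
ocular dominance columns (ODCs) in human V1, together with a synthetic
generator that produces block-design fMRI sessions with known columnar
ground truth.  This note documents the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic validation does
and does not establish about real data.

## Depth convention

Relative cortical depth runs from 0 at the GM/WM boundary to 1 at the
GM/CSF (pial) boundary, everywhere in the package.  The thalamorecipient
layer 4C — where monocular LGN input terminates — sits at roughly 73% of
cortical depth measured from the pial surface, i.e. at **0.27** in this
convention.  Statements like "deeper" always mean toward the white matter.

## Synthetic ODC sessions

**Ocularity pattern.**  ODCs form stripes of alternating eye preference
about 1 mm wide.  The generator band-pass filters white Gaussian noise on a
flattened rectangular patch with an annular Gaussian filter in the 2D
spatial-frequency domain (center `main_frequency`, width `bandwidth`,
cycles/mm), normalizes to unit variance and squashes through
`tanh(sharpness * x)`.  This is the simplest generative model that yields a
stripe pattern with a controllable dominant wavelength; it makes no claim to
the anisotropy or eccentricity scaling of real ODC maps.  Defaults:
`main_frequency = 0.5` cycles/mm (1 mm half-period columns),
`bandwidth = 0.1`, `sharpness = 3` (mostly saturated ocularity with soft
column borders).

**Laminar selectivity.**  The per-depth monocularity profile is a Gaussian
bump centered at depth 0.27 (sd 0.15) on a binocular floor of 0.3, scaled to
peak at 1.  Above and below layer 4C binocular convergence reduces but never
abolishes eye preference, hence the floor.  A vertex with ocularity `o`
responds to its preferred eye with amplitude `|o|` and to the other eye with
`|o| * (1 - m_d)`, where `m_d` is the monocularity at depth `d`; the
decodable left-right contrast is therefore `|o| * m_d`, maximal at the input
layer.

**Draining-vein accumulation.**  Deoxygenated blood drains toward the pial
surface, displacing and amplifying hemodynamic signals upward.  The model is
a linear running depth-integral: the drained amplitude at depth `d_i` is
`s(d_i) + lambda * sum_{j<i} s(d_j) * dd`, multiplied by `sign *
base_amplitude`.  `lambda` defaults encode the qualitative macrovascular
sensitivity ordering of the contrasts: GE-BOLD 2.0 > SE-BOLD 1.0 > VASO 0.3
(per unit relative depth).  The linear form is a deliberate simplification —
it has one interpretable parameter and produces the monotone pial-ward PSC
increase seen empirically; it does not model intracortical vein geometry.

**Time series.**  Condition boxcars are convolved with a canonical
double-gamma HRF (peak 6 s, undershoot 16 s, dispersions 1 s, undershoot
ratio 1/6, 32 s support, normalized to unit integral so a 30 s block
plateaus at its amplitude).  The reference design is 10 runs of 270 s at TR
3 s: 15 s baselines at both ends and eight 30 s blocks, four per eye, in a
per-run pseudorandomized order.  Signals are placed on a baseline level of
100 so amplitudes read directly in percent signal change.  Noise is white
Gaussian per volume and vertex (optional AR(1)); the scalar `noise_sd` is
scaled across depth from 0.8x at GM/WM to 1.2x at the pial surface,
reflecting the higher physiological variability (CSF pulsatility, partial
voluming) of superficial layers.  A slow cosine drift (period twice the run
length, random phase) is added per run.

Defaults `base_amplitude = 2%` and `noise_sd = 5%` correspond to a temporal
SNR of ~20, a realistic figure for 0.8 mm isotropic 7 T acquisitions, and
produce single-time-point decoding accuracies in the 70–95% range across
depth — the regime reported for GE-BOLD ODC decoding — rather than
saturated or chance-level performance.

**VASO.**  VASO sessions emit interleaved blood-nulled / not-nulled volume
pairs at an effective TR of 5 s.  The nulled series carries the
CBV-weighted response with inverted sign and drain 0.3, multiplied by
`(1 + eps * BOLD(t))` as residual BOLD contamination (`eps = 1` by default,
i.e. the full GE-like BOLD weighting that the dynamic division removes
exactly; smaller `eps` leaves a deliberate mismatch).  The not-nulled series
is a pure GE-like BOLD response.

**Volume representation.**  Vertex-depth samples are deposited into a
voxel grid aligned with the patch (one voxel per vertex and depth plane),
and the analysis pipeline samples them back through the generic trilinear
volume-to-surface interpolation.  With the default geometry the round trip
is exact, which is intentional: it exercises the sampling machinery without
conflating the validation with interpolation loss.  Real data add
registration error, curvature and partial voluming that this layout does not
emulate.

## Preprocessing

* **High-pass filtering** regresses out a discrete-cosine basis spanning all
  periods longer than the cutoff (default 1/270 Hz, the run length; the
  retinotopy rule is 1/(3 x cycle period), giving 1/192 and 1/96 Hz for the
  wedge and ring).  The projection is idempotent, and `glm_fit` applies the
  same basis removal to its condition regressors, making "filter then fit"
  exactly equivalent to including the basis as confounds.
* **VASO correction** linearly interpolates (edge hold) nulled and
  not-nulled series onto a common 3 s grid anchored at the run start, then
  divides nulled by not-nulled per voxel and time point.  Denominators below
  10% of the voxel's temporal median are clamped to that floor and flagged —
  the floor prevents ratio blow-up in low-signal voxels; all-zero
  denominators yield a flagged output of 1.
* **GLM** is ordinary least squares on [left ⊗ HRF, right ⊗ HRF, per-run
  intercepts]; no prewhitening is applied, so nominal statistics assume
  temporally white residuals.  t is converted to z by two-sided tail
  matching at the residual degrees of freedom (clipped at 40 sigma).
* **Percent signal change** uses block means by default: stimulation volumes
  minus the first two of each block (the same transient-discard rule as the
  decoder), against baseline volumes minus the first two after each block
  ends — the symmetric rule avoids counting decaying responses as baseline.
  A GLM-beta-based estimator is provided as an alternative.  VASO PSC keeps
  its native (negative) sign and carries a display-inversion flag.
* **Retinotopy phase maps** discard the first quarter stimulus cycle,
  project the remaining integer number of cycles onto the stimulus
  frequency, conjugate the reversed-direction run's coefficient and average,
  cancelling the hemodynamic lag.  Phase is reported for a
  `cos(2*pi*f*t - phase)` response in [-pi, pi).

## Surface sampling

Layers are **equidistant**: layer k of n sits at fraction k/(n-1) along the
white-to-pial segment per vertex (9 intermediate surfaces -> 11 layers).
An equivolume variant (closed form for a linearly varying local area) is
available behind a flag but is never the default.  Volume-to-surface
transfer is trilinear; vertices outside the field of view are flagged NaN
and excluded downstream — the exclusion policy is "missing in any session,
excluded from all".

## Decoding

Retention keeps stimulation volumes only, minus the first two per block:
64 time points per run (32 per eye), 576 training points under
leave-one-run-out with 10 runs.  Per fold, vertices are scored with a
one-way two-group ANOVA F computed on the training runs; by default the
training data are **averaged across depth** first so a single top-200 vertex
set is used at every depth (honoring columnar structure); single-depth and
per-depth selection policies are available for the selection-depth
sensitivity analyses.  Ties in F are broken by ascending vertex index for
cross-platform determinism.  Features are z-scored per vertex with
training-fold statistics applied to the held-out run (the only choice that
avoids leakage; per-time-point scaling is available behind a flag for
sensitivity analysis).  The classifier is a linear soft-margin SVM with
C = 1 — no kernel, no class weights, no calibration.  Constant training
features are set to 0 after standardization, with a warning.

## Statistics

* **Repeatability**: Spearman rank correlation between two sessions'
  per-vertex z-maps, restricted to one seeded random 10% vertex subsample to
  blunt spatial autocorrelation; the null shuffles the second map's
  subsampled values (default n = 10,000).  The corrected p-value adds an
  upper bound of three binomial standard deviations to the exceedance count:
  `p = (k + 3*sqrt(n*p_hat*(1-p_hat))) / n`, floored at 1/n (a permutation
  test cannot resolve smaller p) and declared significant below 0.05.
  The default tail tests the a-priori **positive** alternative — the
  direction a repeatability analysis predicts — which keeps exact type-I
  control; a tail chosen post hoc in the direction of the observed r
  roughly doubles the false-positive rate near threshold and is available
  (with a two-sided option) for sensitivity checks only.
* **Depth profiles** carry 95% percentile bootstrap CIs (n = 1,000).  The
  resampled units are meant to be (participant, session) pairs; a single
  synthetic session has neither, so the pipeline resamples cross-validation
  folds instead and labels them as such.  Fold accuracies are not fully
  independent (shared training data), so these CIs are mildly optimistic —
  acceptable for the synthetic validation, noted for real use.
* **Per-depth significance vs chance**: one-sided bootstrap p-value
  (fraction of resampled means at or below 50%), Benjamini-Hochberg
  corrected across the 11 depths.  BH is order-preserving and monotone but
  not idempotent; q-values are reported, not re-adjustable.

## Validation design

The mechanism-recovery experiment decodes sessions simulated with
`base_amplitude = 1%` against `noise_sd = 5%` so accuracy stays clearly off
both chance and ceiling and the depth of peak accuracy is identifiable; the
drain sweep compares `lambda = 0` (peak expected at the neuronal peak,
0.27 ± one layer) with `lambda = 8` (peak and PSC pushed toward the pial
surface).  Desk-scale problem sizes — a 48 x 48 vertex patch at 0.4 mm
(32 x 32 for the sweep), 11 depth planes, 10 runs — keep a full session
analysis around ten seconds while preserving every procedural element of
the analysis.

**What passing does and does not show.**  The synthetic data share the real
acquisition's timing, contrast conventions and analysis path, but have
white (optionally AR(1)) noise, perfect vertex correspondence, no motion,
no distortion, and a drain model with a single free parameter.  Passing
therefore validates the *procedure* — retention arithmetic, leakage-free
cross-validation, calibrated inference, and the direction of
drain-induced depth biases — not the magnitude of any real-data effect.

## Known limitations

* OLS without prewhitening; with AR(1) noise enabled, nominal GLM z-scores
  are optimistic.
* The voxel grid is axis-aligned with the sheet; oblique geometries exercise
  the interpolation more than the synthetic default does.
* Equivolume layering assumes linear area variation between boundaries.
* The generator pools column width across the patch; real ODC width varies
  with eccentricity.
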