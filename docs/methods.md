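# Methods

## The problem

Distributed MEG source estimation solves the underdetermined linear system
`d = L j` (data `d`, leadfield `L`, source currents `j`) with a linear
operator `ĵ = G d`. Substituting gives `ĵ = G L j = R j`: the resolution
matrix `R` fully characterizes a linear estimator. Its columns are
point-spread functions (PSFs — how a point source is smeared) and its rows
are cross-talk functions (CTFs — how all sources leak into one location's
estimate).

`megres` compares three estimators on synthetic multi-subject cohorts:

* **MNE** — `G = Lᵀ (L Lᵀ + λC)⁻¹`, with noise covariance `C` and
  regularization `λ`.
* **dSPM** — MNE rows divided by the projected noise standard deviation,
  `wᵢ = 1/√([G (C/n_averages) Gᵀ]ᵢᵢ)`.
* **sLORETA** — MNE rows divided by `√([G L]ᵢᵢ)`, the square root of the
  resolution-matrix diagonal.

Both normalizations are diagonal row scalings of `G`, so they reshape PSFs
(columns of `R`) but only rescale CTFs (rows). Three consequences are exact
and are asserted in the acceptance tests: the MNE resolution matrix
`Lᵀ(LLᵀ+λC)⁻¹L` is symmetric (MNE's PSF and CTF maps coincide); CTF-mode
DLE and SD maps are identical for all three methods; and sLORETA's PSFs peak
exactly at the true source (zero dipole localization error, a Cauchy–Schwarz
consequence of the `M⁻¹`-inner-product structure of `R`).

## Resolution metrics

For each PSF/CTF `F` of target source `i` (distances in cm):

* **DLE** = ‖x_peak − xᵢ‖, the distance of the peak of |F| from the true
  source. Peak ties break toward the lowest index (deterministic; logged).
* **SD** = √( Σⱼ dᵢⱼ Fⱼ² / Σⱼ Fⱼ² ), reported in √cm. The amplitude
  weighting exponent is a parameter (`weight_exponent`, default 2).
* **OA** = Σⱼ |Fⱼ|, normalized per subject to its maximum at the map level,
  since only relative amplitudes between locations are interpretable.

Distances are 3-D Euclidean, not geodesic along the shell; a geodesic
variant is a documented extension point, not implemented.

## Synthetic cohort

There is no real data anywhere in the pipeline; the generator emulates the
structure a resolution study needs.

* **Sensors.** 102 magnetometers + 204 planar gradiometers (defaults) on the
  upper hemisphere of a 12 cm helmet, quasi-uniform via a golden-angle
  spiral with seeded tangential jitter. Each site carries one magnetometer
  and a co-located orthogonal gradiometer pair. Gradiometers are two-point
  finite differences across a 16.8 mm baseline.
* **Conductor and forward model.** A homogeneous sphere of radius 9 cm with
  the analytic (Sarvas) dipole field. This preserves what the analysis rests
  on — steep depth falloff and silent radial sources — while being
  dependency-free and exact. No depth weighting; fixed orientations.
* **Source space.** ~500–1000 dipoles on a folded shell
  `r(θ,φ) = (R − 10 mm) − fold_depth·(1 + sin kθ · sin kφ)/2` with
  `fold_depth` 30 mm and `k = 6`: the corrugations stand in for gyri/sulci,
  giving a ~30 mm depth range and non-radial surface-normal orientations on
  fold walls. The 10 mm stand-off between conductor surface and the
  shallowest sources plays the role of the scalp/skull/CSF layers and leaves
  room for per-subject jitter without escaping the conductor.
* **Cohort.** Every subject is the shared template after a small rigid
  rotation (angular scale `jitter_scale / R`) plus vertex-wise Gaussian
  position jitter (`jitter_scale`, default 2 mm). Vertex `i` corresponds
  across subjects by construction, replacing surface morphing.
* **Noise.** Baseline samples are a mixture
  `√(1−f)·white + √f·(L q)/√v`, `v = trace(LLᵀ)/n_channels`, `f` the brain
  noise fraction (default 0.5); the covariance is the two-pass sample
  covariance of `146 trials × 200 ms` at 250 Hz (7300 samples, full rank for
  306 channels). The sampling rate is a free parameter since only the sample
  count matters.

What this does **not** emulate: realistic skull/tissue conductivity, cortical
geometry beyond a sinusoidal fold, sensor noise with vendor-specific spectra
or cross-talk, environmental artifacts, and head-position variability beyond
a rigid rotation. Passing tests therefore demonstrate the estimator theory
and the pipeline's correctness, not performance figures for any real system.

## Regularization and numerical choices

* `λ = trace(LLᵀ)/(trace(C)·snr²)` with `snr = 3` by default: the noise term
  `λC` carries `1/snr²` of the signal term's average sensor power. A welcome
  corollary is invariance to the overall scale of `C`. `λ` can be passed
  explicitly to bypass the convention.
* dSPM scales `C` by `1/n_averages` (default 100) for its weights only; the
  operator itself is built from unscaled `C` (rescaling there would merely
  rescale `λ`'s meaning).
* The MNE system is solved by Cholesky (`scipy.linalg.solve`, `assume_a=
  "pos"`); on failure a one-shot diagonal loading of `1e-10 × mean(diag)` is
  applied and logged. Condition numbers are logged.
* Zero-variance vertices in paired t-tests (exactly the CTF-mode contrasts,
  which are zero by theory) get `t = 0, p = 1` when the mean difference is
  zero, else `t = ±∞, p = 0` with a logged warning — never NaN.
* One master seed fans out through `numpy.random.SeedSequence` keyed on
  `(master_seed, stage_code, subject_index)`, so adding subjects does not
  perturb existing subjects' draws, and reruns are byte-identical (TSV/JSON
  are printed at 17 significant digits).
* Resolution matrices are dense; the config caps the source count at 4000
  by default (override `max_dense_sources`) to bound memory.

## Problem sizes

The shipped configuration and tests run a 17-subject cohort at 500 sources
and 306 channels — large enough for stable group statistics and the
depth-gradient findings, small enough that a full study completes in well
under a minute on one core. `n_sources` ≈ 1000–4000 reproduces the same
qualitative maps at finer granularity.

## Known limitations

* EEG, free/loose orientations, depth weighting and beamformers are out of
  scope.
* The spherical conductor makes truly radial sources silent; the folded
  shell avoids exactly-radial orientations in practice, but sensitivity near
  fold crests is low and OA maps span several orders of magnitude, as
  expected for MEG.
* Group statistics are uncorrected for multiple comparisons by default
  (a Bonferroni option exists in `significance_mask`).
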