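# megres

Resolution analysis of noise-normalized minimum-norm MEG source estimators.

`megres` is for researchers who use distributed source estimates (MNE, dSPM,
sLORETA) and want to quantify what those estimators can and cannot resolve.
It builds fully synthetic multi-subject MEG "cohorts" — helmet sensor
arrays, folded-shell source spaces with gyrus/sulcus-like depth variation,
and simulated baseline noise covariances — computes analytic
spherical-conductor leadfields, assembles the three inverse operators, and
evaluates their resolution matrices through point-spread and cross-talk
functions.

## The model

A linear estimator `ĵ = G d` applied to `d = L j` gives `ĵ = R j` with
resolution matrix `R = G L`. Columns of `R` are point-spread functions
(PSFs), rows are cross-talk functions (CTFs). The estimators are

* MNE: `G = Lᵀ (L Lᵀ + λC)⁻¹`, `λ = trace(LLᵀ)/(trace(C)·snr²)`, snr = 3,
* dSPM: MNE rows × `1/√([G (C/n_avg) Gᵀ]ᵢᵢ)` (projected-noise units),
* sLORETA: MNE rows × `1/√([G L]ᵢᵢ)` (resolution-matrix diagonal).

Each PSF/CTF is summarized by dipole localization error (DLE, cm), spatial
dispersion (SD, √cm) and overall amplitude (OA, normalized per subject);
per-subject maps are aggregated into grand averages, difference maps,
across-subject SDs and paired two-tailed t-test maps on a shared template
source space. See `docs/methods.md` for the full account.

## Worked example

```python
import megres as m

arr = m.make_sensor_array(102, 204, helmet_radius=0.12, seed=1)
src = m.make_source_space(500, conductor_radius=0.09, fold_depth=0.03,
                          fold_frequency=6, seed=2)
L = m.build_leadfield(arr, src)
cov = m.simulate_noise_covariance(arr, L, n_trials=146, baseline_duration=0.2,
                                  sampling_rate=250, brain_noise_fraction=0.5,
                                  seed=5)
for method in ("MNE", "dSPM", "sLORETA"):
    op = m.make_inverse_operator(L, cov, method, snr=3.0)
    R = m.resolution_matrix(op, L)
    maps = m.metric_maps(R, "PSF", src)
    print(method, "max DLE %.2f cm" % maps.dle.max(),
          "mean SD %.2f sqrt-cm" % maps.sd.mean())
```

prints

```
MNE max DLE 9.64 cm mean SD 1.75 sqrt-cm
dSPM max DLE 4.38 cm mean SD 1.86 sqrt-cm
sLORETA max DLE 0.00 cm mean SD 1.84 sqrt-cm
```

— the expected picture: the unnormalized MNE mislocalizes deep sources by
centimeters but produces the most focal spread; dSPM roughly halves the
worst-case localization error; sLORETA localizes every point source exactly
(zero DLE) at the cost of MNE-level dispersion. Because both normalizations
only rescale rows of `R`, CTF-mode DLE/SD maps are identical for all three
methods.

A full study (cohort, operators, metric maps, group contrasts, summary) runs
from the command line:

```sh
megres run-all --set n_subjects=5 --set n_sources=300 --output-dir out/
```

or stage by stage (`megres simulate / forward / invert / metrics / group`),
with `--config study.yaml` for file-based configuration. Outputs are TSV
tables (17 significant digits; byte-reproducible for a fixed `master_seed`)
plus a `summary.json`.

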