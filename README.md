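# phantomiq

Simulation and analysis of PET image quality on the NEMA IEC body
phantom, built to study how the positron energy of a nuclide (F-18,
Ga-68, Cu-64) affects spatial resolution and quantitative image quality
on a modern digital PET/CT.

Positrons from Ga-68 carry roughly three times the endpoint energy of
those from F-18 or Cu-64 and therefore travel much farther in water
before annihilating (mean range 3.5 mm vs 0.6 / 0.7 mm). This extra
travel acts as an additional blur on top of the scanner's point-spread
function (PSF) and degrades recovery of small structures. `phantomiq`
provides:

* **a digital phantom generator** — the IEC body phantom (six fillable
  spheres of 10–37 mm diameter on a 114.4 mm ring, cold 50-mm lung
  insert, torso-shaped background compartment) rasterized with
  partial-volume-exact edge voxels, then degraded in image space with
  Gaussian system + positron-range blur (combined in quadrature), an
  optional unsharp-mask edge overshoot emulating the Gibbs artifact of
  PSF reconstruction, and Poisson count noise scaled to a target number
  of true events;
* **the NEMA NU 2-style metric suite** — background-corrected 50%
  isocontour sphere segmentation, recovery coefficients
  (RC_mean / RC_max / RC_peak with the 12-mm SUV_peak ball), percent
  background variability (CoV_BG over three ≥ 61 mL VOIs), contrast
  recovery coefficient CRC = 100·(measured ratio − 1)/(true ratio − 1),
  contrast-to-noise ratio CNR = (S_mean − B_mean)/B_sd, and the relative
  count error in the lung insert;
* **a sphere-profile resolution estimator** — the exact radial profile of
  a homogeneous sphere convolved with a 3D Gaussian,
  C(r) = S·g(r; R, σ) + B·(1 − g(r; R+w, σ)), fitted to shell-binned
  image data by weighted nonlinear least squares with the sphere radius
  R and wall w fixed, yielding FWHM = 2√(2 ln 2)·σ per sphere;
* **nuclide physics** — a registry of β⁺ yields, half-lives, energies and
  positron ranges, plus the closed-form acquisition-duration matching
  that equalises expected true counts between nuclides,
  N(T) = yield·A₀·(1 − e^(−λT))/λ;
* **comparison reporting** — end-to-end simulate → analyze → fit runs
  assembled into reproducible JSON/CSV reports, and exact re-computation
  of the published study's headline percentages from its packaged
  acquisition and FWHM tables.

## Worked example

```python
import phantomiq as pq

for nuclide, seed in (("F18", 1), ("Ga68", 2)):
    cfg = pq.ExperimentConfig(nuclide=nuclide, seed=seed, shape=(120, 120, 120))
    rep = pq.run_experiment(cfg)
    s10 = rep.per_sphere[0]
    print(
        f"{rep.nuclide:>4}: FWHM {rep.resolution[0]:.2f} +/- {rep.resolution[1]:.2f} mm | "
        f"10-mm sphere RC_mean {s10.rc_mean:.2f}, CRC {s10.crc:.1f}%, CNR {s10.cnr:.1f} | "
        f"CoV_BG {100*rep.cov_bg:.1f}%"
    )
```

prints

```
 F18: FWHM 3.86 +/- 0.05 mm | 10-mm sphere RC_mean 0.85, CRC 79.9%, CNR 15.7 | CoV_BG 15.3%
Ga68: FWHM 7.68 +/- 0.06 mm | 10-mm sphere RC_mean 0.50, CRC 33.9%, CNR 6.8 | CoV_BG 15.1%
```

Both runs use the same scanner PSF (4.4 mm FWHM) and the same target of
7.1×10⁷ true counts; the only difference is the positron-range kernel.
Ga-68's 3.5-mm mean range roughly doubles the fitted FWHM and halves the
contrast recovery and contrast-to-noise ratio of the 10-mm sphere, while
background noise (CoV) stays the same — the positron range, not count
statistics, drives the loss.

A command-line interface mirrors the library:

```bash
phantomiq simulate --nuclide Ga68 --ratio 4 --weight normal --trues 7.1e7 --seed 3 --out run/
phantomiq analyze --image run/image.nii.gz --spec run/provenance.json --out run/report/
phantomiq fit-resolution --image run/image.nii.gz --spec run/provenance.json --out run/report/
phantomiq replicate-tables
```

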