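# nanofret

Ratiometric FRET imaging pipeline for quantifying the integrity of lipid
nanocarriers in living animals.

Lipid nano-emulsion droplets co-encapsulating a near-infrared FRET dye pair
(a Cy5.5-type donor emitting near 700 nm and a Cy7.5-type acceptor near
820 nm) report on their own intactness: while a droplet is intact the dyes sit
within Förster distance and donor excitation yields acceptor emission; when
the droplet disintegrates the dyes dilute into the surrounding tissue lipids
and FRET is lost. Imaging both emission channels in a whole-animal setup
therefore turns carrier integrity into a measurable, concentration-independent
ratio. This package implements the complete analysis chain for such
experiments, for researchers developing nanocarrier drug-delivery systems or
whole-animal NIR imaging assays:

- **Calibration** — the empirical exponential law linking the proximity ratio
  `E = A/(A+D)` to integrity `x` (percent of dye pairs still co-encapsulated),

  `E(x) = a + b·exp(c·x)`,

  fitted to mixture-plate series by nonlinear least squares
  (`CalibrationModel`) and inverted analytically, with out-of-range ratios
  clamped and flagged.
- **Synthetic phantoms** — a forward model generating two-channel 16-bit image
  time series of a stylized mouse with region-specific integrity decay,
  concentration kinetics, autofluorescence backgrounds and shot/read noise,
  so the whole inverse pipeline is testable end to end without animal data.
- **Ratio imaging** — pixel-wise A/D division above an intensity floor and
  intensity-modulated pseudocolor rendering (hue = ratio, blue → red;
  brightness = summed channel intensity).
- **ROI quantification** — region means, background correction against the
  pre-injection frame of the same region, proximity ratio, calibration
  inversion, and replicate aggregation (mean ± SEM over subjects).
- **Kinetics** — four-parameter logistic fits of integrity time courses
  `y(t) = a2 + (a1−a2)/(1+(t/x0)^p)` with a closed-form 50%-crossing
  half-life, and mono-exponential clearance fits for donor-only controls.

## Worked example

Simulate three replicate healthy-mouse phantoms, quantify the liver region,
and fit its disintegration kinetics:

```python
import tempfile
import nanofret as nf
from nanofret.kinetics import LogisticDecayModel

scn = nf.builtin_scenarios(seed=1)["healthy"]
with tempfile.TemporaryDirectory() as d:
    manifests = [nf.generate_timeseries(nf.replicate(scn, i), f"{d}/rep{i}")
                 for i in range(3)]
    courses = nf.integrity_timecourse(manifests, nf.DEFAULT_CALIBRATION)
    liver = courses["liver"]
    print(liver.data.round(3).to_string(index=False))
    print(LogisticDecayModel(liver.times, liver.values).fit().summary())
```

prints

```
 time_h  value   sem  n         flags
   0.25 99.922 0.039  3 above_ceiling
   1.00 98.872 0.013  3
   2.00 95.236 0.007  3
   3.00 89.429 0.012  3
   6.00 65.953 0.018  3
  24.00  9.271 0.049  3

Logistic decay fit: y = a2 + (a1 - a2)/(1 + (t/x0)^p)
  n points: 6   RSS: 1.822e-04
  a1 = 99.99 %   a2 = 0.08367 %
  x0 = 8.183 h   p = 2.128
  integrity half-life: 8.19 h
```

Each row is the mean liver integrity over the three phantoms at one imaging
time (SEM over subjects; the 15-minute point saturates the calibration
ceiling and is flagged). The logistic fit summarises the decay: carriers in
the liver start intact (`a1 ≈ 100%`), disintegrate completely (`a2 ≈ 0%`),
and cross 50% integrity at about 8.2 h — the integrity half-life.

The same workflow is available from the shell:

```
nanofret simulate --scenario healthy --out run0 --seed 1
nanofret quantify --manifest run0/manifest.json --out run0/timecourse.csv
nanofret kinetics --timecourse run0/timecourse.csv --out run0/fits.json
nanofret ratio-image --manifest run0/manifest.json --time 6 --out run0/ratio6h.png
```

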