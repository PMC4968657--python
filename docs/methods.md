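# Methods

## The measurement model

The package treats nanocarrier integrity as an operational quantity defined by
a mixture calibration: 100% integrity is the intact FRET formulation (donor
and acceptor co-encapsulated at 1% each), 0% a mixture of single-dye carriers
at matched total dye concentration, and intermediate levels the fraction of
dye pairs belonging to intact FRET carriers. Imaging a dilution plate of such
mixtures on the same two-channel setup used in vivo gives the proximity ratio
`E = A/(A+D)` per level, which follows an exponential law

    E(x) = a + b·exp(c·x),  x = integrity in percent,

with default parameters a = 0.14572, b = 0.1254, c = 0.01748 (the published
calibration for the Cy5.5/Cy7.5 nano-emulsion system). The law is empirical;
the package deliberately does not model the underlying photophysics (spectral
overlap, Förster radius, linear-mixing of intact/disintegrated populations).
Its role is only to be monotone, fitted once per setup, and invertible:

    x(E) = ln((E − a)/b)/c,

clamped to [0, 100]. Ratios at or below `a` are common late post-injection —
the carriers have disintegrated beyond the model's floor — and are reported as
0% with a `below_floor` flag rather than raised as errors; symmetrically for
ratios at or above `E(100)`. `E` is a semi-quantitative surrogate for FRET
efficiency (it uses band/channel intensities, not corrected quantum yields),
which is exactly why the empirical calibration, acquired on the same
instrument with the same filters, is needed to interpret it.

The in vivo chain per region and timepoint is: ROI mean per channel →
subtraction of the same region's pre-injection mean (per channel) →
`E = A/(A+D)` → inversion to integrity. Background correction is ROI-matched
because autofluorescence differs strongly between regions; corrections that
come out non-positive are flagged (`insufficient_signal`) and, when both
channels are dead, the record is dropped instead of producing a negative
ratio. With replicate subjects, the subject-level ROI means are the unit of
analysis and dispersion is the SEM over subjects.

Integrity time courses are summarised with a four-parameter logistic decay

    y(t) = a2 + (a1 − a2)/(1 + (t/x0)^p),

fitted by bounded least squares (trf), and the integrity half-life is the
earliest 50-absolute-percent crossing, in closed form
`t½ = x0·((a1−a2)/(50−a2) − 1)^(1/p)`. The 50%-crossing definition (rather
than the midpoint x0) matters only when the plateaus differ from 100/0; when
`a2 ≥ 50` the half-life is reported as not reached rather than extrapolated.
Donor-only control series are fitted with a mono-exponential
`I(t) = I0·2^(−t/τ)` whose τ is the circulation half-time.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| calibration (a, b, c) | 0.14572, 0.1254, 0.01748 | ratio offset (–), amplitude (–), rate (per integrity %) of the setup's law |
| intensity floor | background mean + 2·SD of the pre-injection frame | pixels below it are invalid in ratio images; the floor is a display/validity threshold, not part of ROI quantification |
| display range | A/D at 0% and 100% integrity (≈0.372 … 6.458) | pseudocolor hue window, so blue/red map to the calibration extremes |
| logistic bounds | 0 ≤ a2 ≤ a1 ≤ 110, x0, p > 0 | the 110% ceiling tolerates noise overshoot above the physical 100% |
| t-test | Student (equal variance) | Welch available via `equal_var=False` |
| QY windows | donor 690–760 nm, acceptor 790–900 nm | bracket the ~700 and ~820–840 nm emission bands |

## The phantom generator

`synthetic` encodes ground truth as a stylized supine mouse on a 256×256
16-bit grid with four disjoint regions (tail vein, liver, tumor site, body).
Each region has an integrity schedule (logistic), a concentration schedule and
a brightness scale; the forward model splits the total expected signal
`S(t) = brightness·concentration(t)` between channels through the calibration
law itself (acceptor = E·S, donor = (1−E)·S), so donor + acceptor = S exactly
and the forward and inverse models are consistent by construction. Channel
backgrounds (donor 40, acceptor 4 counts — the acceptor channel is ~10× darker
before injection) are added, then Poisson shot noise, Gaussian read noise
(σ = 5 counts) and 16-bit quantization. The pre-injection frame (t = 0)
contains background and noise only. Default imaging times are
{0, 0.25, 1, 2, 3, 6, 24} h.

Quantization is treated as part of the noise model: with noise disabled the
generator emits exact expected counts as float32 TIFFs. This keeps the
noiseless end-to-end contract exact (recovered integrity equals the schedule
to well under 0.1 point at every region and time), which rounding to uint16
would break at low-signal late timepoints.

Built-in scenarios encode the observed endpoints as ground truth:

- **healthy** — liver: logistic 100→0% with x0 = 8.2 h and steepness solved in
  closed form through 66% at 6 h (p = 2.1234; verified against an independent
  root-finder); blood (tail vein): p = 2 logistic through 93% at 6 h
  (x0 = 21.87 h); blood concentration clears exponentially with a 3 h
  half-time, liver uptake saturates with a 0.75 h rise time.
- **tumor_bearing** — tumor: logistic through 77% at 2 h with x0 = 4.4 h
  (p = 1.5325), giving 38.3% at 6 h; tail vein: p = 2 logistic through 71% at
  6 h (x0 = 9.39 h); tumor uptake saturates with a 0.35 h rise time (near its
  plateau by 2 h).
- **donor_only** — all carrier signal in the donor channel; tail-vein
  concentration clears with the 3 h half-time.

Brightness scales (3000 counts per region at unit concentration) put
early-timepoint ROI signals well above background while leaving the 24 h tail
vein near the background floor, which exercises the flagging path. The blood
steepness p = 2 is a modelling choice (only the 6 h endpoints pin the blood
curves); region geometry, backgrounds and noise levels are stated choices of
realistic magnitude, not measured values — no camera SNR specification was
available to reproduce.

What the phantoms do **not** emulate: wavelength-dependent tissue absorption
and scattering (light-penetration depth), organ overlap in projection, subject
motion, spatially varying autofluorescence, or vignetting. Passing the
round-trip tests therefore shows the inverse pipeline is correct and unbiased
under the stated forward model, not that in vivo estimates are free of
optical-path systematics.

## Numerical choices

- Calibration fitting: `scipy.optimize.least_squares` (trf) with bounds
  (0, 1] on all three parameters, xtol 1e-10, ≤1500 function evaluations;
  default start a ≈ min ratio, b ≈ ratio span, c from the log-slope over the
  level range — positivity is guaranteed by construction. A noiseless series
  is recovered to <1e-6 relative; ≥4 distinct levels are required.
- Logistic fitting: trf with tolerances 1e-15 so noiseless round trips
  recover parameters to 1e-5 relative even when a plateau sits on a bound;
  start a1 = first value, a2 = last value, x0 = time of the value nearest the
  plateau midpoint, p = 2. Constant series and fitted-increasing solutions
  raise a degenerate-fit error rather than returning a misleading object.
- Ratio images keep float64 ratios in memory (the algebraic identity
  ratio·donor = acceptor holds to 1e-9); float32 is only a storage format.
- RNG streams derive from `SeedSequence(scenario seed, spawn_key=(time index,
  channel index))`, so every frame is bit-reproducible independently of
  generation order, and replicates differ only by their seed offset.
- Time-course aggregation drops a (region, time) record only when every
  subject lost both channels; per-subject losses reduce n for that record.

## Problem sizes

Tests and the acceptance script use the scenario defaults (256×256 frames,
7 timepoints, 2 channels, 3 replicates per scenario); a full scenario
simulation plus quantification runs in roughly a second, the complete
acceptance script in a few seconds.

## Known limitations

- The calibration floor compresses everything below ~27% ratio into 0%
  integrity; uncertainty near the extremes is strongly asymmetric and is
  reported only through flags, not error bars.
- Half-life estimation assumes the logistic family; multi-phase disintegration
  would bias x0 and p jointly.
- The t-test helper is the plain two-sample test on subject means; no
  correction for multiple regions/timepoints is applied.
- The spectroscopy module's quantum-yield routine uses integrated band areas
  (the standard relative method) while the proximity ratio uses band maxima;
  the two are distinct statistics and are deliberately not interchangeable.
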