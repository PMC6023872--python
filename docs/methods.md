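# Methods

`fretblink` analyses the photophysics of photo-modulatable (PM)
fluorophores whose excited-state kinetics are reshaped by Förster
resonance energy transfer (FRET) to a nearby photostable acceptor dye.
The pipeline covers four measurement modalities: bulk/closed-form FRET
arithmetic, TCSPC lifetime decays, single-molecule blinking movies of
immobilized emitters, and live-cell single-particle trajectories.  Every
analysis stage has a synthetic counterpart that generates its input with
known ground truth, which is how the package validates itself.

## FRET arithmetic (`fret_core`)

Efficiencies come from donor quenching, either steady-state
(`E = 1 - I_D'/I_D`) or time-resolved (`E = 1 - tau_DA/tau_D`, using
amplitude-weighted mean lifetimes).  The distance law
`E = 1/(1 + (r/R0)^6)` and its inverse `r = R0 ((1-E)/E)^(1/6)` connect
efficiency to donor-acceptor separation.

The Förster radius is computed from

    R0^6 = (9 ln10 / 128 pi^5 N_A) * (kappa^2 Q_D / n^4) * J,
    J    = \int f_D(lambda) eps_A(lambda) lambda^4 dlambda,

with the donor emission `f_D` **area-normalized to unit integral** over
the common wavelength range — the standard convention that gives J units
of M^-1 cm^-1 nm^4.  The nm-scale prefactor is derived by dimensional
analysis (1 M^-1 = 1e24 nm^3/mol, 1 cm^-1 = 1e-7 nm^-1), giving
`R0 = 0.02108 nm * (kappa^2 n^-4 Q_D J)^(1/6)`, the familiar
0.211-Angstrom constant.  The unit bookkeeping is cross-checked in the
test suite against an independent SI-unit evaluation.

Defaults: `kappa^2 = 2/3` (freely rotating dipoles), `n = 1.33`
(aqueous).  Spectra are tabulated two-column text, linearly interpolated
onto the union of grid points in the overlap range and integrated by the
trapezoid rule; spectra are smooth, so higher-order quadrature buys
nothing.  Negative efficiencies produced by noise (`I_D' > I_D`) are
clipped to 0 with a warning: small negative E is common in
single-molecule data and a hard error would be wrong, but silently
propagating it would corrupt distance inversions.

## TCSPC lifetime fitting (`lifetime_fit`)

Decays are **tail-fitted** (no IRF deconvolution) to

    I(t) = I_bkgd + sum_i alpha_i exp(-t/tau_i),   i = 1..3,

inside a time window, by default 1.5–7.0 ns.  The model is linear in the
background and amplitudes, so those are profiled out with non-negative
least squares (variable projection) and the nonlinear search runs over
log-lifetimes only, multi-started over the decades 0.3/1/3/10 ns — the
multi-exponential RSS surface is multimodal and a single start is not
trustworthy.  The lowest-RSS solution wins; ties resolve to the first
start in the fixed enumeration order, so fits are deterministic.

Lifetimes are bounded below by the histogram bin spacing: a component
faster than one bin is unresolvable and, if allowed, only chases
single-bin Poisson noise in the high-count region, which inflates the
selected model order.

Model order is chosen with the Bayesian Information Criterion

    BIC = ln[n](p + 1) + n(ln[2 pi RSS / n] + 1),  p = 2*order + 1,

and models are compared by the relative likelihood
`exp((BIC_min - BIC)/2)`.  RSS is always the **unweighted** residual sum
of squares, matching the BIC definition above; a Poisson-weighted fit is
available behind `weighting="poisson"`, but even then BIC is evaluated
on unweighted residuals so that model comparison stays consistent.  The
minimum of 50 photons is enforced per histogram within the fit window.

Two window conventions appear in the validation studies.  Mono-
exponential decays near 3 ns use the default 1.5–7.0 ns window.  For
resolving a 1 ns + 4 ns pair the window keeps the same tail start
(1.5 ns, past the steep high-dynamic-range region, which is the point of
tail fitting) but extends to 20 ns so the slow component decays to
background *inside* the window — otherwise background and slow lifetime
are nearly collinear over a window only ~2 lifetimes long, and the fit
rides a flat background/lifetime ridge.  That ridge, not optimizer
failure, is the dominant error source for short windows; the test suite
verifies the optimizer reaches the global minimum on profile scans.

The lifetime entering FRET efficiencies is the amplitude-weighted mean
`sum(alpha_i tau_i)/sum(alpha_i)`.

## Synthetic data (`synthetic_data`)

### Blinking traces

A molecule occupies one of four states: two fluorescent on-states, a
reversible dark (off) state, and an absorbing bleached state.  The
simulator draws **exact continuous-time exponential dwells** (on -> off
at `k_off`, on -> bleached at `k_bleach / bleach_protection`,
off -> on at `k_on`; photobleaching proceeds only from the excited
manifold, so the off state does not bleach) and then integrates state
occupancy over camera frames.  A frame's ground-truth label is its
majority-occupancy state; its noiseless signal is

    brightness_on * (1 - E) * (fraction of frame spent on),

so frames containing a switching event carry partial signal, exactly as
in real data.  A frame-quantized Markov chain was considered and
rejected: it cannot represent partial-frame occupancy at all, and its
geometric dwells are biased by about half a frame relative to `1/k`,
which breaks dwell-time recovery at realistic exposures.  The
continuous-time path costs nothing and makes the generator's dwell
statistics exact.

The two on-states differ only in brightness (ratio configurable, default
1.0 — i.e. identical); they exist so the four-state analysis model is
exercised, since heterogeneous on-state intensity is a property of real
PM fluorophores.  FRET enters twice: the emitted signal is scaled by
`1 - E`, and the bleach rate is divided by the phenomenological
`bleach_protection` factor (energy transfer depopulates the excited
state before it can enter the photobleaching pathway; no quantitative
mechanistic model is available, so a single factor is the honest
parameterization).

`brightness_on` is trace-level (ROI-mean) ADU for direct trace
simulation — matching the 300 ADU scale of the analysis model's priors —
and total PSF-integrated ADU for movie simulation, where conservation of
the rendered signal is the natural contract.  Photoconversion is modeled
as all molecules starting in an on-state at frame 1.

Camera noise is an effective model: optional Poisson shot noise at an
effective ADU/photon quantum, plus Gaussian read noise, plus (movies
only) a baseline offset.  EMCCD excess-noise statistics are deliberately
out of scope; the Gaussian-emission analysis model would not distinguish
them at the SNRs studied.

Defaults (`k_on = 0.1/s`, `k_off = 1/s`, `k_bleach = 1.2/s`,
300 ADU, 500 frames at 500 ms) describe a donor-only mEos3.2-like
emitter: sub-second on-times, a couple of switching events per molecule,
and most molecules bleached before the movie ends.

### Movies

Emitters are placed uniformly at random with a minimum separation
(rejection sampling with bounded attempts) and a border margin so every
ROI fits.  Each is rendered as a pixel-integrated 2-D Gaussian (erf over
pixel edges, unit mass) carrying its per-frame simulated signal; the
stack is offset, noise-corrupted, rounded and clipped to 16-bit.  No
optics beyond the Gaussian PSF: no astigmatism, z-dependence, drift, or
structured background.

### Decays

Expected counts per bin follow the multi-exponential model, optionally
rescaled to a total count budget, with Poisson sampling.  Scaled ground
truth (amplitudes, background) is returned alongside.

### Trajectories

Tracks jitter about their origin with iid per-axis Gaussian steps
(confined motion); with probability `p_directed` one directed segment of
constant velocity interrupts the confinement, emulating rare transitions
between confined and rapid linear motion.  Localization error is
Gaussian; missed detections are Bernoulli.  An optional FRET-state
mixture assigns each track an efficiency and scales its intensities by
`1 - E`.  Origins respect a minimum separation so ground-truth track
identity is well defined.

All generators are deterministic given their seed (byte-identical
repeat runs), with per-molecule substreams derived from the master seed.

## Movie analysis (`movie_analysis`)

Detection operates on a maximum-intensity projection of the first two
post-conversion frames.  The projection is filtered with a negated
Laplacian-of-Gaussian (sigma 1.2 px, matched to the simulated PSF; the
filter scale is configurable), local maxima are found with a 3x3 maximum
filter, and candidates are kept when the **raw projection value** at the
peak exceeds the threshold (default 600 ADU, camera offset included —
the threshold is interpreted as applying to the projected image rather
than the filter response, and is configurable).  Duplicate maxima of one
spot are merged within 3 px (stronger response wins; ties resolve in
row-major order).  Distinct spots closer than the full ROI extent
(11 px) would mix molecules in one trace, so both are discarded by
default; a flag keeps the brighter instead.  Centers too close to the
border for a full ROI are dropped.  Every rule is replicated by a
plain-loop oracle in the test suite, so the fast implementation and the
specification cannot drift apart.

Traces are extracted from a 7x7-pixel signal region and the surrounding
2-px background ring: per frame, mean(signal) − mean(ring), both from
that frame.  This cancels any per-frame global offset exactly and is
translation-equivariant; both properties are asserted as tests.

## Blinking HMM and metrics (`blink_hmm`)

The analysis model is a 4-state Gaussian-emission HMM on the 1-D trace:
on1, on2, off, bleached.  Initialization: switching transitions (on<->on,
on<->off, off->on) equally likely at 0.1 per frame; transitions into the
bleached state 1/10 of that; the bleached row is the identity and the
start probability of bleached is zero — EM preserves structural zeros,
so the bleached state remains absorbing after training (asserted).
Emission means start at 300 ADU (on) and 0 (off, bleached) and are
learned under a conjugate mean prior of weight 1e3, implemented through
the MAP facilities of `hmmlearn` (`means_prior`/`means_weight`): with a
few thousand on-frames the data dominate and the learned on-means track
a FRET-quenched cohort, while degenerate cohorts fall back to the prior.
One model is trained per fluorophore cohort, pooled over all its traces
in ROI order; training is deterministic given the seed and order.  The
two on-states are collapsed to a single "on" label for every metric.

Per-molecule metrics follow the run-length definitions: a blink is a
maximal run of consecutive on frames; the run count is the number of
switching events; mean run length x exposure is the on-state time;
`k_off = blinks / total on time`, `k_on = blinks / total off time` with
a trailing off-run that continues to the video end excluded (at the end
of a trace "off" and "bleached" are emission-identical, so that time
cannot be attributed).  A never-on molecule is flagged invalid and
excluded from cohort summaries.  These definitions are verified exactly
against a run-length-encoding oracle.

Two refinements exist for cohort-level estimation, where the
per-molecule definitions are statistically blunt:

* `estimate_rates` pools **actual transition counts over time at risk**:
  `k_off = (#on->off)/(total on time)`, `k_on = (#off->on)/(total off
  time, trailing run excluded)`, with standard errors `rate/sqrt(events)`.
  The per-molecule `k_on` counts blinks in the numerator, but blinks
  outnumber off-sojourns by one per molecule (molecules start on after
  photoconversion), which inflates `k_on` when molecules blink only a
  few times; transition counting removes that.
* `on_intensity` returns decoded-on trace values with the first and last
  frame of every on-run excluded: a molecule may switch mid-frame, so
  run edges carry partial signal and dilute cohort brightness means —
  the same reasoning that excludes first/last frames from trajectory
  intensities.

Frame discretization still biases rate recovery when dwells approach the
frame time: on-runs shorter than about half a frame vanish, and run
boundaries quantize.  The validation study therefore measures each rate
from an acquisition matched to its time scale — 20 ms frames for
`k_off = 1/s` (50-frame on-dwells, quantization negligible) and 50 ms
frames for `k_on = 0.2/s` (the 100 s span covers many 5 s off-dwells and
lets most molecules photobleach, keeping end-of-trace censoring small).
These exposures were chosen from the known bias budget of frame-sampled
dwell estimators, and the study asserts recovery within three standard
errors.

Photons: ADU are converted by `n = I / (G_total * TE)` with
`G_total = (1/G_camera) * G_EM * QE` and `TE = eta_coll * T *
eta_EMCCD`.  The gain formula is applied exactly as conventionally
printed even though its unit algebra is loose (ADU/electron appears
inverted); the defaults are chosen so `G_total = 33.1 ADU/photon`, a
typical EMCCD calibration, and `I` is taken in ADU summed over the
signal region.  Recovery of a known photon budget from a rendered movie
is verified to 5%, the residual being PSF mass outside the 7x7 region.

## Tracking (`tracking`)

Linking is greedy frame-by-frame assignment under a 100 nm gate with a
1-frame gap bridge and a 3-localization minimum: candidate
(track, localization) pairs are processed in ascending distance order
(ties by track id, then by localization order after sorting each frame
by x, y, intensity), which realizes mutual-nearest-neighbor matching,
is invariant to input row order, and is reproduced exactly by an
exhaustive plain-loop oracle in the tests.  Gap-bridged frames count
toward track duration but contribute no intensity (nothing was
measured).  `track_length = (last - first frame + 1) x exposure`,
matching the semantics of a "time the molecule stayed on" cutoff.

Per-trajectory FRET uses the mean intensity excluding the first and last
localizations, relative to a donor-only reference, clipped to [0, 1).
The donor-only track-length cutoff is the empirical 99th percentile
(linear interpolation), pooled across cells.  Density maps bin
trajectories by mean position into 312 nm (2 px at 156 nm/px) cells,
reporting counts and mean track lengths classified against the cutoff.

Localization precision uses the consecutive-frame nearest-neighbor
distance distribution: for near-static molecules the same-molecule peak
is the difference of two isotropic Gaussian errors, a Rayleigh of scale
sqrt(2) sigma, `p(d) = (d / 2 sigma^2) exp(-d^2 / 4 sigma^2)`, fitted
together with a uniform (area-growing) background term; sigma is the
reported precision.  Exactly coincident repeats short-circuit to zero.
A radius-5 rolling-ball background subtraction is provided for the
cell-image path.

## Pipeline, configuration, determinism (`config`, `pipeline`, `cli`)

`RunConfig` validates strictly (unknown keys rejected) and hashes
canonically.  Pipeline stages (simulate, detect, trace, hmm, metrics,
lifetime, fret, track, report) write each artifact with a provenance
sidecar (stage, config hash, seed, package and numpy versions, stage
counts); a failing stage removes its partial outputs.  Identical
config + seed reproduces byte-identical CSV/JSON outputs.  The
`fretblink` CLI wraps the library thinly; the `report` stage recomputes
all closed-form quantities derivable from the packaged reference
constants of the two FRET pairs (lifetime efficiencies, distances,
photon-budget fold change).

## Validation study sizes

The self-validation suite runs, among others: 200-molecule x 2000-frame
HMM rate-recovery cohorts at SNR 6; 250-molecule donor-only vs FRET-pair
cohorts (600 frames at 500 ms, E = 0.5, bleach protection 5,
`k_on = k_off = k_bleach = 0.3/s` so on-runs span several frames) for
efficiency recovery within 0.05 and the survival-curve ordering (FRET
cohort >20% on when the donor-only cohort is 99% off); 50 + 50 decays of
1e5 counts for BIC order selection (>=90% correct, mono-lifetime median
error <=2%); 100 random small scenes for linking-oracle identity; and a
3-mode trajectory FRET mixture (E = 0.2/0.45/0.7) recovered by KDE mode
finding within 0.05.  All seeds are fixed; runtimes are kept to a few
minutes total by these sizes.

## What the generators do not emulate

EMCCD excess noise and clock-induced charge; instrument response
functions and pile-up in TCSPC; PSF aberrations, z-dependence and focal
drift; structured cellular background and autofluorescence; spectral
crosstalk and direct acceptor excitation; reversible dark-state
heterogeneity beyond one off-state.  Passing tests therefore demonstrate
the correctness and statistical consistency of the *analysis* under the
stated model, not robustness to every artifact of real microscopes; the
acceptance anchors tied to published values are closed-form arithmetic
and are exact.

## Known limitations

* Rate estimates from frame-decoded paths carry O(k * exposure)
  discretization bias; choose exposures accordingly (see above).
* The off/bleached distinction at the end of a trace is fundamentally
  ambiguous; all time-accounting conventions for it are approximations.
* BIC on unweighted RSS over-penalizes nothing and under-penalizes
  high-count bins of Poisson data; the bin-width lifetime bound and tail
  windows mitigate this, but model selection on decays with extreme
  dynamic range within the window remains less reliable.
* The greedy mutual-nearest linker is exact for the gate semantics but
  is not a global-optimum assignment; at the densities studied the two
  coincide (asserted on small scenes).
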