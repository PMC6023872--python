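# fretblink

Single-molecule photophysics analysis for FRET-enhanced
photo-modulatable fluorophores.

Photo-modulatable (PM) fluorophores — photo-convertible proteins such as
mEos3.2 and photo-activatable dyes such as PA-JF549 — make sptPALM-style
single-molecule tracking possible in dense cellular environments, but
their limited photostability caps how long any molecule can be followed.
Placing a photostable acceptor dye (e.g. JF646) within Förster distance
of the PM donor opens a FRET de-excitation pathway that competes with
photobleaching: the donor dims, but it survives longer and emits more
photons overall.  `fretblink` implements the complete analysis used to
characterize and exploit this effect, for microscopists and
single-molecule analysts who need to quantify it:

* **FRET arithmetic** (`fretblink.fret_core`) — efficiency from donor
  quenching, *E* = 1 − *I*′/*I* or *E* = 1 − τ_DA/τ_D; the distance law
  *E* = 1/(1 + (*r*/*R*₀)⁶) and its inverse; the spectral overlap
  integral *J* = ∫ f̄_D(λ) ε_A(λ) λ⁴ dλ over area-normalized donor
  emission; the Förster radius
  *R*₀⁶ = (9 ln10 / 128 π⁵ *N*_A) (κ² *Q*_D / *n*⁴) *J*.
* **TCSPC lifetime fitting** (`fretblink.lifetime_fit`) — tail fits of
  *I*(*t*) = *I*_bkgd + Σᵢ αᵢ e^(−t/τᵢ) for 1–3 components, model order
  selected by BIC = ln[n](p+1) + n(ln[2πRSS/n]+1) with relative
  likelihoods exp((BIC_min − BIC)/2), and amplitude-weighted mean
  lifetimes Σαᵢτᵢ/Σαᵢ.
* **Blinking analysis** (`fretblink.movie_analysis`,
  `fretblink.blink_hmm`) — LoG spot detection on a max projection,
  7×7-px traces with 2-px background rings, a four-state hidden Markov
  model (two on-states, off, absorbing bleached), and the derived
  metrics: switching events, on-state times, k_on/k_off, and photon
  budgets via *n* = *I*/(G_total · TE).
* **Trajectory analysis** (`fretblink.tracking`) — nearest-neighbor
  linking (100 nm gate, 1-frame gap, ≥3 localizations), track-length
  filtering against a donor-only 99th-percentile cutoff, per-trajectory
  FRET efficiencies, density maps, and NeNA-style localization-precision
  estimation.
* **Synthetic data** (`fretblink.synthetic_data`) — generators with
  ground truth for every input above: Markov blinking traces with
  FRET-scaled brightness and bleach protection, Gaussian-PSF movies on
  an EMCCD-like noise floor, multi-exponential decays with Poisson
  counting noise, and confined/directed trajectories.

See `docs/methods.md` for the models, estimators, conventions and their
limitations.

## Worked example

```python
import numpy as np
from fretblink import (
    PhotophysicsParams, CameraNoiseParams, simulate_movie,
    max_projection, detect_peaks, extract_traces,
    fit_blink_model, decode, blink_metrics, summarize_cohort, CameraModel,
    efficiency_from_lifetime, distance_from_efficiency,
)

# 1. closed-form FRET arithmetic for a measured pair
e = efficiency_from_lifetime(2.9, 2.1)
r = distance_from_efficiency(0.28, 5.81)
print(f"FRET efficiency from lifetimes 2.9/2.1 ns: {e:.2f}")
print(f"donor-acceptor distance at E=0.28, R0=5.81 nm: {r:.1f} nm")

# 2. a small synthetic blinking movie, analysed end to end
params = PhotophysicsParams(k_on=0.3, k_off=1.0, k_bleach=0.6,
                            brightness_on=15000.0, exposure=0.5, n_frames=200)
noise = CameraNoiseParams(read_noise_sd=20.0, offset=100.0,
                          em_gain_factor=33.1, poisson=True)
stack, truth = simulate_movie(25, field=(128, 128), psf_sigma=1.2,
                              params=params, noise=noise,
                              min_separation=14.0, seed=7)
proj = max_projection(stack, first_n=2)
centers = detect_peaks(proj)
traces = extract_traces(stack, centers)
print(f"detected {len(centers)} of {len(truth.positions)} emitters")

model = fit_blink_model(traces, seed=0)
camera = CameraModel()
records = [blink_metrics(decode(t, model), params.exposure, t, camera)
           for t in traces]
summary = summarize_cohort(records)
m = summary["metrics"]
print(f"mean switching events/molecule: {m['blinks']['mean']:.2f}")
print(f"mean total on-state time: {m['total_on_time']['mean']:.2f} s")
print(f"mean photon budget: {m['total_photons']['mean']:.0f} photons")
```

Output:

```
FRET efficiency from lifetimes 2.9/2.1 ns: 0.28
donor-acceptor distance at E=0.28, R0=5.81 nm: 6.8 nm
detected 21 of 25 emitters
mean switching events/molecule: 2.67
mean total on-state time: 3.95 s
mean photon budget: 11006 photons
```

The lifetime drop from 2.9 to 2.1 ns corresponds to 28% energy transfer
and, with a 5.81 nm Förster radius, a ~7 nm donor–acceptor separation.
In the movie, four of the 25 emitters had already switched off during
the two projection frames or fell below the 600 ADU detection threshold;
the mean switching-event count of 2.67 matches the generator's
expectation (k_off + k_bleach)/k_bleach for molecules that blink until
they photobleach.

The same analyses are available from the shell:

```sh
fretblink fret efficiency --from lifetime --tau-d 2.9 --tau-da 2.1
fretblink simulate movie --n-molecules 25 --seed 7 --out run/
fretblink detect run/movie.tif --threshold 600 --out run/rois.csv
fretblink trace run/movie.tif --rois run/rois.csv --out run/traces.csv
fretblink hmm metrics run/traces.csv --exposure 0.5 --out run/
fretblink run --stages simulate,detect,trace,hmm,metrics --out-dir run2 --seed 7
```

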