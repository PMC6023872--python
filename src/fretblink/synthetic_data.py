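"""Synthetic data with ground truth for every stage of the pipeline.

Four generators emulate the statistical structure the analysis assumes:

* :func:`simulate_blink_trace` — a single photo-modulatable fluorophore
  switching between two fluorescent on-states, a reversible off-state and
  an absorbing bleached state.  State dwells are exact exponential
  (continuous-time Markov) draws; the per-frame signal is the
  brightness-weighted fraction of the frame spent in an on-state, scaled
  by (1 - E) for a FRET pair, plus camera noise.  FRET-driven
  photoprotection is phenomenological: the bleach rate is divided by a
  ``bleach_protection`` factor.
* :func:`simulate_movie` — sparse immobilized emitters rendered as
  pixel-integrated 2-D Gaussians whose frame-by-frame brightness follows
  simulated blink traces, on an EMCCD-like noise floor (offset, Gaussian
  read noise, optional Poisson shot noise), written as 16-bit stacks.
* :func:`simulate_decay` — multi-exponential TCSPC decays with Poisson
  counting noise.
* :func:`simulate_trajectories` — localization tables for molecules
  undergoing confined jitter optionally interrupted by one brief directed
  excursion, with localization error, missed detections, and optional
  per-track FRET-scaled intensities.

All generators are deterministic given their seed (byte-identical
outputs across runs) and return a :class:`GroundTruth` alongside the
data product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erf

from .movie_analysis import RoiTrace

__all__ = [
    "ON1",
    "ON2",
    "OFF",
    "BLEACHED",
    "STATE_NAMES",
    "PhotophysicsParams",
    "CameraNoiseParams",
    "GroundTruth",
    "PlacementError",
    "simulate_blink_trace",
    "simulate_movie",
    "simulate_decay",
    "simulate_trajectories",
    "is_on",
]

ON1, ON2, OFF, BLEACHED = 0, 1, 2, 3
STATE_NAMES = ("on1", "on2", "off", "bleached")

#: default pixel size in nm (2 px = 312 nm density bins)
PIXEL_SIZE_NM = 156.0


def is_on(states) -> np.ndarray:
    """Boolean mask of frames spent (mostly) in a fluorescent on-state."""
    return np.asarray(states) <= ON2


@dataclass(frozen=True)
class PhotophysicsParams:
    """Kinetic and brightness parameters of one fluorophore construct.

    Rates are in 1/s: ``k_on`` off->on, ``k_off`` on->off, ``k_bleach``
    on->bleached.  ``brightness_on`` is the expected donor-only signal per
    fully-on frame in ADU — trace-level (ROI-mean) ADU for
    :func:`simulate_blink_trace`, total PSF-integrated ADU for
    :func:`simulate_movie`.  ``fret_efficiency`` scales the emitted donor
    signal by (1 - E); ``bleach_protection`` (>= 1) divides the bleach
    rate, the phenomenological stand-in for FRET depopulating the
    photobleaching pathway.  The two on-states differ only in brightness
    (``on2_brightness_ratio``, default 1 = identical); ``on2_fraction``
    is the probability of entering on2 on each on-switching event.
    """

    k_on: float = 0.1
    k_off: float = 1.0
    k_bleach: float = 1.2
    brightness_on: float = 300.0
    fret_efficiency: float = 0.0
    bleach_protection: float = 1.0
    exposure: float = 0.5
    n_frames: int = 500
    on2_brightness_ratio: float = 1.0
    on2_fraction: float = 0.5

    def __post_init__(self):
        if min(self.k_on, self.k_off, self.k_bleach) < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.fret_efficiency < 1:
            raise ValueError("fret_efficiency must lie in [0, 1)")
        if self.bleach_protection < 1:
            raise ValueError("bleach_protection must be >= 1")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        if self.brightness_on < 0:
            raise ValueError("brightness_on must be non-negative")
        if not 0 <= self.on2_fraction <= 1:
            raise ValueError("on2_fraction must be a probability")

    @property
    def effective_k_bleach(self) -> float:
        return self.k_bleach / self.bleach_protection

    def with_fret(self, efficiency: float, bleach_protection: float) -> "PhotophysicsParams":
        """The same construct as a FRET pair: quenched brightness and
        protected bleaching."""
        return replace(
            self, fret_efficiency=efficiency, bleach_protection=bleach_protection
        )


@dataclass(frozen=True)
class CameraNoiseParams:
    """Effective camera noise model (EMCCD excess noise not modeled).

    ``em_gain_factor`` is the effective ADU per detected photon at the
    scale of the simulated signal: for 1-D traces (ROI-mean ADU) the
    per-pixel gain divided by the number of signal pixels, for movies the
    per-pixel gain itself.  ``poisson`` toggles shot noise; Gaussian read
    noise of ``read_noise_sd`` ADU is always added; ``offset`` is the
    camera baseline (movies only — traces are background-subtracted by
    construction).
    """

    read_noise_sd: float = 20.0
    offset: float = 100.0
    em_gain_factor: float = 33.1
    poisson: bool = True

    def __post_init__(self):
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")
        if self.em_gain_factor <= 0:
            raise ValueError("em_gain_factor must be positive")


@dataclass
class GroundTruth:
    """Everything the generators know that the analysis must recover.

    Only the fields relevant to the generating call are populated.
    ``states`` holds the majority-occupancy state code per frame;
    ``dwells`` the completed (state, seconds) sojourns; ``signal`` the
    noiseless expected ADU per frame; ``photons`` the true emitted-photon
    equivalents per frame when a camera scale is defined.
    """

    states: np.ndarray | None = None
    on_fraction: np.ndarray | None = None
    signal: np.ndarray | None = None
    photons: np.ndarray | None = None
    dwells: list[tuple[int, float]] | None = None
    positions: np.ndarray | None = None  # (n, 2) row, col in px
    molecules: list["GroundTruth"] | None = None
    tracks: pd.DataFrame | None = None
    amplitudes: np.ndarray | None = None
    lifetimes: np.ndarray | None = None
    background: float | None = None
    fret_efficiency: object = None
    params: PhotophysicsParams | None = None

    def to_jsonable(self) -> dict:
        """A JSON-serializable summary (arrays as lists)."""
        out = {}
        for key, val in self.__dict__.items():
            if val is None:
                continue
            if isinstance(val, np.ndarray):
                out[key] = val.tolist()
            elif isinstance(val, pd.DataFrame):
                out[key] = val.to_dict(orient="list")
            elif isinstance(val, GroundTruth):
                out[key] = val.to_jsonable()
            elif isinstance(val, list) and val and isinstance(val[0], GroundTruth):
                out[key] = [v.to_jsonable() for v in val]
            elif isinstance(val, PhotophysicsParams):
                out[key] = val.__dict__
            else:
                out[key] = val
        return out


class PlacementError(RuntimeError):
    """Raised when emitters cannot be placed at the requested separation."""


# ---------------------------------------------------------------------------
# blinking traces


def _simulate_segments(params: PhotophysicsParams, rng: np.random.Generator):
    """Continuous-time path as (state, t_start, t_end) segments over the
    movie duration.  The molecule is photo-converted at t=0 and starts in
    an on-state."""
    total_t = params.n_frames * params.exposure
    k_bleach = params.effective_k_bleach
    state = ON2 if rng.random() < params.on2_fraction else ON1
    t = 0.0
    segments = []
    while t < total_t:
        if state in (ON1, ON2):
            rates = ((OFF, params.k_off), (BLEACHED, k_bleach))
        elif state == OFF:
            rates = ((ON1, params.k_on),)
        else:  # bleached: absorbing
            segments.append((BLEACHED, t, total_t))
            break
        total_rate = sum(k for _, k in rates)
        if total_rate <= 0:
            segments.append((state, t, total_t))
            break
        dwell = rng.exponential(1.0 / total_rate)
        end = min(t + dwell, total_t)
        segments.append((state, t, end))
        if end >= total_t:
            break
        u = rng.random() * total_rate
        acc = 0.0
        nxt = rates[-1][0]
        for s, k in rates:
            acc += k
            if u < acc:
                nxt = s
                break
        if nxt == ON1 and rng.random() < params.on2_fraction:
            nxt = ON2
        state = nxt
        t = end
    return segments


def _frame_occupancy(segments, n_frames: int, dt: float) -> np.ndarray:
    """(n_frames, 4) fraction of each frame spent in each state."""
    occ = np.zeros((n_frames, 4))
    for state, t0, t1 in segments:
        if t1 <= t0:
            continue
        f_lo = min(n_frames - 1, int(t0 / dt))
        f_hi = min(n_frames - 1, int(np.ceil(t1 / dt)) - 1)
        idx = np.arange(f_lo, f_hi + 1)
        starts = np.maximum(t0, idx * dt)
        ends = np.minimum(t1, (idx + 1) * dt)
        occ[idx, state] += np.maximum(ends - starts, 0.0) / dt
    return occ


def _expected_signal(params: PhotophysicsParams, occ: np.ndarray) -> np.ndarray:
    b1 = params.brightness_on
    b2 = params.brightness_on * params.on2_brightness_ratio
    return (occ[:, ON1] * b1 + occ[:, ON2] * b2) * (1.0 - params.fret_efficiency)


def _apply_trace_noise(
    signal: np.ndarray, noise: CameraNoiseParams | None, rng: np.random.Generator
) -> np.ndarray:
    if noise is None:
        return signal.copy()
    out = signal
    if noise.poisson:
        g = noise.em_gain_factor
        out = rng.poisson(np.maximum(signal, 0.0) / g) * g
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd, size=signal.size)
    else:
        out = np.asarray(out, dtype=float).copy()
    return out


def simulate_blink_trace(
    params: PhotophysicsParams,
    noise: CameraNoiseParams | None = None,
    seed: int = 0,
) -> tuple[RoiTrace, GroundTruth]:
    """Simulate one molecule's background-subtracted intensity trace.

    Returns the trace and a :class:`GroundTruth` with the per-frame
    majority state, the exact on-state occupancy per frame, the noiseless
    expected signal, and the completed dwell times (censored final
    sojourns excluded).
    """
    if params.n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    segments = _simulate_segments(params, rng)
    occ = _frame_occupancy(segments, params.n_frames, params.exposure)
    states = occ.argmax(axis=1).astype(np.int8)
    signal = _expected_signal(params, occ)
    values = _apply_trace_noise(signal, noise, rng)
    dwells = [
        (state, t1 - t0)
        for (state, t0, t1) in segments[:-1]  # last segment is censored/absorbed
        if state != BLEACHED
    ]
    truth = GroundTruth(
        states=states,
        on_fraction=occ[:, ON1] + occ[:, ON2],
        signal=signal,
        dwells=dwells,
        fret_efficiency=params.fret_efficiency,
        params=params,
    )
    return RoiTrace(values=values), truth


# ---------------------------------------------------------------------------
# movies


def _pixel_gaussian_weights(shape, center_rc, sigma):
    """Pixel-integrated unit-mass 2-D Gaussian (erf over pixel edges)."""
    h, w = shape
    r0, c0 = center_rc
    s = sigma * math.sqrt(2.0)
    rows = np.arange(h)
    cols = np.arange(w)
    wr = 0.5 * (erf((rows + 0.5 - r0) / s) - erf((rows - 0.5 - r0) / s))
    wc = 0.5 * (erf((cols + 0.5 - c0) / s) - erf((cols - 0.5 - c0) / s))
    return np.outer(wr, wc)


def _place_emitters(n, shape, min_separation, margin, rng, max_attempts=10000):
    h, w = shape
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError("field too small for the ROI margin")
    positions = []
    for _ in range(n):
        for _attempt in range(max_attempts):
            pos = np.array(
                [
                    rng.uniform(margin, h - 1 - margin),
                    rng.uniform(margin, w - 1 - margin),
                ]
            )
            if all(
                np.hypot(*(pos - q)) >= min_separation for q in positions
            ):
                positions.append(pos)
                break
        else:
            raise PlacementError(
                f"could not place {n} emitters at separation {min_separation}"
            )
    return np.array(positions)


def simulate_movie(
    n_molecules: int,
    field: tuple[int, int] = (64, 64),
    psf_sigma: float = 1.2,
    params: PhotophysicsParams | None = None,
    noise: CameraNoiseParams | None = None,
    min_separation: float = 12.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a 16-bit stack of sparse immobilized blinking emitters.

    Each molecule sits at a fixed sub-pixel position and is rendered as a
    pixel-integrated Gaussian carrying its simulated per-frame signal
    (``params.brightness_on`` is the *total* ADU integrated over the PSF
    here).  Ground truth holds positions (row, col, px) and per-molecule
    blink truths.
    """
    params = params or PhotophysicsParams()
    if n_molecules < 1:
        raise ValueError("need at least one molecule")
    rng = np.random.default_rng(seed)
    margin = 6  # full 11x11 ROI plus one pixel of slack
    positions = _place_emitters(n_molecules, field, min_separation, margin, rng)

    mol_seeds = rng.integers(0, 2**31 - 1, size=n_molecules)
    stack = np.zeros((params.n_frames, field[0], field[1]))
    truths = []
    for pos, mol_seed in zip(positions, mol_seeds):
        _, truth = simulate_blink_trace(params, noise=None, seed=int(mol_seed))
        weights = _pixel_gaussian_weights(field, pos, psf_sigma)
        stack += truth.signal[:, None, None] * weights[None, :, :]
        truths.append(truth)

    if noise is not None:
        if noise.poisson:
            g = noise.em_gain_factor
            stack = rng.poisson(np.maximum(stack, 0.0) / g) * g
        stack = stack + noise.offset
        if noise.read_noise_sd > 0:
            stack = stack + rng.normal(0.0, noise.read_noise_sd, size=stack.shape)
    stack = np.clip(np.round(stack), 0, 65535).astype(np.uint16)

    truth = GroundTruth(
        positions=positions,
        molecules=truths,
        fret_efficiency=params.fret_efficiency,
        params=params,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# TCSPC decays


def simulate_decay(
    amplitudes,
    lifetimes,
    background: float = 0.0,
    t_range: tuple[float, float] = (0.0, 25.0),
    n_bins: int = 250,
    total_counts: float | None = None,
    seed: int = 0,
    noise: bool = True,
):
    """Simulate a TCSPC decay histogram.

    The expected curve is ``background + sum_i a_i exp(-t/tau_i)`` on
    ``n_bins`` bin centers spanning ``t_range`` (ns).  If ``total_counts``
    is given the curve is rescaled so its expected sum matches it; Poisson
    counting noise is applied unless ``noise=False``.  Returns the
    histogram (fit window at the default tail range) and the ground truth
    with the scaled amplitudes/background.
    """
    from .lifetime_fit import DecayHistogram

    amps = np.asarray(amplitudes, dtype=float)
    taus = np.asarray(lifetimes, dtype=float)
    if amps.size == 0 or amps.size != taus.size:
        raise ValueError("need matching, non-empty amplitude and lifetime lists")
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    if np.any(amps < 0) or background < 0:
        raise ValueError("amplitudes and background must be non-negative")
    rng = np.random.default_rng(seed)
    edges = np.linspace(t_range[0], t_range[1], n_bins + 1)
    t = 0.5 * (edges[:-1] + edges[1:])
    expected = background + (amps[None, :] * np.exp(-t[:, None] / taus[None, :])).sum(
        axis=1
    )
    bkgd = float(background)
    if total_counts is not None:
        scale = total_counts / expected.sum()
        expected = expected * scale
        amps = amps * scale
        bkgd *= scale
    counts = rng.poisson(expected).astype(float) if noise else expected
    hist = DecayHistogram(bin_times=t, counts=counts)
    truth = GroundTruth(amplitudes=amps, lifetimes=taus, background=bkgd)
    return hist, truth


# ---------------------------------------------------------------------------
# trajectories


def simulate_trajectories(
    n_tracks: int = 50,
    frame_interval: float = 0.5,
    confined_sd: float = 20.0,
    directed_speed: float = 500.0,
    p_directed: float = 0.0,
    detection_p: float = 1.0,
    precision_sd: float = 15.0,
    seed: int = 0,
    *,
    n_frames_per_track: int = 40,
    field_nm: float = 10000.0,
    min_separation_nm: float = 1500.0,
    directed_duration_s: float = 5.0,
    intensity_mean: float = 300.0,
    intensity_cv: float = 0.1,
    fret_states=None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a localization table of confined molecules.

    Tracks jitter about their origin with per-axis sd ``confined_sd``
    (nm); with probability ``p_directed`` a track contains one directed
    segment of ``directed_speed`` nm/s lasting ``directed_duration_s``.
    Localizations add Gaussian error ``precision_sd`` per axis and are
    dropped with probability ``1 - detection_p``.  ``fret_states`` is an
    optional list of (efficiency, weight) pairs; each track draws one
    efficiency and its intensities scale by (1 - E).

    Returns the localization table (frame, x_nm, y_nm, intensity_adu) and
    a ground-truth table carrying track ids, true positions and the
    per-track efficiency.
    """
    for name, p in (("p_directed", p_directed), ("detection_p", detection_p)):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must be a probability")
    if precision_sd < 0 or confined_sd < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_tracks < 1 or n_frames_per_track < 1:
        raise ValueError("need at least one track and one frame")
    rng = np.random.default_rng(seed)
    origins = []
    for _ in range(n_tracks):
        for _attempt in range(10000):
            pos = rng.uniform(0, field_nm, size=2)
            if all(np.hypot(*(pos - q)) >= min_separation_nm for q in origins):
                origins.append(pos)
                break
        else:
            raise PlacementError("could not place track origins at the requested separation")

    if fret_states is not None:
        effs = np.array([e for e, _ in fret_states], dtype=float)
        wts = np.array([w for _, w in fret_states], dtype=float)
        wts = wts / wts.sum()
    rows = []
    for tid, origin in enumerate(origins):
        e = 0.0
        if fret_states is not None:
            e = float(effs[rng.choice(effs.size, p=wts)])
        base = np.tile(origin, (n_frames_per_track, 1))
        if rng.random() < p_directed and directed_speed > 0:
            seg_len = max(1, int(round(directed_duration_s / frame_interval)))
            seg_len = min(seg_len, n_frames_per_track)
            start = rng.integers(0, n_frames_per_track - seg_len + 1)
            theta = rng.uniform(0, 2 * np.pi)
            step = directed_speed * frame_interval
            direction = np.array([np.cos(theta), np.sin(theta)])
            drift = np.zeros((n_frames_per_track, 2))
            ramp = np.arange(1, seg_len + 1)[:, None] * step * direction[None, :]
            drift[start : start + seg_len] = ramp
            drift[start + seg_len :] = ramp[-1]
            base = base + drift
        true_xy = base + rng.normal(0.0, confined_sd, size=base.shape)
        obs_xy = true_xy + rng.normal(0.0, precision_sd, size=base.shape)
        intensity = intensity_mean * (1.0 - e) * (
            1.0 + rng.normal(0.0, intensity_cv, size=n_frames_per_track)
        )
        detected = rng.random(n_frames_per_track) < detection_p
        for f in range(n_frames_per_track):
            rows.append(
                (
                    tid,
                    f,
                    true_xy[f, 0],
                    true_xy[f, 1],
                    obs_xy[f, 0],
                    obs_xy[f, 1],
                    max(intensity[f], 1.0),
                    e,
                    bool(detected[f]),
                )
            )
    truth_df = pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "frame",
            "true_x_nm",
            "true_y_nm",
            "x_nm",
            "y_nm",
            "intensity_adu",
            "fret_efficiency",
            "detected",
        ],
    )
    locs = (
        truth_df[truth_df.detected]
        .loc[:, ["frame", "x_nm", "y_nm", "intensity_adu"]]
        .reset_index(drop=True)
    )
    truth = GroundTruth(tracks=truth_df, fret_efficiency=None)
    return locs, truth
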