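"""TCSPC tail fitting with sums of exponentials and BIC model selection.

A fluorescence decay histogram is tail-fitted (no IRF deconvolution) to

    I(t) = I_bkgd + sum_i alpha_i * exp(-t / tau_i),    i = 1..order,

by bounded nonlinear least squares inside a fixed time window (default
1.5-7.0 ns).  Model order (mono/bi/tri-exponential) is selected with the
Bayesian Information Criterion computed from the unweighted residual sum
of squares,

    BIC = ln[n](p + 1) + n(ln[2 pi RSS / n] + 1),

and competing orders are compared through the relative likelihood
exp((BIC_min - BIC)/2).  The lifetime entering the FRET efficiency is
the amplitude-weighted mean, sum(alpha_i tau_i)/sum(alpha_i).

Multi-exponential least squares is multimodal, so each fit is
multi-started over lifetime decades (0.3/1/3/10 ns combinations); the
lowest-RSS solution wins, ties broken by start order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

__all__ = [
    "DecayHistogram",
    "ExpDecayFit",
    "FitError",
    "tail_fit",
    "bic",
    "bic_score",
    "relative_likelihood",
    "amplitude_weighted_lifetime",
    "select_model",
]

#: default tail-fit window (ns)
DEFAULT_FIT_WINDOW = (1.5, 7.0)
#: minimum photon count in the window for a fit to be attempted
MIN_PHOTONS = 50
#: multi-start lifetime grid (ns)
TAU_STARTS = (0.3, 1.0, 3.0, 10.0)


class FitError(RuntimeError):
    """Raised when a decay cannot be fitted (bad input or non-convergence)."""


@dataclass
class DecayHistogram:
    """A TCSPC decay: photon counts per arrival-time bin."""

    bin_times: np.ndarray  # ns, strictly increasing bin centers
    counts: np.ndarray  # photons per bin, >= 0
    fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW

    def __post_init__(self):
        t = np.asarray(self.bin_times, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ValueError("bin_times and counts must be 1-D and equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("bin_times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        self.bin_times = t
        self.counts = c
        lo, hi = self.fit_window
        if not hi > lo:
            raise ValueError("fit window must have t_max > t_min")

    def windowed(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, counts) restricted to the fit window."""
        lo, hi = self.fit_window
        mask = (self.bin_times >= lo) & (self.bin_times <= hi)
        return self.bin_times[mask], self.counts[mask]

    @classmethod
    def from_text(cls, path, fit_window=DEFAULT_FIT_WINDOW) -> "DecayHistogram":
        from .io import read_two_column

        t, c = read_two_column(path)
        return cls(t, c, fit_window=fit_window)


@dataclass
class ExpDecayFit:
    """Result of a tail fit of fixed order.

    ``components`` are (amplitude, lifetime) pairs sorted by lifetime;
    ``n_params`` counts the background plus one amplitude and one
    lifetime per component (p = 2*order + 1).
    """

    background: float
    components: tuple[tuple[float, float], ...]
    rss: float
    n_points: int
    bic: float = np.nan
    rel_likelihood: float = 1.0
    message: str = ""

    @property
    def order(self) -> int:
        return len(self.components)

    @property
    def n_params(self) -> int:
        return 2 * self.order + 1

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def lifetimes(self) -> np.ndarray:
        return np.array([tau for _, tau in self.components])

    def model(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.background)
        for amp, tau in self.components:
            out = out + amp * np.exp(-t / tau)
        return out


def _linear_solve(taus, t, counts, weights):
    """Best non-negative (background, amplitudes) for fixed lifetimes."""
    design = np.column_stack([np.ones_like(t)] + [np.exp(-t / tau) for tau in taus])
    if weights is not None:
        coef, _ = nnls(design * weights[:, None], counts * weights)
    else:
        coef, _ = nnls(design, counts)
    with np.errstate(invalid="ignore"):
        resid = design @ coef - counts
    return coef, resid


def _profiled_residual(log_taus, t, counts, weights):
    try:
        _, resid = _linear_solve(np.exp(log_taus), t, counts, weights)
    except Exception:
        return np.full_like(counts, 1e12)
    if not np.all(np.isfinite(resid)):
        return np.full_like(counts, 1e12)  # singular design (coincident lifetimes)
    return resid if weights is None else resid * weights


def tail_fit(
    decay: DecayHistogram, order: int, *, weighting: str = "none"
) -> ExpDecayFit:
    """Fit a sum of ``order`` exponentials plus a flat background.

    The model is linear in the background and amplitudes, so those are
    profiled out by non-negative least squares (variable projection) and
    the nonlinear search runs over log-lifetimes only, multi-started over
    lifetime decades.

    ``weighting`` may be "none" (default; RSS and BIC use raw residuals)
    or "poisson" (residuals scaled by 1/sqrt(max(counts, 1)) during
    optimization; the reported RSS and BIC remain unweighted so that
    model comparison matches the BIC definition).

    Raises :class:`FitError` if the window holds fewer than p+2 bins or
    fewer than 50 photons, or if no start converges.
    """
    if order < 1 or order > 3:
        raise ValueError("order must be 1, 2 or 3")
    if weighting not in ("none", "poisson"):
        raise ValueError("weighting must be 'none' or 'poisson'")
    t, c = decay.windowed()
    p = 2 * order + 1
    if t.size < p + 2:
        raise FitError(
            f"only {t.size} bins in the fit window; order {order} needs >= {p + 2}"
        )
    if c.sum() < MIN_PHOTONS:
        raise FitError(
            f"only {c.sum():.0f} photons in the fit window; need >= {MIN_PHOTONS}"
        )
    weights = None
    if weighting == "poisson":
        weights = 1.0 / np.sqrt(np.maximum(c, 1.0))

    # lifetimes below the bin spacing are unresolvable and only serve to
    # chase single-bin noise, so the search is bounded away from them
    tau_min = float(np.median(np.diff(decay.bin_times)))
    bounds = (np.log(tau_min), np.log(1e3))
    best = None
    best_rss = np.inf
    for taus0 in itertools.combinations(TAU_STARTS, order):
        x0 = np.log(taus0)
        try:
            res = least_squares(
                _profiled_residual,
                x0,
                bounds=bounds,
                args=(t, c, weights),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=400,
            )
        except Exception:  # singular design on a degenerate start
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        taus = np.exp(res.x)
        _, raw = _linear_solve(taus, t, c, None)
        rss = float(raw @ raw)
        if rss < best_rss:
            best_rss = rss
            best = taus
    if best is None:
        raise FitError(f"no start converged for order {order}")

    coef, _ = _linear_solve(best, t, c, weights)
    design = np.column_stack([np.ones_like(t)] + [np.exp(-t / tau) for tau in best])
    raw = design @ coef - c
    best_rss = float(raw @ raw)  # BIC always uses the unweighted RSS
    bkgd = float(coef[0])
    comps = sorted(zip(coef[1:].tolist(), best.tolist()), key=lambda at: at[1])
    fit = ExpDecayFit(
        background=bkgd,
        components=tuple((float(a), float(tau)) for a, tau in comps),
        rss=best_rss,
        n_points=int(t.size),
    )
    fit.bic = bic(fit)
    return fit


def bic_score(n_points: int, n_params: int, rss: float) -> float:
    """BIC = ln[n](p + 1) + n(ln[2 pi RSS / n] + 1)."""
    if rss <= 0:
        raise ValueError("RSS must be positive (a perfect fit degenerates the log)")
    if n_points < 1:
        raise ValueError("need at least one data point")
    n = float(n_points)
    return float(np.log(n) * (n_params + 1) + n * (np.log(2.0 * np.pi * rss / n) + 1.0))


def bic(fit: ExpDecayFit) -> float:
    """BIC of a populated fit (n, p, RSS must be set)."""
    return bic_score(fit.n_points, fit.n_params, fit.rss)


def relative_likelihood(bics) -> np.ndarray:
    """exp((BIC_min - BIC)/2) per model; the best model gets exactly 1."""
    b = np.asarray(list(bics), dtype=float)
    if b.size == 0:
        raise ValueError("need at least one BIC value")
    return np.exp((b.min() - b) / 2.0)


def amplitude_weighted_lifetime(fit: ExpDecayFit) -> float:
    """Amplitude-weighted mean lifetime sum(a_i tau_i) / sum(a_i), ns."""
    amps = fit.amplitudes
    total = amps.sum()
    if fit.order < 1:
        raise ValueError("fit has no components")
    if total <= 0:
        raise ValueError("total amplitude is zero")
    return float((amps * fit.lifetimes).sum() / total)


def select_model(
    decay: DecayHistogram, orders=(1, 2, 3), *, weighting: str = "none"
) -> ExpDecayFit:
    """Fit each candidate order and return the BIC-minimal fit.

    The returned fit carries ``rel_likelihood = 1`` and a ``bic_table``
    attribute mapping order -> (bic, rel_likelihood) for every order that
    converged (failed orders map to None).  Raises :class:`FitError` if
    every order fails.
    """
    fits: dict[int, ExpDecayFit | None] = {}
    for order in orders:
        try:
            fits[order] = tail_fit(decay, order, weighting=weighting)
        except FitError as err:
            fits[order] = None
            if all(f is None for f in fits.values()) and order == orders[-1]:
                raise FitError(f"all model orders failed; last error: {err}")
    good = {k: f for k, f in fits.items() if f is not None}
    if not good:
        raise FitError("all model orders failed")
    rel = relative_likelihood([f.bic for f in good.values()])
    for f, r in zip(good.values(), rel):
        f.rel_likelihood = float(r)
    best = min(good.values(), key=lambda f: f.bic)
    table = {
        k: (None if f is None else (f.bic, f.rel_likelihood)) for k, f in fits.items()
    }
    best.bic_table = table  # type: ignore[attr-defined]
    return best
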