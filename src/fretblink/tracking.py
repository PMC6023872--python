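"""Live-cell trajectory linking and FRET-proximity analysis.

Localizations are linked frame by frame: detections in consecutive
frames belong to the same molecule when they are within 100 nm, a single
missed frame is bridged, and trajectories with fewer than 3 localizations
are discarded.  Within each frame pair, candidate matches are resolved as
mutual nearest neighbors processed in ascending distance order with
deterministic tie-breaking, so linking is independent of input row order.

Downstream, trajectories are filtered by track length against the tail of
a donor-only cohort (e.g. the 99th percentile, the "only 1% of donor
tracks last this long" cutoff), per-trajectory FRET efficiencies are
computed from mean intensity relative to a donor-only reference, density
maps bin trajectories into 2-pixel-wide (312 nm) cells, and localization
precision is estimated from the nearest-neighbor distance distribution
between consecutive frames (NeNA-style fit of the Rayleigh-like
same-molecule peak plus a uniform background term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "Trajectory",
    "DensityMap",
    "PrecisionError",
    "link",
    "track_length_cutoff",
    "trajectory_fret",
    "density_map",
    "nn_precision",
    "trajectory_table",
    "rolling_ball_subtract",
]

LOC_COLUMNS = ("frame", "x_nm", "y_nm", "intensity_adu")


class PrecisionError(RuntimeError):
    """Raised when too few localization pairs exist for a precision fit."""


@dataclass
class Trajectory:
    """A linked single-molecule trajectory.

    ``track_length`` spans first to last frame inclusive (bridged gaps
    count — the molecule was on throughout); ``duration`` is the open
    span.  ``mean_intensity`` excludes the first and last localizations,
    where the molecule may not have fluoresced for the whole frame.
    """

    traj_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray
    exposure: float = 0.5
    fret_efficiency: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)

    @property
    def n_localizations(self) -> int:
        return int(self.frames.size)

    @property
    def duration(self) -> float:
        return float((self.frames[-1] - self.frames[0]) * self.exposure)

    @property
    def track_length(self) -> float:
        return float((self.frames[-1] - self.frames[0] + 1) * self.exposure)

    @property
    def mean_intensity(self) -> float:
        if self.n_localizations < 3:
            return float(np.mean(self.intensity))
        return float(np.mean(self.intensity[1:-1]))

    @property
    def mean_position(self) -> tuple[float, float]:
        return float(self.x.mean()), float(self.y.mean())

    def check(self, max_disp: float = 100.0, max_gap: int = 1, min_locs: int = 3):
        """Assert the trajectory's own invariants."""
        assert self.n_localizations >= min_locs
        gaps = np.diff(self.frames)
        assert np.all(gaps >= 1) and np.all(gaps <= max_gap + 1)
        steps = np.hypot(np.diff(self.x), np.diff(self.y))
        assert np.all(steps <= max_disp + 1e-9)


def _as_loc_frame(localizations) -> pd.DataFrame:
    df = pd.DataFrame(localizations)
    missing = [c for c in LOC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"localization table lacks columns {missing}")
    return df.loc[:, list(LOC_COLUMNS)]


def link(
    localizations,
    max_disp: float = 100.0,
    max_gap: int = 1,
    min_locs: int = 3,
    exposure: float = 0.5,
) -> list[Trajectory]:
    """Link a localization table into trajectories.

    Greedy frame-by-frame assignment: at each frame, (active track,
    localization) pairs within ``max_disp`` nm of the track's last
    position are processed in ascending distance order (ties broken by
    track id, then by localization order after sorting by x, y,
    intensity), which realizes mutual-nearest-neighbor matching.  Tracks
    missing for up to ``max_gap`` frames remain eligible.  Trajectories
    with fewer than ``min_locs`` localizations are discarded.
    """
    df = _as_loc_frame(localizations)
    if df.empty:
        return []
    df = df.sort_values(
        ["frame", "x_nm", "y_nm", "intensity_adu"], kind="mergesort"
    ).reset_index(drop=True)

    active: list[dict] = []
    done: list[dict] = []
    next_id = 0
    f_min, f_max = int(df.frame.min()), int(df.frame.max())
    grouped = {int(f): g for f, g in df.groupby("frame")}
    for f in range(f_min, f_max + 1):
        cur = grouped.get(f)
        assigned = set()
        if cur is not None and active:
            elig = [tr for tr in active if 1 <= f - tr["last_frame"] <= max_gap + 1]
            if elig:
                track_xy = np.array([tr["last_xy"] for tr in elig])
                loc_xy = cur[["x_nm", "y_nm"]].to_numpy()
                dists = cdist(track_xy, loc_xy)
                ti, ci = np.nonzero(dists <= max_disp)
                order = sorted(
                    range(ti.size),
                    key=lambda k: (dists[ti[k], ci[k]], elig[ti[k]]["id"], ci[k]),
                )
                used_tracks = set()
                for k in order:
                    tr, c = elig[ti[k]], int(ci[k])
                    if tr["id"] in used_tracks or c in assigned:
                        continue
                    row = cur.iloc[c]
                    tr["locs"].append((f, row.x_nm, row.y_nm, row.intensity_adu))
                    tr["last_frame"] = f
                    tr["last_xy"] = (row.x_nm, row.y_nm)
                    used_tracks.add(tr["id"])
                    assigned.add(c)
        if cur is not None:
            for c in range(len(cur)):
                if c in assigned:
                    continue
                row = cur.iloc[c]
                active.append(
                    {
                        "id": next_id,
                        "locs": [(f, row.x_nm, row.y_nm, row.intensity_adu)],
                        "last_frame": f,
                        "last_xy": (row.x_nm, row.y_nm),
                    }
                )
                next_id += 1
        still = []
        for tr in active:
            if f - tr["last_frame"] >= max_gap + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still
    done.extend(active)

    out = []
    for tr in sorted(done, key=lambda t: t["id"]):
        if len(tr["locs"]) < min_locs:
            continue
        arr = np.array(tr["locs"], dtype=float)
        out.append(
            Trajectory(
                traj_id=len(out),
                frames=arr[:, 0].astype(int),
                x=arr[:, 1],
                y=arr[:, 2],
                intensity=arr[:, 3],
                exposure=exposure,
            )
        )
    return out


def track_length_cutoff(donor_only_lengths, quantile: float = 0.99) -> float:
    """Track-length cutoff below which the given fraction of donor-only
    tracks falls (empirical quantile with linear interpolation).

    With the default 0.99, only 1% of donor-only tracks exceed the
    returned length, so longer tracks in a FRET condition flag molecules
    in proximity to an acceptor."""
    lengths = np.asarray(list(donor_only_lengths), dtype=float)
    if lengths.size == 0:
        raise ValueError("need at least one track length")
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    if lengths.size < 100:
        warnings.warn(
            f"only {lengths.size} donor-only tracks; the {quantile:.0%} "
            "quantile may be unstable",
            stacklevel=2,
        )
    return float(np.quantile(lengths, quantile))


def trajectory_fret(traj: Trajectory, donor_only_mean_intensity: float) -> float:
    """Per-trajectory FRET efficiency: E = 1 - <I>/<I_donor-only>,
    clipped to [0, 1)."""
    if donor_only_mean_intensity <= 0:
        raise ValueError("donor-only reference intensity must be positive")
    if traj.n_localizations < 3:
        raise ValueError("trajectory FRET needs at least 3 localizations")
    e = 1.0 - traj.mean_intensity / donor_only_mean_intensity
    return float(np.clip(e, 0.0, np.nextafter(1.0, 0.0)))


@dataclass
class DensityMap:
    """Binned trajectory counts and mean track lengths.

    ``above_cutoff`` is True where the bin's mean track length exceeds
    the cutoff (NaN-mean bins are False)."""

    bin_width: float
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    mean_track_length: np.ndarray
    above_cutoff: np.ndarray | None = None
    cutoff: float | None = None

    @property
    def n_assigned(self) -> int:
        return int(self.counts.sum())


def density_map(
    trajectories, bin_width: float = 312.0, cutoff: float | None = None
) -> DensityMap:
    """Assign each trajectory to the bin of its mean position and report
    per-bin molecule counts and mean track lengths (classified against
    ``cutoff`` when given)."""
    trajs = list(trajectories)
    if not trajs:
        empty = np.zeros((0, 0))
        return DensityMap(bin_width, np.array([0.0]), np.array([0.0]),
                          empty, empty, None, cutoff)
    xy = np.array([t.mean_position for t in trajs])
    lengths = np.array([t.track_length for t in trajs])
    x_edges = np.arange(
        np.floor(xy[:, 0].min() / bin_width) * bin_width,
        xy[:, 0].max() + bin_width,
        bin_width,
    )
    y_edges = np.arange(
        np.floor(xy[:, 1].min() / bin_width) * bin_width,
        xy[:, 1].max() + bin_width,
        bin_width,
    )
    counts, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=(x_edges, y_edges))
    sums, _, _ = np.histogram2d(
        xy[:, 0], xy[:, 1], bins=(x_edges, y_edges), weights=lengths
    )
    with np.errstate(invalid="ignore"):
        mean_len = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    above = None
    if cutoff is not None:
        above = np.nan_to_num(mean_len, nan=-np.inf) > cutoff
    return DensityMap(bin_width, x_edges, y_edges, counts, mean_len, above, cutoff)


def _nena_pdf(d, sigma, bg_frac, d_max):
    # same-molecule peak: difference of two isotropic Gaussian errors of
    # sd sigma per axis -> Rayleigh with scale sqrt(2)*sigma
    ray = (d / (2.0 * sigma**2)) * np.exp(-(d**2) / (4.0 * sigma**2))
    uniform = 2.0 * d / d_max**2
    return (1.0 - bg_frac) * ray + bg_frac * uniform


def nn_precision(localizations, n_bins: int = 40) -> float:
    """Localization precision (nm) from consecutive-frame nearest-neighbor
    distances.

    For each localization, the nearest neighbor in the next frame is
    collected; repeated localizations of the same (nearly static) molecule
    produce a Rayleigh-shaped peak whose scale is sqrt(2) times the
    per-axis precision.  The histogram is fitted with that peak plus a
    uniform (area-growing) background term; the precision parameter is
    returned.  Raises :class:`PrecisionError` with fewer than 50 pairs.
    """
    df = _as_loc_frame(localizations)
    groups = {
        int(f): g[["x_nm", "y_nm"]].to_numpy() for f, g in df.groupby("frame")
    }
    dists = []
    for f, pts in groups.items():
        nxt = groups.get(f + 1)
        if nxt is None or nxt.shape[0] == 0:
            continue
        tree = cKDTree(nxt)
        dd, _ = tree.query(pts)
        dists.append(dd)
    if not dists:
        raise PrecisionError("no consecutive-frame localization pairs")
    d = np.concatenate(dists)
    if d.size < 50:
        raise PrecisionError(f"only {d.size} nearest-neighbor pairs; need >= 50")
    if np.median(d) < 1e-9:
        return 0.0  # degenerate: repeated localizations coincide exactly
    d_max = float(np.quantile(d, 0.98) * 1.5)
    counts, edges = np.histogram(d[d <= d_max], bins=n_bins, range=(0, d_max),
                                 density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    sigma0 = float(np.median(d) / (1.1774 * np.sqrt(2.0)))
    popt, _ = curve_fit(
        lambda x, s, b: _nena_pdf(x, s, b, d_max),
        centers,
        counts,
        p0=(sigma0, 0.05),
        bounds=((1e-6, 0.0), (d_max, 1.0)),
        maxfev=20000,
    )
    return float(popt[0])


def trajectory_table(trajectories) -> pd.DataFrame:
    """Per-trajectory summary (id, n, duration, track length, mean
    intensity, mean position, optional FRET efficiency)."""
    rows = []
    for t in trajectories:
        mx, my = t.mean_position
        rows.append(
            {
                "traj_id": t.traj_id,
                "n_localizations": t.n_localizations,
                "duration_s": t.duration,
                "track_length_s": t.track_length,
                "mean_intensity_adu": t.mean_intensity,
                "mean_x_nm": mx,
                "mean_y_nm": my,
                "fret_efficiency": t.fret_efficiency,
            }
        )
    return pd.DataFrame(rows)


def rolling_ball_subtract(image: np.ndarray, radius: int = 5) -> np.ndarray:
    """Rolling-ball background subtraction (cell-data path only)."""
    from skimage.restoration import rolling_ball

    img = np.asarray(image, dtype=float)
    return img - rolling_ball(img, radius=radius)
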