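"""Detection of immobilized single molecules and ROI trace extraction.

The in-vitro pipeline works frame-wise on 16-bit image stacks: a
maximum-intensity projection of the first frames after photo-conversion
seeds detection; a Laplacian-of-Gaussian filter plus local-maxima search
finds candidate emitters; candidates are kept when the projection value
at the peak exceeds a threshold (default 600 ADU).  Each accepted
molecule is reduced to a 1-D trace from a 7x7-pixel signal region and a
surrounding 2-pixel-wide background ring: per frame,

    value = mean(signal pixels) - mean(background-ring pixels),

both taken from that frame, so any per-frame global offset cancels
exactly.

Coordinates are 0-based (row, col) with pixel centers at integer
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "RoiTrace",
    "DetectionParams",
    "max_projection",
    "detect_peaks",
    "extract_trace",
    "extract_traces",
]


@dataclass
class RoiTrace:
    """Per-molecule, per-frame background-subtracted mean signal (ADU).

    ``center`` is the (row, col) ROI center, or None for traces produced
    directly by the trace simulator (which has no image geometry).
    """

    values: np.ndarray
    center: tuple[int, int] | None = None
    roi_size: int = 7
    ring_width: int = 2

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def extent(self) -> int:
        """Full ROI width in pixels (signal region plus ring)."""
        return self.roi_size + 2 * self.ring_width

    def total_signal(self) -> np.ndarray:
        """Background-subtracted signal summed over the signal region
        (trace value times the number of signal pixels), for photon
        conversion."""
        return self.values * (self.roi_size**2)


@dataclass
class DetectionParams:
    """Tunables for LoG peak detection.

    ``peak_threshold`` applies to the raw projection value (camera offset
    included) at the candidate peak.  ``merge_distance`` collapses
    duplicate maxima of a single spot (keep the stronger LoG response);
    ``overlap_distance`` is the full ROI extent: distinct spots closer
    than this would mix molecules in one ROI, so by default both members
    of such a pair are discarded (``exclude_overlapping=False`` keeps the
    brighter one instead).
    """

    projection_frames: int = 2
    log_sigma: float = 1.2
    peak_threshold: float = 600.0
    exclude_overlapping: bool = True
    merge_distance: float = 3.0
    overlap_distance: float = 11.0

    def __post_init__(self):
        if self.peak_threshold <= 0:
            raise ValueError("peak_threshold must be positive")
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be positive")
        if self.projection_frames < 1:
            raise ValueError("projection_frames must be >= 1")


def max_projection(stack: np.ndarray, first_n: int = 2) -> np.ndarray:
    """Per-pixel maximum over the first ``first_n`` frames."""
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frames, rows, cols) array")
    if first_n < 1 or first_n > stack.shape[0]:
        raise ValueError(f"first_n must be in 1..{stack.shape[0]}")
    return stack[:first_n].max(axis=0)


def detect_peaks(
    projection: np.ndarray, params: DetectionParams | None = None
) -> list[tuple[int, int]]:
    """Find single-molecule candidates in a projection image.

    Local maxima of the negated Laplacian-of-Gaussian response whose
    projection value exceeds ``peak_threshold`` are kept, duplicates
    within ``merge_distance`` merged (stronger response wins, ties broken
    by row-major order), overlapping ROIs resolved per
    ``exclude_overlapping``, and centers too close to the border for a
    full ROI dropped.  Centers are returned in row-major order.
    """
    params = params or DetectionParams()
    projection = np.asarray(projection)
    if projection.ndim != 2 or projection.size == 0:
        raise ValueError("projection must be a non-empty 2-D image")
    resp = -ndimage.gaussian_laplace(projection.astype(float), params.log_sigma)
    local_max = resp == ndimage.maximum_filter(resp, size=3)
    rows, cols = np.nonzero(local_max & (projection > params.peak_threshold))
    # strongest response first; ties in row-major order
    order = np.lexsort((cols, rows, -resp[rows, cols]))
    cand = list(zip(rows[order].tolist(), cols[order].tolist()))

    # merge duplicate maxima of the same spot
    merged: list[tuple[int, int]] = []
    for r, c in cand:
        if all((r - r2) ** 2 + (c - c2) ** 2 >= params.merge_distance**2
               for r2, c2 in merged):
            merged.append((r, c))

    # resolve overlapping ROIs
    d2 = params.overlap_distance**2
    if params.exclude_overlapping:
        kept = [
            p
            for p in merged
            if all(
                q is p or (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= d2
                for q in merged
            )
        ]
    else:  # keep the nearer-brighter: greedy in response order
        kept = []
        for p in merged:
            if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= d2 for q in kept):
                kept.append(p)

    # the full ROI (signal + ring) must fit inside the image
    half = 5  # (7 + 2*2) // 2
    h, w = projection.shape
    kept = [
        (r, c) for r, c in kept if half <= r <= h - 1 - half and half <= c <= w - 1 - half
    ]
    return sorted(kept)


def extract_trace(
    stack: np.ndarray,
    center: tuple[int, int],
    roi_size: int = 7,
    ring_width: int = 2,
) -> RoiTrace:
    """Extract the background-subtracted 1-D trace for one ROI.

    Raises ``ValueError`` if the full ROI does not fit inside the image.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    r, c = int(center[0]), int(center[1])
    half_in = roi_size // 2
    half = half_in + ring_width
    _, h, w = stack.shape
    if not (half <= r <= h - 1 - half and half <= c <= w - 1 - half):
        raise ValueError(f"ROI at {center} does not fit inside the image")
    sub = stack[:, r - half : r + half + 1, c - half : c + half + 1].astype(float)
    inner = sub[:, ring_width : ring_width + roi_size, ring_width : ring_width + roi_size]
    sig_mean = inner.mean(axis=(1, 2))
    n_ring = sub.shape[1] * sub.shape[2] - roi_size**2
    ring_mean = (sub.sum(axis=(1, 2)) - inner.sum(axis=(1, 2))) / n_ring
    return RoiTrace(values=sig_mean - ring_mean, center=(r, c),
                    roi_size=roi_size, ring_width=ring_width)


def extract_traces(
    stack: np.ndarray, centers, roi_size: int = 7, ring_width: int = 2
) -> list[RoiTrace]:
    """Extract traces for many centers, skipping out-of-bounds ROIs with
    a warning."""
    traces = []
    for center in centers:
        try:
            traces.append(extract_trace(stack, center, roi_size, ring_width))
        except ValueError as err:
            warnings.warn(f"skipping ROI: {err}", stacklevel=2)
    return traces
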