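"""Per-ROI and per-pixel-bin intensity traces and moving-average detrending.

The baseline of slice luminometry drifts over days (substrate depletion,
damping); the standard correction is subtraction of a 24-h centered moving
average, which nulls any trend that is locally constant over one circadian
cycle while leaving a 24-h-periodic component untouched (the mean of a
cosine over a full period is zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .movie_io import MovieStack, RegionMask

_UNIFORMITY_TOL = 1e-9  # hours


@dataclass
class Trace:
    """One ROI/pixel-bin time series: paired times (h) and intensities."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    detrended: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise ValueError(
                f"times ({len(self.times)}) and values ({len(self.values)}) "
                "must have equal length"
            )
        if len(self.times) < 2:
            raise ValueError("a trace needs at least 2 samples")
        dt = np.diff(self.times)
        if dt.min() <= 0:
            raise ValueError("times must be strictly increasing")
        if dt.max() - dt.min() > _UNIFORMITY_TOL:
            raise ValueError(
                f"sampling must be uniform within {_UNIFORMITY_TOL} h, "
                f"spread is {dt.max() - dt.min():.3g} h"
            )

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


def extract_trace(stack: MovieStack, mask: RegionMask, region_or_roi) -> Trace:
    """Mean-intensity trace of a region (name or label) or boolean ROI."""
    mask.check_shape(stack)
    if isinstance(region_or_roi, np.ndarray) and region_or_roi.dtype == bool:
        pix = region_or_roi
        if pix.shape != stack.spatial_shape:
            raise ValueError("ROI shape must match the movie's spatial shape")
        name = "roi"
    else:
        pix = mask.region_pixels(region_or_roi)
        name = (
            region_or_roi
            if isinstance(region_or_roi, str)
            else mask.label_map.get(int(region_or_roi), str(region_or_roi))
        )
    n = int(pix.sum())
    if n == 0:
        raise ValueError(f"region {name!r} has no pixels")
    values = stack.data[:, pix].mean(axis=1)
    return Trace(stack.times, values, label=f"{name}(n={n})",
                 meta={"region": name, "n_pixels": n})


def bin_stack(stack: MovieStack, bin_factor: int):
    """Block-average a movie into non-overlapping bin_factor x bin_factor tiles.

    Returns ``(binned, counts)`` where ``binned`` has shape
    ``(n_rows, n_cols, T)`` (tile means per frame, partial edge tiles use the
    mean over their actual pixels) and ``counts`` the pixels per tile.
    """
    bin_factor = int(bin_factor)
    h, w = stack.spatial_shape
    if bin_factor < 1:
        raise ValueError(f"bin_factor must be >= 1, got {bin_factor}")
    if bin_factor > min(h, w):
        raise ValueError(
            f"bin_factor {bin_factor} exceeds the smaller image side {min(h, w)}"
        )
    row_edges = np.arange(0, h, bin_factor)
    col_edges = np.arange(0, w, bin_factor)
    summed = np.add.reduceat(
        np.add.reduceat(stack.data, row_edges, axis=1), col_edges, axis=2
    )
    rc = np.minimum(row_edges + bin_factor, h) - row_edges
    cc = np.minimum(col_edges + bin_factor, w) - col_edges
    counts = np.outer(rc, cc)
    binned = np.moveaxis(summed, 0, -1) / counts[..., None]
    return binned, counts


def bin_map(image: np.ndarray, bin_factor: int, foreground: np.ndarray | None = None):
    """Block-average a 2-D map into bin_factor x bin_factor tiles.

    With ``foreground`` (boolean, e.g. the tissue mask) the tile mean is
    taken over foreground pixels only — the per-tissue-area reading needed
    when comparing staining intensity against per-bin fit parameters at the
    tissue boundary.  Tiles with no foreground pixel become NaN.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"map must be 2-D, got shape {image.shape}")
    weights = (
        np.ones_like(image)
        if foreground is None
        else np.asarray(foreground, dtype=float)
    )
    h, w = image.shape
    row_edges = np.arange(0, h, int(bin_factor))
    col_edges = np.arange(0, w, int(bin_factor))

    def block_sum(arr):
        return np.add.reduceat(
            np.add.reduceat(arr, row_edges, axis=0), col_edges, axis=1
        )

    num = block_sum(image * weights)
    den = block_sum(weights)
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)


def pixel_traces(stack: MovieStack, bin_factor: int = 1) -> list[Trace]:
    """Traces of all non-overlapping spatial bins, row-major order.

    Each trace's ``meta`` records its ``(row, col)`` bin coordinate, pixel
    count, and whether it is a partial edge tile.
    """
    binned, counts = bin_stack(stack, bin_factor)
    full = int(bin_factor) ** 2
    out = []
    for r in range(binned.shape[0]):
        for c in range(binned.shape[1]):
            n = int(counts[r, c])
            out.append(
                Trace(
                    stack.times,
                    binned[r, c],
                    label=f"bin[{r},{c}]",
                    meta={"row": r, "col": c, "n_pixels": n,
                          "partial": n < full},
                )
            )
    return out


def detrend_window_frames(window: float, dt: float) -> int:
    """Frame count of a moving-average window.

    An exact multiple of the frame interval keeps its frame count (even or
    odd — an even count is what nulls an exactly-one-period cosine); any
    other window is rounded to the nearest odd count for a symmetric center.
    """
    ratio = window / dt
    if abs(ratio - round(ratio)) < 1e-9:
        n = int(round(ratio))
    else:
        n = int(round((ratio - 1) / 2)) * 2 + 1
    return max(n, 1)


def _window_bounds(i: int, n_frames: int, total: int) -> tuple[int, int]:
    """Centered window [lo, hi) around index i, truncated at the edges."""
    lo = i - n_frames // 2
    hi = lo + n_frames
    return max(lo, 0), min(hi, total)


def moving_average_detrend(trace: Trace, window: float = 24.0) -> Trace:
    """Subtract a centered moving-average baseline from a trace.

    At the edges the window is truncated to the available samples, so the
    output keeps the input's length (time-to-first-peak needs the early
    frames).  The effective window, in frames, is recorded in the label and
    ``meta``.
    """
    if window <= 0:
        raise ValueError(f"window must be > 0, got {window}")
    if trace.span < window - 1e-9:
        raise ValueError(
            f"trace spans {trace.span:.3g} h, shorter than the {window:.3g} h "
            "detrend window"
        )
    n_frames = detrend_window_frames(window, trace.dt)
    total = len(trace.values)
    baseline = np.empty(total)
    for i in range(total):
        lo, hi = _window_bounds(i, n_frames, total)
        baseline[i] = np.mean(trace.values[lo:hi])
    meta = dict(trace.meta, detrend_window_frames=n_frames,
                detrend_window_hours=window, edge_frames=n_frames // 2)
    return Trace(
        trace.times,
        trace.values - baseline,
        label=f"{trace.label}|detrended(w={n_frames}f)",
        detrended=True,
        meta=meta,
    )


def detrend_matrix(values: np.ndarray, n_frames: int) -> np.ndarray:
    """Moving-average-detrend many traces at once.

    ``values`` is (n_traces, T); uses the same window bounds (and the same
    axis-wise pairwise summation) as :func:`moving_average_detrend`.
    """
    total = values.shape[1]
    baseline = np.empty_like(values)
    for i in range(total):
        lo, hi = _window_bounds(i, n_frames, total)
        baseline[:, i] = values[:, lo:hi].mean(axis=1)
    return values - baseline
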