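"""Readers and writers for movies, region masks, maps and tables.

Conventions: arrays are indexed ``(row, col)``, 0-based, origin top-left;
the time axis comes first in stacks.  The frame interval is supplied by the
caller (acquisition software records it in too many dialects to parse), not
read from TIFF metadata.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

#: Region vocabulary used throughout: every mask label must map to one of these.
REGION_NAMES = frozenset(
    {
        "background",
        "parenchyma_fibrotic",
        "parenchyma_nonfibrotic",
        "bronchiole_fibrotic",
        "bronchiole_nonfibrotic",
        "other",
    }
)


@dataclass
class MovieStack:
    """A T x Y x X bioluminescence movie with uniform frame spacing.

    ``frame_interval`` is in hours (0.5 h for a 30-min camera integration);
    frame ``i`` was acquired at ``start_time + i * frame_interval``.
    """

    data: np.ndarray
    frame_interval: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"movie must be T x Y x X, got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError(
                f"a movie needs at least 2 frames, got {self.data.shape[0]}"
            )
        if not np.isfinite(self.frame_interval) or self.frame_interval <= 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("movie intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("movie intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame, hours."""
        return self.start_time + np.arange(self.n_frames) * self.frame_interval

    @property
    def duration(self) -> float:
        """Span from first to one past the last frame, hours."""
        return self.n_frames * self.frame_interval


@dataclass
class RegionMask:
    """Labeled image assigning each pixel one region class."""

    labels: np.ndarray
    label_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("mask labels must be integers")
            self.labels = np.round(self.labels).astype(np.int32)
        self.label_map = {int(k): str(v) for k, v in self.label_map.items()}
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = sorted(present - set(self.label_map))
        if missing:
            raise ValueError(
                f"labels present in mask but missing from label map: {missing}"
            )
        bad = sorted(set(self.label_map.values()) - REGION_NAMES)
        if bad:
            raise ValueError(
                f"unknown region names {bad}; allowed: {sorted(REGION_NAMES)}"
            )

    def label_for(self, region: str) -> int:
        for lab, name in self.label_map.items():
            if name == region:
                return lab
        raise KeyError(f"region {region!r} not in label map {self.label_map}")

    def region_pixels(self, region) -> np.ndarray:
        """Boolean pixel mask for a region given by name or integer label."""
        if isinstance(region, str):
            if region == "background":
                known = np.zeros(self.labels.shape, bool)
                for lab in self.label_map:
                    known |= self.labels == lab
                return ~known
            region = self.label_for(region)
        return self.labels == int(region)

    def regions_present(self) -> list[str]:
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        return sorted(self.label_map[lab] for lab in present)

    def check_shape(self, stack: MovieStack) -> None:
        if self.labels.shape != stack.spatial_shape:
            raise ValueError(
                f"mask shape {self.labels.shape} does not match movie spatial "
                f"shape {stack.spatial_shape}"
            )


def read_movie(path, frame_interval: float, start_time: float = 0.0) -> MovieStack:
    """Load a multi-page TIFF as a :class:`MovieStack`.

    Values are cast to nonnegative floats; a single-page file is rejected
    because it cannot carry a time series.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        raise ValueError(f"{path} holds a single page; a movie needs >= 2 frames")
    if arr.ndim != 3:
        raise ValueError(f"{path} has unexpected shape {arr.shape}")
    return MovieStack(
        np.maximum(arr.astype(float), 0.0), frame_interval, start_time=start_time
    )


def write_movie(stack: MovieStack, path) -> None:
    """Write a movie as a multi-page TIFF.

    Integer-valued data that fits is stored as uint16 (lossless round trip);
    anything else as float32.
    """
    data = stack.data
    integral = np.array_equal(data, np.round(data)) and data.max(initial=0) <= 65535
    out = data.astype(np.uint16) if integral else data.astype(np.float32)
    tifffile.imwrite(str(path), out)


def read_mask(path_tiff, path_labelmap_csv) -> RegionMask:
    """Read a labeled mask TIFF together with its label -> region-name CSV."""
    labels = tifffile.imread(str(path_tiff))
    label_map = {}
    with open(path_labelmap_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            label_map[int(row["label"])] = row["region"].strip()
    return RegionMask(labels, label_map)


def write_mask(mask: RegionMask, path_tiff, path_labelmap_csv) -> None:
    tifffile.imwrite(str(path_tiff), mask.labels.astype(np.uint16))
    with open(path_labelmap_csv, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "region"])
        for lab in sorted(mask.label_map):
            w.writerow([lab, mask.label_map[lab]])


def write_table(rows, path, columns=None) -> None:
    """Write tabular output as CSV with a header.

    Accepts a DataFrame or an iterable of dicts; an empty table still gets
    its header row when ``columns`` (or DataFrame columns) are known.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        df = pd.DataFrame(rows, columns=columns if (columns or not rows) else None)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_map(image, path) -> None:
    """Write a 2-D float map (amplitude, phase, ...) as a float32 TIFF."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"map must be 2-D, got shape {image.shape}")
    tifffile.imwrite(str(path), image.astype(np.float32))


def read_map(path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-page map (shape {arr.shape})")
    return arr.astype(float)
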