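"""Time-resolved image stack containers and TIFF + JSON sidecar IO.

A FLIM acquisition is stored as a photon-count hypercube indexed
``(z, y, x, t)`` together with its acquisition metadata: TCSPC time-channel
width, number of time channels, laser repetition period (12.5 ns at 80 MHz),
position of the decay maximum, pixel size and z-step.  On disk the canonical
container is a multi-page 16-bit TIFF with time as the page axis (z-major
ordering for 3D stacks) and the metadata in a JSON sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

from .errors import ShapeError, ValidationError

__all__ = [
    "AcquisitionMetadata",
    "FLIMStack",
    "DecayHistogram",
    "read_flim_stack",
    "write_flim_stack",
]

#: Relative slack on n_time_channels * time_channel_width vs the repetition
#: period.  TCSPC electronics commonly overshoot by a fraction of a channel
#: (e.g. 3128 x 4 ps = 12.512 ns against a 12.5 ns period).
_TIME_RANGE_REL_TOL = 0.01

_SIDECAR_KEYS = {
    "time_channel_width_ns": "time_channel_width",
    "n_time_channels": "n_time_channels",
    "rep_period_ns": "rep_period",
    "peak_position_ns": "peak_position",
    "pixel_size_um": "pixel_size",
    "z_step_um": "z_step",
}


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Timing and geometry of a TCSPC FLIM acquisition.

    Parameters
    ----------
    time_channel_width : float
        Width of one TCSPC time channel in ns.
    n_time_channels : int
        Number of time channels per pixel.
    rep_period : float
        Laser repetition period in ns (12.5 ns at 80 MHz).
    peak_position : float
        Position of the maximum of the intensity decay, in ns from the
        start of the acquisition window.
    pixel_size : float
        Lateral pixel size dx in um/pixel.
    z_step : float or None
        Axial step in um between slices of a z-stack (None for 2D data).
    """

    time_channel_width: float
    n_time_channels: int
    rep_period: float
    peak_position: float
    pixel_size: float
    z_step: float | None = None

    def __post_init__(self) -> None:
        if not self.time_channel_width > 0:
            raise ValidationError(
                f"time_channel_width must be > 0, got {self.time_channel_width}"
            )
        if int(self.n_time_channels) != self.n_time_channels or self.n_time_channels < 2:
            raise ValidationError(
                f"n_time_channels must be an integer >= 2, got {self.n_time_channels}"
            )
        if not self.rep_period > 0:
            raise ValidationError(f"rep_period must be > 0, got {self.rep_period}")
        window = self.n_time_channels * self.time_channel_width
        if window > self.rep_period * (1.0 + _TIME_RANGE_REL_TOL):
            raise ValidationError(
                "time window exceeds the laser repetition period: "
                f"{self.n_time_channels} x {self.time_channel_width} ns = "
                f"{window:g} ns > {self.rep_period:g} ns"
            )
        if not (0.0 <= self.peak_position < window):
            raise ValidationError(
                f"peak_position must lie within [0, {window:g}) ns, "
                f"got {self.peak_position}"
            )
        if not self.pixel_size > 0:
            raise ValidationError(f"pixel_size must be > 0, got {self.pixel_size}")
        if self.z_step is not None and not self.z_step > 0:
            raise ValidationError(f"z_step must be > 0 or None, got {self.z_step}")

    @property
    def time_range(self) -> float:
        """Total acquired time window in ns."""
        return self.n_time_channels * self.time_channel_width

    @property
    def angular_frequency(self) -> float:
        """Fundamental phasor angular frequency omega = 2*pi/rep_period (rad/ns)."""
        return 2.0 * math.pi / self.rep_period

    def channel_centers(self) -> np.ndarray:
        """Centers of the time channels in ns; channel k spans [k*dt, (k+1)*dt)."""
        dt = self.time_channel_width
        return (np.arange(self.n_time_channels) + 0.5) * dt

    def channel_edges(self) -> np.ndarray:
        """The n+1 channel edge times in ns."""
        return np.arange(self.n_time_channels + 1) * self.time_channel_width

    def to_sidecar_dict(self) -> dict:
        return {
            "time_channel_width_ns": self.time_channel_width,
            "n_time_channels": int(self.n_time_channels),
            "rep_period_ns": self.rep_period,
            "peak_position_ns": self.peak_position,
            "pixel_size_um": self.pixel_size,
            "z_step_um": self.z_step,
        }

    @classmethod
    def from_sidecar_dict(cls, data: dict) -> "AcquisitionMetadata":
        missing = [k for k in _SIDECAR_KEYS if k not in data and k != "z_step_um"]
        if missing:
            raise ValidationError(f"sidecar is missing metadata fields: {missing}")
        kwargs = {}
        for json_key, attr in _SIDECAR_KEYS.items():
            if json_key in data:
                kwargs[attr] = data[json_key]
        return cls(**kwargs)


def _validate_counts(counts: np.ndarray, metadata: AcquisitionMetadata) -> np.ndarray:
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        if np.issubdtype(counts.dtype, np.floating) and np.allclose(
            counts, np.round(counts)
        ):
            counts = np.round(counts).astype(np.int64)
        else:
            raise ValidationError(
                f"photon counts must be integers, got dtype {counts.dtype}"
            )
    if counts.size == 0:
        raise ShapeError("photon count array is empty")
    if counts.min() < 0:
        raise ValidationError("photon counts must be non-negative")
    if counts.shape[-1] != metadata.n_time_channels:
        raise ShapeError(
            f"t-axis length {counts.shape[-1]} does not match "
            f"metadata.n_time_channels = {metadata.n_time_channels}"
        )
    return counts


@dataclass(frozen=True)
class DecayHistogram:
    """Photon counts per time channel for a single pixel or ROI."""

    counts: np.ndarray
    metadata: AcquisitionMetadata

    def __post_init__(self) -> None:
        counts = _validate_counts(self.counts, self.metadata)
        if counts.ndim != 1:
            raise ShapeError(f"decay histogram must be 1D, got shape {counts.shape}")
        object.__setattr__(self, "counts", counts)

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FLIMStack:
    """Photon-count hypercube ``(z, y, x, t)`` with acquisition metadata.

    2D acquisitions are stored with a singleton z axis; the constructor
    normalizes ``(y, x, t)`` input accordingly.
    """

    counts: np.ndarray
    metadata: AcquisitionMetadata
    provenance: str = ""

    def __post_init__(self) -> None:
        counts = _validate_counts(self.counts, self.metadata)
        if counts.ndim == 3:
            counts = counts[np.newaxis]
        if counts.ndim != 4:
            raise ShapeError(
                f"FLIM stack must be (z, y, x, t) or (y, x, t), got shape {counts.shape}"
            )
        if min(counts.shape[:3]) < 1:
            raise ShapeError(f"spatial dimensions must be >= 1, got {counts.shape}")
        object.__setattr__(self, "counts", counts)

    @property
    def shape(self) -> tuple:
        return self.counts.shape

    @property
    def n_slices(self) -> int:
        return self.counts.shape[0]

    def pixel_decay(self, z: int, y: int, x: int) -> DecayHistogram:
        return DecayHistogram(self.counts[z, y, x].copy(), self.metadata)

    def with_counts(self, counts: np.ndarray) -> "FLIMStack":
        return replace(self, counts=counts)


def _sidecar_path(path: Path, sidecar) -> Path:
    if sidecar is not None:
        return Path(sidecar)
    return path.with_suffix(".json")


def read_flim_stack(path, sidecar=None) -> FLIMStack:
    """Read a multi-page TIFF + JSON sidecar into a normalized FLIMStack.

    Pages are ordered z-major: page index = z * n_time_channels + t.
    Raises ValidationError for missing/contradictory metadata and
    ShapeError when the container disagrees with the sidecar.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path, sidecar)
    if not path.exists():
        raise ValidationError(f"container does not exist: {path}")
    if not sidecar_path.exists():
        raise ValidationError(f"metadata sidecar does not exist: {sidecar_path}")
    with open(sidecar_path) as fh:
        try:
            meta_dict = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"sidecar is not valid JSON: {exc}") from exc
    metadata = AcquisitionMetadata.from_sidecar_dict(meta_dict)

    pages = tifffile.imread(path)
    pages = np.atleast_2d(pages)
    if pages.ndim == 2:
        pages = pages[np.newaxis]
    if pages.size == 0:
        raise ShapeError(f"container {path} holds no image data")
    n_pages = pages.shape[0]
    nt = metadata.n_time_channels
    if n_pages % nt != 0:
        raise ShapeError(
            f"{n_pages} pages are not divisible by n_time_channels = {nt}"
        )
    nz = n_pages // nt
    counts = pages.reshape(nz, nt, pages.shape[1], pages.shape[2])
    counts = np.moveaxis(counts, 1, -1)  # (z, y, x, t)
    if np.issubdtype(counts.dtype, np.signedinteger) and counts.min() < 0:
        raise ValidationError(f"container {path} holds negative counts")
    return FLIMStack(counts=counts, metadata=metadata, provenance=str(path))


def write_flim_stack(stack: FLIMStack, path, sidecar=None) -> Path:
    """Write a FLIMStack as multi-page TIFF + JSON sidecar; returns the path.

    Round trip is bit-exact: read_flim_stack(write_flim_stack(s)) reproduces
    counts and metadata.
    """
    path = Path(path)
    sidecar_path = _sidecar_path(path, sidecar)
    counts = stack.counts
    if counts.max(initial=0) > np.iinfo(np.uint16).max:
        dtype = np.uint32
    else:
        dtype = np.uint16
    nz, ny, nx, nt = counts.shape
    pages = np.moveaxis(counts, -1, 1).reshape(nz * nt, ny, nx).astype(dtype)
    try:
        tifffile.imwrite(path, pages, photometric="minisblack")
        with open(sidecar_path, "w") as fh:
            json.dump(stack.metadata.to_sidecar_dict(), fh, indent=2)
    except OSError as exc:
        raise IOError(f"cannot write stack to {path}: {exc}") from exc
    return path
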