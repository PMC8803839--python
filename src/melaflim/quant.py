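"""3D epidermal melanin quantification.

Turns a boolean melanin mask stack plus an epidermis segmentation
(per-column skin-surface and dermal-epidermal-junction depths) into the
quantitative endpoints used for in vivo pigmentation studies:

* global 3D melanin density over the epidermis, and over named sub-layers
  (stratum corneum, living epidermis) when their boundaries are provided;
* the z-distribution profile: melanin density in 12 thickness-normalized
  epidermal layers, layer 1 at the DEJ level and layer 12 at the SC level.

Density is defined as the voxel-fraction percentage: 100 x (melanin voxels
in region) / (voxels in region).  A binary mask supports no other notion of
density; the definition is stated here on purpose.

Per-column normalized depth is u = (depth - surface) / (dej - surface), so
u = 0 at the skin surface and u = 1 at the DEJ.  A voxel with normalized
depth u is assigned to layer 12 - floor(12 u), clamped to [1, 12]; bins are
half-open at the shallow side so every epidermal voxel lands in exactly one
layer and the voxel-weighted mean of the 12 layer densities equals the
global density exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CapabilityError, ShapeError, ValidationError

__all__ = [
    "EpidermisSegmentation",
    "MelaninProfile",
    "melanin_density",
    "z_profile",
    "profile_report",
    "plot_profile",
]

N_LAYERS_DEFAULT = 12


@dataclass(frozen=True)
class EpidermisSegmentation:
    """Per-(y, x) surface and DEJ depths in um, with optional sub-layer boundaries.

    ``boundaries`` may carry named interface depth maps; the one the density
    regions use is ``"sc_led"``, the stratum corneum / living epidermis
    interface.  ``valid`` marks columns with usable surfaces.

    The depth axis may run in either direction (a z-flipped stack is handled
    by flipping the maps consistently); the orientation must be uniform:
    dej - surface has the same sign on every valid column.
    """

    surface_depth: np.ndarray
    dej_depth: np.ndarray
    z_step: float
    boundaries: dict = field(default_factory=dict)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        surface = np.asarray(self.surface_depth, dtype=float)
        dej = np.asarray(self.dej_depth, dtype=float)
        if surface.ndim != 2 or surface.shape != dej.shape:
            raise ShapeError(
                f"surface and DEJ depth maps must be 2D with equal shapes, "
                f"got {surface.shape} and {dej.shape}"
            )
        if not self.z_step > 0:
            raise ValidationError(f"z_step must be > 0, got {self.z_step}")
        valid = self.valid
        if valid is None:
            valid = np.isfinite(surface) & np.isfinite(dej)
        else:
            valid = np.asarray(valid, dtype=bool)
            if valid.shape != surface.shape:
                raise ShapeError("valid-column mask shape mismatch")
            valid = valid & np.isfinite(surface) & np.isfinite(dej)
        thickness = dej - surface
        nonzero = valid & (thickness != 0)
        signs = np.sign(thickness[nonzero])
        if signs.size and signs.min() != signs.max():
            raise ValidationError(
                "inconsistent depth-axis orientation: dej - surface changes sign"
            )
        boundaries = dict(self.boundaries)
        for name, bmap in boundaries.items():
            bmap = np.asarray(bmap, dtype=float)
            if bmap.shape != surface.shape:
                raise ShapeError(f"boundary map {name!r} shape mismatch")
            boundaries[name] = bmap
        object.__setattr__(self, "surface_depth", surface)
        object.__setattr__(self, "dej_depth", dej)
        object.__setattr__(self, "boundaries", boundaries)
        object.__setattr__(self, "valid", valid)

    @property
    def shape(self) -> tuple:
        return self.surface_depth.shape

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "surface_depth_um": self.surface_depth.tolist(),
            "dej_depth_um": self.dej_depth.tolist(),
            "z_step_um": self.z_step,
            "boundaries_um": {k: v.tolist() for k, v in self.boundaries.items()},
            "valid": self.valid.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return path

    @classmethod
    def from_json(cls, path) -> "EpidermisSegmentation":
        with open(path) as fh:
            data = json.load(fh)
        try:
            return cls(
                surface_depth=np.asarray(data["surface_depth_um"], dtype=float),
                dej_depth=np.asarray(data["dej_depth_um"], dtype=float),
                z_step=float(data["z_step_um"]),
                boundaries={
                    k: np.asarray(v, dtype=float)
                    for k, v in data.get("boundaries_um", {}).items()
                },
                valid=np.asarray(data["valid"], dtype=bool)
                if "valid" in data
                else None,
            )
        except KeyError as exc:
            raise ValidationError(f"segmentation JSON is missing field {exc}") from exc


@dataclass(frozen=True)
class MelaninProfile:
    """12-layer thickness-normalized melanin z-profile plus global densities.

    ``layer_density[i]`` is the density (%) of layer i+1; layer 1 is the DEJ
    level, layer 12 the SC level.  Counts of (melanin, total) voxels per
    layer are kept so aggregates remain exact.
    """

    layer_density: np.ndarray
    global_density: float
    melanin_counts: np.ndarray
    total_counts: np.ndarray
    sublayer_densities: dict = field(default_factory=dict)
    n_excluded_columns: int = 0

    @property
    def n_layers(self) -> int:
        return len(self.layer_density)

    def as_frame(self, label: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": label,
                "layer": np.arange(1, self.n_layers + 1),
                "density_pct": self.layer_density,
                "melanin_voxels": self.melanin_counts,
                "total_voxels": self.total_counts,
            }
        )


def _as_mask_array(mask) -> np.ndarray:
    # accept a raw boolean stack or anything exposing `.mask` (MelaninMask)
    arr = getattr(mask, "mask", mask)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ShapeError(f"melanin mask must be (z, y, x), got shape {arr.shape}")
    return arr.astype(bool)


def _normalized_depth(mask_shape, seg: EpidermisSegmentation):
    """Per-voxel normalized depth u and the valid-column mask, broadcast to (z, y, x)."""
    nz, ny, nx = mask_shape
    if seg.shape != (ny, nx):
        raise ShapeError(
            f"segmentation {seg.shape} does not match mask columns {(ny, nx)}"
        )
    depth = (np.arange(nz) * seg.z_step)[:, None, None]
    thickness = seg.dej_depth - seg.surface_depth
    degenerate = thickness == 0
    ok = seg.valid & ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (depth - seg.surface_depth[None]) / thickness[None]
    u = np.where(ok[None], u, np.nan)
    n_excluded = int(np.count_nonzero(seg.valid & degenerate))
    return u, ok, n_excluded


def _region_mask(u, depth, seg: EpidermisSegmentation, region: str):
    region = region.lower()
    if region in ("epidermis", "ed", "global"):
        return (u >= 0.0) & (u <= 1.0)
    if region in ("sc", "led", "stratum_corneum", "living_epidermis"):
        if "sc_led" not in seg.boundaries:
            raise CapabilityError(
                f"region {region!r} needs the 'sc_led' boundary in the segmentation"
            )
        b = seg.boundaries["sc_led"][None]
        surface = seg.surface_depth[None]
        dej = seg.dej_depth[None]
        # express the boundary on the normalized axis so flipped stacks work
        with np.errstate(divide="ignore", invalid="ignore"):
            ub = (b - surface) / (dej - surface)
        if region in ("sc", "stratum_corneum"):
            return (u >= 0.0) & (u < ub)
        return (u >= ub) & (u <= 1.0)
    raise ValidationError(f"unknown region {region!r}")


def melanin_density(mask, seg: EpidermisSegmentation, region: str = "epidermis") -> float:
    """Voxel-fraction melanin density (%) within a named region.

    ``region`` is ``"epidermis"`` (surface to DEJ), ``"sc"`` or ``"led"``
    (the latter two need the ``sc_led`` boundary).  Invalid and degenerate
    columns are excluded.
    """
    arr = _as_mask_array(mask)
    u, ok, _ = _normalized_depth(arr.shape, seg)
    depth = (np.arange(arr.shape[0]) * seg.z_step)[:, None, None]
    with np.errstate(invalid="ignore"):
        region_vox = _region_mask(u, depth, seg, region) & ok[None]
    total = int(np.count_nonzero(region_vox))
    if total == 0:
        raise ValidationError(f"region {region!r} contains no voxels")
    mel = int(np.count_nonzero(arr & region_vox))
    return 100.0 * mel / total


def z_profile(mask, seg: EpidermisSegmentation, n_layers: int = N_LAYERS_DEFAULT) -> MelaninProfile:
    """Melanin density per thickness-normalized epidermal layer.

    Voxels are pooled across columns before the per-layer densities are
    computed (per-column averaging is available via ``profile_report`` on a
    list of single-column profiles if ever needed).  Layer 1 contains the
    DEJ (u = 1, by clamping), layer ``n_layers`` the surface (u = 0).
    """
    arr = _as_mask_array(mask)
    u, ok, n_excluded = _normalized_depth(arr.shape, seg)
    with np.errstate(invalid="ignore"):
        in_epidermis = (u >= 0.0) & (u <= 1.0) & ok[None]
    uu = u[in_epidermis]
    mel = arr[in_epidermis]
    layer = n_layers - np.floor(n_layers * uu).astype(int)
    layer = np.clip(layer, 1, n_layers)
    total_counts = np.bincount(layer, minlength=n_layers + 1)[1:]
    mel_counts = np.bincount(layer[mel], minlength=n_layers + 1)[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(
            total_counts > 0, 100.0 * mel_counts / np.maximum(total_counts, 1), 0.0
        )
    total_vox = int(total_counts.sum())
    global_density = 100.0 * mel_counts.sum() / total_vox if total_vox else 0.0
    sublayers = {}
    if "sc_led" in seg.boundaries:
        for name in ("sc", "led"):
            try:
                sublayers[name] = melanin_density(arr, seg, name)
            except ValidationError:
                pass
    return MelaninProfile(
        layer_density=density.astype(float),
        global_density=float(global_density),
        melanin_counts=mel_counts.astype(np.int64),
        total_counts=total_counts.astype(np.int64),
        sublayer_densities=sublayers,
        n_excluded_columns=n_excluded,
    )


def profile_report(profiles, labels=None):
    """Tidy long-format table plus per-layer mean and 95% CI of the mean.

    Returns ``(table, summary)``: ``table`` has one row per (profile, layer);
    ``summary`` one row per layer with mean, ci_low, ci_high (normal CI,
    undefined — NaN — for a single profile).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("profile_report needs at least one profile")
    if labels is None:
        labels = [f"profile_{i}" for i in range(len(profiles))]
    if len(labels) != len(profiles):
        raise ValidationError("labels and profiles length mismatch")
    table = pd.concat(
        [p.as_frame(label) for p, label in zip(profiles, labels)],
        ignore_index=True,
    )
    grouped = table.groupby("layer")["density_pct"]
    summary = grouped.agg(["mean", "std", "count"]).reset_index()
    with np.errstate(invalid="ignore"):
        half = 1.96 * summary["std"] / np.sqrt(summary["count"])
    summary["ci_low"] = summary["mean"] - half
    summary["ci_high"] = summary["mean"] + half
    return table, summary


def plot_profile(summary: pd.DataFrame, ax=None, label: str | None = None):
    """Plot a mean +/- CI z-profile (layer 1 = DEJ ... 12 = SC) on ``ax``."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(
        summary["layer"],
        summary["mean"],
        yerr=np.nan_to_num((summary["ci_high"] - summary["ci_low"]) / 2.0),
        marker="o",
        capsize=3,
        label=label,
    )
    ax.set_xlabel("thickness-normalized layer (1 = DEJ, 12 = SC)")
    ax.set_ylabel("melanin density (%)")
    ax.set_xticks(summary["layer"])
    if label:
        ax.legend()
    return ax
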