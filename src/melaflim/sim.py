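"""Synthetic TCSPC decays, 2D FLIM images and 3D skin phantoms.

The simulator emulates two-photon excited fluorescence decays at 80 MHz
repetition (12.5 ns period) with the decay maximum at 1.33 ns: mono- and
bi-exponential species with Poisson counting noise, uniform background
photons, and periodic wrap of fluorescence emitted beyond the repetition
period (incomplete-decay handling — a 2.7 ns component retains ~0.3% of its
intensity at the end of a 12.5 ns window and re-enters at t = 0).

No instrument response function is modeled: the decay rises as a step at
the peak position, matching the way the analyses bin and fit relative to
the decay maximum.  ``expected_decay`` exposes the analytic per-channel
expectation so tests can check Poisson moments against a closed form.

Reference species
-----------------
``species_a`` (0.1 ns) and ``species_b`` (2.2 ns) are the canonical fast
and slow mono-exponential fluorophores, and ``mixed_ab`` their 90%/10%
relative-amplitude mixture — the decay shape measured in melanin-containing
samples.  The skin phantom's defaults use measured skin decays instead:
``melanin_species`` (66 ps / 1.59 ns, a1 = 99%, the synthetic-melanin
decay) and ``keratinocyte_species`` (419 ps / 2.73 ns, a1 = 60%, the
free/bound NAD(P)H + FAD mixture of non-melanized keratinocytes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ShapeError, ValidationError
from .io import AcquisitionMetadata, DecayHistogram, FLIMStack
from .quant import EpidermisSegmentation

__all__ = [
    "DecayModelParams",
    "SkinPhantomSpec",
    "GroundTruth",
    "expected_decay",
    "simulate_decay",
    "simulate_flim_image",
    "simulate_skin_stack",
    "species_a",
    "species_b",
    "mixed_ab",
    "melanin_species",
    "keratinocyte_species",
    "metadata_invitro_2d",
    "metadata_invivo_2d",
    "metadata_invivo_3d",
    "default_phantom_spec",
]


@dataclass(frozen=True)
class DecayModelParams:
    """Mono- or bi-exponential decay model with photon budget.

    ``amplitudes`` are relative amplitudes of the exponential components
    (normalized to sum to 1 on construction); ``total_photons`` is the
    expected fluorescence photon count over the acquired window and
    ``background_rate`` the expected uniform noise photons per channel.
    ``peak_position`` overrides the metadata's decay-peak position when set.
    """

    lifetimes: tuple
    amplitudes: tuple
    total_photons: float
    background_rate: float = 0.0
    peak_position: float | None = None

    def __post_init__(self) -> None:
        lifetimes = tuple(float(t) for t in np.atleast_1d(self.lifetimes))
        amplitudes = tuple(float(a) for a in np.atleast_1d(self.amplitudes))
        if len(lifetimes) != len(amplitudes) or len(lifetimes) not in (1, 2):
            raise ValidationError(
                "lifetimes and amplitudes must have equal length 1 or 2, "
                f"got {len(lifetimes)} and {len(amplitudes)}"
            )
        if any(t <= 0 for t in lifetimes):
            raise ValidationError(f"all lifetimes must be > 0, got {lifetimes}")
        if any(a < 0 for a in amplitudes):
            raise ValidationError(f"amplitudes must be >= 0, got {amplitudes}")
        total_amp = sum(amplitudes)
        if total_amp <= 0:
            raise ValidationError("amplitudes must not all be zero")
        amplitudes = tuple(a / total_amp for a in amplitudes)
        if self.total_photons < 0:
            raise ValidationError(f"total_photons must be >= 0, got {self.total_photons}")
        if self.background_rate < 0:
            raise ValidationError(
                f"background_rate must be >= 0, got {self.background_rate}"
            )
        object.__setattr__(self, "lifetimes", lifetimes)
        object.__setattr__(self, "amplitudes", amplitudes)


def species_a(total_photons: float = 1e5, background_rate: float = 0.0) -> DecayModelParams:
    """Fast mono-exponential reference fluorophore A, tau = 0.1 ns."""
    return DecayModelParams((0.1,), (1.0,), total_photons, background_rate)


def species_b(total_photons: float = 1e5, background_rate: float = 0.0) -> DecayModelParams:
    """Slow mono-exponential reference fluorophore B, tau = 2.2 ns."""
    return DecayModelParams((2.2,), (1.0,), total_photons, background_rate)


def mixed_ab(total_photons: float = 1e5, background_rate: float = 0.0) -> DecayModelParams:
    """90%/10% relative-amplitude mixture of A and B (melanin-shaped decay)."""
    return DecayModelParams((0.1, 2.2), (0.9, 0.1), total_photons, background_rate)


def melanin_species(
    total_photons: float = 300.0, background_rate: float = 0.02
) -> DecayModelParams:
    """Melanosome-packed pixel decay: tau = (66 ps, 1.59 ns), a1 = 99%."""
    return DecayModelParams((0.066, 1.59), (0.99, 0.01), total_photons, background_rate)


def keratinocyte_species(
    total_photons: float = 80.0, background_rate: float = 0.02
) -> DecayModelParams:
    """Non-melanized keratinocyte decay (NAD(P)H/FAD): (419 ps, 2.73 ns), a1 = 60%."""
    return DecayModelParams((0.419, 2.73), (0.6, 0.4), total_photons, background_rate)


def metadata_invitro_2d(pixel_size: float = 0.4) -> AcquisitionMetadata:
    """In vitro FLIM timing: 3128 channels x 4 ps over a 12.5 ns period."""
    return AcquisitionMetadata(
        time_channel_width=0.004,
        n_time_channels=3128,
        rep_period=12.5,
        peak_position=1.33,
        pixel_size=pixel_size,
    )


def metadata_invivo_2d(pixel_size: float = 1.02) -> AcquisitionMetadata:
    """In vivo 2D FLIM timing: 256 channels x 48.8 ps over 12.5 ns."""
    return AcquisitionMetadata(
        time_channel_width=0.0488,
        n_time_channels=256,
        rep_period=12.5,
        peak_position=1.33,
        pixel_size=pixel_size,
    )


def metadata_invivo_3d(
    pixel_size: float = 0.255, z_step: float = 2.346
) -> AcquisitionMetadata:
    """In vivo 3D clinical timing: 4 channels x 2.08 ns (0-8.33 ns window)."""
    return AcquisitionMetadata(
        time_channel_width=2.08,
        n_time_channels=4,
        rep_period=12.5,
        peak_position=1.33,
        pixel_size=pixel_size,
        z_step=z_step,
    )


def _wrapped_cumulative(x: np.ndarray, t0: float, tau: float, period: float) -> np.ndarray:
    """Integral from 0 to x of exp(-((u - t0) mod period) / tau) du."""
    x = np.asarray(x, dtype=float)
    n_full = np.floor(x / period)
    rem = x - n_full * period
    per_period = tau * -np.expm1(-period / tau)
    # pre-peak part of a period carries the wrapped tail of the previous pulse
    pre_scale = np.exp(-(period - t0) / tau)
    phi_t0 = tau * pre_scale * -np.expm1(-t0 / tau)
    phi = np.where(
        rem <= t0,
        tau * pre_scale * -np.expm1(-rem / tau),
        phi_t0 + tau * -np.expm1(-(rem - t0) / tau),
    )
    return n_full * per_period + phi


def expected_decay(
    params: DecayModelParams, metadata: AcquisitionMetadata
) -> np.ndarray:
    """Analytic per-channel expectation of the simulated decay.

    The multi-exponential shape starts at the peak position, wraps
    periodically at the repetition period, and is normalized so the
    fluorescence expectations sum to ``total_photons`` over the window;
    ``background_rate`` is added uniformly to every channel.
    """
    t0 = (
        params.peak_position
        if params.peak_position is not None
        else metadata.peak_position
    )
    window = metadata.time_range
    if not (0.0 <= t0 < window):
        raise ValidationError(
            f"peak position {t0} ns outside the acquired window [0, {window:g}) ns"
        )
    edges = metadata.channel_edges()
    period = metadata.rep_period
    shape = np.zeros(metadata.n_time_channels, dtype=float)
    for tau, amp in zip(params.lifetimes, params.amplitudes):
        # periodic steady state: each pulse's decay stacks on its predecessors
        wrap_gain = 1.0 / -np.expm1(-period / tau)
        cumulative = _wrapped_cumulative(edges, t0, tau, period)
        shape += amp * wrap_gain * np.diff(cumulative)
    total = shape.sum()
    if total > 0:
        shape = shape * (params.total_photons / total)
    else:
        shape = np.zeros_like(shape)
    return shape + params.background_rate


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_decay(
    params: DecayModelParams, metadata: AcquisitionMetadata, seed
) -> DecayHistogram:
    """Draw one Poisson-noise decay histogram; deterministic given ``seed``."""
    rng = _as_rng(seed)
    expectation = expected_decay(params, metadata)
    counts = rng.poisson(expectation)
    return DecayHistogram(counts=counts, metadata=metadata)


def simulate_flim_image(
    labels: np.ndarray,
    species: Mapping[int, DecayModelParams] | Sequence[DecayModelParams],
    metadata: AcquisitionMetadata,
    seed,
) -> FLIMStack:
    """Simulate a 2D FLIM image from a per-pixel species label layout.

    ``labels`` is a (y, x) integer image; ``species`` maps each label value
    to its DecayModelParams (a sequence is indexed by label).  Every pixel
    is drawn independently; a single-pixel image reproduces
    ``simulate_decay`` for the same seed.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ShapeError(f"label layout must be 2D, got shape {labels.shape}")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValidationError("label layout must be an integer array")
    present = np.unique(labels)
    if isinstance(species, Mapping):
        table = dict(species)
    else:
        table = {i: p for i, p in enumerate(species)}
    missing = [int(v) for v in present if v not in table]
    if missing:
        raise ValidationError(f"layout labels without species params: {missing}")
    expectations = {v: expected_decay(table[v], metadata) for v in table}
    exp_img = np.zeros(labels.shape + (metadata.n_time_channels,), dtype=float)
    for v in present:
        exp_img[labels == v] = expectations[v]
    rng = _as_rng(seed)
    counts = rng.poisson(exp_img)
    return FLIMStack(counts=counts, metadata=metadata, provenance="simulate_flim_image")


def _basal_band_profile(u):
    """Default melanin fraction: melanized basal/suprabasal band, dark-skin-like."""
    return np.where(np.asarray(u, dtype=float) >= 0.85, 0.85, 0.0)


@dataclass(frozen=True)
class SkinPhantomSpec:
    """Geometry, species and melanin distribution of a synthetic skin stack.

    ``melanin_fraction_profile`` maps normalized epidermal depth
    u = (depth - surface)/(dej - surface), u = 1 at the DEJ, to the
    probability that an epidermal pixel is melanized; pixels are drawn
    independently (no melanosome clustering).  ``surface_depth`` /
    ``dej_depth`` may be scalars or (y, x) maps in um.
    """

    shape: tuple
    surface_depth: object = 7.0
    dej_depth: object = 65.0
    melanin_fraction_profile: Callable = _basal_band_profile
    melanin_params: DecayModelParams = field(default_factory=melanin_species)
    epidermis_params: DecayModelParams = field(default_factory=keratinocyte_species)
    dermis_params: DecayModelParams = field(
        default_factory=lambda: keratinocyte_species(total_photons=60.0)
    )
    background_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValidationError(f"phantom shape must be (z, y, x), got {self.shape}")
        ny, nx = self.shape[1:]
        surface = np.broadcast_to(np.asarray(self.surface_depth, float), (ny, nx)).copy()
        dej = np.broadcast_to(np.asarray(self.dej_depth, float), (ny, nx)).copy()
        if not np.all(dej > surface):
            raise ValidationError("DEJ must be deeper than the surface everywhere")
        probe = self.melanin_fraction_profile(np.linspace(0.0, 1.0, 101))
        probe = np.asarray(probe, dtype=float)
        if probe.min() < 0 or probe.max() > 1:
            raise ValidationError("melanin_fraction_profile must map into [0, 1]")
        if self.background_rate < 0:
            raise ValidationError("background_rate must be >= 0")
        object.__setattr__(self, "surface_depth", surface)
        object.__setattr__(self, "dej_depth", dej)


@dataclass(frozen=True)
class GroundTruth:
    """Per-voxel truth for a simulated skin stack.

    ``labels``: 0 = above-surface background, 1 = epidermis (non-melanin),
    2 = melanin, 3 = dermis.
    """

    melanin_mask: np.ndarray
    labels: np.ndarray
    segmentation: EpidermisSegmentation


def default_phantom_spec(seed: int = 0, shape: tuple = (40, 64, 64)) -> SkinPhantomSpec:
    """Standard skin phantom: gently undulating surfaces, basal melanin band.

    The lateral field of view at the clinical pixel size (0.255 um/px,
    64 px) is ~16 um, over which real surface/DEJ relief is small; the maps
    undulate by 0.5 um (surface) and 2 um (DEJ) around 7 um and 65 um.
    """
    nz, ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    surface = 7.0 + 0.5 * np.sin(2 * np.pi * xx / nx)
    dej = 65.0 + 2.0 * np.sin(2 * np.pi * (xx / nx + yy / ny))
    return SkinPhantomSpec(
        shape=shape, surface_depth=surface, dej_depth=dej, seed=seed
    )


def simulate_skin_stack(
    spec: SkinPhantomSpec, metadata: AcquisitionMetadata
) -> tuple[FLIMStack, GroundTruth]:
    """Simulate a 3D skin z-stack with known melanin ground truth.

    Voxels above the surface carry background only; epidermal voxels are
    melanin-species with probability ``melanin_fraction_profile(u)`` and
    keratinocyte-species otherwise; voxels below the DEJ are dermis.
    """
    if metadata.z_step is None:
        raise ValidationError("phantom simulation needs metadata.z_step")
    nz, ny, nx = spec.shape
    depth = (np.arange(nz) * metadata.z_step)[:, None, None]
    surface = spec.surface_depth[None]
    dej = spec.dej_depth[None]
    u = (depth - surface) / (dej - surface)
    in_epidermis = (u >= 0.0) & (u <= 1.0)
    below = depth > dej

    rng = np.random.default_rng(spec.seed)
    p_mel = np.zeros((nz, ny, nx), dtype=float)
    p_mel[in_epidermis] = np.asarray(
        spec.melanin_fraction_profile(u[in_epidermis]), dtype=float
    )
    melanized = in_epidermis & (rng.random((nz, ny, nx)) < p_mel)

    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    labels[in_epidermis] = 1
    labels[melanized] = 2
    labels[below] = 3

    def _with_bg(params: DecayModelParams) -> DecayModelParams:
        return replace(params, background_rate=spec.background_rate)

    background_only = DecayModelParams(
        (1.0,), (1.0,), total_photons=0.0, background_rate=spec.background_rate
    )
    expectations = {
        0: expected_decay(background_only, metadata),
        1: expected_decay(_with_bg(spec.epidermis_params), metadata),
        2: expected_decay(_with_bg(spec.melanin_params), metadata),
        3: expected_decay(_with_bg(spec.dermis_params), metadata),
    }
    exp_stack = np.zeros((nz, ny, nx, metadata.n_time_channels), dtype=float)
    for v, exp_vec in expectations.items():
        exp_stack[labels == v] = exp_vec
    counts = rng.poisson(exp_stack)
    stack = FLIMStack(counts=counts, metadata=metadata, provenance="skin_phantom")
    segmentation = EpidermisSegmentation(
        surface_depth=spec.surface_depth,
        dej_depth=spec.dej_depth,
        z_step=metadata.z_step,
    )
    truth = GroundTruth(
        melanin_mask=melanized, labels=labels, segmentation=segmentation
    )
    return stack, truth
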