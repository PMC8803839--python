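"""Phasor (Fourier) analysis of TCSPC decays.

Every decay is mapped to the first harmonic of the laser repetition period:

    g = sum_k I_k cos(omega t_k) / sum_k I_k
    s = sum_k I_k sin(omega t_k) / sum_k I_k,   omega = 2*pi / rep_period,

with t_k measured from the peak channel (plus an optional fixed shift).
Mono-exponential decays lie on the universal semicircle
s^2 + (g - 1/2)^2 = 1/4; mixtures lie on the chord joining their component
phasors, with intensity-fraction weights.  Derived quantities: modulation
m = |(g, s)|, phase phi, phase lifetime tau_phi = tan(phi)/omega and
modulation lifetime tau_m = sqrt(1/m^2 - 1)/omega.

Finite time channels distort the discrete phasor.  Two corrections are
offered (``correction=``):

* ``"sinc"`` (default): multiply by exp(i*omega*dt/2) * sinc(omega*dt/2),
  the fixed linear factor that removes the half-channel phase and the
  lifetime-independent amplitude bias.  Being a constant complex factor it
  preserves phasor linearity exactly; a residual error of order
  omega*dt^2/tau remains for lifetimes comparable to the channel width.
* ``"mono"``: exact inversion of the discrete geometric-sum phasor,
  a = (1 - w)/(1 - w z) with z = exp(i*omega*dt), tau = -dt/ln(a).  Exact
  (to rounding) for mono-exponential decays sampled over a full period —
  the mode used to validate the semicircle identity — but nonlinear, so
  not meaningful for mixtures.
* ``"none"``: the raw discrete phasor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import CapabilityError, UndefinedPhasorError, ValidationError
from .io import AcquisitionMetadata, DecayHistogram, FLIMStack

__all__ = [
    "PhasorResult",
    "MixtureFractions",
    "decay_to_phasor",
    "phasor_image",
    "mixture_fractions",
    "phasor_mask",
    "phasor_histogram",
    "MIN_PHASOR_CHANNELS",
]

#: Minimum channels to resolve the fundamental harmonic per pixel.
MIN_PHASOR_CHANNELS = 8

_CORRECTIONS = ("none", "sinc", "mono")


@dataclass(frozen=True)
class PhasorResult:
    """Phasor coordinates and derived lifetimes of one decay."""

    g: float
    s: float
    m: float
    phi: float
    tau_phi: float
    tau_m: float

    @property
    def complex(self) -> complex:
        return complex(self.g, self.s)


@dataclass(frozen=True)
class MixtureFractions:
    """Relative intensity fractions of two reference species; f_a + f_b = 1."""

    f_a: float
    f_b: float


def _peak_channel(metadata: AcquisitionMetadata, shift: int) -> int:
    return int(metadata.peak_position // metadata.time_channel_width) + shift


def _raw_phasor(counts: np.ndarray, metadata: AcquisitionMetadata, shift: int):
    """Discrete phasor over the last axis, times at channel starts from the peak channel."""
    omega = metadata.angular_frequency
    dt = metadata.time_channel_width
    k0 = _peak_channel(metadata, shift)
    t = (np.arange(metadata.n_time_channels) - k0) * dt
    weights = np.exp(1j * omega * t)
    total = counts.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (counts * weights).sum(axis=-1) / total
    return p, total


def _apply_correction(p, metadata: AcquisitionMetadata, correction: str):
    if correction not in _CORRECTIONS:
        raise ValidationError(f"unknown channel-width correction {correction!r}")
    omega = metadata.angular_frequency
    dt = metadata.time_channel_width
    if correction == "none":
        return p
    if correction == "sinc":
        half = omega * dt / 2.0
        return p * np.exp(1j * half) * np.sinc(half / math.pi)
    # exact mono-exponential inversion of the discrete geometric-sum phasor
    z = np.exp(1j * omega * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (1.0 - p) / (1.0 - p * z)
    a_real = np.clip(np.real(a), 0.0, None)
    scalar = np.ndim(p) == 0
    a_real = np.atleast_1d(a_real)
    out = np.empty(a_real.shape, dtype=complex)
    delta = a_real <= 0.0  # zero-lifetime limit
    infinite = a_real >= 1.0
    ok = ~delta & ~infinite
    out[delta] = 1.0 + 0.0j
    out[infinite] = 0.0 + 0.0j
    tau = -dt / np.log(a_real[ok])
    out[ok] = 1.0 / (1.0 - 1j * omega * tau)
    return out[0] if scalar else out.reshape(np.shape(p))


def _derive(p, metadata: AcquisitionMetadata):
    omega = metadata.angular_frequency
    g = np.real(p)
    s = np.imag(p)
    m = np.abs(p)
    phi = np.arctan2(s, g)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau_phi = np.tan(phi) / omega
        tau_m = np.sqrt(np.maximum(1.0 / (m * m) - 1.0, 0.0)) / omega
    return g, s, m, phi, tau_phi, tau_m


def decay_to_phasor(
    decay: DecayHistogram, shift: int = 0, correction: str = "sinc"
) -> PhasorResult:
    """Phasor of a single decay; raises UndefinedPhasorError on zero counts."""
    counts = decay.counts.astype(float)
    if counts.sum() <= 0:
        raise UndefinedPhasorError("phasor undefined for a zero-count decay")
    p, _ = _raw_phasor(counts, decay.metadata, shift)
    p = _apply_correction(p, decay.metadata, correction)
    g, s, m, phi, tau_phi, tau_m = _derive(p, decay.metadata)
    return PhasorResult(
        g=float(g), s=float(s), m=float(m), phi=float(phi),
        tau_phi=float(tau_phi), tau_m=float(tau_m),
    )


def phasor_image(
    stack: FLIMStack, shift: int = 0, correction: str = "sinc"
) -> dict:
    """Per-pixel phasor maps (g, s, m, phi, tau_phi, tau_m) plus ``valid``.

    Zero-count pixels are invalid (NaN).  Raises CapabilityError on stacks
    with fewer than 8 time channels (e.g. 4-channel clinical stacks).
    """
    metadata = stack.metadata
    if metadata.n_time_channels < MIN_PHASOR_CHANNELS:
        raise CapabilityError(
            f"phasor analysis of {metadata.n_time_channels}-time-channel stacks "
            "is refused; use the slope (Pseudo-FLIM) method"
        )
    counts = stack.counts.astype(float)
    p, total = _raw_phasor(counts, metadata, shift)
    valid = total > 0
    p = np.where(valid, p, np.nan + 0j)
    p = _apply_correction(p, metadata, correction)
    g, s, m, phi, tau_phi, tau_m = _derive(p, metadata)
    return {
        "g": g, "s": s, "m": m, "phi": phi,
        "tau_phi": tau_phi, "tau_m": tau_m, "valid": valid,
    }


def mixture_fractions(
    p: PhasorResult, ref_a: PhasorResult, ref_b: PhasorResult
) -> MixtureFractions:
    """Two-component intensity fractions from phasor-chord distances.

    ``p`` is projected orthogonally onto the segment joining the reference
    phasors; f_a is the normalized distance from the projection to ref B
    (so p = ref A gives f_a = 1), clipped to [0, 1].
    """
    pa = np.array([ref_a.g, ref_a.s])
    pb = np.array([ref_b.g, ref_b.s])
    ab = pa - pb
    norm2 = float(ab @ ab)
    if norm2 < 1e-24:
        raise ValidationError("reference phasors coincide; fractions undefined")
    pp = np.array([p.g, p.s])
    f_a = float(np.clip((pp - pb) @ ab / norm2, 0.0, 1.0))
    return MixtureFractions(f_a=f_a, f_b=1.0 - f_a)


_OPS = {
    "lt": np.less, "<": np.less,
    "le": np.less_equal, "<=": np.less_equal,
    "gt": np.greater, ">": np.greater,
    "ge": np.greater_equal, ">=": np.greater_equal,
}


def phasor_mask(maps: dict, predicates) -> np.ndarray:
    """Boolean mask where every (field, op, threshold) predicate holds.

    The canonical melanin predicates are (g > 0.5 and s < 0.3) and
    tau_phi < 1.1 ns.  Invalid pixels are always False.
    """
    if isinstance(predicates, tuple) and len(predicates) == 3:
        predicates = [predicates]
    mask = np.asarray(maps["valid"], dtype=bool).copy()
    for field, op, threshold in predicates:
        if field not in maps or field == "valid":
            raise ValidationError(f"unknown phasor field {field!r}")
        if op not in _OPS:
            raise ValidationError(f"unknown comparison {op!r}")
        with np.errstate(invalid="ignore"):
            mask &= _OPS[op](maps[field], threshold)
    return mask


def phasor_histogram(maps: dict, bins: int = 100):
    """2D (g, s) density over [0, 1] x [0, 0.6]; total mass = valid pixels in range.

    Returns (hist, g_edges, s_edges) with hist indexed [g_bin, s_bin].
    """
    valid = np.asarray(maps["valid"], dtype=bool)
    g = np.asarray(maps["g"])[valid]
    s = np.asarray(maps["s"])[valid]
    hist, g_edges, s_edges = np.histogram2d(
        g, s, bins=bins, range=[[0.0, 1.0], [0.0, 0.6]]
    )
    return hist, g_edges, s_edges
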