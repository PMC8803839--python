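"""Per-pixel bi-exponential TCSPC decay fitting and lifetime-threshold masks.

The decay model is I(t) = a1*exp(-t/tau1) + a2*exp(-t/tau2) + offset, fit
on the tail from the first complete channel after the decay maximum (no IRF
deconvolution; an optional integer channel shift mimics a fixed calibration
shift).  The default estimator is maximum likelihood via Poisson deviance
residuals, unbiased down to the low-count tail; weighted least squares with
Neyman weights max(count, 1) is available as an option (it pulls long
lifetimes down by a few percent when tail counts are small).

Reported quantities follow TCSPC convention: components ordered
tau1 <= tau2, relative amplitudes a1[%] = 100*a1/(a1+a2), the
amplitude-weighted average lifetime tauAvAmp = (a1 tau1 + a2 tau2)/(a1+a2)
and the intensity-weighted tauAvInt = (a1 tau1^2 + a2 tau2^2)/(a1 tau1 + a2 tau2).

Bi-exponential fitting of 4-time-channel clinical stacks is refused (five
unknowns against four samples); the slope method exists for that regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import CapabilityError, ValidationError
from .io import AcquisitionMetadata, DecayHistogram, FLIMStack

__all__ = [
    "BiExpFitResult",
    "FitConfig",
    "derived_lifetimes",
    "fit_decay",
    "fit_stack",
    "lifetime_mask",
    "MIN_FIT_CHANNELS",
]

#: Minimum number of time channels for a per-pixel bi-exponential fit.
MIN_FIT_CHANNELS = 8


def derived_lifetimes(tau1, tau2, a1, a2):
    """Amplitude- and intensity-weighted average lifetimes.

    tauAvAmp = (a1 tau1 + a2 tau2) / (a1 + a2)
    tauAvInt = (a1 tau1^2 + a2 tau2^2) / (a1 tau1 + a2 tau2)
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ValidationError("lifetimes must be > 0")
    if a1 < 0 or a2 < 0:
        raise ValidationError("amplitudes must be >= 0")
    total = a1 + a2
    if total == 0:
        raise ValidationError("amplitude sum is zero: average lifetimes undefined")
    tau_av_amp = (a1 * tau1 + a2 * tau2) / total
    denom = a1 * tau1 + a2 * tau2
    tau_av_int = (a1 * tau1**2 + a2 * tau2**2) / denom
    return tau_av_amp, tau_av_int


@dataclass(frozen=True)
class BiExpFitResult:
    """Bi-exponential fit parameters for one pixel/ROI."""

    tau1: float
    tau2: float
    a1_pct: float
    a2_pct: float
    tau_av_amp: float
    tau_av_int: float
    offset: float
    chi2_reduced: float
    converged: bool
    photon_starved: bool = False


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the tail fit.

    ``tau1_bounds``/``tau2_bounds`` span all lifetimes seen in skin
    autofluorescence (tens of ps to a few ns).  ``channel_shift`` moves the
    fit origin by whole channels relative to the detected peak channel and
    is meant to be fixed once per dataset.  ``spatial_binning`` pools the
    photon counts of the (2b+1)^2 neighborhood before fitting.
    """

    tail_start_offset: int = 0
    tau1_bounds: tuple = (0.01, 0.8)
    tau2_bounds: tuple = (0.3, 6.0)
    min_photons: int = 100
    spatial_binning: int = 0
    channel_shift: int = 0
    estimator: str = "mle"
    max_iter: int = 200
    tol: float = 1e-10

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("tau1_bounds", self.tau1_bounds),
            ("tau2_bounds", self.tau2_bounds),
        ):
            if not (0 < lo < hi):
                raise ValidationError(f"{name} must be positive and ordered, got {(lo, hi)}")
        if self.min_photons < 0:
            raise ValidationError("min_photons must be >= 0")
        if self.estimator not in ("wls", "mle"):
            raise ValidationError(f"unknown estimator {self.estimator!r}")
        if self.spatial_binning < 0:
            raise ValidationError("spatial_binning must be >= 0")


def _tail_window(metadata: AcquisitionMetadata, config: FitConfig):
    dt = metadata.time_channel_width
    t0 = metadata.peak_position + config.channel_shift * dt
    k_start = int(math.ceil(t0 / dt - 1e-12)) + config.tail_start_offset
    k_start = max(k_start, 0)
    centers = metadata.channel_centers()
    return k_start, centers[k_start:] - t0


def _starved(offset: float = 0.0) -> BiExpFitResult:
    return BiExpFitResult(
        tau1=np.nan,
        tau2=np.nan,
        a1_pct=np.nan,
        a2_pct=np.nan,
        tau_av_amp=np.nan,
        tau_av_int=np.nan,
        offset=offset,
        chi2_reduced=np.nan,
        converged=False,
        photon_starved=True,
    )


def _log_linear_init(t, y, tau1_bounds, tau2_bounds):
    """Two-segment log-linear heuristic: late tail -> tau2, early tail -> tau1."""

    def _segment(tt, yy, default_tau, bounds):
        pos = yy > 0
        if pos.sum() >= 2:
            slope, intercept = np.polyfit(tt[pos], np.log(yy[pos]), 1)
            if slope < 0:
                tau = -1.0 / slope
                amp = math.exp(min(intercept, 700.0))
                return float(np.clip(tau, *bounds)), amp
        return default_tau, max(yy.max(initial=0.0), 1.0)

    t_split = 0.3 * t[-1] if len(t) else 0.0
    late = t >= t_split
    tau2, a2 = _segment(t[late], y[late], math.sqrt(tau2_bounds[0] * tau2_bounds[1]), tau2_bounds)
    residual = y - a2 * np.exp(-t / tau2)
    early = t < t_split
    tau1, a1 = _segment(
        t[early], residual[early], math.sqrt(tau1_bounds[0] * tau1_bounds[1]), tau1_bounds
    )
    return a1, a2, tau1, tau2


def _residual_factory(t, counts, estimator):
    if estimator == "wls":
        w = 1.0 / np.sqrt(np.maximum(counts, 1.0))

        def residuals(p):
            a1, a2, tau1, tau2, off = p
            model = off + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)
            return (model - counts) * w

    else:  # Poisson deviance residuals

        def residuals(p):
            a1, a2, tau1, tau2, off = p
            model = off + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)
            model = np.maximum(model, 1e-12)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(counts > 0, counts * np.log(counts / model), 0.0)
            dev = 2.0 * (model - counts + term)
            return np.sign(counts - model) * np.sqrt(np.maximum(dev, 0.0))

    return residuals


def _mono_fit(t, counts, tau_bounds, offset0, estimator, max_iter, tol):
    y = counts - offset0
    pos = y > 0
    tau0 = math.sqrt(tau_bounds[0] * tau_bounds[1])
    if pos.sum() >= 2:
        slope, _ = np.polyfit(t[pos], np.log(y[pos]), 1)
        if slope < 0:
            tau0 = float(np.clip(-1.0 / slope, *tau_bounds))
    a0 = max(counts.max(initial=1.0) - offset0, 1.0)
    w = 1.0 / np.sqrt(np.maximum(counts, 1.0))

    def residuals(p):
        a, tau, off = p
        return (off + a * np.exp(-t / tau) - counts) * w

    res = least_squares(
        residuals,
        x0=[a0, tau0, max(offset0, 0.0)],
        bounds=([0.0, tau_bounds[0], 0.0], [np.inf, tau_bounds[1], np.inf]),
        max_nfev=max_iter * 10,
        xtol=tol,
        ftol=tol,
        gtol=tol,
    )
    return res


def fit_decay(decay: DecayHistogram, config: FitConfig = FitConfig()) -> BiExpFitResult:
    """Fit a bi-exponential model to one decay histogram.

    Returns a photon-starved result (never raises) when the tail holds
    fewer than ``config.min_photons`` photons; a non-converged fit reports
    the best iterate with ``converged=False``.
    """
    metadata = decay.metadata
    if metadata.n_time_channels < MIN_FIT_CHANNELS:
        raise CapabilityError(
            f"bi-exponential fitting needs >= {MIN_FIT_CHANNELS} time channels, "
            f"got {metadata.n_time_channels}; use the slope (Pseudo-FLIM) method"
        )
    k_start, t = _tail_window(metadata, config)
    counts = decay.counts[k_start:].astype(float)
    if len(t) < 6:
        raise CapabilityError("tail window too short for a 5-parameter fit")
    if counts.sum() < max(config.min_photons, 1):
        return _starved()

    pre = decay.counts[: max(k_start - 1, 0)]
    offset0 = float(pre.mean()) if pre.size else 0.0
    a1_0, a2_0, tau1_0, tau2_0 = _log_linear_init(
        t, counts - offset0, config.tau1_bounds, config.tau2_bounds
    )
    eps = 1e-9
    x0 = [
        max(a1_0, eps),
        max(a2_0, eps),
        float(np.clip(tau1_0, config.tau1_bounds[0] + eps, config.tau1_bounds[1] - eps)),
        float(np.clip(tau2_0, config.tau2_bounds[0] + eps, config.tau2_bounds[1] - eps)),
        max(offset0, 0.0),
    ]
    lo = [0.0, 0.0, config.tau1_bounds[0], config.tau2_bounds[0], 0.0]
    hi = [np.inf, np.inf, config.tau1_bounds[1], config.tau2_bounds[1], np.inf]
    residuals = _residual_factory(t, counts, config.estimator)
    result = least_squares(
        residuals,
        x0=x0,
        bounds=(lo, hi),
        max_nfev=config.max_iter * 10,
        xtol=config.tol,
        ftol=config.tol,
        gtol=config.tol,
    )
    a1, a2, tau1, tau2, offset = result.x
    if tau1 > tau2:
        tau1, tau2 = tau2, tau1
        a1, a2 = a2, a1

    # degenerate separation: collapse to a mono-exponential
    if tau2 - tau1 < metadata.time_channel_width:
        mono = _mono_fit(
            t,
            counts,
            (config.tau1_bounds[0], config.tau2_bounds[1]),
            offset0,
            config.estimator,
            config.max_iter,
            config.tol,
        )
        a_m, tau_m, off_m = mono.x
        tau1 = tau2 = float(tau_m)
        a1, a2 = float(a_m), 0.0
        offset = float(off_m)
        result = mono

    amp_total = a1 + a2
    if amp_total <= 0:
        return _starved(offset=float(offset))
    a1_pct = 100.0 * a1 / amp_total
    a2_pct = 100.0 * a2 / amp_total
    tau_av_amp, tau_av_int = derived_lifetimes(tau1, tau2, a1, a2)

    model = offset + a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)
    chi2 = float(np.sum((model - counts) ** 2 / np.maximum(counts, 1.0)))
    dof = max(len(t) - 5, 1)
    return BiExpFitResult(
        tau1=float(tau1),
        tau2=float(tau2),
        a1_pct=float(a1_pct),
        a2_pct=float(a2_pct),
        tau_av_amp=float(tau_av_amp),
        tau_av_int=float(tau_av_int),
        offset=float(offset),
        chi2_reduced=chi2 / dof,
        converged=bool(result.success),
        photon_starved=False,
    )


_MAP_FIELDS = (
    "tau1",
    "tau2",
    "a1_pct",
    "a2_pct",
    "tau_av_amp",
    "tau_av_int",
    "offset",
    "chi2_reduced",
)


def fit_stack(stack: FLIMStack, config: FitConfig = FitConfig()) -> dict:
    """Per-pixel bi-exponential fit of a stack; returns parametric maps.

    The returned dict holds one float map per fit field plus a boolean
    ``valid`` map (False where photon-starved or non-converged).  Raises
    CapabilityError on stacks with fewer than 8 time channels.
    """
    metadata = stack.metadata
    if metadata.n_time_channels < MIN_FIT_CHANNELS:
        raise CapabilityError(
            f"bi-exponential fitting of {metadata.n_time_channels}-time-channel "
            "stacks is refused; use the slope (Pseudo-FLIM) method"
        )
    counts = stack.counts
    if config.spatial_binning > 0:
        from scipy.ndimage import uniform_filter

        size = 2 * config.spatial_binning + 1
        counts = uniform_filter(
            counts.astype(float), size=(1, size, size, 1), mode="nearest"
        ) * (size * size)
        counts = np.round(counts).astype(np.int64)
    nz, ny, nx, _ = counts.shape
    maps = {f: np.full((nz, ny, nx), np.nan) for f in _MAP_FIELDS}
    maps["valid"] = np.zeros((nz, ny, nx), dtype=bool)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                decay = DecayHistogram(counts[z, y, x], metadata)
                fit = fit_decay(decay, config)
                if fit.photon_starved:
                    continue
                for f in _MAP_FIELDS:
                    maps[f][z, y, x] = getattr(fit, f)
                maps["valid"][z, y, x] = fit.converged
    return maps


_OPS = {
    "lt": np.less,
    "<": np.less,
    "le": np.less_equal,
    "<=": np.less_equal,
    "gt": np.greater,
    ">": np.greater,
    "ge": np.greater_equal,
    ">=": np.greater_equal,
}


def lifetime_mask(maps: dict, field: str, op: str, threshold: float) -> np.ndarray:
    """Boolean melanin mask from a thresholded parametric map.

    Canonical melanin predicates: tau1 < 0.08/0.10/0.15 ns, a1_pct > 90,
    tau_av_amp < 0.4 ns.  Invalid pixels are always False.
    """
    if field not in maps or field == "valid":
        raise ValidationError(f"unknown parametric field {field!r}")
    if op not in _OPS:
        raise ValidationError(f"unknown comparison {op!r}")
    arr = maps[field]
    with np.errstate(invalid="ignore"):
        mask = _OPS[op](arr, threshold)
    valid = maps.get("valid")
    if valid is not None:
        mask = mask & valid
    return np.asarray(mask, dtype=bool)
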