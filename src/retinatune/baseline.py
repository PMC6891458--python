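"""Comparison baseline: simplified visual-system filter + Poisson spiking.

A luminance-compressed, spatially and temporally band-passed rate signal is
rectified and fed to an inhomogeneous Poisson spike generator.  Poisson
output carries no refractoriness or bursting, which is exactly what makes it
a useful contrast to the integrate-and-fire model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .retina import SpikeRaster, SpikeTrain, _patch_at, gaussian_kernel
from .stimulus import FrameSequence

__all__ = ["RateSequence", "hvs_filter", "poisson_spikes"]


@dataclass(frozen=True)
class RateSequence:
    """Nonnegative per-frame firing rates in Hz."""

    rates_hz: np.ndarray
    frame_rate_hz: float

    def __post_init__(self) -> None:
        r = np.asarray(self.rates_hz, dtype=np.float64)
        if not np.all(np.isfinite(r)) or np.any(r < 0):
            raise ValueError("rates must be finite and nonnegative")
        object.__setattr__(self, "rates_hz", r)


def hvs_filter(
    stim: FrameSequence,
    adaptation_halfpoint: float = 0.5,
    sigma_c: float = 1.0,
    sigma_s: float = 3.0,
    tau_fast_ms: float = 20.0,
    tau_slow_ms: float = 120.0,
    center: tuple[int, int] | None = None,
    gain_hz: float = 200.0,
) -> RateSequence:
    """Compression, spatial band-pass and temporal band-pass at one pixel.

    Intensity is compressed by x / (x + h); the spatial band-pass is a
    difference of Gaussian blurs (sampled at ``center``); the temporal
    band-pass is the difference of two first-order exponential low-passes
    with time constants tau_fast and tau_slow; negative output is rectified
    to zero and scaled to Hz.
    """
    for v in (adaptation_halfpoint, sigma_c, sigma_s, tau_fast_ms, tau_slow_ms, gain_hz):
        if v <= 0:
            raise ValueError("all filter parameters must be positive")
    if center is None:
        center = (stim.shape[0] // 2, stim.shape[1] // 2)

    intensity = stim.intensity()
    compressed = intensity / (intensity + adaptation_halfpoint)

    kc_size = int(2 * np.ceil(3 * sigma_c) + 1)
    ks_size = int(2 * np.ceil(3 * sigma_s) + 1)
    kc = gaussian_kernel(sigma_c, 0.0, kc_size)[::-1, ::-1]
    ks = gaussian_kernel(sigma_s, 0.0, ks_size)[::-1, ::-1]
    spatial = np.array(
        [
            float(np.vdot(kc, _patch_at(frame, center, kc_size)))
            - float(np.vdot(ks, _patch_at(frame, center, ks_size)))
            for frame in compressed
        ]
    )

    dt = stim.frame_period_ms
    a_fast = np.exp(-dt / tau_fast_ms)
    a_slow = np.exp(-dt / tau_slow_ms)
    fast = slow = 0.0
    out = np.empty_like(spatial)
    for i, x in enumerate(spatial):
        fast = a_fast * fast + (1.0 - a_fast) * x
        slow = a_slow * slow + (1.0 - a_slow) * x
        out[i] = fast - slow
    rates = gain_hz * np.maximum(out, 0.0)
    return RateSequence(rates, stim.frame_rate_hz)


def poisson_spikes(
    r: RateSequence,
    n_trials: int = 4,
    seed: int = 0,
    cell_id: str = "cell0",
    stimulus_id: str = "stim0",
) -> SpikeRaster:
    """Inhomogeneous Poisson raster: per-frame counts, uniform times in frame."""
    period_ms = 1000.0 / r.frame_rate_hz
    duration_ms = r.rates_hz.size * period_ms
    means = r.rates_hz * (period_ms / 1000.0)
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n_trials):
        times: list[float] = []
        for i, mu in enumerate(means):
            count = rng.poisson(mu) if mu > 0 else 0
            if count:
                times.extend(np.sort(i * period_ms + rng.uniform(0, period_ms, count)))
        t = np.asarray(times)
        t = t[t < duration_ms]
        # enforce strict increase in the (measure-zero) event of a tie
        t = np.unique(t)
        trains.append(SpikeTrain(t, duration_ms))
    return SpikeRaster(tuple(trains), cell_id=cell_id, stimulus_id=stimulus_id)
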