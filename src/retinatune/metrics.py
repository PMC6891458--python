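"""Objective functions comparing candidate and reference spike rasters.

Four minimised objectives: Kullback-Leibler divergence between peristimulus
time histograms (PSTH-KLD) and between interspike-interval histograms
(ISIH-KLD), the absolute firing-rate difference (FRAD, Hz) and the absolute
receptive-field-size difference (RFAD, um^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .retina import SpikeRaster
from .stimulus import FrameSequence

__all__ = [
    "Histogram",
    "ObjectiveVector",
    "MetricConfig",
    "psth",
    "isih",
    "kld",
    "firing_rate",
    "frad",
    "receptive_field_size",
    "objective_vector",
    "pcc",
]


@dataclass(frozen=True)
class Histogram:
    bin_edges_ms: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_ms, dtype=np.float64)
        masses = np.asarray(self.masses, dtype=np.float64)
        if masses.size != edges.size - 1:
            raise ValueError("need one more edge than masses")
        if np.any(masses < 0):
            raise ValueError("masses must be nonnegative")
        object.__setattr__(self, "bin_edges_ms", edges)
        object.__setattr__(self, "masses", masses)


@dataclass(frozen=True)
class ObjectiveVector:
    """The four minimised objectives, in fixed order."""

    psth_kld: float
    isih_kld: float
    frad_hz: float
    rfad_um2: float

    def __post_init__(self) -> None:
        for v in self.as_array():
            if not np.isfinite(v) or v < 0:
                raise ValueError("objectives must be finite and nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([self.psth_kld, self.isih_kld, self.frad_hz, self.rfad_um2])


@dataclass(frozen=True)
class MetricConfig:
    """Histogram/divergence settings; none are prescribed, all overridable."""

    psth_bin_ms: float = 10.0
    psth_smooth_sigma_ms: float = 20.0
    isih_bin_ms: float = 5.0
    isih_max_ms: float = 500.0
    epsilon: float = 1e-6
    rf_latency_ms: float = 50.0
    rf_threshold_frac: float = 0.5
    stimuli: Mapping[int, FrameSequence] | None = field(default=None, compare=False)


def _normalise(counts: np.ndarray) -> np.ndarray:
    """Probability mass; an all-zero histogram degenerates to uniform."""
    total = counts.sum()
    if total <= 0:
        return np.full(counts.size, 1.0 / counts.size)
    return counts / total


def psth(r: SpikeRaster, bin_ms: float = 10.0, smooth_sigma_ms: float = 20.0) -> Histogram:
    """Trial-summed spike counts per bin, Gaussian-smoothed, normalised."""
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    n_bins = max(1, int(math.ceil(r.duration_ms / bin_ms)))
    edges = np.arange(n_bins + 1) * bin_ms
    counts = np.zeros(n_bins)
    for trial in r.trials:
        c, _ = np.histogram(trial.spike_times_ms, bins=edges)
        counts += c
    if smooth_sigma_ms > 0:
        counts = ndimage.gaussian_filter1d(counts, smooth_sigma_ms / bin_ms, mode="constant")
        counts = np.maximum(counts, 0.0)
    return Histogram(edges, _normalise(counts))


def isih(r: SpikeRaster, bin_ms: float = 5.0, max_isi_ms: float = 500.0) -> Histogram:
    """Within-trial interspike-interval histogram, clipped at max_isi_ms."""
    n_bins = max(1, int(math.ceil(max_isi_ms / bin_ms)))
    edges = np.arange(n_bins + 1) * bin_ms
    isis: list[np.ndarray] = []
    for trial in r.trials:
        if trial.n_spikes >= 2:
            isis.append(np.diff(trial.spike_times_ms))
    if isis:
        all_isis = np.minimum(np.concatenate(isis), edges[-1] - 1e-9)
        counts, _ = np.histogram(all_isis, bins=edges)
        counts = counts.astype(np.float64)
    else:
        counts = np.zeros(n_bins)
    return Histogram(edges, _normalise(counts))


def kld(p: Histogram, q: Histogram, epsilon: float = 1e-6) -> float:
    """Kullback-Leibler divergence sum p~ ln(p~/q~) after epsilon smoothing."""
    if p.masses.size != q.masses.size or not np.allclose(p.bin_edges_ms, q.bin_edges_ms):
        raise ValueError("histograms must share their binning")
    pm = _normalise(p.masses) + epsilon
    qm = _normalise(q.masses) + epsilon
    pm /= pm.sum()
    qm /= qm.sum()
    return float(np.sum(pm * np.log(pm / qm)))


def firing_rate(r: SpikeRaster) -> float:
    """Mean spike count per trial divided by duration, in Hz."""
    mean_count = np.mean([t.n_spikes for t in r.trials])
    return float(mean_count / (r.duration_ms / 1000.0))


def frad(a: SpikeRaster | float, b: SpikeRaster | float) -> float:
    ra = a if isinstance(a, (int, float)) else firing_rate(a)
    rb = b if isinstance(b, (int, float)) else firing_rate(b)
    return abs(float(ra) - float(rb))


def receptive_field_size(
    rasters: Mapping[int, SpikeRaster],
    stimuli: Mapping[int, FrameSequence],
    latency_ms: float = 50.0,
    threshold_frac: float = 0.5,
) -> float:
    """Receptive-field area (um^2) by reverse correlation.

    Spike-triggered average of the stimulus frames at the given lag, pooled
    across directions and trials; thresholded at threshold_frac of the peak;
    the area is that of the connected component containing the peak.
    """
    if set(rasters) != set(stimuli):
        raise ValueError("rasters and stimuli must cover the same directions")
    sta = None
    n_spikes = 0
    pixel_scale = None
    for key, raster in rasters.items():
        stim = stimuli[key]
        pixel_scale = stim.pixel_scale_um
        intensity = stim.intensity()
        period = stim.frame_period_ms
        if sta is None:
            sta = np.zeros(stim.shape)
        for trial in raster.trials:
            idx = np.floor((trial.spike_times_ms - latency_ms) / period).astype(int)
            idx = idx[(idx >= 0) & (idx < stim.n_frames)]
            for i in idx:
                sta += intensity[i]
            n_spikes += idx.size
    if sta is None or n_spikes == 0:
        return 0.0
    sta /= n_spikes
    peak = sta.max()
    if peak <= 0:
        return 0.0
    mask = sta >= threshold_frac * peak
    labels, _ = ndimage.label(mask)
    peak_label = labels[np.unravel_index(np.argmax(sta), sta.shape)]
    area_px = int(np.sum(labels == peak_label))
    return float(area_px) * pixel_scale**2


def objective_vector(
    reference: Mapping[int, SpikeRaster],
    candidate: Mapping[int, SpikeRaster],
    cfg: MetricConfig = MetricConfig(),
) -> ObjectiveVector:
    """Evaluate the four objectives of a candidate against a reference.

    PSTH-KLD and ISIH-KLD are averaged over stimuli (reference as p,
    candidate as q); FRAD uses rates pooled over all stimuli; RFAD compares
    reverse-correlation receptive-field sizes when stimuli are configured
    (and is 0 otherwise).
    """
    if set(reference) != set(candidate):
        raise ValueError("reference and candidate must cover the same stimuli")
    if not reference:
        raise ValueError("need at least one stimulus")

    psth_klds = []
    isih_klds = []
    ref_rates = []
    cand_rates = []
    for key in reference:
        ref, cand = reference[key], candidate[key]
        psth_klds.append(
            kld(
                psth(ref, cfg.psth_bin_ms, cfg.psth_smooth_sigma_ms),
                psth(cand, cfg.psth_bin_ms, cfg.psth_smooth_sigma_ms),
                cfg.epsilon,
            )
        )
        isih_klds.append(
            kld(
                isih(ref, cfg.isih_bin_ms, cfg.isih_max_ms),
                isih(cand, cfg.isih_bin_ms, cfg.isih_max_ms),
                cfg.epsilon,
            )
        )
        ref_rates.append(firing_rate(ref))
        cand_rates.append(firing_rate(cand))

    rfad_um2 = 0.0
    if cfg.stimuli is not None:
        stims = {k: cfg.stimuli[k] for k in reference}
        rf_ref = receptive_field_size(
            dict(reference), stims, cfg.rf_latency_ms, cfg.rf_threshold_frac
        )
        rf_cand = receptive_field_size(
            dict(candidate), stims, cfg.rf_latency_ms, cfg.rf_threshold_frac
        )
        rfad_um2 = abs(rf_ref - rf_cand)

    return ObjectiveVector(
        psth_kld=float(np.mean(psth_klds)),
        isih_kld=float(np.mean(isih_klds)),
        frad_hz=abs(float(np.mean(ref_rates)) - float(np.mean(cand_rates))),
        rfad_um2=rfad_um2,
    )


def pcc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equal-length rate traces."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("traces must share a length of at least 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant trace")
    return float(np.corrcoef(a, b)[0, 1])
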