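"""Sleep spindle detection via the cubed sigma-band RMS envelope.

The frontal EEG is band-passed 9-15 Hz, a sliding RMS is computed and
cubed, and spindles are maximal intervals above 1.5x the NREM-mean
envelope that also reach 3.5x it, gated to NREM sleep and bounded in
duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .exceptions import ConfigurationError, UndefinedMetricError
from .sleep import Hypnogram, NREM

LIGHTS_ON_H = 12.0


@dataclass
class SpindleParams:
    band_lo_hz: float = 9.0
    band_hi_hz: float = 15.0
    rms_window_s: float = 0.75
    selection_mult: float = 1.5
    detection_mult: float = 3.5
    min_dur_s: float = 0.5
    max_dur_s: float = 10.0
    nrem_only: bool = True
    min_nrem_fraction: float = 0.5  # strict containment when 1.0
    baseline_stat: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if not self.band_lo_hz < self.band_hi_hz:
            raise ConfigurationError("band_lo_hz must be < band_hi_hz")
        if not self.detection_mult > self.selection_mult > 0:
            raise ConfigurationError("need detection_mult > selection_mult > 0")


@dataclass
class SpindleEvent:
    start_sample: int
    end_sample: int
    duration_s: float
    peak_amplitude_uv: float
    mean_freq_hz: float
    power_uv2: float
    epoch_indices: tuple[int, ...]


def bandpass_sigma(signal: np.ndarray, fs: float, params: SpindleParams) -> np.ndarray:
    if params.band_hi_hz >= fs / 2:
        raise ConfigurationError("sigma band must lie below Nyquist")
    sos = sps.butter(
        4, [params.band_lo_hz, params.band_hi_hz], btype="bandpass", fs=fs,
        output="sos",
    )
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))


def sigma_envelope(
    signal: np.ndarray, fs: float, params: SpindleParams | None = None
) -> np.ndarray:
    """Cubed centred sliding RMS of the 9-15 Hz band-passed signal.

    Output has the same length as the input (edge samples use
    nearest-value padding of the squared signal).
    """
    if params is None:
        params = SpindleParams()
    win = int(round(params.rms_window_s * fs))
    if win < 2:
        raise ConfigurationError(f"RMS window of {win} samples is too short")
    bp = bandpass_sigma(signal, fs, params)
    ms = uniform_filter1d(bp * bp, size=win, mode="nearest")
    return np.sqrt(np.maximum(ms, 0.0)) ** 3


def _zero_crossing_freq(seg: np.ndarray, fs: float) -> float:
    """Oscillation frequency from zero-crossing spacing.

    Crossing positions are interpolated to sub-sample accuracy and the
    median half-period is used, which is robust to the low-amplitude
    noisy edges of a detected event.
    """
    sign_change = np.signbit(seg[:-1]) != np.signbit(seg[1:])
    idx = np.flatnonzero(sign_change)
    if len(idx) < 3:
        return float(len(idx)) / (2.0 * len(seg) / fs)
    frac = seg[idx] / (seg[idx] - seg[idx + 1])
    pos = idx + frac
    half_period = np.median(np.diff(pos)) / fs
    return float(1.0 / (2.0 * half_period))


def _nrem_sample_mask(hypnogram: Hypnogram, fs: float, n_samples: int) -> np.ndarray:
    spe = int(round(hypnogram.epoch_len_s * fs))
    mask = np.zeros(n_samples, dtype=bool)
    for i, s in enumerate(hypnogram.states):
        if s == NREM:
            mask[i * spe : (i + 1) * spe] = True
    return mask


def detect_spindles(
    signal: np.ndarray,
    fs: float,
    hypnogram: Hypnogram,
    params: SpindleParams | None = None,
) -> list[SpindleEvent]:
    """Double-threshold spindle detection on the cubed-RMS envelope.

    Baseline is the mean (or median) envelope over NREM samples, so
    detection is invariant to global amplitude rescaling.
    """
    if params is None:
        params = SpindleParams()
    signal = np.asarray(signal, dtype=float)
    bp = bandpass_sigma(signal, fs, params)
    win = int(round(params.rms_window_s * fs))
    if win < 2:
        raise ConfigurationError("RMS window too short")
    ms = uniform_filter1d(bp * bp, size=win, mode="nearest")
    env = np.sqrt(np.maximum(ms, 0.0)) ** 3

    nrem = _nrem_sample_mask(hypnogram, fs, len(signal))
    if not nrem.any():
        warnings.warn("no NREM epochs; no spindles detectable")
        return []
    stat = np.median if params.baseline_stat == "median" else np.mean
    baseline = float(stat(env[nrem]))
    sel_thr = params.selection_mult * baseline
    det_thr = params.detection_mult * baseline

    above = env > sel_thr
    # maximal runs above the selection threshold
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        ends = np.concatenate((ends, [len(above)]))

    spe = int(round(hypnogram.epoch_len_s * fs))
    out: list[SpindleEvent] = []
    for a, b in zip(starts, ends):
        if env[a:b].max() < det_thr:
            continue
        dur = (b - a) / fs
        if not params.min_dur_s <= dur <= params.max_dur_s:
            continue
        if params.nrem_only:
            frac = nrem[a:b].mean()
            if frac < params.min_nrem_fraction or frac == 0:
                continue
        seg = bp[a:b]
        out.append(
            SpindleEvent(
                start_sample=int(a),
                end_sample=int(b),
                duration_s=dur,
                peak_amplitude_uv=float(np.max(np.abs(seg))),
                mean_freq_hz=_zero_crossing_freq(seg, fs),
                power_uv2=float(np.mean(seg**2)),
                epoch_indices=tuple(
                    range(int(a // spe), int((b - 1) // spe) + 1)
                ),
            )
        )
    return out


def _nrem_minutes(hypnogram: Hypnogram, epoch_mask: np.ndarray | None = None) -> float:
    sel = hypnogram.states == NREM
    if epoch_mask is not None:
        sel &= epoch_mask
    return float(np.sum(sel)) * hypnogram.epoch_len_s / 60.0


def spindle_metrics(
    spindles: list[SpindleEvent],
    hypnogram: Hypnogram,
    fs: float,
    lights_on_only: bool = False,
) -> dict:
    """Density (/min NREM) and mean duration/amplitude/frequency/power.

    ``lights_on_only`` restricts both spindles and the NREM denominator
    to ZT0-12.
    """
    epoch_mask = None
    sel = spindles
    if lights_on_only:
        zt = hypnogram.epoch_zt_hours()
        epoch_mask = zt < LIGHTS_ON_H
        spe = int(round(hypnogram.epoch_len_s * fs))
        sel = [
            sp for sp in spindles
            if epoch_mask[min(sp.start_sample // spe, len(epoch_mask) - 1)]
        ]
    nrem_min = _nrem_minutes(hypnogram, epoch_mask)
    if nrem_min == 0:
        raise UndefinedMetricError("zero NREM minutes; density undefined")
    return {
        "n_spindles": len(sel),
        "nrem_minutes": nrem_min,
        "density_per_min": len(sel) / nrem_min,
        "mean_duration_s": float(np.mean([s.duration_s for s in sel])) if sel else np.nan,
        "mean_peak_amplitude_uv": (
            float(np.mean([s.peak_amplitude_uv for s in sel])) if sel else np.nan
        ),
        "mean_freq_hz": float(np.mean([s.mean_freq_hz for s in sel])) if sel else np.nan,
        "mean_power_uv2": float(np.mean([s.power_uv2 for s in sel])) if sel else np.nan,
    }


def bin_spindle_density(
    spindles: list[SpindleEvent],
    hypnogram: Hypnogram,
    fs: float,
    bin_h: float = 6.0,
) -> pd.DataFrame:
    """Spindle density per diurnal bin (spindles starting in the bin over
    NREM minutes in the bin); density is NaN where a bin has no NREM."""
    if bin_h <= 0 or abs(24.0 / bin_h - round(24.0 / bin_h)) > 1e-9:
        raise ConfigurationError(f"bin_h={bin_h} must divide 24")
    n_bins = int(round(24.0 / bin_h))
    zt = hypnogram.epoch_zt_hours()
    epoch_bin = np.minimum((zt // bin_h).astype(int), n_bins - 1)
    epm = hypnogram.epoch_len_s / 60.0
    nrem_min = np.array(
        [
            np.sum((hypnogram.states == NREM) & (epoch_bin == b)) * epm
            for b in range(n_bins)
        ]
    )
    spe = int(round(hypnogram.epoch_len_s * fs))
    counts = np.zeros(n_bins, dtype=int)
    for sp in spindles:
        e = min(sp.start_sample // spe, len(epoch_bin) - 1)
        counts[epoch_bin[e]] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(nrem_min > 0, counts / nrem_min, np.nan)
    return pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "n_spindles": counts,
            "nrem_minutes": nrem_min,
            "density_per_min": density,
        }
    ).set_index("bin")


def spindles_to_table(spindles: list[SpindleEvent], fs: float) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_s": s.start_sample / fs,
                "end_s": s.end_sample / fs,
                "duration_s": s.duration_s,
                "peak_uv": s.peak_amplitude_uv,
                "freq_hz": s.mean_freq_hz,
                "power_uv2": s.power_uv2,
            }
            for s in spindles
        ],
        columns=["start_s", "end_s", "duration_s", "peak_uv", "freq_hz", "power_uv2"],
    )
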