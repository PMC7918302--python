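"""Per-epoch power spectra, band powers and normalized delta (nDelta).

Each 4-s epoch gets a Hann-windowed periodogram (0.25 Hz resolution at
1024 Hz); delta power (0.5-4 Hz) is normalized by the summed band
powers so the statistic is amplitude-scale invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as sci_stats

from .exceptions import ConfigurationError
from .sleep import Hypnogram, NREM

DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (5.0, 9.0),
    "sigma": (10.0, 14.0),
    "gamma": (25.0, 100.0),
}


@dataclass
class BandScheme:
    """Band edges in Hz plus the nDelta denominator convention.

    Defaults follow the Methods variant (theta 5-9, sigma 10-14) with
    delta included in the denominator so nDelta is bounded in [0, 1];
    both choices are configurable because the source conventions differ
    between the methods text and the figure legends.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    include_delta_in_denominator: bool = True

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not 0 <= lo < hi:
                raise ConfigurationError(f"band {name}: need 0 <= lo < hi")


def epoch_psd(epoch: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hann periodogram of a single epoch (µV²/Hz).

    Parseval-consistent: sum(psd)*df approximates the epoch variance.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 1 or epoch.size < 8:
        raise ConfigurationError("epoch must be a 1-D array of >= 8 samples")
    freqs, psd = sps.periodogram(
        epoch, fs=fs, window="hann", detrend="constant", scaling="density"
    )
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi] (inclusive edges)."""
    nyq = float(freqs[-1])
    if hi > nyq + 1e-9:
        raise ConfigurationError(f"band edge {hi} Hz above Nyquist {nyq} Hz")
    mask = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    if mask.sum() < 2:
        raise ConfigurationError(f"band [{lo}, {hi}] covers <2 PSD bins")
    return float(np.trapezoid(psd[mask], freqs[mask]))


def normalized_delta(band_powers: dict[str, float], scheme: BandScheme | None = None) -> float:
    """delta / (delta? + theta + sigma + gamma); NaN when denominator 0."""
    if scheme is None:
        scheme = BandScheme()
    delta = band_powers["delta"]
    denom = sum(band_powers[b] for b in scheme.bands if b != "delta")
    if scheme.include_delta_in_denominator:
        denom += delta
    if denom == 0:
        return float("nan")
    return delta / denom


def compute_epoch_spectra(
    signal: np.ndarray,
    fs: float,
    hypnogram: Hypnogram | None = None,
    scheme: BandScheme | None = None,
    epoch_len_s: float = 4.0,
) -> pd.DataFrame:
    """Band powers and nDelta for every epoch of a recording.

    Returns a frame with epoch_index, state (if a hypnogram is given),
    one column per band (µV²) and n_delta.
    """
    if scheme is None:
        scheme = BandScheme()
    signal = np.asarray(signal, dtype=float)
    spe = epoch_len_s * fs
    if abs(spe - round(spe)) > 1e-9:
        raise ConfigurationError("epoch_len_s*fs must be an integer")
    spe = int(round(spe))
    n_epochs = len(signal) // spe
    if hypnogram is not None:
        n_epochs = min(n_epochs, len(hypnogram))
    rows = np.empty((n_epochs, len(scheme.bands)))
    band_items = list(scheme.bands.items())
    for e in range(n_epochs):
        freqs, psd = epoch_psd(signal[e * spe : (e + 1) * spe], fs)
        for j, (name, (lo, hi)) in enumerate(band_items):
            rows[e, j] = band_power(freqs, psd, lo, hi)
    df = pd.DataFrame(rows, columns=[name for name, _ in band_items])
    df.insert(0, "epoch_index", np.arange(n_epochs))
    if hypnogram is not None:
        df.insert(1, "state", hypnogram.states[:n_epochs])
    df["n_delta"] = [
        normalized_delta({b: df[b].iloc[e] for b in scheme.bands}, scheme)
        for e in range(n_epochs)
    ]
    return df


def nrem_delta_profile(
    spectra: pd.DataFrame,
    hypnogram: Hypnogram,
    bin_h: float = 4.0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Mean NREM nDelta per diurnal bin with a t-based CI.

    Bins are anchored at lights-on; artifact/seizure epochs are excluded
    by virtue of not being NREM.  Bins without NREM epochs report NaN.
    """
    if bin_h <= 0 or abs(24.0 / bin_h - round(24.0 / bin_h)) > 1e-9:
        raise ConfigurationError(f"bin_h={bin_h} must divide 24")
    n_bins = int(round(24.0 / bin_h))
    zt = hypnogram.epoch_zt_hours()
    epoch_bin = np.minimum((zt // bin_h).astype(int), n_bins - 1)

    idx = spectra["epoch_index"].to_numpy()
    nd = spectra["n_delta"].to_numpy()
    states = hypnogram.states[idx]
    rows = []
    for b in range(n_bins):
        sel = (states == NREM) & (epoch_bin[idx] == b) & np.isfinite(nd)
        vals = nd[sel]
        n = len(vals)
        if n == 0:
            rows.append({"bin": b, "mean_n_delta": np.nan, "ci_lo": np.nan,
                         "ci_hi": np.nan, "n_epochs": 0})
            continue
        m = float(np.mean(vals))
        if n > 1:
            half = float(
                sci_stats.t.ppf(0.5 + ci / 2, n - 1) * np.std(vals, ddof=1) / np.sqrt(n)
            )
        else:
            half = np.nan
        rows.append(
            {"bin": b, "mean_n_delta": m, "ci_lo": m - half, "ci_hi": m + half,
             "n_epochs": n}
        )
    return pd.DataFrame(rows).set_index("bin")
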