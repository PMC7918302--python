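"""EDF loading, zero-phase filtering and fixed-length epoching.

Conventions used throughout the package:

* sample indices are 0-based, epoch intervals half-open ``[start, stop)``;
* zeitgeber time (ZT) 0 is lights-on (default 06:30 wall clock);
* signals are in µV.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time

import numpy as np
from scipy import signal as sps

from .exceptions import ConfigurationError, TooShortSignalError
from . import edf as edfio

ROLE_FRONTAL = "frontal_eeg"
ROLE_PARIETAL = "parietal_eeg"
ROLE_EMG = "emg"

DEFAULT_LIGHTS_ON = time(6, 30)


@dataclass
class FilterSpec:
    """Zero-phase filter chain: Chebyshev-II notch + Chebyshev-I high-pass.

    Orders/ripple are not dictated by the analysis contract (which is
    about attenuation and zero phase), so they are exposed here.
    """

    notch_hz: float = 60.0
    highpass_hz: float = 0.5
    notch_order: int = 4
    notch_atten_db: float = 40.0
    notch_bw_hz: float = 2.0
    highpass_order: int = 4
    highpass_ripple_db: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.highpass_hz < self.notch_hz):
            raise ConfigurationError(
                "need 0 < highpass_hz < notch_hz, got "
                f"{self.highpass_hz}, {self.notch_hz}"
            )

    def sos(self, fs: float) -> np.ndarray:
        """Cascade of second-order sections for sampling rate ``fs``.

        The notch is skipped (with the high-pass retained) when the stop
        band would reach Nyquist, as happens for heavily decimated test
        signals.
        """
        if self.notch_hz >= fs / 2:
            raise ConfigurationError(
                f"notch at {self.notch_hz} Hz not below Nyquist ({fs / 2} Hz)"
            )
        sections = [
            sps.cheby1(
                self.highpass_order,
                self.highpass_ripple_db,
                self.highpass_hz,
                btype="highpass",
                fs=fs,
                output="sos",
            )
        ]
        hi = self.notch_hz + self.notch_bw_hz
        if hi < fs / 2:
            sections.append(
                sps.cheby2(
                    self.notch_order,
                    self.notch_atten_db,
                    [self.notch_hz - self.notch_bw_hz, hi],
                    btype="bandstop",
                    fs=fs,
                    output="sos",
                )
            )
        return np.vstack(sections)


@dataclass
class EEGRecording:
    """Multichannel recording with channel roles and a lights-on anchor."""

    signals: dict[str, np.ndarray]
    fs: float
    channel_roles: dict[str, str]
    start_clock_time: datetime
    lights_on_clock_time: time = DEFAULT_LIGHTS_ON

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.signals.values()}
        if len(lengths) > 1:
            raise ConfigurationError("channels have unequal lengths")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        frontal = [c for c, r in self.channel_roles.items() if r == ROLE_FRONTAL]
        if len(frontal) != 1:
            raise ConfigurationError(
                f"exactly one channel must be tagged {ROLE_FRONTAL!r}, "
                f"found {len(frontal)}"
            )
        missing = set(self.channel_roles) - set(self.signals)
        if missing:
            raise ConfigurationError(f"roles reference unknown channels: {missing}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.signals.values())))

    def channel(self, role: str) -> np.ndarray:
        for name, r in self.channel_roles.items():
            if r == role:
                return self.signals[name]
        raise ConfigurationError(f"no channel with role {role!r}")

    def frontal(self) -> np.ndarray:
        return self.channel(ROLE_FRONTAL)

    @property
    def start_zeitgeber_h(self) -> float:
        """Hours since lights-on at the first sample, in [0, 24)."""
        t0 = self.start_clock_time
        lo = self.lights_on_clock_time
        dh = (
            (t0.hour - lo.hour)
            + (t0.minute - lo.minute) / 60.0
            + (t0.second - lo.second) / 3600.0
        )
        return dh % 24.0


@dataclass
class EpochGrid:
    """Non-overlapping contiguous fixed-length epochs over a signal."""

    epoch_len_s: float
    n_epochs: int
    samples_per_epoch: int

    def epoch_slice(self, i: int) -> slice:
        if not 0 <= i < self.n_epochs:
            raise IndexError(i)
        return slice(i * self.samples_per_epoch, (i + 1) * self.samples_per_epoch)

    def sample_to_epoch(self, sample: int) -> int:
        return int(sample // self.samples_per_epoch)


def load_edf(
    path,
    role_map: dict[str, str],
    lights_on_clock_time: time = DEFAULT_LIGHTS_ON,
) -> EEGRecording:
    """Load an EDF file, tagging channels with roles from ``role_map``."""
    signals, fs, start = edfio.read_edf(path)
    unknown = set(role_map) - set(signals)
    if unknown:
        raise ConfigurationError(
            f"role map names channels absent from the EDF: {sorted(unknown)}"
        )
    return EEGRecording(
        signals=signals,
        fs=fs,
        channel_roles=dict(role_map),
        start_clock_time=start,
        lights_on_clock_time=lights_on_clock_time,
    )


def apply_zero_phase(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Forward-backward (zero net group delay) filtering of one channel."""
    if spec is None:
        spec = FilterSpec()
    x = np.asarray(x, dtype=float)
    sos = spec.sos(fs)
    # the 0.5 Hz high-pass rings for seconds: pad by ~3 of its periods,
    # clipped to the signal length
    min_pad = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= 3 * min_pad:
        raise TooShortSignalError(
            f"signal of {len(x)} samples too short for filter warm-up"
        )
    padlen = min(int(3 * fs / spec.highpass_hz), len(x) - 1)
    return sps.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def epoch_signal(rec_or_n, fs: float | None = None, epoch_len_s: float = 4.0) -> EpochGrid:
    """Partition a recording into fixed epochs; trailing partial dropped.

    Accepts either an :class:`EEGRecording` or an explicit sample count
    plus ``fs``.
    """
    if isinstance(rec_or_n, EEGRecording):
        n, fs = rec_or_n.n_samples, rec_or_n.fs
    else:
        n = int(rec_or_n)
        if fs is None:
            raise ConfigurationError("fs required when passing a sample count")
    spe = epoch_len_s * fs
    if abs(spe - round(spe)) > 1e-9:
        raise ConfigurationError(
            f"epoch_len_s*fs = {spe} is not an integer number of samples"
        )
    spe = int(round(spe))
    return EpochGrid(
        epoch_len_s=epoch_len_s,
        n_epochs=n // spe,
        samples_per_epoch=spe,
    )
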