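"""Synthetic EEG/EMG cohorts with exact ground truth.

Generates, per animal: a semi-Markov hypnogram with diurnal modulation,
a state-conditioned EEG (1/f background, NREM delta, REM theta, wake
mixed activity, EMG atonia structure), and injected transients —
NREM-gated sigma-band spindle bursts, sparse high-amplitude spikes with
arm-specific waveform shapes, and rare rhythmic spike-wave seizures.
All injections are logged so downstream detectors can be scored against
truth.  These are statistical stand-ins, not biophysical simulations.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from . import edf as edfio
from .exceptions import ConfigurationError
from .preprocess import EEGRecording, ROLE_FRONTAL, ROLE_PARIETAL, ROLE_EMG
from .sleep import Hypnogram, WAKE, NREM, REM, SEIZURE

ARMS = ("NC", "sham", "CCI")

# Paul Kellet's economy pink-noise filter (approximate 1/f over audio-like
# normalized frequencies; adequate as an EEG-shaped background).
_PINK_B = [0.049922035, -0.095993537, 0.050612699, -0.004408786]
_PINK_A = [1.0, -2.494956002, 2.017265875, -0.522189400]


@dataclass
class CohortConfig:
    n_per_arm: dict[str, int] = field(
        default_factory=lambda: {"NC": 3, "sham": 3, "CCI": 4}
    )
    hours: float = 24.0
    fs: float = 256.0
    epoch_len_s: float = 4.0
    seed: int = 0
    start_zt_h: float = 0.0

    # mean bout lengths in epochs, (lights_on, lights_off)
    wake_bout_epochs: tuple[float, float] = (15.0, 45.0)
    nrem_bout_epochs: tuple[float, float] = (25.0, 12.0)
    rem_bout_epochs: tuple[float, float] = (4.0, 3.0)
    p_nrem_to_rem: float = 0.35
    p_rem_to_wake: float = 0.5
    arm_bout_scale: dict[str, float] = field(
        default_factory=lambda: {"NC": 1.0, "sham": 0.75, "CCI": 0.6}
    )

    # spectral content (µV amplitudes)
    background_uv: float = 10.0
    arm_delta_uv: dict[str, float] = field(
        default_factory=lambda: {"NC": 20.0, "sham": 28.0, "CCI": 36.0}
    )
    theta_uv: float = 15.0
    wake_osc_uv: float = 6.0
    sigma_background_uv: float = 6.0
    emg_uv: dict[str, float] = field(
        default_factory=lambda: {WAKE: 30.0, NREM: 10.0, REM: 3.0}
    )

    # spindles
    spindle_density_per_min: tuple[float, float] = (2.0, 1.0)  # on, off
    spindle_dur_s: tuple[float, float] = (1.0, 0.2)  # mean, sd
    spindle_freq_hz: tuple[float, float] = (10.0, 14.0)
    spindle_amp_factor: float = 4.0  # x sigma_background_uv

    # spikes
    arm_sharp_rate_per_h: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.0, "sham": 8.0, "CCI": 16.0}
    )
    background_spike_rate_per_h: float = 4.0
    spike_amp_uv: float = 400.0

    # seizures
    seizure_prob: dict[str, float] = field(
        default_factory=lambda: {"NC": 0.0, "sham": 0.0, "CCI": 0.25}
    )
    seizure_dur_s: tuple[float, float] = (20.0, 160.0)
    seizure_freq_hz: float = 6.0

    def __post_init__(self) -> None:
        for p in list(self.seizure_prob.values()):
            if not 0 <= p <= 1:
                raise ConfigurationError("seizure probabilities must be in [0,1]")
        if self.hours <= 0 or self.fs <= 0:
            raise ConfigurationError("hours and fs must be positive")

    def config_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class GroundTruth:
    hypnogram: Hypnogram
    events: pd.DataFrame  # time_s, template, amp_uv
    spindles: pd.DataFrame  # start_s, duration_s, freq_hz, amp_uv
    seizures: pd.DataFrame  # onset_s, duration_s


def _bout_means(cfg: CohortConfig, arm: str, lights_on: bool) -> dict[str, float]:
    i = 0 if lights_on else 1
    scale = cfg.arm_bout_scale.get(arm, 1.0)
    return {
        WAKE: max(cfg.wake_bout_epochs[i] * scale, 1.0),
        NREM: max(cfg.nrem_bout_epochs[i] * scale, 1.0),
        REM: max(cfg.rem_bout_epochs[i] * scale, 1.0),
    }


def expected_state_fractions(
    cfg: CohortConfig, arm: str = "NC", lights_on: bool = True
) -> dict[str, float]:
    """Analytic long-run time fraction per state for one light phase.

    Semi-Markov stationary occupancy: embedded-chain weights times mean
    bout length.  Used as the oracle for the generator.
    """
    p, q = cfg.p_nrem_to_rem, cfg.p_rem_to_wake
    pi = {WAKE: (1 - p) + p * q, NREM: 1.0, REM: p}
    m = _bout_means(cfg, arm, lights_on)
    w = {s: pi[s] * m[s] for s in pi}
    tot = sum(w.values())
    return {s: w[s] / tot for s in w}


def simulate_hypnogram(
    cfg: CohortConfig, seed: int, arm: str = "NC"
) -> tuple[Hypnogram, pd.DataFrame]:
    """Semi-Markov wake/NREM/REM hypnogram with lights-phase modulation.

    Geometric bout lengths (mean set per state/phase/arm); REM is
    entered only from NREM.  Returns the hypnogram and a bout table
    (ground truth).
    """
    if not (0 <= cfg.p_nrem_to_rem <= 1 and 0 <= cfg.p_rem_to_wake <= 1):
        raise ConfigurationError("transition probabilities must be in [0,1]")
    rng = np.random.default_rng(seed)
    n_epochs = int(round(cfg.hours * 3600.0 / cfg.epoch_len_s))
    eph = 3600.0 / cfg.epoch_len_s  # epochs per hour
    states = np.empty(n_epochs, dtype="U8")
    bouts = []
    pos = 0
    state = WAKE
    while pos < n_epochs:
        zt = (cfg.start_zt_h + pos / eph) % 24.0
        means = _bout_means(cfg, arm, lights_on=zt < 12.0)
        length = int(rng.geometric(1.0 / means[state]))
        length = min(length, n_epochs - pos)
        states[pos : pos + length] = state
        bouts.append({"state": state, "start_epoch": pos, "n_epochs": length})
        pos += length
        if state == WAKE:
            state = NREM
        elif state == NREM:
            state = REM if rng.random() < cfg.p_nrem_to_rem else WAKE
        else:  # REM
            state = WAKE if rng.random() < cfg.p_rem_to_wake else NREM
    hyp = Hypnogram(states, cfg.epoch_len_s, cfg.start_zt_h)
    return hyp, pd.DataFrame(bouts)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    white = rng.standard_normal(n + 2048)
    pink = sps.lfilter(_PINK_B, _PINK_A, white)[2048:]
    return pink / pink.std()


def synthesize_eeg(
    hypnogram: Hypnogram, cfg: CohortConfig, seed: int, arm: str = "NC"
) -> EEGRecording:
    """State-conditioned EEG/EMG: 1/f background plus per-epoch
    oscillations (NREM delta at arm-specific amplitude, REM theta, a
    weak wake rhythm, continuous NREM sigma background) and an EMG
    channel whose variance tracks the state (wake high, REM atonia)."""
    rng = np.random.default_rng(seed)
    fs = cfg.fs
    spe = int(round(hypnogram.epoch_len_s * fs))
    n = len(hypnogram) * spe
    states = np.repeat(hypnogram.states, spe)

    n_ep = len(hypnogram)
    freq_ep = np.empty(n_ep)
    amp_ep = np.empty(n_ep)
    for i, s in enumerate(hypnogram.states):
        if s == NREM:
            freq_ep[i] = rng.uniform(1.5, 3.5)
            amp_ep[i] = cfg.arm_delta_uv.get(arm, 20.0)
        elif s == REM:
            freq_ep[i] = rng.uniform(6.5, 7.5)
            amp_ep[i] = cfg.theta_uv
        elif s == WAKE:
            freq_ep[i] = rng.uniform(6.0, 9.0)
            amp_ep[i] = cfg.wake_osc_uv
        else:
            freq_ep[i] = 0.0
            amp_ep[i] = 0.0
    freq = np.repeat(freq_ep, spe)
    amp = np.repeat(amp_ep, spe)
    phase = 2 * np.pi * np.cumsum(freq) / fs
    osc = amp * np.sin(phase)

    t = np.arange(n) / fs
    sigma_bg = (
        cfg.sigma_background_uv
        * (states == NREM)
        * np.sin(2 * np.pi * 11.5 * t + rng.uniform(0, 2 * np.pi))
    )
    frontal = cfg.background_uv * _pink_noise(rng, n) + osc + sigma_bg
    parietal = cfg.background_uv * _pink_noise(rng, n) + 0.6 * osc + 0.6 * sigma_bg

    emg_sd = np.ones(n) * cfg.emg_uv[NREM]
    for s, sd in cfg.emg_uv.items():
        emg_sd[states == s] = sd
    emg = emg_sd * rng.standard_normal(n)

    return EEGRecording(
        signals={"EEG Fr": frontal, "EEG Par": parietal, "EMG": emg},
        fs=fs,
        channel_roles={"EEG Fr": ROLE_FRONTAL, "EEG Par": ROLE_PARIETAL, "EMG": ROLE_EMG},
        start_clock_time=datetime(2021, 1, 1, 6, 30, 0),
    )


def _sharp_template(fs: float, amp: float) -> np.ndarray:
    """Brief biphasic epileptiform spike (~60 ms footprint)."""
    t = np.arange(-0.05, 0.05, 1 / fs)
    w = np.exp(-((t / 0.008) ** 2)) - 0.9 * np.exp(-(((t - 0.02) / 0.016) ** 2))
    return amp * w / np.max(np.abs(w))


def _blunt_template(fs: float, amp: float) -> np.ndarray:
    """Wide monophasic high-amplitude wave (~160 ms footprint)."""
    t = np.arange(-0.12, 0.12, 1 / fs)
    w = np.exp(-((t / 0.045) ** 2))
    return amp * w / np.max(np.abs(w))


def _add_at(x: np.ndarray, center: int, tmpl: np.ndarray) -> None:
    half = len(tmpl) // 2
    a = center - half
    b = a + len(tmpl)
    ta, tb = max(0, -a), len(tmpl) - max(0, b - len(x))
    x[max(a, 0) : min(b, len(x))] += tmpl[ta:tb]


def inject_transients(
    rec: EEGRecording,
    hypnogram: Hypnogram,
    cfg: CohortConfig,
    seed: int,
    arm: str = "NC",
) -> GroundTruth:
    """Add spindles, spikes and (optionally) one seizure in place.

    Spindle starts are Poisson-thinned per NREM epoch at the configured
    phase-specific density and fully contained in their epoch.  Spikes
    are a homogeneous Poisson process per template family with enforced
    >0.5 s separation.  Seizure epochs are relabelled SEIZURE in the
    returned hypnogram copy.
    """
    rng = np.random.default_rng(seed)
    fs = rec.fs
    frontal = rec.channel(ROLE_FRONTAL)
    parietal = rec.channel(ROLE_PARIETAL)
    n = len(frontal)
    spe = int(round(hypnogram.epoch_len_s * fs))
    zt = hypnogram.epoch_zt_hours()

    # --- spindles -----------------------------------------------------
    sp_rows = []
    amp = cfg.spindle_amp_factor * cfg.sigma_background_uv
    for i, s in enumerate(hypnogram.states):
        if s != NREM:
            continue
        dens = cfg.spindle_density_per_min[0 if zt[i] < 12.0 else 1]
        count = rng.poisson(dens * hypnogram.epoch_len_s / 60.0)
        for _ in range(count):
            dur = float(np.clip(rng.normal(*cfg.spindle_dur_s), 0.4,
                                hypnogram.epoch_len_s))
            start_off = rng.uniform(0, hypnogram.epoch_len_s - dur)
            start = int((i * hypnogram.epoch_len_s + start_off) * fs)
            m = int(dur * fs)
            if start + m > n:
                continue
            f = rng.uniform(*cfg.spindle_freq_hz)
            tt = np.arange(m) / fs
            burst = amp * np.sin(np.pi * tt / dur) ** 2 * np.sin(
                2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi)
            )
            frontal[start : start + m] += burst
            parietal[start : start + m] += 0.6 * burst
            sp_rows.append(
                {"start_s": start / fs, "duration_s": dur, "freq_hz": f,
                 "amp_uv": amp}
            )

    # --- spikes -------------------------------------------------------
    ev_rows = []
    sharp = _sharp_template(fs, cfg.spike_amp_uv)
    blunt = _blunt_template(fs, 0.7 * cfg.spike_amp_uv)
    dur_h = n / fs / 3600.0
    for template, tmpl, rate in (
        ("sharp", sharp, cfg.arm_sharp_rate_per_h.get(arm, 0.0)),
        ("blunt", blunt, cfg.background_spike_rate_per_h),
    ):
        k = rng.poisson(rate * dur_h)
        times = np.sort(rng.uniform(1.0, n / fs - 1.0, size=k))
        kept = []
        for tme in times:
            if kept and tme - kept[-1] < 0.5:
                continue
            kept.append(tme)
        for tme in kept:
            _add_at(frontal, int(tme * fs), tmpl)
            _add_at(parietal, int(tme * fs), 0.5 * tmpl)
            ev_rows.append(
                {"time_s": tme, "template": template, "amp_uv": float(np.max(np.abs(tmpl)))}
            )

    # --- seizure ------------------------------------------------------
    sz_rows = []
    new_states = hypnogram.states.copy()
    if rng.random() < cfg.seizure_prob.get(arm, 0.0):
        dur = float(rng.uniform(*cfg.seizure_dur_s))
        dur = min(dur, n / fs - 2.0)
        onset = float(rng.uniform(1.0, n / fs - dur - 1.0))
        n_spk = int(dur * cfg.seizure_freq_hz)
        for j in range(n_spk):
            ts = onset + j / cfg.seizure_freq_hz
            ramp = 0.3 + 0.7 * min(1.0, 3.0 * j / max(n_spk, 1))
            _add_at(frontal, int(ts * fs), ramp * sharp)
            _add_at(parietal, int(ts * fs), 0.5 * ramp * sharp)
        e0 = int(onset // hypnogram.epoch_len_s)
        e1 = int((onset + dur) // hypnogram.epoch_len_s) + 1
        new_states[e0 : min(e1, len(new_states))] = SEIZURE
        sz_rows.append({"onset_s": onset, "duration_s": dur})

    gt_hyp = Hypnogram(new_states, hypnogram.epoch_len_s, hypnogram.start_zeitgeber_h)
    return GroundTruth(
        hypnogram=gt_hyp,
        events=pd.DataFrame(ev_rows, columns=["time_s", "template", "amp_uv"]),
        spindles=pd.DataFrame(
            sp_rows, columns=["start_s", "duration_s", "freq_hz", "amp_uv"]
        ),
        seizures=pd.DataFrame(sz_rows, columns=["onset_s", "duration_s"]),
    )


def simulate_animal(
    cfg: CohortConfig, arm: str, seed: int
) -> tuple[EEGRecording, GroundTruth]:
    """Hypnogram + EEG + injections for one animal (no file I/O)."""
    hyp, _ = simulate_hypnogram(cfg, seed, arm)
    rec = synthesize_eeg(hyp, cfg, seed + 1, arm)
    gt = inject_transients(rec, hyp, cfg, seed + 2, arm)
    return rec, gt


def animal_ids(cfg: CohortConfig) -> list[tuple[str, str]]:
    """Deterministic (animal_id, arm) listing for a cohort."""
    out = []
    for arm in ARMS:
        for i in range(cfg.n_per_arm.get(arm, 0)):
            out.append((f"{arm}{i + 1:02d}", arm))
    return out


def write_fixture_cohort(cfg: CohortConfig, outdir) -> Path:
    """Write EDFs + ground-truth sidecars + a YAML manifest.

    Deterministic: per-animal seeds derive from ``cfg.seed`` and the
    animal index, and the manifest embeds the config hash, so reruns are
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "fs": cfg.fs,
        "epoch_len_s": cfg.epoch_len_s,
        "start_zt_h": cfg.start_zt_h,
        "channel_roles": {"EEG Fr": ROLE_FRONTAL, "EEG Par": ROLE_PARIETAL,
                          "EMG": ROLE_EMG},
        "animals": [],
    }
    for idx, (aid, arm) in enumerate(animal_ids(cfg)):
        seed = cfg.seed * 10007 + idx * 13
        rec, gt = simulate_animal(cfg, arm, seed)
        edfio.write_edf(
            outdir / f"{aid}.edf", rec.signals, rec.fs, rec.start_clock_time,
            patient_id=aid, recording_id=f"arm {arm}",
        )
        gt.hypnogram.to_csv(outdir / f"{aid}_hypnogram.csv")
        gt.events.to_csv(outdir / f"{aid}_events.csv", index=False)
        gt.spindles.to_csv(outdir / f"{aid}_spindles.csv", index=False)
        gt.seizures.to_csv(outdir / f"{aid}_seizures.csv", index=False)
        manifest["animals"].append(
            {
                "animal_id": aid,
                "arm": arm,
                "seed": seed,
                "edf": f"{aid}.edf",
                "hypnogram": f"{aid}_hypnogram.csv",
                "seizure_positive": bool(len(gt.seizures)),
            }
        )
    path = outdir / "manifest.yml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path
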