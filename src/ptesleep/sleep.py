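"""Sleep architecture from per-epoch hypnograms.

States are scored in 4-s epochs as WAKE / NREM / REM, with ARTIFACT and
SEIZURE epochs excluded from all sleep metrics.  Sleep efficiency is
sleep time over scored (non-excluded) time, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, UndefinedMetricError

WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
ARTIFACT = "ARTIFACT"
SEIZURE = "SEIZURE"

VIGILANCE_STATES = (WAKE, NREM, REM)
EXCLUDED_STATES = (ARTIFACT, SEIZURE)
ALL_STATES = VIGILANCE_STATES + EXCLUDED_STATES


@dataclass
class Hypnogram:
    states: np.ndarray  # dtype str, values in ALL_STATES
    epoch_len_s: float = 4.0
    start_zeitgeber_h: float = 0.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="U8")
        if self.states.size == 0:
            raise ConfigurationError("empty hypnogram")
        bad = set(np.unique(self.states)) - set(ALL_STATES)
        if bad:
            raise ConfigurationError(f"unknown states: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def n_epochs(self) -> int:
        return len(self.states)

    def epoch_zt_hours(self) -> np.ndarray:
        """ZT of each epoch's start, in hours, wrapped to [0, 24)."""
        t = self.start_zeitgeber_h + np.arange(len(self)) * self.epoch_len_s / 3600.0
        return t % 24.0

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"epoch_index": np.arange(len(self)), "state": self.states}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, epoch_len_s: float = 4.0, start_zeitgeber_h: float = 0.0):
        df = pd.read_csv(path)
        return cls(df["state"].to_numpy(), epoch_len_s, start_zeitgeber_h)


@dataclass
class Bout:
    state: str
    start_epoch: int
    n_epochs: int
    epoch_len_s: float = 4.0
    truncated: bool = False  # touches a record edge

    @property
    def length_s(self) -> float:
        return self.n_epochs * self.epoch_len_s


def score_times(h: Hypnogram) -> dict:
    """Minutes per vigilance state plus sleep efficiency (%).

    Excluded (artifact/seizure) epochs count in neither numerator nor
    denominator.
    """
    epm = h.epoch_len_s / 60.0
    minutes = {s: float(np.sum(h.states == s)) * epm for s in ALL_STATES}
    scored = sum(minutes[s] for s in VIGILANCE_STATES)
    if scored == 0:
        raise UndefinedMetricError("all epochs excluded; efficiency undefined")
    sleep_min = minutes[NREM] + minutes[REM]
    out = {f"{s.lower()}_min": minutes[s] for s in ALL_STATES}
    out["scored_min"] = scored
    out["sleep_efficiency_pct"] = 100.0 * sleep_min / scored
    return out


def extract_bouts(h: Hypnogram, bridge_exclusions: bool = False) -> list[Bout]:
    """Maximal runs of identical vigilance state.

    Artifact/seizure epochs break bouts by default (``bridge_exclusions``
    treats runs separated only by exclusions as one bout).  Excluded
    states themselves never form bouts.
    """
    states = h.states
    bouts: list[Bout] = []
    i = 0
    n = len(states)
    while i < n:
        s = states[i]
        if s in EXCLUDED_STATES:
            i += 1
            continue
        j = i + 1
        while j <= n:
            if j == n:
                break
            nxt = states[j]
            if nxt == s:
                j += 1
            elif bridge_exclusions and nxt in EXCLUDED_STATES:
                # look past the exclusion run
                k = j
                while k < n and states[k] in EXCLUDED_STATES:
                    k += 1
                if k < n and states[k] == s:
                    j = k + 1
                else:
                    break
            else:
                break
        if bridge_exclusions:
            n_state = int(np.sum(states[i:j] == s))
        else:
            n_state = j - i
        bouts.append(
            Bout(
                state=s,
                start_epoch=i,
                n_epochs=n_state,
                epoch_len_s=h.epoch_len_s,
                truncated=(i == 0 or j == n),
            )
        )
        i = j
    return bouts


def bout_summary(bouts: list[Bout], include_edge_bouts: bool = True) -> pd.DataFrame:
    """Bout count and mean length (s) per vigilance state."""
    rows = []
    for s in VIGILANCE_STATES:
        sel = [
            b for b in bouts
            if b.state == s and (include_edge_bouts or not b.truncated)
        ]
        rows.append(
            {
                "state": s,
                "bout_count": len(sel),
                "mean_bout_length_s": (
                    float(np.mean([b.length_s for b in sel])) if sel else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("state")


def bin_states(h: Hypnogram, bin_h: float = 4.0) -> pd.DataFrame:
    """Minutes per state per diurnal bin anchored at lights-on.

    Bin 0 covers ZT0-``bin_h``; an epoch is assigned by its start time.
    Records longer than 24 h accumulate into the same diurnal bins.
    """
    if bin_h <= 0 or abs(24.0 / bin_h - round(24.0 / bin_h)) > 1e-9:
        raise ConfigurationError(f"bin_h={bin_h} must divide 24")
    n_bins = int(round(24.0 / bin_h))
    zt = h.epoch_zt_hours()
    bin_idx = np.minimum((zt // bin_h).astype(int), n_bins - 1)
    epm = h.epoch_len_s / 60.0
    out = pd.DataFrame(
        0.0, index=pd.RangeIndex(n_bins, name="bin"), columns=list(ALL_STATES)
    )
    for s in ALL_STATES:
        counts = np.bincount(bin_idx[h.states == s], minlength=n_bins)
        out[s] = counts * epm
    return out


def architecture_summary(h: Hypnogram, bin_h: float = 4.0) -> dict:
    """Bundle time-in-state, efficiency, bout stats and binned minutes."""
    times = score_times(h)
    bouts = extract_bouts(h)
    return {
        "times": times,
        "bouts": bout_summary(bouts).reset_index().to_dict(orient="records"),
        "binned_minutes": bin_states(h, bin_h)[list(VIGILANCE_STATES)]
        .reset_index()
        .to_dict(orient="records"),
    }
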