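"""High-amplitude interictal event analysis.

Detection: an event starts when the signal's absolute deviation from the
record mean crosses above ``onset_sd`` standard deviations and ends at
the next crossing back below ``offset_sd`` SD.  Discrete spikes are
events briefer than 200 ms and separated from neighbours by more than
200 ms.  Spike waveforms are projected onto their first three principal
components and clustered with a 9-component Gaussian mixture; each
cluster is scored by the fraction of its members coming from injured
(CCI) versus uninjured (NC) animals, and clusters at ratio >= 0.90 are
flagged injury-related.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .exceptions import (
    ConfigurationError,
    InsufficientReplicationError,
    ModelDegeneracyError,
)
from . import stats as _stats

GROUP_NC = "NC"
GROUP_SHAM = "sham"
GROUP_CCI = "CCI"


@dataclass
class EventDetectionParams:
    onset_sd: float = 5.0
    offset_sd: float = 1.0
    spike_max_dur_ms: float = 200.0
    min_separation_ms: float = 200.0
    two_sided: bool = True  # detect on |x - mean|; False = positive-going only

    def __post_init__(self) -> None:
        if not self.onset_sd > self.offset_sd > 0:
            raise ConfigurationError("need onset_sd > offset_sd > 0")
        if self.spike_max_dur_ms <= 0 or self.min_separation_ms <= 0:
            raise ConfigurationError("durations must be positive")


@dataclass
class DetectedEvent:
    onset_sample: int
    offset_sample: int
    peak_sample: int
    peak_amplitude_uv: float
    duration_ms: float
    is_discrete_spike: bool = False
    cluster: int = -1
    animal_id: str = ""
    group: str = ""


def _deviation(x: np.ndarray, params: EventDetectionParams) -> np.ndarray:
    dev = x - x.mean()
    return np.abs(dev) if params.two_sided else dev


def detect_events(
    signal: np.ndarray, fs: float, params: EventDetectionParams | None = None
) -> list[DetectedEvent]:
    """Threshold-crossing event detection on a filtered frontal channel.

    Returns maximal, non-overlapping, onset-ordered intervals.  An event
    still open at the record end is closed there.
    """
    if params is None:
        params = EventDetectionParams()
    x = np.asarray(signal, dtype=float)
    sd = float(x.std())
    if sd == 0:
        warnings.warn("constant signal: SD=0, no events detectable")
        return []
    dev = _deviation(x, params)
    on_thr = params.onset_sd * sd
    off_thr = params.offset_sd * sd

    above = dev > on_thr
    below = dev < off_thr
    # crossing above: sample i is above while i-1 was not (sample 0 counts)
    up = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    down = np.flatnonzero(below & ~np.concatenate(([False], below[:-1])))

    events: list[DetectedEvent] = []
    cursor = 0
    ui = 0
    n = len(x)
    while ui < len(up):
        onset = up[ui]
        if onset < cursor:
            ui += 1
            continue
        di = np.searchsorted(down, onset, side="right")
        offset = int(down[di]) if di < len(down) else n
        seg = dev[onset:offset]
        peak_rel = int(np.argmax(np.abs(seg)))
        events.append(
            DetectedEvent(
                onset_sample=int(onset),
                offset_sample=int(offset),
                peak_sample=int(onset) + peak_rel,
                peak_amplitude_uv=float(x[onset + peak_rel] - x.mean()),
                duration_ms=(offset - onset) / fs * 1000.0,
            )
        )
        cursor = offset
        ui = int(np.searchsorted(up, offset, side="left"))
    return events


def classify_discrete_spikes(
    events: list[DetectedEvent], fs: float, params: EventDetectionParams | None = None
) -> list[DetectedEvent]:
    """Flag events that are brief (<200 ms) and isolated (>200 ms gaps).

    First/last events use one-sided gaps.  Returns the same list with
    ``is_discrete_spike`` set.
    """
    if params is None:
        params = EventDetectionParams()
    for i, ev in enumerate(events):
        ok = ev.duration_ms < params.spike_max_dur_ms
        if ok and i > 0:
            gap_ms = (ev.onset_sample - events[i - 1].offset_sample) / fs * 1000.0
            ok = gap_ms > params.min_separation_ms
        if ok and i < len(events) - 1:
            gap_ms = (events[i + 1].onset_sample - ev.offset_sample) / fs * 1000.0
            ok = gap_ms > params.min_separation_ms
        ev.is_discrete_spike = bool(ok)
    return events


def extract_waveforms(
    signal: np.ndarray,
    events: list[DetectedEvent],
    fs: float,
    window_ms: float = 400.0,
    zscore: bool = True,
) -> np.ndarray:
    """Peak-centred snippets, one row per event.

    Row length is ``2*floor(window_ms*fs/2000) + 1`` (odd, centre sample
    included).  Edges are reflection-padded.  Rows are z-scored by
    default so clustering reflects shape, not amplitude.
    """
    half = int(window_ms * fs / 2000.0)
    width = 2 * half + 1
    if not events:
        return np.empty((0, width))
    x = np.asarray(signal, dtype=float)
    padded = np.pad(x, half, mode="reflect")
    rows = np.empty((len(events), width))
    for i, ev in enumerate(events):
        c = ev.peak_sample + half  # index in padded array
        rows[i] = padded[c - half : c + half + 1]
    if zscore:
        mu = rows.mean(axis=1, keepdims=True)
        sd = rows.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        rows = (rows - mu) / sd
    return rows


@dataclass
class EventClusterModel:
    n_clusters: int
    n_components: int
    pca: PCA
    gmm: GaussianMixture
    assignments: np.ndarray  # cluster index per event
    cluster_ratio: np.ndarray  # CCI/(CCI+NC) per cluster, NaN if empty
    ratio_threshold: float
    rng_seed: int

    def cci_related_clusters(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.flatnonzero(self.cluster_ratio >= self.ratio_threshold)

    def predict(self, waveforms: np.ndarray) -> np.ndarray:
        return self.gmm.predict(self.pca.transform(waveforms))


def fit_cluster_model(
    waveforms: np.ndarray,
    groups: np.ndarray,
    n_clusters: int = 9,
    n_components: int = 3,
    ratio_threshold: float = 0.90,
    seed: int = 0,
) -> EventClusterModel:
    """PCA (3 PCs) + full-covariance Gaussian mixture over event shapes.

    ``groups`` gives the treatment arm per event.  Cluster ratio is
    n_CCI/(n_CCI + n_NC) per cluster; sham events are assigned but do
    not enter the ratio.
    """
    waveforms = np.asarray(waveforms, dtype=float)
    groups = np.asarray(groups)
    if len(waveforms) != len(groups):
        raise ConfigurationError("waveforms and groups must align")
    if len(waveforms) < n_clusters:
        raise ModelDegeneracyError(
            f"{len(waveforms)} events < {n_clusters} clusters; reduce n_clusters"
        )
    if not (np.any(groups == GROUP_CCI) and np.any(groups == GROUP_NC)):
        raise ModelDegeneracyError(
            "cluster ratio needs at least one CCI and one NC event"
        )
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(waveforms)
    gmm = GaussianMixture(
        n_components=n_clusters,
        covariance_type="full",
        n_init=10,
        init_params="k-means++",
        random_state=seed,
        reg_covar=1e-6,
    )
    gmm.fit(scores)
    resp = gmm.predict_proba(scores)
    assignments = np.argmax(resp, axis=1)  # argmax takes lowest index on ties

    ratio = np.full(n_clusters, np.nan)
    for k in range(n_clusters):
        n_cci = int(np.sum((assignments == k) & (groups == GROUP_CCI)))
        n_nc = int(np.sum((assignments == k) & (groups == GROUP_NC)))
        if n_cci + n_nc:
            ratio[k] = n_cci / (n_cci + n_nc)
    return EventClusterModel(
        n_clusters=n_clusters,
        n_components=n_components,
        pca=pca,
        gmm=gmm,
        assignments=assignments,
        cluster_ratio=ratio,
        ratio_threshold=ratio_threshold,
        rng_seed=seed,
    )


def summarize_event_rates(
    event_table: pd.DataFrame,
    model: EventClusterModel,
    recording_hours: dict[str, float],
) -> pd.DataFrame:
    """Per-animal events/hour and injury-related events/hour.

    ``event_table`` needs columns animal_id, cluster.  Animals in
    ``recording_hours`` with no events get zero rates.
    """
    for aid, hours in recording_hours.items():
        if hours <= 0:
            raise ConfigurationError(f"recording_hours <= 0 for {aid}")
    related = set(model.cci_related_clusters().tolist())
    rows = []
    for aid, hours in recording_hours.items():
        sub = event_table[event_table["animal_id"] == aid]
        n_all = len(sub)
        n_rel = int(sub["cluster"].isin(related).sum())
        rows.append(
            {
                "animal_id": aid,
                "recording_hours": hours,
                "events_per_hour": n_all / hours,
                "cci_related_events_per_hour": n_rel / hours,
            }
        )
    return pd.DataFrame(rows).set_index("animal_id")


def compare_event_rates(rates_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Welch t-tests of CCI vs NC and CCI vs sham, Bonferroni-doubled."""
    for g in (GROUP_CCI, GROUP_NC, GROUP_SHAM):
        if g in rates_by_group and len(rates_by_group[g]) < 2:
            raise InsufficientReplicationError(f"group {g} has <2 animals")
    pairs = {}
    if GROUP_NC in rates_by_group:
        pairs["CCI_vs_NC"] = (rates_by_group[GROUP_CCI], rates_by_group[GROUP_NC])
    if GROUP_SHAM in rates_by_group:
        pairs["CCI_vs_sham"] = (rates_by_group[GROUP_CCI], rates_by_group[GROUP_SHAM])
    return _stats.welch_bonferroni(pairs, n_comparisons=2)


def events_to_table(
    events: list[DetectedEvent],
    fs: float,
    model: EventClusterModel | None = None,
) -> pd.DataFrame:
    """Tidy event table (one row per event) for CSV export."""
    rows = []
    for i, ev in enumerate(events):
        rows.append(
            {
                "animal_id": ev.animal_id,
                "group": ev.group,
                "onset_s": ev.onset_sample / fs,
                "offset_s": ev.offset_sample / fs,
                "duration_ms": ev.duration_ms,
                "peak_uv": ev.peak_amplitude_uv,
                "is_discrete_spike": ev.is_discrete_spike,
                "cluster": ev.cluster,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "animal_id", "group", "onset_s", "offset_s", "duration_ms",
            "peak_uv", "is_discrete_spike", "cluster",
        ],
    )
    if model is not None and len(df):
        ratio = np.full(len(df), np.nan)
        ok = df["cluster"].to_numpy() >= 0
        ratio[ok] = model.cluster_ratio[df["cluster"].to_numpy()[ok]]
        df["cluster_ratio"] = ratio
        with np.errstate(invalid="ignore"):
            df["is_cci_related"] = ratio >= model.ratio_threshold
    return df
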