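import numpy as np
import pytest

from ptesleep import events as ev
from ptesleep.exceptions import (
    ConfigurationError,
    InsufficientReplicationError,
    ModelDegeneracyError,
)


def oracle_scan(x, on_sd=5.0, off_sd=1.0):
    """Independent O(n) state machine over |x - mean| (boundary oracle)."""
    x = np.asarray(x, dtype=float)
    dev = np.abs(x - x.mean())
    on = on_sd * x.std()
    off = off_sd * x.std()
    out = []
    i, n = 0, len(x)
    while i < n:
        if dev[i] > on:
            j = i + 1
            while j < n and not dev[j] < off:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def biphasic_pulse(fs, dur_ms=100, amp=150.0):
    n = int(dur_ms / 1000 * fs)
    t = np.linspace(0, 1, n)
    return amp * np.sin(2 * np.pi * t) * np.hanning(n)


def monophasic_pulse(fs, dur_ms=100, amp=150.0):
    n = int(dur_ms / 1000 * fs)
    return amp * np.hanning(n)


class TestDetectEvents:
    fs = 256.0

    def test_subthreshold_sine_no_events(self):
        t = np.arange(0, 30, 1 / self.fs)
        x = np.sin(2 * np.pi * 2 * t)
        assert ev.detect_events(x, self.fs) == []

    def test_constant_signal_warns_empty(self):
        with pytest.warns(UserWarning):
            assert ev.detect_events(np.full(1000, 3.0), self.fs) == []

    def test_single_pulse_bracketed(self, rng):
        x = 10 * rng.standard_normal(int(60 * self.fs))
        pulse = monophasic_pulse(self.fs)
        at = int(30 * self.fs)
        x[at : at + len(pulse)] += pulse
        evs = ev.detect_events(x, self.fs)
        assert len(evs) == 1
        assert evs[0].onset_sample >= at
        assert evs[0].offset_sample <= at + len(pulse) + int(0.05 * self.fs)
        assert [(e.onset_sample, e.offset_sample) for e in evs] == oracle_scan(x)

    def test_two_pulses_merge_or_split(self):
        fs = self.fs
        base = np.sin(2 * np.pi * 2 * np.arange(0, 60, 1 / fs))  # sd ~0.707
        # split case: pulses separated by quiet baseline
        x = base.copy()
        p = biphasic_pulse(fs, dur_ms=50, amp=30)
        a, gap = int(20 * fs), int(0.05 * fs)
        x[a : a + len(p)] += p
        b = a + len(p) + gap
        x[b : b + len(p)] += p
        split = ev.detect_events(x, fs)
        # merged case: a pedestal keeps |x-mean| above 1 SD between pulses
        y = x.copy()
        y[a : b + len(p)] += 5 * y.std()
        merged = ev.detect_events(y, fs)
        assert [(e.onset_sample, e.offset_sample) for e in split] == oracle_scan(x)
        assert [(e.onset_sample, e.offset_sample) for e in merged] == oracle_scan(y)
        assert len(split) == 2
        assert len(merged) == 1

    def test_oracle_equivalence_random_signals(self):
        rng = np.random.default_rng(99)
        fs = 128.0
        for _ in range(200):
            x = 10 * rng.standard_normal(int(60 * fs))
            for _ in range(rng.integers(0, 4)):
                p = biphasic_pulse(fs, dur_ms=int(rng.integers(40, 300)),
                                   amp=rng.uniform(80, 200))
                at = int(rng.integers(0, len(x) - len(p)))
                x[at : at + len(p)] += p
            got = [(e.onset_sample, e.offset_sample)
                   for e in ev.detect_events(x, fs)]
            assert got == oracle_scan(x)

    def test_onset_threshold_monotonicity(self, rng):
        x = 10 * rng.standard_normal(int(120 * self.fs))
        for _ in range(5):
            p = biphasic_pulse(self.fs, amp=rng.uniform(60, 160))
            at = int(rng.integers(0, len(x) - len(p)))
            x[at : at + len(p)] += p
        counts = [
            len(ev.detect_events(x, self.fs, ev.EventDetectionParams(onset_sd=sd)))
            for sd in (3, 4, 5, 6, 8)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_params(self):
        with pytest.raises(ConfigurationError):
            ev.EventDetectionParams(onset_sd=1.0, offset_sd=2.0)


def _mk_event(fs, onset_s, dur_ms):
    onset = int(onset_s * fs)
    offset = onset + int(dur_ms / 1000 * fs)
    return ev.DetectedEvent(
        onset_sample=onset, offset_sample=offset, peak_sample=onset,
        peak_amplitude_uv=100.0, duration_ms=(offset - onset) / fs * 1000,
    )


class TestDiscreteSpikeRule:
    fs = 1000.0  # 1 sample per ms keeps the grid exact

    def test_single_brief_event_is_spike(self):
        evs = ev.classify_discrete_spikes([_mk_event(self.fs, 1.0, 150)], self.fs)
        assert evs[0].is_discrete_spike

    def test_long_event_never_spike(self):
        evs = ev.classify_discrete_spikes([_mk_event(self.fs, 1.0, 250)], self.fs)
        assert not evs[0].is_discrete_spike

    def test_close_pair_not_spikes(self):
        a = _mk_event(self.fs, 1.0, 100)
        b = _mk_event(self.fs, 1.0 + 0.100 + 0.150, 100)  # 150 ms gap
        evs = ev.classify_discrete_spikes([a, b], self.fs)
        assert not evs[0].is_discrete_spike
        assert not evs[1].is_discrete_spike

    def test_truth_table_grid(self):
        # truth: spike iff dur < 200 and every gap > 200 (strict)
        for dur_ms in (100, 150, 199, 200, 250):
            for gap_ms in (100, 199, 200, 201, 300):
                a = _mk_event(self.fs, 1.0, 100)
                b = _mk_event(self.fs, 1.0 + 0.1 + gap_ms / 1000, dur_ms)
                c = _mk_event(self.fs, b.offset_sample / self.fs + gap_ms / 1000, 100)
                evs = ev.classify_discrete_spikes([a, b, c], self.fs)
                expect = (dur_ms < 200) and (gap_ms > 200)
                assert evs[1].is_discrete_spike == expect, (dur_ms, gap_ms)


class TestExtractWaveforms:
    def test_row_length(self, rng):
        fs = 1024.0
        x = rng.standard_normal(int(10 * fs))
        e = _mk_event(fs, 5.0, 100)
        wf = ev.extract_waveforms(x, [e], fs, window_ms=400)
        assert wf.shape == (1, 409)  # 2*floor(0.4*1024/2)+1

    def test_identical_pulses_identical_rows(self):
        fs = 256.0
        x = np.zeros(int(20 * fs))
        p = biphasic_pulse(fs)
        for at_s in (5.0, 12.0):
            at = int(at_s * fs)
            x[at : at + len(p)] += p
        evs = [
            ev.DetectedEvent(0, 1, int(5 * fs) + int(np.argmax(p)), 0, 0),
            ev.DetectedEvent(0, 1, int(12 * fs) + int(np.argmax(p)), 0, 0),
        ]
        wf = ev.extract_waveforms(x, evs, fs)
        np.testing.assert_allclose(wf[0], wf[1], atol=1e-12)

    def test_edge_reflection(self, rng):
        fs = 256.0
        x = rng.standard_normal(int(2 * fs))
        e = ev.DetectedEvent(0, 1, 10, 0, 0)
        wf = ev.extract_waveforms(x, [e], fs, window_ms=400, zscore=False)
        half = int(400 * fs / 2000)
        # left part comes from reflect padding of the first samples
        padded = np.pad(x, half, mode="reflect")
        np.testing.assert_allclose(wf[0], padded[10 : 10 + 2 * half + 1])

    def test_empty(self):
        wf = ev.extract_waveforms(np.zeros(100), [], 100.0)
        assert wf.shape[0] == 0


def _family_waveforms(rng, n, kind, width=64):
    t = np.linspace(-1, 1, width)
    if kind == "sharp":
        base = np.exp(-((t / 0.08) ** 2)) - 0.9 * np.exp(-(((t - 0.2) / 0.15) ** 2))
    else:
        base = np.exp(-((t / 0.5) ** 2))
    return base + 0.05 * rng.standard_normal((n, width))


class TestClusterModel:
    def test_nc_only_rejected(self, rng):
        wf = _family_waveforms(rng, 30, "blunt")
        with pytest.raises(ModelDegeneracyError):
            ev.fit_cluster_model(wf, np.array(["NC"] * 30))

    def test_too_few_events(self, rng):
        wf = _family_waveforms(rng, 5, "blunt")
        with pytest.raises(ModelDegeneracyError):
            ev.fit_cluster_model(wf, np.array(["NC", "CCI"] * 2 + ["NC"]))

    def test_injury_specific_family_recovered(self):
        rng = np.random.default_rng(3)
        sharp = _family_waveforms(rng, 120, "sharp")
        blunt = _family_waveforms(rng, 120, "blunt")
        wf = np.vstack([sharp, blunt])
        groups = np.array(["CCI"] * 120 + ["NC"] * 60 + ["CCI"] * 60)
        model = ev.fit_cluster_model(wf, groups, seed=0)
        related = set(model.cci_related_clusters().tolist())
        assert related
        sharp_clusters = model.assignments[:120]
        captured = np.isin(sharp_clusters, list(related)).mean()
        assert captured >= 0.8

    def test_shared_blob_ratios_near_half(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            wf = rng.standard_normal((900, 32))
            groups = np.array(["CCI", "NC"] * 450)
            model = ev.fit_cluster_model(wf, groups, seed=seed)
            ratios = model.cluster_ratio[np.isfinite(model.cluster_ratio)]
            assert np.all((ratios >= 0.3) & (ratios <= 0.7)), ratios

    def test_ratio_conservation(self, rng):
        wf = rng.standard_normal((100, 32))
        groups = np.array(["CCI"] * 40 + ["NC"] * 40 + ["sham"] * 20)
        model = ev.fit_cluster_model(wf, groups, seed=1)
        total = 0
        for k in range(model.n_clusters):
            sel = model.assignments == k
            total += np.sum(sel & (groups != "sham"))
        assert total == 80

    def test_deterministic_given_seed(self, rng):
        wf = rng.standard_normal((60, 32))
        groups = np.array(["CCI", "NC"] * 30)
        m1 = ev.fit_cluster_model(wf, groups, seed=5)
        m2 = ev.fit_cluster_model(wf, groups, seed=5)
        np.testing.assert_array_equal(m1.assignments, m2.assignments)


def _model_with_ratios(ratios, thr=0.90):
    return ev.EventClusterModel(
        n_clusters=len(ratios), n_components=3, pca=None, gmm=None,
        assignments=np.array([]), cluster_ratio=np.asarray(ratios, float),
        ratio_threshold=thr, rng_seed=0,
    )


class TestRateSummary:
    def test_basic_arithmetic(self):
        import pandas as pd

        model = _model_with_ratios([0.95, 0.5])
        table = pd.DataFrame(
            {"animal_id": ["a"] * 48, "cluster": [0] * 12 + [1] * 36}
        )
        out = ev.summarize_event_rates(table, model, {"a": 24.0})
        assert out.loc["a", "events_per_hour"] == pytest.approx(2.0)
        assert out.loc["a", "cci_related_events_per_hour"] == pytest.approx(0.5)

    def test_threshold_inclusive(self):
        import pandas as pd

        model = _model_with_ratios([0.90])
        table = pd.DataFrame({"animal_id": ["a"] * 10, "cluster": [0] * 10})
        out = ev.summarize_event_rates(table, model, {"a": 10.0})
        assert out.loc["a", "cci_related_events_per_hour"] == pytest.approx(1.0)

    def test_zero_events(self):
        import pandas as pd

        model = _model_with_ratios([0.95])
        table = pd.DataFrame({"animal_id": [], "cluster": []})
        out = ev.summarize_event_rates(table, model, {"a": 24.0})
        assert out.loc["a", "events_per_hour"] == 0.0
        assert out.loc["a", "cci_related_events_per_hour"] == 0.0

    def test_bad_hours(self):
        import pandas as pd

        model = _model_with_ratios([0.95])
        with pytest.raises(ConfigurationError):
            ev.summarize_event_rates(
                pd.DataFrame({"animal_id": [], "cluster": []}), model, {"a": 0.0}
            )


class TestCompareEventRates:
    def test_identical_groups(self):
        same = np.array([1.0, 2.0, 3.0])
        out = ev.compare_event_rates({"CCI": same, "NC": same, "sham": same})
        assert out.loc["CCI_vs_NC", "t"] == pytest.approx(0.0)
        assert out.loc["CCI_vs_NC", "p_corrected"] == pytest.approx(1.0)

    def test_welch_df_closed_form(self, rng):
        a = rng.standard_normal(10)
        b = 2 * rng.standard_normal(10)
        out = ev.compare_event_rates({"CCI": a, "NC": b})
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 10 + vb / 10
        df_expect = se2**2 / ((va / 10) ** 2 / 9 + (vb / 10) ** 2 / 9)
        assert out.loc["CCI_vs_NC", "df"] == pytest.approx(df_expect)

    def test_power_on_separated_groups(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            out = ev.compare_event_rates(
                {"CCI": 10 + r.standard_normal(10), "NC": 2 + r.standard_normal(10)}
            )
            hits += out.loc["CCI_vs_NC", "p_corrected"] < 0.01
        assert hits == 20

    def test_insufficient_replication(self):
        with pytest.raises(InsufficientReplicationError):
            ev.compare_event_rates({"CCI": np.array([1.0]), "NC": np.array([1.0, 2.0])})
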