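"""End-to-end orchestration over a fixture cohort directory.

``run_pipeline`` consumes the manifest written by
:func:`ptesleep.synth.write_fixture_cohort` (or a hand-written one with
the same layout), runs preprocess -> events -> sleep -> spindles ->
spectral -> stats, and returns a JSON-serializable report whose content
hash is stable across reruns.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import sleep as sl
from . import spectral as spc
from . import spindles as spn
from . import stats as st
from .exceptions import PtesleepError
from .preprocess import FilterSpec, apply_zero_phase, load_edf
from .sleep import Hypnogram

REPORT_SECTIONS = (
    "event_rates",
    "time_in_state",
    "binned_states",
    "bout_stats",
    "spindle_metrics",
    "nrem_ndelta",
)


def _jsonable(obj):
    """Recursively convert numpy/pandas values; NaN becomes None."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) or math.isinf(f) else round(f, 10)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def report_hash(report: dict) -> str:
    blob = json.dumps(_jsonable(report), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(
    cohort_dir,
    filter_spec: FilterSpec | None = None,
    event_params: ev.EventDetectionParams | None = None,
    spindle_params: spn.SpindleParams | None = None,
    band_scheme: spc.BandScheme | None = None,
    bin_h_states: float = 4.0,
    bin_h_spindles: float = 6.0,
    bin_h_ndelta: float = 4.0,
    n_clusters: int = 9,
    seed: int = 0,
) -> dict:
    """Run every stage on each animal of a cohort and pool group stats.

    A missing hypnogram skips the sleep-dependent stages for that animal
    with an explicit log entry; a failed clustering stage (e.g. no CCI
    or NC events) is reported in-place without aborting other sections.
    """
    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "manifest.yml") as fh:
        manifest = yaml.safe_load(fh)
    filter_spec = filter_spec or FilterSpec()
    event_params = event_params or ev.EventDetectionParams()
    spindle_params = spindle_params or spn.SpindleParams()
    band_scheme = band_scheme or spc.BandScheme()

    log: list[str] = []
    report: dict = {
        "params": {
            "seed": seed,
            "n_clusters": n_clusters,
            "config_hash": manifest.get("config_hash"),
            "bin_h_states": bin_h_states,
            "bin_h_spindles": bin_h_spindles,
        },
        "log": log,
    }

    role_map = manifest["channel_roles"]
    epoch_len_s = float(manifest.get("epoch_len_s", 4.0))
    start_zt_h = float(manifest.get("start_zt_h", 0.0))

    all_waveforms = []
    all_groups = []
    all_events = []
    rec_hours: dict[str, float] = {}
    group_of: dict[str, str] = {}
    per_animal: dict[str, dict] = {}

    for animal in manifest["animals"]:
        aid, arm = animal["animal_id"], animal["arm"]
        group_of[aid] = arm
        rec = load_edf(cohort_dir / animal["edf"], role_map)
        frontal = apply_zero_phase(rec.frontal(), rec.fs, filter_spec)
        rec_hours[aid] = len(frontal) / rec.fs / 3600.0

        evs = ev.detect_events(frontal, rec.fs, event_params)
        ev.classify_discrete_spikes(evs, rec.fs, event_params)
        for e in evs:
            e.animal_id, e.group = aid, arm
        spikes = [e for e in evs if e.is_discrete_spike]
        if spikes:
            wf = ev.extract_waveforms(frontal, spikes, rec.fs)
            all_waveforms.append(wf)
            all_groups.extend([arm] * len(spikes))
        all_events.extend(spikes)

        entry: dict = {"arm": arm, "recording_hours": rec_hours[aid],
                       "n_events": len(evs), "n_discrete_spikes": len(spikes)}
        hyp_path = cohort_dir / animal.get("hypnogram", "__missing__")
        if not hyp_path.exists():
            log.append(f"{aid}: hypnogram missing; sleep stages skipped")
            per_animal[aid] = entry
            continue
        hyp = Hypnogram.from_csv(hyp_path, epoch_len_s, start_zt_h)

        entry["sleep"] = sl.architecture_summary(hyp, bin_h_states)
        sps_ = spn.detect_spindles(frontal, rec.fs, hyp, spindle_params)
        entry["spindles"] = spn.spindle_metrics(sps_, hyp, rec.fs)
        entry["spindle_density_bins"] = spn.bin_spindle_density(
            sps_, hyp, rec.fs, bin_h_spindles
        )
        spectra = spc.compute_epoch_spectra(
            frontal, rec.fs, hyp, band_scheme, epoch_len_s
        )
        entry["ndelta_bins"] = spc.nrem_delta_profile(spectra, hyp, bin_h_ndelta)
        per_animal[aid] = entry

    # ---- pooled event clustering and rates ---------------------------
    try:
        if not all_waveforms:
            raise PtesleepError("no discrete spikes detected in cohort")
        waveforms = np.vstack(all_waveforms)
        model = ev.fit_cluster_model(
            waveforms, np.array(all_groups), n_clusters=n_clusters, seed=seed
        )
        for e, c in zip(all_events, model.assignments):
            e.cluster = int(c)
        table = ev.events_to_table(
            all_events, fs=float(manifest.get("fs", 1.0)), model=model
        )
        rates = ev.summarize_event_rates(table, model, rec_hours)
        rates["group"] = [group_of[a] for a in rates.index]
        report["event_rates"] = {
            "per_animal": rates,
            "cluster_ratios": model.cluster_ratio,
            "cci_related_clusters": model.cci_related_clusters(),
        }
        by_group = {
            g: rates.loc[rates["group"] == g, "events_per_hour"].to_numpy()
            for g in sorted(set(group_of.values()))
        }
        if all(len(v) >= 2 for v in by_group.values()) and "CCI" in by_group:
            report["event_rates"]["welch_tests"] = ev.compare_event_rates(by_group)
    except PtesleepError as exc:
        log.append(f"event-rate stage failed: {exc}")
        report["event_rates"] = {"error": str(exc)}

    # ---- sleep / spindle / spectral group summaries ------------------
    def collect(key, extractor):
        out = {}
        for aid, entry in per_animal.items():
            if key in entry:
                out[aid] = extractor(entry)
        return out

    eff = collect("sleep", lambda e: e["sleep"]["times"]["sleep_efficiency_pct"])
    report["time_in_state"] = {
        "per_animal": {a: e["sleep"]["times"] for a, e in per_animal.items()
                       if "sleep" in e},
        "sleep_efficiency_pct": eff,
    }
    report["binned_states"] = {
        a: e["sleep"]["binned_minutes"] for a, e in per_animal.items() if "sleep" in e
    }
    report["bout_stats"] = {
        a: e["sleep"]["bouts"] for a, e in per_animal.items() if "sleep" in e
    }
    report["spindle_metrics"] = {
        "per_animal": {a: e["spindles"] for a, e in per_animal.items()
                       if "spindles" in e},
        "density_bins": {a: e["spindle_density_bins"] for a, e in per_animal.items()
                         if "spindle_density_bins" in e},
    }
    report["nrem_ndelta"] = {
        a: e["ndelta_bins"] for a, e in per_animal.items() if "ndelta_bins" in e
    }

    # ---- group statistics -------------------------------------------
    stats_out: dict = {}
    eff_groups = {}
    for aid, v in eff.items():
        eff_groups.setdefault(group_of[aid], []).append(v)
    if len(eff_groups) >= 2 and all(len(v) >= 2 for v in eff_groups.values()):
        res = st.one_way_anova_holm({g: np.array(v) for g, v in eff_groups.items()})
        stats_out["sleep_efficiency_anova"] = res
    nd_rows = []
    for aid, entry in per_animal.items():
        if "ndelta_bins" not in entry:
            continue
        for b, row in entry["ndelta_bins"].iterrows():
            nd_rows.append(
                {"animal_id": aid, "group": group_of[aid], "bin": b,
                 "value": row["mean_n_delta"]}
            )
    if nd_rows:
        nd_df = pd.DataFrame(nd_rows).dropna()
        counts = nd_df.groupby("group")["animal_id"].nunique()
        if len(counts) >= 2 and (counts >= 2).all():
            try:
                stats_out["ndelta_mixed_anova"] = st.mixed_anova(nd_df)
            except PtesleepError as exc:
                log.append(f"ndelta mixed ANOVA skipped: {exc}")
        stats_out["ndelta_group_means"] = (
            nd_df.groupby("group")["value"].mean().to_dict()
        )
    report["stats"] = stats_out
    report["content_hash"] = report_hash(
        {k: v for k, v in report.items() if k != "content_hash"}
    )
    return report


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)


def report_to_markdown(report: dict) -> str:
    lines = ["# Cohort report", ""]
    lines.append(f"content hash: `{report.get('content_hash', '')}`")
    for section in REPORT_SECTIONS:
        lines.append(f"\n## {section}\n")
        lines.append("```json")
        lines.append(json.dumps(_jsonable(report.get(section, {})), indent=1,
                                sort_keys=True)[:4000])
        lines.append("```")
    if report.get("log"):
        lines.append("\n## log\n")
        lines.extend(f"- {entry}" for entry in report["log"])
    return "\n".join(lines)
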