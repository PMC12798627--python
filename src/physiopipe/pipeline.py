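"""End-to-end orchestration: sessions -> cleaned signals -> features -> stats.

``process_session`` runs every modality chain on one recording and
returns a feature row plus a QC record; ``run_pipeline`` maps it over
many sessions, assembles the feature table, writes outputs and runs the
configured rmANOVA contrasts on each physiological variable family.
Sessions that fail to load are logged and skipped; a run with zero usable
sessions is an error.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import ecg as ecg_mod
from . import eda as eda_mod
from . import hrv as hrv_mod
from . import resp as resp_mod
from .features import (
    BR_COLS,
    EDA_COLS,
    HR_COLS,
    ParticipantFeatures,
    assemble_features,
    feature_table,
    long_format,
)
from .io import SessionRecording, load_session, trim_to_experience, write_outputs
from .stats import apply_fdr, results_table, rm_anova_gg

log = logging.getLogger("physiopipe")


@dataclass
class PipelineConfig:
    """Parameter blocks for every stage plus run-level settings."""

    ecg: ecg_mod.EcgParams = field(default_factory=ecg_mod.EcgParams)
    eda: eda_mod.EdaParams = field(default_factory=eda_mod.EdaParams)
    resp: resp_mod.RespParams = field(default_factory=resp_mod.RespParams)
    hrv: hrv_mod.HrvParams = field(default_factory=hrv_mod.HrvParams)
    hrv_source: str = "tachogram"  # or "raw": literal waveform band power
    anova_models: tuple[str, ...] = (
        "time_only",
        "time_by_tech",
        "time_by_stim",
        "time_by_tech_by_stim",
    )
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def process_session(
    rec: SessionRecording, cfg: PipelineConfig | None = None
) -> tuple[ParticipantFeatures, dict]:
    """Run all modality chains on one (already trimmed) session."""
    cfg = cfg or PipelineConfig()
    qc: dict = {"participant": rec.participant_id, "channels": {}}
    span = 0.0
    start = rec.marker_time("experience_start")
    end = rec.marker_time("experience_end")
    if start is not None and end is not None:
        span = end - start
    if span <= 0:
        span = max((ch.duration for ch in rec.channels.values()), default=0.0)

    # --- ECG -> HR + HRV
    hr = None
    hrv_first = hrv_last = np.nan
    ecg_ok = False
    if rec.has("ECG"):
        try:
            ok_wander, wander = ecg_mod.assess_ecg_acceptability(rec.channels["ECG"], cfg.ecg)
            cleaned = ecg_mod.clean_ecg(rec.channels["ECG"], cfg.ecg)
            ecg_ok = ok_wander and cleaned.acceptable
            rp = ecg_mod.detect_r_peaks(cleaned.channel, cfg.ecg)
            ecg_ok = ecg_ok and rp.acceptable
            if ecg_ok:
                hr = ecg_mod.heart_rate_series(rp, span_s=span)
                if cfg.hrv_source == "raw":
                    first = hrv_mod.lf_hf_from_signal(
                        cleaned.channel, (0.0, 300.0), cfg.hrv, "first_5min")
                    last = hrv_mod.lf_hf_from_signal(
                        cleaned.channel, (span - 300.0, span), cfg.hrv, "last_5min")
                else:
                    first, last = hrv_mod.hrv_first_last(rp, span_s=span, p=cfg.hrv)
                hrv_first, hrv_last = first.lf_hf_ratio, last.lf_hf_ratio
                qc["channels"]["HRV"] = {
                    "first": {"lf": first.lf_power, "hf": first.hf_power},
                    "last": {"lf": last.lf_power, "hf": last.hf_power},
                }
            qc["channels"]["ECG"] = {
                "verdict": "acceptable" if ecg_ok else "unacceptable",
                "wander": wander,
                "masked_fraction": cleaned.masked_fraction,
                "n_peaks": rp.n_peaks,
                "notes": cleaned.notes + rp.notes,
            }
        except (ValueError, ecg_mod.UnsupportedRateError) as e:
            qc["channels"]["ECG"] = {"verdict": "error", "error": str(e)}
    else:
        qc["channels"]["ECG"] = {"verdict": "absent"}

    # --- EMG-guided EDA cleaning -> quality index -> tonic means
    tonic = None
    eda_ok = False
    if rec.has("EDA"):
        try:
            windows = eda_mod.detect_motion_windows(
                rec.channels.get("EMG"), cfg.eda
            )
            cleaned_eda = eda_mod.clean_eda(rec.channels["EDA"], windows, cfg.eda)
            qi, qi_ok = eda_mod.eda_quality_index(cleaned_eda.channel, cfg.eda)
            eda_ok = cleaned_eda.acceptable and qi_ok
            if eda_ok:
                tonic = eda_mod.tonic_series(cleaned_eda.channel, cfg.eda, span_s=span)
            qc["channels"]["EDA"] = {
                "verdict": "acceptable" if eda_ok else "unacceptable",
                "quality_index": qi,
                "artifact_window_count": len(windows.intervals),
                "artifact_coverage_fraction": cleaned_eda.artifact_coverage,
                "notes": cleaned_eda.notes,
            }
        except ValueError as e:
            qc["channels"]["EDA"] = {"verdict": "error", "error": str(e)}
    else:
        qc["channels"]["EDA"] = {"verdict": "absent"}

    # --- respiration -> breath rates + QA gate
    br = None
    resp_ok = False
    if rec.has("RESP"):
        try:
            sm = resp_mod.smooth_respiration(rec.channels["RESP"], cfg.resp)
            ev = resp_mod.detect_breath_onsets(sm, cfg.resp)
            brr = resp_mod.breath_rate_series(ev, span_s=span, p=cfg.resp)
            resp_ok = brr.qa_pass and ev.n_breaths > 0
            if resp_ok:
                br = brr.rates_bpm
            qc["channels"]["RESP"] = {
                "verdict": "acceptable" if resp_ok else "unacceptable",
                "mean_rate_bpm": brr.mean_rate_bpm,
                "n_breaths": ev.n_breaths,
                "first5_count": brr.first5_count,
                "last5_count": brr.last5_count,
                "period_estimates_s": sm.periods_s,
                "notes": ev.notes,
            }
        except ValueError as e:
            qc["channels"]["RESP"] = {"verdict": "error", "error": str(e)}
    else:
        qc["channels"]["RESP"] = {"verdict": "absent"}

    feats = assemble_features(
        participant=rec.participant_id,
        breath_rates=br,
        heart_rates=hr,
        tonic_eda=tonic,
        hrv_first=hrv_first,
        hrv_last=hrv_last,
        resp_ok=resp_ok,
        ecg_ok=ecg_ok,
        eda_ok=eda_ok,
        tech=rec.group_labels.get("tech", ""),
        stim=rec.group_labels.get("stim", ""),
    )
    if feats.excluded:
        qc["excluded"] = feats.exclusion_reason
    return feats, qc


def analyze_features(
    df: pd.DataFrame, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """rmANOVA battery over the physiological DV families.

    Runs each configured model on breath rate, heart rate and tonic EDA
    (HRV has only two windows and is covered by the time_only /
    interaction models as well) and BH-corrects within each DV family
    across models, mirroring an FDR-per-measure correction scheme.
    """
    cfg = cfg or PipelineConfig()
    families = {
        "breath_rate": BR_COLS,
        "heart_rate": HR_COLS,
        "tonic_eda": EDA_COLS,
        "hrv": ["HRV_first", "HRV_last"],
    }
    frames = []
    for dv, cols in families.items():
        long = long_format(df, cols)
        results = []
        for model in cfg.anova_models:
            need_cols = {"time_by_tech": ["tech"], "time_by_stim": ["stim"],
                         "time_by_tech_by_stim": ["tech", "stim"]}.get(model, [])
            if any(df[c].nunique() < 2 for c in need_cols):
                continue
            try:
                res = rm_anova_gg(long.dropna(subset=["value"]), model=model)
            except ValueError as e:
                log.warning("rmANOVA %s on %s failed: %s", model, dv, e)
                continue
            for r in res:
                r.term = f"{model}:{r.term}"
            results.extend(res)
        if results:
            apply_fdr(results)
            tab = results_table(results)
            tab.insert(0, "dv", dv)
            frames.append(tab)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_pipeline(
    sessions: Iterable[SessionRecording | str | Path],
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    overwrite: bool = False,
) -> tuple[pd.DataFrame, list[dict], pd.DataFrame]:
    """Process sessions end to end; returns (features, qc, stats table)."""
    cfg = cfg or PipelineConfig()
    rows: list[ParticipantFeatures] = []
    qc_all: list[dict] = []
    n_failed = 0
    for item in sessions:
        try:
            rec = item if isinstance(item, SessionRecording) else load_session(item)
            rec = trim_to_experience(rec)
        except Exception as e:
            log.warning("skipping session %s: %s", item, e)
            n_failed += 1
            continue
        feats, qc = process_session(rec, cfg)
        qc_all.append(qc)
        if not feats.excluded:
            rows.append(feats)
    if not rows:
        raise RuntimeError("no usable sessions")
    df = feature_table(rows)
    stats_df = analyze_features(df, cfg) if df.shape[0] >= 4 else pd.DataFrame()
    if out_dir is not None:
        f_feat, f_qc = write_outputs(df, qc_all, out_dir, overwrite=overwrite)
        if not stats_df.empty:
            stats_df.to_csv(Path(out_dir) / "stats.tsv", sep="\t", index=False)
        manifest = {
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "n_sessions": len(qc_all),
            "n_failed": n_failed,
            "n_rows": int(df.shape[0]),
        }
        (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return df, qc_all, stats_df
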