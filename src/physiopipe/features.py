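"""Per-participant windowed feature table and derived covariates.

One row per participant: five 2-minute breath rates (BR_t1..BR_t5), ten
1-minute heart rates (HR_t1..HR_t10), five 2-minute tonic EDA means
(EDA_t1..EDA_t5), and two 5-minute LF/HF ratios (HRV_first, HRV_last),
plus initial/change covariates (first window, last minus first window)
and per-modality acceptability flags.  Rejected modalities leave their
columns missing (empty cells, never 0) with a recorded exclusion reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BR_COLS = [f"BR_t{i}" for i in range(1, 6)]
HR_COLS = [f"HR_t{i}" for i in range(1, 11)]
EDA_COLS = [f"EDA_t{i}" for i in range(1, 6)]
HRV_COLS = ["HRV_first", "HRV_last"]
DERIVED_COLS = ["BR_initial", "BR_change", "HR_initial", "HR_change",
                "HRV_initial", "HRV_change"]
FLAG_COLS = ["ecg_ok", "eda_ok", "resp_ok"]
FEATURE_COLS = BR_COLS + HR_COLS + EDA_COLS + HRV_COLS
ALL_COLS = (["participant", "tech", "stim"] + FEATURE_COLS + DERIVED_COLS + FLAG_COLS)


@dataclass
class ParticipantFeatures:
    row: dict
    exclusion_reason: str | None = None

    @property
    def excluded(self) -> bool:
        return self.exclusion_reason is not None


def _fill(row: dict, cols: list[str], values: np.ndarray | None) -> None:
    vals = np.full(len(cols), np.nan) if values is None else np.asarray(values, float)
    for i, c in enumerate(cols):
        row[c] = float(vals[i]) if i < vals.size and np.isfinite(vals[i]) else np.nan


def _change(row: dict, prefix: str, first_col: str, last_col: str) -> None:
    a, b = row.get(first_col, np.nan), row.get(last_col, np.nan)
    row[f"{prefix}_initial"] = a
    row[f"{prefix}_change"] = b - a if np.isfinite(a) and np.isfinite(b) else np.nan


def assemble_features(
    participant: str,
    breath_rates: np.ndarray | None = None,
    heart_rates: np.ndarray | None = None,
    tonic_eda: np.ndarray | None = None,
    hrv_first: float = np.nan,
    hrv_last: float = np.nan,
    resp_ok: bool = True,
    ecg_ok: bool = True,
    eda_ok: bool = True,
    tech: str = "",
    stim: str = "",
) -> ParticipantFeatures:
    """Build one feature row; rejected modalities produce missing columns.

    Change covariates are last-minus-first and inherit missingness from
    either endpoint.  If every modality is rejected the participant is
    excluded with a reason.
    """
    row: dict = {"participant": participant, "tech": tech, "stim": stim}
    _fill(row, BR_COLS, breath_rates if resp_ok else None)
    _fill(row, HR_COLS, heart_rates if ecg_ok else None)
    _fill(row, EDA_COLS, tonic_eda if eda_ok else None)
    row["HRV_first"] = float(hrv_first) if ecg_ok and np.isfinite(hrv_first) else np.nan
    row["HRV_last"] = float(hrv_last) if ecg_ok and np.isfinite(hrv_last) else np.nan
    _change(row, "BR", "BR_t1", "BR_t5")
    _change(row, "HR", "HR_t1", "HR_t10")
    row["HRV_initial"] = row["HRV_first"]
    row["HRV_change"] = (
        row["HRV_last"] - row["HRV_first"]
        if np.isfinite(row["HRV_first"]) and np.isfinite(row["HRV_last"])
        else np.nan
    )
    row["ecg_ok"] = bool(ecg_ok)
    row["eda_ok"] = bool(eda_ok)
    row["resp_ok"] = bool(resp_ok)
    reason = None
    if not (ecg_ok or eda_ok or resp_ok):
        reason = "all modalities rejected"
    return ParticipantFeatures(row=row, exclusion_reason=reason)


def feature_table(rows: list[ParticipantFeatures]) -> pd.DataFrame:
    """Stack participant rows into the fixed-column-order table."""
    data = [r.row for r in rows if not r.excluded]
    df = pd.DataFrame(data, columns=ALL_COLS)
    return df


def long_format(
    df: pd.DataFrame, cols: list[str], value_name: str = "value"
) -> pd.DataFrame:
    """Melt one windowed feature family into the long layout used by rmANOVA."""
    out = df.melt(
        id_vars=["participant", "tech", "stim"],
        value_vars=cols,
        var_name="timepoint",
        value_name=value_name,
    )
    out["timepoint"] = out["timepoint"].map({c: i + 1 for i, c in enumerate(cols)})
    return out
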