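"""CSV and config readers/writers.

Interchange dialects (all plain CSV with named header columns):

* Trace CSV: ``time_s,voltage_v,channel`` with channel in
  {reference, phosphorescence, dark}; multiple acquisitions are grouped by
  an optional ``acq_id`` column.
* Lifetime CSV: ``timestamp_s,delta_theta_rad,lifetime_s,temp_c``.
* Calibration CSV: ``timestamp_s,lifetime_s,temp_c,pO2_ref_mmHg``.
* Agreement CSV: ``mean,diff`` pairs preceded by ``#``-commented stats lines.

Models are serialized as JSON with exactly the SternVolmerModel field names.
Configs are JSON or YAML whose keys mirror AcquisitionSettings (and
optionally GroundTruth) field names.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .acquisition import CHANNELS, AcquisitionSettings, GroundTruth, ModulatedTrace
from .calibration import AgreementStats
from .phase import LifetimeSample

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_lifetimes_csv",
    "read_lifetimes_csv",
    "read_calibration_csv",
    "write_calibration_csv",
    "write_agreement_csv",
    "load_config",
    "settings_from_config",
    "truth_from_config",
]

TRACE_COLUMNS = ["time_s", "voltage_v", "channel"]
LIFETIME_COLUMNS = ["timestamp_s", "delta_theta_rad", "lifetime_s", "temp_c"]
CALIBRATION_COLUMNS = ["timestamp_s", "lifetime_s", "temp_c", "pO2_ref_mmHg"]

# repr-roundtrip float formatting so CSV round trips are bit-identical
_FLOAT_FMT = "%.17g"


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def write_traces_csv(path, traces, acq_ids: Optional[List[int]] = None) -> None:
    """Write one or more ModulatedTrace objects to a Trace CSV."""
    frames = []
    for i, trace in enumerate(traces):
        df = pd.DataFrame(
            {"time_s": trace.times_s, "voltage_v": trace.voltages_v, "channel": trace.channel}
        )
        if acq_ids is not None:
            df["acq_id"] = acq_ids[i]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_traces_csv(path, settings: Optional[AcquisitionSettings] = None) -> Dict:
    """Read a Trace CSV into ``{(acq_id, channel): ModulatedTrace}``.

    Without an ``acq_id`` column all rows belong to acquisition 0.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACE_COLUMNS, path)
    bad = set(df["channel"].unique()) - set(CHANNELS)
    if bad:
        raise ValueError(f"{path}: unknown channel value(s) {sorted(bad)}; expected {CHANNELS}")
    if "acq_id" not in df.columns:
        df = df.assign(acq_id=0)
    settings = settings or AcquisitionSettings()
    out = {}
    for (acq, chan), grp in df.groupby(["acq_id", "channel"], sort=True):
        out[(int(acq), str(chan))] = ModulatedTrace(
            str(chan), grp["time_s"].to_numpy(), grp["voltage_v"].to_numpy(), settings
        )
    return out


def write_lifetimes_csv(path, samples: List[LifetimeSample]) -> None:
    df = pd.DataFrame(
        {
            "timestamp_s": [s.timestamp_s for s in samples],
            "delta_theta_rad": [s.delta_theta_rad for s in samples],
            "lifetime_s": [s.lifetime_s for s in samples],
            "temp_c": [s.temp_c for s in samples],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_lifetimes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["lifetime_s"], path)
    return df


def read_calibration_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["lifetime_s", "pO2_ref_mmHg"], path)
    return df


def write_calibration_csv(path, df: pd.DataFrame) -> None:
    cols = [c for c in CALIBRATION_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_agreement_csv(path, measured, reference, stats: AgreementStats) -> None:
    """Bland-Altman output: commented stats block, then mean/diff pairs."""
    m = np.asarray(measured, float)
    r = np.asarray(reference, float)
    with open(path, "w") as fh:
        fh.write(f"# bias_mmHg,{stats.bias:.17g}\n")
        fh.write(f"# loa_low_mmHg,{stats.loa_low:.17g}\n")
        fh.write(f"# loa_high_mmHg,{stats.loa_high:.17g}\n")
        fh.write(f"# sd_diff_mmHg,{stats.sd_diff:.17g}\n")
        fh.write(f"# n,{stats.n}\n")
        fh.write("mean,diff\n")
        for mean, diff in zip((m + r) / 2.0, m - r):
            fh.write(f"{mean:.17g},{diff:.17g}\n")


def load_config(path) -> dict:
    """Load a JSON or YAML config; format chosen by suffix (YAML default)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


_SETTINGS_KEYS = (
    "modulation_hz",
    "n_background",
    "n_signal",
    "sample_rate_hz",
    "adc_bits",
    "adc_vref_v",
    "seed",
)
_TRUTH_KEYS = ("lifetime_s", "amplitude_v", "background_v", "noise_sd_v", "bleach_per_acq")


def settings_from_config(cfg: dict) -> AcquisitionSettings:
    """Build AcquisitionSettings from a config dict.

    Accepts the settings keys at the top level or under an ``acquisition``
    section; unknown keys in the section raise with the offending name.
    """
    section = cfg.get("acquisition", cfg)
    unknown = set(section) - set(_SETTINGS_KEYS) - {"truth"}
    if "acquisition" in cfg and unknown:
        raise ValueError(f"unknown acquisition config key(s): {sorted(unknown)}")
    kwargs = {k: section[k] for k in _SETTINGS_KEYS if k in section and section[k] is not None}
    return AcquisitionSettings(**kwargs)


def truth_from_config(cfg: dict) -> GroundTruth:
    section = cfg.get("truth", cfg)
    if "lifetime_s" not in section:
        raise ValueError("config missing required truth key 'lifetime_s'")
    kwargs = {k: section[k] for k in _TRUTH_KEYS if k in section}
    return GroundTruth(**kwargs)
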