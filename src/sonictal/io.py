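"""File interfaces: EDF signal files, CSV event/index tables, YAML
configs and JSON reports.

EDF (European Data Format) files are written with a minimal
single-channel 16-bit writer (physical units microvolts) and read back
through MNE, which also accepts user-supplied real recordings.
Filenames written by :func:`write_cohort_edf` follow
``<animal>_<period>_s<session>.edf`` so session metadata survives the
round trip.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .records import EEGRecord
from .synthetic import CohortConfig, DialysisConfig, InterventionEffect

_EDF_NAME_RE = re.compile(r"(?P<animal>[^_]+)_(?P<period>pre|post)_s(?P<session>\d+)\.edf$")


def write_edf(record: EEGRecord, path: str | Path) -> Path:
    """Write one record as a single-channel 16-bit EDF file.

    Data records are one second long, so the record length must be a
    whole number of seconds at an integer sampling rate.
    """
    path = Path(path)
    fs = record.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s data record
    n = record.n_samples
    if n % spr != 0:
        raise ValueError("record length must be a whole number of seconds")
    n_records = n // spr
    x = record.samples
    phys_max = float(np.max(np.abs(x))) or 1.0
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((x - phys_min) * scale + dig_min).astype("<i2")

    def pad(s: str, width: int) -> bytes:
        return s[:width].ljust(width).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad(record.animal_id, 80),
            pad(f"Startdate 01-JAN-2000 {record.group or 'X'}", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad("1", 4),
            # one signal header
            pad("EEG", 16),
            pad("synthetic" if record.group else "", 80),
            pad("uV", 8),
            pad(f"{phys_min:.6g}", 8),
            pad(f"{phys_max:.6g}", 8),
            pad(str(dig_min), 8),
            pad(str(dig_max), 8),
            pad("", 80),
            pad(str(spr), 8),
            pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())
    return path


def read_edf(path: str | Path, channel: int = 0) -> EEGRecord:
    """Read one channel of an EDF file into an :class:`EEGRecord` (uV).

    Session metadata is recovered from filenames of the form
    ``<animal>_<period>_s<session>.edf``; other names yield an
    ``unknown`` pre-period record.
    """
    import mne  # deferred: heavy import

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()[channel] * 1e6  # MNE returns volts
    m = _EDF_NAME_RE.search(path.name)
    animal, period, session = "unknown", "pre", 0
    if m:
        animal, period, session = m["animal"], m["period"], int(m["session"])
    return EEGRecord(
        animal_id=animal,
        period=period,
        session=session,
        sampling_rate=float(raw.info["sfreq"]),
        samples=data,
    )


def write_cohort_edf(
    records: Iterable[EEGRecord], out_dir: str | Path
) -> list[Path]:
    """Write every session record of a cohort under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in records:
        name = f"{rec.animal_id}_{rec.period}_s{rec.session}.edf"
        paths.append(write_edf(rec, out_dir / name))
    return paths


def write_events_csv(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    events.to_csv(path, index=False)
    return path


def read_events_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_report_json(report: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_sanitize(report), fh, indent=2, default=_json_default)
    return path


def _sanitize(obj):
    """Strict JSON: non-finite floats become null, numpy scalars native."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    return obj


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return v if math.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# YAML configuration


def cohort_config_from_yaml(path: str | Path) -> CohortConfig:
    """Load a :class:`CohortConfig`; nested ``effects`` maps group labels
    to ``{rate_multiplier, duration_multiplier, amplitude_multiplier}``."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "effects" in data:
        data["effects"] = {
            g: InterventionEffect(**spec) for g, spec in data["effects"].items()
        }
    if "groups" in data:
        data["groups"] = tuple(data["groups"])
    if "duration_lognorm" in data:
        data["duration_lognorm"] = tuple(data["duration_lognorm"])
    if "racine_weights" in data:
        data["racine_weights"] = tuple(data["racine_weights"])
    return CohortConfig(**data)


def dialysis_config_from_yaml(path: str | Path) -> DialysisConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return DialysisConfig(**data)
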