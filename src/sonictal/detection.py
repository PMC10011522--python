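"""Rule-based ictal-event detection and its evaluation harness.

The detector automates the screening rule used for chronic-mTLE EEG:
an ictal event is an interval of repetitive 2-20 Hz sharp waves whose
amplitude deviates from the inter-ictal background and which lasts at
least 3 s.  Operationally:

1. zero-phase band-pass the record to the ictal band;
2. compute a sliding-window RMS envelope;
3. threshold the envelope at ``median + k * MAD`` (robust to the small
   ictal fraction contaminating the baseline);
4. merge supra-threshold runs separated by short gaps, discard runs
   shorter than the minimum ictal duration, and read event boundaries
   off the outer threshold crossings.

Because the threshold is derived from the record itself, detections are
invariant to an overall gain change of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .indices import ictal_amplitude
from .records import EEGRecord, EVENT_COLUMNS


class DetectionError(RuntimeError):
    """Raised when a record is too short or degenerate to screen."""


@dataclass
class DetectorConfig:
    """Tunable parameters of the envelope-threshold detector."""

    band: tuple[float, float] = (2.0, 20.0)
    envelope_window: float = 0.5  # s
    envelope_step: float = 0.1  # s
    threshold_k: float = 5.0  # MAD multiples above the median envelope
    merge_gap: float = 1.0  # s
    min_duration: float = 3.0  # s
    display_lowpass: float = 30.0  # Hz; display aid only, not used in detection
    #: Compute the event amplitude statistic on the band-passed trace
    #: (default) or on the raw trace.
    amplitude_on_bandpassed: bool = True
    #: Two-pass threshold refinement (exclude first-pass candidates and
    #: re-estimate the baseline statistics); off by default since the
    #: ictal fraction is small.
    two_pass_threshold: bool = False

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError("band must satisfy 0 < low < high")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be positive")
        if self.envelope_window <= 0 or self.envelope_step <= 0:
            raise ValueError("envelope window and step must be positive")


def bandpass(record: EEGRecord, band: tuple[float, float] = (2.0, 20.0)) -> EEGRecord:
    """Zero-phase band-pass filtered copy of a record (DC removed)."""
    low, high = band
    nyq = record.sampling_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValueError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    sos = scipy.signal.butter(
        4, [low, high], btype="bandpass", fs=record.sampling_rate, output="sos"
    )
    x = record.samples - np.mean(record.samples)
    return record.copy_with(scipy.signal.sosfiltfilt(sos, x))


def envelope(
    record: EEGRecord, window: float = 0.5, step: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window RMS envelope of a record.

    Returns ``(times, values)`` where ``times`` are window centres on the
    record's clock and there are ``floor((T - window)/step) + 1`` values.
    """
    fs = record.sampling_rate
    w = int(round(window * fs))
    s = int(round(step * fs))
    if w <= 0 or s <= 0:
        raise ValueError("window and step must be positive")
    if w > record.n_samples:
        raise ValueError("window longer than the record")
    x = record.samples
    csum = np.concatenate(([0.0], np.cumsum(x * x)))
    starts = np.arange(0, x.size - w + 1, s)
    values = np.sqrt((csum[starts + w] - csum[starts]) / w)
    times = record.start_time + (starts + 0.5 * w) / fs
    return times, values


def detect_events(record: EEGRecord, config: DetectorConfig | None = None) -> pd.DataFrame:
    """Detect ictal events in one record.

    Returns a tidy event table (:data:`sonictal.records.EVENT_COLUMNS`,
    with ``racine`` unknown, encoded as -1) sorted by start time; events
    are non-overlapping and every reported duration is at least
    ``config.min_duration``.
    """
    config = config or DetectorConfig()
    if record.duration_s <= config.min_duration:
        raise DetectionError("record shorter than the minimum ictal duration")
    filtered = bandpass(record, config.band)
    times, env = envelope(filtered, config.envelope_window, config.envelope_step)
    if env.size < 3:
        raise DetectionError("envelope has fewer than 3 points")
    threshold = _threshold(env, config.threshold_k)
    if config.two_pass_threshold:
        keep = env <= threshold
        if keep.sum() >= 3:
            threshold = _threshold(env[keep], config.threshold_k)
    intervals = _supra_intervals(times, env, threshold)
    intervals = _merge_intervals(intervals, config.merge_gap)
    intervals = [iv for iv in intervals if iv[1] - iv[0] >= config.min_duration]
    amp_src = filtered if config.amplitude_on_bandpassed else record
    rows = []
    for start, end in intervals:
        i0 = int(round((start - record.start_time) * record.sampling_rate))
        i1 = int(round((end - record.start_time) * record.sampling_rate))
        seg = amp_src.samples[max(i0, 0) : min(i1 + 1, record.n_samples)]
        rows.append(
            {
                "animal_id": record.animal_id,
                "group": record.group,
                "period": record.period,
                "session": record.session,
                "start_s": start,
                "duration_s": end - start,
                "amplitude_uV": ictal_amplitude(seg, record.sampling_rate),
                "racine": -1,
            }
        )
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))


def _threshold(env: np.ndarray, k: float) -> float:
    med = float(np.median(env))
    mad = float(np.median(np.abs(env - med)))
    return med + k * mad


def _supra_intervals(
    times: np.ndarray, env: np.ndarray, threshold: float
) -> list[tuple[float, float]]:
    """Contiguous supra-threshold runs with interpolated outer crossings."""
    above = env > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = [0] if above[0] else []
    starts += list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]])
    if above[-1]:
        ends.append(env.size - 1)
    out = []
    for i0, i1 in zip(starts, ends):
        t0 = _cross_time(times, env, i0, threshold, rising=True)
        t1 = _cross_time(times, env, i1, threshold, rising=False)
        out.append((t0, t1))
    return out


def _cross_time(
    times: np.ndarray, env: np.ndarray, idx: int, threshold: float, rising: bool
) -> float:
    """Linear interpolation of the threshold crossing next to sample ``idx``."""
    j = idx - 1 if rising else idx + 1
    if j < 0 or j >= env.size:
        return float(times[idx])
    lo, hi = (j, idx) if rising else (idx, j)
    e0, e1 = env[lo], env[hi]
    if e0 == e1:
        return float(times[idx])
    frac = (threshold - e0) / (e1 - e0)
    frac = min(max(frac, 0.0), 1.0)
    return float(times[lo] + frac * (times[hi] - times[lo]))


def _merge_intervals(
    intervals: list[tuple[float, float]], merge_gap: float
) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for start, end in intervals:
        if merged and start - merged[-1][1] < merge_gap:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(a, b) for a, b in merged]


# ---------------------------------------------------------------------------
# evaluation against ground truth


def match_events(
    truth: pd.DataFrame,
    detected: pd.DataFrame,
    min_overlap: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Greedy one-to-one matching of detections to ground-truth events.

    Overlap fraction is ``intersection / min(truth, detected)`` duration;
    pairs with overlap below ``min_overlap`` stay unmatched.  Ties on
    overlap are broken by the smaller start-boundary error.  Returns the
    match table and a summary with sensitivity, false-discovery rate and
    boundary-error quantiles.
    """
    t = truth.reset_index(drop=True)
    d = detected.reset_index(drop=True)
    _check_no_overlap(t)
    pairs = []
    for ti in t.itertuples():
        t0, t1 = ti.start_s, ti.start_s + ti.duration_s
        for di in d.itertuples():
            d0, d1 = di.start_s, di.start_s + di.duration_s
            inter = min(t1, d1) - max(t0, d0)
            if inter <= 0:
                continue
            frac = inter / min(t1 - t0, d1 - d0)
            if frac >= min_overlap:
                pairs.append((frac, -abs(d0 - t0), ti.Index, di.Index))
    pairs.sort(reverse=True)
    used_t: set[int] = set()
    used_d: set[int] = set()
    rows = []
    for frac, neg_err, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        rows.append(
            {
                "truth_id": i,
                "detected_id": j,
                "overlap_fraction": frac,
                "boundary_error_start": d.start_s[j] - t.start_s[i],
                "boundary_error_end": (d.start_s[j] + d.duration_s[j])
                - (t.start_s[i] + t.duration_s[i]),
            }
        )
    for i in range(len(t)):
        if i not in used_t:
            rows.append(
                {
                    "truth_id": i,
                    "detected_id": None,
                    "overlap_fraction": 0.0,
                    "boundary_error_start": np.nan,
                    "boundary_error_end": np.nan,
                }
            )
    for j in range(len(d)):
        if j not in used_d:
            rows.append(
                {
                    "truth_id": None,
                    "detected_id": j,
                    "overlap_fraction": 0.0,
                    "boundary_error_start": np.nan,
                    "boundary_error_end": np.nan,
                }
            )
    matches = pd.DataFrame(
        rows,
        columns=[
            "truth_id",
            "detected_id",
            "overlap_fraction",
            "boundary_error_start",
            "boundary_error_end",
        ],
    )
    n_match = len(used_t)
    errs = np.abs(
        np.concatenate(
            [
                matches.boundary_error_start.dropna().to_numpy(float),
                matches.boundary_error_end.dropna().to_numpy(float),
            ]
        )
    )
    summary = {
        "n_truth": len(t),
        "n_detected": len(d),
        "n_matched": n_match,
        "sensitivity": n_match / len(t) if len(t) else np.nan,
        "fdr": (len(d) - n_match) / len(d) if len(d) else 0.0,
        "boundary_error_median_s": float(np.median(errs)) if errs.size else np.nan,
        "boundary_error_p95_s": float(np.quantile(errs, 0.95)) if errs.size else np.nan,
    }
    return matches, summary


def _check_no_overlap(events: pd.DataFrame) -> None:
    for (_, _, _), grp in events.groupby(
        ["animal_id", "period", "session"], dropna=False, sort=False
    ):
        g = grp.sort_values("start_s")
        ends = (g.start_s + g.duration_s).to_numpy()
        if np.any(g.start_s.to_numpy()[1:] < ends[:-1] - 1e-9):
            raise ValueError("truth events overlap within one record")
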