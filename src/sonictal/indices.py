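"""Per-animal seizure indices, pre/post normalization, Racine tallies.

Three indices summarize one animal's ictal activity over one observation
period: the count of ictal events, the mean ictal duration per event,
and the mean ictal amplitude per event, where the amplitude of an event
is the area under the rectified signal divided by the event duration.
Normalized indices are the per-animal post/pre ratios of these — each
animal is normalized individually, never via group means of raw indices,
because the group mean of per-animal ratios is a different (and here the
reported) estimator from the ratio of group means.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INDEX_NAMES = ("count", "duration", "amplitude")


def ictal_amplitude(segment: np.ndarray, sampling_rate: float) -> float:
    """Time-averaged rectified amplitude of an event segment, in uV.

    Computes ``(integral of |x(t)| dt) / T`` with the trapezoid rule over
    the segment, so a constant ``|x| = A`` returns ``A`` and a full-cycle
    sine of amplitude ``A`` returns ``2A/pi``.
    """
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise ValueError("empty segment")
    if x.size == 1:
        return float(abs(x[0]))
    dt = 1.0 / sampling_rate
    t_total = (x.size - 1) * dt
    return float(np.trapezoid(np.abs(x), dx=dt) / t_total)


def compute_indices(
    events: pd.DataFrame,
    hours_observed: float,
    animals: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Seizure indices per animal and period.

    Parameters
    ----------
    events
        Event table with at least ``animal_id, group, period, duration_s,
        amplitude_uV`` columns (one row per ictal event).
    hours_observed
        Observation time represented by each period, in hours.
    animals
        Optional roster frame with ``animal_id, group`` to force a row
        (with zero count and undefined means) for animal/periods that
        produced no events.

    Returns
    -------
    DataFrame with one row per animal x period: ``ictal_count``,
    ``ictal_duration_per_event`` (s), ``ictal_amplitude_per_event`` (uV),
    ``hours_observed``.  Mean fields are NaN when the count is zero.
    """
    if hours_observed <= 0:
        raise ValueError("hours_observed must be positive")
    rows = []
    grouped = events.groupby(["animal_id", "period"], sort=True)
    seen = set()
    for (animal, period), grp in grouped:
        seen.add((animal, period))
        rows.append(
            {
                "animal_id": animal,
                "group": grp["group"].iloc[0] if "group" in grp else "",
                "period": period,
                "ictal_count": len(grp),
                "ictal_duration_per_event": float(grp.duration_s.mean()),
                "ictal_amplitude_per_event": float(grp.amplitude_uV.mean()),
                "hours_observed": hours_observed,
            }
        )
    if animals is not None:
        for a in animals.itertuples():
            for period in ("pre", "post"):
                if (a.animal_id, period) not in seen:
                    rows.append(
                        {
                            "animal_id": a.animal_id,
                            "group": a.group,
                            "period": period,
                            "ictal_count": 0,
                            "ictal_duration_per_event": np.nan,
                            "ictal_amplitude_per_event": np.nan,
                            "hours_observed": hours_observed,
                        }
                    )
    out = pd.DataFrame(
        rows,
        columns=[
            "animal_id",
            "group",
            "period",
            "ictal_count",
            "ictal_duration_per_event",
            "ictal_amplitude_per_event",
            "hours_observed",
        ],
    )
    return out.sort_values(["animal_id", "period"]).reset_index(drop=True)


def normalize_indices(indices: pd.DataFrame) -> pd.DataFrame:
    """Per-animal post/pre normalized indices and percent changes.

    For each animal present with both periods, forms the ratio
    ``post/pre`` for each index and ``percent_change = 100 * (ratio - 1)``.
    An animal with a zero (or undefined) pre-period index is flagged and
    gets NaN for that index's ratio; callers drop such animals from that
    index's group statistics.
    """
    cols = {
        "count": "ictal_count",
        "duration": "ictal_duration_per_event",
        "amplitude": "ictal_amplitude_per_event",
    }
    rows = []
    for animal, grp in indices.groupby("animal_id", sort=True):
        by_period = {p.period: p for p in grp.itertuples()}
        if "pre" not in by_period or "post" not in by_period:
            logger.warning("animal %s lacks a period; skipped", animal)
            continue
        pre, post = by_period["pre"], by_period["post"]
        row = {"animal_id": animal, "group": getattr(pre, "group", "")}
        for name, col in cols.items():
            a = getattr(pre, col)
            b = getattr(post, col)
            if not np.isfinite(a) or a == 0:
                logger.warning(
                    "animal %s has undefined pre-period %s; ratio flagged", animal, name
                )
                ratio = np.nan
            elif not np.isfinite(b):
                ratio = np.nan
            else:
                ratio = b / a
            row[f"{name}_ratio"] = ratio
            row[f"{name}_percent_change"] = 100.0 * (ratio - 1.0)
        rows.append(row)
    return pd.DataFrame(rows)


def racine_tally(events: pd.DataFrame) -> pd.DataFrame:
    """Count partial (Racine 1-2) and tonic-clonic (3-5) events.

    Events without a valid label (outside 1-5) are tallied separately as
    ``unknown_count`` with a warning.  One row per animal x period.
    """
    rows = []
    for (animal, period), grp in events.groupby(["animal_id", "period"], sort=True):
        labels = pd.to_numeric(grp["racine"], errors="coerce")
        partial = int(labels.isin([1, 2]).sum())
        tc = int(labels.isin([3, 4, 5]).sum())
        unknown = len(grp) - partial - tc
        if unknown:
            logger.warning(
                "%d unlabelled events for %s/%s counted as unknown",
                unknown,
                animal,
                period,
            )
        rows.append(
            {
                "animal_id": animal,
                "group": grp["group"].iloc[0] if "group" in grp else "",
                "period": period,
                "partial_count": partial,
                "tonic_clonic_count": tc,
                "unknown_count": unknown,
            }
        )
    return pd.DataFrame(rows)
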