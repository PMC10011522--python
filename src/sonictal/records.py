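"""Core record containers shared across the pipeline.

An :class:`EEGRecord` holds one channel of sampled EEG for one recording
session of one animal, in physical units of microvolts.  Detected and
planted seizure events travel through the pipeline as tidy
:class:`pandas.DataFrame` tables whose column contracts are documented in
:data:`EVENT_COLUMNS` and :data:`TRUTH_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Columns of a detected-event table.
EVENT_COLUMNS = (
    "animal_id",
    "group",
    "period",
    "session",
    "start_s",
    "duration_s",
    "amplitude_uV",
    "racine",
)

#: Columns of a ground-truth event table emitted by the generator.
TRUTH_COLUMNS = EVENT_COLUMNS + (
    "rep_freq_hz",
    "peak_amplitude_uV",
    "is_subthreshold",
)

PERIODS = ("pre", "post")


@dataclass
class EEGRecord:
    """One channel of sampled EEG with its timebase and provenance labels.

    Parameters
    ----------
    animal_id
        Label of the animal the session belongs to.
    period
        ``"pre"`` or ``"post"`` intervention.
    session
        Zero-based session index within the period.
    sampling_rate
        Sampling rate in Hz.  Must exceed 40 Hz so the 2-20 Hz ictal band
        is resolved with margin.
    samples
        Signal samples in microvolts.
    start_time
        Time of the first sample in seconds (session-local clock).
    group
        Experimental group label, if known.
    """

    animal_id: str
    period: str
    session: int
    sampling_rate: float
    samples: np.ndarray
    start_time: float = 0.0
    group: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 40.0:
            raise ValueError(
                f"sampling_rate must exceed 40 Hz, got {self.sampling_rate}"
            )
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds on the session-local clock."""
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, samples: np.ndarray) -> "EEGRecord":
        return EEGRecord(
            animal_id=self.animal_id,
            period=self.period,
            session=self.session,
            sampling_rate=self.sampling_rate,
            samples=samples,
            start_time=self.start_time,
            group=self.group,
        )
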