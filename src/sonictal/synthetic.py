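"""Seeded synthetic inputs: chronic-mTLE EEG cohorts and dialysis tables.

The generator emulates the statistical structure the downstream analysis
assumes rather than the biophysics of epileptogenesis:

* **Background EEG** is pink (1/f-power) noise with a single RMS scale —
  the standard single-parameter approximation of inter-ictal EEG.
* **Ictal events** are trains of biphasic sharp transients repeating at
  2-20 Hz, the electrographic signature screened for in chronic
  mesial-temporal-lobe-epilepsy rodents, with a raised-cosine onset and
  offset ramp.  Electrographic seizures are defined as lasting at least
  3 s; shorter spindle/artifact bursts are planted separately and carry
  an ``is_subthreshold`` flag.
* **Per-animal seizure counts** are strongly overdispersed (SD of the
  same order as the mean).  Each animal carries a latent per-period rate
  drawn from a floored gamma distribution; the floor encodes the
  screening inclusion criterion (only animals with established
  spontaneous recurrent seizures enter the cohort), and pre- and
  post-intervention counts are Poisson draws that share the latent rate,
  which is what makes per-animal post/pre normalization meaningful.
* **Interventions** act multiplicatively on rate, event duration and
  event amplitude, with a small lognormal animal-to-animal spread.

A cohort period always represents the study's 24 h observation protocol:
the expected number of planted events per period is governed by
``event_rate_mean`` alone, while ``sessions_per_period`` and
``session_hours`` control how much synthetic signal carries those events.
Scaling sessions down therefore shortens the inter-ictal background
without thinning the seizure sample the indices are computed from.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Tuple

import numpy as np
import pandas as pd

from .records import EEGRecord, PERIODS, TRUTH_COLUMNS

logger = logging.getLogger(__name__)

#: Hours of observation one generated period stands for.
PERIOD_HOURS = 24.0

#: Minimum duration (s) for an event to count as ictal.
MIN_ICTAL_DURATION_S = 3.0

DEFAULT_GROUPS = ("PHT+FUS", "PHT_ONLY", "FUS_ONLY")

#: Baseline expected ictal events per 24 h period, per group.
DEFAULT_EVENT_RATES: Dict[str, float] = {
    "PHT+FUS": 145.0,
    "PHT_ONLY": 89.0,
    "FUS_ONLY": 133.0,
}


class GenerationError(RuntimeError):
    """Raised when drawn events cannot be packed into the sessions."""


@dataclass(frozen=True)
class InterventionEffect:
    """Multiplicative post/pre effect of an intervention.

    The identity effect is ``(1, 1, 1)``.  Multipliers act on the
    per-animal latent event rate, on the event-duration scale and on the
    event-amplitude scale respectively.
    """

    rate_multiplier: float = 1.0
    duration_multiplier: float = 1.0
    amplitude_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rate_multiplier", "duration_multiplier", "amplitude_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: Default intervention effects, calibrated so that the full pipeline on
#: the default cohort recovers the per-animal mean normalized changes of
#: the study conditions: ictal count -57% / -27% / +13% and ictal
#: duration/event -15% / +22% / +20% for the three groups.  The rate
#: multipliers differ slightly from the raw count ratios because the
#: group mean of per-animal post/pre ratios is a different estimator from
#: the ratio of group means.
DEFAULT_EFFECTS: Dict[str, InterventionEffect] = {
    "PHT+FUS": InterventionEffect(0.425, 0.85, 1.0),
    "PHT_ONLY": InterventionEffect(0.717, 1.22, 1.0),
    "FUS_ONLY": InterventionEffect(1.115, 1.20, 1.0),
}

#: Categorical weights of modified-Racine classes 1-5 for planted events.
#: Heavily weighted to partial seizures (classes 1-2); tonic-clonic
#: events (3-5) are rare in this model.
DEFAULT_RACINE_WEIGHTS = (0.60, 0.35, 0.03, 0.015, 0.005)


@dataclass
class CohortConfig:
    """Configuration of a synthetic three-group EEG cohort."""

    groups: Tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: int = 10
    sessions_per_period: int = 8
    session_hours: float = 3.0
    sampling_rate: float = 500.0
    background_rms: float = 50.0
    event_rate_mean: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_RATES)
    )
    #: Gamma shape of the latent-rate distribution (negative-binomial size).
    event_rate_dispersion: float = 0.3
    #: Screening floor: minimum latent rate as a fraction of the group mean.
    rate_floor: float = 0.4
    #: (mu, sigma) of log event duration in seconds; mean exp(mu+sigma^2/2).
    duration_lognorm: Tuple[float, float] = (1.76051, 0.25)
    #: Ratio of ictal peak amplitude scale to background RMS.
    event_snr: float = 5.0
    #: Lognormal sigma of per-event peak amplitudes.
    amplitude_sigma: float = 0.2
    #: Sub-threshold (< 3 s) artifact bursts per hour of signal.
    artifact_rate: float = 2.0
    #: Lognormal sigma of the per-animal intervention-effect multiplier.
    effect_sd: float = 0.05
    racine_weights: Tuple[float, ...] = DEFAULT_RACINE_WEIGHTS
    effects: Mapping[str, InterventionEffect] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.sampling_rate < 100.0:
            raise ValueError(
                "sampling_rate must be >= 100 Hz (Nyquist margin over 2-20 Hz)"
            )
        if self.event_snr <= 0:
            raise ValueError("event_snr must be positive")
        if self.sessions_per_period < 1 or self.session_hours <= 0:
            raise ValueError("session layout must be positive")
        if self.artifact_rate < 0 or self.event_rate_dispersion <= 0:
            raise ValueError("rates must be >= 0 and dispersion > 0")
        if not 0 <= self.rate_floor < 1:
            raise ValueError("rate_floor must lie in [0, 1)")
        for g in self.groups:
            if self.rate(g) < 0:
                raise ValueError(f"event rate for group {g!r} must be >= 0")

    def rate(self, group: str) -> float:
        if isinstance(self.event_rate_mean, Mapping):
            return float(self.event_rate_mean[group])
        return float(self.event_rate_mean)

    def effect(self, group: str) -> InterventionEffect:
        return self.effects.get(group, InterventionEffect())

    @property
    def session_seconds(self) -> float:
        return self.session_hours * 3600.0


def _rng(seed, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + key))


def generate_background(
    duration: float,
    sampling_rate: float,
    rms: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EEGRecord:
    """Generate a pink-noise (1/f power) background EEG trace.

    The spectrum follows 1/f power above a 0.5 Hz knee (flat below, to
    keep the variance finite) and the realized trace is rescaled to the
    requested RMS exactly.

    Parameters
    ----------
    duration
        Trace length in seconds.
    sampling_rate
        Sampling rate in Hz.
    rms
        Target root-mean-square amplitude in microvolts.
    seed, rng
        Either a seed or an existing generator; a fixed seed gives a
        bit-identical trace.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be positive")
    if rms < 0:
        raise ValueError("rms must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    samples = _pink_noise(n, sampling_rate, rms, rng)
    return EEGRecord(
        animal_id="synthetic",
        period="pre",
        session=0,
        sampling_rate=sampling_rate,
        samples=samples,
    )


def _pink_noise(
    n: int, sampling_rate: float, rms: float, rng: np.random.Generator
) -> np.ndarray:
    if rms == 0.0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    knee = 0.5  # Hz; flat below to avoid the 1/f divergence at DC
    amp = 1.0 / np.sqrt(np.maximum(freqs, knee))
    amp[0] = 0.0  # no DC
    spec = (rng.standard_normal(amp.size) + 1j * rng.standard_normal(amp.size)) * amp
    x = np.fft.irfft(spec, n)
    x *= rms / np.sqrt(np.mean(x * x))
    return x


def synth_ictal_waveform(
    duration: float,
    rep_freq: float,
    peak_amplitude: float,
    sampling_rate: float,
) -> np.ndarray:
    """Train of biphasic sharp transients repeating at ``rep_freq``.

    Each period of the train carries a sharp positive deflection followed
    by a slower negative afterwave (a difference of two Gaussians whose
    widths scale with the repetition period), so the dominant spectral
    peak sits at the repetition frequency.  A raised-cosine ramp of at
    most 0.5 s shapes onset and offset, and the waveform is normalized so
    ``max(|x|)`` equals ``peak_amplitude``.
    """
    if not 2.0 <= rep_freq <= 20.0:
        raise ValueError("rep_freq must lie in [2, 20] Hz for the ictal class")
    if duration <= 0 or sampling_rate <= 0:
        raise ValueError("duration and sampling_rate must be positive")
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    period = 1.0 / rep_freq
    # phase within the period, centred so transients sit mid-period
    tau = np.mod(t, period) - 0.5 * period
    sigma_sharp = period / 8.0
    sigma_slow = 1.6 * sigma_sharp
    lag = 1.2 * sigma_sharp
    x = np.exp(-0.5 * (tau / sigma_sharp) ** 2) - 0.55 * np.exp(
        -0.5 * ((tau - lag) / sigma_slow) ** 2
    )
    x *= _cosine_ramp(n, sampling_rate, min(0.5, duration / 4.0))
    peak = np.max(np.abs(x))
    if peak > 0 and peak_amplitude > 0:
        x *= peak_amplitude / peak
    else:
        x = np.zeros(n)
    return x


def _cosine_ramp(n: int, sampling_rate: float, ramp_s: float) -> np.ndarray:
    env = np.ones(n)
    m = int(round(ramp_s * sampling_rate))
    if m > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(m) / m))
        env[:m] = ramp
        env[-m:] = ramp[::-1]
    return env


# ---------------------------------------------------------------------------
# cohort generation


def plan_cohort_truth(config: CohortConfig) -> pd.DataFrame:
    """Draw the ground-truth event table for a cohort without rendering EEG.

    Returns a tidy frame with one row per planted event (ictal and
    sub-threshold artifact), :data:`sonictal.records.TRUTH_COLUMNS`.
    Deterministic under ``config.seed``.
    """
    rows: list[dict] = []
    for g_idx, group in enumerate(config.groups):
        for a_idx in range(config.n_per_group):
            animal = _animal_label(group, a_idx)
            rng = _rng(config.seed, 1, g_idx, a_idx)
            rows.extend(_plan_animal(config, group, animal, rng))
    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return truth.sort_values(
        ["group", "animal_id", "period", "session", "start_s"]
    ).reset_index(drop=True)


def _animal_label(group: str, a_idx: int) -> str:
    prefix = {"PHT+FUS": "PF", "PHT_ONLY": "P", "FUS_ONLY": "F"}.get(group, group[:2])
    return f"{prefix}{a_idx + 1}"


def _plan_animal(
    config: CohortConfig, group: str, animal: str, rng: np.random.Generator
) -> list[dict]:
    mu = config.rate(group)
    k = config.event_rate_dispersion
    floor = config.rate_floor
    # latent per-period rate; floored gamma encodes the screening criterion
    lam_pre = mu * (floor + rng.gamma(k, (1.0 - floor) / k))
    effect = config.effect(group)
    eps = rng.lognormal(-0.5 * config.effect_sd**2, config.effect_sd)
    rows: list[dict] = []
    for period in PERIODS:
        if period == "pre":
            lam, dur_mult, amp_mult = lam_pre, 1.0, 1.0
        else:
            lam = lam_pre * effect.rate_multiplier * eps
            dur_mult = effect.duration_multiplier
            amp_mult = effect.amplitude_multiplier
        n_events = int(rng.poisson(lam))
        durations = _draw_ictal_durations(config, n_events, dur_mult, rng)
        rep_freqs = rng.uniform(2.0, 20.0, n_events)
        amps = (
            config.event_snr
            * config.background_rms
            * amp_mult
            * rng.lognormal(
                -0.5 * config.amplitude_sigma**2, config.amplitude_sigma, n_events
            )
        )
        racine = rng.choice(
            np.arange(1, len(config.racine_weights) + 1),
            size=n_events,
            p=np.asarray(config.racine_weights) / np.sum(config.racine_weights),
        )
        # sub-threshold artifact bursts, per session signal hour
        n_art = int(
            rng.poisson(
                config.artifact_rate * config.session_hours * config.sessions_per_period
            )
        )
        art_dur = rng.uniform(0.5, 2.5, n_art)
        art_freq = rng.uniform(2.0, 20.0, n_art)
        art_amp = (
            config.event_snr
            * config.background_rms
            * rng.lognormal(
                -0.5 * config.amplitude_sigma**2, config.amplitude_sigma, n_art
            )
        )
        all_dur = np.concatenate([durations, art_dur])
        placement = _pack_events(config, all_dur, rng)
        for i, (sess, start) in enumerate(placement):
            sub = i >= n_events
            rows.append(
                {
                    "animal_id": animal,
                    "group": group,
                    "period": period,
                    "session": sess,
                    "start_s": start,
                    "duration_s": all_dur[i],
                    "amplitude_uV": np.nan,
                    "racine": 0 if sub else int(racine[i]),
                    "rep_freq_hz": art_freq[i - n_events] if sub else rep_freqs[i],
                    "peak_amplitude_uV": art_amp[i - n_events] if sub else amps[i],
                    "is_subthreshold": sub,
                }
            )
    return rows


def _draw_ictal_durations(
    config: CohortConfig, n: int, dur_mult: float, rng: np.random.Generator
) -> np.ndarray:
    """Lognormal durations, left-truncated at the 3 s ictal definition."""
    mu, sigma = config.duration_lognorm
    mu = mu + math.log(dur_mult)
    out = rng.lognormal(mu, sigma, n)
    for _ in range(100):
        bad = out < MIN_ICTAL_DURATION_S
        if not bad.any():
            break
        out[bad] = rng.lognormal(mu, sigma, int(bad.sum()))
    else:
        raise GenerationError("could not draw ictal durations >= 3 s")
    return out


def _pack_events(
    config: CohortConfig, durations: np.ndarray, rng: np.random.Generator
) -> list[tuple[int, float]]:
    """Assign events to sessions and draw non-overlapping start times.

    Events are spread over sessions at random subject to capacity, then
    placed with uniform spacings (Dirichlet gaps) separated by at least
    ``min_gap`` so that distinct events are never merged by the detector.
    Returns ``(session, start)`` pairs in the order of ``durations``.
    """
    n_sess = config.sessions_per_period
    length = config.session_seconds
    min_gap = 3.0
    order = np.argsort(durations)[::-1]  # pack long events first
    for attempt in range(20):
        assign: list[list[int]] = [[] for _ in range(n_sess)]
        load = np.zeros(n_sess)
        ok = True
        for i in order:
            d = durations[i]
            if d >= length:
                raise GenerationError(
                    f"event of {d:.1f} s cannot fit a {length:.0f} s session"
                )
            # random session among those with room, else least-loaded
            cand = [
                s
                for s in rng.permutation(n_sess)
                if load[s] + d + min_gap * (len(assign[s]) + 2) <= length
            ]
            if cand:
                s = cand[0]
            else:
                s = int(np.argmin(load))
                if load[s] + d >= length:
                    ok = False
                    logger.warning(
                        "packing attempt %d failed; resampling assignment", attempt
                    )
                    break
            assign[s].append(i)
            load[s] += d
        if ok:
            break
    else:
        raise GenerationError("could not pack drawn events into sessions")
    placement: dict[int, tuple[int, float]] = {}
    for s in range(n_sess):
        idx = assign[s]
        if not idx:
            continue
        durs = durations[idx]
        k = len(idx)
        slack = length - durs.sum() - min_gap * (k + 1)
        gap_floor = min_gap if slack >= 0 else 0.0
        if slack < 0:
            slack = length - durs.sum()
            if slack < 0:
                raise GenerationError("session overfull after assignment")
        gaps = gap_floor + slack * rng.dirichlet(np.ones(k + 1))
        perm = rng.permutation(k)  # random temporal order within the session
        t = 0.0
        for j, gap in zip(perm, gaps[:-1]):
            t += gap
            placement[idx[j]] = (s, t)
            t += durs[j]
    return [placement[i] for i in range(len(durations))]


def render_session(
    config: CohortConfig,
    truth: pd.DataFrame,
    group: str,
    animal_id: str,
    period: str,
    session: int,
) -> EEGRecord:
    """Render one session's EEG from the planted event table."""
    g_idx = config.groups.index(group)
    a_idx = int(animal_id[len(_animal_label(group, 0)) - 1 :]) - 1
    p_idx = PERIODS.index(period)
    rng = _rng(config.seed, 2, g_idx, a_idx, p_idx, session)
    fs = config.sampling_rate
    n = int(round(config.session_seconds * fs))
    x = _pink_noise(n, fs, config.background_rms, rng)
    sel = truth[
        (truth.animal_id == animal_id)
        & (truth.period == period)
        & (truth.session == session)
    ]
    for row in sel.itertuples():
        w = synth_ictal_waveform(
            row.duration_s, row.rep_freq_hz, row.peak_amplitude_uV, fs
        )
        i0 = int(round(row.start_s * fs))
        i1 = min(i0 + w.size, n)
        x[i0:i1] += w[: i1 - i0]
    return EEGRecord(
        animal_id=animal_id,
        period=period,
        session=session,
        sampling_rate=fs,
        samples=x,
        group=group,
    )


def iter_cohort_records(
    config: CohortConfig, truth: pd.DataFrame
) -> Iterator[EEGRecord]:
    """Yield every session record of the cohort, one at a time.

    Rendering is lazy so that a full cohort never needs to be held in
    memory; records are bit-identical for a fixed ``config.seed``
    regardless of consumption order.
    """
    for group in config.groups:
        for a_idx in range(config.n_per_group):
            animal = _animal_label(group, a_idx)
            for period in PERIODS:
                for session in range(config.sessions_per_period):
                    yield render_session(config, truth, group, animal, period, session)


def generate_cohort(
    config: CohortConfig, lazy: bool = False
) -> tuple[Iterable[EEGRecord], pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns ``(records, truth)`` where ``truth`` is the ground-truth
    event table and ``records`` is a list of :class:`EEGRecord` (or a
    lazy iterator when ``lazy=True``, recommended for full-size cohorts).
    """
    truth = plan_cohort_truth(config)
    records = iter_cohort_records(config, truth)
    if not lazy:
        records = list(records)
    return records, truth


# ---------------------------------------------------------------------------
# equilibrium-dialysis tables

#: Default unbound-phenytoin condition means (ug/mL): unsonicated control,
#: cassette outside the beam path, and the cassette at the ultrasound focus
#: under each of the six pulsing parameter sets (sets 1-3: 25% duty cycle,
#: sets 4-6: 50% duty cycle; set 4 = 50 ms pulses at 10 Hz).
DEFAULT_DIALYSIS_MEANS: Dict[str, float] = {
    "Ctrl": 0.55,
    "FO": 0.59,
    "FF_set1": 0.60,
    "FF_set2": 0.60,
    "FF_set3": 0.62,
    "FF_set4": 0.65,
    "FF_set5": 0.64,
    "FF_set6": 0.64,
}

DEFAULT_DIALYSIS_SDS: Dict[str, float] = {
    "Ctrl": 0.07,
    "FO": 0.09,
    "FF_set1": 0.10,
    "FF_set2": 0.10,
    "FF_set3": 0.10,
    "FF_set4": 0.10,
    "FF_set5": 0.10,
    "FF_set6": 0.10,
}


@dataclass
class DialysisConfig:
    """Configuration of the paired equilibrium-dialysis emulator."""

    condition_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIALYSIS_MEANS)
    )
    condition_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DIALYSIS_SDS)
    )
    n_paired_runs: int = 8
    run_effect_sd: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_paired_runs < 2:
            raise ValueError("n_paired_runs must be >= 2")
        if any(m <= 0 for m in self.condition_means.values()):
            raise ValueError("condition means must be positive")
        if any(s < 0 for s in self.condition_sds.values()) or self.run_effect_sd < 0:
            raise ValueError("standard deviations must be >= 0")


def generate_dialysis_samples(config: DialysisConfig) -> pd.DataFrame:
    """Paired unbound-drug concentration samples, one row per cassette.

    Each paired run ``r`` draws a shared run effect ``b_r ~ N(0,
    run_effect_sd)``; the sample for condition ``c`` is ``mean_c + b_r +
    N(0, sd_c)``, truncated at zero (with a warning) since concentrations
    cannot be negative.  Columns: ``run``, ``condition``,
    ``concentration_ug_ml``.
    """
    rng = np.random.default_rng(config.seed)
    conditions = list(config.condition_means)
    rows = []
    for run in range(config.n_paired_runs):
        b = rng.normal(0.0, config.run_effect_sd)
        for cond in conditions:
            v = config.condition_means[cond] + b + rng.normal(
                0.0, config.condition_sds[cond]
            )
            if v < 0:
                logger.warning(
                    "negative drawn concentration for %s in run %d truncated at 0",
                    cond,
                    run,
                )
                v = 0.0
            rows.append(
                {"run": run, "condition": cond, "concentration_ug_ml": v}
            )
    return pd.DataFrame(rows)
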