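"""Group statistics: paired t, one-way and repeated-measures ANOVA,
Tukey-Kramer / LSD / Bonferroni post-hocs, and the cohort and dialysis
report assemblies.

Standard tests are delegated to scipy/statsmodels behind small result
dataclasses; the repeated-measures ANOVA is computed from its
sums of squares directly (no sphericity correction by default, with a
Greenhouse-Geisser option).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

logger = logging.getLogger(__name__)


class DegenerateDataError(ValueError):
    """Raised for inputs on which a test statistic is undefined."""


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    tail: str  # "two-sided", "less" or "greater"
    mean_difference: float


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    design: str  # "between" or "within"


@dataclass
class PosthocResult:
    pair: tuple[str, str]
    estimate: float
    p_adjusted: float
    method: str


def paired_t(
    x: Sequence[float], y: Sequence[float], tail: str = "two-sided"
) -> PairedTestResult:
    """Paired t-test on ``x - y``.

    ``tail`` follows scipy's ``alternative`` convention: ``"greater"``
    tests ``mean(x - y) > 0``.  Identical pairs (all differences zero)
    give ``t = 0`` and two-sided ``p = 1``; constant nonzero differences
    leave the statistic undefined and raise :class:`DegenerateDataError`.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equal length")
    n = x.size
    if n < 2:
        raise DegenerateDataError("need at least 2 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            p = {"two-sided": 1.0, "greater": 0.5, "less": 0.5}[tail]
            return PairedTestResult(0.0, n - 1, p, tail, 0.0)
        raise DegenerateDataError("zero-variance nonzero differences")
    res = scipy.stats.ttest_rel(x, y, alternative=tail)
    return PairedTestResult(
        float(res.statistic), n - 1, float(res.pvalue), tail, float(d.mean())
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way between-subjects ANOVA."""
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    res = scipy.stats.f_oneway(*arrays)
    return AnovaResult(
        float(res.statistic), k - 1, n_total - k, float(res.pvalue), "between"
    )


def rm_anova(table: np.ndarray, correction: str | None = None) -> AnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    Uses the within-subject decomposition with ``df = (k - 1,
    (k - 1)(n - 1))``.  ``correction="gg"`` applies the
    Greenhouse-Geisser epsilon to both degrees of freedom and the
    p-value; the default applies no sphericity correction.  Missing
    cells are rejected (no imputation).
    """
    y = np.asarray(table, float)
    if y.ndim != 2:
        raise ValueError("table must be 2-D (subjects x conditions)")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    if not np.all(np.isfinite(y)):
        raise ValueError("missing or non-finite cells are not supported")
    grand = y.mean()
    subj_means = y.mean(axis=1)
    cond_means = y.mean(axis=0)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_cond - ss_subj
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    tiny = 1e-12 * max(ss_total, 1.0)
    if ms_err <= tiny:
        f = 0.0 if ss_cond <= tiny else np.inf
        p = 1.0 if ss_cond <= tiny else 0.0
        return AnovaResult(f, df1, df2, p, "within")
    f = ms_cond / ms_err
    if correction == "gg":
        eps = _greenhouse_geisser_epsilon(y)
        p = float(scipy.stats.f.sf(f, df1 * eps, df2 * eps))
    elif correction is None:
        p = float(scipy.stats.f.sf(f, df1, df2))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return AnovaResult(float(f), df1, df2, p, "within")


def _greenhouse_geisser_epsilon(y: np.ndarray) -> float:
    k = y.shape[1]
    s = np.cov(y, rowvar=False)
    mean_diag = np.trace(s) / k
    num = (k * (mean_diag - s.mean())) ** 2
    den = (k - 1) * (np.sum(s * s) - 2 * k * np.sum(s.mean(axis=0) ** 2) + k * k * s.mean() ** 2)
    eps = num / den if den > 0 else 1.0
    return float(min(max(eps, 1.0 / (k - 1)), 1.0))


def tukey_kramer(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> list[PosthocResult]:
    """All pairwise comparisons via the studentized-range distribution.

    With unequal group sizes this is the Tukey-Kramer harmonic-mean
    correction; with equal sizes it reduces exactly to Tukey's HSD.
    """
    arrays = [np.asarray(g, float) for g in groups]
    labels = list(labels) if labels is not None else [str(i) for i in range(len(arrays))]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df_w = n_total - k
    mse = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / df_w
    out = []
    for i, j in combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        diff = a.mean() - b.mean()
        se = np.sqrt(mse / 2.0 * (1.0 / a.size + 1.0 / b.size))
        q = abs(diff) / se if se > 0 else np.inf
        p = float(scipy.stats.studentized_range.sf(q, k, df_w))
        out.append(
            PosthocResult((labels[i], labels[j]), float(diff), min(p, 1.0), "tukey_kramer")
        )
    return out


def lsd(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> list[PosthocResult]:
    """Fisher's least-significant-difference pairwise t-tests.

    Pairwise t with the pooled within-group variance and its degrees of
    freedom; no multiplicity adjustment (combine with
    :func:`bonferroni` if one is wanted).
    """
    arrays = [np.asarray(g, float) for g in groups]
    labels = list(labels) if labels is not None else [str(i) for i in range(len(arrays))]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least 2 observations")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df_w = n_total - k
    mse = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / df_w
    out = []
    for i, j in combinations(range(k), 2):
        a, b = arrays[i], arrays[j]
        diff = a.mean() - b.mean()
        se = np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
        t = diff / se if se > 0 else np.inf
        p = float(2.0 * scipy.stats.t.sf(abs(t), df_w))
        out.append(PosthocResult((labels[i], labels[j]), float(diff), min(p, 1.0), "lsd"))
    return out


def bonferroni(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values: ``min(1, p * m)``."""
    p = np.asarray(pvalues, float)
    m = int(m) if m is not None else p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(p * m, 1.0)


# ---------------------------------------------------------------------------
# report assemblies


def analyze_cohort(
    normalized: pd.DataFrame, raw_indices: pd.DataFrame | None = None
) -> dict:
    """Statistical report over a table of per-animal normalized indices.

    Per group and index: mean and SD of the percent changes.  Between
    groups: one-way ANOVA on the normalized ratios followed by
    Tukey-Kramer pairwise comparisons (a Bonferroni-adjusted variant of
    the same pairwise p-values is reported alongside).  If raw indices
    are supplied, within-group paired t-tests compare post against pre,
    one-tailed in the ``post < pre`` direction for count and duration
    (the pre-specified hypothesis) and two-tailed for amplitude.
    Animals with an undefined ratio are dropped listwise per index, with
    counts logged.
    """
    report: dict = {"groups": {}, "between_groups": {}, "within_groups": {}}
    groups = sorted(normalized.group.unique())
    for g in groups:
        sub = normalized[normalized.group == g]
        entry = {}
        for name in ("count", "duration", "amplitude"):
            pc = sub[f"{name}_percent_change"].dropna()
            dropped = len(sub) - len(pc)
            if dropped:
                logger.warning(
                    "group %s: %d animal(s) dropped from %s (undefined ratio)",
                    g,
                    dropped,
                    name,
                )
            entry[name] = {
                "n": int(len(pc)),
                "mean_percent_change": float(pc.mean()) if len(pc) else np.nan,
                "sd_percent_change": float(pc.std(ddof=1)) if len(pc) > 1 else np.nan,
            }
        report["groups"][g] = entry
    for name in ("count", "duration", "amplitude"):
        vectors, labels = [], []
        for g in groups:
            v = normalized.loc[normalized.group == g, f"{name}_ratio"].dropna().to_numpy()
            if v.size >= 2:
                vectors.append(v)
                labels.append(g)
        if len(vectors) < 2:
            warnings.warn(
                f"fewer than 2 usable groups for {name}; between-group tests skipped"
            )
            report["between_groups"][name] = None
            continue
        anova = one_way_anova(vectors)
        posthoc = tukey_kramer(vectors, labels)
        bonf = bonferroni([p.p_adjusted for p in posthoc])
        report["between_groups"][name] = {
            "anova": anova.__dict__,
            "tukey_kramer": [p.__dict__ for p in posthoc],
            "bonferroni_adjusted": {
                f"{p.pair[0]} vs {p.pair[1]}": float(b) for p, b in zip(posthoc, bonf)
            },
        }
    if raw_indices is not None:
        col = {
            "count": "ictal_count",
            "duration": "ictal_duration_per_event",
            "amplitude": "ictal_amplitude_per_event",
        }
        for g in groups:
            sub = raw_indices[raw_indices.group == g]
            wide = sub.pivot(index="animal_id", columns="period", values=list(col.values()))
            entry = {}
            for name, c in col.items():
                pre = wide[(c, "pre")].to_numpy(float)
                post = wide[(c, "post")].to_numpy(float)
                ok = np.isfinite(pre) & np.isfinite(post)
                tail = "less" if name in ("count", "duration") else "two-sided"
                try:
                    res = paired_t(post[ok], pre[ok], tail=tail)
                    entry[name] = res.__dict__
                except (DegenerateDataError, ValueError) as exc:
                    logger.warning("paired t for %s/%s skipped: %s", g, name, exc)
                    entry[name] = None
            report["within_groups"][g] = entry
    return report


def analyze_dialysis(samples: pd.DataFrame) -> dict:
    """Statistical report over a paired dialysis concentration table.

    Expects columns ``run``, ``condition``, ``concentration_ug_ml``.
    Reports the repeated-measures ANOVA across all conditions, a
    three-condition RM-ANOVA over control / off-focus / pooled-focus
    cassettes when the focus conditions are split by parameter set,
    Bonferroni-adjusted paired contrasts against the control, and the
    relative concentration increase of every condition over control.
    """
    wide = samples.pivot(index="run", columns="condition", values="concentration_ug_ml")
    if wide.isna().any().any():
        raise ValueError("incomplete paired design (missing run x condition cells)")
    conditions = list(wide.columns)
    if "Ctrl" not in conditions:
        raise ValueError("expected a 'Ctrl' condition")
    report: dict = {"conditions": conditions, "n_runs": int(len(wide))}
    ff = [c for c in conditions if c.startswith("FF")]
    report["rm_anova_ff_sets"] = (
        rm_anova(wide[ff].to_numpy()).__dict__ if len(ff) >= 2 else None
    )
    if len(ff) >= 2 and "FO" in conditions:
        pooled = np.column_stack(
            [wide["Ctrl"], wide["FO"], wide[ff].mean(axis=1)]
        )
        report["rm_anova_ctrl_fo_ff"] = rm_anova(pooled).__dict__
    contrasts = {}
    others = [c for c in conditions if c != "Ctrl"]
    raw_p = []
    tested = []
    for c in others:
        try:
            res = paired_t(wide[c].to_numpy(), wide["Ctrl"].to_numpy(), tail="two-sided")
        except DegenerateDataError as exc:
            logger.warning("contrast %s vs Ctrl skipped: %s", c, exc)
            contrasts[c] = None
            continue
        contrasts[c] = res.__dict__
        raw_p.append(res.p)
        tested.append(c)
    adj = bonferroni(raw_p) if raw_p else []
    for c, p in zip(tested, adj):
        contrasts[c]["p_bonferroni"] = float(p)
    report["contrasts_vs_ctrl"] = contrasts
    ctrl_mean = float(wide["Ctrl"].mean())
    report["condition_means_ug_ml"] = {c: float(wide[c].mean()) for c in conditions}
    report["relative_increase_vs_ctrl_percent"] = {
        c: 100.0 * (float(wide[c].mean()) - ctrl_mean) / ctrl_mean for c in others
    }
    return report
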