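"""Behavioural exclusions, summaries and group statistics.

Three two-choice tasks share a common coding: each has a low-variance and a
high-variance stimulus class with matching response labels,

========================  ==============  =============
task                      low class       high class
========================  ==============  =============
discrimination            anticlockwise   clockwise
detection                 absent ('no')   present ('yes')
tilt_recognition          vertical        tilted
========================  ==============  =============

Block-level exclusion rules: more than 20% missed trials, accuracy below
60%, the same response on more than 80% of usable trials, or the same
confidence level on more than 90% of trials for some response.  The first
trial of every block is dropped from all analyses (25 usable of 26), and a
subject is retained only with at least three surviving blocks per task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import integrate, stats

from . import sdt
from .sdt import MetacogSummary, RatingCountTable

__all__ = [
    "TASKS",
    "RESPONSES",
    "CLASSES",
    "ExclusionReport",
    "GroupStats",
    "apply_exclusions",
    "summarize_behavior",
    "rating_table_from_trials",
    "ttest_with_d",
    "rm_anova",
    "jzs_bf01",
]

TASKS = ("discrimination", "detection", "tilt_recognition")
# (low-variance response, high-variance response)
RESPONSES = {
    "discrimination": ("anticlockwise", "clockwise"),
    "detection": ("no", "yes"),
    "tilt_recognition": ("vertical", "tilted"),
}
# (low-variance class, high-variance class)
CLASSES = {
    "discrimination": ("anticlockwise", "clockwise"),
    "detection": ("absent", "present"),
    "tilt_recognition": ("vertical", "tilted"),
}

MISSED_FRAC = 0.20
MIN_ACCURACY = 0.60
SAME_RESPONSE_FRAC = 0.80
SAME_CONFIDENCE_FRAC = 0.90
MIN_TRIALS_PER_RESPONSE = 5  # guard for the same-confidence rule
MIN_BLOCKS_PER_TASK = 3


@dataclass
class ExclusionReport:
    blocks: pd.DataFrame  # one row per subject x block with flags
    subjects: pd.DataFrame  # per subject: included flag + per-task block counts

    @property
    def n_excluded_blocks(self) -> int:
        return int(self.blocks["excluded"].sum())

    @property
    def included_subjects(self) -> list:
        return list(self.subjects.index[self.subjects["included"]])


def _block_flags(block: pd.DataFrame) -> dict[str, bool]:
    """Flags for one block.  The missed fraction uses all trials; the other
    rules use responded trials among the 25 usable (trial 1 dropped)."""
    missed = block["missed"].astype(bool)
    flags = {"flag_missed": missed.mean() > MISSED_FRAC}
    usable = block.loc[block["trial_in_block"] > 1]
    responded = usable.loc[~usable["missed"].astype(bool)]
    if len(responded) == 0:
        flags.update(
            flag_accuracy=True, flag_same_response=True, flag_same_confidence=False
        )
        return flags
    flags["flag_accuracy"] = responded["correct"].mean() < MIN_ACCURACY
    resp_counts = responded["response"].value_counts()
    flags["flag_same_response"] = (
        resp_counts.iloc[0] / len(responded) > SAME_RESPONSE_FRAC
    )
    same_conf = False
    for response, grp in responded.groupby("response"):
        if len(grp) >= MIN_TRIALS_PER_RESPONSE:
            top = grp["confidence"].value_counts().iloc[0]
            if top / len(grp) > SAME_CONFIDENCE_FRAC:
                same_conf = True
    flags["flag_same_confidence"] = same_conf
    return flags


def apply_exclusions(
    tables: Mapping[str, pd.DataFrame],
) -> tuple[ExclusionReport, dict[str, pd.DataFrame]]:
    """Apply block- and subject-level exclusion rules.

    Returns the report and, for each included subject, their trial table
    restricted to usable trials (trial 1 of each block dropped, excluded
    blocks removed).  Flags are computed per block independently, so the
    outcome does not depend on block order.
    """
    block_rows = []
    for subject, table in tables.items():
        _validate_trials(table)
        for (run, block), grp in table.groupby(["run", "block"], sort=True):
            flags = _block_flags(grp)
            row = {
                "subject": subject,
                "run": run,
                "block": block,
                "task": grp["task"].iloc[0],
                "n_trials": len(grp),
                **flags,
            }
            row["excluded"] = any(flags.values())
            block_rows.append(row)
    blocks = pd.DataFrame(block_rows)
    subj_rows = {}
    filtered: dict[str, pd.DataFrame] = {}
    for subject, table in tables.items():
        mine = blocks.loc[blocks["subject"] == subject]
        kept = mine.loc[~mine["excluded"]]
        per_task = {
            f"blocks_{task}": int((kept["task"] == task).sum()) for task in TASKS
        }
        included = all(per_task[f"blocks_{task}"] >= MIN_BLOCKS_PER_TASK for task in TASKS)
        subj_rows[subject] = {"included": included, **per_task}
        if included:
            keep_keys = set(zip(kept["run"], kept["block"]))
            sel = [
                (r, b) in keep_keys
                for r, b in zip(table["run"], table["block"])
            ]
            out = table.loc[sel]
            out = out.loc[out["trial_in_block"] > 1].reset_index(drop=True)
            filtered[subject] = out
    subjects = pd.DataFrame.from_dict(subj_rows, orient="index")
    subjects.index.name = "subject"
    return ExclusionReport(blocks=blocks, subjects=subjects), filtered


def _validate_trials(table: pd.DataFrame) -> None:
    required = {
        "task",
        "stim_class",
        "response",
        "correct",
        "confidence",
        "missed",
        "block",
        "run",
        "trial_in_block",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")


def rating_table_from_trials(
    trials: pd.DataFrame, task: str, n_conf_levels: int = 6
) -> RatingCountTable:
    """Fold responded trials of ``task`` onto the 12-point rating scale."""
    sub = trials.loc[(trials["task"] == task) & ~trials["missed"].astype(bool)]
    low_class, high_class = CLASSES[task]
    low_resp, high_resp = RESPONSES[task]
    counts = np.zeros((2, 2 * n_conf_levels), dtype=np.int64)
    for _, row in sub.iterrows():
        cls = 1 if row["stim_class"] == high_class else 0
        is_high = row["response"] == high_resp
        b = sdt.rating_bin(is_high, int(row["confidence"]), n_conf_levels)
        counts[cls, b] += 1
    return RatingCountTable(counts, n_conf_levels)


def summarize_behavior(
    trials: pd.DataFrame, n_conf_levels: int = 6
) -> dict[str, MetacogSummary]:
    """Per-task accuracy, response proportions, mean confidence, AUROC2 per
    response and the type-1 zROC slope (delegated to :mod:`uvconf.sdt`)."""
    out: dict[str, MetacogSummary] = {}
    for task in TASKS:
        sub = trials.loc[(trials["task"] == task) & ~trials["missed"].astype(bool)]
        if len(sub) == 0:
            continue
        low_resp, high_resp = RESPONSES[task]
        accuracy = float(sub["correct"].mean())
        rate_low = float((sub["response"] == low_resp).mean())
        mean_conf = []
        aurocs = []
        for response in (low_resp, high_resp):
            grp = sub.loc[sub["response"] == response]
            mean_conf.append(float(grp["confidence"].mean()) if len(grp) else np.nan)
            try:
                correct = np.bincount(
                    grp.loc[grp["correct"].astype(bool), "confidence"].astype(int),
                    minlength=n_conf_levels + 1,
                )[1:]
                errors = np.bincount(
                    grp.loc[~grp["correct"].astype(bool), "confidence"].astype(int),
                    minlength=n_conf_levels + 1,
                )[1:]
                aurocs.append(sdt.auroc2(correct, errors))
            except ValueError:
                aurocs.append(np.nan)
        try:
            slope = sdt.zroc_slope(rating_table_from_trials(sub, task, n_conf_levels))
        except ValueError:
            slope = np.nan
        out[task] = MetacogSummary(
            zroc_slope=slope,
            auroc2_by_response=(aurocs[0], aurocs[1]),
            accuracy=accuracy,
            response_rate_low=rate_low,
            mean_confidence_by_response=(mean_conf[0], mean_conf[1]),
            n_trials=len(sub),
        )
    return out


@dataclass
class GroupStats:
    """Container for group-level test statistics.

    For one-sample/paired t-tests ``d = t / sqrt(n)`` (Cohen's d) and
    ``df = n - 1``.  For repeated-measures ANOVA, ``F`` with ``(df1, df2)``
    is filled instead of ``t``/``d``.
    """

    n: int
    t: float | None = None
    df: int | None = None
    p: float = np.nan
    d: float | None = None
    F: float | None = None
    df1: int | None = None
    df2: int | None = None
    bf01: float | None = None


def ttest_with_d(values, null: float = 0.0) -> GroupStats:
    """One-sample t-test against ``null`` with Cohen's d = t / sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-d vector with n >= 2")
    n = len(x)
    sd = x.std(ddof=1)
    if sd == 0:
        if np.isclose(x.mean(), null):
            return GroupStats(n=n, t=0.0, df=n - 1, p=1.0, d=0.0)
        raise ValueError("zero variance with a nonzero mean difference")
    res = stats.ttest_1samp(x, null)
    t = float(res.statistic)
    return GroupStats(n=n, t=t, df=n - 1, p=float(res.pvalue), d=t / np.sqrt(n))


def rm_anova(matrix) -> GroupStats:
    """One-way repeated-measures ANOVA (subjects x conditions).

    Classic within-subject decomposition: F = MS_condition / MS_error with
    df (k - 1, (k - 1)(n - 1)), subject effects removed from the error term.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix has missing cells")
    n, k = X.shape
    grand = X.mean()
    ss_cond = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((X - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        return GroupStats(n=n, F=0.0, df1=df1, df2=df2, p=1.0)
    F = ms_cond / ms_err
    p = float(stats.f.sf(F, df1, df2))
    return GroupStats(n=n, F=float(F), df1=df1, df2=df2, p=p)


def jzs_bf01(t: float, n: int, scale: float = np.sqrt(2) / 2) -> float:
    """JZS Bayes factor in favour of the null for a one-sample/paired t.

    The alternative places a Cauchy(0, ``scale``) prior on the standardized
    effect size, equivalently an inverse-gamma(1/2, scale^2/2) prior on g;
    the marginal likelihood is obtained by numerical integration over g
    (Rouder et al. 2009 t-form).  BF01 decreases monotonically in |t|.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if scale <= 0:
        raise ValueError("scale must be positive")
    t = float(t)
    nu = n - 1
    null_like = (1 + t * t / nu) ** (-(nu + 1) / 2)

    r2 = scale * scale

    def integrand(g: float) -> float:
        shrink = 1.0 + n * g
        like = shrink ** -0.5 * (1 + t * t / (shrink * nu)) ** (-(nu + 1) / 2)
        prior = (
            (r2 / 2) ** 0.5
            / np.sqrt(np.pi)
            * g ** -1.5
            * np.exp(-r2 / (2 * g))
        )
        return like * prior

    alt_like, err = integrate.quad(
        integrand, 0, np.inf, limit=200, epsabs=1e-12, epsrel=1e-10
    )
    if not np.isfinite(alt_like) or alt_like <= 0 or err > 1e-4 * alt_like:
        raise ArithmeticError(
            f"BF integration failed (value={alt_like}, abs err={err})"
        )
    return float(null_like / alt_like)
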