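"""Representational similarity analysis over the 12 trial categories.

Conditions are the crossing of task (discrimination, detection, tilt
recognition), response (one low- and one high-variance response per task)
and confidence (low / high by a per-response median split), in the fixed
order ``CONDITIONS``.

Eight theory-specified model RDMs (A-H) are provided:

A  task identity
B  variance structure ({discrimination}, {detection-yes, tilt-tilted},
   {detection-no, tilt-vertical})
C  detection decision only
D  decision in both unequal-variance tasks
E  task-invariant confidence
F  confidence graded by variance structure
G  detection-only confidence
H  confidence in the unequal-variance tasks only

Models carry a no-prediction mask.  The convention: single-factor
within-task models (C, D, G, H) predict only within their task block(s)
and only for condition pairs differing in exactly one of (response,
confidence); confidence models E and F predict within-cell (same task and
response) contrasts and all cross-task pairs (confidence-aligned similar,
crossed dissimilar), with within-task cross-response pairs masked.  Under
this convention G equals 1 - C on their shared domain, so their
off-diagonal Spearman correlation is exactly -1, and the 18 sub-RDMs of
the decomposition exactly span E's unmasked support.  A mask-free binary
variant is available with ``masked=False``.

Empirical RDMs are mean cross-run Euclidean distances: entry (i, j)
averages ||pattern(i, run r) - pattern(j, run s)|| over all ordered run
pairs r != s, so the diagonal holds cross-run self-distances and never
mixes within-run noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import RESPONSES, TASKS, GroupStats, ttest_with_d

__all__ = [
    "CONDITIONS",
    "RDM",
    "SubRDM",
    "theoretical_rdms",
    "empirical_rdm",
    "rdm_diagnostics",
    "model_correlations",
    "subrdm_set",
    "subrdm_regression",
    "split_confidence",
]

UV_TASKS = ("detection", "tilt_recognition")
CONF_LEVELS = ("low", "high")


def _build_conditions():
    conds = []
    for task in TASKS:
        for response in RESPONSES[task]:
            for conf in CONF_LEVELS:
                conds.append(f"{task}:{response}:{conf}")
    return tuple(conds)


CONDITIONS = _build_conditions()


def _attrs(label: str) -> tuple[str, str, str]:
    task, response, conf = label.split(":")
    return task, response, conf


def _variance_group(task: str, response: str) -> str:
    if task == "discrimination":
        return "equal"
    return "high" if response == RESPONSES[task][1] else "low"


@dataclass
class RDM:
    """A labelled 12x12 dissimilarity matrix.

    ``mask`` is True where the entry is defined.  Theoretical RDMs mask
    their diagonal (and any no-prediction entries); empirical RDMs keep the
    diagonal, which holds the cross-run self-distance.
    """

    values: np.ndarray
    mask: np.ndarray
    labels: tuple[str, ...] = CONDITIONS
    kind: str = "theoretical"
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        k = len(self.labels)
        if self.values.shape != (k, k) or self.mask.shape != (k, k):
            raise ValueError("RDM values/mask must be square over the labels")
        if not np.allclose(
            np.where(self.mask & self.mask.T, self.values, 0),
            np.where(self.mask & self.mask.T, self.values.T, 0),
            atol=1e-12,
        ):
            raise ValueError("RDM must be symmetric on defined entries")
        if self.kind == "empirical" and (self.values[self.mask] < 0).any():
            raise ValueError("empirical dissimilarities must be >= 0")

    def offdiag_defined(self) -> np.ndarray:
        off = ~np.eye(len(self.labels), dtype=bool)
        return self.mask & off


def theoretical_rdms(masked: bool = True) -> dict[str, RDM]:
    """The eight a priori model RDMs (see module docstring for the masking
    convention).  With ``masked=False``, out-of-domain entries become 0 and
    the confidence contrast applies everywhere."""
    k = len(CONDITIONS)
    attrs = [_attrs(c) for c in CONDITIONS]
    vgroups = [_variance_group(t, r) for t, r, _ in attrs]
    out: dict[str, RDM] = {}

    def build(name, fn):
        vals = np.zeros((k, k))
        msk = np.zeros((k, k), dtype=bool)
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                defined, value = fn(i, j)
                if not masked:
                    defined = True
                msk[i, j] = defined
                vals[i, j] = value if defined else 0.0
        out[name] = RDM(vals, msk, kind="theoretical", name=name)

    def single_factor(i, j, tasks, factor):
        ti, ri, ci = attrs[i]
        tj, rj, cj = attrs[j]
        if ti != tj or ti not in tasks:
            return False, 0.0
        n_diff = int(ri != rj) + int(ci != cj)
        if n_diff != 1:
            return False, 0.0
        if factor == "response":
            return True, float(ri != rj)
        return True, float(ci != cj)

    def conf_model(i, j, weight_fn):
        ti, ri, ci = attrs[i]
        tj, rj, cj = attrs[j]
        if ti == tj and ri != rj:
            return False, 0.0
        value = weight_fn(i, j) if ci != cj else 0.0
        return True, value

    build("A", lambda i, j: (True, float(attrs[i][0] != attrs[j][0])))
    build("B", lambda i, j: (True, float(vgroups[i] != vgroups[j])))
    build("C", lambda i, j: single_factor(i, j, ("detection",), "response"))
    build("D", lambda i, j: single_factor(i, j, UV_TASKS, "response"))
    build("E", lambda i, j: conf_model(i, j, lambda i, j: 1.0))

    def f_weight(i, j):
        w = {
            "discrimination": 0.5,
            "detection": 1.0,
            "tilt_recognition": 1.0,
        }
        return 0.5 * (w[attrs[i][0]] + w[attrs[j][0]])

    build("F", lambda i, j: conf_model(i, j, f_weight))
    build("G", lambda i, j: single_factor(i, j, ("detection",), "confidence"))
    build("H", lambda i, j: single_factor(i, j, UV_TASKS, "confidence"))
    return out


def empirical_rdm(patterns: np.ndarray, labels=CONDITIONS) -> RDM:
    """Mean cross-run Euclidean RDM from (runs, conditions, voxels) patterns."""
    P = np.asarray(patterns, dtype=float)
    if P.ndim != 3:
        raise ValueError("patterns must be (runs, conditions, voxels)")
    n_runs, k, _ = P.shape
    if n_runs < 2:
        raise ValueError("need at least 2 runs for cross-run distances")
    if k != len(labels):
        raise ValueError("condition count does not match labels")
    if not np.all(np.isfinite(P)):
        raise ValueError("a condition pattern is missing (non-finite values)")
    acc = np.zeros((k, k))
    n_pairs = 0
    for r in range(n_runs):
        for s in range(n_runs):
            if r == s:
                continue
            diff = P[r][:, None, :] - P[s][None, :, :]
            acc += np.sqrt((diff**2).sum(axis=2))
            n_pairs += 1
    values = acc / n_pairs
    return RDM(values, np.ones((k, k), dtype=bool), tuple(labels), kind="empirical")


def rdm_diagnostics(subject_rdms: list[RDM]) -> dict:
    """Reliability diagnostics over subjects' empirical RDMs.

    ``diag_stat``: per subject, entries are rank-transformed and the mean
    off-diagonal rank minus the mean diagonal rank computed; condition-
    specific structure makes it positive (cross-run self-distances are the
    smallest).  A one-sample t-test summarises the group.

    ``noise_ceiling_lower``: mean leave-one-out Spearman correlation
    between each subject's off-diagonal entries and the average ranked
    off-diagonal RDM of the remaining subjects.
    """
    if len(subject_rdms) < 2:
        raise ValueError("need at least 2 subjects")
    k = len(subject_rdms[0].labels)
    off = ~np.eye(k, dtype=bool)
    diag_stats = []
    ranked_off = []
    raw_off = []
    for r in subject_rdms:
        ranks = stats.rankdata(r.values.ravel()).reshape(k, k)
        diag_stats.append(ranks[off].mean() - np.diag(ranks).mean())
        ranked_off.append(stats.rankdata(r.values[off]))
        raw_off.append(r.values[off])
    try:
        diag_test = ttest_with_d(diag_stats, 0.0)
    except ValueError:  # identical subjects: degenerate variance
        diag_test = GroupStats(n=len(diag_stats), t=np.nan, p=np.nan)
    ceilings = []
    for i in range(len(subject_rdms)):
        others = np.mean([ranked_off[j] for j in range(len(ranked_off)) if j != i], axis=0)
        ceilings.append(stats.spearmanr(raw_off[i], others).statistic)
    return {
        "diag_stat": np.asarray(diag_stats),
        "diag_test": diag_test,
        "noise_ceiling_lower": float(np.mean(ceilings)),
        "ceiling_per_subject": np.asarray(ceilings),
    }


def model_correlations(empirical: RDM, models: dict[str, RDM]) -> dict[str, float]:
    """Spearman correlation with each model over off-diagonal entries where
    the model makes a prediction (average-rank tie handling)."""
    out = {}
    k = len(empirical.labels)
    off = ~np.eye(k, dtype=bool)
    for name, model in models.items():
        if model.labels != empirical.labels:
            raise ValueError(f"model {name} has a different condition order")
        sel = off & model.mask & empirical.mask
        if sel.sum() < 3:
            raise ValueError(f"model {name} has fewer than 3 usable entries")
        rho = stats.spearmanr(empirical.values[sel], model.values[sel]).statistic
        out[name] = float(rho)
    return out


@dataclass
class SubRDM:
    name: str
    values: np.ndarray
    support: np.ndarray  # bool, the cell pair's entries


def subrdm_set() -> list[SubRDM]:
    """The 18 constituents of the task-invariant confidence RDM (E).

    6 within-cell sub-RDMs (one per task x response cell, contrasting its
    high vs low confidence conditions) and 12 between-cell sub-RDMs (one
    per across-task pair of cells, confidence-aligned entries similar,
    confidence-crossed dissimilar).  Within-task cross-response pairs are
    not part of the decomposition, matching E's mask.
    """
    idx = {c: i for i, c in enumerate(CONDITIONS)}
    k = len(CONDITIONS)
    cells = [(t, r) for t in TASKS for r in RESPONSES[t]]
    subs: list[SubRDM] = []

    def entry(cell, conf):
        return idx[f"{cell[0]}:{cell[1]}:{conf}"]

    for cell in cells:
        vals = np.zeros((k, k))
        sup = np.zeros((k, k), dtype=bool)
        i, j = entry(cell, "low"), entry(cell, "high")
        sup[i, j] = sup[j, i] = True
        vals[i, j] = vals[j, i] = 1.0
        subs.append(SubRDM(f"within:{cell[0]}:{cell[1]}", vals, sup))
    for a in range(len(cells)):
        for b in range(a + 1, len(cells)):
            c1, c2 = cells[a], cells[b]
            if c1[0] == c2[0]:
                continue  # within-task cross-response pairs excluded
            vals = np.zeros((k, k))
            sup = np.zeros((k, k), dtype=bool)
            for conf1 in CONF_LEVELS:
                for conf2 in CONF_LEVELS:
                    i, j = entry(c1, conf1), entry(c2, conf2)
                    sup[i, j] = sup[j, i] = True
                    v = 1.0 if conf1 != conf2 else 0.0
                    vals[i, j] = vals[j, i] = v
            subs.append(
                SubRDM(f"between:{c1[0]}:{c1[1]}|{c2[0]}:{c2[1]}", vals, sup)
            )
    assert len(subs) == 18
    return subs


# Beta combinations: response-specific detection<->tilt similarity pairs the
# variance-matched responses; response-invariant tilt<->discrimination
# averages all four response pairings.
COMBINATION_DET_TILT = (
    "between:detection:yes|tilt_recognition:tilted",
    "between:detection:no|tilt_recognition:vertical",
)
COMBINATION_TILT_DISC = (
    "between:discrimination:anticlockwise|tilt_recognition:vertical",
    "between:discrimination:anticlockwise|tilt_recognition:tilted",
    "between:discrimination:clockwise|tilt_recognition:vertical",
    "between:discrimination:clockwise|tilt_recognition:tilted",
)


@dataclass
class RSARegression:
    betas: pd.Series
    intercept: float
    combinations: dict[str, float] = field(default_factory=dict)


def subrdm_regression(empirical: RDM, subrdms: list[SubRDM] | None = None) -> RSARegression:
    """Multiple regression of the empirical off-diagonal entries on the 18
    sub-RDM predictors plus an intercept, over the union of their supports
    (upper triangle).  Returns the betas and the two hypothesis-encoding
    combinations: response-specific detection-tilt similarity and
    response-invariant tilt-discrimination similarity (equal weights within
    each combination)."""
    subs = subrdms if subrdms is not None else subrdm_set()
    k = len(empirical.labels)
    triu = np.triu(np.ones((k, k), dtype=bool), 1)
    union = np.zeros((k, k), dtype=bool)
    for s in subs:
        union |= s.support
    rows = triu & union & empirical.mask
    y = empirical.values[rows]
    X = np.column_stack(
        [np.ones(rows.sum())] + [s.values[rows] for s in subs]
    )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:].T)
        pairs = [
            (subs[i].name, subs[j].name)
            for i in range(len(subs))
            for j in range(i + 1, len(subs))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise np.linalg.LinAlgError(f"collinear sub-RDM predictors: {pairs}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    betas = pd.Series(coef[1:], index=[s.name for s in subs])
    combos = {
        "det_tilt_response_specific": float(
            np.mean([betas[n] for n in COMBINATION_DET_TILT])
        ),
        "tilt_disc_response_invariant": float(
            np.mean([betas[n] for n in COMBINATION_TILT_DISC])
        ),
    }
    return RSARegression(betas=betas, intercept=float(coef[0]), combinations=combos)


def split_confidence(
    trials: pd.DataFrame, response_invariant: bool = False
) -> pd.Series:
    """Label each responded trial 'low' or 'high' confidence.

    Default: median split within each response category, ratings at or
    below the median count as low.  ``response_invariant=True`` applies a
    single cutoff at the overall median instead (the supplementary
    convention).
    """
    responded = trials.loc[~trials["missed"].astype(bool)]
    conf = responded["confidence"].astype(float)
    if response_invariant:
        cut = conf.median()
        labels = np.where(conf <= cut, "low", "high")
        return pd.Series(labels, index=responded.index)
    out = pd.Series(index=responded.index, dtype=object)
    for response, grp in responded.groupby("response"):
        cut = grp["confidence"].astype(float).median()
        out.loc[grp.index] = np.where(
            grp["confidence"].astype(float) <= cut, "low", "high"
        )
    return out


def condition_of_trials(trials: pd.DataFrame, response_invariant: bool = False) -> pd.Series:
    """Map responded trials to the 12 RSA condition labels."""
    split = split_confidence(trials, response_invariant)
    responded = trials.loc[split.index]
    return (
        responded["task"].astype(str)
        + ":"
        + responded["response"].astype(str)
        + ":"
        + split.astype(str)
    )
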