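"""Confidence design matrices and ROI GLM estimation.

Two routes to the linear and quadratic confidence effects are implemented:

* the quadratic-confidence design matrix (QC-DM): one 4-s boxcar regressor
  per response plus two parametric modulators per response carrying the
  mean-centred linear and (serially orthogonalized) quadratic confidence,
  all convolved with the canonical HRF — 18 regressors of interest when all
  six responses occur;

* the categorical route: per task, a single regressor of interest modulated
  by 12 dummy (0/1) columns (2 responses x 6 confidence levels) whose betas
  are then fed to an unorthogonalized second-step polynomial fit in which
  every confidence level carries equal weight regardless of its trial
  frequency, making the estimates insensitive to confidence-distribution
  biases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .behavior import RESPONSES, TASKS, GroupStats, rm_anova, ttest_with_d

__all__ = [
    "DesignMatrix",
    "ModulationEstimate",
    "GLMFit",
    "canonical_hrf",
    "build_qc_dm",
    "build_categorical_dm",
    "fit_glm",
    "two_step_polyfit",
    "group_contrast",
    "group_anova",
]

BOXCAR_DURATION = 4.0  # s, stimulus onset through end of the rating phase
HRF_SUPPORT = 32.0  # s


def canonical_hrf(dt: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt`` seconds, peak-normalised.

    Difference of two gamma densities (shapes 6 and 16, unit scale), giving
    a main peak near 5 s and an undershoot near 15 s over a 32 s support.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, HRF_SUPPORT, dt)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    return h / h.max()


@dataclass
class DesignMatrix:
    """Time x regressor matrix with of-interest flags and modulator metadata.

    ``meta[name]`` records, for modulator columns, the parent response and
    the polynomial order (0 main effect, 1 linear, 2 quadratic).
    """

    data: pd.DataFrame
    tr: float
    of_interest: list[str]
    meta: dict[str, dict] = field(default_factory=dict)

    @property
    def n_scans(self) -> int:
        return len(self.data)

    @property
    def names(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path, sidecar_path=None) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.8g")
        if sidecar_path is not None:
            import json

            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "tr": self.tr,
                        "of_interest": self.of_interest,
                        "meta": self.meta,
                    },
                    fh,
                    indent=1,
                )


def _convolved_regressor(
    onsets, durations, amplitudes, n_scans: int, tr: float, dt: float = 0.1
) -> np.ndarray:
    """Amplitude-weighted boxcars convolved with the HRF, sampled each TR."""
    n_fine = int(np.ceil(n_scans * tr / dt)) + 1
    x = np.zeros(n_fine)
    for on, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(on / dt))
        i1 = max(i0 + 1, int(round((on + dur) / dt)))
        if i0 >= n_fine:
            continue
        x[i0 : min(i1, n_fine)] += amp
    conv = np.convolve(x, canonical_hrf(dt))[:n_fine]
    scan_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    return conv[scan_idx]


def _n_scans_for(trials: pd.DataFrame, tr: float) -> int:
    return int(np.ceil((trials["onset"].max() + HRF_SUPPORT) / tr))


def _run_constant_columns(trials: pd.DataFrame, n_scans: int, tr: float):
    """0/1 columns partitioning scans into runs (scan assigned to the run of
    the latest trial onset at or before it; leading scans go to run 1)."""
    runs = np.sort(trials["run"].unique())
    starts = {r: trials.loc[trials["run"] == r, "onset"].min() for r in runs}
    scan_t = np.arange(n_scans) * tr
    cols = {}
    bounds = [starts[r] for r in runs]
    assign = np.searchsorted(bounds, scan_t, side="right") - 1
    assign[assign < 0] = 0
    for i, r in enumerate(runs):
        cols[f"run{r}_constant"] = (assign == i).astype(float)
    return cols


def _centered_modulators(conf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centred linear and serially orthogonalized quadratic confidence."""
    lin = conf - conf.mean()
    quad = conf.astype(float) ** 2
    quad = quad - quad.mean()
    denom = lin @ lin
    if denom > 0:
        quad = quad - (quad @ lin) / denom * lin
    return lin, quad


def _nuisance_columns(
    trials: pd.DataFrame,
    n_scans: int,
    tr: float,
    motion: np.ndarray | None,
    physio: np.ndarray | None,
) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    dur = np.full(1, BOXCAR_DURATION)

    def box(sel):
        sub = trials.loc[sel]
        return _convolved_regressor(
            sub["onset"].to_numpy(),
            np.full(len(sub), BOXCAR_DURATION),
            np.ones(len(sub)),
            n_scans,
            tr,
        )

    missed = trials["missed"].astype(bool)
    first = trials["trial_in_block"] == 1
    excluded = (
        trials["excluded_block"].astype(bool)
        if "excluded_block" in trials
        else pd.Series(False, index=trials.index)
    )
    if missed.any():
        cols["missed_trials"] = box(missed)
    if first.any():
        cols["first_trials"] = box(first)
    if excluded.any():
        cols["excluded_trials"] = box(excluded & ~missed & ~first)

    # instruction screen at the start of every block (2 s before trial 1)
    instr = (
        trials.groupby(["run", "block"], sort=True)["onset"].min() - 2.0
    ).to_numpy()
    instr = np.clip(instr, 0.0, None)
    cols["instructions"] = _convolved_regressor(
        instr, np.full(len(instr), 2.0), np.ones(len(instr)), n_scans, tr
    )

    # button presses: two right-hand response buttons + pooled left presses
    resp = trials.loc[~missed]
    low_set = {RESPONSES[t][0] for t in TASKS}
    is_low = resp["response"].isin(low_set)
    t_dec = resp["onset"].to_numpy() + 1.0
    t_rate = resp["onset"].to_numpy() + 1.5
    for name, sel in (("button_right1", is_low), ("button_right2", ~is_low)):
        ons = t_dec[sel.to_numpy()]
        if len(ons):
            cols[name] = _convolved_regressor(
                ons, np.full(len(ons), 0.0), np.ones(len(ons)), n_scans, tr
            )
    cols["button_left"] = _convolved_regressor(
        t_rate, np.zeros(len(t_rate)), np.ones(len(t_rate)), n_scans, tr
    )

    for label, mat in (("motion", motion), ("physio", physio)):
        if mat is not None:
            mat = np.atleast_2d(np.asarray(mat, dtype=float))
            if mat.shape[0] != n_scans:
                mat = mat.T
            if mat.shape[0] != n_scans:
                raise ValueError(f"{label} regressors must have {n_scans} rows")
            for j in range(mat.shape[1]):
                cols[f"{label}_{j + 1}"] = mat[:, j]

    cols.update(_run_constant_columns(trials, n_scans, tr))
    return cols


def build_qc_dm(
    trials: pd.DataFrame,
    tr: float = 2.0,
    n_scans: int | None = None,
    motion: np.ndarray | None = None,
    physio: np.ndarray | None = None,
) -> DesignMatrix:
    """Quadratic-confidence design matrix.

    Per response: a 4-s boxcar, a mean-centred linear confidence modulator
    and a quadratic modulator orthogonalized against the linear one
    (serial order main -> linear -> quadratic), all convolved with the HRF.
    Missed trials, first trials of each block, excluded-block trials,
    instruction screens, button presses, optional motion/physiological
    columns and run constants enter as nuisance regressors.
    """
    if n_scans is None:
        n_scans = _n_scans_for(trials, tr)
    usable = (
        (~trials["missed"].astype(bool))
        & (trials["trial_in_block"] > 1)
        & ~(
            trials["excluded_block"].astype(bool)
            if "excluded_block" in trials
            else False
        )
    )
    cols: dict[str, np.ndarray] = {}
    of_interest: list[str] = []
    meta: dict[str, dict] = {}
    for task in TASKS:
        for response in RESPONSES[task]:
            sel = usable & (trials["response"] == response)
            sub = trials.loc[sel]
            if len(sub) == 0:
                warnings.warn(
                    f"response {response!r} absent; its 3 columns are omitted"
                )
                continue
            ons = sub["onset"].to_numpy()
            durs = np.full(len(sub), BOXCAR_DURATION)
            conf = sub["confidence"].to_numpy(dtype=float)
            lin, quad = _centered_modulators(conf)
            for name, amps, order in (
                (response, np.ones(len(sub)), 0),
                (f"{response}_conf", lin, 1),
                (f"{response}_conf2", quad, 2),
            ):
                cols[name] = _convolved_regressor(ons, durs, amps, n_scans, tr)
                of_interest.append(name)
                meta[name] = {"response": response, "task": task, "order": order}
    cols.update(_nuisance_columns(trials, n_scans, tr, motion, physio))
    return DesignMatrix(pd.DataFrame(cols), tr, of_interest, meta)


def build_categorical_dm(
    trials: pd.DataFrame,
    task: str,
    tr: float = 2.0,
    n_scans: int | None = None,
    motion: np.ndarray | None = None,
    physio: np.ndarray | None = None,
    n_conf_levels: int = 6,
) -> DesignMatrix:
    """Categorical-confidence design matrix for one task.

    A single of-interest boxcar covers all included trials of ``task``; 12
    dummy (0/1) modulators — one per response x confidence level — ride on
    it.  Trials of the other tasks stay in the baseline.  Note the base
    regressor equals the sum of the dummy columns, so the design is
    rank-deficient by construction; fit with ``allow_rank_deficient=True``
    (the polynomial contrasts of interest are estimable, see docs).
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if n_scans is None:
        n_scans = _n_scans_for(trials, tr)
    usable = (
        (~trials["missed"].astype(bool))
        & (trials["trial_in_block"] > 1)
        & ~(
            trials["excluded_block"].astype(bool)
            if "excluded_block" in trials
            else False
        )
        & (trials["task"] == task)
    )
    sub = trials.loc[usable]
    ons = sub["onset"].to_numpy()
    durs = np.full(len(sub), BOXCAR_DURATION)
    cols: dict[str, np.ndarray] = {}
    meta: dict[str, dict] = {}
    base_name = f"{task}_trials"
    cols[base_name] = _convolved_regressor(ons, durs, np.ones(len(sub)), n_scans, tr)
    meta[base_name] = {"task": task, "order": 0}
    of_interest = [base_name]
    for response in RESPONSES[task]:
        for level in range(1, n_conf_levels + 1):
            dummy = (
                (sub["response"] == response)
                & (sub["confidence"] == level)
            ).to_numpy(dtype=float)
            name = f"{response}_conf{level}"
            if dummy.sum() == 0:
                warnings.warn(f"empty category {name}; column omitted")
                continue
            cols[name] = _convolved_regressor(ons, durs, dummy, n_scans, tr)
            of_interest.append(name)
            meta[name] = {"response": response, "task": task, "level": level}
    # responded trials of the other two tasks: one aggregate nuisance boxcar,
    # so their evoked signal does not leak into the task of interest
    others = trials.loc[
        (~trials["missed"].astype(bool)) & (trials["task"] != task)
    ]
    if len(others):
        cols["other_task_trials"] = _convolved_regressor(
            others["onset"].to_numpy(),
            np.full(len(others), BOXCAR_DURATION),
            np.ones(len(others)),
            n_scans,
            tr,
        )
    cols.update(_nuisance_columns(trials, n_scans, tr, motion, physio))
    return DesignMatrix(pd.DataFrame(cols), tr, of_interest, meta)


@dataclass
class GLMFit:
    betas: pd.Series
    se: pd.Series
    residual_variance: float
    df_resid: int

    def tvalue(self, name: str) -> float:
        return float(self.betas[name] / self.se[name])


def fit_glm(
    timeseries: np.ndarray, dm: DesignMatrix, allow_rank_deficient: bool = False
) -> GLMFit:
    """Ordinary least squares fit of a design matrix to one time series.

    A rank-deficient design raises an error naming the collinear columns
    unless ``allow_rank_deficient`` is set, in which case the minimum-norm
    solution is returned (needed for the categorical design, whose base
    regressor is the sum of its dummy columns).
    """
    y = np.asarray(timeseries, dtype=float).ravel()
    X = dm.data.to_numpy(dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError(
            f"timeseries has {len(y)} scans but design has {X.shape[0]} rows"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1] and not allow_rank_deficient:
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [dm.names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-8 * diag[0]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = len(y) - rank
    sigma2 = float(resid @ resid / df_resid) if df_resid > 0 else np.nan
    cov_diag = np.diag(np.linalg.pinv(X.T @ X)) * sigma2
    se = np.sqrt(np.clip(cov_diag, 0, None))
    return GLMFit(
        betas=pd.Series(beta, index=dm.names),
        se=pd.Series(se, index=dm.names),
        residual_variance=sigma2,
        df_resid=df_resid,
    )


@dataclass
class ModulationEstimate:
    """Per-response polynomial confidence effects (and task aggregates)."""

    coefficients: pd.DataFrame  # index response; columns intercept/linear/quadratic
    se: pd.DataFrame | None = None

    def task_aggregate(self, task: str) -> pd.Series:
        rows = [r for r in RESPONSES[task] if r in self.coefficients.index]
        if not rows:
            raise KeyError(f"no responses estimated for task {task!r}")
        return self.coefficients.loc[rows].mean(axis=0)


def two_step_polyfit(
    betas_by_response: dict[str, dict[int, float]],
    n_conf_levels: int = 6,
) -> ModulationEstimate:
    """Second step of the categorical route: per response, regress the
    confidence-level betas on {1, conf, conf^2} (raw confidence levels, no
    orthogonalization — linear and quadratic terms compete for variance).
    Every available level carries equal weight.
    Responses with fewer than 3 levels are skipped with a warning.
    """
    rows = {}
    for response, level_betas in betas_by_response.items():
        levels = sorted(level_betas)
        if len(levels) < 3:
            warnings.warn(
                f"response {response!r} has {len(levels)} confidence levels; skipped"
            )
            continue
        c = np.asarray(levels, dtype=float)
        y = np.asarray([level_betas[v] for v in levels], dtype=float)
        X = np.column_stack([np.ones_like(c), c, c**2])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rows[response] = coef
    if not rows:
        raise ValueError("no response had enough confidence levels")
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["intercept", "linear", "quadratic"]
    )
    return ModulationEstimate(coefficients=df)


def categorical_betas_by_response(
    fit: GLMFit, dm: DesignMatrix
) -> dict[str, dict[int, float]]:
    """Collect the 12 dummy-modulator betas keyed by response and level."""
    out: dict[str, dict[int, float]] = {}
    for name in dm.of_interest:
        info = dm.meta.get(name, {})
        if "level" in info:
            out.setdefault(info["response"], {})[info["level"]] = float(
                fit.betas[name]
            )
    return out


def qc_gain_estimates(fit: GLMFit, trials: pd.DataFrame) -> pd.DataFrame:
    """Per-response (linear, quadratic) gains in the generating coding.

    The QC-DM quadratic beta is the quadratic gain directly.  The linear
    beta absorbs two bookkeeping terms: the covariance the serial
    orthogonalization moved out of the quadratic column (``alpha``, the
    regression coefficient of the centred squared confidence on the centred
    confidence) and the ``2 * mean(conf)`` shift between squaring raw and
    centred confidence.  Subtracting ``quad_beta * (alpha - 2 * mean)``
    recovers the linear gain in the generating (centred) coding.
    """
    usable = (
        (~trials["missed"].astype(bool))
        & (trials["trial_in_block"] > 1)
        & ~(
            trials["excluded_block"].astype(bool)
            if "excluded_block" in trials
            else False
        )
    )
    rows = {}
    for task in TASKS:
        for response in RESPONSES[task]:
            name = f"{response}_conf"
            if name not in fit.betas.index:
                continue
            conf = trials.loc[
                usable & (trials["response"] == response), "confidence"
            ].to_numpy(dtype=float)
            c = conf - conf.mean()
            q = conf**2 - (conf**2).mean()
            alpha = (q @ c) / (c @ c) if (c @ c) > 0 else 0.0
            g2 = float(fit.betas[f"{response}_conf2"])
            g1 = float(fit.betas[name]) - g2 * (alpha - 2 * conf.mean())
            rows[response] = {"linear": g1, "quadratic": g2}
    return pd.DataFrame.from_dict(rows, orient="index")


def categorical_gain_estimates(
    est: ModulationEstimate, trials: pd.DataFrame
) -> pd.DataFrame:
    """Two-step estimates re-expressed as gains at each response's mean
    confidence (the generating coding): the quadratic coefficient carries
    over, the linear gain is the polynomial's slope evaluated there."""
    usable = (
        (~trials["missed"].astype(bool))
        & (trials["trial_in_block"] > 1)
        & ~(
            trials["excluded_block"].astype(bool)
            if "excluded_block" in trials
            else False
        )
    )
    rows = {}
    for response in est.coefficients.index:
        conf = trials.loc[
            usable & (trials["response"] == response), "confidence"
        ].to_numpy(dtype=float)
        mu = conf.mean()
        lin = est.coefficients.loc[response, "linear"]
        quad = est.coefficients.loc[response, "quadratic"]
        rows[response] = {
            "linear": float(lin + 2 * quad * mu),
            "quadratic": float(quad),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def group_contrast(
    subject_estimates: pd.DataFrame, contrast: dict[str, float]
) -> GroupStats:
    """One-sample t on a per-subject linear combination of estimate columns."""
    missing = [k for k in contrast if k not in subject_estimates.columns]
    if missing:
        raise KeyError(f"contrast labels not found: {missing}")
    values = sum(
        w * subject_estimates[name].to_numpy() for name, w in contrast.items()
    )
    return ttest_with_d(values, 0.0)


def group_anova(subject_estimates: pd.DataFrame, columns: list[str]) -> GroupStats:
    """Repeated-measures ANOVA over named estimate columns."""
    missing = [k for k in columns if k not in subject_estimates.columns]
    if missing:
        raise KeyError(f"ANOVA labels not found: {missing}")
    return rm_anova(subject_estimates[columns].to_numpy())
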