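"""Synthetic data for the three-task confidence pipeline.

Everything the analysis consumes can be generated here: dynamic grating-in-
noise stimulus clips, calibrated multi-task behavioural sessions driven by
unequal-variance signal-detection observers, ROI time series carrying known
linear and quadratic confidence modulations, and run-wise multivoxel
condition patterns whose geometry follows a chosen generating RDM.

Stimulus clips follow the experimental recipe: 10 frames of 142x142 random
luminance, a sinusoidal grating (24 pixels/period, random phase) pasted
pixel-wise with per-frame probability p_i = v * exp(-|i - 5| / 2), peaking
at frame 5 at the visibility level v (v = 0 on target-absent trials).

Sessions comprise 5-6 runs of three 26-trial blocks (one per task) with
jittered rest (0.5-4 s), 0.5 s fixation, 0.5 s stimulus, 1 s decision
window and 2.5 s confidence rating.  Difficulty is calibrated like the
experiment's staircase: a within-block rule every 10 trials during practice
and a between-block rule (thresholds 52.5% / 85%, factor 0.95) during the
scanned session.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import CLASSES, RESPONSES, TASKS
from .sdt import UVSDTParams

__all__ = [
    "StimulusClip",
    "SessionDesign",
    "NeuralSpec",
    "visibility_envelope",
    "generate_stimulus",
    "calibrate_step",
    "default_observers",
    "simulate_session",
    "simulate_roi_timeseries",
    "simulate_patterns",
    "seed_from_protocol",
    "seed_from_hex_digest",
]

N_FRAMES = 10
FRAME_SIZE = 142
PIXELS_PER_PERIOD = 24


def visibility_envelope(v: float) -> np.ndarray:
    """Per-frame grating visibility p_i = v * exp(-|i - 5| / 2), i = 1..10."""
    if not 0.0 <= v <= 1.0:
        raise ValueError("visibility v must lie in [0, 1]")
    i = np.arange(1, N_FRAMES + 1)
    return v * np.exp(-np.abs(i - 5) / 2.0)


@dataclass(frozen=True)
class StimulusClip:
    """A 10-frame dynamic stimulus with its generating ingredients."""

    frames: np.ndarray  # (10, 142, 142) luminance in [0, 1]
    grating: np.ndarray  # (142, 142) 0/1-normalised sinusoid
    envelope: np.ndarray  # p_i per frame
    replaced: np.ndarray  # (10, 142, 142) bool, True where grating was pasted
    v: float
    orientation_deg: float

    def __post_init__(self) -> None:
        assert self.frames.shape == (N_FRAMES, FRAME_SIZE, FRAME_SIZE)


def generate_stimulus(
    v: float, orientation_deg: float, seed: int | np.random.Generator
) -> StimulusClip:
    """Render a stimulus clip: noise frames with per-pixel grating pasting.

    Each pixel of frame i is independently replaced by the corresponding
    grating pixel with probability p_i.
    """
    if not np.isfinite(orientation_deg):
        raise ValueError("orientation must be finite")
    env = visibility_envelope(v)
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    theta = np.deg2rad(orientation_deg)
    idx = np.arange(FRAME_SIZE) - (FRAME_SIZE - 1) / 2
    xx, yy = np.meshgrid(idx, idx)
    carrier = xx * np.sin(theta) + yy * np.cos(theta)
    grating = 0.5 * (1 + np.sin(2 * np.pi * carrier / PIXELS_PER_PERIOD + phase))
    frames = rng.random((N_FRAMES, FRAME_SIZE, FRAME_SIZE))
    replaced = rng.random((N_FRAMES, FRAME_SIZE, FRAME_SIZE)) < env[:, None, None]
    frames[replaced] = np.broadcast_to(grating, frames.shape)[replaced]
    return StimulusClip(
        frames=frames,
        grating=grating,
        envelope=env,
        replaced=replaced,
        v=v,
        orientation_deg=orientation_deg,
    )


CALIBRATION_FACTOR = 0.95
WITHIN_BLOCK_BAND = (0.60, 0.80)
BETWEEN_BLOCK_BAND = (0.525, 0.85)


def calibrate_step(current: float, recent_accuracy: float, scope: str) -> float:
    """One staircase update of a difficulty parameter (visibility or
    orientation spread).  Dividing by 0.95 makes the task easier.

    ``within_block_10trial``: accuracy < 60% -> easier, > 80% -> harder.
    ``between_block``: accuracy <= 52.5% -> easier, >= 85% -> harder.
    """
    if current <= 0:
        raise ValueError("difficulty parameter must be positive")
    if scope == "within_block_10trial":
        lo, hi = WITHIN_BLOCK_BAND
        if recent_accuracy < lo:
            return current / CALIBRATION_FACTOR
        if recent_accuracy > hi:
            return current * CALIBRATION_FACTOR
        return current
    if scope == "between_block":
        lo, hi = BETWEEN_BLOCK_BAND
        if recent_accuracy <= lo:
            return current / CALIBRATION_FACTOR
        if recent_accuracy >= hi:
            return current * CALIBRATION_FACTOR
        return current
    raise ValueError(f"unknown calibration scope {scope!r}")


@dataclass(frozen=True)
class SessionDesign:
    """Timing and structure of one scanning session."""

    tasks: tuple[str, ...] = TASKS
    runs: int = 6
    trials_per_block: int = 26
    class_prob_high: float = 0.5
    rest_jitter: tuple[float, float] = (0.5, 4.0)  # s, uniform
    fixation: float = 0.5
    stimulus: float = 0.5
    decision_window: float = 1.0
    rating_window: float = 2.5
    instruction: float = 2.0
    sigma_orientation: float = 8.0  # deg, tilt-recognition spread

    @property
    def trial_tail(self) -> float:
        return self.fixation + self.stimulus + self.decision_window + self.rating_window


def default_observers(
    sigma_ratios: dict[str, float] | None = None,
    separation: float = 1.4,
) -> dict[str, UVSDTParams]:
    """Observers emulating the study conditions: an equal-variance
    discrimination observer and unequal-variance detection / tilt observers
    with sigma_low / sigma_high of about 0.74 and 0.55 respectively, tuned
    near ~75% accuracy."""
    ratios = sigma_ratios or {
        "discrimination": 1.0,
        "detection": 0.74,
        "tilt_recognition": 0.55,
    }
    out = {}
    for task in TASKS:
        out[task] = UVSDTParams(
            mu_low=0.0,
            sigma_low=1.0,
            mu_high=separation,
            sigma_high=1.0 / ratios[task],
        )
    return out


def simulate_session(
    design: SessionDesign,
    observers: dict[str, UVSDTParams] | None = None,
    lapse_rate: float = 0.03,
    seed: int | np.random.Generator = 0,
    initial_gain: float = 1.0,
) -> pd.DataFrame:
    """Simulate one subject's scanned session as a trial table.

    Evidence is drawn from the task's observer model with a per-task
    difficulty gain scaling the mean separation; ratings fall out of the
    observer's criteria.  Missed trials are independent Bernoulli events
    with no recorded response or confidence.  After each block, the gain is
    updated with the between-block staircase rule.  Fully reproducible from
    the seed.
    """
    observers = observers or default_observers()
    rng = np.random.default_rng(seed)
    gains = {task: float(initial_gain) for task in design.tasks}
    rows = []
    t = 0.0
    block_id = 0
    for run in range(1, design.runs + 1):
        task_order = list(rng.permutation(design.tasks))
        for task in task_order:
            block_id += 1
            t += design.instruction
            obs = observers[task].with_separation_gain(gains[task])
            low_class, high_class = CLASSES[task]
            low_resp, high_resp = RESPONSES[task]
            mapping = int(rng.integers(2))  # counterbalanced response mapping
            n_correct = 0
            n_responded = 0
            for trial in range(1, design.trials_per_block + 1):
                t += rng.uniform(*design.rest_jitter) + design.fixation
                onset = t
                t += design.stimulus + design.decision_window + design.rating_window
                is_high = rng.random() < design.class_prob_high
                mu = obs.mu_high if is_high else obs.mu_low
                sigma = obs.sigma_high if is_high else obs.sigma_low
                x = rng.normal(mu, sigma)
                b = int(np.searchsorted(np.asarray(obs.criteria), x))
                resp_is_high = b >= obs.n_conf_levels
                confidence = (
                    b - obs.n_conf_levels + 1 if resp_is_high else obs.n_conf_levels - b
                )
                missed = rng.random() < lapse_rate
                if task == "discrimination":
                    orientation = 45.0 if is_high else -45.0
                elif task == "tilt_recognition":
                    orientation = (
                        rng.normal(0.0, design.sigma_orientation) if is_high else 0.0
                    )
                else:
                    orientation = (
                        rng.normal(0.0, design.sigma_orientation) if is_high else np.nan
                    )
                response = (
                    pd.NA
                    if missed
                    else (high_resp if resp_is_high else low_resp)
                )
                correct = pd.NA if missed else bool(resp_is_high == is_high)
                if not missed:
                    n_responded += 1
                    n_correct += int(resp_is_high == is_high)
                rows.append(
                    {
                        "onset": round(onset, 3),
                        "duration": design.stimulus,
                        "task": task,
                        "stim_class": high_class if is_high else low_class,
                        "orientation": orientation,
                        "response": response,
                        "correct": correct,
                        "confidence": pd.NA if missed else int(confidence),
                        "missed": bool(missed),
                        "block": block_id,
                        "run": run,
                        "trial_in_block": trial,
                        "mapping": mapping,
                    }
                )
            if n_responded > 0:
                gains[task] = calibrate_step(
                    gains[task], n_correct / n_responded, "between_block"
                )
    table = pd.DataFrame(rows)
    table["confidence"] = table["confidence"].astype("Int64")
    table["correct"] = table["correct"].astype("boolean")
    return table


@dataclass(frozen=True)
class NeuralSpec:
    """Generating model for one ROI's confidence-modulated time series and
    for its multivoxel condition patterns."""

    response_amp: dict = field(
        default_factory=lambda: {
            r: 1.0 for task in TASKS for r in RESPONSES[task]
        }
    )
    linear_gain: dict = field(default_factory=lambda: {t: 0.0 for t in TASKS})
    quadratic_gain: dict = field(default_factory=lambda: {t: 0.0 for t in TASKS})
    noise_sd: float = 1.0
    tr: float = 2.0
    n_voxels: int = 60
    pattern_noise_sd: float = 1.0
    # spread of the true confidence gains across subjects (used by the
    # cohort pipeline to give each simulated subject their own gains)
    gain_between_subject_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.noise_sd < 0 or self.pattern_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


def simulate_roi_timeseries(
    trials: pd.DataFrame,
    spec: NeuralSpec,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, dict]:
    """ROI time series with known linear/quadratic confidence modulations.

    Each usable responded trial contributes a 4-s boxcar with amplitude
    ``response_amp[r] + g1 * c + g2 * c^2`` where ``c`` is confidence
    mean-centred within the response over those trials (the same coding and
    trial selection the QC-DM uses, so generated and estimated gains share
    a scale).  First-of-block and excluded-block trials contribute
    unmodulated unit boxcars, mirroring their nuisance treatment.  Boxcars
    are convolved with the canonical HRF and white noise is added.
    """
    from .glm import BOXCAR_DURATION, _convolved_regressor, _n_scans_for

    rng = np.random.default_rng(seed)
    n_scans = _n_scans_for(trials, spec.tr)
    responded = trials.loc[~trials["missed"].astype(bool)]
    excluded = (
        responded["excluded_block"].astype(bool)
        if "excluded_block" in responded
        else pd.Series(False, index=responded.index)
    )
    usable = (responded["trial_in_block"] > 1) & ~excluded
    y = np.zeros(n_scans)
    nuis = responded.loc[~usable]
    if len(nuis):
        y += _convolved_regressor(
            nuis["onset"].to_numpy(),
            np.full(len(nuis), BOXCAR_DURATION),
            np.ones(len(nuis)),
            n_scans,
            spec.tr,
        )
    for task in TASKS:
        for response in RESPONSES[task]:
            sub = responded.loc[usable & (responded["response"] == response)]
            if len(sub) == 0:
                continue
            conf = sub["confidence"].to_numpy(dtype=float)
            c = conf - conf.mean()
            amp = (
                spec.response_amp[response]
                + spec.linear_gain[task] * c
                + spec.quadratic_gain[task] * c**2
            )
            y += _convolved_regressor(
                sub["onset"].to_numpy(),
                np.full(len(sub), BOXCAR_DURATION),
                amp,
                n_scans,
                spec.tr,
            )
    y = y + rng.normal(0.0, spec.noise_sd, size=n_scans)
    truth = {
        "linear_gain": dict(spec.linear_gain),
        "quadratic_gain": dict(spec.quadratic_gain),
        "response_amp": dict(spec.response_amp),
        "n_scans": n_scans,
        "tr": spec.tr,
    }
    return y, truth


def _mds_embedding(rdm_values: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    """Classical MDS treating RDM entries as squared distances.

    Masked (no-prediction) entries are filled with the mean of the defined
    off-diagonal entries; negative eigenvalues are clipped.  Any monotone
    embedding suffices because downstream comparisons are rank-based.
    """
    D = np.array(rdm_values, dtype=float)
    k = D.shape[0]
    off = ~np.eye(k, dtype=bool)
    if mask is not None:
        fill = D[mask & off].mean() if (mask & off).any() else 0.0
        D = np.where(mask, D, fill)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    J = np.eye(k) - np.ones((k, k)) / k
    B = -0.5 * J @ D @ J
    w, V = np.linalg.eigh(B)
    if w.min() < -1e-10 * max(w.max(), 1.0):
        # not Euclidean-embeddable as squared distances: shift all
        # off-diagonal entries by a constant, which preserves ranks and
        # makes the Gram matrix positive semi-definite
        D = D + 2.0 * abs(w.min()) * (1.0 - np.eye(k))
        B = -0.5 * J @ D @ J
        w, V = np.linalg.eigh(B)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def simulate_patterns(
    conditions,
    runs: int,
    generating_rdm,
    pattern_noise_sd: float = 1.0,
    voxels: int = 60,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Run-wise condition x voxel patterns with a controllable geometry.

    Condition prototypes are embedded from ``generating_rdm`` (values
    attribute or plain matrix) so that their pairwise Euclidean distances
    are monotone in the generating entries, rotated into voxel space, and
    independent Gaussian run noise is added.  Returns an array of shape
    (runs, n_conditions, voxels).
    """
    if runs < 2:
        raise ValueError("cross-run distances need at least 2 runs")
    values = getattr(generating_rdm, "values", generating_rdm)
    mask = getattr(generating_rdm, "mask", None)
    values = np.asarray(values, dtype=float)
    k = values.shape[0]
    if len(conditions) != k:
        raise ValueError("condition labels do not match the RDM size")
    if voxels < k:
        raise ValueError("need at least as many voxels as conditions")
    rng = np.random.default_rng(seed)
    proto = _mds_embedding(values, mask)  # (k, k)
    Q, _ = np.linalg.qr(rng.standard_normal((voxels, k)))
    proto_vox = proto @ Q.T  # (k, voxels)
    noise = rng.normal(0.0, pattern_noise_sd, size=(runs, k, voxels))
    return proto_vox[None, :, :] + noise


def seed_from_protocol(data: bytes) -> int:
    """Translate protocol-folder bytes into an RNG seed via SHA256.

    The first 8 digest bytes are read as a big-endian unsigned integer.
    """
    if not isinstance(data, (bytes, bytearray, memoryview)):
        raise TypeError("expected raw bytes")
    digest = hashlib.sha256(bytes(data)).hexdigest()
    return seed_from_hex_digest(digest)


def seed_from_hex_digest(hexdigest: str) -> int:
    """Seed from the first 8 bytes of a printed SHA256 hex digest."""
    if len(hexdigest) < 16:
        raise ValueError("digest too short")
    return int(hexdigest[:16], 16)
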