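import numpy as np
import pandas as pd
import pytest

from uvconf import synth
from uvconf.behavior import CLASSES, RESPONSES


@pytest.fixture(scope="session")
def small_session() -> pd.DataFrame:
    """A 3-run lapse-free session (one block per task per run)."""
    design = synth.SessionDesign(runs=3)
    return synth.simulate_session(design, lapse_rate=0.0, seed=42)


@pytest.fixture(scope="session")
def default_session() -> pd.DataFrame:
    """A full 6-run session with lapses, as the pipeline simulates."""
    design = synth.SessionDesign(runs=6)
    return synth.simulate_session(design, lapse_rate=0.03, seed=7)


def make_block(
    task="detection",
    block=1,
    run=1,
    n_trials=26,
    n_missed=0,
    accuracy=0.8,
    response_fracs=(0.5, 0.5),
    confidences=None,
    seed=0,
):
    """Hand-assemble one block of trials with controllable statistics."""
    rng = np.random.default_rng(seed)
    low_resp, high_resp = RESPONSES[task]
    low_class, high_class = CLASSES[task]
    rows = []
    n_responded = n_trials - n_missed
    n_correct = int(round(accuracy * n_responded))
    n_low = int(round(response_fracs[0] * n_responded))
    correct_flags = np.zeros(n_responded, dtype=bool)
    correct_flags[:n_correct] = True
    rng.shuffle(correct_flags)  # spread errors over both responses
    for i in range(n_trials):
        missed = i < n_missed
        if missed:
            response = correct = confidence = pd.NA
            stim = low_class
        else:
            j = i - n_missed
            response = low_resp if j < n_low else high_resp
            correct = bool(correct_flags[j])
            if confidences is None:
                confidence = int(rng.integers(1, 7))
            else:
                confidence = confidences[j % len(confidences)]
            resp_is_low = response == low_resp
            stim_if_correct = low_class if resp_is_low else high_class
            stim_if_wrong = high_class if resp_is_low else low_class
            stim = stim_if_correct if correct else stim_if_wrong
        rows.append(
            {
                "onset": 100.0 * block + 12.0 * i,
                "duration": 0.5,
                "task": task,
                "stim_class": stim,
                "orientation": 0.0,
                "response": response,
                "correct": correct,
                "confidence": confidence,
                "missed": missed,
                "block": block,
                "run": run,
                "trial_in_block": i + 1,
            }
        )
    table = pd.DataFrame(rows)
    table["confidence"] = table["confidence"].astype("Int64")
    table["correct"] = table["correct"].astype("boolean")
    return table


def make_clean_subject(seed=0):
    """A subject with 3 compliant blocks per task."""
    blocks = []
    b = 0
    for run in (1, 2, 3):
        for task in ("discrimination", "detection", "tilt_recognition"):
            b += 1
            blocks.append(
                make_block(task=task, block=b, run=run, accuracy=0.8, seed=seed + b)
            )
    return pd.concat(blocks, ignore_index=True)


@pytest.fixture
def clean_subject():
    return make_clean_subject()
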