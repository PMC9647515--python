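"""Shared fixtures: tiny hand-built ESM frames and small simulated datasets."""

import numpy as np
import pandas as pd
import pytest

from esm_mediation import EsmDataset, EsmDesign, GROUPS


def beep_row(
    subject="s1",
    group="control",
    day=1,
    beep=1,
    delay_min=0.0,
    stress=3.0,
    na=3.0,
    pe=2.0,
    age=40.0,
    gender="female",
    answered=True,
):
    """One beep record; ``delay_min`` sets completion lateness."""
    sched = (
        pd.Timestamp("2024-01-01 07:30")
        + pd.Timedelta(days=day - 1)
        + pd.Timedelta(minutes=90 * (beep - 1))
    )
    comp = sched + pd.Timedelta(minutes=delay_min) if answered else pd.NaT
    return {
        "subject_id": subject,
        "group": group,
        "day": day,
        "beep": beep,
        "scheduled_time": sched,
        "completed_time": comp,
        "stress": stress,
        "negative_affect": na,
        "psychotic_experiences": pe,
        "age": age,
        "gender": gender,
    }


def make_dataset(rows, design=None) -> EsmDataset:
    frame = pd.DataFrame(rows)
    frame["group"] = pd.Categorical(frame["group"], categories=GROUPS)
    return EsmDataset(frame, design or EsmDesign())


@pytest.fixture
def tiny_dataset():
    """Three fully compliant subjects, one per group, two days of beeps."""
    rows = []
    for i, group in enumerate(GROUPS):
        for day in (1, 2):
            for beep in range(1, 11):
                rows.append(
                    beep_row(
                        subject=f"s{i + 1}",
                        group=group,
                        day=day,
                        beep=beep,
                        stress=3.0 + i * 0.5,
                        na=3.0,
                        pe=2.0 + i * 0.5,
                        age=30.0 + 5 * i,
                        gender="female" if i % 2 else "male",
                    )
                )
    return make_dataset(rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
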