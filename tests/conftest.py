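import io

import numpy as np
import pandas as pd
import pytest

from agreekit import (
    ActivitySpec,
    MeasurementTable,
    SyntheticDesign,
    generate,
    pair_differences,
)
from agreekit.data import from_records


@pytest.fixture
def tiny_csv(tmp_path):
    """2 subjects x 2 devices x 1 activity x 1 replicate, constant value."""
    path = tmp_path / "tiny.csv"
    path.write_text(
        "subject,device,activity,value\n"
        "A,gold,sitting,7.0\nA,chest,sitting,7.0\n"
        "B,gold,sitting,7.0\nB,chest,sitting,7.0\n"
    )
    return path


def make_table(rows, reference="gold", test="chest"):
    """rows: (subject, device, activity, replicate, value)"""
    return from_records(rows, reference_device=reference, test_device=test)


@pytest.fixture
def simple_table():
    return make_table(
        [
            ("A", "gold", "sit", 1, 20.0),
            ("A", "chest", "sit", 1, 18.0),
            ("B", "gold", "sit", 1, 16.0),
            ("B", "chest", "sit", 1, 14.0),
            ("A", "gold", "walk", 1, 24.0),
            ("A", "chest", "walk", 1, 23.0),
            ("B", "gold", "walk", 1, 20.0),
            ("B", "chest", "walk", 1, 17.0),
        ]
    )


@pytest.fixture
def constant_table():
    rows = [
        (s, d, a, t, 7.0)
        for s in "ABC"
        for d in ("gold", "chest")
        for a in ("sit", "walk")
        for t in (1, 2)
    ]
    return make_table(rows)


def small_design(seed=0, n_subjects=8, **overrides):
    """Quick-to-fit design used across the engine tests."""
    kw = dict(
        n_subjects=n_subjects,
        activities=(
            ActivitySpec("sit", 2, 3),
            ActivitySpec("walk", 1, 2),
            ActivitySpec("run", 1, 1, participation=0.9),
        ),
        mu=20.0,
        device_diff=-1.0,
        var_subject=4.0,
        var_activity=2.0,
        var_subject_device=0.5,
        var_subject_activity=1.0,
        var_device_activity=0.5,
        var_resid=2.0,
        seed=seed,
    )
    kw.update(overrides)
    return SyntheticDesign(**kw)


@pytest.fixture
def small_synth_table():
    return generate(small_design(seed=7))


@pytest.fixture
def small_pairs(small_synth_table):
    return pair_differences(small_synth_table)
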