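"""Synthetic measurement tables with known variance components.

The generator draws from the crossed two-device model: every reading is
the overall mean plus a fixed device effect (sum-to-zero) plus
independent normal subject, activity, subject x device,
subject x activity and device x activity effects plus residual noise.
Both devices are always observed at every generated (subject, activity,
replicate), giving time-matched pairs.  An unbalanced template mimicking
a respiratory-rate comparison study (21 subjects, 11 activities, one
frequent sitting activity, a few strenuous activities that some subjects
skip) is provided so that every pipeline stage is testable without any
external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import MeasurementTable, PairedDifferenceTable
from .errors import DataError

__all__ = [
    "ActivitySpec",
    "SyntheticDesign",
    "DiffDesign",
    "generate",
    "generate_differences",
    "sample_paired_differences",
    "copd_like_design",
]


@dataclass(frozen=True)
class ActivitySpec:
    """Replicate schedule of one activity.

    Each participating subject performs between ``min_reps`` and
    ``max_reps`` time-matched replicate pairs (uniform over the range, or
    weighted by ``rep_weights`` when given); participation is an
    independent coin flip per subject with the given probability.
    """

    label: str
    min_reps: int = 1
    max_reps: int = 1
    participation: float = 1.0
    rep_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.min_reps < 1 or self.max_reps < self.min_reps:
            raise DataError(f"bad replicate range for activity {self.label!r}")
        if not (0 < self.participation <= 1):
            raise DataError("participation probability must lie in (0, 1]")
        if self.rep_weights is not None:
            k = self.max_reps - self.min_reps + 1
            if len(self.rep_weights) != k or min(self.rep_weights) < 0:
                raise DataError(f"rep_weights must have {k} non-negative entries")


@dataclass(frozen=True)
class SyntheticDesign:
    """Full generative design for the two-device crossed model."""

    n_subjects: int
    activities: tuple[ActivitySpec, ...]
    mu: float = 20.0
    device_diff: float = 0.0  # beta_test - beta_reference
    var_subject: float = 0.0
    var_activity: float = 0.0
    var_subject_device: float = 0.0
    var_subject_activity: float = 0.0
    var_device_activity: float = 0.0
    var_resid: float = 0.0
    seed: int = 0
    reference_device: str = "gold"
    test_device: str = "test"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise DataError("need at least 2 subjects")
        if not self.activities:
            raise DataError("need at least 1 activity")
        for v in (
            self.var_subject,
            self.var_activity,
            self.var_subject_device,
            self.var_subject_activity,
            self.var_device_activity,
            self.var_resid,
        ):
            if v < 0:
                raise DataError("variances must be non-negative")

    def with_seed(self, seed: int) -> "SyntheticDesign":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class DiffDesign:
    """Reduced design generating paired differences directly."""

    n_subjects: int
    activities: tuple[ActivitySpec, ...]
    mu_star: float = 0.0
    var_subject_star: float = 0.0
    var_activity_star: float = 0.0
    var_resid_star: float = 0.0
    seed: int = 0


def copd_like_design(
    seed: int = 0,
    n_subjects: int = 21,
    mu: float = 20.0,
    device_diff: float = -1.28,
    var_subject: float = 11.4,
    var_activity: float = 16.6,
    var_subject_device: float = 0.4,
    var_subject_activity: float = 6.0,
    var_device_activity: float = 3.7,
    var_resid: float = 10.5,
) -> SyntheticDesign:
    """Unbalanced 11-activity template with 15-19 paired readings per
    subject (mean about 18): sitting contributes 6-7 replicates, standing
    and walking 1-3 (skewed high), every other activity one, and the two
    treadmill activities are skipped by ~20% of subjects."""
    acts = [
        ActivitySpec("sitting", 6, 7, rep_weights=(0.25, 0.75)),
        ActivitySpec("standing_walking", 1, 3, rep_weights=(0.1, 0.15, 0.75)),
        ActivitySpec("lying"),
        ActivitySpec("standing"),
        ActivitySpec("slow_walking"),
        ActivitySpec("fast_walking"),
        ActivitySpec("sweeping"),
        ActivitySpec("lifting"),
        ActivitySpec("stairs"),
        ActivitySpec("treadmill_flat", participation=0.8),
        ActivitySpec("treadmill_slope", participation=0.8),
    ]
    return SyntheticDesign(
        n_subjects=n_subjects,
        activities=tuple(acts),
        mu=mu,
        device_diff=device_diff,
        var_subject=var_subject,
        var_activity=var_activity,
        var_subject_device=var_subject_device,
        var_subject_activity=var_subject_activity,
        var_device_activity=var_device_activity,
        var_resid=var_resid,
        seed=seed,
    )


def _schedule(design, rng: np.random.Generator) -> list[tuple[str, str, int]]:
    """Draw the (subject, activity, n_replicates) schedule."""
    width = len(str(design.n_subjects - 1))
    subjects = [f"s{i:0{width}d}" for i in range(design.n_subjects)]
    out = []
    for subj in subjects:
        any_row = False
        for spec in design.activities:
            if spec.participation < 1.0 and rng.random() >= spec.participation:
                continue
            if spec.rep_weights is not None:
                w = np.asarray(spec.rep_weights, float)
                reps = int(
                    rng.choice(
                        np.arange(spec.min_reps, spec.max_reps + 1), p=w / w.sum()
                    )
                )
            else:
                reps = int(rng.integers(spec.min_reps, spec.max_reps + 1))
            out.append((subj, spec.label, reps))
            any_row = True
        if not any_row:  # guarantee every subject appears at least once
            spec = design.activities[0]
            out.append((subj, spec.label, spec.min_reps))
    return out


def generate(design: SyntheticDesign) -> MeasurementTable:
    """Draw a time-matched two-device measurement table from the design.

    Deterministic given ``design.seed``.  Latent effect draws are attached
    to the returned table's ``validation`` report under ``"latents"`` for
    white-box tests.
    """
    rng = np.random.default_rng(design.seed)
    sched = _schedule(design, rng)
    subjects = sorted({s for s, _, _ in sched})
    activities = sorted({a for _, a, _ in sched})
    devices = [design.reference_device, design.test_device]
    beta = {
        design.reference_device: -design.device_diff / 2.0,
        design.test_device: design.device_diff / 2.0,
    }

    def draws(labels, sd):
        return dict(zip(labels, rng.normal(0.0, sd, size=len(labels))))

    alpha = draws(subjects, np.sqrt(design.var_subject))
    gamma = draws(activities, np.sqrt(design.var_activity))
    ab = draws(
        [(s, d) for s in subjects for d in devices], np.sqrt(design.var_subject_device)
    )
    ag = draws(
        [(s, a) for s in subjects for a in activities],
        np.sqrt(design.var_subject_activity),
    )
    bg = draws(
        [(d, a) for d in devices for a in activities],
        np.sqrt(design.var_device_activity),
    )

    rows = []
    sd_eps = np.sqrt(design.var_resid)
    for subj, act, reps in sched:
        for t in range(1, reps + 1):
            for dev in devices:
                eps = rng.normal(0.0, sd_eps)
                value = (
                    design.mu
                    + alpha[subj]
                    + beta[dev]
                    + gamma[act]
                    + ab[(subj, dev)]
                    + ag[(subj, act)]
                    + bg[(dev, act)]
                    + eps
                )
                rows.append((subj, dev, act, t, value))
    df = pd.DataFrame(rows, columns=["subject", "device", "activity", "replicate", "value"])
    table = MeasurementTable(
        df,
        reference_device=design.reference_device,
        test_device=design.test_device,
        validation={
            "latents": {
                "subject": alpha,
                "activity": gamma,
                "subject_device": ab,
                "subject_activity": ag,
                "device_activity": bg,
            }
        },
    )
    return table


def generate_differences(design: DiffDesign) -> PairedDifferenceTable:
    """Draw paired differences directly from the differences model.

    The pair-average column is not defined by this reduced generator and
    is filled with the difference midpoint convention ``avg = NaN`` — use
    ``generate`` + ``pair_differences`` when averages are needed.
    """
    rng = np.random.default_rng(design.seed)
    sched = _schedule(design, rng)
    subjects = sorted({s for s, _, _ in sched})
    activities = sorted({a for _, a, _ in sched})
    alpha = dict(zip(subjects, rng.normal(0, np.sqrt(design.var_subject_star), len(subjects))))
    gamma = dict(
        zip(activities, rng.normal(0, np.sqrt(design.var_activity_star), len(activities)))
    )
    sd_eps = np.sqrt(design.var_resid_star)
    rows = []
    for subj, act, reps in sched:
        for t in range(1, reps + 1):
            d = design.mu_star + alpha[subj] + gamma[act] + rng.normal(0.0, sd_eps)
            rows.append((subj, act, t, d, np.nan))
    df = pd.DataFrame(rows, columns=["subject", "activity", "replicate", "diff", "avg"])
    return PairedDifferenceTable(data=df)


def sample_paired_differences(
    n: int,
    device_diff: float,
    var_subject_device: float,
    var_device_activity: float,
    var_resid: float,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Draw ``n`` independent between-device differences implied by the
    full model, each pair on a fresh subject and activity.

    The difference decomposes as the mean device difference plus the
    subject-device contrast (variance 2 x subject-device), the
    device-activity contrast (variance 2 x device-activity) and the
    residual contrast (variance 2 x residual) — a cheap Monte Carlo oracle
    for the mean-squared-deviation and coverage-probability formulas.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    sd = np.sqrt(
        2.0 * var_subject_device + 2.0 * var_device_activity + 2.0 * var_resid
    )
    return device_diff + rng.normal(0.0, sd, size=n)
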