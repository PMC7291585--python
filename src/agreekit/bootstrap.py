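"""Subject-level (cluster) nonparametric bootstrap for agreement indices.

Whole subjects are resampled with replacement — the clusters in these
designs — so within-subject dependence is preserved; activities travel
with their subject and are never resampled independently.  Intervals are
percentile intervals of the replicate index values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .data import MeasurementTable, PairedDifferenceTable, pair_differences
from .errors import DataError
from .indices import (
    ccc_repeated,
    cia,
    coverage_probability,
    loa_from_diff_model,
    msd,
    tdi,
)
from .lmm import fit_diff_model, fit_full_model

logger = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "cluster_bootstrap", "make_index_fn", "INDEX_PIPELINES"]


@dataclass
class BootstrapResult:
    index_name: str
    estimates: np.ndarray
    n_failed: int
    ci: tuple[float, float]
    conf: float
    seed: int
    B: int
    unreliable: bool = False
    point: float | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "index_name": self.index_name,
            "point": self.point,
            "ci": [float(self.ci[0]), float(self.ci[1])],
            "conf": self.conf,
            "B": self.B,
            "n_failed": self.n_failed,
            "unreliable": self.unreliable,
            "seed": self.seed,
        }

    def estimates_to_csv(self, path) -> None:
        pd.DataFrame({self.index_name: self.estimates}).to_csv(path, index=False)


def resample_subjects(
    table: MeasurementTable, rng: np.random.Generator
) -> MeasurementTable:
    """One cluster-bootstrap resample: subjects drawn with replacement and
    relabeled uniquely so repeated draws stay distinct clusters."""
    subjects = table.subjects
    picks = rng.choice(len(subjects), size=len(subjects), replace=True)
    idx_map = table.data.groupby("subject").indices
    chunks = [idx_map[subjects[j]] for j in picks]
    df = table.data.take(np.concatenate(chunks)).reset_index(drop=True)
    df["subject"] = np.repeat(
        [f"b{i:03d}" for i in range(len(picks))], [len(c) for c in chunks]
    )
    return MeasurementTable(
        df, reference_device=table.reference_device, test_device=table.test_device
    )


def resample_pairs_by_subject(
    pairs: PairedDifferenceTable, rng: np.random.Generator
) -> PairedDifferenceTable:
    subjects = pairs.subjects
    picks = rng.choice(len(subjects), size=len(subjects), replace=True)
    idx_map = pairs.data.groupby("subject").indices
    chunks = [idx_map[subjects[j]] for j in picks]
    df = pairs.data.take(np.concatenate(chunks)).reset_index(drop=True)
    df["subject"] = np.repeat(
        [f"b{i:03d}" for i in range(len(picks))], [len(c) for c in chunks]
    )
    return PairedDifferenceTable(data=df, orientation=pairs.orientation)


def cluster_bootstrap(
    table: MeasurementTable,
    index_fn: "Callable[[MeasurementTable], float] | str",
    B: int = 1000,
    conf: float = 0.95,
    seed: int = 0,
    index_name: str | None = None,
    max_failure_rate: float = 0.2,
    **pipeline_kwargs,
) -> BootstrapResult:
    """Percentile bootstrap CI for an index, resampling subjects.

    ``index_fn`` is either a callable mapping a MeasurementTable to a
    scalar or the name of a built-in pipeline (see ``INDEX_PIPELINES``).
    Replicates whose refit raises are skipped and counted; if more than
    ``max_failure_rate`` of them fail the result is flagged unreliable.
    Deterministic given (data, B, seed).
    """
    if table.n_subjects < 2:
        raise DataError("cluster bootstrap needs at least 2 subjects")
    if B < 1:
        raise DataError("B must be >= 1")
    if isinstance(index_fn, str):
        index_name = index_name or index_fn
        index_fn = make_index_fn(index_fn, table=table, **pipeline_kwargs)
    index_name = index_name or getattr(index_fn, "__name__", "index")

    rng = np.random.default_rng(seed)
    estimates = []
    n_failed = 0
    for _ in range(B):
        resample = resample_subjects(table, rng)
        try:
            estimates.append(float(index_fn(resample)))
        except Exception as e:  # noqa: BLE001 - any refit failure is skipped
            logger.debug("bootstrap replicate failed: %s", e)
            n_failed += 1
    if not estimates:
        raise DataError("every bootstrap replicate failed")
    est = np.asarray(estimates)
    alpha = (1.0 - conf) / 2.0
    ci = (float(np.quantile(est, alpha)), float(np.quantile(est, 1.0 - alpha)))
    point = None
    try:
        point = float(index_fn(table))
    except Exception:  # noqa: BLE001
        pass
    return BootstrapResult(
        index_name=index_name,
        estimates=est,
        n_failed=n_failed,
        ci=ci,
        conf=conf,
        seed=seed,
        B=B,
        unreliable=n_failed > max_failure_rate * B,
        point=point,
    )


# ---------------------------------------------------------------------------
# named index pipelines (table -> scalar), with warm-started refits


def make_index_fn(
    name: str,
    table: MeasurementTable | None = None,
    delta: float = 5.0,
    p: float = 0.95,
    multiplier: float = 1.96,
    n_starts: int = 1,
) -> Callable[[MeasurementTable], float]:
    """Build a named index pipeline.

    When the original ``table`` is given, the parent model is fitted once
    and its variance ratios warm-start every bootstrap refit, which cuts
    refit cost substantially without changing the optimum sought.
    """
    if name not in INDEX_PIPELINES:
        raise DataError(f"unknown index pipeline {name!r}; have {sorted(INDEX_PIPELINES)}")
    uses_full, extract = INDEX_PIPELINES[name]
    warm = None
    if table is not None:
        try:
            if uses_full:
                parent = fit_full_model(table)
                if parent.engine is not None and parent.var_resid > 0:
                    warm = np.array(
                        [
                            parent.engine.var_components[t]
                            for t in parent.engine.var_components
                        ]
                    ) / parent.var_resid
            else:
                parent = fit_diff_model(pair_differences(table))
                if parent.engine is not None and parent.var_resid_star > 0:
                    warm = np.array(
                        [
                            parent.engine.var_components[t]
                            for t in parent.engine.var_components
                        ]
                    ) / parent.var_resid_star
        except Exception:  # noqa: BLE001 - warm start is best-effort
            warm = None

    def pipeline(tbl: MeasurementTable) -> float:
        if uses_full:
            fit = fit_full_model(tbl, n_starts=n_starts, start_ratios=warm)
            return extract(fit, delta=delta, p=p, multiplier=multiplier)
        fit = fit_diff_model(pair_differences(tbl), n_starts=n_starts, start_ratios=warm)
        return extract(fit, delta=delta, p=p, multiplier=multiplier)

    pipeline.__name__ = name
    return pipeline


INDEX_PIPELINES: dict[str, tuple[bool, Callable]] = {
    "ccc": (True, lambda fit, **kw: ccc_repeated(fit)),
    "msd": (True, lambda fit, **kw: msd(fit)),
    "cp": (True, lambda fit, *, delta, **kw: coverage_probability(msd(fit), delta)),
    "tdi": (True, lambda fit, *, p, **kw: tdi(msd(fit), p)),
    "cia": (True, lambda fit, **kw: cia(fit)),
    "loa_lower": (
        False,
        lambda fit, *, multiplier, **kw: loa_from_diff_model(fit, multiplier)[1],
    ),
    "loa_upper": (
        False,
        lambda fit, *, multiplier, **kw: loa_from_diff_model(fit, multiplier)[2],
    ),
    "bias": (False, lambda fit, **kw: fit.mu0_star),
}
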