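"""Long-format measurement tables and time-matched paired differences.

Data are stored in long format with one row per reading: a subject
identifier, a device label (exactly two levels per analysis, one of which
is flagged as the reference or "gold standard"), an activity/condition
label, an integer replicate index within (subject, device, activity), and
a continuous measurement value.  Replicates stand in for measurement
times: readings taken under the same subject, device and activity are
treated as exchangeable replications, and pairing across devices is by
replicate index.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "MeasurementTable",
    "PairedDifferenceTable",
    "read_measurements",
    "pair_differences",
]

#: canonical column order of the internal long-format frame
COLUMNS = ["subject", "device", "activity", "replicate", "value"]

#: default CSV column mapping (canonical name -> file column name)
DEFAULT_MAPPING = {
    "subject": "subject",
    "device": "device",
    "activity": "activity",
    "time": "time",
    "value": "value",
}


@dataclass(frozen=True)
class MeasurementTable:
    """Validated long-format table of readings from two devices.

    Parameters
    ----------
    data:
        Frame with columns ``subject``, ``device``, ``activity``,
        ``replicate``, ``value``.  Labels are opaque strings; replicate is
        a positive integer index within (subject, device, activity).
    reference_device:
        Label of the gold-standard device.
    test_device:
        Label of the device under evaluation.
    validation:
        Structured validation report (row counts per subject / device /
        activity) attached at construction time.
    """

    data: pd.DataFrame
    reference_device: str
    test_device: str
    validation: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        _validate_measurements(self.data, self.reference_device, self.test_device)

    def summary(self) -> dict:
        """Row counts per subject / device / activity (computed on demand)."""
        return _validation_report(self.data)

    # -- convenience accessors -------------------------------------------
    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject"].unique())

    @property
    def activities(self) -> list[str]:
        return sorted(self.data["activity"].unique())

    @property
    def n_subjects(self) -> int:
        return self.data["subject"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def with_devices_swapped(self) -> "MeasurementTable":
        """Return the same table with reference and test roles exchanged."""
        return MeasurementTable(
            data=self.data.copy(),
            reference_device=self.test_device,
            test_device=self.reference_device,
        )

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class PairedDifferenceTable:
    """Time-matched between-device differences.

    One row per complete (subject, activity, replicate) pair, with
    ``diff = test - reference`` (sign configurable at construction) and
    ``avg = (test + reference) / 2`` — the ordinate and abscissa of a
    Bland-Altman plot.
    """

    data: pd.DataFrame  # columns: subject, activity, replicate, diff, avg
    n_dropped: int = 0
    orientation: str = "test_minus_reference"

    def __post_init__(self) -> None:
        missing = {"subject", "activity", "replicate", "diff", "avg"} - set(
            self.data.columns
        )
        if missing:
            raise DataError(f"paired-difference table missing columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise DataError("no complete device pairs: cannot build difference table")
        if not np.all(np.isfinite(self.data["diff"].to_numpy(float))):
            raise DataError("non-finite paired differences")

    @property
    def diffs(self) -> np.ndarray:
        return self.data["diff"].to_numpy(float)

    @property
    def avgs(self) -> np.ndarray:
        return self.data["avg"].to_numpy(float)

    @property
    def n_pairs(self) -> int:
        return len(self.data)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.data["subject"].unique())

    def pairs_per_subject(self) -> pd.Series:
        return self.data.groupby("subject").size()

    def to_csv(self, path: str | Path) -> None:
        self.data[["subject", "activity", "replicate", "diff", "avg"]].to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# construction


def read_measurements(
    path: str | Path | io.IOBase,
    mapping: Mapping[str, str] | None = None,
    reference_device: str | None = None,
    test_device: str | None = None,
    delimiter: str = ",",
) -> MeasurementTable:
    """Read a long-format CSV of device readings.

    Parameters
    ----------
    path:
        CSV file (UTF-8, header row) or open text handle.
    mapping:
        Column-name mapping with keys ``subject``, ``device``, ``activity``,
        ``value`` and optionally ``time``.  Unmapped keys fall back to the
        canonical names.  If no time/replicate column is present, replicate
        indices are synthesized in file order within each
        (subject, device, activity) cell.
    reference_device:
        Label of the gold-standard device.  Required when it cannot be
        guessed; must be one of the device levels.
    test_device:
        Optional label of the test device; used to subset a device column
        with more than two levels.
    """
    colmap = dict(DEFAULT_MAPPING)
    if mapping:
        unknown = set(mapping) - set(DEFAULT_MAPPING)
        if unknown:
            raise ConfigurationError(f"unknown mapping keys: {sorted(unknown)}")
        colmap.update({k: v for k, v in mapping.items() if v})

    if isinstance(path, (str, Path)):
        if not Path(path).exists():
            raise ConfigurationError(f"input file not found: {path}")
        raw = pd.read_csv(path, sep=delimiter, dtype=str)
    else:
        raw = pd.read_csv(path, sep=delimiter, dtype=str)

    required = ["subject", "device", "activity", "value"]
    for key in required:
        if colmap[key] not in raw.columns:
            raise ConfigurationError(
                f"column {colmap[key]!r} (mapped from {key!r}) not present in input; "
                f"available: {list(raw.columns)}"
            )

    df = pd.DataFrame(
        {
            "subject": raw[colmap["subject"]].astype(str),
            "device": raw[colmap["device"]].astype(str),
            "activity": raw[colmap["activity"]].astype(str),
        }
    )
    values = pd.to_numeric(raw[colmap["value"]], errors="coerce")
    bad = values.isna() & raw[colmap["value"]].notna()
    if bad.any():
        rows = (np.flatnonzero(bad.to_numpy()) + 2).tolist()  # 1-based incl. header
        raise DataError(f"non-numeric measurement value at file row(s) {rows[:10]}")
    if values.isna().any():
        rows = (np.flatnonzero(values.isna().to_numpy()) + 2).tolist()
        raise DataError(f"missing measurement value at file row(s) {rows[:10]}")
    df["value"] = values.astype(float)

    if colmap["time"] in raw.columns:
        df["replicate"] = _replicates_from_time(df, raw[colmap["time"]])
    else:
        df["replicate"] = df.groupby(
            ["subject", "device", "activity"], sort=False
        ).cumcount() + 1

    devices = sorted(df["device"].unique())
    if test_device is not None or (reference_device is not None and len(devices) > 2):
        keep = {reference_device, test_device} - {None}
        df = df[df["device"].isin(keep)].reset_index(drop=True)
        devices = sorted(df["device"].unique())
    if len(devices) != 2:
        raise DataError(
            f"device column must have exactly 2 levels after subsetting, got {devices}"
        )
    if reference_device is None:
        raise ConfigurationError(
            f"reference_device must be specified; device levels are {devices}"
        )
    if reference_device not in devices:
        raise DataError(
            f"reference device {reference_device!r} not among device levels {devices}"
        )
    test = next(d for d in devices if d != reference_device)
    df = df[COLUMNS]
    return MeasurementTable(
        df,
        reference_device=reference_device,
        test_device=test,
        validation=_validation_report(df),
    )


def _replicates_from_time(df: pd.DataFrame, time_col: pd.Series) -> np.ndarray:
    """Rank readings within each (subject, device, activity) by time value."""
    t = pd.to_numeric(time_col, errors="coerce")
    if t.isna().any():  # opaque time labels: rank lexically, stable
        t = time_col.astype(str)
    key = df[["subject", "device", "activity"]].copy()
    key["t"] = t.to_numpy()
    ranks = key.groupby(["subject", "device", "activity"], sort=False)["t"].rank(
        method="first"
    )
    return ranks.astype(int).to_numpy()


def from_records(
    records: pd.DataFrame | Sequence[tuple],
    reference_device: str,
    test_device: str,
) -> MeasurementTable:
    """Build a MeasurementTable from in-memory rows (subject, device,
    activity, replicate, value)."""
    df = pd.DataFrame(records, columns=COLUMNS) if not isinstance(
        records, pd.DataFrame
    ) else records[COLUMNS].copy()
    for col in ("subject", "device", "activity"):
        df[col] = df[col].astype(str)
    df["replicate"] = df["replicate"].astype(int)
    df["value"] = df["value"].astype(float)
    return MeasurementTable(df, reference_device=reference_device, test_device=test_device)


def pair_differences(
    table: MeasurementTable, orientation: str = "test_minus_reference"
) -> PairedDifferenceTable:
    """Construct time-matched paired differences from a measurement table.

    Rows exist only where both devices have a reading at the same
    (subject, activity, replicate); incomplete pairs are dropped and
    counted in ``n_dropped``.  With the default orientation,
    ``diff = test - reference``.
    """
    if orientation not in ("test_minus_reference", "reference_minus_test"):
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    wide = table.data.pivot_table(
        index=["subject", "activity", "replicate"],
        columns="device",
        values="value",
        aggfunc="first",
    )
    ref, tst = table.reference_device, table.test_device
    complete = wide.dropna(subset=[ref, tst])
    n_dropped = len(wide) - len(complete)
    if len(complete) == 0:
        raise DataError("zero complete device pairs")
    diff = complete[tst] - complete[ref]
    if orientation == "reference_minus_test":
        diff = -diff
    out = complete.reset_index()[["subject", "activity", "replicate"]].copy()
    out["diff"] = diff.to_numpy(float)
    out["avg"] = ((complete[tst] + complete[ref]) / 2.0).to_numpy(float)
    return PairedDifferenceTable(
        data=out.reset_index(drop=True), n_dropped=n_dropped, orientation=orientation
    )


# ---------------------------------------------------------------------------
# validation helpers


def _validate_measurements(df: pd.DataFrame, reference: str, test: str) -> None:
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"measurement table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(df["value"].to_numpy(float))):
        raise DataError("non-finite measurement values")
    devices = set(df["device"].unique())
    if devices != {reference, test}:
        raise DataError(
            f"device levels {sorted(devices)} do not match "
            f"reference={reference!r}, test={test!r}"
        )
    if df["subject"].nunique() < 2:
        raise DataError("need at least 2 distinct subjects")
    if (df["replicate"].to_numpy(int) < 1).any():
        raise DataError("replicate indices must be >= 1")
    dup = df.duplicated(subset=["subject", "device", "activity", "replicate"])
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise DataError(
            "duplicate record for (subject, device, activity, replicate) = "
            f"({first['subject']}, {first['device']}, {first['activity']}, "
            f"{first['replicate']})"
        )


def _validation_report(df: pd.DataFrame) -> dict:
    return {
        "n_obs": int(len(df)),
        "n_subjects": int(df["subject"].nunique()),
        "n_activities": int(df["activity"].nunique()),
        "obs_per_device": df.groupby("device").size().to_dict(),
        "obs_per_subject": df.groupby("subject").size().to_dict(),
        "obs_per_activity": df.groupby("activity").size().to_dict(),
    }
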