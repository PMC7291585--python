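"""Agreement indices computed from fitted variance components.

Five indices are provided: the repeated-measures concordance correlation
coefficient (a variance-ratio ICC), mixed-effects limits of agreement
(from either the differences model or the full two-device model), the
coverage probability, the total deviation index, and the coefficient of
individual agreement.  All are deterministic functions of variance
components and the mean device difference, so they can be evaluated
either on a fresh REML fit or on published component values via
``FullModelFit.from_components`` / ``DiffModelFit.from_components``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .data import MeasurementTable, PairedDifferenceTable
from .errors import DataError, UndefinedIndexError
from .lmm import DiffModelFit, FullModelFit

__all__ = [
    "AgreementSettings",
    "AgreementReport",
    "ccc_repeated",
    "msd",
    "coverage_probability",
    "tdi",
    "cia",
    "repeatability_coefficient",
    "loa_from_diff_model",
    "loa_from_full_model",
    "naive_indices",
    "anova_loa",
    "build_report",
]


@dataclass(frozen=True)
class AgreementSettings:
    """Decision thresholds for agreement verdicts.

    ``cad_delta`` is the clinically acceptable difference half-width, in
    measurement units; it must be fixed before analysis.  ``tdi_p`` is the
    containment probability for the TDI.
    """

    cad_delta: float = 5.0
    tdi_p: float = 0.95
    cp_threshold: float = 0.95
    cia_threshold: float = 0.8
    loa_multiplier: float = 1.96
    ccc_threshold: float | None = None

    def __post_init__(self) -> None:
        if not (self.cad_delta > 0):
            raise DataError("cad_delta must be positive")
        if not (0 < self.tdi_p < 1):
            raise DataError("tdi_p must lie in (0, 1)")
        if not (0 < self.cp_threshold <= 1) or not (0 < self.cia_threshold <= 1):
            raise DataError("thresholds must lie in (0, 1]")


# ---------------------------------------------------------------------------
# index functions


def ccc_repeated(fit: FullModelFit) -> float:
    """Concordance correlation coefficient for repeated measurements.

    Under a fixed device effect this coincides with the intraclass
    correlation: the ratio of the subject/activity-attributable variance
    to the total variance including the fixed-device contribution
    (sum of the two squared device effects).
    """
    num = fit.var_subject + fit.var_activity + fit.var_subject_activity
    den = (
        num
        + fit.phi_beta_sq
        + fit.var_subject_device
        + fit.var_device_activity
        + fit.var_resid
    )
    if den <= 0:
        raise UndefinedIndexError(
            "total variance is zero: CCC undefined (no variability to apportion)"
        )
    return num / den


def msd(fit: FullModelFit) -> float:
    """Mean squared deviation between time-matched readings of the two
    devices: squared mean device difference plus twice the sum of the
    subject-device, device-activity and residual variances."""
    return fit.device_diff**2 + 2.0 * (
        fit.var_subject_device + fit.var_device_activity + fit.var_resid
    )


def coverage_probability(msd_value: float, delta: float) -> float:
    """Probability that a between-device difference falls within ±delta,
    assuming normal differences with the given mean squared deviation."""
    if msd_value < 0:
        raise DataError("msd_value must be non-negative")
    if delta <= 0:
        raise DataError("delta must be positive")
    if msd_value == 0:
        return 1.0
    return float(1.0 - 2.0 * (1.0 - norm.cdf(delta / math.sqrt(msd_value))))


def tdi(msd_value: float, p: float = 0.95) -> float:
    """Total deviation index: half-width containing a proportion ``p`` of
    between-device differences; the inverse of the coverage probability."""
    if msd_value < 0:
        raise DataError("msd_value must be non-negative")
    if not (0 < p < 1):
        raise DataError("p must lie in (0, 1)")
    return float(norm.ppf((1.0 + p) / 2.0) * math.sqrt(msd_value))


def cia(fit: FullModelFit) -> float:
    """Coefficient of individual agreement: within-device replication MSD
    (twice the residual variance) over the between-device MSD."""
    if fit.var_resid <= 0:
        raise UndefinedIndexError(
            "residual variance is zero: the within-device replication "
            "benchmark is degenerate and the CIA is undefined"
        )
    return 2.0 * fit.var_resid / msd(fit)


def repeatability_coefficient(fit: FullModelFit, multiplier: float = 1.96) -> float:
    """95% bound on the difference between two replicate readings by the
    same device under identical conditions."""
    return float(multiplier * math.sqrt(2.0 * fit.var_resid))


def loa_from_diff_model(
    diff_fit: DiffModelFit, multiplier: float = 1.96
) -> tuple[float, float, float]:
    """Limits of agreement from the paired-differences model.

    Bias is the bias-only sub-model mean; the standard deviation sums the
    subject, activity and residual variances of the differences model.
    Returns ``(bias, lower, upper)``.
    """
    bias = diff_fit.mu0_star
    sd = math.sqrt(
        diff_fit.var_subject_star + diff_fit.var_activity_star + diff_fit.var_resid_star
    )
    return (bias, bias - multiplier * sd, bias + multiplier * sd)


def loa_from_full_model(
    fit: FullModelFit, multiplier: float = 1.96
) -> tuple[float, float, float]:
    """Limits of agreement implied by the full two-device model: bias is
    the mean device difference and the difference variance is twice the
    sum of subject-device, device-activity and residual variances."""
    bias = fit.device_diff
    half = multiplier * math.sqrt(
        2.0 * (fit.var_subject_device + fit.var_device_activity + fit.var_resid)
    )
    return (bias, bias - half, bias + half)


def naive_indices(
    pairs: PairedDifferenceTable,
    raw: MeasurementTable | None = None,
    multiplier: float = 1.96,
) -> dict:
    """Naive agreement summaries that ignore clustering.

    Returns Pearson's correlation of the paired readings, Lin's
    concordance correlation coefficient, and simple limits of agreement
    (mean difference ± multiplier x SD of differences).  Reported for
    comparison only: with repeated measures per subject these intervals
    are biased.
    """
    d = pairs.diffs
    a = pairs.avgs
    if len(d) < 3:
        raise DataError("need at least 3 pairs for naive indices")
    test = a + d / 2.0
    ref = a - d / 2.0
    s1 = float(np.var(ref, ddof=1))
    s2 = float(np.var(test, ddof=1))
    if s1 <= 0 or s2 <= 0:
        raise UndefinedIndexError("zero variance in one device: correlation undefined")
    s12 = float(np.cov(ref, test, ddof=1)[0, 1])
    pearson = s12 / math.sqrt(s1 * s2)
    m1, m2 = float(np.mean(ref)), float(np.mean(test))
    # Lin's CCC uses the biased (maximum-likelihood) moments
    n = len(d)
    s1_ml, s2_ml, s12_ml = (
        s1 * (n - 1) / n,
        s2 * (n - 1) / n,
        s12 * (n - 1) / n,
    )
    lin = 2.0 * s12_ml / (s1_ml + s2_ml + (m1 - m2) ** 2)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return {
        "pearson": pearson,
        "lin_ccc": lin,
        "bias": bias,
        "simple_loa": (bias - multiplier * sd, bias + multiplier * sd),
    }


def anova_loa(
    pairs: PairedDifferenceTable, multiplier: float = 1.96
) -> tuple[float, float, float]:
    """Fixed-effects one-way ANOVA limits of agreement on the differences.

    The total difference variance is the sum of the within-subject mean
    square and the between-subject component (MSB - MSW) / n0, truncated
    at zero, with n0 the unbalanced-design average cluster size
    [sum(m_i) - sum(m_i^2)/sum(m_i)] / (k - 1).
    """
    df = pairs.data
    groups = df.groupby("subject")["diff"]
    k = groups.ngroups
    if k < 2:
        raise DataError("need at least 2 subjects for the ANOVA limits of agreement")
    m = groups.size().to_numpy(float)
    if (m <= 1).all():
        raise DataError(
            "all subjects have a single difference: within-subject variance "
            "is inestimable; use the mixed-model limits of agreement instead"
        )
    d = df["diff"].to_numpy(float)
    grand = float(np.mean(d))
    means = groups.mean().to_numpy(float)
    ssw = float(groups.apply(lambda g: ((g - g.mean()) ** 2).sum()).sum())
    msw = ssw / (m.sum() - k)
    msb = float((m * (means - grand) ** 2).sum()) / (k - 1)
    n0 = (m.sum() - (m**2).sum() / m.sum()) / (k - 1)
    var_between = max((msb - msw) / n0, 0.0)
    sd = math.sqrt(var_between + msw)
    return (grand, grand - multiplier * sd, grand + multiplier * sd)


# ---------------------------------------------------------------------------
# report assembly


@dataclass
class AgreementReport:
    """All computable agreement indices, with verdicts and provenance."""

    settings: AgreementSettings
    ccc: float | None = None
    msd: float | None = None
    cp: float | None = None
    tdi: float | None = None
    cia: float | None = None
    repeatability: float | None = None
    loa: dict = field(default_factory=dict)  # source -> (bias, lower, upper)
    naive: dict | None = None
    intervals: dict = field(default_factory=dict)  # index name -> (lo, hi)
    verdicts: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["settings"] = asdict(self.settings)
        return out

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), default=_jsonable, **kw)

    def to_text(self) -> str:
        s = self.settings
        lines = ["Agreement summary", "================="]

        def fmt(x, nd=3):
            return "n/a" if x is None else f"{x:.{nd}f}"

        if "diff_model" in self.loa:
            b, lo, hi = self.loa["diff_model"]
            lines.append(
                f"Mean bias {b:.2f} ({s.loa_multiplier:g}x LoA {lo:.2f} to {hi:.2f})"
                f"  [differences model]  -> {self.verdicts.get('loa', 'n/a')}"
            )
        for src in ("full_model", "anova", "naive"):
            if src in self.loa:
                b, lo, hi = self.loa[src]
                lines.append(f"  LoA [{src}]: bias {b:.2f}, {lo:.2f} to {hi:.2f}")
        lines.append(f"CCC  {fmt(self.ccc)}  -> {self.verdicts.get('ccc', 'no threshold set')}")
        lines.append(f"MSD  {fmt(self.msd, 1)}")
        lines.append(
            f"CP(delta={s.cad_delta:g})  {fmt(self.cp, 2)}  -> {self.verdicts.get('cp', 'n/a')}"
        )
        lines.append(
            f"TDI(p={s.tdi_p:g})  {fmt(self.tdi, 1)}  -> {self.verdicts.get('tdi', 'n/a')}"
        )
        lines.append(f"CIA  {fmt(self.cia, 2)}  -> {self.verdicts.get('cia', 'n/a')}")
        lines.append(f"Repeatability coefficient  {fmt(self.repeatability, 2)}")
        for name, (lo, hi) in self.intervals.items():
            lines.append(f"  95% CI [{name}]: {lo:.3f} to {hi:.3f}")
        if self.flags:
            lines.append("Flags: " + "; ".join(self.flags))
        return "\n".join(lines)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")


def build_report(
    full_fit: FullModelFit | None = None,
    diff_fit: DiffModelFit | None = None,
    pairs: PairedDifferenceTable | None = None,
    settings: AgreementSettings | None = None,
    intervals: dict | None = None,
) -> AgreementReport:
    """Assemble an agreement report from whichever fits are available.

    Verdicts follow the usual decision rules: the devices "agree" by the
    LoA criterion when both limits fall inside ±delta, by the CP criterion
    when CP >= its threshold, by the TDI criterion when TDI <= delta, and
    by the CIA criterion when CIA >= its threshold.  The CCC gets a
    verdict only when an explicit threshold is supplied, since an
    acceptable CCC level must be agreed in advance.
    """
    if full_fit is None and diff_fit is None:
        raise DataError("at least one fitted model is required")
    settings = settings or AgreementSettings()
    rpt = AgreementReport(settings=settings)
    delta, p, m = settings.cad_delta, settings.tdi_p, settings.loa_multiplier

    if full_fit is not None:
        rpt.msd = msd(full_fit)
        rpt.cp = coverage_probability(rpt.msd, delta)
        rpt.tdi = tdi(rpt.msd, p)
        rpt.repeatability = repeatability_coefficient(full_fit, m)
        try:
            rpt.ccc = ccc_repeated(full_fit)
        except UndefinedIndexError as e:
            rpt.flags.append(f"ccc undefined: {e}")
        try:
            rpt.cia = cia(full_fit)
        except UndefinedIndexError as e:
            rpt.flags.append(f"cia undefined: {e}")
        rpt.loa["full_model"] = loa_from_full_model(full_fit, m)
        rpt.provenance.update(
            {k: "full_model" for k in ("msd", "cp", "tdi", "cia", "ccc", "repeatability")}
        )
        if full_fit.boundary:
            rpt.flags.append(
                f"full model variance components at boundary: {full_fit.boundary}"
            )
    if diff_fit is not None:
        rpt.loa["diff_model"] = loa_from_diff_model(diff_fit, m)
        rpt.provenance["loa"] = "diff_model"
        if diff_fit.boundary:
            rpt.flags.append(
                f"differences model variance components at boundary: {diff_fit.boundary}"
            )
    else:
        rpt.provenance["loa"] = "full_model"
    if pairs is not None:
        try:
            rpt.naive = naive_indices(pairs, multiplier=m)
            rpt.loa["naive"] = (
                rpt.naive["bias"],
                rpt.naive["simple_loa"][0],
                rpt.naive["simple_loa"][1],
            )
        except (DataError, UndefinedIndexError) as e:
            rpt.flags.append(f"naive indices unavailable: {e}")
        try:
            rpt.loa["anova"] = anova_loa(pairs, m)
        except DataError as e:
            rpt.flags.append(f"anova LoA unavailable: {e}")

    # verdicts (primary LoA source: differences model when available)
    primary = rpt.loa.get("diff_model") or rpt.loa.get("full_model")
    if primary is not None:
        _, lo, hi = primary
        rpt.verdicts["loa"] = "agree" if (lo >= -delta and hi <= delta) else "do not agree"
    if rpt.cp is not None:
        rpt.verdicts["cp"] = (
            "agree" if rpt.cp >= settings.cp_threshold else "do not agree"
        )
    if rpt.tdi is not None:
        rpt.verdicts["tdi"] = "agree" if rpt.tdi <= delta else "do not agree"
    if rpt.cia is not None:
        rpt.verdicts["cia"] = (
            "agree" if rpt.cia >= settings.cia_threshold else "do not agree"
        )
    if rpt.ccc is not None and settings.ccc_threshold is not None:
        rpt.verdicts["ccc"] = (
            "agree" if rpt.ccc >= settings.ccc_threshold else "do not agree"
        )
    rpt.intervals = dict(intervals or {})
    return rpt
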