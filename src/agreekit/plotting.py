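"""Bland-Altman plot data (and optional rendering).

The tested artifact is the JSON-serializable spec: scatter points of
paired differences against pair averages, plus bias / limit lines and
optional clinically-acceptable-difference and bootstrap-CI lines.
Rendering to an image is best-effort and headless-safe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import PairedDifferenceTable
from .errors import DataError
from .indices import AgreementReport, AgreementSettings

__all__ = ["BlandAltmanSpec", "bland_altman"]


@dataclass
class BlandAltmanSpec:
    points_avg: list[float]
    points_diff: list[float]
    bias: float
    loa_lower: float
    loa_upper: float
    cad: float | None = None
    ci_lines: dict = field(default_factory=dict)  # line name -> (lo, hi)
    source: str = "diff_model"

    def to_dict(self) -> dict:
        return {
            "points_avg": [float(x) for x in self.points_avg],
            "points_diff": [float(x) for x in self.points_diff],
            "bias": float(self.bias),
            "loa_lower": float(self.loa_lower),
            "loa_upper": float(self.loa_upper),
            "cad": None if self.cad is None else float(self.cad),
            "ci_lines": {k: [float(a), float(b)] for k, (a, b) in self.ci_lines.items()},
            "source": self.source,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_json(cls, text: str) -> "BlandAltmanSpec":
        d = json.loads(text)
        d["ci_lines"] = {k: tuple(v) for k, v in d.get("ci_lines", {}).items()}
        return cls(**d)

    def render(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 5))
        ax.scatter(self.points_avg, self.points_diff, s=18, alpha=0.7, color="k")
        ax.axhline(self.bias, color="red", ls="--", label=f"bias {self.bias:.2f}")
        ax.axhline(self.loa_lower, color="blue", ls="--", label="limits of agreement")
        ax.axhline(self.loa_upper, color="blue", ls="--")
        if self.cad is not None:
            ax.axhline(self.cad, color="green", ls=":", label=f"CAD ±{self.cad:g}")
            ax.axhline(-self.cad, color="green", ls=":")
        for lo, hi in self.ci_lines.values():
            ax.axhline(lo, color="grey", ls=":", lw=0.8)
            ax.axhline(hi, color="grey", ls=":", lw=0.8)
        ax.set_xlabel("average of paired readings")
        ax.set_ylabel("difference (test − reference)")
        ax.legend(loc="best", fontsize=8)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def bland_altman(
    pairs: PairedDifferenceTable,
    report: AgreementReport,
    settings: AgreementSettings | None = None,
) -> BlandAltmanSpec:
    """Build a Bland-Altman spec from a difference table and a report.

    Uses the report's primary limits-of-agreement source (the differences
    model when present, otherwise the full model).
    """
    if pairs.n_pairs == 0:
        raise DataError("no pairs to plot")
    settings = settings or report.settings
    source = "diff_model" if "diff_model" in report.loa else "full_model"
    if source not in report.loa:
        raise DataError("report carries no limits of agreement")
    bias, lo, hi = report.loa[source]
    ci_lines = {
        k: v for k, v in report.intervals.items() if k in ("bias", "loa_lower", "loa_upper")
    }
    return BlandAltmanSpec(
        points_avg=list(np.asarray(pairs.avgs, float)),
        points_diff=list(np.asarray(pairs.diffs, float)),
        bias=bias,
        loa_lower=lo,
        loa_upper=hi,
        cad=settings.cad_delta,
        ci_lines=ci_lines,
        source=source,
    )
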