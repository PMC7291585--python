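"""Model-assumption diagnostics: Q-Q data for every random-effect vector
and for residuals, residual-vs-fitted pairs, and simple skewness flags.

Agreement indices inherit the mixed model's assumptions (independent
subjects, normal random effects, normal errors, constant variability and
fixed bias across the measurement range), so each fit should be checked
before its indices are trusted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConvergenceError
from .lmm import DiffModelFit, FullModelFit, REMLFit

__all__ = ["DiagnosticsBundle", "model_diagnostics", "qq_data"]

#: |sample skewness| beyond this trips the non-normality flag
SKEW_FLAG_THRESHOLD = 1.0


def qq_data(values: np.ndarray) -> dict[str, np.ndarray]:
    """Sorted sample quantiles against standard-normal plotting positions
    ((i - 0.5) / n)."""
    v = np.sort(np.asarray(values, float))
    n = v.size
    theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n) if n else np.empty(0)
    return {"theoretical": theo, "sample": v}


@dataclass
class DiagnosticsBundle:
    qq: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    residual_vs_fitted: dict[str, np.ndarray] = field(default_factory=dict)
    standardized_residual_vs_fitted: dict[str, np.ndarray] = field(default_factory=dict)
    skewness: dict[str, float] = field(default_factory=dict)
    flags: dict[str, bool] = field(default_factory=dict)

    def to_dict(self) -> dict:
        tolist = lambda d: {k: np.asarray(v).tolist() for k, v in d.items()}  # noqa: E731
        return {
            "qq": {name: tolist(d) for name, d in self.qq.items()},
            "residual_vs_fitted": tolist(self.residual_vs_fitted),
            "standardized_residual_vs_fitted": tolist(
                self.standardized_residual_vs_fitted
            ),
            "skewness": {k: float(v) for k, v in self.skewness.items()},
            "flags": dict(self.flags),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _engine_of(fit) -> REMLFit:
    if isinstance(fit, REMLFit):
        return fit
    engine = getattr(fit, "engine", None)
    if engine is None:
        raise ConvergenceError(
            "fit carries no engine state; diagnostics need a model fitted "
            "from data, not one built from published components"
        )
    return engine


def model_diagnostics(fit: FullModelFit | DiffModelFit | REMLFit) -> DiagnosticsBundle:
    """Assemble Q-Q and residual diagnostics for a fitted model.

    One Q-Q block per random-effect BLUP vector plus one for residuals;
    the skew flag for a vector trips when its absolute sample skewness
    exceeds 1 (vectors with fewer than 8 points are never flagged).
    """
    engine = _engine_of(fit)
    bundle = DiagnosticsBundle()
    resid = engine.residuals()
    fitted = engine.fitted_values()
    vectors = dict(engine.blups())
    vectors["residuals"] = resid
    for name, vec in vectors.items():
        bundle.qq[name] = qq_data(vec)
        sk = float(stats.skew(vec)) if vec.size >= 3 and np.std(vec) > 0 else 0.0
        bundle.skewness[name] = sk
        bundle.flags[f"{name}_skew"] = bool(
            vec.size >= 8 and abs(sk) > SKEW_FLAG_THRESHOLD
        )
    bundle.residual_vs_fitted = {"fitted": fitted, "residual": resid}
    sd = float(np.std(resid))
    std_resid = resid / sd if sd > 0 else np.zeros_like(resid)
    bundle.standardized_residual_vs_fitted = {"fitted": fitted, "residual": std_resid}
    return bundle
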