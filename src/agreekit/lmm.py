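"""REML estimation of Gaussian linear mixed models with crossed random
intercepts.

The models handled here all have the form

    y = X b + sum_k Z_k u_k + e,      u_k ~ N(0, s2_k I),  e ~ N(0, s2_e I)

with X an intercept (plus, for the full two-device model, a sum-to-zero
device contrast) and each Z_k the indicator matrix of a crossed grouping
factor (subject, activity, subject x device, subject x activity,
device x activity).  Estimation maximizes the restricted likelihood

    l_R = -1/2 [ (n-p) log 2pi + log|V| + log|X' V^-1 X| + y' P y ]

with V = sum_k s2_k Z_k Z_k' + s2_e I and P the REML projection.  The
residual variance and the fixed effects are profiled out analytically, so
the optimizer works on the K variance *ratios* r_k = s2_k / s2_e on a
square-root scale (which allows exact boundary zeros).  Writing
W = I + sum_k r_k Z_k Z_k' and using the Woodbury identity, every
objective evaluation reduces to one factorization of the q x q capacitance
matrix M = I_q + D^{1/2} Z'Z D^{1/2} (q = total number of random-effect
levels), which is formed once from precomputed cross-products.  Dense
Cholesky is used for small q; for large crossed designs the biggest
factor (whose own block of M is diagonal) is eliminated by a Schur
complement and the small remainder is factored densely, with sparse LU
as a last resort.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize

from .data import MeasurementTable, PairedDifferenceTable
from .errors import ConvergenceError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "RandomTerm",
    "REMLFit",
    "FullModelFit",
    "DiffModelFit",
    "reml_fit",
    "fit_full_model",
    "fit_diff_model",
]

#: switch from dense Cholesky to sparse LU above this many random levels
_DENSE_Q_MAX = 600
#: convergence tolerance on the (profiled, -2x) REML criterion
_FTOL = 1e-10
#: finite-difference step for the numerical gradient; the criterion can be
#: O(1e5) so the default machine-eps step drowns in round-off
_FD_EPS = 1e-5
#: a fitted ratio below this fraction of the largest is snapped to zero
_BOUNDARY_TOL = 1e-8


@dataclass(frozen=True)
class RandomTerm:
    """A crossed random-intercept term.

    ``codes`` holds, for every observation, the integer level index of the
    grouping factor; ``levels`` the corresponding labels.
    """

    name: str
    codes: np.ndarray
    levels: tuple

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @staticmethod
    def from_labels(name: str, labels: Sequence) -> "RandomTerm":
        codes, levels = pd_factorize(labels)
        return RandomTerm(name=name, codes=codes, levels=tuple(levels))

    @staticmethod
    def interaction(name: str, a: Sequence, b: Sequence) -> "RandomTerm":
        combo = [f"{x}␟{y}" for x, y in zip(a, b)]
        return RandomTerm.from_labels(name, combo)


def pd_factorize(labels: Sequence) -> tuple[np.ndarray, np.ndarray]:
    import pandas as pd

    codes, levels = pd.factorize(np.asarray(labels), sort=True)
    return codes.astype(np.int64), np.asarray(levels)


@dataclass
class REMLFit:
    """Result of a restricted-maximum-likelihood fit.

    Attributes
    ----------
    fixed_effects:
        GLS estimates of the fixed coefficients at the variance optimum.
    var_components:
        Estimated variance per random term, in squared measurement units.
        Boundary estimates are exact zeros.
    var_resid:
        Residual variance estimate.
    reml_loglik:
        Restricted log-likelihood at the optimum, constant included
        (``-0.5 * (n - p) * log(2*pi)`` term), comparable across software.
        ``inf`` for degenerate (zero-residual) data.
    """

    fixed_names: list[str]
    fixed_effects: np.ndarray
    var_components: dict[str, float]
    var_resid: float
    reml_loglik: float
    converged: bool
    boundary: list[str]
    degenerate: bool
    n_obs: int
    message: str = ""
    dropped_terms: list[str] = field(default_factory=list)
    _problem: "_REMLProblem | None" = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "fixed_effects": dict(zip(self.fixed_names, map(float, self.fixed_effects))),
            "var_components": {k: float(v) for k, v in self.var_components.items()},
            "var_resid": float(self.var_resid),
            "reml_loglik": float(self.reml_loglik),
            "converged": bool(self.converged),
            "boundary": list(self.boundary),
            "degenerate": bool(self.degenerate),
            "n_obs": int(self.n_obs),
            "dropped_terms": list(self.dropped_terms),
            "message": self.message,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    # -- empirical BLUPs and residuals (used by diagnostics) -------------
    def blups(self) -> dict[str, np.ndarray]:
        """Empirical best linear unbiased predictors, one vector per term."""
        if self._problem is None:
            raise ConvergenceError("fit carries no design information for BLUPs")
        return self._problem.blups(self)

    def fitted_values(self) -> np.ndarray:
        if self._problem is None:
            raise ConvergenceError("fit carries no design information")
        return self._problem.fitted(self)

    def residuals(self) -> np.ndarray:
        if self._problem is None:
            raise ConvergenceError("fit carries no design information")
        return self._problem.y - self._problem.fitted(self)


class _REMLProblem:
    """Precomputed cross-products and the profiled REML objective."""

    def __init__(self, y: np.ndarray, X: np.ndarray, terms: list[RandomTerm]):
        y = np.asarray(y, float).ravel()
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if len(y) != n:
            raise DataError("response and design lengths differ")
        if n <= p:
            raise DataError("more fixed-effect parameters than observations")
        if np.linalg.matrix_rank(X) < p:
            raise DataError("singular fixed-effect design")
        self.y, self.X, self.terms = y, X, terms
        self.n, self.p = n, p

        # block structure: slice of the stacked random-effect vector per term
        sizes = [t.n_levels for t in terms]
        offs = np.concatenate([[0], np.cumsum(sizes)])
        self.q = int(offs[-1])
        self.slices = [slice(int(a), int(b)) for a, b in zip(offs[:-1], offs[1:])]

        # sparse Z' (q x n): one indicator row per random level
        rows = np.concatenate(
            [t.codes + offs[i] for i, t in enumerate(terms)]
        ) if terms else np.empty(0, np.int64)
        cols = np.tile(np.arange(n), len(terms))
        Zt = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.q, n)
        )
        self.Zt = Zt
        ZtZ = (Zt @ Zt.T).tocsc()
        self.ZtX = Zt @ X
        self.Zty = Zt @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

        # factorization strategy for M = I + D^.5 Z'Z D^.5:
        #   dense Cholesky for small q;
        #   otherwise eliminate the largest term by a Schur complement
        #   (every term's own block of Z'Z is diagonal) when the remainder
        #   is small enough; sparse LU as a last resort.
        sizes_arr = np.array(sizes) if terms else np.empty(0, int)
        if self.q <= _DENSE_Q_MAX:
            self.mode = "dense"
            self.ZtZ = ZtZ.toarray()
        elif terms and self.q - sizes_arr.max() <= 4 * _DENSE_Q_MAX:
            self.mode = "schur"
            self.ZtZ = ZtZ
            kbig = int(sizes_arr.argmax())
            self.big_slice = self.slices[kbig]
            rest_idx = np.concatenate(
                [np.arange(s.start, s.stop) for i, s in enumerate(self.slices) if i != kbig]
            )
            self.rest_idx = rest_idx
            big = ZtZ[:, self.big_slice].tocsr()
            self.big_counts = np.asarray(
                big[self.big_slice, :].diagonal()
            ).ravel()
            self.ZtZ_rr = ZtZ[:, rest_idx].tocsr()[rest_idx, :].toarray()
            self.ZtZ_rb = big[rest_idx, :].tocsr()
        else:
            self.mode = "sparse"
            self.ZtZ = ZtZ

    # -- objective -------------------------------------------------------
    def _expand(self, ratios: np.ndarray) -> np.ndarray:
        """Per-level vector of sqrt variance ratios."""
        ds = np.empty(self.q)
        for r, slc in zip(ratios, self.slices):
            ds[slc] = math.sqrt(max(r, 0.0))
        return ds

    def _factor(self, ds: np.ndarray):
        """Factor M = I + diag(ds) Z'Z diag(ds); return (logdet, solve)."""
        if self.mode == "dense":
            M = self.ZtZ * ds[:, None] * ds[None, :]
            M[np.diag_indices_from(M)] += 1.0
            c, low = sla.cho_factor(M, lower=True, check_finite=False)
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            return logdet, lambda rhs: sla.cho_solve((c, low), rhs, check_finite=False)
        if self.mode == "schur":
            ds_r = ds[self.rest_idx]
            ds_b = ds[self.big_slice]
            mb = 1.0 + ds_b * ds_b * self.big_counts  # diagonal big block of M
            B = sp.diags(ds_r) @ self.ZtZ_rb @ sp.diags(ds_b)
            S = self.ZtZ_rr * ds_r[:, None] * ds_r[None, :]
            S[np.diag_indices_from(S)] += 1.0
            S -= (B @ sp.diags(1.0 / mb) @ B.T).toarray()
            c, low = sla.cho_factor(S, lower=True, check_finite=False)
            logdet = float(np.sum(np.log(mb))) + 2.0 * float(
                np.sum(np.log(np.diag(c)))
            )

            def solve(rhs: np.ndarray) -> np.ndarray:
                rhs2 = rhs if rhs.ndim == 2 else rhs[:, None]
                rr = rhs2[self.rest_idx]
                rb = rhs2[self.big_slice]
                xb0 = rb / mb[:, None]
                xr = sla.cho_solve((c, low), rr - B @ xb0, check_finite=False)
                xb = (rb - B.T @ xr) / mb[:, None]
                out = np.empty_like(rhs2)
                out[self.rest_idx] = xr
                out[self.big_slice] = xb
                return out if rhs.ndim == 2 else out[:, 0]

            return logdet, solve
        D = sp.diags(ds)
        M = (sp.eye(self.q, format="csc") + D @ self.ZtZ @ D).tocsc()
        lu = spla.splu(M)
        # M is SPD so det > 0; |det| = prod |diag(U)|
        logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        return logdet, lu.solve

    def _core(self, ratios: np.ndarray):
        """Factor M and return (logdet W, X'W^-1 X, X'W^-1 y, y'W^-1 y)."""
        ds = self._expand(ratios)
        A = ds[:, None] * self.ZtX
        a = ds * self.Zty
        rhs = np.column_stack([A, a])
        logdet, solve = self._factor(ds)
        sol = solve(rhs)
        XtWiX = self.XtX - A.T @ sol[:, : self.p]
        XtWiy = self.Xty - A.T @ sol[:, self.p]
        ytWiy = self.yty - float(a @ sol[:, self.p])
        return logdet, XtWiX, XtWiy, ytWiy

    def profiled(self, ratios: np.ndarray):
        """Profiled -2 REML criterion (constants dropped) and byproducts."""
        logdetW, XtWiX, XtWiy, ytWiy = self._core(ratios)
        sign, logdet_xwx = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return np.inf, None
        b = np.linalg.solve(XtWiX, XtWiy)
        ypy = ytWiy - float(b @ XtWiy)
        ypy = max(ypy, 1e-300)
        s2e = ypy / (self.n - self.p)
        crit = (self.n - self.p) * math.log(s2e) + logdetW + logdet_xwx
        return crit, (b, s2e, logdetW, logdet_xwx)

    def objective(self, s: np.ndarray) -> float:
        crit, _ = self.profiled(s * s)
        return crit

    def objective_and_grad(self, s: np.ndarray) -> tuple[float, np.ndarray]:
        """Profiled criterion with its analytic gradient (dense mode only).

        Uses d log|W| / dr_k = tr(Z_k' W^-1 Z_k),
        d log|X'W^-1X| / dr_k = -tr[(X'W^-1X)^-1 U_k' U_k] with
        U_k = Z_k' W^-1 X, and d(y'Py) / dr_k = -||Z_k' P y||^2, chained
        through r_k = s_k^2.
        """
        ratios = s * s
        ds = self._expand(ratios)
        A = ds[:, None] * self.ZtX
        a = ds * self.Zty
        rhs = np.column_stack([A, a])
        M = self.ZtZ * ds[:, None] * ds[None, :]
        M[np.diag_indices_from(M)] += 1.0
        c, low = sla.cho_factor(M, lower=True, check_finite=False)
        logdetW = 2.0 * float(np.sum(np.log(np.diag(c))))
        sol = sla.cho_solve((c, low), rhs, check_finite=False)
        XtWiX = self.XtX - A.T @ sol[:, : self.p]
        XtWiy = self.Xty - A.T @ sol[:, self.p]
        ytWiy = self.yty - float(a @ sol[:, self.p])
        sign, logdet_xwx = np.linalg.slogdet(XtWiX)
        if sign <= 0:
            return np.inf, np.zeros_like(s)
        b = np.linalg.solve(XtWiX, XtWiy)
        ypy = max(ytWiy - float(b @ XtWiy), 1e-300)
        s2e = ypy / (self.n - self.p)
        crit = (self.n - self.p) * math.log(s2e) + logdetW + logdet_xwx

        ZtZd = self.ZtZ * ds[None, :]
        C = sla.cho_solve((c, low), (self.ZtZ * ds[:, None]), check_finite=False)
        diag_ZtWiZ = np.diag(self.ZtZ) - np.einsum("ij,ji->i", ZtZd, C)
        ZtWiX = self.ZtX - ZtZd @ sol[:, : self.p]
        ZtWiy = self.Zty - ZtZd @ sol[:, self.p]
        g = ZtWiy - ZtWiX @ b  # = Z' P y (up to the 1/s2e scale, which cancels)
        H = np.linalg.inv(XtWiX)
        UH = ZtWiX @ H
        per_level_xwx = np.einsum("ij,ij->i", UH, ZtWiX)
        grad = np.empty_like(s)
        for k, slc in enumerate(self.slices):
            d_logdetW = float(np.sum(diag_ZtWiZ[slc]))
            d_logdet_xwx = -float(np.sum(per_level_xwx[slc]))
            d_ypy = -float(np.sum(g[slc] ** 2))
            d_r = d_logdetW + d_logdet_xwx + (self.n - self.p) / ypy * d_ypy
            grad[k] = 2.0 * s[k] * d_r
        return crit, grad

    def loglik_at(self, variances: np.ndarray, var_resid: float) -> float:
        """Full restricted log-likelihood at given absolute components."""
        if var_resid <= 0:
            return math.inf
        ratios = np.asarray(variances, float) / var_resid
        logdetW, XtWiX, XtWiy, ytWiy = self._core(ratios)
        _, logdet_xwx = np.linalg.slogdet(XtWiX)
        b = np.linalg.solve(XtWiX, XtWiy)
        ypy = (ytWiy - float(b @ XtWiy)) / var_resid
        npp = self.n - self.p
        logdetV = self.n * math.log(var_resid) + logdetW
        logdet_xvx = logdet_xwx - self.p * math.log(var_resid)
        return -0.5 * (npp * math.log(2 * math.pi) + logdetV + logdet_xvx + ypy)

    # -- post-fit extraction ---------------------------------------------
    def gls(self, ratios: np.ndarray) -> tuple[np.ndarray, float]:
        crit, by = self.profiled(ratios)
        if by is None:
            raise ConvergenceError("GLS failed at the reported optimum")
        b, s2e, *_ = by
        return b, s2e

    def blups(self, fit: REMLFit) -> dict[str, np.ndarray]:
        if fit.degenerate or fit.var_resid <= 0:
            return {t.name: np.zeros(t.n_levels) for t in self.terms}
        ratios = np.array(
            [fit.var_components[t.name] / fit.var_resid for t in self.terms]
        )
        r = self.y - self.X @ fit.fixed_effects
        Ztr = self.Zt @ r
        ds = self._expand(ratios)
        a = ds * Ztr
        _, solve = self._factor(ds)
        Minv_a = solve(a)
        ZtWir = Ztr - (self.ZtZ @ (ds * Minv_a))
        u = np.concatenate(
            [ratios[i] * ZtWir[slc] for i, slc in enumerate(self.slices)]
        ) if self.terms else np.empty(0)
        return {t.name: u[slc] for t, slc in zip(self.terms, self.slices)}

    def fitted(self, fit: REMLFit) -> np.ndarray:
        mu = self.X @ fit.fixed_effects
        if not self.terms:
            return mu
        u = np.concatenate([self.blups(fit)[t.name] for t in self.terms])
        return mu + self.Zt.T @ u


def _start_points(k: int, n_starts: int) -> list[np.ndarray]:
    """Deterministic restart grid on the sqrt-ratio scale."""
    base = [
        np.full(k, math.sqrt(1.0 / max(k, 1))),
        np.full(k, 1.0),
        np.full(k, math.sqrt(0.05)),
        np.full(k, math.sqrt(5.0)),
    ]
    rng = np.random.default_rng(0)
    while len(base) < n_starts:
        base.append(np.exp(rng.normal(0.0, 1.0, size=k) / 2.0))
    return base[:max(n_starts, 1)]


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    terms: Sequence[RandomTerm],
    fixed_names: Sequence[str] | None = None,
    n_starts: int = 3,
    start_ratios: np.ndarray | None = None,
    max_iter: int = 500,
) -> REMLFit:
    """Fit a Gaussian mixed model by REML.

    Parameters
    ----------
    y:
        Response vector (readings or paired differences).
    X:
        Fixed-effect design (intercept, optionally a sum-to-zero device
        contrast column).
    terms:
        Crossed random-intercept terms.  Terms with a single level are
        dropped with a warning (their variance is unidentifiable).
    n_starts:
        Number of deterministic restarts of the optimizer.
    start_ratios:
        Optional warm-start variance ratios (s2_k / s2_e); when given, the
        warm start is tried first and ``n_starts`` extra restarts are
        skipped unless it fails.
    """
    terms = list(terms)
    dropped = [t.name for t in terms if t.n_levels < 2]
    if dropped:
        warnings.warn(
            f"dropping random terms with a single level: {dropped}", stacklevel=2
        )
        terms = [t for t in terms if t.n_levels >= 2]
    prob = _REMLProblem(y, X, terms)
    names = list(fixed_names) if fixed_names else [f"b{i}" for i in range(prob.p)]

    # degenerate data: OLS residual variance ~ 0 -> all components at zero
    b_ols, *_ = np.linalg.lstsq(prob.X, prob.y, rcond=None)
    resid_ols = prob.y - prob.X @ b_ols
    scale = max(float(np.mean(prob.y**2)), 1.0)
    if float(resid_ols @ resid_ols) / prob.n < 1e-12 * scale:
        return REMLFit(
            fixed_names=names,
            fixed_effects=b_ols,
            var_components={t.name: 0.0 for t in terms},
            var_resid=0.0,
            reml_loglik=math.inf,
            converged=True,
            boundary=[t.name for t in terms],
            degenerate=True,
            n_obs=prob.n,
            message="degenerate: response is exactly linear in the fixed design",
            dropped_terms=dropped,
            _problem=prob,
        )

    k = len(terms)
    if k == 0:
        s2e = float(resid_ols @ resid_ols) / (prob.n - prob.p)
        return REMLFit(
            fixed_names=names,
            fixed_effects=b_ols,
            var_components={},
            var_resid=s2e,
            reml_loglik=prob.loglik_at(np.empty(0), s2e),
            converged=True,
            boundary=[],
            degenerate=False,
            n_obs=prob.n,
            dropped_terms=dropped,
            _problem=prob,
        )

    starts: list[np.ndarray]
    if start_ratios is not None:
        starts = [np.sqrt(np.maximum(np.asarray(start_ratios, float), 1e-8))]
    else:
        starts = _start_points(k, n_starts)

    if prob.mode == "dense":  # analytic gradient available
        fun, jac, opts = prob.objective_and_grad, True, {
            "maxiter": max_iter, "ftol": _FTOL, "gtol": 1e-7,
        }
    else:
        fun, jac, opts = prob.objective, None, {
            "maxiter": max_iter, "ftol": _FTOL, "gtol": 1e-7, "eps": _FD_EPS,
        }

    def _run(s0):
        return minimize(fun, s0, jac=jac, method="L-BFGS-B", options=opts)

    best = None
    for s0 in starts:
        res = _run(s0)
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if start_ratios is not None and (best is None or not np.isfinite(best.fun)):
        for s0 in _start_points(k, n_starts):  # warm start failed: fall back
            res = _run(s0)
            if best is None or res.fun < best.fun - 1e-12:
                best = res

    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("REML optimization failed from every start")

    converged = bool(best.success)
    if not converged:
        # rare line-search (ABNORMAL) exits sit at the optimum with a noisy
        # gradient; a short simplex polish settles them
        polish = minimize(
            prob.objective, best.x, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 400},
        )
        if polish.fun <= best.fun + 1e-9:
            best = polish
            converged = bool(polish.success)

    ratios = best.x * best.x
    # snap negligible ratios to the boundary
    top = max(float(np.max(ratios)), 1.0)
    ratios[ratios < _BOUNDARY_TOL * top] = 0.0
    b, s2e = prob.gls(ratios)
    variances = ratios * s2e
    loglik = prob.loglik_at(variances, s2e)
    boundary = [t.name for t, r in zip(terms, ratios) if r == 0.0]
    if not converged:
        logger.warning("REML optimizer: %s", best.message)
    return REMLFit(
        fixed_names=names,
        fixed_effects=b,
        var_components={t.name: float(v) for t, v in zip(terms, variances)},
        var_resid=float(s2e),
        reml_loglik=float(loglik),
        converged=converged,
        boundary=boundary,
        degenerate=False,
        n_obs=prob.n,
        message=str(best.message),
        dropped_terms=dropped,
        _problem=prob,
    )


# ---------------------------------------------------------------------------
# the two concrete agreement models


_FULL_TERMS = (
    "subject",
    "activity",
    "subject_device",
    "subject_activity",
    "device_activity",
)


@dataclass
class FullModelFit:
    """Fit of the crossed two-device model for raw readings.

    Holds the overall mean, the sum-to-zero device effects
    (``beta_reference + beta_test = 0``) and the six variance components:
    subject, activity, subject x device, subject x activity,
    device x activity, residual.
    """

    mu: float
    beta_reference: float
    beta_test: float
    var_subject: float
    var_activity: float
    var_subject_device: float
    var_subject_activity: float
    var_device_activity: float
    var_resid: float
    reml_loglik: float = math.nan
    converged: bool = True
    n_obs: int = 0
    n_subjects: int = 0
    boundary: list[str] = field(default_factory=list)
    dropped_terms: list[str] = field(default_factory=list)
    engine: REMLFit | None = field(default=None, repr=False, compare=False)

    @property
    def device_diff(self) -> float:
        """Mean device difference ``beta_test - beta_reference``."""
        return self.beta_test - self.beta_reference

    @property
    def phi_beta_sq(self) -> float:
        """Variance attributable to the fixed device factor, sum of beta_j^2."""
        return self.beta_reference**2 + self.beta_test**2

    @classmethod
    def from_components(
        cls,
        device_diff: float,
        var_subject: float,
        var_activity: float,
        var_subject_device: float,
        var_subject_activity: float,
        var_device_activity: float,
        var_resid: float,
        mu: float = 0.0,
    ) -> "FullModelFit":
        """Build a fit object directly from known variance components
        (e.g. published estimates), for desk-scale index computation."""
        half = device_diff / 2.0
        return cls(
            mu=mu,
            beta_reference=-half,
            beta_test=half,
            var_subject=var_subject,
            var_activity=var_activity,
            var_subject_device=var_subject_device,
            var_subject_activity=var_subject_activity,
            var_device_activity=var_device_activity,
            var_resid=var_resid,
        )

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "beta_reference": self.beta_reference,
            "beta_test": self.beta_test,
            "device_diff": self.device_diff,
            "var_subject": self.var_subject,
            "var_activity": self.var_activity,
            "var_subject_device": self.var_subject_device,
            "var_subject_activity": self.var_subject_activity,
            "var_device_activity": self.var_device_activity,
            "var_resid": self.var_resid,
            "reml_loglik": self.reml_loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "boundary": self.boundary,
            "dropped_terms": self.dropped_terms,
        }


@dataclass
class DiffModelFit:
    """Fits of the paired-differences model (subject + activity random
    intercepts) and of the bias-only sub-model (subject intercept only);
    the mean bias ``mu0_star`` is taken from the latter."""

    mu_star: float
    var_subject_star: float
    var_activity_star: float
    var_resid_star: float
    mu0_star: float
    var_subject0: float
    var_resid0: float
    reml_loglik: float = math.nan
    reml_loglik0: float = math.nan
    converged: bool = True
    n_obs: int = 0
    n_subjects: int = 0
    boundary: list[str] = field(default_factory=list)
    engine: REMLFit | None = field(default=None, repr=False, compare=False)
    engine0: REMLFit | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_components(
        cls,
        mu0_star: float,
        var_subject_star: float,
        var_activity_star: float,
        var_resid_star: float,
        mu_star: float | None = None,
    ) -> "DiffModelFit":
        return cls(
            mu_star=mu0_star if mu_star is None else mu_star,
            var_subject_star=var_subject_star,
            var_activity_star=var_activity_star,
            var_resid_star=var_resid_star,
            mu0_star=mu0_star,
            var_subject0=var_subject_star,
            var_resid0=var_resid_star,
        )

    def to_dict(self) -> dict:
        return {
            "mu_star": self.mu_star,
            "var_subject_star": self.var_subject_star,
            "var_activity_star": self.var_activity_star,
            "var_resid_star": self.var_resid_star,
            "mu0_star": self.mu0_star,
            "var_subject0": self.var_subject0,
            "var_resid0": self.var_resid0,
            "reml_loglik": self.reml_loglik,
            "reml_loglik0": self.reml_loglik0,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "boundary": self.boundary,
        }


def fit_full_model(
    table: MeasurementTable,
    n_starts: int = 3,
    start_ratios: np.ndarray | None = None,
) -> FullModelFit:
    """Fit the crossed random-effects model to raw readings of both devices.

    The fixed design is an intercept plus a sum-to-zero device contrast
    (reference coded -1, test coded +1).  Random terms: subject, activity,
    subject x device, subject x activity, device x activity.  With a single
    activity the activity-related terms are dropped with a warning.
    """
    df = table.data
    y = df["value"].to_numpy(float)
    contrast = np.where(df["device"].to_numpy() == table.test_device, 1.0, -1.0)
    X = np.column_stack([np.ones(len(y)), contrast])

    subj = df["subject"].to_numpy()
    act = df["activity"].to_numpy()
    dev = df["device"].to_numpy()
    terms = [
        RandomTerm.from_labels("subject", subj),
        RandomTerm.from_labels("activity", act),
        RandomTerm.interaction("subject_device", subj, dev),
        RandomTerm.interaction("subject_activity", subj, act),
        RandomTerm.interaction("device_activity", dev, act),
    ]
    single_activity = df["activity"].nunique() < 2
    if single_activity:
        warnings.warn(
            "single activity level: dropping activity, subject_activity and "
            "device_activity random terms",
            stacklevel=2,
        )
        terms = [t for t in terms if t.name in ("subject", "subject_device")]

    fit = reml_fit(
        y, X, terms, fixed_names=["mu", "device"], n_starts=n_starts,
        start_ratios=start_ratios,
    )
    vc = fit.var_components
    b_dev = float(fit.fixed_effects[1])
    return FullModelFit(
        mu=float(fit.fixed_effects[0]),
        beta_reference=-b_dev,
        beta_test=b_dev,
        var_subject=vc.get("subject", 0.0),
        var_activity=vc.get("activity", 0.0),
        var_subject_device=vc.get("subject_device", 0.0),
        var_subject_activity=vc.get("subject_activity", 0.0),
        var_device_activity=vc.get("device_activity", 0.0),
        var_resid=fit.var_resid,
        reml_loglik=fit.reml_loglik,
        converged=fit.converged,
        n_obs=fit.n_obs,
        n_subjects=table.n_subjects,
        boundary=fit.boundary,
        dropped_terms=fit.dropped_terms + (
            ["activity", "subject_activity", "device_activity"] if single_activity else []
        ),
        engine=fit,
    )


def fit_diff_model(
    diffs: PairedDifferenceTable,
    n_starts: int = 3,
    start_ratios: np.ndarray | None = None,
) -> DiffModelFit:
    """Fit the paired-differences model and the bias-only sub-model.

    Variance components for the limits of agreement come from the model
    with subject and activity random intercepts; the mean bias from the
    bias-only model (intercept plus subject intercept), which weights
    subjects appropriately under unbalance.
    """
    df = diffs.data
    if df["subject"].nunique() < 2:
        raise DataError("need at least 2 subjects with differences")
    y = df["diff"].to_numpy(float)
    X = np.ones((len(y), 1))
    subj = df["subject"].to_numpy()
    act = df["activity"].to_numpy()

    terms_full = [
        RandomTerm.from_labels("subject", subj),
        RandomTerm.from_labels("activity", act),
    ]
    if df["activity"].nunique() < 2:
        warnings.warn("single activity level: dropping activity term", stacklevel=2)
        terms_full = terms_full[:1]
    fit = reml_fit(y, X, terms_full, fixed_names=["mu_star"], n_starts=n_starts,
                   start_ratios=start_ratios)
    fit0 = reml_fit(
        y, X, [RandomTerm.from_labels("subject", subj)], fixed_names=["mu0_star"],
        n_starts=n_starts,
    )
    return DiffModelFit(
        mu_star=float(fit.fixed_effects[0]),
        var_subject_star=fit.var_components.get("subject", 0.0),
        var_activity_star=fit.var_components.get("activity", 0.0),
        var_resid_star=fit.var_resid,
        mu0_star=float(fit0.fixed_effects[0]),
        var_subject0=fit0.var_components.get("subject", 0.0),
        var_resid0=fit0.var_resid,
        reml_loglik=fit.reml_loglik,
        reml_loglik0=fit0.reml_loglik,
        converged=fit.converged and fit0.converged,
        n_obs=fit.n_obs,
        n_subjects=int(df["subject"].nunique()),
        boundary=fit.boundary,
        engine=fit,
        engine0=fit0,
    )
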