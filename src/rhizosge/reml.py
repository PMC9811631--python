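"""Restricted maximum likelihood for Gaussian mixed models with crossed random effects.

The model is

    y = X b + sum_k Z_k u_k + e,     u_k ~ N(0, s2_k I),   e ~ N(0, s2_e I)

with arbitrary (typically crossed, non-nested) incidence matrices ``Z_k``.
Estimation maximizes the restricted likelihood — the density of any set of
orthonormal error contrasts ``K'y`` with ``K'X = 0`` — over non-negative
variances; a maximum-likelihood mode is available for fixed-effect
likelihood-ratio tests.

Numerics
--------
Variances are parameterized as ratios ``gamma_k = s2_k / s2_e`` and optimized
on the log scale (keeping every variance positive without a constrained
solver; a floor of 1e-10 on the ratio stands in for the boundary at zero).
The residual variance is profiled out analytically.  Each likelihood
evaluation reduces, via the Woodbury identity on ``H = I + Z G Z'``, to a
Cholesky factorization of a q x q matrix (q = total number of random-effect
levels), with analytic gradients; cross-products ``Z'Z, Z'X, Z'y, ...`` are
formed once per model.  The reported log-likelihood includes all constants of
the error-contrast density, so values are directly comparable with a
brute-force multivariate-normal computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg, optimize

_LOG2PI = float(np.log(2.0 * np.pi))
GAMMA_FLOOR = 1e-10
GAMMA_CEIL = 1e7
#: ratios at or below this are reported as boundary (zero-variance) estimates
BOUNDARY_TOL = 1e-8


class ConvergenceError(RuntimeError):
    """REML optimizer failed; carries the per-start diagnostic trajectory."""

    def __init__(self, message: str, trajectory: Optional[list] = None):
        super().__init__(message)
        self.trajectory = trajectory or []


@dataclass(frozen=True)
class RandomTerm:
    """One random effect: a name and its n x q incidence (design) matrix."""

    name: str
    Z: np.ndarray

    @staticmethod
    def from_codes(name: str, codes: Sequence, signs: Optional[np.ndarray] = None,
                   levels: Optional[Sequence] = None) -> "RandomTerm":
        """Incidence from a factor coding, optionally signed (+1/-1) per row."""
        codes = list(codes)
        if levels is None:
            levels = sorted(set(codes))
        index = {lev: j for j, lev in enumerate(levels)}
        Z = np.zeros((len(codes), len(levels)))
        for i, c in enumerate(codes):
            Z[i, index[c]] = 1.0 if signs is None else float(signs[i])
        return RandomTerm(name, Z)


@dataclass
class VarianceComponentFit:
    """REML/ML estimates for one fitted mixed model."""

    components: dict[str, float]          # s2_k per random term
    resid: float                          # s2_e
    loglik: float                         # restricted (or full ML) log-likelihood
    method: str                           # "reml" | "ml"
    converged: bool
    n_iter: int
    n_obs: int
    gammas: dict[str, float] = field(default_factory=dict)

    def variance_proportions(self, count_twice: Sequence[str] = ()) -> dict[str, float]:
        """Share of phenotypic variance per component (residual included).

        Components named in ``count_twice`` contribute their variance twice to
        the denominator — the reporting convention for a constrained model in
        which one strain effect enters each observation through two incidence
        columns (focal and competitor), so phenotypic variance carries it twice.
        """
        total = self.resid + sum(self.components.values())
        total += sum(self.components[k] for k in count_twice)
        out = {k: v / total for k, v in self.components.items()}
        out["residual"] = self.resid / total
        return out


class MixedModel:
    """A Gaussian mixed model held as dense design matrices plus cross-products."""

    def __init__(self, y: np.ndarray, X: np.ndarray, terms: Sequence[RandomTerm]):
        y = np.asarray(y, float).ravel()
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != y.size:
            raise ValueError("X and y disagree on n")
        if not terms:
            raise ValueError("need at least one random term")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        self.y, self.X = y, X
        self.terms = list(terms)
        self.n, self.p = X.shape
        if self.n <= self.p:
            raise ValueError("need more observations than fixed-effect columns")
        Z = np.hstack([t.Z for t in terms])
        self._slices = []
        start = 0
        for t in terms:
            self._slices.append(slice(start, start + t.Z.shape[1]))
            start += t.Z.shape[1]
        self.q = Z.shape[1]
        # cross-products formed once; every likelihood evaluation is O(q^3)
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        sign, self._logdet_XtX = np.linalg.slogdet(self.XtX)
        if sign <= 0:
            raise ValueError("singular X'X")

    # -- likelihood ---------------------------------------------------------

    def _expand(self, gamma: np.ndarray) -> np.ndarray:
        d = np.empty(self.q)
        for g, sl in zip(gamma, self._slices):
            d[sl] = g
        return d

    def _core(self, gamma: np.ndarray):
        """Cholesky pieces shared by value and gradient at one gamma."""
        d = np.sqrt(self._expand(gamma))
        M = self.ZtZ * np.outer(d, d)
        M[np.diag_indices_from(M)] += 1.0
        L = linalg.cholesky(M, lower=True)
        S1 = linalg.solve_triangular(L, d[:, None] * self.ZtX, lower=True)
        s2 = linalg.solve_triangular(L, d * self.Zty, lower=True)
        XtHiX = self.XtX - S1.T @ S1
        XtHiy = self.Xty - S1.T @ s2
        ytHiy = self.yty - s2 @ s2
        Lx = linalg.cholesky(XtHiX, lower=True)
        beta = linalg.cho_solve((Lx, True), XtHiy)
        yPy = max(ytHiy - XtHiy @ beta, 1e-300)
        logdet_H = 2.0 * float(np.sum(np.log(np.diag(L))))
        logdet_XtHiX = 2.0 * float(np.sum(np.log(np.diag(Lx))))
        return d, L, S1, s2, XtHiX, XtHiy, yPy, Lx, beta, logdet_H, logdet_XtHiX

    def neg2_reml(self, gamma: np.ndarray, resid: Optional[float] = None) -> float:
        """-2 x restricted log-likelihood, residual variance profiled unless given."""
        *_, yPy, _, _, logdet_H, logdet_XtHiX = self._core(np.asarray(gamma, float))
        df = self.n - self.p
        base = logdet_H + logdet_XtHiX - self._logdet_XtX + df * _LOG2PI
        if resid is None:
            return base + df * (np.log(yPy / df) + 1.0)
        return base + df * np.log(resid) + yPy / resid

    def neg2_ml(self, gamma: np.ndarray, resid: Optional[float] = None) -> float:
        *_, yPy, _, _, logdet_H, _ = self._core(np.asarray(gamma, float))
        base = logdet_H + self.n * _LOG2PI
        if resid is None:
            return base + self.n * (np.log(yPy / self.n) + 1.0)
        return base + self.n * np.log(resid) + yPy / resid

    def _value_grad(self, theta: np.ndarray, reml: bool):
        """Profiled -2 loglik and its gradient w.r.t. theta = log(gamma)."""
        gamma = np.exp(theta)
        d, L, S1, s2, XtHiX, XtHiy, yPy, Lx, beta, logdet_H, logdet_XtHiX = \
            self._core(gamma)
        df = (self.n - self.p) if reml else self.n
        sigma2 = yPy / df
        if reml:
            value = (logdet_H + logdet_XtHiX - self._logdet_XtX
                     + df * (_LOG2PI + np.log(sigma2) + 1.0))
        else:
            value = logdet_H + df * (_LOG2PI + np.log(sigma2) + 1.0)

        # gradient: d(-2l)/dgamma_k = tr(P Zk Zk') - ||Zk' P y||^2 / sigma2
        # (for ML the trace is against H^-1, not P)
        G1 = linalg.solve_triangular(L, d[:, None] * self.ZtZ, lower=True)
        diag_ZtHiZ = np.diag(self.ZtZ) - np.einsum("ij,ij->j", G1, G1)
        ZtHiX = self.ZtX - G1.T @ S1
        ZtHiy = self.Zty - G1.T @ s2
        ZPy = ZtHiy - ZtHiX @ beta
        if reml:
            W = linalg.solve_triangular(Lx, ZtHiX.T, lower=True)  # p x q
            diag_tr = diag_ZtHiZ - np.einsum("ij,ij->j", W, W)
        else:
            diag_tr = diag_ZtHiZ
        grad = np.empty(len(self.terms))
        for k, sl in enumerate(self._slices):
            grad[k] = float(np.sum(diag_tr[sl]) - ZPy[sl] @ ZPy[sl] / sigma2)
        return value, grad * gamma, sigma2

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        method: str = "reml",
        starts: Optional[Sequence[Sequence[float]]] = None,
        gtol: float = 1e-8,
        maxiter: int = 500,
    ) -> VarianceComponentFit:
        """Maximize the (restricted) likelihood over variance ratios.

        Runs L-BFGS-B on log-ratios from each start (default: all ratios at
        0.1 and at 1.0) and keeps the best converged solution.
        """
        if method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        reml = method == "reml"
        K = len(self.terms)
        if starts is None:
            starts = [[0.1] * K, [1.0] * K]
        bounds = [(np.log(GAMMA_FLOOR), np.log(GAMMA_CEIL))] * K

        best = None
        trajectory = []
        for s in starts:
            theta0 = np.log(np.clip(np.asarray(s, float), GAMMA_FLOOR, GAMMA_CEIL))
            res = optimize.minimize(
                lambda th: self._value_grad(th, reml)[:2],
                theta0,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"gtol": gtol, "ftol": 1e-13, "maxiter": maxiter},
            )
            trajectory.append({"start": list(s), "fun": float(res.fun),
                               "nit": int(res.nit), "status": int(res.status),
                               "message": str(res.message)})
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ConvergenceError("REML optimization failed from all starts", trajectory)
        # status 0 = converged, 1 = maxiter; gradient can legitimately stall at
        # the variance floor, so accept any finite optimum but flag status.
        converged = any(t["status"] == 0 for t in trajectory
                        if abs(t["fun"] - float(best.fun)) < 1e-6)
        gamma = np.exp(best.x)
        gamma[gamma <= BOUNDARY_TOL] = 0.0
        _, _, sigma2 = self._value_grad(np.log(np.clip(gamma, GAMMA_FLOOR, None)), reml)
        loglik = -0.5 * float(best.fun)
        return VarianceComponentFit(
            components={t.name: float(g * sigma2) for t, g in zip(self.terms, gamma)},
            resid=float(sigma2),
            loglik=loglik,
            method=method,
            converged=bool(converged),
            n_iter=int(best.nit),
            n_obs=self.n,
            gammas={t.name: float(g) for t, g in zip(self.terms, gamma)},
        )

    def drop_term(self, name: str) -> "MixedModel":
        """The nested model without one random term (for likelihood-ratio tests)."""
        if name == "residual":
            raise ValueError("the residual cannot be removed")
        kept = [t for t in self.terms if t.name != name]
        if len(kept) == len(self.terms):
            raise KeyError(f"no random term named {name!r}")
        if not kept:
            raise ValueError("cannot drop the only random term")
        return MixedModel(self.y, self.X, kept)


@dataclass
class LRTResult:
    """Likelihood-ratio test of one (set of) variance parameter(s)."""

    chi2: float
    df: int
    p_value: float
    loglik_full: float
    loglik_reduced: float


def likelihood_ratio_test(full: VarianceComponentFit, reduced: VarianceComponentFit,
                          df: int = 1) -> LRTResult:
    """chi2 = 2 (logL_full - logL_reduced), clamped at 0, against chi2_df.

    The chi2_df reference is conservative when the true variance sits on the
    boundary at zero; no boundary-mixture correction is applied.
    """
    from scipy.stats import chi2 as chi2_dist

    if full.method != reduced.method:
        raise ValueError("full and reduced fits use different estimation methods")
    stat = 2.0 * (full.loglik - reduced.loglik)
    # small negatives arise when the dropped variance is truly on the boundary
    # and both optima agree to optimizer tolerance
    if stat < -1e-3:
        raise ValueError(
            f"reduced model has higher log-likelihood (chi2 = {stat:.3g}); "
            "models are not nested or a fit did not converge"
        )
    stat = max(stat, 0.0)
    return LRTResult(
        chi2=float(stat),
        df=int(df),
        p_value=float(chi2_dist.sf(stat, df)),
        loglik_full=full.loglik,
        loglik_reduced=reduced.loglik,
    )
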