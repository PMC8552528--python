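"""Penalized cubic regression spline with random intercepts, fitted by REML.

The smooth is represented in mixed-model form: a cubic B-spline basis with a
second-difference penalty splits into an unpenalized linear part (absorbed
into the fixed effects) and a penalized part treated as iid random
coefficients.  Together with a per-participant random intercept this gives a
Gaussian additive mixed model

    y = X beta + Z_s u + Z_p b + e,
    u ~ N(0, tau^2 I),  b ~ N(0, psi^2 I),  e ~ N(0, sigma^2 I)

whose two variance ratios are optimized by restricted maximum likelihood
with sigma^2 profiled out; all per-evaluation work is on precomputed
cross-product (Gram) matrices, so refits are cheap.
"""

from __future__ import annotations

import numpy as np
from scipy import interpolate, optimize


def bspline_basis(x, n_basis: int, degree: int = 3, knots=None):
    """Cubic B-spline design matrix with knots at quantiles of ``x``.

    Returns (basis matrix, full knot vector).  Evaluation clamps to the
    training range so refits on subsets stay evaluable on a common grid.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        n_interior = n_basis - degree - 1
        if n_interior < 0:
            raise ValueError("n_basis too small for cubic basis")
        lo, hi = float(np.min(x)), float(np.max(x))
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(x, qs)
        else:
            interior = np.array([])
        knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    xc = np.clip(x, knots[0], knots[-1])
    n_b = len(knots) - degree - 1
    basis = np.empty((len(xc), n_b))
    for j in range(n_b):
        coefs = np.zeros(n_b)
        coefs[j] = 1.0
        basis[:, j] = interpolate.BSpline(knots, coefs, degree, extrapolate=False)(xc)
    return np.nan_to_num(basis), knots


def _penalty_split(basis: np.ndarray):
    """Split a spline basis into unpenalized (linear) and penalized parts
    under a second-difference penalty on the coefficients."""
    k = basis.shape[1]
    D = np.diff(np.eye(k), n=2, axis=0)  # (k-2) x k
    # penalized directions: Z = B D^T (D D^T)^-1 ; null space spans linear trends
    Z = basis @ D.T @ np.linalg.inv(D @ D.T)
    return Z


class PSplineMixedModel:
    """REML-fitted penalized-spline mixed model with participant intercepts."""

    def __init__(self, n_basis: int = 10, degree: int = 3):
        self.n_basis = n_basis
        self.degree = degree

    def get_params(self, deep=True):
        return {"n_basis": self.n_basis, "degree": self.degree}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, ga, y, groups=None, fixed=None):
        """ga: gestational ages; y: response; groups: participant labels;
        fixed: optional extra fixed-effect columns (e.g. cohort dummies)."""
        ga = np.asarray(ga, float)
        y = np.asarray(y, float)
        n = len(y)
        n_basis = min(self.n_basis, max(len(np.unique(ga)) - 1, 2) + 2)
        basis, knots = bspline_basis(ga, n_basis, self.degree)
        self.knots_ = knots
        Zs = _penalty_split(basis)
        self._ga_center, self._ga_scale = float(np.mean(ga)), float(np.std(ga) or 1.0)
        Xcols = [np.ones(n), (ga - self._ga_center) / self._ga_scale]
        if fixed is not None:
            fixed = np.atleast_2d(np.asarray(fixed, float))
            if fixed.shape[0] != n:
                fixed = fixed.T
            Xcols.extend(fixed.T)
        X = np.column_stack(Xcols)

        if groups is not None:
            groups = np.asarray(groups)
            self._group_levels = np.unique(groups)
            gidx = np.searchsorted(self._group_levels, groups)
            Zp = np.zeros((n, len(self._group_levels)))
            Zp[np.arange(n), gidx] = 1.0
            use_groups = len(self._group_levels) > 1
        else:
            use_groups = False
        if not use_groups:
            Zp = np.zeros((n, 0))

        p, q1, q2 = X.shape[1], Zs.shape[1], Zp.shape[1]
        W = np.hstack([X, Zs, Zp])
        G = W.T @ W
        Wy = W.T @ y
        yy = float(y @ y)

        def neg2_reml(log_lams):
            lam = np.exp(log_lams)
            pen = np.concatenate([
                np.zeros(p), np.full(q1, 1.0 / lam[0]),
                np.full(q2, 1.0 / lam[1]) if q2 else np.zeros(0),
            ])
            C = G + np.diag(pen)
            try:
                Lc = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))
            except np.linalg.LinAlgError:
                return 1e12
            sol = np.linalg.solve(Lc.T, np.linalg.solve(Lc, Wy))
            rss = max(yy - Wy @ sol, 1e-300)
            logdetC = 2.0 * np.log(np.diag(Lc)).sum()
            logdetLam = q1 * log_lams[0] + (q2 * log_lams[1] if q2 else 0.0)
            return logdetC + logdetLam + (n - p) * np.log(rss)

        x0 = np.array([0.0, 0.0])
        res = optimize.minimize(neg2_reml, x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
        lam = np.exp(res.x)
        pen = np.concatenate([
            np.zeros(p), np.full(q1, 1.0 / lam[0]),
            np.full(q2, 1.0 / lam[1]) if q2 else np.zeros(0),
        ])
        C = G + np.diag(pen)
        coef = np.linalg.solve(C + 1e-10 * np.eye(len(C)), Wy)
        rss = max(yy - Wy @ coef, 0.0)
        self.sigma2_ = rss / max(n - p, 1)
        self.lambda_ = lam
        self.smoothing_ = float(1.0 / lam[0])
        self.tau2_ = float(lam[0] * self.sigma2_)
        self.subject_variance_ = float(lam[1] * self.sigma2_) if q2 else 0.0
        self._p, self._q1, self._q2 = p, q1, q2
        self.coef_ = coef
        # Bayesian covariance of (beta, u): sigma^2 * C^-1
        self._cov = self.sigma2_ * np.linalg.inv(C + 1e-10 * np.eye(len(C)))
        self.converged_ = bool(res.success or res.fun < 1e11)
        return self

    def _design_curve(self, ga):
        ga = np.asarray(ga, float)
        basis = np.empty((len(ga), len(self.knots_) - self.degree - 1))
        xc = np.clip(ga, self.knots_[0], self.knots_[-1])
        n_b = basis.shape[1]
        for j in range(n_b):
            coefs = np.zeros(n_b)
            coefs[j] = 1.0
            basis[:, j] = interpolate.BSpline(self.knots_, coefs, self.degree,
                                              extrapolate=False)(xc)
        basis = np.nan_to_num(basis)
        Zs = _penalty_split(basis) if self._q1 else basis[:, :0]
        X = np.column_stack([np.ones(len(ga)), (ga - self._ga_center) / self._ga_scale])
        pad = np.zeros((len(ga), self._p - 2))  # extra fixed effects at reference (0)
        return np.hstack([X, pad, Zs])

    def predict_curve(self, ga):
        """Population mean curve (reference level of extra fixed effects)."""
        D = self._design_curve(ga)
        idx = np.arange(self._p + self._q1)
        return D[:, : self._p + self._q1] @ self.coef_[idx]

    def curve_band(self, ga, level: float = 0.95):
        """Pointwise interval for the mean curve from the (beta, u) covariance."""
        from scipy.stats import norm

        D = self._design_curve(ga)[:, : self._p + self._q1]
        cov = self._cov[: self._p + self._q1, : self._p + self._q1]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", D, cov, D), 0.0))
        z = norm.ppf(0.5 + level / 2.0)
        mid = D @ self.coef_[: self._p + self._q1]
        return mid - z * se, mid + z * se
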