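"""Fast random-intercept linear mixed model, REML-profiled.

For the model ``y = X beta + b_g + e`` with one random intercept per group
(``b_g ~ N(0, tau^2)``, ``e ~ N(0, sigma^2)``), everything profiles down to
a one-dimensional REML search over the variance ratio ``lambda = tau^2 /
sigma^2``: with ``V* = I + lambda J`` block-diagonal over groups,

    (I + lambda J_g)^-1 = I - lambda/(1 + lambda n_g) * J_g

so GLS cross-products are closed-form group sums.  This is exactly the
model statsmodels' MixedLM fits with a random intercept (the test suite
cross-checks the two); it exists because the jackknife/robustness loops
refit thousands of such models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats


class RandomInterceptLMM:
    """REML fit of a Gaussian LMM with a single random intercept."""

    def __init__(self, log_lambda_bounds=(-12.0, 12.0)):
        self.log_lambda_bounds = log_lambda_bounds

    def fit(self, X, y, groups):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n, p = X.shape
        if n <= p:
            raise ValueError("more parameters than observations")
        codes, _ = pd.factorize(np.asarray(groups))
        G = codes.max() + 1
        n_g = np.bincount(codes, minlength=G).astype(float)
        # per-group sums
        gx = np.zeros((G, p))
        np.add.at(gx, codes, X)
        gy = np.bincount(codes, weights=y, minlength=G)
        XtX = X.T @ X
        Xty = X.T @ y
        yty = float(y @ y)

        def crossprods(lam):
            c = lam / (1.0 + lam * n_g)
            A = XtX - np.einsum("g,gp,gq->pq", c, gx, gx)
            b = Xty - gx.T @ (c * gy)
            q = yty - float(c @ gy**2)
            return A, b, q

        def neg2_reml(log_lam):
            lam = np.exp(log_lam)
            A, b, q = crossprods(lam)
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return 1e12
            try:
                beta = np.linalg.solve(A, b)
            except np.linalg.LinAlgError:
                return 1e12
            rss = max(q - b @ beta, 1e-300)
            return float(np.log1p(lam * n_g).sum() + logdetA + (n - p) * np.log(rss))

        lo, hi = self.log_lambda_bounds
        res = optimize.minimize_scalar(neg2_reml, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-8})
        # compare against the boundary (zero random-effect variance)
        lam = float(np.exp(res.x))
        if neg2_reml(np.log(1e-12)) <= res.fun + 1e-10:
            lam = 0.0
        A, b, q = crossprods(lam)
        # pseudo-inverse guards against rank-deficient subset designs
        Ainv = np.linalg.pinv(A, hermitian=True)
        beta = Ainv @ b
        rss = max(q - b @ beta, 0.0)
        sigma2 = rss / (n - p)
        self.lambda_ = lam
        self.sigma2_ = float(sigma2)
        self.tau2_ = float(lam * sigma2)
        self.coef_ = beta
        self.cov_ = sigma2 * Ainv
        self.se_ = np.sqrt(np.maximum(np.diag(self.cov_), 0.0))
        self.nobs_ = n
        return self


class FormulaLMM:
    """Patsy-formula front end over :class:`RandomInterceptLMM`.

    Mimics the parts of the statsmodels results API the pipeline uses:
    ``params``, ``bse``, ``pvalues`` (Wald, normal reference) and
    ``predict(exog=...)`` for fixed-effect predictions.
    """

    def __init__(self, formula: str, data: pd.DataFrame, groups):
        import patsy

        self.formula = formula
        y_dm, x_dm = patsy.dmatrices(formula, data, return_type="dataframe")
        self._design_info = x_dm.design_info
        self._model = RandomInterceptLMM().fit(
            x_dm.to_numpy(), y_dm.to_numpy().ravel(),
            np.asarray(data.loc[x_dm.index, groups] if isinstance(groups, str)
                       else groups),
        )
        names = list(x_dm.columns)
        self.params = pd.Series(self._model.coef_, index=names)
        self.bse = pd.Series(self._model.se_, index=names)
        z = self._model.coef_ / np.where(self._model.se_ > 0, self._model.se_, np.inf)
        self.pvalues = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
        self.scale = self._model.sigma2_
        self.group_var = self._model.tau2_

    def predict(self, exog: pd.DataFrame):
        import patsy

        (x,) = patsy.build_design_matrices([self._design_info], exog)
        return np.asarray(x) @ self._model.coef_
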