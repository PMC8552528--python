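"""Immunoassay preprocessing: from raw fluorescence to an analysis-ready panel.

Stages, in pipeline order:

1. inter-lot correction of fluorescence intensities (FI) via bridge samples
   re-assayed in a reference lot;
2. intra-lot (plate-to-plate) correction via an anchor sample set expected
   equal on group level (pooled controls by default);
3. 5PL calibration with a power model of variance, detection (LOD) and
   quantification (LOQ) limits;
4. censoring handling: values above ULOD capped at ULOD, values below LLOD
   imputed with a left-censored lognormal EM; analytes with more than 25% of
   measurements outside [LLOQ, ULOQ] are excluded;
5. housekeeping: missing gestational-age substitution, PCA-based outlier
   screening, cohort accounting, panel normalization, covariate derivation.

All corrections act multiplicatively on FI (additively on log FI):
``adjusted FI = exp(log FI - mean_source + mean_target)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import digamma

from ._fivepl import FivePL, fivepl
from .gestation import trimester

__all__ = [
    "AdjustmentFactors",
    "StandardCurve",
    "StandardCurveModel",
    "CensoredLognormalImputer",
    "PanelNormalizer",
    "AlignmentError",
    "CoverageError",
    "CalibrationError",
    "CensoringError",
    "compute_inter_lot_adjustment",
    "correct_inter_lot",
    "apply_intra_lot_adjustment",
    "fit_standard_curve",
    "estimate_limits",
    "fi_to_concentration",
    "impute_below_llod",
    "apply_panel_exclusions",
    "impute_missing_ga",
    "screen_outliers",
    "cohort_accounting",
    "normalize_panel",
    "derive_covariates",
    "build_panel",
]


class AlignmentError(ValueError):
    """Bridge-sample identities do not match between lots."""


class CoverageError(ValueError):
    """A plate has no anchor samples for intra-lot correction."""


class CalibrationError(RuntimeError):
    """Standard-curve fitting failed or produced a non-monotone curve."""


class CensoringError(ValueError):
    """Too few quantified values / too much censoring for EM imputation."""


@dataclass(frozen=True)
class AdjustmentFactors:
    scope: str  # 'inter_lot' | 'intra_lot'
    lot_id: str
    cytokine: str
    delta_log: float
    plate_id: str | None = None


# ---------------------------------------------------------------------------
# batch / plate correction
# ---------------------------------------------------------------------------

def compute_inter_lot_adjustment(bridge_fi_origin, bridge_fi_reference,
                                 cytokine: str, lot_id: str = "") -> AdjustmentFactors:
    """Inter-lot log-offset from bridge samples measured in both lots.

    ``delta_log = mean(log FI in reference re-assay) - mean(log FI in origin
    lot)``; adding it to log FI moves the origin lot onto the reference scale.
    Inputs are mappings/Series indexed by sample id with matching identities.
    """
    orig = pd.Series(bridge_fi_origin, dtype=float)
    ref = pd.Series(bridge_fi_reference, dtype=float)
    if len(orig) == 0 or len(ref) == 0:
        raise AlignmentError("bridge sets must be non-empty")
    if set(orig.index) != set(ref.index):
        raise AlignmentError(
            f"bridge identities differ between lots for {cytokine}: "
            f"{sorted(set(orig.index) ^ set(ref.index))[:5]}"
        )
    if (orig <= 0).any() or (ref <= 0).any():
        raise ValueError("bridge FI values must be positive")
    delta = float(np.log(ref).mean() - np.log(orig).mean())
    return AdjustmentFactors("inter_lot", lot_id, cytokine, delta)


def correct_inter_lot(fi_long: pd.DataFrame, bridge_manifest: pd.DataFrame,
                      reference_lot: str):
    """Apply inter-lot correction to a long FI table (all roles on the lot).

    Returns ``(adjusted fi table, list of AdjustmentFactors)``.  The
    reference lot has delta 0 by construction.
    """
    out = fi_long.copy()
    factors = []
    for lot in sorted(set(out["lot"])):
        if lot == reference_lot:
            continue
        ids = bridge_manifest.loc[bridge_manifest["origin_lot"] == lot, "sample_id"]
        if ids.empty:
            raise AlignmentError(f"no bridge samples for lot {lot}")
        for cyt in sorted(set(out["cytokine"])):
            m_or = (out["lot"] == lot) & out["sample_id"].isin(ids) & (out["cytokine"] == cyt)
            m_re = ((out["lot"] == reference_lot) & (out["role"] == "bridge")
                    & out["sample_id"].isin(ids) & (out["cytokine"] == cyt))
            orig = out.loc[m_or].groupby("sample_id")["fi"].mean()
            re = out.loc[m_re].groupby("sample_id")["fi"].mean()
            adj = compute_inter_lot_adjustment(orig, re, cyt, lot_id=lot)
            mask = (out["lot"] == lot) & (out["cytokine"] == cyt)
            out.loc[mask, "fi"] = np.exp(np.log(out.loc[mask, "fi"]) + adj.delta_log)
            factors.append(adj)
    return out, factors


def apply_intra_lot_adjustment(fi_long: pd.DataFrame, anchor_ids=None,
                               anchor_role: str = "control"):
    """Plate-to-plate correction within each lot from an anchor sample set.

    Anchors are wells expected equal on group level across plates (pooled
    control wells by default, or explicit sample ids such as a same-GA cohort
    subset).  Every well on a plate is scaled so that, per cytokine, the
    plate mean of log anchor FI equals the lot-wide anchor mean.
    """
    out = fi_long.copy()
    if anchor_ids is not None:
        anchor_mask = out["sample_id"].isin(set(anchor_ids))
    else:
        anchor_mask = out["role"] == anchor_role
    if not anchor_mask.any():
        raise CoverageError("no anchor wells found")
    factors = []
    log_fi = np.log(out["fi"].to_numpy(float))
    for (lot, cyt), idx in out.groupby(["lot", "cytokine"]).groups.items():
        sub_anchor = anchor_mask.loc[idx] & (out.loc[idx, "fi"] > 0)
        anchors = out.loc[idx][sub_anchor.to_numpy()]
        plates = sorted(set(out.loc[idx, "plate"]))
        missing = [p for p in plates if p not in set(anchors["plate"])]
        if missing:
            raise CoverageError(f"plate(s) {missing} in lot {lot} have no anchors")
        lot_mean = float(np.log(anchors["fi"]).mean())
        for plate in plates:
            pm = float(np.log(anchors.loc[anchors["plate"] == plate, "fi"]).mean())
            delta = lot_mean - pm
            sel = out.index.isin(idx) & (out["plate"] == plate).to_numpy()
            log_fi[sel] += delta
            factors.append(AdjustmentFactors("intra_lot", lot, cyt, delta, plate_id=plate))
    out["fi"] = np.exp(log_fi)
    return out, factors


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class StandardCurve:
    """Fitted 5PL calibration with power variance model and limits."""

    cytokine: str
    params: FivePL
    theta: tuple  # (theta0, theta1): var(FI) = theta0 * mean**theta1
    llod: float = np.nan
    ulod: float = np.nan
    lloq: float = np.nan
    uloq: float = np.nan
    flags: list = field(default_factory=list)

    def sd_model(self, mean_fi):
        t0, t1 = self.theta
        return np.sqrt(t0 * np.maximum(np.asarray(mean_fi, float), 1e-12) ** t1)

    def to_dict(self):
        return {
            "cytokine": self.cytokine,
            "params": dict(zip("abcdg", self.params.as_array().tolist())),
            "theta": list(self.theta),
            "llod": self.llod, "ulod": self.ulod,
            "lloq": self.lloq, "uloq": self.uloq,
            "flags": list(self.flags),
        }


class StandardCurveModel:
    """Variance-weighted 5PL calibration fit (sklearn-style estimator).

    ``fit(conc, fi, groups=None)`` estimates the power variance model from
    replicate groups (log replicate variance regressed on log replicate mean,
    with the small-sample bias of log sample variances corrected via the
    digamma function), then minimizes variance-weighted squared error.
    """

    def __init__(self, cytokine: str = "", max_nfev: int = 20000):
        self.cytokine = cytokine
        self.max_nfev = max_nfev

    def get_params(self, deep=True):
        return {"cytokine": self.cytokine, "max_nfev": self.max_nfev}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    @staticmethod
    def _fit_theta(conc, fi, groups):
        key = pd.MultiIndex.from_arrays([np.asarray(conc), np.asarray(groups)])
        df = pd.DataFrame({"fi": np.asarray(fi, float)}, index=key)
        g = df.groupby(level=[0, 1])["fi"].agg(["mean", "var", "count"])
        g = g[(g["count"] >= 2) & (g["mean"] > 0)]
        g = g[g["var"] > 0]
        if len(g) < 3:
            return 0.0, 0.0  # effectively noiseless; unweighted fit
        dof = g["count"] - 1
        bias = digamma(dof / 2.0) - np.log(dof / 2.0)  # E[log s^2] - log sigma^2
        y = np.log(g["var"]) - bias
        x = np.log(g["mean"])
        slope, intercept = np.polyfit(x, y, 1)
        return float(np.exp(intercept)), float(max(slope, 0.0))

    def fit(self, conc, fi, groups=None):
        conc = np.asarray(conc, float)
        fi = np.asarray(fi, float)
        if len(np.unique(conc)) < 5:
            raise CalibrationError("need >= 5 distinct standard concentrations")
        if groups is None:
            groups = np.zeros(len(conc))
        t0, t1 = self._fit_theta(conc, fi, groups)
        self.theta_ = (t0, t1)

        lo_fi, hi_fi = float(np.min(fi)), float(np.max(fi))
        pos = conc[conc > 0]
        x0 = np.array([lo_fi, 1.0, float(np.exp(np.mean(np.log(pos)))),
                       hi_fi * 1.05, 1.0])
        lower = [-np.inf, 1e-3, 1e-12, -np.inf, 1e-3]
        upper = [np.inf, 50.0, np.inf, np.inf, 50.0]

        def resid(p, weights):
            return (fivepl(conc, *p) - fi) / weights

        w = np.ones_like(fi)
        sol = None
        for _ in range(3):  # iteratively reweight from the fitted mean
            sol = optimize.least_squares(
                resid, x0, args=(w,), bounds=(lower, upper),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=self.max_nfev,
            )
            x0 = sol.x
            if t0 <= 0:
                break
            mean_fit = np.maximum(fivepl(conc, *sol.x), 1e-12)
            w = np.sqrt(t0 * mean_fit ** t1)
            w = np.maximum(w, 1e-12)
        if sol is None or not sol.success:
            raise CalibrationError(
                f"5PL fit failed for {self.cytokine!r}: "
                f"{getattr(sol, 'message', 'no solution')}"
            )
        a, b, c, d, g = sol.x
        try:
            self.curve_ = FivePL(a=float(a), b=float(b), c=float(c), d=float(d), g=float(g))
        except ValueError as exc:
            raise CalibrationError(f"degenerate 5PL for {self.cytokine!r}: {exc}") from exc
        self.residual_ = float(np.sqrt(np.mean((fivepl(conc, *sol.x) - fi) ** 2)))
        return self


def fit_standard_curve(standards: pd.DataFrame, cytokine: str) -> StandardCurve:
    """Fit one analyte's calibration from a replicate standards table
    (columns: conc, fi, and plate/lot for replicate grouping)."""
    sub = standards[standards["cytokine"] == cytokine] if "cytokine" in standards else standards
    if sub.empty:
        raise CalibrationError(f"no standards for {cytokine!r}")
    group_cols = [c for c in ("lot", "plate") if c in sub.columns]
    groups = (sub[group_cols].astype(str).agg("|".join, axis=1)
              if group_cols else np.zeros(len(sub)))
    model = StandardCurveModel(cytokine=cytokine).fit(sub["conc"], sub["fi"], groups=groups)
    return StandardCurve(cytokine=cytokine, params=model.curve_, theta=model.theta_)


def estimate_limits(curve: StandardCurve, blanks) -> StandardCurve:
    """Populate LOD/LOQ limits on a fitted curve.

    LLOD is the concentration whose expected FI equals blank mean + 3 model
    SD; ULOD the concentration at upper asymptote - 3 model SD.  LLOQ/ULOQ
    bound the region where the model CV of back-calculated concentration,
    ``sd(FI) / (|dFI/dconc| * conc)``, stays below 20%.
    """
    blanks = np.asarray(blanks, float)
    if blanks.size == 0:
        raise ValueError("blank FI set must be non-empty")
    p = curve.params
    lo_asym, hi_asym = sorted((p.a, p.d))
    blank_mean = float(np.mean(blanks))

    fi_l = blank_mean + 3.0 * float(curve.sd_model(blank_mean))
    if fi_l <= lo_asym:
        llod = 0.0
    elif fi_l >= hi_asym:
        llod, curve.flags = 0.0, curve.flags + ["llod_above_curve"]
    else:
        llod = float(p.inverse(fi_l))

    fi_u = hi_asym - 3.0 * float(curve.sd_model(hi_asym))
    if fi_u <= lo_asym:
        fi_u = lo_asym + 0.999 * (hi_asym - lo_asym)
        curve.flags.append("flat_curve_ulod")
    ulod = float(p.inverse(fi_u))
    if not np.isfinite(ulod):
        ulod = float(p.inverse(lo_asym + 0.999 * (hi_asym - lo_asym)))
        curve.flags.append("ulod_at_support_bound")

    t0 = curve.theta[0]
    if t0 <= 0:
        lloq, uloq = max(llod, 0.0), ulod
    else:
        lo_grid = max(llod, ulod * 1e-8, 1e-12)
        grid = np.geomspace(lo_grid, ulod, 2000)
        mean_fi = p(grid)
        eps = 1e-6
        deriv = (p(grid * (1 + eps)) - p(grid * (1 - eps))) / (2 * eps * grid)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = curve.sd_model(mean_fi) / np.abs(deriv * grid)
        ok = np.where(cv <= 0.20)[0]
        if ok.size == 0:
            lloq, uloq = llod, ulod
            curve.flags.append("no_quantifiable_region")
        else:
            lloq, uloq = float(grid[ok[0]]), float(grid[ok[-1]])
    curve.llod, curve.ulod = llod, ulod
    curve.lloq = float(np.clip(lloq, llod, ulod))
    curve.uloq = float(np.clip(uloq, curve.lloq, ulod))
    return curve


def fi_to_concentration(fi_table: pd.DataFrame, curve: StandardCurve) -> pd.DataFrame:
    """Invert the calibration for one analyte's sample wells.

    Status: ``quantified``; ``capped_ulod`` (FI at/above the upper invertible
    range -> conc = ULOD); ``below_llod`` (left for EM imputation);
    ``flagged`` for NaN FI.
    """
    if not np.isfinite(curve.ulod):
        raise ValueError("curve limits must be populated before inversion")
    p = curve.params
    lo_asym, hi_asym = sorted((p.a, p.d))
    fi = fi_table["fi"].to_numpy(float)
    conc = p.inverse(fi)
    fi_llod = p(curve.llod) if curve.llod > 0 else lo_asym

    status = np.full(len(fi), "quantified", dtype=object)
    nanfi = ~np.isfinite(fi)
    high = (~nanfi) & ((fi >= p(curve.ulod)) | (fi >= hi_asym))
    low = (~nanfi) & ~high & ((fi <= fi_llod) | ~np.isfinite(conc) | (conc < curve.llod))
    status[high], status[low], status[nanfi] = "capped_ulod", "below_llod", "flagged"
    conc = np.where(high, curve.ulod, conc)
    conc = np.where(low | nanfi, np.nan, conc)

    out = fi_table[[c for c in ("sample_id", "cytokine", "lot", "plate", "role")
                    if c in fi_table.columns]].copy()
    out["conc"] = conc
    out["status"] = status
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log_conc"] = np.log(out["conc"])
    return out


# ---------------------------------------------------------------------------
# left-censored lognormal EM
# ---------------------------------------------------------------------------

class CensoredLognormalImputer:
    """EM for a univariate lognormal with left-censoring at a detection limit.

    E-step uses the full conditional first and second moments of the
    truncated normal on the log scale; M-step updates (mu, sigma).  Imputed
    values are the conditional means ``E[X | X < limit]`` (strictly below the
    limit).  Iterates until |d mu| + |d sigma| < tol.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 500,
                 max_censored_frac: float = 0.8):
        self.tol = tol
        self.max_iter = max_iter
        self.max_censored_frac = max_censored_frac

    def get_params(self, deep=True):
        return {"tol": self.tol, "max_iter": self.max_iter,
                "max_censored_frac": self.max_censored_frac}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, values, censored, limit: float):
        values = np.asarray(values, float)
        censored = np.asarray(censored, bool)
        obs = values[~censored]
        n_cens = int(censored.sum())
        n = len(values)
        if len(obs) < 3:
            raise CensoringError("need >= 3 quantified values for EM")
        if n_cens / n >= self.max_censored_frac:
            raise CensoringError(
                f"censored fraction {n_cens / n:.2f} >= {self.max_censored_frac}"
            )
        if limit <= 0:
            raise ValueError("detection limit must be positive")
        x_obs = np.log(obs)
        L = np.log(limit)
        mu, sigma = float(np.mean(x_obs)), float(np.std(x_obs, ddof=0))
        sigma = max(sigma, 1e-6)
        self.n_iter_ = 0
        if n_cens == 0:
            self.mu_, self.sigma_, self.limit_ = mu, sigma, limit
            self.converged_ = True
            return self
        for it in range(self.max_iter):
            alpha = (L - mu) / sigma
            lam = np.exp(stats.norm.logpdf(alpha) - stats.norm.logcdf(alpha))
            ez = -lam  # E[z | z < alpha], standard normal
            ez2 = 1.0 - alpha * lam
            ex = mu + sigma * ez
            ex2 = mu**2 + 2 * mu * sigma * ez + sigma**2 * ez2
            s1 = x_obs.sum() + n_cens * ex
            s2 = (x_obs**2).sum() + n_cens * ex2
            mu_new = s1 / n
            var_new = max(s2 / n - mu_new**2, 1e-12)
            sigma_new = np.sqrt(var_new)
            delta = abs(mu_new - mu) + abs(sigma_new - sigma)
            mu, sigma = float(mu_new), float(sigma_new)
            self.n_iter_ = it + 1
            if delta < self.tol:
                break
        self.converged_ = delta < self.tol
        self.mu_, self.sigma_, self.limit_ = mu, sigma, limit
        return self

    def conditional_mean_below_limit(self) -> float:
        """E[X | X < limit] on the natural scale (always < limit)."""
        mu, sigma, L = self.mu_, self.sigma_, np.log(self.limit_)
        alpha = (L - mu) / sigma
        log_num = stats.norm.logcdf(alpha - sigma)
        log_den = stats.norm.logcdf(alpha)
        return float(np.exp(mu + sigma**2 / 2.0 + log_num - log_den))

    def transform(self, values, censored):
        values = np.asarray(values, float).copy()
        values[np.asarray(censored, bool)] = self.conditional_mean_below_limit()
        return values


def impute_below_llod(records: pd.DataFrame, llod: float) -> pd.DataFrame:
    """Impute ``below_llod`` records for one analyte; returns updated records."""
    out = records.copy()
    cens = (out["status"] == "below_llod").to_numpy()
    if not cens.any():
        return out
    quantified = out["status"].isin(["quantified", "capped_ulod"]).to_numpy()
    values = out["conc"].to_numpy(float).copy()
    values[cens] = llod / 2.0  # placeholder, replaced by EM conditional mean
    em = CensoredLognormalImputer().fit(values[quantified | cens], cens[quantified | cens], llod)
    imputed = em.conditional_mean_below_limit()
    out.loc[cens, "conc"] = imputed
    out.loc[cens, "status"] = "imputed_below_llod"
    out.loc[cens, "log_conc"] = np.log(imputed)
    out.attrs["em_params"] = {"mu": em.mu_, "sigma": em.sigma_, "n_iter": em.n_iter_}
    return out


# ---------------------------------------------------------------------------
# panel-level rules
# ---------------------------------------------------------------------------

def apply_panel_exclusions(panel: pd.DataFrame, curves: dict) -> tuple[list, pd.DataFrame]:
    """Exclude analytes with more than 25% of measurements outside
    [LLOQ, ULOQ]; the threshold is strict (exactly 25% is retained)."""
    rows = []
    for cyt, sub in panel.groupby("cytokine"):
        curve = curves[cyt]
        conc = sub["conc"].to_numpy(float)
        out_frac = float(np.mean((conc < curve.lloq) | (conc > curve.uloq)
                                 | ~np.isfinite(conc)))
        rows.append({"cytokine": cyt, "out_of_range_frac": out_frac,
                     "retained": out_frac <= 0.25})
    report = pd.DataFrame(rows).sort_values("cytokine").reset_index(drop=True)
    retained = report.loc[report["retained"], "cytokine"].tolist()
    return retained, report


def impute_missing_ga(samples: pd.DataFrame, by=("cohort", "visit")):
    """Fill missing gestational age with the mean observed GA of similar
    samples (same cohort and visit number); returns (samples, log)."""
    out = samples.copy()
    missing = out["ga_sampling"].isna()
    log_rows = []
    if missing.any():
        donor_means = out.loc[~missing].groupby(list(by))["ga_sampling"].mean()
        drop = []
        for idx in out.index[missing]:
            key = tuple(out.loc[idx, list(by)])
            if key in donor_means.index:
                val = float(donor_means.loc[key])
                out.loc[idx, "ga_sampling"] = val
                log_rows.append({"sample_id": out.loc[idx, "sample_id"],
                                 "imputed_ga": val, "donor_group": str(key)})
            else:
                warnings.warn(f"sample {out.loc[idx, 'sample_id']}: no donor group; dropped")
                drop.append(idx)
        out = out.drop(index=drop)
    return out, pd.DataFrame(log_rows, columns=["sample_id", "imputed_ga", "donor_group"])


def screen_outliers(panel: pd.DataFrame, participants: pd.DataFrame,
                    quantile: float = 0.999, min_cohort: int = 10) -> pd.DataFrame:
    """Advisory PCA outlier screen per cohort.

    Per cohort: PCA on the autoscaled log panel (samples x analytes); robust
    Mahalanobis distance on (PC1, PC2); flag participants with any sample
    beyond the chi-square(2) ``quantile``.  Removal stays opt-in (the screen
    mirrors manual score inspection).
    """
    from sklearn.covariance import MinCovDet
    from sklearn.decomposition import PCA

    wide = panel.pivot_table(index="sample_id", columns="cytokine", values="log_conc")
    meta = panel.drop_duplicates("sample_id").set_index("sample_id")
    cohort_of = meta["cohort"]
    pid_of = meta["participant_id"]
    thresh = stats.chi2.ppf(quantile, df=2)
    flagged = []
    for cohort, ids in cohort_of.groupby(cohort_of).groups.items():
        sub = wide.loc[wide.index.intersection(ids)].dropna(axis=0, how="any")
        n_part = pid_of.loc[sub.index].nunique()
        if n_part < min_cohort:
            continue
        X = sub.to_numpy(float)
        keep = X.std(axis=0) > 0
        if not keep.all():
            warnings.warn(f"cohort {cohort}: constant analyte column(s) dropped from PCA")
            X = X[:, keep]
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        scores = PCA(n_components=2, random_state=0).fit_transform(X)
        mcd = MinCovDet(random_state=0).fit(scores)
        d2 = mcd.mahalanobis(scores)
        for sid, dist in zip(sub.index, d2):
            if dist > thresh:
                flagged.append({"participant_id": pid_of.loc[sid], "sample_id": sid,
                                "cohort": cohort, "distance2": float(dist)})
    return pd.DataFrame(flagged, columns=["participant_id", "sample_id", "cohort", "distance2"])


def cohort_accounting(participants: pd.DataFrame | None = None,
                      outlier_ids=(), samples: pd.DataFrame | None = None,
                      counts: dict | None = None) -> dict:
    """Exclusion accounting with a fixed priority order.

    Either derive category counts from a participant table with eligibility
    fields (``complication`` flag, ``bmi``, ``has_samples``) plus an outlier
    removal list, or pass printed ``counts`` directly (keys: assessed,
    complications, bmi_low, bmi_high, missing_samples, outliers).  Overlaps
    resolve as complications > BMI > missing samples; categories are
    mutually exclusive and always sum to the assessed total.
    """
    report: dict = {}
    if counts is not None:
        c = dict(counts)
        assessed = int(c["assessed"])
        excl = {k: int(c.get(k, 0)) for k in
                ("complications", "bmi_low", "bmi_high", "missing_samples")}
        outliers = int(c.get("outliers", 0))
    elif participants is not None:
        assessed = len(participants)
        comp = participants.get("complication", pd.Series(False, index=participants.index)).astype(bool)
        bmi = participants["bmi"].astype(float)
        has = participants.get("has_samples", pd.Series(True, index=participants.index)).astype(bool)
        cat = np.select(
            [comp, (~comp) & (bmi < 18.5), (~comp) & (bmi >= 40.0),
             (~comp) & (bmi >= 18.5) & (bmi < 40.0) & (~has)],
            ["complications", "bmi_low", "bmi_high", "missing_samples"],
            default="eligible",
        )
        excl = {k: int((cat == k).sum()) for k in
                ("complications", "bmi_low", "bmi_high", "missing_samples")}
        eligible_ids = participants.loc[cat == "eligible", "participant_id"]
        outliers = int(eligible_ids.isin(set(outlier_ids)).sum())
    else:
        raise ValueError("provide either a participant table or printed counts")

    total_excluded = sum(excl.values())
    included = assessed - total_excluded - outliers
    report.update({
        "assessed": assessed,
        "excluded": excl,
        "excluded_total": total_excluded,
        "outliers_removed": outliers,
        "final_included": included,
    })
    if participants is not None and counts is None:
        kept = participants.loc[
            (~participants["participant_id"].isin(set(outlier_ids)))
            & participants["participant_id"].isin(set(eligible_ids))
        ]
        grp = kept["study_group"].value_counts().to_dict()
        report["study_groups"] = {k: int(grp.get(k, 0)) for k in ("term", "late_term")}
        if samples is not None:
            s = samples[samples["participant_id"].isin(kept["participant_id"])]
            tri = trimester(s["ga_sampling"])
            cnt = pd.Series(tri).value_counts()
            term_counts = {t: int(cnt.get(t, 0)) for t in ("T1", "T2", "T3")}
            report["trimester_counts"] = term_counts
            report["trimester_percent"] = trimester_shares(term_counts)
    assert report["assessed"] == (report["final_included"] + report["excluded_total"]
                                  + report["outliers_removed"])
    return report


def trimester_shares(counts: dict) -> dict:
    """Integer-rounded percentage shares of per-trimester sample counts."""
    total = sum(counts.values())
    if total == 0:
        return {k: 0 for k in counts}
    return {k: int(np.floor(100.0 * v / total + 0.5)) for k, v in counts.items()}


# ---------------------------------------------------------------------------
# normalization / covariates
# ---------------------------------------------------------------------------

class PanelNormalizer:
    """Per-analyte normalization (sklearn-style transformer).

    ``scheme='rmasca'``: subtract the overall mean (across cohorts) and
    divide by the *unweighted mean* of the per-cohort standard deviations.
    ``scheme='zscore'``: plain per-analyte standardization (used for the
    late-term regressions).  Constants are stored for inverse transforms.
    """

    def __init__(self, scheme: str = "rmasca"):
        if scheme not in ("rmasca", "zscore"):
            raise ValueError("scheme must be 'rmasca' or 'zscore'")
        self.scheme = scheme

    def get_params(self, deep=True):
        return {"scheme": self.scheme}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, panel: pd.DataFrame, value_col: str = "log_conc"):
        self.value_col = value_col
        center, scale, flagged = {}, {}, []
        for cyt, sub in panel.groupby("cytokine"):
            v = sub[value_col].astype(float)
            mean = float(v.mean())
            if self.scheme == "rmasca":
                sds = sub.groupby("cohort")[value_col].std(ddof=1)
                sds = sds.dropna()
                if (sds <= 0).any() or sds.empty:
                    flagged.append(cyt)
                    continue
                div = float(sds.mean())
            else:
                div = float(v.std(ddof=1))
                if not div > 0:
                    flagged.append(cyt)
                    continue
            center[cyt], scale[cyt] = mean, div
        self.center_, self.scale_, self.flagged_ = center, scale, flagged
        return self

    def transform(self, panel: pd.DataFrame) -> pd.DataFrame:
        out = panel[panel["cytokine"].isin(self.center_)].copy()
        c = out["cytokine"].map(self.center_)
        s = out["cytokine"].map(self.scale_)
        out["value"] = (out[self.value_col].astype(float) - c) / s
        return out

    def fit_transform(self, panel: pd.DataFrame, value_col: str = "log_conc"):
        return self.fit(panel, value_col).transform(panel)

    def inverse_transform(self, panel: pd.DataFrame) -> pd.DataFrame:
        out = panel.copy()
        c = out["cytokine"].map(self.center_)
        s = out["cytokine"].map(self.scale_)
        out[self.value_col] = out["value"] * s + c
        return out


def normalize_panel(panel: pd.DataFrame, scheme: str = "rmasca"):
    """Functional wrapper around :class:`PanelNormalizer`; returns
    (normalized panel with a ``value`` column, fitted normalizer)."""
    norm = PanelNormalizer(scheme=scheme)
    return norm.fit_transform(panel), norm


def derive_covariates(participants: pd.DataFrame,
                      bw_reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Add BMI class (WHO cuts, left-closed), parity group, birth-weight
    z-score / percentile group, and BMI eligibility flag."""
    from .lateterm import birthweight_zscore

    out = participants.copy()
    bmi = out["bmi"].astype(float)
    out["bmi_class"] = np.select([bmi < 25.0, bmi < 30.0], ["normal", "overweight"], "obese")
    out["eligible_bmi"] = (bmi >= 18.5) & (bmi < 40.0)
    out["parity_group"] = np.where(out["parity"].astype(int) == 0, "nulliparous", "multiparous")
    if bw_reference is not None:
        z = birthweight_zscore(out["birth_weight"], out["ga_delivery"],
                               out["fetal_sex"], bw_reference)
        out["bw_zscore"] = z
        q25, q75 = stats.norm.ppf(0.25), stats.norm.ppf(0.75)
        out["bw_group"] = np.select([z < q25, z > q75], ["<25th", ">75th"], "25-75th")
    return out


# ---------------------------------------------------------------------------
# end-to-end preprocessing
# ---------------------------------------------------------------------------

def build_panel(fi_long, bridge_manifest, standards, samples, participants,
                reference_lot: str, anchor_ids=None, exclude: bool = True):
    """Full preprocessing: corrections, calibration, limits, censoring,
    exclusions; returns (panel, curves, reports).

    Standard and blank wells pass through the same FI corrections as
    samples; curves are fitted on reference-lot standards.
    """
    fi1, inter = correct_inter_lot(fi_long, bridge_manifest, reference_lot)
    fi2, intra = apply_intra_lot_adjustment(fi1, anchor_ids=anchor_ids)

    # intra-lot corrections also apply to standards (same plates)
    std = standards.copy()
    intra_map = {(f.lot_id, f.plate_id, f.cytokine): f.delta_log for f in intra}
    deltas = np.array([
        intra_map.get((lo, pl, cy), 0.0)
        for lo, pl, cy in zip(std["lot"], std["plate"], std["cytokine"])
    ])
    std["fi"] = np.exp(np.log(std["fi"]) + deltas)

    curves, records = {}, []
    for cyt in sorted(set(fi_long["cytokine"])):
        ref_std = std[(std["cytokine"] == cyt) & (std["lot"] == reference_lot)]
        curve = fit_standard_curve(ref_std, cyt)
        blanks = fi2[(fi2["cytokine"] == cyt) & (fi2["role"] == "blank")
                     & (fi2["lot"] == reference_lot)]["fi"]
        curve = estimate_limits(curve, blanks.to_numpy())
        curves[cyt] = curve
        sample_fi = fi2[(fi2["cytokine"] == cyt) & (fi2["role"] == "sample")]
        recs = fi_to_concentration(sample_fi, curve)
        if (recs["status"] == "below_llod").any():
            try:
                recs = impute_below_llod(recs, curve.llod)
            except CensoringError:
                curve.flags.append("censoring_over_limit")
        records.append(recs)
    panel = pd.concat(records, ignore_index=True)

    reports = {"inter_lot": [f.__dict__ for f in inter]}
    if exclude:
        retained, excl_report = apply_panel_exclusions(panel, curves)
        panel = panel[panel["cytokine"].isin(retained)].reset_index(drop=True)
        reports["exclusions"] = excl_report
    panel = panel.merge(samples[["sample_id", "participant_id", "visit", "ga_sampling", "cohort"]],
                        on="sample_id", how="left")
    panel["trimester"] = trimester(panel["ga_sampling"])
    keep_cols = [c for c in ("participant_id", "study_group", "bmi_class", "smoking",
                             "parity", "fetal_sex", "bw_group", "age", "bmi",
                             "ga_delivery")
                 if c in participants.columns]
    panel = panel.merge(participants[keep_cols], on="participant_id", how="left")
    return panel, curves, reports
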