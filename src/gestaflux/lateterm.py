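"""Analyses of pregnancies beyond week 40+3.

* term vs late-term per-analyte comparisons (Mann-Whitney U on log
  concentrations, optional exclusion of women delivering within four days);
* association with time to spontaneous labor via Fine-Gray subdistribution
  hazards regression with competing risks (censoring-weighted Cox partial
  likelihood, one analyte at a time);
* prediction of spontaneous labor within four days via O-PLS-DA with
  holdout metrics and label-permutation testing;
* linear regressions of late-term analyte levels on maternal/fetal
  covariates, with birth-weight z-scores from a configurable reference.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .gestation import LATE_TERM_AFTER_DAY, TERM_DELIVERY_MIN_DAY
from .trajectories import bh_adjust

__all__ = [
    "compare_term_lateterm",
    "FineGrayEstimator",
    "fit_fine_gray",
    "OPLSDA",
    "fit_oplsda",
    "evaluate_and_permute",
    "lateterm_regressions",
    "birthweight_zscore",
]

EVENT_CODES = {"spontaneous": 1, "induced_clinical": 2, "cesarean": 2,
               "induced_randomized": 0}


# ---------------------------------------------------------------------------
# term vs late-term comparison
# ---------------------------------------------------------------------------

def compare_term_lateterm(panel: pd.DataFrame,
                          exclude_within_days: int | None = None) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per analyte: term (GA at sampling in
    [259, 283] days) vs late term (GA > 283), on log concentrations.

    With ``exclude_within_days`` set (the sensitivity analysis uses 4),
    women with any delivery within that many days of sampling are removed
    first.  BH adjustment across analytes.
    """
    df = panel.dropna(subset=["log_conc", "ga_sampling"]).copy()
    df = df[df["ga_sampling"] >= TERM_DELIVERY_MIN_DAY]
    if exclude_within_days is not None:
        days_left = df["ga_delivery"].astype(float) - df["ga_sampling"].astype(float)
        df = df[days_left > exclude_within_days]
    if df.empty:
        raise ValueError("comparison groups emptied"
                         + (" by the delivery-window exclusion" if exclude_within_days else ""))
    late = df["ga_sampling"] > LATE_TERM_AFTER_DAY
    rows = []
    for cyt, sub in df.groupby("cytokine"):
        x = sub.loc[late.loc[sub.index], "log_conc"].to_numpy(float)
        y = sub.loc[~late.loc[sub.index], "log_conc"].to_numpy(float)
        if len(x) == 0 or len(y) == 0:
            raise ValueError(
                f"{cyt}: a comparison group is empty"
                + (" after the delivery-window exclusion" if exclude_within_days else "")
            )
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        rows.append({
            "cytokine": cyt, "U": float(res.statistic), "p": float(res.pvalue),
            "median_late": float(np.median(np.exp(x))),
            "median_term": float(np.median(np.exp(y))),
            "n_late": len(x), "n_term": len(y),
        })
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"])
    return out


# ---------------------------------------------------------------------------
# Fine-Gray subdistribution hazards
# ---------------------------------------------------------------------------

def _km_censoring(times, events):
    """Kaplan-Meier estimate of the censoring survival function G; returns a
    step-function evaluator (right-continuous)."""
    order = np.argsort(times, kind="stable")
    t = np.asarray(times, float)[order]
    cens = (np.asarray(events)[order] == 0)
    uniq = np.unique(t)
    n = len(t)
    surv, s = [], 1.0
    at_risk = n
    for u in uniq:
        here = t == u
        d = int((cens & here).sum())
        if at_risk > 0 and d > 0:
            s *= 1.0 - d / at_risk
        at_risk -= int(here.sum())
        surv.append(s)
    surv = np.asarray(surv)

    def G(q):
        q = np.asarray(q, float)
        idx = np.searchsorted(uniq, q, side="right") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return out

    return G


class FineGrayEstimator:
    """Fine-Gray subdistribution hazard regression (competing risks).

    Event coding: 1 = event of interest (spontaneous labor), 2 = competing
    event (clinically indicated induction / cesarean), 0 = censored
    (randomized induction without labor).  Subjects with a competing event
    remain in the risk set with inverse-probability-of-censoring (Kaplan-
    Meier) weights; ties are handled by Breslow's method and the score
    equation is solved by Newton iterations to gradient norm < 1e-8.

    Model-based (inverse-information) standard errors are reported; they are
    exact partial-likelihood SEs when no independent censoring is present.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def get_params(self, deep=True):
        return {"tol": self.tol, "max_iter": self.max_iter}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def fit(self, X, durations, events):
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != len(durations):
            X = X.T
        t = np.asarray(durations, float)
        ev = np.asarray(events)
        if np.issubdtype(ev.dtype, np.str_) or ev.dtype == object:
            ev = np.array([EVENT_CODES[e] for e in ev])
        n, p = X.shape
        if (ev == 1).sum() < 2:
            raise ValueError("need >= 2 events of interest")

        G = _km_censoring(t, ev)
        ev_times = np.unique(t[ev == 1])
        K = len(ev_times)
        # weight matrix W[k, j]: subject j's weight in the risk set at event
        # time s_k under the subdistribution risk-set convention
        W = np.zeros((K, n))
        Gs = G(ev_times)
        Gt = G(t)
        for k, s in enumerate(ev_times):
            at_risk = t >= s
            prior_competing = (ev == 2) & (t < s)
            W[k, at_risk] = 1.0
            with np.errstate(divide="ignore", invalid="ignore"):
                w2 = np.where(Gt > 0, Gs[k] / Gt, 0.0)
            W[k, prior_competing] = w2[prior_competing]
        d_k = np.array([(ev == 1)[t == s].sum() for s in ev_times], float)
        x_events = np.vstack([X[(t == s) & (ev == 1)].sum(axis=0) for s in ev_times])

        beta = np.zeros(p)
        loglik = -np.inf
        for it in range(self.max_iter):
            r = np.exp(np.clip(X @ beta, -500, 500))
            S0 = W @ r
            S1 = W @ (r[:, None] * X)
            Ebar = S1 / S0[:, None]
            ll = float(np.sum(x_events @ beta) - np.sum(d_k * np.log(S0)))
            grad = (x_events - d_k[:, None] * Ebar).sum(axis=0)
            S2 = np.einsum("kj,j,jp,jq->kpq", W, r, X, X)
            H = -np.einsum("k,kpq->pq", d_k, S2 / S0[:, None, None]) \
                + np.einsum("k,kp,kq->pq", d_k, Ebar, Ebar)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError("singular information matrix") from exc
            new_beta = beta - step
            # step-halving if the likelihood does not improve
            for _ in range(30):
                r2 = np.exp(np.clip(X @ new_beta, -500, 500))
                ll_new = float(np.sum(x_events @ new_beta)
                               - np.sum(d_k * np.log(W @ r2)))
                if ll_new >= ll - 1e-12 or not np.isfinite(ll):
                    break
                new_beta = (beta + new_beta) / 2.0
            beta = new_beta
            loglik = ll_new
            if np.linalg.norm(grad) < self.tol:
                break
        if np.any(np.abs(beta) > 50):
            raise RuntimeError("monotone likelihood: estimate diverged")
        self.converged_ = np.linalg.norm(grad) < max(self.tol, 1e-6)
        if not self.converged_:
            raise RuntimeError("Newton iterations did not converge")
        cov = np.linalg.inv(-H)
        self.coef_ = beta
        self.se_ = np.sqrt(np.diag(cov))
        self.cov_ = cov
        self.loglik_ = loglik
        z = beta / self.se_
        self.p_ = 2.0 * stats.norm.sf(np.abs(z))
        self.hazard_ratios_ = np.exp(beta)
        return self


def fit_fine_gray(outcomes: pd.DataFrame, X: pd.DataFrame) -> pd.DataFrame:
    """Univariate Fine-Gray fit per analyte.

    ``outcomes``: participant_id, days_to_delivery, event (labels or codes);
    ``X``: normalized log-concentration matrix indexed by participant_id
    (one sampling-time row per woman).  BH adjustment across analytes.
    """
    merged = outcomes.set_index("participant_id").join(X, how="inner")
    if (pd.Series(merged["event"]).map(EVENT_CODES).fillna(merged["event"]) == 1).sum() < 10:
        raise ValueError("need >= 10 events of interest")
    rows = []
    for cyt in X.columns:
        try:
            est = FineGrayEstimator().fit(
                merged[[cyt]].to_numpy(), merged["days_to_delivery"].to_numpy(),
                merged["event"].to_numpy(),
            )
            rows.append({"cytokine": cyt, "beta": float(est.coef_[0]),
                         "se": float(est.se_[0]), "hr": float(est.hazard_ratios_[0]),
                         "p": float(est.p_[0]), "converged": True})
        except RuntimeError as exc:
            warnings.warn(f"{cyt}: {exc}")
            rows.append({"cytokine": cyt, "beta": np.nan, "se": np.nan,
                         "hr": np.nan, "p": np.nan, "converged": False})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"])
    return out


# ---------------------------------------------------------------------------
# O-PLS-DA
# ---------------------------------------------------------------------------

class OPLSDA:
    """Orthogonalized PLS discriminant analysis with a single predictive
    component.

    ``n_orth`` y-orthogonal components are removed by orthogonal projection
    before the predictive component is extracted; classification thresholds
    the predictive score at the cut maximizing training balanced accuracy.
    VIP is computed from the predictive-component weights (mean squared VIP
    is 1 by construction).
    """

    def __init__(self, n_orth: int = 1, scale: bool = True):
        self.n_orth = n_orth
        self.scale = scale

    def get_params(self, deep=True):
        return {"n_orth": self.n_orth, "scale": self.scale}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    def _prep(self, X):
        X = np.asarray(X, float)
        X = X[:, self.keep_]
        return (X - self.x_mean_) / self.x_sd_

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("O-PLS-DA requires exactly two classes")
        counts = [(y == c).sum() for c in self.classes_]
        if min(counts) < 5:
            raise ValueError("both classes need >= 5 members")
        sd = X.std(axis=0, ddof=1)
        self.keep_ = sd > 0
        if not self.keep_.all():
            warnings.warn(f"{int((~self.keep_).sum())} constant column(s) removed")
        X = X[:, self.keep_]
        if self.scale:
            self.x_mean_, self.x_sd_ = X.mean(axis=0), X.std(axis=0, ddof=1)
        else:
            self.x_mean_, self.x_sd_ = np.zeros(X.shape[1]), np.ones(X.shape[1])
        Xc = (X - self.x_mean_) / self.x_sd_
        if self.n_orth >= np.linalg.matrix_rank(Xc):
            raise ValueError("n_orth must be below the rank of X")
        yc = np.where(y == self.classes_[1], 1.0, -1.0)
        yc = yc - yc.mean()

        W_o, P_o = [], []
        Xf = Xc.copy()
        for _ in range(self.n_orth):
            w = Xf.T @ yc
            w /= np.linalg.norm(w)
            t = Xf @ w
            p_load = Xf.T @ t / (t @ t)
            w_o = p_load - (w @ p_load) * w
            nrm = np.linalg.norm(w_o)
            if nrm < 1e-12:
                break
            w_o /= nrm
            t_o = Xf @ w_o
            p_o = Xf.T @ t_o / (t_o @ t_o)
            Xf = Xf - np.outer(t_o, p_o)
            W_o.append(w_o)
            P_o.append(p_o)
        self.orth_weights_ = np.array(W_o)
        self.orth_loadings_ = np.array(P_o)

        w = Xf.T @ yc
        w /= np.linalg.norm(w)
        t = Xf @ w
        self.weights_ = w
        self.loadings_ = Xf.T @ t / (t @ t)
        self.q_ = float(yc @ t / (t @ t))
        self.scores_ = t
        p_eff = Xc.shape[1]
        self.vip_ = np.sqrt(p_eff) * np.abs(w)  # ||w|| == 1 -> mean(VIP^2) == 1

        # training threshold maximizing balanced accuracy
        pos = y == self.classes_[1]
        order = np.argsort(t)
        cand = np.concatenate([[t.min() - 1], (t[order][1:] + t[order][:-1]) / 2,
                               [t.max() + 1]])
        best_acc, best_thr = -1.0, 0.0
        for thr in cand:
            pred_pos = t > thr
            sens = (pred_pos & pos).sum() / max(pos.sum(), 1)
            spec = (~pred_pos & ~pos).sum() / max((~pos).sum(), 1)
            bal = (sens + spec) / 2.0
            if bal > best_acc:
                best_acc, best_thr = bal, float(thr)
        self.threshold_ = best_thr
        self.training_balanced_accuracy_ = best_acc
        return self

    def decision_function(self, X):
        Xf = self._prep(X)
        for w_o, p_o in zip(self.orth_weights_, self.orth_loadings_):
            t_o = Xf @ w_o
            Xf = Xf - np.outer(t_o, p_o)
        return Xf @ self.weights_

    def predict(self, X):
        return np.where(self.decision_function(X) > self.threshold_,
                        self.classes_[1], self.classes_[0])


def fit_oplsda(X, y, n_orth: int = 1) -> OPLSDA:
    """Fit an O-PLS-DA model on an (autoscaled) analyte matrix."""
    return OPLSDA(n_orth=n_orth).fit(X, y)


def _holdout_metrics(model, X_te, y_te, pos_label):
    pred = model.predict(X_te)
    err = float(np.mean(pred != y_te))
    pos = y_te == pos_label
    sens = float((pred[pos] == pos_label).mean()) if pos.any() else np.nan
    spec = float((pred[~pos] != pos_label).mean()) if (~pos).any() else np.nan
    return err, sens, spec


def _stratified_split(y, holdout, rng):
    idx_tr, idx_te = [], []
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        rng.shuffle(idx)
        n_te = max(int(round(len(idx) * holdout)), 1)
        idx_te.extend(idx[:n_te])
        idx_tr.extend(idx[n_te:])
    return np.asarray(idx_tr), np.asarray(idx_te)


def evaluate_and_permute(X, y, n_orth: int = 1, n_perm: int = 1000,
                         holdout: float = 0.10, seed: int = 0,
                         pos_label=None) -> dict:
    """Holdout metrics of the labor classifier plus a permutation p value.

    One stratified 90/10 split yields the observed classification error,
    sensitivity and specificity; each permutation shuffles the outcome,
    redraws a split, refits, and records the holdout error.  The p value is
    the (add-one smoothed) proportion of permutations with error less than
    or equal to the observed error, never below 1/(n_perm + 1).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if len(y) < 20:
        raise ValueError("need n >= 20 for holdout evaluation")
    if pos_label is None:
        pos_label = np.unique(y)[1]
    rng = np.random.default_rng(seed)
    idx_tr, idx_te = _stratified_split(y, holdout, rng)
    model = OPLSDA(n_orth=n_orth).fit(X[idx_tr], y[idx_tr])
    err, sens, spec = _holdout_metrics(model, X[idx_te], y[idx_te], pos_label)

    perm_errors = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(y)
        # stratified splitting guarantees both classes on each side
        itr, ite = _stratified_split(yp, holdout, rng)
        try:
            m = OPLSDA(n_orth=n_orth).fit(X[itr], yp[itr])
            perm_errors[b] = np.mean(m.predict(X[ite]) != yp[ite])
        except ValueError:
            perm_errors[b] = 1.0
    p = (1.0 + np.sum(perm_errors <= err)) / (n_perm + 1.0)
    return {
        "error_rate": err, "accuracy": 1.0 - err,
        "sensitivity": sens, "specificity": spec,
        "permutation_p": float(p), "n_perm": n_perm,
        "perm_errors": perm_errors, "model": model,
    }


# ---------------------------------------------------------------------------
# late-term covariate regressions / birth-weight z-scores
# ---------------------------------------------------------------------------

def birthweight_zscore(weight, ga_delivery, sex, reference: pd.DataFrame):
    """z = (weight - ref_mean(GA, sex)) / ref_sd(GA, sex), linearly
    interpolating the reference table between tabulated GA points; GA outside
    the table's support is clamped to the nearest endpoint (with a warning).
    """
    weight = np.asarray(weight, float)
    ga = np.asarray(ga_delivery, float)
    sex = np.asarray(sex)
    z = np.full(len(np.atleast_1d(weight)), np.nan)
    weight, ga, sex = np.atleast_1d(weight), np.atleast_1d(ga), np.atleast_1d(sex)
    for s in np.unique(sex):
        ref = reference[reference["sex"] == s].sort_values("ga_days")
        if ref.empty:
            raise ValueError(f"reference table has no rows for sex {s!r}")
        m = sex == s
        lo, hi = ref["ga_days"].iloc[0], ref["ga_days"].iloc[-1]
        if np.any((ga[m] < lo) | (ga[m] > hi)):
            warnings.warn("gestational age outside reference support; "
                          "nearest-endpoint extrapolation used")
        gac = np.clip(ga[m], lo, hi)
        mean = np.interp(gac, ref["ga_days"], ref["mean_g"])
        sd = np.interp(gac, ref["ga_days"], ref["sd_g"])
        z[m] = (weight[m] - mean) / sd
    return z if z.size > 1 else float(z[0])


def lateterm_regressions(panel_z: pd.DataFrame, participants: pd.DataFrame,
                         bw_reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-analyte linear models of normalized late-term levels on maternal
    age, BMI, parity and birth-weight z-score (continuous, standardized) plus
    smoking and fetal sex (categorical; references non-smoking / female).

    ``panel_z`` must hold one z-score-normalized sample per late-term
    participant with a ``value`` column.  BH correction spans the full
    analyte x covariate grid.
    """
    import statsmodels.api as sm

    cov = participants.set_index("participant_id").copy()
    if "bw_zscore" not in cov.columns:
        if bw_reference is None:
            raise ValueError("need bw_zscore column or a reference table")
        cov["bw_zscore"] = birthweight_zscore(
            cov["birth_weight"], cov["ga_delivery"], cov["fetal_sex"], bw_reference
        )
    design = pd.DataFrame(index=cov.index)
    for col in ("age", "bmi", "parity", "bw_zscore"):
        v = cov[col].astype(float)
        design[col] = (v - v.mean()) / v.std(ddof=1)
    design["smoking"] = cov["smoking"].astype(bool).astype(float)
    design["fetal_sex_male"] = (cov["fetal_sex"] == "male").astype(float)
    design = sm.add_constant(design)
    cond = np.linalg.cond(design.to_numpy())
    if cond > 1e4:
        warnings.warn(f"collinear covariates: condition number {cond:.1e}")

    rows = []
    for cyt, sub in panel_z.groupby("cytokine"):
        per_part = sub.drop_duplicates("participant_id").set_index("participant_id")
        if per_part["value"].index.duplicated().any() or len(per_part) != len(sub["participant_id"].unique()):
            raise ValueError("expected one sample per late-term participant")
        common = design.index.intersection(per_part.index)
        Xd = design.loc[common]
        yv = per_part.loc[common, "value"].astype(float)
        res = sm.OLS(yv, Xd).fit()
        for term in design.columns:
            if term == "const":
                continue
            rows.append({"cytokine": cyt, "covariate": term,
                         "coef": float(res.params[term]), "se": float(res.bse[term]),
                         "p": float(res.pvalues[term])})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"])
    return out
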