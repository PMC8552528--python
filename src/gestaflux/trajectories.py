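"""Gestational trajectory modelling per analyte.

Continuous curves come from an additive mixed model (penalized cubic
regression spline over gestational age + cohort fixed effects + participant
random intercept) fitted to *untransformed* concentrations; trimester-binned
contrasts come from linear mixed models on *log* concentrations with the
first trimester as baseline.  A subsampling screen (50 refits on stratified
80% subsets, mean Spearman correlation against the mean-of-runs curve,
threshold 0.90) flags analytes whose continuous trajectory is unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._pspline import PSplineMixedModel

__all__ = [
    "TrajectoryFit",
    "RobustnessReport",
    "fit_trajectory",
    "assess_robustness",
    "fit_trimester_lmm",
    "trimester_effects_panel",
    "correlations_by_trimester",
    "bh_adjust",
]

RELIABILITY_THRESHOLD = 0.90


def bh_adjust(pvals):
    """Benjamini-Hochberg adjusted p values (NaN-safe)."""
    p = np.asarray(pvals, float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class TrajectoryFit:
    cytokine: str
    grid: np.ndarray
    mean_curve: np.ndarray
    band: tuple  # (lower, upper) pointwise 95%
    smoothing: float
    cohort_effects: dict
    subject_variance: float
    model: PSplineMixedModel = field(repr=False, default=None)

    def __call__(self, ga):
        return self.model.predict_curve(np.asarray(ga, float))


def _cohort_dummies(cohorts):
    levels = sorted(pd.unique(cohorts))
    ref = levels[0]
    cols = {f"cohort[{lv}]": (np.asarray(cohorts) == lv).astype(float)
            for lv in levels[1:]}
    return (np.column_stack(list(cols.values())) if cols else None,
            list(cols.keys()), ref)


def fit_trajectory(panel_slice: pd.DataFrame, n_basis: int = 10,
                   grid: np.ndarray | None = None, grid_size: int = 100) -> TrajectoryFit:
    """Fit one analyte's continuous trajectory.

    ``panel_slice`` needs columns conc, ga_sampling, cohort, participant_id.
    The curve is evaluated at the reference cohort on ``grid`` (default: 100
    equispaced points between the 1st and 99th GA percentiles).
    """
    df = panel_slice.dropna(subset=["conc", "ga_sampling"])
    if len(df) < 30:
        raise ValueError("need >= 30 observations to fit a trajectory")
    ga = df["ga_sampling"].to_numpy(float)
    if len(np.unique(ga)) < 2:
        raise ValueError("need >= 2 distinct gestational ages")
    y = df["conc"].to_numpy(float)
    fixed, names, _ = _cohort_dummies(df["cohort"])
    model = PSplineMixedModel(n_basis=n_basis)
    try:
        model.fit(ga, y, groups=df["participant_id"].to_numpy(), fixed=fixed)
    except np.linalg.LinAlgError:
        warnings.warn("singular spline fit; falling back to reduced basis")
        model = PSplineMixedModel(n_basis=max(4, n_basis // 2))
        model.fit(ga, y, groups=df["participant_id"].to_numpy(), fixed=fixed)
    if grid is None:
        grid = np.linspace(np.percentile(ga, 1), np.percentile(ga, 99), grid_size)
    curve = model.predict_curve(grid)
    lo, hi = model.curve_band(grid)
    cohort_fx = dict(zip(names, model.coef_[2:2 + len(names)]))
    cyt = df["cytokine"].iloc[0] if "cytokine" in df else ""
    return TrajectoryFit(
        cytokine=cyt, grid=np.asarray(grid), mean_curve=curve, band=(lo, hi),
        smoothing=model.smoothing_, cohort_effects=cohort_fx,
        subject_variance=model.subject_variance_, model=model,
    )


@dataclass
class RobustnessReport:
    cytokine: str
    run_curves: np.ndarray  # runs x grid
    rho: np.ndarray
    mean_rho: float
    reliable: bool
    grid: np.ndarray
    n_failed: int = 0


def assess_robustness(panel_slice: pd.DataFrame, n_runs: int = 50,
                      drop_frac: float = 0.20, seed: int = 0,
                      n_basis: int = 10, grid_size: int = 100,
                      min_successful: int | None = None) -> RobustnessReport:
    """Trajectory stability screen by stratified participant subsampling.

    Each run refits the trajectory on a random (100*(1-drop_frac))% of
    participants, stratified by cohort; runs are compared with the
    mean-of-runs curve via Spearman correlation on a common grid, and the
    analyte is flagged unreliable when the average correlation falls below
    0.90.
    """
    rng = np.random.default_rng(seed)
    parts = panel_slice[["participant_id", "cohort"]].drop_duplicates()
    ga = panel_slice["ga_sampling"].to_numpy(float)
    grid = np.linspace(np.percentile(ga, 1), np.percentile(ga, 99), grid_size)
    curves, n_failed = [], 0
    for _ in range(n_runs):
        keep_ids = []
        for _, sub in parts.groupby("cohort"):
            ids = sub["participant_id"].to_numpy()
            n_keep = max(int(round(len(ids) * (1.0 - drop_frac))), 1)
            keep_ids.extend(rng.choice(ids, size=n_keep, replace=False))
        run_df = panel_slice[panel_slice["participant_id"].isin(keep_ids)]
        try:
            fit = fit_trajectory(run_df, n_basis=n_basis, grid=grid)
            curves.append(fit.mean_curve)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if min_successful is None:
        min_successful = max(int(0.8 * n_runs), 1)
    if len(curves) < min_successful:
        raise RuntimeError(f"only {len(curves)}/{n_runs} robustness runs succeeded")
    run_curves = np.asarray(curves)
    mean_curve = run_curves.mean(axis=0)
    rho = np.array([stats.spearmanr(rc, mean_curve).statistic for rc in run_curves])
    mean_rho = float(np.mean(rho))
    cyt = panel_slice["cytokine"].iloc[0] if "cytokine" in panel_slice else ""
    return RobustnessReport(
        cytokine=cyt, run_curves=run_curves, rho=rho, mean_rho=mean_rho,
        reliable=mean_rho >= RELIABILITY_THRESHOLD, grid=grid, n_failed=n_failed,
    )


def _fit_lmm(formula: str, data: pd.DataFrame, groups: str):
    from ._lmm import FormulaLMM

    return FormulaLMM(formula, data, groups)


def fit_trimester_lmm(panel_slice: pd.DataFrame) -> pd.DataFrame:
    """Per-trimester log-scale contrasts vs the first trimester.

    LMM: log concentration ~ trimester + cohort with participant random
    intercept; Wald tests per contrast.  Returns one row per represented
    non-baseline stratum (T2, T3, late_term).
    """
    df = panel_slice.dropna(subset=["log_conc"]).copy()
    present = [t for t in ("T1", "T2", "T3", "late_term") if t in set(df["trimester"])]
    if len(present) < 2:
        raise ValueError("need >= 2 trimesters represented")
    df["trimester"] = pd.Categorical(df["trimester"], categories=present)
    formula = "log_conc ~ C(trimester, Treatment('T1')) + C(cohort)"
    if df["cohort"].nunique() < 2:
        formula = "log_conc ~ C(trimester, Treatment('T1'))"
    res = _fit_lmm(formula, df, "participant_id")
    rows = []
    cyt = df["cytokine"].iloc[0] if "cytokine" in df else ""
    for t in present:
        if t == "T1":
            continue
        name = f"C(trimester, Treatment('T1'))[T.{t}]"
        if name not in res.params.index:
            warnings.warn(f"{cyt}: contrast {t} unrepresented; omitted")
            continue
        rows.append({
            "cytokine": cyt, "contrast": t,
            "estimate": float(res.params[name]),
            "se": float(res.bse[name]),
            "p": float(res.pvalues[name]),
        })
    return pd.DataFrame(rows)


def trimester_effects_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Trimester contrasts for every analyte with BH correction across the
    whole cytokine x contrast family."""
    frames = []
    for _, sub in panel.groupby("cytokine"):
        try:
            frames.append(fit_trimester_lmm(sub))
        except ValueError as exc:
            warnings.warn(str(exc))
    out = pd.concat(frames, ignore_index=True)
    out["p_adj"] = bh_adjust(out["p"])
    return out


def correlations_by_trimester(panel: pd.DataFrame, min_stratum: int = 10):
    """Pairwise Spearman correlations of log concentrations per gestational
    stratum (T1/T2/T3/late term), one sample per participant per stratum
    (earliest kept); BH adjustment over all pairs within a stratum.

    Returns ``{stratum: (rho DataFrame, p_adj DataFrame)}``.
    """
    results = {}
    for stratum, sub in panel.groupby("trimester", observed=True):
        dedup = (sub.sort_values("ga_sampling")
                 .drop_duplicates(["participant_id", "cytokine"], keep="first"))
        wide = dedup.pivot_table(index="participant_id", columns="cytokine",
                                 values="log_conc")
        wide = wide.dropna(axis=0, how="any")
        if len(wide) < min_stratum:
            warnings.warn(f"stratum {stratum}: {len(wide)} samples < {min_stratum}; skipped")
            continue
        cols = wide.columns
        if len(cols) < 2:
            continue
        rho_mat, p_mat = stats.spearmanr(wide.to_numpy())
        if np.ndim(rho_mat) == 0:  # scipy returns scalars for two variables
            rho_mat = np.array([[1.0, rho_mat], [rho_mat, 1.0]])
            p_mat = np.array([[0.0, p_mat], [p_mat, 0.0]])
        iu = np.triu_indices(len(cols), k=1)
        p_adj_flat = bh_adjust(p_mat[iu])
        p_adj = np.full_like(p_mat, np.nan)
        p_adj[iu] = p_adj_flat
        p_adj.T[iu] = p_adj_flat
        np.fill_diagonal(p_adj, 0.0)
        results[str(stratum)] = (
            pd.DataFrame(rho_mat, index=cols, columns=cols),
            pd.DataFrame(p_adj, index=cols, columns=cols),
        )
    return results
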