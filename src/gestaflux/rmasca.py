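"""Repeated-measures ASCA+ (RM-ASCA+).

Two-step multivariate decomposition of longitudinal panel data: first a
linear mixed model per analyte (fixed: time, group, time:group, cohort;
random: participant intercept), then PCA of the fixed-effect matrices.  The
time effect and the group + time:group interaction are separated into two
effect matrices so that within-group time trajectories and between-group
differences can be inspected independently.  Design cells are weighted by
their observation counts before the SVD (the unbalanced-data ASCA+
convention), and uncertainty comes from a stratified leave-subset-out
jackknife with component sign/order alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ModelSpec", "RMASCA", "fit_effect_models", "build_effect_matrices",
           "pca_effects", "jackknife_validate"]


@dataclass
class ModelSpec:
    """RM-ASCA+ model specification.

    ``group_col=None`` gives the pure time analysis (time + cohort only);
    otherwise fixed effects are time * group + cohort.  Reference levels:
    first time level (T1) and ``group_ref``.
    """

    time_col: str = "trimester"
    time_levels: tuple = ("T1", "T2", "T3")
    group_col: str | None = None
    group_ref: str | None = None
    covariate_col: str | None = "cohort"
    subject_col: str = "participant_id"
    value_col: str = "value"


def _fit_one_lmm(df: pd.DataFrame, formula: str, subject: str):
    from ._lmm import FormulaLMM

    return FormulaLMM(formula, df, subject)


class RMASCA:
    """RM-ASCA+ estimator (scikit-learn style).

    Fitted attributes: ``effect_matrices_`` (partition -> cells x analytes
    DataFrame, weighted-column-centered), ``scores_``, ``loadings_``,
    ``explained_variance_ratio_`` (per partition), ``cell_counts_``, and
    after :meth:`jackknife` the percentile ``bands_``.
    """

    def __init__(self, spec: ModelSpec | None = None, n_components: int = 2):
        self.spec = spec or ModelSpec()
        self.n_components = n_components

    def get_params(self, deep=True):
        return {"spec": self.spec, "n_components": self.n_components}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self

    # -- model fitting ------------------------------------------------------
    def _formula(self, df):
        s = self.spec
        t = f"C({s.time_col}, Treatment('{self._time_ref}'))"
        parts = [t]
        if s.group_col is not None:
            g = f"C({s.group_col}, Treatment('{self._group_ref}'))"
            parts = [t, g, f"{t}:{g}"]
        if s.covariate_col is not None and df[s.covariate_col].nunique() > 1:
            parts.append(f"C({s.covariate_col})")
        return f"{s.value_col} ~ " + " + ".join(parts)

    def fit(self, panel: pd.DataFrame):
        """``panel``: long normalized table with one row per observation and
        columns per :class:`ModelSpec` plus ``cytokine``."""
        s = self.spec
        df = panel.dropna(subset=[s.value_col]).copy()
        self._time_ref = s.time_levels[0]
        times = [t for t in s.time_levels if t in set(df[s.time_col])]
        if self._time_ref not in times:
            raise ValueError(f"baseline time level {self._time_ref!r} absent")
        if s.group_col is not None:
            glv = list(pd.unique(df[s.group_col]))
            ref = s.group_ref if s.group_ref is not None else sorted(glv)[0]
            if ref not in glv:
                raise ValueError(f"group reference {ref!r} absent")
            self._group_ref = ref
            groups = [ref] + sorted(g for g in glv if g != ref)
        else:
            self._group_ref = None
            groups = [None]
        self.time_levels_, self.group_levels_ = times, groups

        df = df[df[s.time_col].isin(times)]
        self.cytokines_ = sorted(df["cytokine"].unique())
        if len(self.cytokines_) < 2:
            raise ValueError("RM-ASCA+ needs >= 2 analytes")
        self.models_, self.aliased_ = {}, []
        for cyt in self.cytokines_:
            sub = df[df["cytokine"] == cyt]
            res = _fit_one_lmm(sub, self._formula(sub), s.subject_col)
            if not np.isfinite(res.params.to_numpy()).all():
                self.aliased_.append(cyt)
            self.models_[cyt] = res

        self._panel = df
        self._build_effect_matrices(df)
        self._pca()
        return self

    def coefficient_table(self) -> pd.DataFrame:
        rows = []
        for cyt, res in self.models_.items():
            for name, val in res.params.items():
                if name in ("Group Var",):
                    continue
                rows.append({"cytokine": cyt, "term": name, "estimate": float(val)})
        return pd.DataFrame(rows)

    def _cells(self, df):
        s = self.spec
        if s.group_col is None:
            obs = {(t, None) for t in df[s.time_col].unique()}
        else:
            obs = set(map(tuple, df[[s.time_col, s.group_col]].drop_duplicates().to_numpy()))
        cells, dropped = [], []
        for t in self.time_levels_:
            for g in self.group_levels_:
                if (t, g) in obs:
                    cells.append((t, g))
                else:
                    dropped.append((t, g))
        if dropped:
            warnings.warn(f"design cells missing from data, dropped: {dropped}")
        self.dropped_cells_ = dropped
        return cells

    def _cell_frame(self, cells, time=None, group=None):
        s = self.spec
        data = {s.time_col: [time if time is not None else c[0] for c in cells]}
        if s.group_col is not None:
            data[s.group_col] = [group if group is not None else c[1] for c in cells]
        if s.covariate_col is not None and self._has_covariate:
            data[s.covariate_col] = [self._covariate_ref] * len(cells)
        return pd.DataFrame(data)

    def _build_effect_matrices(self, df):
        s = self.spec
        cells = self._cells(df)
        self._has_covariate = (s.covariate_col is not None
                               and df[s.covariate_col].nunique() > 1)
        if self._has_covariate:
            self._covariate_ref = sorted(df[s.covariate_col].unique())[0]
        counts = []
        for t, g in cells:
            m = df[s.time_col] == t
            if g is not None:
                m &= df[s.group_col] == g
            counts.append(int(m.sum()) // max(len(self.cytokines_), 1))
        self.cell_counts_ = np.maximum(np.asarray(counts, float), 1.0)

        idx = pd.MultiIndex.from_tuples(cells, names=[s.time_col, s.group_col or "group"])
        time_m = pd.DataFrame(index=idx, columns=self.cytokines_, dtype=float)
        group_m = pd.DataFrame(index=idx, columns=self.cytokines_, dtype=float)
        for cyt in self.cytokines_:
            res = self.models_[cyt]
            base = self._cell_frame(cells, time=self._time_ref, group=self._group_ref)
            at_ref_group = self._cell_frame(cells, group=self._group_ref)
            full = self._cell_frame(cells)
            p0 = np.asarray(res.predict(exog=base), float)
            p_t = np.asarray(res.predict(exog=at_ref_group), float)
            p_f = np.asarray(res.predict(exog=full), float)
            time_m[cyt] = p_t - p0
            group_m[cyt] = p_f - p_t
        self.effect_matrices_raw_ = {"time": time_m}
        if s.group_col is not None:
            self.effect_matrices_raw_["group"] = group_m
        # weighted column centering (weights = cell observation counts)
        w = self.cell_counts_ / self.cell_counts_.sum()
        self.effect_matrices_ = {
            k: m - (m.mul(w, axis=0)).sum(axis=0)
            for k, m in self.effect_matrices_raw_.items()
        }

    def _pca(self):
        self.scores_, self.loadings_, self.explained_variance_ratio_ = {}, {}, {}
        for part, M in self.effect_matrices_.items():
            sc, ld, ev = _weighted_pca(M, self.cell_counts_, self.n_components)
            self.scores_[part], self.loadings_[part] = sc, ld
            self.explained_variance_ratio_[part] = ev
        return self

    # -- jackknife ----------------------------------------------------------
    def jackknife(self, n_folds: int = 7, n_iter: int = 100, seed: int = 0,
                  min_success_frac: float = 0.8):
        """Leave-subset-out percentile bands for scores and loadings.

        Per iteration, participants are partitioned into ``n_folds``
        stratified subsets (relative group sizes preserved) and the model is
        refitted with one subset excluded; components are aligned to the
        full-data loadings by maximal absolute correlation, then 2.5th /
        97.5th percentiles are taken.
        """
        s = self.spec
        rng = np.random.default_rng(seed)
        df = self._panel
        parts = df[[s.subject_col] + ([s.group_col] if s.group_col else [])].drop_duplicates(s.subject_col)
        strata = (parts.groupby(s.group_col)[s.subject_col].apply(list).to_dict()
                  if s.group_col else {"all": parts[s.subject_col].tolist()})
        for g, ids in strata.items():
            if len(ids) < n_folds:
                raise ValueError(f"stratum {g!r} has fewer participants than folds")

        collected = {p: {"scores": [], "loadings": []} for p in self.effect_matrices_}
        n_ok = 0
        for it in range(n_iter):
            folds = [[] for _ in range(n_folds)]
            for ids in strata.values():
                ids = list(ids)
                rng.shuffle(ids)
                for j, pid in enumerate(ids):
                    folds[j % n_folds].append(pid)
            drop = set(folds[it % n_folds])
            sub = df[~df[s.subject_col].isin(drop)]
            try:
                jk = RMASCA(spec=s, n_components=self.n_components).fit(sub)
            except (ValueError, np.linalg.LinAlgError):
                continue
            ok = True
            for part in self.effect_matrices_:
                try:
                    sc, ld = _align_components(
                        self.loadings_[part], jk.loadings_[part], jk.scores_[part],
                        self.scores_[part].index,
                    )
                except KeyError:
                    ok = False
                    break
                collected[part]["scores"].append(sc)
                collected[part]["loadings"].append(ld)
            n_ok += ok
        if n_ok < min_success_frac * n_iter:
            raise RuntimeError(f"only {n_ok}/{n_iter} jackknife iterations succeeded")
        self.bands_ = {}
        for part, d in collected.items():
            sc = np.stack([x.to_numpy() for x in d["scores"]])
            ld = np.stack([x.to_numpy() for x in d["loadings"]])
            self.bands_[part] = {
                "scores_lo": pd.DataFrame(np.percentile(sc, 2.5, axis=0),
                                          index=self.scores_[part].index,
                                          columns=self.scores_[part].columns),
                "scores_hi": pd.DataFrame(np.percentile(sc, 97.5, axis=0),
                                          index=self.scores_[part].index,
                                          columns=self.scores_[part].columns),
                "loadings_lo": pd.DataFrame(np.percentile(ld, 2.5, axis=0),
                                            index=self.loadings_[part].index,
                                            columns=self.loadings_[part].columns),
                "loadings_hi": pd.DataFrame(np.percentile(ld, 97.5, axis=0),
                                            index=self.loadings_[part].index,
                                            columns=self.loadings_[part].columns),
                "n_iterations": n_ok,
            }
        return self.bands_


def _weighted_pca(M: pd.DataFrame, weights, n_components: int):
    """SVD of the row-weighted effect matrix.

    Rows (design cells) are weighted by sqrt(observation count); loadings are
    orthonormal analyte directions, scores are *unweighted* cell projections.
    Sign convention: the largest-magnitude loading of each component is
    positive.
    """
    X = M.to_numpy(float)
    if not np.isfinite(X).all():
        raise ValueError("effect matrix contains non-finite values")
    w = np.sqrt(np.asarray(weights, float) / np.sum(weights))
    Xw = X * w[:, None]
    U, sv, Vt = np.linalg.svd(Xw, full_matrices=False)
    total = float(np.sum(sv**2))
    k = int(min(n_components, np.sum(sv > max(sv.max(), 1e-300) * 1e-12))) if sv.size else 0
    if total <= 0 or k == 0:
        cols = [f"PC{i+1}" for i in range(n_components)]
        warnings.warn("zero effect matrix; components undefined")
        zero_sc = pd.DataFrame(0.0, index=M.index, columns=cols)
        zero_ld = pd.DataFrame(0.0, index=M.columns, columns=cols)
        return zero_sc, zero_ld, np.full(n_components, np.nan)
    V = Vt[:k].T
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    V = V * flip
    scores = X @ V
    cols = [f"PC{i+1}" for i in range(k)]
    ev = sv[:k] ** 2 / total
    return (pd.DataFrame(scores, index=M.index, columns=cols),
            pd.DataFrame(V, index=M.columns, columns=cols),
            ev)


def _align_components(ref_loadings: pd.DataFrame, loadings: pd.DataFrame,
                      scores: pd.DataFrame, score_index):
    """Match refit components to the full-data components by maximal absolute
    correlation of loadings, then flip signs to positive correlation."""
    L = loadings.loc[ref_loadings.index]
    sc = scores.loc[score_index]
    out_ld = pd.DataFrame(index=ref_loadings.index, columns=ref_loadings.columns,
                          dtype=float)
    out_sc = pd.DataFrame(index=score_index, columns=ref_loadings.columns, dtype=float)
    used = set()
    for comp in ref_loadings.columns:
        ref = ref_loadings[comp].to_numpy()
        best, best_val, best_sign = None, -np.inf, 1.0
        for cand in L.columns:
            if cand in used:
                continue
            v = L[cand].to_numpy()
            denom = np.linalg.norm(ref) * np.linalg.norm(v)
            c = float(ref @ v) / denom if denom > 0 else 0.0
            if abs(c) > best_val:
                best, best_val, best_sign = cand, abs(c), np.sign(c) or 1.0
        if best is None:
            raise KeyError("no matching component")
        used.add(best)
        out_ld[comp] = L[best].to_numpy() * best_sign
        out_sc[comp] = sc[best].to_numpy() * best_sign
    return out_sc, out_ld


# -- functional wrappers ----------------------------------------------------

def fit_effect_models(panel: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Per-analyte LMM coefficient table (time, group, interaction, cohort)."""
    model = RMASCA(spec=spec).fit(panel)
    return model.coefficient_table()


def build_effect_matrices(panel: pd.DataFrame, spec: ModelSpec) -> dict:
    """Separated, weighted-centered effect matrices per partition term."""
    return RMASCA(spec=spec).fit(panel).effect_matrices_


def pca_effects(panel: pd.DataFrame, spec: ModelSpec, n_components: int = 2) -> "RMASCA":
    """Fit RM-ASCA+ and return the estimator with scores/loadings."""
    return RMASCA(spec=spec, n_components=n_components).fit(panel)


def jackknife_validate(panel: pd.DataFrame, spec: ModelSpec, n_folds: int = 7,
                       n_iter: int = 100, seed: int = 0, n_components: int = 2) -> dict:
    """Percentile bands on scores/loadings via the stratified jackknife."""
    model = RMASCA(spec=spec, n_components=n_components).fit(panel)
    return model.jackknife(n_folds=n_folds, n_iter=n_iter, seed=seed)
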