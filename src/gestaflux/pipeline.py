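"""End-to-end pipeline: simulate -> preprocess -> trajectories -> RM-ASCA+
-> late-term, from a validated configuration, with a reproducibility
manifest (config hash, seed, versions, per-stage row counts)."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, assayproc, lateterm, rmasca, synthdata, trajectories
from .config import config_hash, validate_config
from .gestation import LATE_TERM_AFTER_DAY

log = logging.getLogger("gestaflux")


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {exc}")


def run_pipeline(config: dict | None, outdir) -> dict:
    """Execute enabled stages in dependency order; artifacts land in
    ``outdir`` and a manifest.json records how they were made."""
    cfg = validate_config(config)  # idempotent on an already-merged config
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    manifest = {
        "config_hash": config_hash(cfg), "seed": seed,
        "gestaflux_version": __version__,
        "numpy_version": np.__version__, "pandas_version": pd.__version__,
        "rows": {}, "stages_run": [],
    }
    stages = cfg["stages"]
    study = panel = norm_panel = None

    def _finish():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        if stages["simulate"]:
            log.info("stage simulate: n_women=%d", cfg["n_women"])
            study = synthdata.generate_study(cfg["n_women"], seed=seed)
            synthdata.write_study(study, out / "synthetic")
            manifest["rows"]["participants"] = len(study["participants"])
            manifest["rows"]["samples"] = len(study["samples"])
            manifest["rows"]["fi_long"] = len(study["fi_long"])
            manifest["stages_run"].append("simulate")
    except Exception as exc:  # noqa: BLE001 - halt with stage name
        _finish()
        raise StageError("simulate", exc) from exc

    try:
        if stages["preprocess"]:
            if study is None:
                raise RuntimeError("preprocess requires the simulate stage")
            panel, curves, reports = assayproc.build_panel(
                study["fi_long"], study["bridge_manifest"], study["standards"],
                study["samples"], study["participants"],
                reference_lot=cfg["preprocess"]["reference_lot"],
            )
            removals = set(cfg["outliers"]["removals"])
            if removals:
                panel = panel[~panel["participant_id"].isin(removals)]
            panel.to_csv(out / "panel.csv", index=False)
            (out / "curves.json").write_text(json.dumps(
                {c: cv.to_dict() for c, cv in curves.items()}, indent=2))
            part = study["participants"]
            accounting = assayproc.cohort_accounting(
                part.assign(has_samples=part["participant_id"].isin(study["samples"]["participant_id"])),
                outlier_ids=removals, samples=study["samples"])
            accounting["config_hash"] = manifest["config_hash"]
            (out / "accounting.json").write_text(json.dumps(accounting, indent=2))
            manifest["rows"]["panel"] = len(panel)
            manifest["stages_run"].append("preprocess")
    except Exception as exc:  # noqa: BLE001
        _finish()
        raise StageError("preprocess", exc) from exc

    term_panel = None
    if panel is not None:
        term_panel = panel[panel["ga_sampling"] <= LATE_TERM_AFTER_DAY]

    try:
        if stages["trajectories"] and panel is not None:
            tcfg = cfg["trajectories"]
            curves_rows, robust = [], {}
            for cyt, sub in term_panel.groupby("cytokine"):
                fit = trajectories.fit_trajectory(sub, n_basis=tcfg["n_basis"])
                curves_rows.append(pd.DataFrame({
                    "cytokine": cyt, "ga": fit.grid, "curve": fit.mean_curve,
                    "lo": fit.band[0], "hi": fit.band[1]}))
                rep = trajectories.assess_robustness(
                    sub, n_runs=tcfg["n_runs"], drop_frac=tcfg["drop_frac"],
                    seed=seed, n_basis=tcfg["n_basis"])
                robust[cyt] = {"mean_rho": rep.mean_rho,
                               "reliable": bool(rep.mean_rho >= tcfg["rho_threshold"])}
            pd.concat(curves_rows).to_csv(out / "trajectories.csv", index=False)
            (out / "robustness.json").write_text(json.dumps(robust, indent=2))
            effects = trajectories.trimester_effects_panel(panel)
            effects.to_csv(out / "trimester_effects.csv", index=False)
            corr = trajectories.correlations_by_trimester(panel)
            (out / "correlations").mkdir(exist_ok=True)
            for stratum, (rho, padj) in corr.items():
                rho.to_csv(out / "correlations" / f"rho_{stratum}.csv")
                padj.to_csv(out / "correlations" / f"padj_{stratum}.csv")
            manifest["rows"]["trimester_effects"] = len(effects)
            manifest["stages_run"].append("trajectories")
    except Exception as exc:  # noqa: BLE001
        _finish()
        raise StageError("trajectories", exc) from exc

    try:
        if stages["rmasca"] and panel is not None:
            rcfg = cfg["rmasca"]
            norm_panel, _ = assayproc.normalize_panel(term_panel, scheme="rmasca")
            spec = rmasca.ModelSpec(group_col=rcfg["group"], group_ref=rcfg["group_ref"])
            model = rmasca.RMASCA(spec=spec, n_components=rcfg["n_components"]).fit(norm_panel)
            model.jackknife(n_folds=rcfg["n_folds"], n_iter=rcfg["n_iter"], seed=seed)
            _write_sca(model, out)
            manifest["stages_run"].append("rmasca")
    except Exception as exc:  # noqa: BLE001
        _finish()
        raise StageError("rmasca", exc) from exc

    try:
        if stages["lateterm"] and panel is not None:
            lcfg = cfg["lateterm"]
            tests = lateterm.compare_term_lateterm(panel)
            tests.to_csv(out / "lateterm_tests.csv", index=False)
            try:
                tests4 = lateterm.compare_term_lateterm(
                    panel, exclude_within_days=lcfg["window_days"])
                tests4.to_csv(out / "lateterm_tests_excl4d.csv", index=False)
            except ValueError as exc:
                log.warning("delivery-window sensitivity comparison skipped: %s", exc)
            late = panel[panel["ga_sampling"] > LATE_TERM_AFTER_DAY]
            norm_late, _ = assayproc.normalize_panel(late, scheme="zscore")
            X = norm_late.pivot_table(index="participant_id", columns="cytokine",
                                      values="value")
            X = X.dropna(axis=0)
            fg = lateterm.fit_fine_gray(study["outcomes"], X)
            fg.to_csv(out / "finegray.csv", index=False)
            outc = study["outcomes"].set_index("participant_id").loc[X.index]
            within = ((outc["event"] == "spontaneous")
                      & (outc["days_to_delivery"] <= lcfg["window_days"]))
            y = np.where(within, "within", "after")
            metrics = lateterm.evaluate_and_permute(
                X.to_numpy(), y, n_orth=lcfg["n_orth"], n_perm=lcfg["n_perm"],
                holdout=lcfg["holdout"], seed=seed, pos_label="within")
            model = metrics.pop("model")
            metrics.pop("perm_errors")
            metrics["vip"] = dict(zip(X.columns[model.keep_], model.vip_.tolist()))
            (out / "oplsda.json").write_text(json.dumps(metrics, indent=2))
            bw_ref = synthdata.synthetic_birthweight_reference()
            regs = lateterm.lateterm_regressions(
                norm_late, study["participants"], bw_reference=bw_ref)
            regs.to_csv(out / "regressions.csv", index=False)
            manifest["rows"]["finegray"] = len(fg)
            manifest["stages_run"].append("lateterm")
    except Exception as exc:  # noqa: BLE001
        _finish()
        raise StageError("lateterm", exc) from exc

    _finish()
    return {"config": cfg, "manifest": manifest, "outdir": out,
            "study": study, "panel": panel}


def _write_sca(model, out: Path):
    scores, loadings, bands = [], [], []
    for part in model.scores_:
        sc = model.scores_[part].reset_index()
        sc.insert(0, "partition", part)
        scores.append(sc)
        ld = model.loadings_[part].reset_index(names="cytokine")
        ld.insert(0, "partition", part)
        loadings.append(ld)
        if hasattr(model, "bands_"):
            b = model.bands_[part]
            for which in ("scores", "loadings"):
                lo = b[f"{which}_lo"].reset_index()
                hi = b[f"{which}_hi"].reset_index()
                lo.insert(0, "bound", "lo")
                hi.insert(0, "bound", "hi")
                for f in (lo, hi):
                    f.insert(0, "partition", part)
                    f.insert(0, "which", which)
                bands.extend([lo, hi])
    pd.concat(scores).to_csv(out / "sca_scores.csv", index=False)
    pd.concat(loadings).to_csv(out / "sca_loadings.csv", index=False)
    if bands:
        pd.concat(bands).to_csv(out / "sca_bands.csv", index=False)
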