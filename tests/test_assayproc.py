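"""Preprocessing: batch correction, calibration, censoring, panel rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from gestaflux import assayproc as ap
from gestaflux import synthdata as sd
from gestaflux._fivepl import FivePL
from gestaflux.gestation import trimester


class TestInterLot:
    def test_hand_example_doubling(self):
        origin = pd.Series([50.0] * 8, index=[f"s{i}" for i in range(8)])
        ref = pd.Series([100.0] * 8, index=[f"s{i}" for i in range(8)])
        adj = ap.compute_inter_lot_adjustment(origin, ref, "X", lot_id="L2")
        assert adj.delta_log == pytest.approx(np.log(2.0), abs=1e-12)
        assert 100.0 * np.exp(adj.delta_log) == pytest.approx(200.0)

    def test_identity_sets_give_zero_delta(self):
        s = pd.Series([10.0, 20.0, 30.0], index=list("abc"))
        adj = ap.compute_inter_lot_adjustment(s, s, "X")
        assert adj.delta_log == pytest.approx(0.0, abs=1e-14)

    def test_mismatched_identities_rejected(self):
        a = pd.Series([1.0], index=["a"])
        b = pd.Series([1.0], index=["b"])
        with pytest.raises(ap.AlignmentError):
            ap.compute_inter_lot_adjustment(a, b, "X")

    def test_nonpositive_fi_rejected(self):
        a = pd.Series([1.0, -2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            ap.compute_inter_lot_adjustment(a, a.abs(), "X")

    @given(st.floats(-1.0, 1.0))
    @settings(max_examples=20, deadline=None)
    def test_delta_recovers_injected_lot_offset(self, offset):
        base = pd.Series(np.geomspace(10, 1000, 8), index=[f"s{i}" for i in range(8)])
        adj = ap.compute_inter_lot_adjustment(base * np.exp(offset), base, "X")
        assert adj.delta_log == pytest.approx(-offset, abs=1e-10)


def _two_plate_table():
    rows = []
    for plate, anchor_fi in (("P1", 10.0), ("P2", 40.0)):
        rows.append(("A1", "X", anchor_fi, "L1", plate, "w", "control", False))
        rows.append((f"s_{plate}", "X", 100.0, "L1", plate, "w", "sample", False))
    return pd.DataFrame(rows, columns=["sample_id", "cytokine", "fi", "lot",
                                       "plate", "well", "role", "clipped"])


class TestIntraLot:
    def test_hand_example_two_plates(self):
        # anchor means log10 and log40 -> lot mean log20 -> x2 and x0.5
        out, factors = ap.apply_intra_lot_adjustment(_two_plate_table())
        s1 = out[(out["sample_id"] == "s_P1")]["fi"].iloc[0]
        s2 = out[(out["sample_id"] == "s_P2")]["fi"].iloc[0]
        assert s1 == pytest.approx(200.0, rel=1e-12)
        assert s2 == pytest.approx(50.0, rel=1e-12)

    def test_single_plate_lot_unchanged(self):
        tab = _two_plate_table()
        tab = tab[tab["plate"] == "P1"]
        out, _ = ap.apply_intra_lot_adjustment(tab)
        np.testing.assert_allclose(out["fi"], tab["fi"], rtol=1e-14)

    def test_plate_without_anchor_rejected(self):
        tab = _two_plate_table()
        tab = tab[~((tab["plate"] == "P2") & (tab["role"] == "control"))]
        with pytest.raises(ap.CoverageError):
            ap.apply_intra_lot_adjustment(tab)

    def test_anchor_means_equalized_and_idempotent(self, noisy_study):
        fi = noisy_study["fi_long"]
        out, _ = ap.apply_intra_lot_adjustment(fi)
        anchors = out[out["role"] == "control"]
        for (lot, cyt), g in anchors.groupby(["lot", "cytokine"]):
            lot_mean = np.log(g["fi"]).mean()
            for _, pg in g.groupby("plate"):
                assert np.log(pg["fi"]).mean() == pytest.approx(lot_mean, abs=1e-10)
        out2, factors2 = ap.apply_intra_lot_adjustment(out)
        assert max(abs(f.delta_log) for f in factors2) < 1e-10

    def test_within_plate_rank_order_preserved(self, noisy_study):
        fi = noisy_study["fi_long"]
        out, _ = ap.apply_intra_lot_adjustment(fi)
        for (_, _, _), grp in list(out.groupby(["lot", "plate", "cytokine"]))[:5]:
            before = fi.loc[grp.index, "fi"].rank()
            after = grp["fi"].rank()
            assert (before == after).all()


class TestCalibration:
    def test_noiseless_recovery_to_1e4(self):
        truth = FivePL(a=40, b=1.3, c=120, d=20000, g=1.1)
        conc = np.tile(120 * 4.0 ** np.arange(-4, 4), 2)
        fi = truth(conc)
        model = ap.StandardCurveModel("X").fit(conc, fi)
        np.testing.assert_allclose(model.curve_.as_array(), truth.as_array(), rtol=1e-4)

    def test_power_variance_exponent_recovered(self, rng):
        truth = FivePL(a=40, b=1.2, c=100, d=20000, g=1.0)
        rows = []
        for plate in range(4):
            for conc in 100 * 4.0 ** np.arange(-4, 4):
                mean = truth(conc)
                sd_ = np.sqrt(0.01 * mean ** 1.8)
                for _ in range(2):
                    rows.append((conc, mean + rng.normal(0, sd_), plate))
        df = pd.DataFrame(rows, columns=["conc", "fi", "plate"])
        model = ap.StandardCurveModel("X").fit(df["conc"], df["fi"], groups=df["plate"])
        assert model.theta_[1] == pytest.approx(1.8, abs=0.2)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ap.CalibrationError):
            ap.StandardCurveModel("X").fit([1, 2, 3, 4], [1, 2, 3, 4])

    def test_limits_zero_variance_blanks(self):
        curve = ap.StandardCurve("X", FivePL(a=50, b=1.5, c=100, d=20000), theta=(0.0, 0.0))
        curve = ap.estimate_limits(curve, blanks=[50.0, 50.0])
        # blank mean equals the lower asymptote and SD is zero -> LLOD at the
        # inverse of the blank mean, i.e. zero concentration
        assert curve.llod == 0.0
        assert curve.llod <= curve.lloq < curve.uloq <= curve.ulod

    def test_more_noise_raises_lloq(self):
        p = FivePL(a=50, b=1.5, c=100, d=20000)
        c1 = ap.estimate_limits(ap.StandardCurve("X", p, theta=(0.5, 1.4)), [52.0, 49.0])
        c2 = ap.estimate_limits(ap.StandardCurve("X", p, theta=(1.0, 1.4)), [52.0, 49.0])
        assert c2.lloq > c1.lloq

    def test_inversion_round_trip_and_capping(self):
        p = FivePL(a=50, b=1.5, c=100, d=20000)
        curve = ap.estimate_limits(ap.StandardCurve("X", p, theta=(0.2, 1.3)), [51.0, 49.5])
        tab = pd.DataFrame({
            "sample_id": ["a", "b", "c"], "cytokine": "X",
            "fi": [float(p(100.0)), 25000.0, np.nan],
        })
        rec = ap.fi_to_concentration(tab, curve)
        assert rec.loc[0, "conc"] == pytest.approx(100.0, rel=1e-8)
        assert rec.loc[1, "status"] == "capped_ulod"
        assert rec.loc[1, "conc"] == pytest.approx(curve.ulod)
        assert rec.loc[2, "status"] == "flagged"


class TestCensoredEM:
    def test_uncensored_limit_equals_sample_moments(self, rng):
        x = rng.lognormal(0.5, 0.3, 200)
        em = ap.CensoredLognormalImputer().fit(x, np.zeros(200, bool), limit=1e-9)
        assert em.mu_ == pytest.approx(np.log(x).mean(), abs=1e-12)
        assert em.sigma_ == pytest.approx(np.log(x).std(), abs=1e-12)

    def test_matches_direct_censored_mle(self, rng):
        x = rng.lognormal(1.0, 0.5, 2000)
        limit = float(np.quantile(x, 0.20))
        cens = x < limit
        em = ap.CensoredLognormalImputer().fit(np.where(cens, limit / 2, x), cens, limit)

        def nll(p):
            mu, ls = p
            s = np.exp(ls)
            ll = stats.norm.logpdf(np.log(x[~cens]), mu, s).sum()
            ll += cens.sum() * stats.norm.logcdf((np.log(limit) - mu) / s)
            return -ll

        mle = optimize.minimize(nll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-11})
        assert em.mu_ == pytest.approx(mle.x[0], abs=1e-3)
        assert em.sigma_ == pytest.approx(np.exp(mle.x[1]), abs=1e-3)

    def test_imputed_values_strictly_below_limit(self, rng):
        x = rng.lognormal(0.0, 0.6, 500)
        limit = float(np.quantile(x, 0.3))
        cens = x < limit
        em = ap.CensoredLognormalImputer().fit(np.where(cens, limit / 2, x), cens, limit)
        out = em.transform(np.where(cens, limit / 2, x), cens)
        assert (out[cens] < limit).all()

    def test_over_censoring_refused(self, rng):
        x = rng.lognormal(0.0, 0.5, 100)
        cens = np.ones(100, bool)
        cens[:10] = False
        with pytest.raises(ap.CensoringError):
            ap.CensoredLognormalImputer().fit(x, cens, limit=float(x.max()))

    def test_impute_records_only_touches_below_llod(self):
        rec = pd.DataFrame({
            "sample_id": list("abcd"), "cytokine": "X",
            "conc": [5.0, 7.0, np.nan, 9.0],
            "status": ["quantified", "quantified", "below_llod", "quantified"],
        })
        rec["log_conc"] = np.log(rec["conc"])
        out = ap.impute_below_llod(rec, llod=4.0)
        assert out.loc[2, "status"] == "imputed_below_llod"
        assert out.loc[2, "conc"] < 4.0
        assert (out.loc[[0, 1, 3], "conc"] == rec.loc[[0, 1, 3], "conc"]).all()


class TestPanelRules:
    def _panel(self, frac_below):
        n = 100
        k = int(round(frac_below * n))
        curve = ap.StandardCurve("X", FivePL(a=50, b=1.5, c=100, d=20000),
                                 theta=(0, 0), llod=0.1, ulod=1e5, lloq=1.0, uloq=1e4)
        conc = np.concatenate([np.full(k, 0.5), np.full(n - k, 50.0)])
        panel = pd.DataFrame({"cytokine": "X", "conc": conc, "sample_id": range(n)})
        return panel, {"X": curve}

    @pytest.mark.parametrize("frac,kept", [(0.26, False), (0.0, True), (0.25, True)])
    def test_25_percent_rule_is_strict(self, frac, kept):
        panel, curves = self._panel(frac)
        retained, report = ap.apply_panel_exclusions(panel, curves)
        assert ("X" in retained) is kept
        assert report["out_of_range_frac"].iloc[0] == pytest.approx(frac)

    def test_missing_ga_mean_substitution(self):
        samples = pd.DataFrame({
            "sample_id": ["a", "b", "c"], "cohort": ["A"] * 3, "visit": [2, 2, 2],
            "ga_sampling": [100.0, 110.0, np.nan],
        })
        out, log = ap.impute_missing_ga(samples)
        assert out.loc[2, "ga_sampling"] == pytest.approx(105.0)
        assert len(log) == 1

    def test_no_missing_ga_is_noop(self):
        samples = pd.DataFrame({"sample_id": ["a"], "cohort": ["A"], "visit": [1],
                                "ga_sampling": [100.0]})
        out, log = ap.impute_missing_ga(samples)
        assert log.empty and out.equals(samples)

    def test_21_missing_entries_give_21_substitutions(self, rng):
        n = 200
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "cohort": rng.choice(["A", "B"], n),
            "visit": rng.integers(1, 4, n),
            "ga_sampling": rng.uniform(50, 280, n),
        })
        idx = rng.choice(n, 21, replace=False)
        samples.loc[idx, "ga_sampling"] = np.nan
        out, log = ap.impute_missing_ga(samples)
        assert len(log) == 21
        assert out["ga_sampling"].notna().all()


class TestOutlierScreen:
    def _null_panel(self, rng, n=500, p=8):
        rows = []
        for i in range(n):
            for j in range(p):
                rows.append((f"S{i}", f"P{i}", 1, f"C{j}", rng.normal()))
        return pd.DataFrame(rows, columns=["sample_id", "participant_id",
                                           "cohort", "cytokine", "log_conc"])

    def test_null_flags_close_to_chi2_calibration(self, rng):
        pan = self._null_panel(rng)
        flagged = ap.screen_outliers(pan, None)
        assert len(flagged["participant_id"].unique()) <= 0.01 * 500

    def test_displaced_participant_flagged(self, rng):
        pan = self._null_panel(rng)
        mask = (pan["participant_id"] == "P0") & pan["cytokine"].isin(["C0", "C1"])
        pan.loc[mask, "log_conc"] += 10.0
        flagged = ap.screen_outliers(pan, None)
        assert "P0" in set(flagged["participant_id"])


class TestCohortAccounting:
    def test_printed_category_counts_reproduce_totals(self):
        rep = ap.cohort_accounting(counts={
            "assessed": 943, "complications": 147, "bmi_low": 6, "bmi_high": 8,
            "missing_samples": 66, "outliers": 9,
        })
        assert rep["excluded_total"] == 227
        assert rep["final_included"] == 707

    def test_no_exclusions_final_equals_assessed(self):
        rep = ap.cohort_accounting(counts={"assessed": 50})
        assert rep["final_included"] == 50

    def test_trimester_shares_integer_rounding(self):
        shares = ap.trimester_shares({"T1": 192, "T2": 367, "T3": 194})
        assert shares == {"T1": 25, "T2": 49, "T3": 26}

    def test_priority_order_never_double_counts(self):
        parts = pd.DataFrame({
            "participant_id": list("abcd"),
            "complication": [True, False, False, False],
            "bmi": [17.0, 17.0, 45.0, 22.0],  # 'a' overlaps two categories
            "has_samples": [False, True, True, False],
            "study_group": ["term"] * 4,
        })
        rep = ap.cohort_accounting(parts)
        assert rep["excluded"] == {"complications": 1, "bmi_low": 1,
                                   "bmi_high": 1, "missing_samples": 1}
        assert rep["assessed"] == rep["final_included"] + rep["excluded_total"] + rep["outliers_removed"]


class TestNormalization:
    def test_rmasca_divisor_is_unweighted_mean_of_cohort_sds(self, rng):
        rows = []
        for cohort, sdv in (("A", 1.0), ("B", 3.0)):
            n = 4000 if cohort == "A" else 4000
            for v in rng.normal(0.0, sdv, n):
                rows.append((cohort, "X", v))
        panel = pd.DataFrame(rows, columns=["cohort", "cytokine", "log_conc"])
        norm = ap.PanelNormalizer("rmasca").fit(panel)
        assert norm.scale_["X"] == pytest.approx(2.0, rel=0.05)

    def test_single_cohort_divisor_is_its_sd(self, rng):
        panel = pd.DataFrame({"cohort": "A", "cytokine": "X",
                              "log_conc": rng.normal(1.0, 2.0, 3000)})
        norm = ap.PanelNormalizer("rmasca").fit(panel)
        sd = panel["log_conc"].std(ddof=1)
        assert norm.scale_["X"] == pytest.approx(sd, rel=1e-12)

    def test_zscore_scheme_standardizes(self, rng):
        panel = pd.DataFrame({"cohort": "A", "cytokine": "X",
                              "log_conc": rng.normal(3.0, 2.0, 500)})
        out, norm = ap.normalize_panel(panel, scheme="zscore")
        assert out["value"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["value"].std(ddof=1) == pytest.approx(1.0, rel=1e-12)
        back = norm.inverse_transform(out)
        np.testing.assert_allclose(back["log_conc"], panel["log_conc"], rtol=1e-12)

    def test_constant_cytokine_flagged_not_normalized(self):
        panel = pd.DataFrame({"cohort": ["A", "A"], "cytokine": "X",
                              "log_conc": [1.0, 1.0]})
        norm = ap.PanelNormalizer("zscore").fit(panel)
        assert norm.flagged_ == ["X"]


class TestCovariateDerivation:
    def test_bmi_classes_left_closed(self):
        parts = pd.DataFrame({
            "participant_id": list("abc"), "bmi": [24.9, 25.0, 30.0],
            "parity": [0, 1, 2],
        })
        out = ap.derive_covariates(parts)
        assert list(out["bmi_class"]) == ["normal", "overweight", "obese"]
        assert list(out["parity_group"]) == ["nulliparous", "multiparous", "multiparous"]

    @pytest.mark.parametrize("ga,expect", [
        (97, "T1"), (98, "T2"), (195, "T2"), (196, "T3"), (283, "T3"), (284, "late_term"),
    ])
    def test_trimester_boundaries(self, ga, expect):
        assert trimester(ga) == expect

    def test_bw_zscore_groups_from_reference(self):
        ref = sd.synthetic_birthweight_reference()
        parts = pd.DataFrame({
            "participant_id": ["a", "b"], "bmi": [22.0, 22.0], "parity": [0, 0],
            "birth_weight": [3650.0, 3650.0 + 2 * 450.0],
            "ga_delivery": [282.0, 282.0], "fetal_sex": ["male", "male"],
        })
        out = ap.derive_covariates(parts, bw_reference=ref)
        assert out.loc[0, "bw_zscore"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[1, "bw_zscore"] == pytest.approx(2.0, abs=1e-12)
        assert out.loc[0, "bw_group"] == "25-75th"
        assert out.loc[1, "bw_group"] == ">75th"


def test_full_roundtrip_identity_noiseless_offset_free():
    """conc -> FI -> corrections -> calibration -> conc within [LLOQ, ULOQ]."""
    templates = sd.generate_trajectory_params(["CRP", "IL-6", "eotaxin"], seed=3)
    for t in templates:
        t.subject_sd = t.residual_sd = 0.0
    parts, samples = sd.generate_cohort(40, seed=3)
    truth = sd.simulate_concentrations(parts, samples, templates, seed=3)
    assay = sd.default_assay_config([t.cytokine for t in templates], seed=3,
                                    lot_sd=0.0, plate_sd=0.0, theta=(0.0, 0.0))
    fi, bridge, std = sd.simulate_assay_fi(truth, assay, seed=3)
    panel, curves, _ = ap.build_panel(fi, bridge, std, samples, parts,
                                      reference_lot="L1", exclude=False)
    m = panel.merge(truth, on=["sample_id", "cytokine"])
    q = m[m["status"] == "quantified"]
    in_range = np.zeros(len(q), bool)
    for cyt, cv in curves.items():
        sel = (q["cytokine"] == cyt).to_numpy()
        in_range |= sel & (q["true_conc"].to_numpy() >= cv.lloq) \
            & (q["true_conc"].to_numpy() <= cv.uloq)
    rel = np.abs(q["conc"].to_numpy() / q["true_conc"].to_numpy() - 1.0)
    assert in_range.any()
    assert rel[in_range].max() < 1e-6
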