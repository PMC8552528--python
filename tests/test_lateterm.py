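"""Late-term analyses: term comparison, Fine-Gray, O-PLS-DA, regressions."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gestaflux import lateterm as lt
from gestaflux import synthdata as sd


def _mw_panel(rng, shift=0.0, n_term=44, n_late=396, days_left_term=10.0):
    rows = []
    for i in range(n_term):
        rows.append((f"T{i}", 270.0, 270.0 + days_left_term, "X", rng.normal(0, 1)))
    for i in range(n_late):
        rows.append((f"L{i}", 289.0, 294.5, "X", rng.normal(shift, 1)))
    return pd.DataFrame(rows, columns=["participant_id", "ga_sampling",
                                       "ga_delivery", "cytokine", "log_conc"])


class TestTermComparison:
    def test_null_type_one_error_near_nominal(self):
        hits = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            out = lt.compare_term_lateterm(_mw_panel(rng, 0.0, 50, 50))
            hits += out["p"].iloc[0] < 0.05
        assert 0.01 <= hits / 200 <= 0.10

    def test_power_exceeds_95_at_study_group_sizes(self):
        hits = 0
        for s in range(60):
            rng = np.random.default_rng(s)
            out = lt.compare_term_lateterm(_mw_panel(rng, 1.0))
            hits += out["p"].iloc[0] < 0.05
        assert hits / 60 > 0.95

    @given(st.sampled_from(["exp", "cube", "affine"]))
    @settings(max_examples=6, deadline=None)
    def test_p_invariant_under_monotone_transform(self, kind):
        rng = np.random.default_rng(5)
        pan = _mw_panel(rng, 0.5, 30, 40)
        f = {"exp": np.exp, "cube": lambda v: v**3,
             "affine": lambda v: 2.0 * v + 7.0}[kind]
        pan2 = pan.assign(log_conc=f(pan["log_conc"]))
        p1 = lt.compare_term_lateterm(pan)["p"].iloc[0]
        p2 = lt.compare_term_lateterm(pan2)["p"].iloc[0]
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_four_day_window_excludes_imminent_deliveries(self):
        rng = np.random.default_rng(1)
        pan = _mw_panel(rng, 0.0, 40, 40, days_left_term=3.0)
        full = lt.compare_term_lateterm(pan)
        assert full["n_term"].iloc[0] == 40
        with pytest.raises(ValueError):
            # all term women deliver within 4 days -> group emptied
            lt.compare_term_lateterm(pan, exclude_within_days=4)


def _competing_data(rng, n, beta=0.0, p1=0.45, censor=False):
    x = rng.normal(0, 1, n)
    eta = np.exp(beta * x)
    c1 = rng.random(n) < 1 - (1 - p1) ** eta
    u = rng.random(n)
    inner = (1 - u * (1 - (1 - p1) ** eta)) ** (1 / eta)
    t1 = -3.0 * np.log(1 - (1 - inner) / p1)
    t = np.where(c1, t1, rng.exponential(5.0, n))
    ev = np.where(c1, 1, 2)
    if censor:
        cens_t = rng.exponential(8.0, n)
        ev = np.where(cens_t < t, 0, ev)
        t = np.minimum(t, cens_t)
    return x, t, ev


class TestFineGray:
    def test_reduces_to_cox_without_competing_or_censoring(self, rng):
        from lifelines import CoxPHFitter

        n = 250
        x = rng.normal(0, 1, n)
        t = rng.exponential(np.exp(-0.5 * x))
        fg = lt.FineGrayEstimator().fit(x[:, None], t, np.ones(n, int))
        cph = CoxPHFitter().fit(pd.DataFrame({"t": t, "e": 1, "x": x}), "t", "e")
        assert fg.coef_[0] == pytest.approx(float(cph.params_["x"]), abs=1e-6)
        assert fg.se_[0] == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-6)

    def test_matches_cmprsk_crr_oracle(self, rng, tmp_path):
        x, t, ev = _competing_data(rng, 300, beta=0.6, censor=True)
        fg = lt.FineGrayEstimator().fit(x[:, None], t, ev)
        csv = tmp_path / "d.csv"
        pd.DataFrame({"t": t, "e": ev, "x": x}).to_csv(csv, index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             f'd <- read.csv("{csv}"); suppressMessages(library(cmprsk));'
             'm <- crr(d$t, d$e, cbind(x=d$x), failcode=1, cencode=0);'
             'cat(sprintf("%.8f", m$coef))'],
            capture_output=True, text=True, timeout=120,
        )
        assert r.returncode == 0, r.stderr
        assert fg.coef_[0] == pytest.approx(float(r.stdout), abs=1e-3)

    def test_recovers_generative_beta(self, rng):
        x, t, ev = _competing_data(rng, 2000, beta=0.5)
        fg = lt.FineGrayEstimator().fit(x[:, None], t, ev)
        assert fg.coef_[0] == pytest.approx(0.5, abs=0.1)

    def test_null_wald_p_close_to_uniform(self):
        ps = []
        for s in range(200):
            rng = np.random.default_rng(s)
            x, t, ev = _competing_data(rng, 150, beta=0.0)
            ps.append(lt.FineGrayEstimator().fit(x[:, None], t, ev).p_[0])
        ps = np.asarray(ps)
        assert 0.01 <= (ps < 0.05).mean() <= 0.10
        assert 0.35 <= ps.mean() <= 0.65

    def test_per_cytokine_table_with_bh(self, rng):
        x1, t, ev = _competing_data(rng, 300, beta=0.8)
        X = pd.DataFrame({"A": x1, "B": rng.normal(0, 1, 300)},
                         index=pd.Index([f"P{i}" for i in range(300)],
                                        name="participant_id"))
        out = pd.DataFrame({"participant_id": X.index,
                            "days_to_delivery": t, "event": ev})
        res = lt.fit_fine_gray(out, X)
        res = res.set_index("cytokine")
        assert res.loc["A", "p"] < res.loc["B", "p"]
        assert (res["p_adj"] >= res["p"] - 1e-12).all()
        assert (res["hr"] > 0).all()

    def test_too_few_events_rejected(self, rng):
        X = pd.DataFrame({"A": rng.normal(size=20)},
                         index=pd.Index([f"P{i}" for i in range(20)],
                                        name="participant_id"))
        out = pd.DataFrame({"participant_id": X.index,
                            "days_to_delivery": rng.exponential(3, 20),
                            "event": [1] * 5 + [0] * 15})
        with pytest.raises(ValueError):
            lt.fit_fine_gray(out, X)


def _separable(rng, n=60, p=8, sep=2.0, noise=0.3):
    d = rng.normal(0, 1, p)
    d /= np.linalg.norm(d)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 1, (n, p)) * noise + np.outer(np.where(y == 1, sep, -sep), d)
    return X, y, d


class TestOPLSDA:
    def test_separable_training_error_zero(self, rng):
        X, y, _ = _separable(rng)
        m = lt.OPLSDA(n_orth=1).fit(X, y)
        assert np.mean(m.predict(X) != y) == 0.0

    def test_orthogonal_variation_removed(self, rng):
        X, y, _ = _separable(rng)
        m0 = lt.OPLSDA(n_orth=0, scale=False).fit(X, y)
        Xo = X + np.outer(rng.normal(0, 3, len(y)), rng.normal(0, 1, X.shape[1]))
        m1 = lt.OPLSDA(n_orth=1, scale=False).fit(Xo, y)
        cos = abs(m0.weights_ @ m1.weights_)
        assert cos > 0.95

    def test_vip_mean_square_is_one(self, rng):
        for s in range(5):
            X, y, _ = _separable(np.random.default_rng(s), n=40)
            m = lt.OPLSDA(n_orth=1).fit(X, y)
            assert np.mean(m.vip_**2) == pytest.approx(1.0, abs=1e-10)

    def test_constant_column_removed_with_warning(self, rng):
        X, y, _ = _separable(rng)
        X[:, 0] = 5.0
        with pytest.warns(UserWarning):
            m = lt.OPLSDA(n_orth=1).fit(X, y)
        assert m.keep_.sum() == X.shape[1] - 1

    def test_excess_orthogonal_components_rejected(self, rng):
        X, y, _ = _separable(rng, n=20, p=3)
        with pytest.raises(ValueError):
            lt.OPLSDA(n_orth=5).fit(X, y)

    def test_small_class_rejected(self, rng):
        X = rng.normal(0, 1, (12, 4))
        y = np.array([0] * 9 + [1] * 3)
        with pytest.raises(ValueError):
            lt.OPLSDA().fit(X, y)


class TestPermutation:
    def test_separable_p_at_smoothing_floor(self, rng):
        X, y, _ = _separable(rng, n=200, p=10)
        res = lt.evaluate_and_permute(X, y, n_perm=100, seed=3)
        assert res["error_rate"] == 0.0
        assert res["permutation_p"] == pytest.approx(1.0 / 101.0)

    def test_null_p_super_uniform(self):
        ps = []
        for s in range(25):
            rng = np.random.default_rng(s)
            X = rng.normal(0, 1, (100, 8))
            y = np.repeat([0, 1], 50)
            ps.append(lt.evaluate_and_permute(X, y, n_perm=60, seed=s)["permutation_p"])
        ps = np.asarray(ps)
        assert (ps <= 0.05).mean() <= 0.10
        assert ps.mean() > 0.40

    def test_metrics_reported(self, rng):
        X, y, _ = _separable(rng, n=100)
        res = lt.evaluate_and_permute(X, y, n_perm=20, seed=0)
        for key in ("error_rate", "sensitivity", "specificity", "permutation_p"):
            assert np.isfinite(res[key])
        assert 0 < res["permutation_p"] <= 1


class TestBirthweightZscore:
    def test_definitional_values(self):
        ref = pd.DataFrame({"ga_days": [275, 282, 289] * 2,
                            "sex": ["male"] * 3 + ["female"] * 3,
                            "mean_g": [3500, 3600, 3700] * 2,
                            "sd_g": [450] * 6})
        assert lt.birthweight_zscore(3600, 282, "male", ref) == pytest.approx(0.0)
        assert lt.birthweight_zscore(3600 + 900, 282, "male", ref) == pytest.approx(2.0)
        assert lt.birthweight_zscore(4050, 282, "male", ref) == pytest.approx(1.0)

    def test_interpolation_between_tabulated_points(self):
        ref = pd.DataFrame({"ga_days": [280, 284], "sex": ["male"] * 2,
                            "mean_g": [3500, 3700], "sd_g": [400, 400]})
        assert lt.birthweight_zscore(3600, 282, "male", ref) == pytest.approx(0.0)

    def test_out_of_support_extrapolates_with_warning(self):
        ref = pd.DataFrame({"ga_days": [280, 284], "sex": ["male"] * 2,
                            "mean_g": [3500, 3700], "sd_g": [400, 400]})
        with pytest.warns(UserWarning):
            z = lt.birthweight_zscore(3500, 260, "male", ref)
        assert z == pytest.approx(0.0)


class TestLatetermRegressions:
    def _setup(self, rng, coef=0.3, noise=0.5, n=400):
        parts = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(n)],
            "age": rng.normal(30, 4.5, n), "bmi": rng.normal(25, 4, n),
            "parity": rng.integers(0, 3, n),
            "smoking": rng.random(n) < 0.1,
            "fetal_sex": rng.choice(["female", "male"], n),
            "birth_weight": rng.normal(4000, 430, n),
            "ga_delivery": rng.uniform(284, 296, n),
        })
        ref = sd.synthetic_birthweight_reference()
        bmi_z = (parts["bmi"] - parts["bmi"].mean()) / parts["bmi"].std(ddof=1)
        value = coef * bmi_z + rng.normal(0, noise, n)
        panel = pd.DataFrame({"participant_id": parts["participant_id"],
                              "cytokine": "X", "value": value})
        return panel, parts, ref

    def test_injected_bmi_coefficient_recovered(self, rng):
        panel, parts, ref = self._setup(rng)
        res = lt.lateterm_regressions(panel, parts, bw_reference=ref)
        bmi = res[(res["cytokine"] == "X") & (res["covariate"] == "bmi")]
        assert bmi["coef"].iloc[0] == pytest.approx(0.3, abs=0.08)

    def test_noiseless_standardized_response_gives_unit_coefficient(self, rng):
        panel, parts, ref = self._setup(rng, coef=1.0, noise=0.0)
        res = lt.lateterm_regressions(panel, parts, bw_reference=ref)
        bmi = res[res["covariate"] == "bmi"]
        assert bmi["coef"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_covariate_set_and_reference_coding(self, rng):
        panel, parts, ref = self._setup(rng)
        res = lt.lateterm_regressions(panel, parts, bw_reference=ref)
        assert set(res["covariate"]) == {"age", "bmi", "parity", "bw_zscore",
                                         "smoking", "fetal_sex_male"}
        assert (res["p_adj"] >= res["p"] - 1e-12).all()


def test_event_code_mapping_matches_study_design():
    assert lt.EVENT_CODES["spontaneous"] == 1
    assert lt.EVENT_CODES["induced_randomized"] == 0  # censored
    assert lt.EVENT_CODES["induced_clinical"] == 2  # competing
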