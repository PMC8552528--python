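"""Synthetic multi-cohort longitudinal pregnancy study generator.

Emulates the statistical structure of a five-cohort maternal-serum cytokine
study: ~700 women sampled 1-4 times between gestational day ~40 and ~295,
a 22-cytokine + CRP panel following four canonical trajectory shapes
(monotone increase, monotone decrease, mid-pregnancy peak, mid-pregnancy
dip), covariate effects (BMI class, smoking, parity, fetal sex, birth-weight
percentile), a forward immunoassay model (5PL response, multiplicative
lot/plate artifacts, power-law noise, bridge samples, plate-replicated
standards/blanks/pooled controls), and late-term labor outcomes with
competing events.

Every generator draws from its own :class:`numpy.random.Generator` stream
seeded from a master seed, so each stage is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from ._fivepl import FivePL
from .gestation import LATE_TERM_AFTER_DAY

__all__ = [
    "CYTOKINES",
    "PANEL",
    "UNITS",
    "StudyConfig",
    "AssayConfig",
    "TrajectoryTemplate",
    "generate_trajectory_params",
    "generate_cohort",
    "simulate_concentrations",
    "simulate_assay_fi",
    "simulate_labor_outcomes",
    "default_assay_config",
    "synthetic_birthweight_reference",
    "generate_study",
]

CYTOKINES = [
    "eotaxin", "FGF-b", "G-CSF", "GM-CSF", "IP-10", "IL-1b", "IL-1Ra",
    "IL-2", "IL-4", "IL-6", "IL-7", "IL-8", "IL-9", "IL-12", "IL-13",
    "IL-15", "IL-17", "MCP-1", "MIP-1a", "MIP-1b", "PDGF-BB", "TNF-a",
]
PANEL = CYTOKINES + ["CRP"]

#: CRP is carried in µg/mL, all other analytes in pg/mL; units are metadata
#: and never converted.
UNITS = {c: "pg/mL" for c in CYTOKINES}
UNITS["CRP"] = "ug/mL"

# Canonical shape assignment: most analytes decline over gestation; a few
# rise steadily; CRP and IL-7 peak mid-pregnancy; IL-1b/IL-6 dip mid-pregnancy.
_SHAPE_MAP = {
    "eotaxin": "decrease", "MCP-1": "decrease", "MIP-1a": "decrease",
    "MIP-1b": "decrease", "IL-1Ra": "decrease", "IL-9": "decrease",
    "PDGF-BB": "decrease", "IL-2": "decrease", "IL-8": "decrease",
    "IL-17": "decrease", "IP-10": "decrease", "IL-15": "decrease",
    "IL-12": "decrease", "TNF-a": "decrease", "IL-5": "decrease",
    "G-CSF": "increase", "IL-13": "increase", "IL-4": "increase",
    "GM-CSF": "increase", "FGF-b": "increase",
    "CRP": "peak_mid", "IL-7": "peak_mid",
    "IL-1b": "dip_mid", "IL-6": "dip_mid",
}

SHAPES = ("increase", "decrease", "peak_mid", "dip_mid")

# Cubic B-spline shape basis on gestational days [40, 290] with 4 interior
# knots -> 8 basis functions; shapes are parameterized by knot heights.
_GA_LO, _GA_HI = 40.0, 290.0
_INTERIOR_KNOTS = np.linspace(_GA_LO, _GA_HI, 6)[1:-1]
_KNOTS = np.concatenate([[_GA_LO] * 4, _INTERIOR_KNOTS, [_GA_HI] * 4])

_SHAPE_COEFS = {
    "increase": np.linspace(0.0, 1.0, 8),
    "decrease": np.linspace(1.0, 0.0, 8),
    "peak_mid": np.array([0.0, 0.35, 0.80, 1.00, 1.00, 0.70, 0.35, 0.10]),
    "dip_mid": 1.0 - np.array([0.0, 0.35, 0.80, 1.00, 1.00, 0.70, 0.35, 0.10]),
}
_SHAPE_SPLINES = {
    name: BSpline(_KNOTS, coefs, 3, extrapolate=False)
    for name, coefs in _SHAPE_COEFS.items()
}


def _shape_value(shape: str, ga):
    ga = np.clip(np.asarray(ga, dtype=float), _GA_LO, _GA_HI)
    return _SHAPE_SPLINES[shape](ga)


# Covariate predicates on the participant table; covariate_effects keys must
# be drawn from this registry.
_PREDICATES = {
    "obese": lambda p: p["bmi_class"].to_numpy() == "obese",
    "overweight": lambda p: p["bmi_class"].to_numpy() == "overweight",
    "smoking": lambda p: p["smoking"].to_numpy().astype(bool),
    "multiparous": lambda p: p["parity"].to_numpy() > 0,
    "female_fetus": lambda p: p["fetal_sex"].to_numpy() == "female",
    "bw_high": lambda p: p["bw_group"].to_numpy() == ">75th",
    "bw_low": lambda p: p["bw_group"].to_numpy() == "<25th",
}

# Piecewise time profiles (weights per gestational stratum).
_PROFILES = {
    "constant": lambda ga: np.ones_like(np.asarray(ga, dtype=float)),
    "t1": lambda ga: (np.asarray(ga, float) < 98).astype(float),
    "t1_minus_t3": lambda ga: np.select(
        [np.asarray(ga, float) < 98, np.asarray(ga, float) >= 196], [1.0, -1.0], 0.0
    ),
    "t23": lambda ga: (np.asarray(ga, float) >= 98).astype(float),
    "late": lambda ga: (np.asarray(ga, float) > LATE_TERM_AFTER_DAY).astype(float),
}


@dataclass
class TrajectoryTemplate:
    """Generative log-scale trajectory for one analyte.

    The noiseless mean log-concentration at gestational day ``ga`` is
    ``baseline_log + amplitude_log * shape(ga) + late_surge_log * ramp(ga)``
    plus any covariate effects; subject random intercepts and residuals are
    added on top by :func:`simulate_concentrations`.
    """

    cytokine: str
    shape: str
    baseline_log: float
    amplitude_log: float = 0.8
    covariate_effects: dict = field(default_factory=dict)
    subject_sd: float = 0.5
    residual_sd: float = 0.4
    late_surge_log: float = 0.5

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown trajectory shape {self.shape!r}")
        for key, (_, profile) in self.covariate_effects.items():
            if key not in _PREDICATES:
                raise ValueError(f"unknown covariate predicate {key!r}")
            if profile not in _PROFILES:
                raise ValueError(f"unknown time profile {profile!r}")

    def mean_log(self, ga):
        """Noiseless population log-concentration at gestational day(s) ga."""
        ga = np.asarray(ga, dtype=float)
        val = self.baseline_log + self.amplitude_log * _shape_value(self.shape, ga)
        if self.late_surge_log:
            ramp = np.clip((ga - LATE_TERM_AFTER_DAY) / 10.0, 0.0, 1.0)
            val = val + self.late_surge_log * ramp
        return val


# Default covariate effect maps (log scale), qualitative mirror of the
# modifier analyses: obesity raises most analytes in all trimesters (CRP and
# IL-1Ra most), smoking raises IL-12/IL-17/CRP, parity flips sign between
# first and third trimester, a female fetus raises first-trimester IL-9,
# large fetuses raise IL-2/FGF-b throughout, small fetuses from mid-pregnancy.
_DEFAULT_EFFECTS = {
    "CRP": {"obese": (0.5, "constant"), "overweight": (0.25, "constant"),
            "smoking": (0.3, "constant"), "multiparous": (0.25, "t1_minus_t3")},
    "IL-1Ra": {"obese": (0.45, "constant"), "overweight": (0.2, "constant")},
    "IL-6": {"obese": (0.3, "constant"), "multiparous": (0.25, "t1_minus_t3")},
    "MCP-1": {"obese": (0.25, "constant")},
    "IL-12": {"smoking": (0.3, "constant")},
    "IL-17": {"smoking": (0.3, "constant")},
    "IL-9": {"female_fetus": (0.25, "t1"), "obese": (0.2, "constant")},
    "IL-2": {"bw_high": (0.3, "constant"), "bw_low": (0.25, "t23")},
    "FGF-b": {"bw_high": (0.3, "constant"), "bw_low": (0.25, "t23")},
}

# Rough per-analyte abundance scale (log pg/mL; CRP log µg/mL).
_BASELINE_LOG = {
    "eotaxin": np.log(90.0), "FGF-b": np.log(40.0), "G-CSF": np.log(25.0),
    "GM-CSF": np.log(15.0), "IP-10": np.log(450.0), "IL-1b": np.log(2.5),
    "IL-1Ra": np.log(120.0), "IL-2": np.log(8.0), "IL-4": np.log(4.0),
    "IL-6": np.log(5.0), "IL-7": np.log(9.0), "IL-8": np.log(12.0),
    "IL-9": np.log(25.0), "IL-12": np.log(10.0), "IL-13": np.log(6.0),
    "IL-15": np.log(5.0), "IL-17": np.log(20.0), "MCP-1": np.log(35.0),
    "MIP-1a": np.log(4.0), "MIP-1b": np.log(70.0), "PDGF-BB": np.log(900.0),
    "TNF-a": np.log(30.0), "CRP": np.log(4.0),
}


def generate_trajectory_params(panel=None, seed: int = 0) -> list[TrajectoryTemplate]:
    """Assign each analyte a trajectory template with documented defaults.

    Analytes with a canonical shape (e.g. eotaxin -> decrease) use it; any
    others are assigned a shape pseudo-randomly from the master seed.
    """
    panel = list(PANEL if panel is None else panel)
    if not panel:
        raise ValueError("panel must be non-empty")
    if len(set(panel)) != len(panel):
        raise ValueError("panel names must be unique")
    rng = np.random.default_rng([seed, 101])
    templates = []
    for cyt in panel:
        shape = _SHAPE_MAP.get(cyt, SHAPES[int(rng.integers(len(SHAPES)))])
        base = _BASELINE_LOG.get(cyt, float(rng.uniform(np.log(5.0), np.log(200.0))))
        surge = 0.0 if cyt == "FGF-b" else 0.5
        templates.append(
            TrajectoryTemplate(
                cytokine=cyt,
                shape=shape,
                baseline_log=base,
                covariate_effects=dict(_DEFAULT_EFFECTS.get(cyt, {})),
                late_surge_log=surge,
            )
        )
    return templates


@dataclass
class StudyConfig:
    """Study-design knobs; defaults mirror the emulated multi-cohort design."""

    late_term_frac: float = 0.56  # ~396/707 women sampled beyond week 40+3
    smoking_prev: float = 0.10
    nulliparous_prev: float = 0.46
    female_prev: float = 0.42
    bmi_class_probs: tuple = (0.64, 0.26, 0.10)  # normal / overweight / obese
    term_cohorts: tuple = (1, 2, 3, 4)
    late_term_cohort: int = 5
    n_samples_probs: tuple = (0.16, 0.28, 0.28, 0.28)  # 1..4 samples; 84% > 1
    trimester_probs: tuple = (0.25, 0.49, 0.26)  # T1 / T2 / T3 sampling mix
    age_mean: float = 30.0
    age_sd: float = 4.5
    late_term_sampling_day: int = 289  # ~week 41+2
    late_term_sampling_jitter: int = 2  # discrete uniform +/- days

    def validate(self):
        for name in ("late_term_frac", "smoking_prev", "nulliparous_prev", "female_prev"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.term_cohorts:
            raise ValueError("term_cohorts must be non-empty")
        if abs(sum(self.bmi_class_probs) - 1.0) > 1e-9:
            raise ValueError("bmi_class_probs must sum to 1")
        return self


def synthetic_birthweight_reference() -> pd.DataFrame:
    """Synthetic sex-specific birth-weight reference (mean/SD in g by GA days).

    A deliberately simple linear-growth stand-in for population references:
    ~3650 g for boys at day 282, growing 22 g/day, girls 130 g lighter,
    SD 450 g.  Used both to simulate birth weights and to compute z-scores.
    """
    ga = np.arange(231, 309, 7)
    rows = []
    for sex in ("male", "female"):
        mean = 3650.0 + 22.0 * (ga - 282.0) - (130.0 if sex == "female" else 0.0)
        rows.append(pd.DataFrame({"ga_days": ga, "sex": sex, "mean_g": mean, "sd_g": 450.0}))
    return pd.concat(rows, ignore_index=True)


def _bw_mean(ga, sex):
    base = 3650.0 + 22.0 * (np.asarray(ga, float) - 282.0)
    return base - np.where(np.asarray(sex) == "female", 130.0, 0.0)


def generate_cohort(n_women: int, config: StudyConfig | None = None, seed: int = 0):
    """Draw participants and their serum-sampling schedule.

    Returns ``(participants, samples)`` data frames.  Term-group women get
    1-4 samples spread over trimesters; late-term women exactly one sample
    near day 289.
    """
    config = (config or StudyConfig()).validate()
    if n_women < 2:
        raise ValueError("n_women must be >= 2")
    rng = np.random.default_rng([seed, 11])

    n = n_women
    late = rng.random(n) < config.late_term_frac
    cohort = np.where(
        late,
        config.late_term_cohort,
        rng.choice(config.term_cohorts, size=n),
    )
    smoking = rng.random(n) < config.smoking_prev
    parity = np.where(rng.random(n) < config.nulliparous_prev, 0, rng.integers(1, 4, size=n))
    fetal_sex = np.where(rng.random(n) < config.female_prev, "female", "male")
    bmi_class = rng.choice(
        ["normal", "overweight", "obese"], size=n, p=list(config.bmi_class_probs)
    )
    bmi = np.select(
        [bmi_class == "normal", bmi_class == "overweight"],
        [rng.uniform(18.5, 25.0, n), rng.uniform(25.0, 30.0, n)],
        rng.uniform(30.0, 40.0, n),
    )
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 45)

    # Sampling schedule first (late-term delivery must follow sampling).
    pid = np.array([f"P{i:04d}" for i in range(n)])
    sample_rows = []
    ga_sampling_late = np.full(n, np.nan)
    for i in range(n):
        if late[i]:
            j = config.late_term_sampling_jitter
            ga = config.late_term_sampling_day + int(rng.integers(-j, j + 1))
            ga_sampling_late[i] = ga
            sample_rows.append((pid[i], 1, ga))
        else:
            k = 1 + int(rng.choice(4, p=list(config.n_samples_probs)))
            tri = rng.choice(3, size=k, p=list(config.trimester_probs))
            windows = [(45.0, 97.0), (98.0, 195.0), (196.0, 280.0)]
            gas = np.sort([rng.uniform(*windows[t]) for t in tri])
            # enforce >= 7 days between repeat visits
            for v in range(1, k):
                gas[v] = max(gas[v], gas[v - 1] + 7.0)
            gas = np.clip(gas, 45.0, 280.0)
            for v, ga in enumerate(np.unique(np.round(gas, 1)), start=1):
                sample_rows.append((pid[i], v, float(ga)))

    ga_delivery = np.where(
        late,
        ga_sampling_late + np.clip(rng.normal(3.4, 2.5, n), 0.5, 13.0),
        np.clip(rng.normal(280.2, 8.8, n), 259, 295),
    )
    ga_delivery = np.clip(ga_delivery, 259, 302)

    bw_z = rng.normal(0.0, 1.0, n)
    birth_weight = _bw_mean(ga_delivery, fetal_sex) + 450.0 * bw_z
    bw_group = np.select(
        [bw_z < -0.6745, bw_z > 0.6745], ["<25th", ">75th"], "25-75th"
    )

    event = np.where(
        late,
        rng.choice(["spontaneous", "induced_randomized", "induced_clinical"],
                   size=n, p=[0.43, 0.40, 0.17]),
        rng.choice(["spontaneous", "cesarean", "induced_clinical"],
                   size=n, p=[0.80, 0.10, 0.10]),
    )

    participants = pd.DataFrame({
        "participant_id": pid,
        "cohort": cohort.astype(int),
        "age": np.round(age, 1),
        "bmi": np.round(bmi, 1),
        "bmi_class": bmi_class,
        "smoking": smoking,
        "parity": parity.astype(int),
        "fetal_sex": fetal_sex,
        "birth_weight": np.round(birth_weight, 0),
        "ga_delivery": np.round(ga_delivery, 1),
        "study_group": np.where(late, "late_term", "term"),
        "delivery_event": event,
        "bw_group": bw_group,
    })
    samples = pd.DataFrame(sample_rows, columns=["participant_id", "visit", "ga_sampling"])
    samples.insert(0, "sample_id", [f"S{i:05d}" for i in range(len(samples))])
    samples = samples.merge(participants[["participant_id", "cohort"]], on="participant_id")
    return participants, samples


def simulate_concentrations(participants, samples, templates, seed: int = 0) -> pd.DataFrame:
    """Realize true analyte concentrations for every (sample, analyte) pair.

    log-concentration = template mean at GA + covariate effects + subject
    random intercept + residual; concentrations are strictly positive.
    """
    ga = samples["ga_sampling"].to_numpy(float)
    if np.any((ga < 30) | (ga > 302)):
        raise ValueError("sample gestational ages must lie in [30, 302] days")
    rng = np.random.default_rng([seed, 23])
    part = participants.set_index("participant_id")
    sample_pid = samples["participant_id"].to_numpy()
    part_rows = part.loc[sample_pid].reset_index()

    out = []
    pids = participants["participant_id"].to_numpy()
    for tpl in templates:
        log_c = tpl.mean_log(ga).astype(float).copy()
        for key, (delta, profile) in tpl.covariate_effects.items():
            mask = _PREDICATES[key](part_rows)
            log_c += delta * mask * _PROFILES[profile](ga)
        if tpl.subject_sd > 0:
            intercepts = dict(zip(pids, rng.normal(0.0, tpl.subject_sd, len(pids))))
            log_c += np.array([intercepts[p] for p in sample_pid])
        if tpl.residual_sd > 0:
            log_c += rng.normal(0.0, tpl.residual_sd, len(ga))
        out.append(pd.DataFrame({
            "sample_id": samples["sample_id"].to_numpy(),
            "participant_id": sample_pid,
            "cytokine": tpl.cytokine,
            "true_conc": np.exp(log_c),
            "true_log_conc": log_c,
            "unit": UNITS.get(tpl.cytokine, "pg/mL"),
        }))
    return pd.concat(out, ignore_index=True)


@dataclass
class AssayConfig:
    """Forward assay model: lots/plates, multiplicative offsets, 5PL truth,
    power-law noise var(FI) = theta0 * mean(FI)**theta1, bridge re-assays."""

    lots: tuple = ("L1", "L2", "L3")
    reference_lot: str = "L1"
    plates_per_lot: int = 4
    lot_offsets: dict = field(default_factory=dict)  # (lot, cytokine) -> log offset
    plate_offsets: dict = field(default_factory=dict)  # (lot, plate, cytokine) -> log offset
    curve_params: dict = field(default_factory=dict)  # cytokine -> FivePL
    theta: tuple = (0.5, 1.4)
    bridge_n: int = 8
    n_standard_levels: int = 8
    standard_dilution: float = 4.0

    def validate(self):
        if self.reference_lot not in self.lots:
            raise ValueError("reference_lot must be one of lots")
        t0, t1 = self.theta
        if t0 < 0 or t1 < 0:
            raise ValueError("noise power model requires theta0 >= 0, theta1 >= 0")
        if self.bridge_n < 1:
            raise ValueError("bridge_n must be >= 1")
        return self


def default_assay_config(
    cytokines=None,
    seed: int = 0,
    n_lots: int = 3,
    plates_per_lot: int = 4,
    lot_sd: float = 0.2,
    plate_sd: float = 0.1,
    theta: tuple = (0.5, 1.4),
    bridge_n: int = 8,
) -> AssayConfig:
    """Draw a realistic assay configuration for the given panel."""
    cytokines = list(PANEL if cytokines is None else cytokines)
    rng = np.random.default_rng([seed, 37])
    lots = tuple(f"L{i + 1}" for i in range(n_lots))
    curve_params, lot_offsets, plate_offsets = {}, {}, {}
    for cyt in cytokines:
        scale = np.exp(_BASELINE_LOG.get(cyt, np.log(20.0)))
        curve_params[cyt] = FivePL(
            a=50.0, b=1.2, c=4.0 * scale, d=24000.0,
            g=float(rng.uniform(0.8, 1.3)),
        )
        for lot in lots:
            off = 0.0 if lot == lots[0] else float(rng.normal(0.0, lot_sd))
            lot_offsets[(lot, cyt)] = off
            for p in range(1, plates_per_lot + 1):
                plate_offsets[(lot, f"{lot}-P{p}", cyt)] = float(rng.normal(0.0, plate_sd))
    return AssayConfig(
        lots=lots, reference_lot=lots[0], plates_per_lot=plates_per_lot,
        lot_offsets=lot_offsets, plate_offsets=plate_offsets,
        curve_params=curve_params, theta=theta, bridge_n=bridge_n,
    )


def _noisy_fi(mean_fi, theta, rng):
    t0, t1 = theta
    if t0 == 0:
        return np.asarray(mean_fi, float).copy(), np.zeros(np.shape(mean_fi), bool)
    sd = np.sqrt(t0 * np.asarray(mean_fi, float) ** t1)
    fi = np.asarray(mean_fi, float) + rng.normal(0.0, 1.0, np.shape(mean_fi)) * sd
    clipped = fi <= 0
    return np.where(clipped, 1e-6, fi), clipped


def simulate_assay_fi(true_conc: pd.DataFrame, assay: AssayConfig, seed: int = 0):
    """Forward immunoassay model: FI tables, bridge manifest, standards.

    Returns ``(fi_long, bridge_manifest, standards)``.  ``fi_long`` holds
    sample, bridge, standard, blank and pooled-control wells; the pooled
    control is replicated in duplicate on every plate (a natural intra-lot
    anchor set), standards and blanks in duplicate per plate.
    """
    assay.validate()
    rng = np.random.default_rng([seed, 53])
    cytokines = sorted(true_conc["cytokine"].unique())
    for cyt in cytokines:
        if cyt not in assay.curve_params:
            raise ValueError(f"no 5PL truth configured for {cyt!r}")

    sample_ids = true_conc["sample_id"].unique()
    order = rng.permutation(len(sample_ids))
    lot_of, plate_of = {}, {}
    plates = {lot: [f"{lot}-P{p}" for p in range(1, assay.plates_per_lot + 1)]
              for lot in assay.lots}
    for pos, idx in enumerate(order):
        lot = assay.lots[pos % len(assay.lots)]
        lot_of[sample_ids[idx]] = lot
        plate_of[sample_ids[idx]] = plates[lot][(pos // len(assay.lots)) % len(plates[lot])]

    conc_wide = true_conc.pivot(index="sample_id", columns="cytokine", values="true_conc")

    def _measure(conc_vec, lot, plate, cyt):
        curve = assay.curve_params[cyt]
        off = assay.lot_offsets.get((lot, cyt), 0.0) + assay.plate_offsets.get((lot, plate, cyt), 0.0)
        mean_fi = curve(conc_vec) * np.exp(off)
        return _noisy_fi(mean_fi, assay.theta, rng)

    rows = []
    well_counter = [0]

    def _well():
        well_counter[0] += 1
        return f"W{well_counter[0]:06d}"

    # --- study samples
    for cyt in cytokines:
        conc = conc_wide[cyt]
        lots_arr = np.array([lot_of[s] for s in conc.index])
        plates_arr = np.array([plate_of[s] for s in conc.index])
        for lot in assay.lots:
            for plate in plates[lot]:
                m = (lots_arr == lot) & (plates_arr == plate)
                if not m.any():
                    continue
                fi, clip = _measure(conc[m].to_numpy(), lot, plate, cyt)
                for sid, f, cl in zip(conc.index[m], fi, clip):
                    rows.append((sid, cyt, f, lot, plate, _well(), "sample", cl))

    # --- bridge re-assays: bridge_n samples per non-reference lot re-measured
    # in the reference lot
    manifest = []
    ref = assay.reference_lot
    for lot in assay.lots:
        if lot == ref:
            continue
        in_lot = [s for s in sample_ids if lot_of[s] == lot]
        chosen = list(rng.choice(in_lot, size=min(assay.bridge_n, len(in_lot)), replace=False))
        for k, sid in enumerate(chosen):
            ref_plate = plates[ref][k % len(plates[ref])]
            manifest.append((sid, lot, plate_of[sid], ref_plate))
            for cyt in cytokines:
                fi, clip = _measure(np.array([conc_wide.loc[sid, cyt]]), ref, ref_plate, cyt)
                rows.append((sid, cyt, fi[0], ref, ref_plate, _well(), "bridge", clip[0]))
    bridge_manifest = pd.DataFrame(
        manifest, columns=["sample_id", "origin_lot", "origin_plate", "reference_plate"]
    )

    # --- pooled control, duplicate per plate, common true concentration
    ctrl_conc = {c: float(np.exp(np.log(conc_wide[c]).mean())) for c in cytokines}
    for lot in assay.lots:
        for plate in plates[lot]:
            for rep in (1, 2):
                for cyt in cytokines:
                    fi, clip = _measure(np.array([ctrl_conc[cyt]]), lot, plate, cyt)
                    rows.append((f"CTRL-{lot}-{plate}-{rep}", cyt, fi[0], lot, plate,
                                 _well(), "control", clip[0]))

    # --- standards (duplicate per plate) and blanks
    std_rows = []
    n_lvl, dil = assay.n_standard_levels, assay.standard_dilution
    for cyt in cytokines:
        top = assay.curve_params[cyt].c * dil ** 2
        levels = top / dil ** np.arange(n_lvl)
        for lot in assay.lots:
            for plate in plates[lot]:
                for lvl, conc in enumerate(levels, start=1):
                    for rep in (1, 2):
                        fi, _ = _measure(np.array([conc]), lot, plate, cyt)
                        std_rows.append((cyt, lot, plate, _well(), lvl, conc, fi[0]))
                for rep in (1, 2):
                    fi, clip = _measure(np.array([0.0]), lot, plate, cyt)
                    rows.append((f"BLANK-{lot}-{plate}-{rep}", cyt, fi[0], lot, plate,
                                 _well(), "blank", clip[0]))
    standards = pd.DataFrame(
        std_rows, columns=["cytokine", "lot", "plate", "well", "level", "conc", "fi"]
    )
    fi_long = pd.DataFrame(
        rows, columns=["sample_id", "cytokine", "fi", "lot", "plate", "well", "role", "clipped"]
    )
    return fi_long, bridge_manifest, standards


def simulate_labor_outcomes(
    late_term_participants: pd.DataFrame,
    X: pd.DataFrame | None = None,
    association: dict | None = None,
    seed: int = 0,
    base_incidence: float = 0.45,
    delay_scale: float = 4.8,
    induction_window: tuple = (8, 13),
) -> pd.DataFrame:
    """Draw sampling-to-delivery times under a subdistribution-hazard model.

    Spontaneous labor is the event of interest with cumulative incidence
    ``F1(t; x) = 1 - (1 - p * (1 - exp(-t / s)))**exp(x @ beta)`` (p =
    ``base_incidence``, s = ``delay_scale``); women not in spontaneous labor
    by their scheduled induction day are censored (``induced_randomized``);
    clinically indicated inductions are a competing event.  ``X`` holds one
    normalized cytokine row per participant; ``association`` maps cytokine ->
    log subdistribution hazard ratio (empty/None = all-null model).
    """
    rng = np.random.default_rng([seed, 71])
    part = late_term_participants.reset_index(drop=True)
    n = len(part)
    association = dict(association or {})
    eta = np.zeros(n)
    if association:
        if X is None:
            raise ValueError("association given but no cytokine matrix X")
        Xa = X.loc[part["participant_id"]] if X.index.name == "participant_id" else X.reset_index(drop=True)
        for cyt, beta in association.items():
            eta += beta * np.asarray(Xa[cyt], dtype=float)
    eta = np.exp(eta)

    p, s = base_incidence, delay_scale
    if not 0 < p < 1:
        raise ValueError("base_incidence must be in (0, 1)")
    cause1 = rng.random(n) < 1.0 - (1.0 - p) ** eta
    u = rng.random(n)
    # inverse of the conditional cause-1 subdistribution
    inner = (1.0 - u * (1.0 - (1.0 - p) ** eta)) ** (1.0 / eta)
    t1 = -s * np.log(1.0 - (1.0 - inner) / p)
    t2 = rng.exponential(25.0, n)  # clinically indicated induction (most women
    # instead reach their scheduled randomized induction and are censored)
    admin = rng.integers(induction_window[0], induction_window[1] + 1, n).astype(float)

    t_event = np.where(cause1, t1, t2)
    if np.any(t_event < 0):
        raise RuntimeError("negative latent event time")
    event = np.where(cause1, "spontaneous", "induced_clinical")
    censored = t_event > admin
    days = np.where(censored, admin, t_event)
    event = np.where(censored, "induced_randomized", event)
    return pd.DataFrame({
        "participant_id": part["participant_id"].to_numpy(),
        "days_to_delivery": np.round(days, 3),
        "event": event,
    })


def generate_study(n_women: int = 700, seed: int = 0, config: StudyConfig | None = None,
                   assay: AssayConfig | None = None, templates=None):
    """One-call generator: returns a dict with every study table plus truth."""
    config = config or StudyConfig()
    templates = templates if templates is not None else generate_trajectory_params(seed=seed)
    participants, samples = generate_cohort(n_women, config, seed=seed)
    truth = simulate_concentrations(participants, samples, templates, seed=seed)
    assay = assay or default_assay_config([t.cytokine for t in templates], seed=seed)
    fi_long, bridge_manifest, standards = simulate_assay_fi(truth, assay, seed=seed)
    late = participants[participants["study_group"] == "late_term"]
    outcomes = simulate_labor_outcomes(late, seed=seed)
    # keep participant delivery data consistent with the drawn outcomes
    participants = participants.merge(outcomes, on="participant_id", how="left")
    late_mask = participants["study_group"] == "late_term"
    ga_samp = samples.set_index("participant_id")["ga_sampling"]
    participants.loc[late_mask, "delivery_event"] = participants.loc[late_mask, "event"]
    participants.loc[late_mask, "ga_delivery"] = np.round(
        ga_samp.loc[participants.loc[late_mask, "participant_id"]].to_numpy()
        + participants.loc[late_mask, "days_to_delivery"].to_numpy(), 1
    )
    participants = participants.drop(columns=["days_to_delivery", "event"])
    return {
        "participants": participants, "samples": samples, "truth": truth,
        "fi_long": fi_long, "bridge_manifest": bridge_manifest,
        "standards": standards, "outcomes": outcomes,
        "assay": assay, "templates": templates, "config": config,
    }


_SCHEMA = {
    "participants.csv": {
        "participant_id": "opaque id", "cohort": "1..5 (5 = late-term cohort)",
        "age": "years", "bmi": "kg/m^2", "bmi_class": "normal|overweight|obese",
        "smoking": "bool", "parity": "prior births (0 = nulliparous)",
        "fetal_sex": "female|male", "birth_weight": "grams",
        "ga_delivery": "gestational days at delivery",
        "study_group": "term|late_term",
        "delivery_event": "spontaneous|induced_randomized|induced_clinical|cesarean",
        "bw_group": "<25th|25-75th|>75th birth-weight percentile",
    },
    "samples.csv": {"sample_id": "opaque id", "participant_id": "fk",
                    "visit": "1..4", "ga_sampling": "gestational days",
                    "cohort": "fk"},
    "fi_long.csv": {"sample_id": "fk (or control/blank well id)",
                    "cytokine": "analyte name", "fi": "fluorescence units",
                    "lot": "reagent lot", "plate": "assay plate", "well": "well id",
                    "role": "sample|bridge|standard|blank|control",
                    "clipped": "bool, noise clipped at zero"},
    "bridge_manifest.csv": {"sample_id": "fk", "origin_lot": "lot of first assay",
                            "origin_plate": "plate of first assay",
                            "reference_plate": "re-assay plate in reference lot"},
    "standards.csv": {"cytokine": "analyte", "lot": "lot", "plate": "plate",
                      "well": "well id", "level": "dilution level (1 = top)",
                      "conc": "nominal concentration", "fi": "fluorescence"},
    "outcomes.csv": {"participant_id": "fk",
                     "days_to_delivery": "days from sampling",
                     "event": "spontaneous|induced_randomized|induced_clinical"},
    "units": {"CRP": "ug/mL", "other analytes": "pg/mL"},
    "encoding": "UTF-8, header row, ISO floats",
}


def write_study(study: dict, outdir) -> None:
    """Write the generated tables as UTF-8 CSV under ``outdir`` (truth under
    truth/), plus a schema.json documenting column semantics."""
    import json
    from pathlib import Path

    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    (out / "schema.json").write_text(json.dumps(_SCHEMA, indent=2))
    study["participants"].to_csv(out / "participants.csv", index=False)
    study["samples"].to_csv(out / "samples.csv", index=False)
    study["fi_long"].to_csv(out / "fi_long.csv", index=False)
    study["bridge_manifest"].to_csv(out / "bridge_manifest.csv", index=False)
    study["standards"].to_csv(out / "standards.csv", index=False)
    study["outcomes"].to_csv(out / "outcomes.csv", index=False)
    study["truth"].to_csv(out / "truth" / "concentrations.csv", index=False)
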