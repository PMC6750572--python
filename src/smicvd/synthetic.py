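"""Synthetic linked person + service-contact tables for a risk-assessment cohort.

The generator emulates a primary-care CVD risk-assessment cohort linked to
specialist mental-health service-contact records: ~5.8% of persons have a
qualifying face-to-face contact in the five years before their index
assessment, ~15.5% of those carry a functional-psychosis (F20-F31)
diagnosis, a large fraction of contact diagnosis codes are missing,
staggered entry over a 12.2-year study window yields a mean realized
follow-up of about 4.5 years, and an excess CVD event risk in the exposed
group — absent from the scoring equation — can be injected on either the
risk or the hazard scale.

Event times are drawn by inverse transform from the true cumulative risk

    risk_ratio mode:   R_true(t) = min(1, m * (1 - S0(t)^exp(LP)))
    hazard_ratio mode: R_true(t) = 1 - S0(t)^(m * exp(LP))

with m the sex-specific excess factor for exposed persons (m = 1 for the
unexposed) and S0(t) a Weibull-shaped baseline anchored at the equation's
S0(horizon).  Non-CVD death is an independent exponential competing
censoring time; administrative censoring runs from entry to study end.
Generation is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import prioritized_ethnicity
from .errors import ConfigurationError
from .risk import RiskEquationSpec, default_equation, linear_predictor_frame

STUDY_START = pd.Timestamp("2004-10-20")
STUDY_END = pd.Timestamp("2016-12-31")
DAYS_PER_YEAR = 365.25

PSYCHOSIS_CODES = ("F20.0", "F20.9", "F23.2", "F25.1", "F29", "F30.1", "F31.9")
OTHER_MH_CODES = ("F32.1", "F33.2", "F41.1", "F43.1", "F10.2", "F60.3")


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    n_total: int = 100_000
    sex_split: float = 0.44  # proportion female
    smi_prevalence: float = 0.058
    psychosis_fraction_of_smi: float = 0.155
    missing_diagnosis_fraction: float = 0.362
    excess_mode: str = "risk_ratio"  # or "hazard_ratio"
    excess_factor_female: float = 1.64
    excess_factor_male: float = 1.29
    followup_max_years: float = 12.2
    entry_window_years: float = 12.2
    # entry density over the window is proportional to x^(entry_shape - 1):
    # recruitment accelerates over time, which is what pulls mean follow-up
    # down to ~4.5y while a thin early-entry tail preserves the 12.2y maximum
    entry_shape: float = 1.6
    noncvd_death_rate: float = 0.005  # per-year hazard
    baseline_weibull_shape: float = 1.15
    # missingness (person level)
    missing_smoking_rate: float = 5e-6
    missing_tchdl_rate: float = 0.0054
    missing_bmi_rate: float = 0.197
    # age structure (years); SMI persons are younger on average
    age_mean_female: float = 56.5
    age_mean_male: float = 52.5
    age_sd: float = 10.5
    age_smi_shift: float = -5.0
    age_clip: tuple[float, float] = (28.0, 77.0)  # slightly beyond 30-74 to exercise filters
    # risk-factor distributions (Table-2-like magnitudes)
    sbp_mean: float = 128.0
    sbp_sd: float = 17.0
    tchdl_mean_female: float = 3.72
    tchdl_mean_male: float = 4.40
    tchdl_sd: float = 1.2
    bmi_mean: float = 29.2
    bmi_sd: float = 6.5
    smoke_current_rate: float = 0.13
    smoke_current_rate_smi: float = 0.36
    smoke_past_rate: float = 0.165
    diabetes_rate: float = 0.105
    diabetes_psychosis_multiplier: float = 1.8
    af_rate: float = 0.010
    family_history_rate: float = 0.105
    bp_lowering_rate: float = 0.22
    lipid_lowering_rate: float = 0.15
    antithrombotic_rate: float = 0.09
    prior_cvd_rate: float = 0.120
    prior_renal_failure_rate: float = 0.012
    deprivation_probs: tuple[float, ...] = (0.215, 0.200, 0.182, 0.184, 0.219)
    deprivation_probs_smi: tuple[float, ...] = (0.14, 0.15, 0.17, 0.21, 0.33)
    ethnicity_probs: tuple[float, ...] = (0.125, 0.122, 0.085, 0.105, 0.563)
    ethnicity_probs_smi: tuple[float, ...] = (0.30, 0.125, 0.043, 0.045, 0.487)
    second_ethnicity_record_rate: float = 0.30
    # contacts
    mean_extra_qualifying_contacts: float = 2.0
    inpatient_fraction: float = 0.15
    decoy_contact_rate: float = 0.05
    post_index_psychosis_code_rate: float = 0.20
    seed: int = 0

    def validate(self) -> None:
        if self.n_total <= 0:
            raise ConfigurationError("n_total must be positive")
        proportions = {
            "sex_split": self.sex_split,
            "smi_prevalence": self.smi_prevalence,
            "psychosis_fraction_of_smi": self.psychosis_fraction_of_smi,
            "missing_diagnosis_fraction": self.missing_diagnosis_fraction,
            "missing_smoking_rate": self.missing_smoking_rate,
            "missing_tchdl_rate": self.missing_tchdl_rate,
            "missing_bmi_rate": self.missing_bmi_rate,
            "smoke_current_rate": self.smoke_current_rate,
            "smoke_current_rate_smi": self.smoke_current_rate_smi,
            "smoke_past_rate": self.smoke_past_rate,
            "prior_cvd_rate": self.prior_cvd_rate,
            "prior_renal_failure_rate": self.prior_renal_failure_rate,
            "decoy_contact_rate": self.decoy_contact_rate,
            "inpatient_fraction": self.inpatient_fraction,
            "post_index_psychosis_code_rate": self.post_index_psychosis_code_rate,
        }
        for name, value in proportions.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.excess_factor_female <= 0 or self.excess_factor_male <= 0:
            raise ConfigurationError("excess factors must be positive")
        if self.excess_mode not in ("risk_ratio", "hazard_ratio"):
            raise ConfigurationError(f"unknown excess_mode {self.excess_mode!r}")
        if self.followup_max_years <= 0:
            raise ConfigurationError("followup_max_years must be positive")
        if self.entry_window_years <= 0 or self.entry_shape <= 0:
            raise ConfigurationError("entry_window_years and entry_shape must be positive")
        if self.noncvd_death_rate < 0:
            raise ConfigurationError("noncvd_death_rate must be non-negative")
        for name in ("deprivation_probs", "deprivation_probs_smi",
                     "ethnicity_probs", "ethnicity_probs_smi"):
            probs = getattr(self, name)
            if len(probs) == 0 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ConfigurationError(f"{name} must be non-negative and sum to 1")

    # --- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(doc) - set(fields)
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        kwargs = {}
        for key, value in doc.items():
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(doc or {})


_ETHNICITY_CATS = ("maori", "pacific", "indian", "chinese_asian", "european_other")


def _generate_persons(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_total
    sex = np.where(rng.random(n) < cfg.sex_split, "F", "M")
    smi = rng.random(n) < cfg.smi_prevalence
    psychosis = smi & (rng.random(n) < cfg.psychosis_fraction_of_smi)

    age_mean = np.where(sex == "F", cfg.age_mean_female, cfg.age_mean_male)
    age = rng.normal(age_mean + np.where(smi, cfg.age_smi_shift, 0.0), cfg.age_sd)
    age = np.clip(age, *cfg.age_clip).round(1)

    # ethnicity: 1-2 raw records; second record exercises the prioritization
    eth_p = np.asarray(cfg.ethnicity_probs)
    eth_p_smi = np.asarray(cfg.ethnicity_probs_smi)
    u = rng.random(n)
    cum = np.cumsum(eth_p)
    cum_smi = np.cumsum(eth_p_smi)
    primary_idx = np.where(
        smi, np.searchsorted(cum_smi, u), np.searchsorted(cum, u)
    ).clip(0, 4)
    primary = np.take(_ETHNICITY_CATS, primary_idx)
    second_mask = rng.random(n) < cfg.second_ethnicity_record_rate
    second_idx = rng.integers(0, len(_ETHNICITY_CATS), n)
    records = np.where(
        second_mask,
        np.char.add(np.char.add(primary.astype("U32"), "|"),
                    np.take(_ETHNICITY_CATS, second_idx)),
        primary,
    )

    dep_u = rng.random(n)
    dep = np.where(
        smi,
        np.searchsorted(np.cumsum(cfg.deprivation_probs_smi), dep_u),
        np.searchsorted(np.cumsum(cfg.deprivation_probs), dep_u),
    ).clip(0, 4) + 1

    smoke_u = rng.random(n)
    current_rate = np.where(smi, cfg.smoke_current_rate_smi, cfg.smoke_current_rate)
    smoker = np.where(
        smoke_u < current_rate,
        "current",
        np.where(smoke_u < current_rate + cfg.smoke_past_rate, "past", "never"),
    ).astype(object)
    smoker[rng.random(n) < cfg.missing_smoking_rate] = None

    sbp = rng.normal(cfg.sbp_mean + 0.25 * (age - 55.0), cfg.sbp_sd).round(1)
    sbp = np.clip(sbp, 80.0, 230.0)
    dbp = np.clip(
        (0.35 * sbp + 34.0 + rng.normal(0.0, 8.0, n)).round(1), 45.0, sbp
    )

    tchdl_mean = np.where(sex == "F", cfg.tchdl_mean_female, cfg.tchdl_mean_male)
    tchdl = np.clip(rng.normal(tchdl_mean, cfg.tchdl_sd), 1.5, 12.0).round(2)
    tchdl = tchdl.astype(object)
    tchdl[rng.random(n) < cfg.missing_tchdl_rate] = None

    bmi = np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, n), 15.0, 65.0).round(1)
    bmi = bmi.astype(object)
    bmi[rng.random(n) < cfg.missing_bmi_rate] = None

    diabetes_rate = np.where(
        psychosis, min(1.0, cfg.diabetes_rate * cfg.diabetes_psychosis_multiplier),
        cfg.diabetes_rate,
    )
    diabetes = rng.random(n) < diabetes_rate
    af = rng.random(n) < cfg.af_rate
    fh = rng.random(n) < cfg.family_history_rate
    bp_med = rng.random(n) < cfg.bp_lowering_rate
    lipid_med = rng.random(n) < cfg.lipid_lowering_rate
    at_med = rng.random(n) < cfg.antithrombotic_rate
    prior_cvd = rng.random(n) < cfg.prior_cvd_rate
    renal = rng.random(n) < cfg.prior_renal_failure_rate

    # staggered entry: density over the window proportional to x^(shape-1)
    window_days = (STUDY_END - STUDY_START).days
    entry_frac = rng.beta(cfg.entry_shape, 1.0, n)
    entry_days = np.floor(entry_frac * min(
        window_days, cfg.entry_window_years * DAYS_PER_YEAR)).astype(int)
    index_date = STUDY_START + pd.to_timedelta(entry_days, unit="D")

    return pd.DataFrame(
        {
            "person_id": [f"P{i:07d}" for i in range(n)],
            "sex": sex,
            "age_at_index": age,
            "ethnicity_records": records,
            "deprivation_quintile": dep.astype(int),
            "smoker_status": smoker,
            "diabetes": diabetes,
            "atrial_fibrillation": af,
            "family_history": fh,
            "sbp": sbp,
            "dbp": dbp,
            "tchdl": tchdl,
            "bmi": bmi,
            "bp_lowering": bp_med,
            "lipid_lowering": lipid_med,
            "antithrombotic": at_med,
            "prior_cvd": prior_cvd,
            "prior_renal_failure": renal,
            "index_date": index_date.strftime("%Y-%m-%d"),
            "true_smi": smi,
            "true_psychosis": psychosis,
        }
    )


def simulate_outcomes(
    persons: pd.DataFrame,
    equation: RiskEquationSpec | None,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Populate event_time_years and event_type by inverse-transform sampling.

    The true cumulative event risk multiplies (risk_ratio mode) or
    exponent-scales (hazard_ratio mode) the equation's risk by the
    sex-specific excess factor for exposed persons.  Missing covariates are
    imputed internally for generation only (sex-mean TC:HDL, never-smoker);
    the emitted table keeps its original missingness.
    """
    config.validate()
    if equation is None:
        equation = default_equation()
    if abs(equation.horizon_years - 5.0) > 10.0 or (
        equation.horizon_years > config.followup_max_years
    ):
        raise ConfigurationError(
            "equation horizon_years inconsistent with followup_max_years"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    n = len(persons)
    scored = persons.copy()
    # generation-only imputation so every person has a linear predictor
    tch = pd.to_numeric(scored["tchdl"], errors="coerce")
    sex_mean = scored["sex"].map(
        {"F": config.tchdl_mean_female, "M": config.tchdl_mean_male}
    )
    scored["tchdl"] = tch.fillna(sex_mean)
    scored["smoker_status"] = scored["smoker_status"].fillna("never")
    scored["ethnicity"] = scored["ethnicity_records"].map(prioritized_ethnicity)

    lp = linear_predictor_frame(scored, equation).to_numpy()
    s0h = scored["sex"].map(
        {
            "F": equation.female.baseline_survival_at_horizon,
            "M": equation.male.baseline_survival_at_horizon,
        }
    ).to_numpy(dtype=float)
    h = equation.horizon_years
    k = config.baseline_weibull_shape
    exposed = scored["true_smi"].to_numpy(dtype=bool)
    m = np.where(
        exposed,
        np.where(scored["sex"].to_numpy() == "F",
                 config.excess_factor_female, config.excess_factor_male),
        1.0,
    )

    u = rng.random(n)
    log_s0 = np.log(s0h)
    t_event = np.full(n, np.inf)
    active = log_s0 < 0  # S0(h) = 1 means no event hazard at all
    if config.excess_mode == "risk_ratio":
        # solve m * (1 - S0(h)^((t/h)^k e^LP)) = u
        frac = u / m
        solvable = active & (frac < 1.0)
        arg = np.log1p(-frac[solvable])
        t_event[solvable] = h * (
            arg / (np.exp(lp[solvable]) * log_s0[solvable])
        ) ** (1.0 / k)
    else:  # hazard_ratio: m scales exp(LP) inside the exponent
        solvable = active
        arg = np.log1p(-u[solvable])
        t_event[solvable] = h * (
            arg / (m[solvable] * np.exp(lp[solvable]) * log_s0[solvable])
        ) ** (1.0 / k)

    if config.noncvd_death_rate > 0:
        t_death = rng.exponential(1.0 / config.noncvd_death_rate, n)
    else:
        t_death = np.full(n, np.inf)

    index_dates = pd.to_datetime(persons["index_date"])
    admin = np.minimum(
        config.followup_max_years,
        (STUDY_END - index_dates).dt.days.to_numpy() / DAYS_PER_YEAR,
    )

    stacked = np.vstack([t_event, t_death, admin])
    winner = np.argmin(stacked, axis=0)
    out = persons.copy()
    out["event_time_years"] = np.round(stacked[winner, np.arange(n)], 6)
    out["event_type"] = np.take(["cvd", "noncvd_death", "censored"], winner)
    return out


def _generate_contacts(
    persons: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Qualifying contacts for exposed persons, decoys for some unexposed.

    Exposed persons get 1 + Poisson(mean_extra) contacts uniformly in the
    half-open 5-year pre-index window.  Psychosis persons additionally get
    one guaranteed F20-F31-coded contact (sometimes dated after the index
    assessment, exercising the any-date diagnosis rule).  Decoys are either
    older than the window or have setting='other', so they never qualify.
    """
    ids = persons["person_id"].to_numpy()
    index_dates = pd.to_datetime(persons["index_date"])
    smi = persons["true_smi"].to_numpy(dtype=bool)
    psych = persons["true_psychosis"].to_numpy(dtype=bool)

    # day-count of each person's 5-year lookback window (calendar offset)
    window_days = (index_dates - (index_dates - pd.DateOffset(years=5))).dt.days.to_numpy()

    rows_id, rows_date, rows_setting, rows_code = [], [], [], []

    def emit(pid, date, setting, code):
        rows_id.append(pid)
        rows_date.append(date)
        rows_setting.append(setting)
        rows_code.append(code)

    exp_idx = np.flatnonzero(smi)
    n_contacts = 1 + rng.poisson(cfg.mean_extra_qualifying_contacts, exp_idx.size)
    for j, i in enumerate(exp_idx):
        idx_date = index_dates.iloc[i]
        offsets = rng.integers(1, window_days[i] + 1, n_contacts[j])
        for off in offsets:
            setting = (
                "inpatient" if rng.random() < cfg.inpatient_fraction
                else "community_face_to_face"
            )
            if rng.random() < cfg.missing_diagnosis_fraction:
                code = None
            elif psych[i]:
                pool = PSYCHOSIS_CODES + OTHER_MH_CODES
                code = pool[rng.integers(0, len(pool))]
            else:
                code = OTHER_MH_CODES[rng.integers(0, len(OTHER_MH_CODES))]
            emit(ids[i], idx_date - pd.Timedelta(days=int(off)), setting, code)
        if psych[i]:
            # guaranteed psychosis-coded contact; any date qualifies for the
            # diagnosis rule, so a fraction lands after the index assessment
            code = PSYCHOSIS_CODES[rng.integers(0, len(PSYCHOSIS_CODES))]
            if rng.random() < cfg.post_index_psychosis_code_rate:
                date = idx_date + pd.Timedelta(days=int(rng.integers(1, 365)))
            else:
                date = idx_date - pd.Timedelta(
                    days=int(rng.integers(1, window_days[i] + 1))
                )
            emit(ids[i], date, "community_face_to_face", code)

    decoy_idx = np.flatnonzero(~smi & (rng.random(len(persons)) < cfg.decoy_contact_rate))
    for i in decoy_idx:
        idx_date = index_dates.iloc[i]
        if rng.random() < 0.5:  # stale contact: strictly before the window
            off = int(rng.integers(window_days[i] + 1, window_days[i] + 1096))
            emit(ids[i], idx_date - pd.Timedelta(days=off), "community_face_to_face",
                 OTHER_MH_CODES[rng.integers(0, len(OTHER_MH_CODES))])
        else:  # non-face-to-face activity inside the window
            off = int(rng.integers(1, window_days[i] + 1))
            emit(ids[i], idx_date - pd.Timedelta(days=off), "other", None)

    contacts = pd.DataFrame(
        {
            "person_id": rows_id,
            "contact_date": [d.strftime("%Y-%m-%d") for d in rows_date],
            "setting": rows_setting,
            "diagnosis_code": rows_code,
        }
    )
    return contacts.sort_values(
        ["person_id", "contact_date", "setting"], kind="stable"
    ).reset_index(drop=True)


def generate_cohort(
    config: SimulationConfig, equation: RiskEquationSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate linked (person, contact) tables; pure function of (config, seed).

    The person table includes populated outcome fields and the generator's
    ground-truth exposure columns (``true_smi``, ``true_psychosis``), which
    downstream analysis stages never read — exposure is re-ascertained from
    the contact table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    persons = _generate_persons(config, rng)
    persons = simulate_outcomes(persons, equation, config, rng=rng)
    contacts = _generate_contacts(persons, config, rng)
    return persons, contacts


def write_tables(
    persons: pd.DataFrame, contacts: pd.DataFrame, outdir: str | Path
) -> tuple[Path, Path]:
    """Write persons.csv and contacts.csv (UTF-8, header row, ISO dates)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = outdir / "persons.csv"
    c = outdir / "contacts.csv"
    persons.to_csv(p, index=False)
    contacts.to_csv(c, index=False)
    return p, c
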