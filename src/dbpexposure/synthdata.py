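"""Synthetic monitoring data, cohorts and outcomes for pipeline testing.

No deposited data exist for this kind of study, so the package ships a
generator that emulates the statistical structure the analysis assumes:

* eight water supply zones sampled roughly nine times a year for THMs
  (2006-01 to 2011-03) and quarterly for HAAs (mid-2007 to late-2010),
  with zone offsets, seasonal structure, water-chemistry covariates and
  below-LOD censoring;
* a multi-ethnic pregnancy cohort whose water-use and covariate
  distributions differ by ethnicity the way a northern English city's do
  (Pakistani-origin women drink less tap water overall, bathe less, swim
  rarely, smoke rarely, and are less often employed than white British
  women);
* birth weights generated from a linear model with ethnicity-specific
  baselines, covariate effects, an exposure-tertile effect and normal
  residual noise, so the regression module's estimates can be checked
  against known truth.

Distributional forms (log-normal concentrations, gamma volumes, Bernoulli
participation) are modelling choices of this package; every parameter is
exposed on :class:`ScenarioConfig`.  All randomness flows through
``numpy.random.default_rng`` seeded from the config, so runs are
bit-reproducible.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .concentration import MONITORING_COLUMNS

ETHNICITIES = ("white_British", "Pakistani_origin", "other")


def _default_ethnicity_mix():
    return {"white_British": 0.40, "Pakistani_origin": 0.45, "other": 0.15}


def _default_water_use():
    # targets: cold tap 1.11 vs 1.18 L/day, hot 0.72 vs 0.33, bottled
    # 0.40 vs 0.15; shower 86 vs 94, bath 151 vs 96 min/wk among doers;
    # swimming participation 14% vs 2%
    return {
        "white_British": dict(
            cold_tap_mean=1.11, cold_tap_doer=0.91, hot_mean=0.72,
            hot_doer=0.81, bottled_mean=0.40, bottled_doer=0.47,
            shower_mean=86.0, shower_doer=0.71, bath_mean=151.0,
            bath_doer=0.76, swim_mean=72.0, swim_doer=0.14,
        ),
        "Pakistani_origin": dict(
            cold_tap_mean=1.18, cold_tap_doer=0.98, hot_mean=0.33,
            hot_doer=0.81, bottled_mean=0.15, bottled_doer=0.21,
            shower_mean=94.0, shower_doer=0.69, bath_mean=96.0,
            bath_doer=0.66, swim_mean=75.0, swim_doer=0.02,
        ),
        "other": dict(
            cold_tap_mean=1.14, cold_tap_doer=0.94, hot_mean=0.50,
            hot_doer=0.81, bottled_mean=0.29, bottled_doer=0.35,
            shower_mean=93.0, shower_doer=0.72, bath_mean=123.0,
            bath_doer=0.68, swim_mean=73.0, swim_doer=0.07,
        ),
    }


def _default_covariates():
    return {
        "white_British": dict(
            employed=0.64, smoking_current=0.28, smoking_ever=0.20,
            caffeine=0.31, age_mean=27.9, age_sd=5.8,
            fasting_mean=4.4, fasting_sd=0.4, postload_mean=5.4,
            postload_sd=1.3, bmi_mean=28.9, bmi_sd=5.8,
            parity_probs=(0.48, 0.29, 0.23),
            education_probs=(0.20, 0.34, 0.17, 0.19, 0.10),
            imd_probs=(0.50, 0.22, 0.18, 0.06, 0.04),
        ),
        "Pakistani_origin": dict(
            employed=0.23, smoking_current=0.03, smoking_ever=0.05,
            caffeine=0.06, age_mean=27.4, age_sd=5.3,
            fasting_mean=4.6, fasting_sd=0.6, postload_mean=5.9,
            postload_sd=1.6, bmi_mean=27.9, bmi_sd=5.2,
            parity_probs=(0.33, 0.25, 0.42),
            education_probs=(0.26, 0.31, 0.13, 0.26, 0.04),
            imd_probs=(0.79, 0.14, 0.06, 0.008, 0.002),
        ),
        "other": dict(
            employed=0.40, smoking_current=0.12, smoking_ever=0.12,
            caffeine=0.15, age_mean=27.6, age_sd=5.5,
            fasting_mean=4.5, fasting_sd=0.5, postload_mean=5.7,
            postload_sd=1.5, bmi_mean=28.3, bmi_sd=5.5,
            parity_probs=(0.40, 0.27, 0.33),
            education_probs=(0.21, 0.31, 0.15, 0.25, 0.08),
            imd_probs=(0.66, 0.18, 0.11, 0.03, 0.02),
        ),
    }


def _default_covariate_effects():
    """Birth-weight shifts (g) for covariates; invented, realistic scale."""
    return {
        "sex_male": 130.0,
        "smoking": {"never": 0.0, "ever": -40.0, "current": -160.0},
        "caffeine_ge200": -30.0,
        "parity": (0.0, 55.0, 80.0),
        "fasting_glucose_per_mmol": 25.0,    # centred at 4.5
        "postload_glucose_per_mmol": 10.0,   # centred at 5.7
        "age_per_year": 1.5,                 # centred at 27
        "bmi_quartile": (0.0, 40.0, 65.0, 85.0),
        "imd_quintile": (0.0, 10.0, 20.0, 30.0, 35.0),
        "education": (0.0, 10.0, 15.0, 25.0, 10.0),
        "ga_linear": 135.0,                  # per week, centred at 40
        "ga_quadratic": -6.0,
    }


@dataclass
class ScenarioConfig:
    """All knobs of the synthetic study, with defaults set to the study
    conditions the pipeline is meant to operate under."""

    seed: int = 0
    # -- monitoring -------------------------------------------------------
    n_zones: int = 8
    thm_samples_per_zone_year: int = 9
    thm_start: str = "2006-01"
    thm_end: str = "2011-03"
    haa_start: str = "2007Q2"
    haa_end: str = "2010Q4"
    # species means (ug/L); TTHM is their sum at the sample level
    thm_species_mean: dict = field(default_factory=lambda: {
        "chloroform": 37.8, "BDCM": 6.6, "DBCM": 0.9, "bromoform": 0.3})
    haa_mean: dict = field(default_factory=lambda: {
        "DCAA": 8.9, "TCAA": 12.5, "BDCAA": 1.3})
    zone_offset_sd: float = 0.08      # log-scale between-zone spread
    seasonal_amplitude: float = 0.15  # log-scale sinusoid amplitude
    thm_resid_sd: float = 0.15        # log-scale residual
    haa_resid_sd: float = 0.12        # transformed-scale residual
    thm_lod: dict = field(default_factory=lambda: {
        "chloroform": 0.5, "BDCM": 0.2, "DBCM": 0.2, "bromoform": 0.5})
    haa_lod: dict = field(default_factory=lambda: {
        "DCAA": 0.5, "TCAA": 0.5, "BDCAA": 0.2})
    # transformed-scale coefficients on standardised covariates
    haa_cov_coefs: dict = field(default_factory=lambda: {
        "DCAA": {"conductivity": 0.10, "temperature": 0.08},
        "TCAA": {"conductivity": 0.10, "temperature": 0.08, "toc": 0.08},
        "BDCAA": {"conductivity": 0.08, "total_chlorine": 0.08}})
    covariate_missing_rate: float = 0.10
    # -- cohort -----------------------------------------------------------
    n_records: int = 13525
    ethnicity_mix: dict = field(default_factory=_default_ethnicity_mix)
    water_use: dict = field(default_factory=_default_water_use)
    covariates: dict = field(default_factory=_default_covariates)
    non_singleton_rate: float = 326 / 13525
    repeat_mother_rate: float = 0.107        # mothers with a 2nd pregnancy
    missing_water_use_rate: float = 2100 / 11928
    thm_incomplete_rate: float = 98 / 9828
    missing_birth_weight_rate: float = 1 / 9730
    preterm_rate: float = 531 / 9729
    workplace_assignable_rate: float = 2353 / 4024
    filter_home_rate: float = 0.15
    conception_start: str = "2006-06-01"
    conception_end: str = "2010-06-30"
    # -- outcomes ---------------------------------------------------------
    baseline_bw: dict = field(default_factory=lambda: {
        "white_British": 3424.0, "Pakistani_origin": 3186.0, "other": 3280.0})
    residual_bw_sd: float = 450.0
    covariate_effects: dict = field(default_factory=_default_covariate_effects)

    def __post_init__(self):
        total = sum(self.ethnicity_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"ethnicity mix sums to {total}, not 1")
        if self.residual_bw_sd <= 0:
            raise ValueError("residual birth-weight SD must be positive")
        if self.thm_samples_per_zone_year <= 0:
            raise ValueError("THM sampling rate must be positive")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# monitoring
# ---------------------------------------------------------------------------

def _seasonal(month, amplitude):
    # concentrations peak in late summer/autumn in chlorinated systems
    return amplitude * np.sin(2 * np.pi * (np.asarray(month) - 4) / 12.0)


def simulate_monitoring(config: ScenarioConfig) -> pd.DataFrame:
    """Simulate the THM + HAA monitoring record for all zones.

    THM species are log-normal around their target means with shared zone
    offsets and a seasonal sinusoid; TTHM rows are the sample-level sum of
    the four species.  HAA samples are quarterly, carry water-chemistry
    covariates (with missingness) and depend on them on the model's
    transformed scale.  Values under the configured LOD are flagged
    ``below_lod`` with value set to the LOD pending half-LOD substitution.
    """
    rng = np.random.default_rng(config.seed)
    zones = [f"WSZ{z + 1}" for z in range(config.n_zones)]
    zone_off = dict(zip(zones, rng.normal(0, config.zone_offset_sd,
                                          config.n_zones)))
    rows = []

    months = pd.period_range(config.thm_start, config.thm_end, freq="M")
    years = sorted({m.year for m in months})
    for zone in zones:
        for year in years:
            year_months = [m for m in months if m.year == year]
            n_year = max(1, round(config.thm_samples_per_zone_year
                                  * len(year_months) / 12))
            chosen = rng.choice(len(year_months), size=n_year, replace=True)
            for k in chosen:
                m = year_months[k]
                day = int(rng.integers(1, m.days_in_month + 1))
                date = dt.date(m.year, m.month, day)
                season = _seasonal(m.month, config.seasonal_amplitude)
                shock = rng.normal(0, config.thm_resid_sd)
                species_vals = {}
                for sp, mean in config.thm_species_mean.items():
                    logc = (np.log(mean) + zone_off[zone] + season + shock
                            + rng.normal(0, 0.05))
                    species_vals[sp] = float(np.exp(logc))
                for sp, val in species_vals.items():
                    lod = config.thm_lod[sp]
                    below = val < lod
                    rows.append(dict(
                        wsz_id=zone, date=date, analyte=sp,
                        value=lod if below else val, below_lod=below,
                        lod=lod, conductivity=np.nan, temperature=np.nan,
                        toc=np.nan, total_chlorine=np.nan,
                    ))
                rows.append(dict(
                    wsz_id=zone, date=date, analyte="TTHM",
                    value=sum(species_vals.values()), below_lod=False,
                    lod=np.nan, conductivity=np.nan, temperature=np.nan,
                    toc=np.nan, total_chlorine=np.nan,
                ))

    quarters = pd.period_range(config.haa_start, config.haa_end, freq="Q")
    trans = {"DCAA": np.sqrt, "TCAA": np.sqrt, "BDCAA": np.log}
    back = {"DCAA": np.square, "TCAA": np.square, "BDCAA": np.exp}
    cov_scale = {"conductivity": (500.0, 40.0), "temperature": (11.0, 4.0),
                 "toc": (1.5, 0.4), "total_chlorine": (1.0, 0.25)}
    for zone in zones:
        for q in quarters:
            mid_month = (q.quarter - 1) * 3 + 2
            day = int(rng.integers(1, 28))
            date = dt.date(q.year, mid_month, day)
            covs = {}
            for name, (mu, sd) in cov_scale.items():
                base = mu + sd * _seasonal(mid_month, 1.0) * \
                    (1.0 if name == "temperature" else 0.2)
                covs[name] = float(rng.normal(base, sd * 0.5))
            season = _seasonal(mid_month, config.seasonal_amplitude)
            for analyte, mean in config.haa_mean.items():
                t0 = trans[analyte](mean)
                eta = t0 * (1.0 + 0.5 * zone_off[zone] + 0.3 * season)
                for name, coef in config.haa_cov_coefs[analyte].items():
                    mu, sd = cov_scale[name]
                    eta += coef * (covs[name] - mu) / sd
                eta += rng.normal(0, config.haa_resid_sd)
                val = float(back[analyte](max(eta, 1e-3)))
                lod = config.haa_lod[analyte]
                below = val < lod
                cov_out = {
                    name: (np.nan if rng.random() < config.covariate_missing_rate
                           else covs[name])
                    for name in cov_scale
                }
                rows.append(dict(
                    wsz_id=zone, date=date, analyte=analyte,
                    value=lod if below else val, below_lod=below, lod=lod,
                    **cov_out,
                ))
    out = pd.DataFrame(rows)[list(MONITORING_COLUMNS)]
    out["date"] = pd.to_datetime(out["date"])
    return out


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _sample_gamma(rng, mean, cv=0.7, size=None):
    """Gamma draw with the given mean and coefficient of variation."""
    shape = 1.0 / cv ** 2
    return rng.gamma(shape, mean / shape, size=size)


def _draw_water_use(rng, params) -> dict:
    def doer_amount(mean, doer_p, cv=0.7):
        return float(_sample_gamma(rng, mean, cv)) if rng.random() < doer_p else 0.0

    # drink-volume targets are population means; activity-minute targets
    # are means among those undertaking the activity
    cold = doer_amount(params["cold_tap_mean"] / params["cold_tap_doer"],
                       params["cold_tap_doer"])
    hot = doer_amount(params["hot_mean"] / params["hot_doer"],
                      params["hot_doer"])
    squash_share = rng.uniform(0.0, 0.4)
    tea_share = rng.uniform(0.4, 0.8)
    return dict(
        tap_Lday=cold * (1 - squash_share),
        squash_Lday=cold * squash_share,
        tea_Lday=hot * tea_share,
        coffee_Lday=hot * (1 - tea_share),
        bottled_Lday=doer_amount(params["bottled_mean"] / params["bottled_doer"],
                                 params["bottled_doer"]),
        shower_minwk=doer_amount(params["shower_mean"], params["shower_doer"], 0.6),
        bath_minwk=doer_amount(params["bath_mean"], params["bath_doer"], 0.8),
        swim_minwk=doer_amount(params["swim_mean"], params["swim_doer"], 0.5),
    )


def _draw_covariates(rng, params) -> dict:
    u = rng.random()
    smoking = ("current" if u < params["smoking_current"]
               else "ever" if u < params["smoking_current"] + params["smoking_ever"]
               else "never")
    return dict(
        employed=bool(rng.random() < params["employed"]),
        smoking=smoking,
        caffeine_ge200=int(rng.random() < params["caffeine"]),
        age=float(np.clip(rng.normal(params["age_mean"], params["age_sd"]),
                          16, 45)),
        fasting_glucose=float(rng.normal(params["fasting_mean"],
                                         params["fasting_sd"])),
        postload_glucose=float(rng.normal(params["postload_mean"],
                                          params["postload_sd"])),
        bmi=float(np.clip(rng.normal(params["bmi_mean"], params["bmi_sd"]),
                          15, 55)),
        parity_cat=int(rng.choice(3, p=params["parity_probs"])),
        education=["none", "school", "further", "higher", "other"][
            int(rng.choice(5, p=params["education_probs"]))],
        imd_quintile=int(rng.choice(5, p=params["imd_probs"])) + 1,
    )


def simulate_cohort(config: ScenarioConfig) -> pd.DataFrame:
    """Simulate the raw pregnancy records entering the eligibility cascade.

    Records carry the flags the cascade consumes (singleton, water use
    present, THM computable, birth weight present via NaN, term status via
    gestational age), ethnicity-conditional water use and covariates,
    conception/delivery dates and zone assignments.  Birth weight is
    generated separately by :func:`simulate_outcomes` once exposure is
    known; here it is initialised to NaN only for the configured missing
    fraction bookkeeping, with a placeholder weight for the rest.
    """
    rng = np.random.default_rng(config.seed + 1)
    zones = [f"WSZ{z + 1}" for z in range(config.n_zones)]
    eth_names = list(config.ethnicity_mix)
    eth_probs = np.array([config.ethnicity_mix[e] for e in eth_names])

    # mothers; a configured fraction have a second pregnancy on record
    n_mothers = int(round(config.n_records /
                          (1 + config.repeat_mother_rate)))
    mother_eth = rng.choice(len(eth_names), size=n_mothers, p=eth_probs)
    repeat = rng.random(n_mothers) < config.repeat_mother_rate

    start = pd.Timestamp(config.conception_start)
    end = pd.Timestamp(config.conception_end)
    span_days = (end - start).days

    rows = []
    preg_id = 0
    for mother in range(n_mothers):
        n_preg = 2 if repeat[mother] else 1
        eth = eth_names[mother_eth[mother]]
        wu_params = config.water_use[eth]
        cov_params = config.covariates[eth]
        res_wsz = zones[int(rng.integers(len(zones)))]
        for _ in range(n_preg):
            preg_id += 1
            conception = (start +
                          pd.Timedelta(days=int(rng.integers(span_days))))
            preterm = rng.random() < config.preterm_rate
            if preterm:
                gest_days = int(rng.normal(245, 14))
            else:
                gest_days = int(np.clip(rng.normal(280, 8), 259, 300))
            covs = _draw_covariates(rng, cov_params)
            has_wu = rng.random() >= config.missing_water_use_rate
            wu = _draw_water_use(rng, wu_params) if has_wu else {
                k: np.nan for k in ("tap_Lday", "squash_Lday", "tea_Lday",
                                    "coffee_Lday", "bottled_Lday",
                                    "shower_minwk", "bath_minwk", "swim_minwk")}
            employed = covs.pop("employed")
            work_wsz = np.nan
            if employed and rng.random() < config.workplace_assignable_rate:
                work_wsz = zones[int(rng.integers(len(zones)))]
            rows.append(dict(
                mother_id=f"M{mother:06d}", pregnancy_id=f"P{preg_id:06d}",
                singleton=bool(rng.random() >= config.non_singleton_rate),
                ethnicity=eth,
                conception_date=conception.date(),
                delivery_date=(conception
                               + pd.Timedelta(days=gest_days)).date(),
                gestational_age_wk=gest_days / 7.0,
                sex="M" if rng.random() < 0.51 else "F",
                employed=employed,
                res_wsz=res_wsz, work_wsz=work_wsz,
                has_water_use=has_wu,
                thm_complete=bool(rng.random() >= config.thm_incomplete_rate),
                filter_home=bool(rng.random() < config.filter_home_rate),
                birth_weight_g=(np.nan if rng.random()
                                < config.missing_birth_weight_rate else 0.0),
                **covs, **wu,
            ))
    df = pd.DataFrame(rows)
    # BMI quartiles are computed within the generated population
    df["bmi_quartile"] = pd.qcut(df["bmi"], 4, labels=[1, 2, 3, 4]).astype(int)
    return df


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def _linear_predictor(df: pd.DataFrame, config: ScenarioConfig) -> np.ndarray:
    eff = config.covariate_effects
    lp = df["ethnicity"].map(config.baseline_bw).to_numpy(dtype=float)
    lp += np.where(df["sex"].to_numpy() == "M", eff["sex_male"], 0.0)
    lp += df["smoking"].map(eff["smoking"]).to_numpy(dtype=float)
    lp += eff["caffeine_ge200"] * df["caffeine_ge200"].to_numpy(dtype=float)
    lp += np.asarray(eff["parity"])[df["parity_cat"].to_numpy(dtype=int)]
    lp += eff["fasting_glucose_per_mmol"] * (df["fasting_glucose"] - 4.5)
    lp += eff["postload_glucose_per_mmol"] * (df["postload_glucose"] - 5.7)
    lp += eff["age_per_year"] * (df["age"] - 27.0)
    lp += np.asarray(eff["bmi_quartile"])[df["bmi_quartile"].to_numpy(dtype=int) - 1]
    lp += np.asarray(eff["imd_quintile"])[df["imd_quintile"].to_numpy(dtype=int) - 1]
    edu_idx = df["education"].map(
        {"none": 0, "school": 1, "further": 2, "higher": 3, "other": 4})
    lp += np.asarray(eff["education"])[edu_idx.to_numpy(dtype=int)]
    ga = df["gestational_age_wk"].to_numpy(dtype=float) - 40.0
    lp += eff["ga_linear"] * ga + eff["ga_quadratic"] * ga ** 2
    return np.asarray(lp, dtype=float)


def simulate_outcomes(cohort: pd.DataFrame, exposure_codes: pd.DataFrame,
                      true_effects: dict, config: ScenarioConfig,
                      noise: bool = True) -> pd.Series:
    """Generate birth weights under known tertile effects.

    ``exposure_codes`` holds one integer-coded column per exposure term,
    aligned with ``cohort``; ``true_effects`` maps each column to either a
    per-level effect vector or an {ethnicity: vector} mapping.  The
    outcome is the ethnicity baseline plus covariate effects plus the
    exposure effects plus (optionally) N(0, residual_bw_sd^2) noise.
    """
    if len(exposure_codes) != len(cohort):
        raise ValueError("exposure codes and cohort are misaligned")
    rng = np.random.default_rng(config.seed + 2)
    lp = _linear_predictor(cohort, config)
    eth = cohort["ethnicity"].to_numpy()
    for col, effects in true_effects.items():
        codes = exposure_codes[col].to_numpy(dtype=int)
        if isinstance(effects, dict):
            shift = np.array([
                np.asarray(effects[e])[c] for e, c in zip(eth, codes)
            ])
        else:
            shift = np.asarray(effects, dtype=float)[codes]
        lp = lp + shift
    if noise:
        lp = lp + rng.normal(0, config.residual_bw_sd, size=len(lp))
    return pd.Series(lp, index=cohort.index, name="birth_weight_g")


# ---------------------------------------------------------------------------
# stratum simulator for effect recovery
# ---------------------------------------------------------------------------

def simulate_stratum(n: int, exposures: dict, seed: int,
                     ethnicity: str = "Pakistani_origin",
                     config: ScenarioConfig | None = None) -> pd.DataFrame:
    """Simulate a single-ethnicity analysis dataset with known effects.

    ``exposures`` maps a metric name to a dict with keys ``mean`` and
    ``sd`` (log-normal scale of the continuous metric) and ``effects``
    (per-tertile birth-weight shifts in g).  The continuous metric depends
    mildly on age and smoking so that adjustment does real work; tertiles
    are cut within the simulated sample, as in the analysis population.
    Returns a frame ready for the regression module, with one
    ``<name>_tert`` column per exposure and known truth in ``attrs``.
    """
    config = config or ScenarioConfig()
    rng = np.random.default_rng(seed)
    cov_params = config.covariates[ethnicity]
    rows = [_draw_covariates(rng, cov_params) for _ in range(n)]
    df = pd.DataFrame(rows)
    df["ethnicity"] = ethnicity
    df["sex"] = np.where(rng.random(n) < 0.51, "M", "F")
    df["gestational_age_wk"] = np.clip(rng.normal(39.8, 1.1, n), 37, 42.9)
    df["bmi_quartile"] = pd.qcut(df["bmi"], 4, labels=[1, 2, 3, 4]).astype(int)

    tert_cols = {}
    for name, spec in exposures.items():
        mean, sd = spec["mean"], spec["sd"]
        # log-normal with the requested raw-scale mean and sd
        s2 = np.log(1 + (sd / mean) ** 2)
        mu = np.log(mean) - s2 / 2
        logx = rng.normal(mu, np.sqrt(s2), n)
        logx = logx + 0.005 * (df["age"] - 27.0) \
            + 0.15 * (df["smoking"] == "current").astype(float)
        x = np.exp(logx)
        df[name] = x
        cuts = np.quantile(x, [1 / 3, 2 / 3])
        df[f"{name}_tert"] = np.searchsorted(cuts, x, side="right")
        tert_cols[f"{name}_tert"] = np.asarray(spec["effects"], dtype=float)

    out_cfg = replace(config, seed=seed)
    df["birth_weight_g"] = simulate_outcomes(
        df, df[list(tert_cols)], tert_cols, out_cfg)
    df.attrs["true_effects"] = {k: v.tolist() for k, v in tert_cols.items()}
    return df


# ---------------------------------------------------------------------------
# exact-cascade fixture
# ---------------------------------------------------------------------------

def exact_cascade_fixture() -> pd.DataFrame:
    """Deterministic record set reproducing the reference exclusion cascade exactly.

    13,525 input records: 326 non-singleton; 1,271 mothers with two fully
    eligible pregnancies each (so the one-per-mother stage removes exactly
    1,271 whichever is kept); then, among single-pregnancy mothers, 2,100
    missing water use, 98 with THM exposure not computable, 1 missing
    birth weight and 531 preterm.  9,198 records survive.
    """
    counts = dict(non_singleton=326, duplicate_mothers=1271,
                  missing_water_use=2100, thm_incomplete=98,
                  missing_birth_weight=1, preterm=531, clean_singles=7927)
    rows = []
    preg = 0
    mother = 0

    def base_row():
        return dict(singleton=True, has_water_use=True, thm_complete=True,
                    birth_weight_g=3300.0, gestational_age_wk=40.0)

    for _ in range(counts["non_singleton"]):
        mother += 1
        preg += 1
        r = base_row()
        r.update(singleton=False)
        rows.append(dict(mother_id=f"M{mother:06d}",
                         pregnancy_id=f"P{preg:06d}", **r))
    for _ in range(counts["duplicate_mothers"]):
        mother += 1
        for _ in range(2):
            preg += 1
            rows.append(dict(mother_id=f"M{mother:06d}",
                             pregnancy_id=f"P{preg:06d}", **base_row()))
    defects = (
        [("has_water_use", False)] * counts["missing_water_use"]
        + [("thm_complete", False)] * counts["thm_incomplete"]
        + [("birth_weight_g", np.nan)] * counts["missing_birth_weight"]
        + [("gestational_age_wk", 35.0)] * counts["preterm"]
        + [(None, None)] * counts["clean_singles"]
    )
    for key, value in defects:
        mother += 1
        preg += 1
        r = base_row()
        if key is not None:
            r[key] = value
        rows.append(dict(mother_id=f"M{mother:06d}",
                         pregnancy_id=f"P{preg:06d}", **r))
    return pd.DataFrame(rows)
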