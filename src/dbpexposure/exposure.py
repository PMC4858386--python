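"""Per-pregnancy exposure metrics from concentration surfaces and water use.

The exposure model combines three ingredients:

* a concentration surface (ug/L per WSZ per month or quarter),
* the calendar overlap of a pregnancy window with those time cells, and
* the woman's questionnaire water use (drink volumes, filter use, minutes
  of showering/bathing/swimming).

Time-weighted average (TWA) concentrations weight each cell by the
proportion of the window's days falling inside it.  Women with an assigned
workplace zone get a 40/112 workplace + 72/112 residence split, the waking
week being 112 hours of which 40 are spent at work.  Ingestion multiplies
TWA concentration by drink volumes with boiling and filtering adjustments;
integrated uptake converts ingestion, showering, bathing and swimming into
a blood dose via pathway-specific uptake factors, swimming using pool
rather than tap concentrations.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .analytes import HAA_ANALYTES, THM_EXPOSURE_ANALYTES, is_thm
from .factors import UptakeFactorTable, adjustment_for

WORK_WEIGHT = 40.0 / 112.0
RESIDENCE_WEIGHT = 72.0 / 112.0

#: first/last gestational day (1-based, inclusive) of each trimester;
#: trimester 3 and the whole window end the day before delivery
TRIMESTER_1 = (1, 93)
TRIMESTER_2 = (94, 186)
TRIMESTER_3_START = 187


class CoverageError(KeyError):
    """A pregnancy window extends outside the concentration surface."""


@dataclass(frozen=True)
class ExposureWindow:
    label: str          # whole | T1 | T2 | T3
    start_day: int      # gestational day, 1-based inclusive
    end_day: int

    def __post_init__(self):
        if self.end_day < self.start_day:
            raise ValueError(
                f"empty exposure window {self.label}: "
                f"days {self.start_day}-{self.end_day}"
            )

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1


def pregnancy_windows(conception: dt.date, delivery: dt.date,
                      labels: Sequence[str] = ("whole", "T1", "T2", "T3"),
                      ) -> dict[str, ExposureWindow]:
    """Trimester and whole-pregnancy windows in gestational days.

    Day 1 is the first day of pregnancy (the conception date as recorded);
    all windows end no later than the day preceding delivery.
    """
    last_day = (delivery - conception).days  # day before delivery, 1-based
    if last_day < 1:
        raise ValueError("delivery must fall after conception")
    out: dict[str, ExposureWindow] = {}
    for label in labels:
        if label == "whole":
            out[label] = ExposureWindow("whole", 1, last_day)
        elif label == "T1":
            out[label] = ExposureWindow("T1", TRIMESTER_1[0],
                                        min(TRIMESTER_1[1], last_day))
        elif label == "T2":
            if last_day < TRIMESTER_2[0]:
                raise ValueError("pregnancy too short for trimester 2")
            out[label] = ExposureWindow("T2", TRIMESTER_2[0],
                                        min(TRIMESTER_2[1], last_day))
        elif label == "T3":
            if last_day < TRIMESTER_3_START:
                raise ValueError("pregnancy too short for trimester 3")
            out[label] = ExposureWindow("T3", TRIMESTER_3_START, last_day)
        else:
            raise ValueError(f"unknown window label {label!r}")
    return out


def compute_time_weights(window: ExposureWindow, conception: dt.date,
                         delivery: dt.date, grid: str) -> dict[pd.Period, float]:
    """Proportion of the window's days falling in each month or quarter.

    Weights are nonnegative and sum to one; the weight of a cell is the
    count of window days inside it divided by the window length.
    """
    if grid not in ("month", "quarter", "M", "Q"):
        raise ValueError(f"unknown grid {grid!r}")
    freq = "M" if grid in ("month", "M") else "Q"
    last_day = (delivery - conception).days
    if window.end_day > last_day:
        raise ValueError("window extends beyond the day preceding delivery")
    start_date = conception + dt.timedelta(days=window.start_day - 1)
    end_date = conception + dt.timedelta(days=window.end_day - 1)
    n_days = window.n_days
    weights: dict[pd.Period, float] = {}
    cell = pd.Period(start_date, freq=freq)
    last_cell = pd.Period(end_date, freq=freq)
    while cell <= last_cell:
        cell_start = cell.start_time.date()
        cell_end = cell.end_time.date()
        overlap = (min(end_date, cell_end) - max(start_date, cell_start)).days + 1
        weights[cell] = overlap / n_days
        cell += 1
    return weights


def twa_concentration(surface, weights: Mapping[pd.Period, float],
                      residence_wsz, work_wsz=None, *,
                      on_missing: str = "nan") -> float:
    """Time-weighted average concentration over a pregnancy window.

    With an assigned workplace zone the cell concentration is the 72/112
    residence + 40/112 workplace mixture; otherwise residence only.  If any
    needed cell is outside the surface the metric is missing (NaN), never
    silently zero.
    """
    total = 0.0
    for cell, w in weights.items():
        zones = [residence_wsz] if work_wsz is None else [residence_wsz, work_wsz]
        if not all(surface.covers(z, cell) for z in zones):
            if on_missing == "raise":
                raise CoverageError(
                    f"cell {cell} not covered for zones {zones}"
                )
            return float("nan")
        c_res = surface.value(residence_wsz, cell)
        if work_wsz is None:
            c = c_res
        else:
            c = RESIDENCE_WEIGHT * c_res + WORK_WEIGHT * surface.value(work_wsz, cell)
        total += w * c
    return total


# ---------------------------------------------------------------------------
# water use
# ---------------------------------------------------------------------------

@dataclass
class WaterUseProfile:
    """Questionnaire water use: drink volumes (L/day) and activity minutes
    per week.  Cold tap = tap + squash; hot tap = tea + coffee."""

    tap_Lday: float = 0.0
    bottled_Lday: float = 0.0
    tea_Lday: float = 0.0
    coffee_Lday: float = 0.0
    squash_Lday: float = 0.0
    filter_home: bool = False
    filter_work: bool = False
    shower_minwk: float = 0.0
    bath_minwk: float = 0.0
    swim_minwk: float = 0.0

    def __post_init__(self):
        for name in ("tap_Lday", "bottled_Lday", "tea_Lday", "coffee_Lday",
                     "squash_Lday", "shower_minwk", "bath_minwk", "swim_minwk"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def cold_tap_Lday(self) -> float:
        return self.tap_Lday + self.squash_Lday

    @property
    def hot_tap_Lday(self) -> float:
        return self.tea_Lday + self.coffee_Lday

    @property
    def total_tap_Lday(self) -> float:
        return self.cold_tap_Lday + self.hot_tap_Lday


def ingestion(profile: WaterUseProfile, twa: Mapping[str, float],
              factors: UptakeFactorTable) -> dict[str, float]:
    """Ingested dose (ug/day) per analyte plus HAA3 and DBP7 aggregates.

    Each drink class carries its own modifier: hot beverages get the
    boiling adjustment, the tap-water component of cold tap gets the
    filtering adjustment when a home filter is used, squash is always
    unfiltered, and bottled water contributes nothing.
    """
    out: dict[str, float] = {}
    for analyte, conc in twa.items():
        if np.isnan(conc):
            out[analyte] = float("nan")
            continue
        boil = adjustment_for(factors.boil_adjust, analyte)
        filt = adjustment_for(factors.filter_adjust, analyte)
        cold_filtered = profile.tap_Lday if profile.filter_home else 0.0
        cold_unfiltered = (profile.tap_Lday - cold_filtered) + profile.squash_Lday
        dose = conc * (
            cold_unfiltered
            + cold_filtered * (1.0 + filt)
            + profile.hot_tap_Lday * (1.0 + boil)
        )
        if dose < 0:
            raise ValueError(
                f"negative adjusted ingestion for {analyte}: "
                "check adjustment factors"
            )
        out[analyte] = dose
    if all(a in out for a in HAA_ANALYTES):
        out["HAA3"] = sum(out[a] for a in HAA_ANALYTES)
        if "TTHM" in out:
            out["DBP7"] = out["TTHM"] + out["HAA3"]
    return out


def integrated_uptake(profile: WaterUseProfile, twa: Mapping[str, float],
                      factors: UptakeFactorTable,
                      analytes: Iterable[str] = THM_EXPOSURE_ANALYTES,
                      ) -> dict[str, dict[str, float]]:
    """Blood dose (ug/day) per THM analyte, resolved by pathway.

    Pathways: ingestion (adjusted ingested dose x ingestion factor),
    shower and bath (tap TWA x minutes/day x factor), swim (pool
    concentration x minutes/day x factor).  ``total`` sums the pathways
    and ``sbs`` is the shower+bath+swim subtotal used in the joint
    THM-HAA models.
    """
    ing = ingestion(profile, {a: twa[a] for a in analytes if a in twa}, factors)
    out: dict[str, dict[str, float]] = {}
    for analyte in analytes:
        if not is_thm(analyte):
            raise ValueError(f"integrated uptake is THM-only; got {analyte!r}")
        if analyte not in twa:
            continue
        conc = twa[analyte]
        pathways = {
            "ingestion": ing[analyte] * factors.factor("ingestion", analyte),
            "shower": conc * (profile.shower_minwk / 7.0)
                      * factors.factor("shower", analyte),
            "bath": conc * (profile.bath_minwk / 7.0)
                    * factors.factor("bath", analyte),
            "swim": factors.pool_conc.get(analyte, 0.0)
                    * (profile.swim_minwk / 7.0) * factors.factor("swim", analyte),
        }
        pathways["total"] = sum(pathways[p] for p in
                                ("ingestion", "shower", "bath", "swim"))
        pathways["sbs"] = pathways["shower"] + pathways["bath"] + pathways["swim"]
        out[analyte] = pathways
    return out


# ---------------------------------------------------------------------------
# categorisation
# ---------------------------------------------------------------------------

#: fixed questionnaire bin edges (value -> category code); the questionnaire
#: records consumption in 0.2 L/day steps, so cuts sit between levels
FIXED_SCHEMES = {
    "cold_tap": ([0.5, 1.1, 1.5],
                 ["0.0-0.4", "0.6-1.0", "1.2-1.4", ">=1.6"]),
    "shower": ([0.5, 60.5, 105.5], ["0", "1-60", "61-105", ">105"]),
    "bath": ([0.5, 60.5, 120.5], ["0", "1-60", "61-120", ">120"]),
}


@dataclass
class Categorization:
    codes: np.ndarray          # float; NaN where the value was missing
    labels: list[str]
    cutpoints: list[float]


def categorize(values, scheme: str = "tertile") -> Categorization:
    """Assign category codes under a tertile or fixed questionnaire scheme.

    Tertile cutpoints are computed on the supplied (analysis) population
    and reported; intervals are closed below and open above except the top
    category, which is closed (>= upper cutpoint).  Missing values get a
    missing code, never a bin.
    """
    x = np.asarray(values, dtype=float)
    codes = np.full(x.shape, np.nan)
    obs = ~np.isnan(x)
    if scheme == "tertile":
        if obs.sum() < 3:
            raise ValueError("need at least 3 observed values for tertiles")
        cuts = list(np.quantile(x[obs], [1 / 3, 2 / 3]))
        labels = [f"< {cuts[0]:.3g}", f">= {cuts[0]:.3g} to < {cuts[1]:.3g}",
                  f">= {cuts[1]:.3g}"]
    elif scheme == "swim":
        codes[obs] = (x[obs] > 0).astype(float)
        return Categorization(codes, ["no", "yes"], [0.0])
    elif scheme in FIXED_SCHEMES:
        cuts, labels = FIXED_SCHEMES[scheme]
    else:
        raise ValueError(f"unknown categorisation scheme {scheme!r}")
    codes[obs] = np.searchsorted(cuts, x[obs], side="right")
    return Categorization(codes, list(labels), list(cuts))


def correlate_metrics(metrics: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Spearman rank correlations between exposure metrics.

    Pairwise-complete: each pair uses the rows where both metrics are
    observed.  Pairs with fewer than ``min_pairs`` complete observations,
    or with a constant metric, are reported as NaN.
    """
    cols = list(metrics.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            pair = metrics[[a, b]].dropna()
            if len(pair) < min_pairs or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                rho = np.nan
            else:
                rho = stats.spearmanr(pair[a], pair[b]).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def workplace_assignment_summary(cohort: pd.DataFrame) -> dict:
    """Bookkeeping for workplace-zone assignment among employed women.

    Expects boolean ``employed`` and a nullable ``work_wsz`` column; the
    rate is the percentage of employed women with an assigned (geocodable,
    in-zone) workplace.
    """
    employed = cohort["employed"].fillna(False).astype(bool)
    n_employed = int(employed.sum())
    assigned = employed & cohort["work_wsz"].notna()
    n_assigned = int(assigned.sum())
    rate = 100.0 * n_assigned / n_employed if n_employed else float("nan")
    return {"n_employed": n_employed, "n_assigned": n_assigned,
            "assignment_rate_pct": rate}


# ---------------------------------------------------------------------------
# cohort-level exposure table
# ---------------------------------------------------------------------------

def build_exposure_table(cohort: pd.DataFrame,
                         thm_surfaces: Mapping[str, "ConcentrationSurface"],
                         haa_surfaces: Mapping[str, "ConcentrationSurface"],
                         factors: UptakeFactorTable,
                         windows: Sequence[str] = ("whole", "T1", "T2", "T3"),
                         ) -> pd.DataFrame:
    """One row per pregnancy x window with every exposure metric.

    THM metrics use monthly surfaces and HAA metrics quarterly surfaces;
    a window outside a surface's coverage yields NaN metrics for the
    affected analytes (flagged via ``haa_missing`` / ``thm_missing``).
    """
    records = []
    for row in cohort.itertuples():
        conception = pd.Timestamp(row.conception_date).date()
        delivery = pd.Timestamp(row.delivery_date).date()
        profile = WaterUseProfile(
            tap_Lday=row.tap_Lday, bottled_Lday=row.bottled_Lday,
            tea_Lday=row.tea_Lday, coffee_Lday=row.coffee_Lday,
            squash_Lday=row.squash_Lday,
            filter_home=bool(row.filter_home),
            filter_work=bool(getattr(row, "filter_work", False)),
            shower_minwk=row.shower_minwk, bath_minwk=row.bath_minwk,
            swim_minwk=row.swim_minwk,
        )
        work = row.work_wsz if pd.notna(row.work_wsz) else None
        try:
            wins = pregnancy_windows(conception, delivery, labels=windows)
        except ValueError:
            continue
        for label, window in wins.items():
            rec = {"pregnancy_id": row.pregnancy_id, "window": label}
            mw = compute_time_weights(window, conception, delivery, "month")
            qw = compute_time_weights(window, conception, delivery, "quarter")
            twa: dict[str, float] = {}
            for analyte, surf in thm_surfaces.items():
                twa[analyte] = twa_concentration(surf, mw, row.res_wsz, work)
            for analyte, surf in haa_surfaces.items():
                twa[analyte] = twa_concentration(surf, qw, row.res_wsz, work)
            for analyte, v in twa.items():
                rec[f"twa_{analyte}"] = v
            if all(a in twa for a in HAA_ANALYTES) and "TTHM" in twa:
                rec["twa_DBP7"] = twa["TTHM"] + sum(twa[a] for a in HAA_ANALYTES)
            ing = ingestion(profile, twa, factors)
            for analyte, v in ing.items():
                rec[f"ing_{analyte}"] = v
            thm_present = [a for a in THM_EXPOSURE_ANALYTES if a in twa]
            upt = integrated_uptake(profile, twa, factors, analytes=thm_present)
            for analyte, pathways in upt.items():
                rec[f"upt_{analyte}"] = pathways["total"]
                if analyte == "TTHM":
                    rec["upt_TTHM_sbs"] = pathways["sbs"]
            rec["thm_missing"] = any(
                np.isnan(rec.get(f"twa_{a}", np.nan)) for a in thm_present
            )
            rec["haa_missing"] = any(
                np.isnan(rec.get(f"twa_{a}", np.nan)) for a in HAA_ANALYTES
            )
            records.append(rec)
    return pd.DataFrame.from_records(records)
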