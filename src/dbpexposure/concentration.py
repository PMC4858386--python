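"""Zone- and time-resolved predictive models of tap-water DBP concentrations.

Routine monitoring of a water network is sparse: each water supply zone
(WSZ) is sampled a handful of times per year for THMs and quarterly for
HAAs.  To assign exposures over whole pregnancies we therefore fit
regression models that smooth the monitoring record over season, year and
zone, and predict a complete concentration surface — one mean concentration
per analyte x WSZ x calendar month (THMs) or year-quarter (HAAs).

THMs are modelled on the log scale with a spline in month-of-year, a year
factor and a WSZ factor.  DCAA and TCAA are modelled on the square-root
scale and BDCAA on the log scale, each with a WSZ factor, a spline on
continuous quarter index and an analyte-specific set of water-chemistry
covariates (conductivity for all three; temperature for DCAA/TCAA; TOC for
TCAA; total chlorine for BDCAA).  The HAA models can be run in a Bayesian
mode (Gibbs sampling with conjugate updates) which propagates parameter
uncertainty and imputes missing covariate values inside the model.

Values reported below a limit of detection (LOD) are substituted at LOD/2
before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm

from .analytes import BROMINATED_THMS, HAA_ANALYTES, THM_MODEL_ANALYTES

MONITORING_COLUMNS = (
    "wsz_id", "date", "analyte", "value", "below_lod", "lod",
    "conductivity", "temperature", "toc", "total_chlorine",
)

HAA_COVARIATES = {
    "DCAA": ("conductivity", "temperature"),
    "TCAA": ("conductivity", "temperature", "toc"),
    "BDCAA": ("conductivity", "total_chlorine"),
}

HAA_TRANSFORM = {"DCAA": "sqrt", "TCAA": "sqrt", "BDCAA": "log"}


class ConvergenceError(RuntimeError):
    """Raised when the Bayesian sampler fails its R-hat diagnostic."""


# ---------------------------------------------------------------------------
# censored-value handling
# ---------------------------------------------------------------------------

def substitute_half_lod(samples: pd.DataFrame) -> pd.DataFrame:
    """Replace below-LOD concentrations with half the detection limit.

    Detected samples are passed through unchanged and row order is
    preserved.  A censored sample without a stated LOD is a data error.
    """
    out = samples.copy()
    below = out["below_lod"].fillna(False).astype(bool)
    if below.any():
        lods = out.loc[below, "lod"]
        if lods.isna().any():
            bad = out.index[below & out["lod"].isna()].tolist()
            raise ValueError(
                f"below-LOD samples without a stated LOD at rows {bad[:10]}"
            )
        if (lods <= 0).any():
            raise ValueError("below-LOD samples must have LOD > 0")
        out.loc[below, "value"] = lods / 2.0
    return out


def aggregate_thmbr(samples: pd.DataFrame) -> pd.DataFrame:
    """Build sample-level THMBr rows as the sum of the brominated species.

    Bromoform is too heavily censored to model on its own, so the three
    brominated THMs are summed per (zone, date) *after* half-LOD
    substitution and the total is modelled instead.
    """
    br = samples[samples["analyte"].isin(BROMINATED_THMS)]
    if br.empty:
        raise ValueError("no brominated THM rows to aggregate")
    grouped = (
        br.groupby(["wsz_id", "date"], as_index=False)
        .agg(value=("value", "sum"))
    )
    grouped["analyte"] = "THMBr"
    grouped["below_lod"] = False
    grouped["lod"] = np.nan
    for c in ("conductivity", "temperature", "toc", "total_chlorine"):
        grouped[c] = np.nan
    return grouped[list(MONITORING_COLUMNS)]


# ---------------------------------------------------------------------------
# surfaces
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationSurface:
    """Predicted mean concentration per (WSZ, time cell) for one analyte.

    ``frame`` holds columns wsz_id, time_cell (pandas Period), pred_ugL,
    sd, provenance in {fitted, gap_filled, extrapolated}.
    """

    analyte: str
    freq: str  # "M" or "Q"
    frame: pd.DataFrame
    _lookup: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if (self.frame["pred_ugL"] <= 0).any():
            raise ValueError("concentration surface contains non-positive cells")
        self._lookup = {
            (r.wsz_id, r.time_cell): r.pred_ugL
            for r in self.frame.itertuples()
        }

    def covers(self, wsz_id, cell: pd.Period) -> bool:
        return (wsz_id, cell) in self._lookup

    def value(self, wsz_id, cell: pd.Period) -> float:
        try:
            return self._lookup[(wsz_id, cell)]
        except KeyError:
            raise KeyError(
                f"surface for {self.analyte} has no cell ({wsz_id}, {cell})"
            ) from None

    @property
    def zones(self) -> list:
        return sorted(self.frame["wsz_id"].unique())

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "analyte", self.analyte)
        out["time_cell"] = out["time_cell"].astype(str)
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ConcentrationSurface":
        raw = pd.read_csv(path)
        analyte = raw["analyte"].iloc[0]
        freq = "Q" if "Q" in str(raw["time_cell"].iloc[0]) else "M"
        raw["time_cell"] = pd.PeriodIndex(raw["time_cell"], freq=freq)
        return cls(analyte=analyte, freq=freq,
                   frame=raw.drop(columns=["analyte"]))


def month_grid(start: str = "2006-01", end: str = "2011-03") -> pd.PeriodIndex:
    return pd.period_range(start, end, freq="M")


def quarter_grid(start: str = "2007Q1", end: str = "2011Q1") -> pd.PeriodIndex:
    return pd.period_range(start, end, freq="Q")


def _period_of(dates: pd.Series, freq: str) -> pd.PeriodIndex:
    return pd.DatetimeIndex(dates).to_period(freq)


# ---------------------------------------------------------------------------
# THM model: log(conc) ~ spline(month-of-year) + C(year) + C(wsz)
# ---------------------------------------------------------------------------

class ThmModel:
    """Log-linear seasonal model for one THM analyte."""

    def __init__(self, analyte: str, result, design_info, freq: str = "M",
                 training_cells: pd.PeriodIndex | None = None,
                 smearing: bool = False):
        self.analyte = analyte
        self.result = result
        self.design_info = design_info
        self.freq = freq
        self.training_cells = training_cells
        self.smearing = smearing
        self._smear = float(np.mean(np.exp(result.resid))) if smearing else 1.0

    @property
    def residual_variance(self) -> float:
        return float(self.result.mse_resid)

    def predict_cells(self, zones: Sequence, cells: pd.PeriodIndex) -> pd.DataFrame:
        rows = [(z, c) for z in zones for c in cells]
        df = pd.DataFrame(rows, columns=["wsz_id", "time_cell"])
        df["month"] = [c.month for c in df["time_cell"]]
        df["year"] = [c.year for c in df["time_cell"]]
        (X,) = patsy.build_design_matrices([self.design_info], df)
        pred = self.result.predict(np.asarray(X))
        df["pred_ugL"] = np.exp(pred) * self._smear
        se = np.sqrt(self.result.mse_resid)
        df["sd"] = df["pred_ugL"] * se  # delta-method scale on the raw scale
        return df[["wsz_id", "time_cell", "pred_ugL", "sd"]]


def fit_thm_model(samples: pd.DataFrame, analyte: str, *, month_df: int = 4,
                  cyclic: bool = False, exclude_cells: Iterable[pd.Period] = (),
                  smearing: bool = False) -> ThmModel:
    """Fit the seasonal log-linear model for one THM analyte.

    Bromoform is refused by design: its record is dominated by censored
    values, so only the brominated total (THMBr) is modelled.
    """
    if analyte == "bromoform":
        raise ValueError("bromoform is not modelled individually; fit THMBr")
    if analyte not in THM_MODEL_ANALYTES:
        raise ValueError(f"unknown THM model analyte {analyte!r}")
    df = samples[samples["analyte"] == analyte].copy()
    if df.empty:
        raise ValueError(f"no monitoring rows for analyte {analyte!r}")
    df["cell"] = _period_of(df["date"], "M")
    exclude = set(exclude_cells)
    if exclude:
        df = df[~df["cell"].isin(exclude)]
    df["month"] = pd.DatetimeIndex(df["date"]).month
    df["year"] = pd.DatetimeIndex(df["date"]).year
    if df["wsz_id"].nunique() < 2 or df["year"].nunique() < 2:
        raise ValueError("need at least 2 zones and 2 years of monitoring data")
    if (df["value"] <= 0).any():
        raise ValueError("non-positive concentrations; run substitute_half_lod first")
    df["logc"] = np.log(df["value"].astype(float))
    basis = "cc" if cyclic else "cr"
    # centering constraint keeps the spline basis orthogonal to the intercept
    formula = (f"logc ~ {basis}(month, df={month_df}, constraints='center')"
               " + C(year) + C(wsz_id)")
    y, X = patsy.dmatrices(formula, df, return_type="dataframe")
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError(
            "singular THM design (too few samples per zone/year cell); "
            f"n={len(df)}, p={X.shape[1]}"
        )
    res = sm.OLS(np.asarray(y).ravel(), np.asarray(X)).fit()
    return ThmModel(analyte, res, X.design_info, freq="M",
                    training_cells=pd.PeriodIndex(sorted(df["cell"].unique()), freq="M"),
                    smearing=smearing)


# ---------------------------------------------------------------------------
# HAA models
# ---------------------------------------------------------------------------

def _transform(values: np.ndarray, kind: str) -> np.ndarray:
    return np.sqrt(values) if kind == "sqrt" else np.log(values)


def _back_transform(values: np.ndarray, kind: str) -> np.ndarray:
    if kind == "sqrt":
        return np.square(np.clip(values, 1e-6, None))
    return np.exp(values)


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-R-hat per parameter; ``chains`` is (n_chain, n_iter, p)."""
    n_chain, n_iter, p = chains.shape
    half = n_iter // 2
    seqs = np.concatenate(
        [chains[:, :half, :], chains[:, half:2 * half, :]], axis=0
    )
    m, n = seqs.shape[0], seqs.shape[1]
    means = seqs.mean(axis=1)                     # (m, p)
    variances = seqs.var(axis=1, ddof=1)          # (m, p)
    w = variances.mean(axis=0)
    b = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * w + b / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / w)
    return np.where(w > 0, rhat, 1.0)


class HaaModel:
    """Transformed-scale regression for one HAA, frequentist or Bayesian."""

    def __init__(self, analyte, mode, design_info, cov_names, cov_mean, cov_sd,
                 transform, freq="Q", training_cells=None, smearing=False,
                 result=None, beta_draws=None, sigma_draws=None, rhat=None,
                 converged=True, cov_climatology=None):
        self.analyte = analyte
        self.mode = mode
        self.design_info = design_info
        self.cov_names = cov_names
        self.cov_mean = cov_mean
        self.cov_sd = cov_sd
        self.transform = transform
        self.freq = freq
        self.training_cells = training_cells
        self.smearing = smearing
        self.result = result
        self.beta_draws = beta_draws
        self.sigma_draws = sigma_draws
        self.rhat = rhat
        self.converged = converged
        self.cov_climatology = cov_climatology or {}

    # -- design helpers ---------------------------------------------------
    def _grid_design(self, zones, cells):
        rows = [(z, c) for z in zones for c in cells]
        df = pd.DataFrame(rows, columns=["wsz_id", "time_cell"])
        df["qidx"] = [_quarter_index(c) for c in df["time_cell"]]
        (S,) = patsy.build_design_matrices([self.design_info], df)
        Z = np.zeros((len(df), len(self.cov_names)))
        for j, name in enumerate(self.cov_names):
            vals = np.array([
                self._cell_covariate(name, z, c) for z, c in rows
            ])
            Z[:, j] = (vals - self.cov_mean[j]) / self.cov_sd[j]
        return df, np.hstack([np.asarray(S), Z])

    def _cell_covariate(self, name, zone, cell) -> float:
        clim = self.cov_climatology.get(name, {})
        for key in ((zone, cell), (zone, cell.quarter), ("__all__", cell.quarter),
                    ("__all__", None)):
            if key in clim:
                return clim[key]
        return self.cov_mean[self.cov_names.index(name)]

    # -- prediction -------------------------------------------------------
    def predict_cells(self, zones, cells) -> pd.DataFrame:
        df, X = self._grid_design(zones, cells)
        if self.mode == "bayesian":
            draws = X @ self.beta_draws.T            # (cells, draws)
            raw = _back_transform(draws, self.transform)
            df["pred_ugL"] = raw.mean(axis=1)
            df["sd"] = raw.std(axis=1, ddof=1)
        else:
            fitted = X @ self.result.params
            if self.smearing:
                resid = self.result.resid
                if self.transform == "log":
                    pred = np.exp(fitted) * np.mean(np.exp(resid))
                else:
                    pred = np.square(np.clip(fitted, 1e-6, None)) + np.mean(resid ** 2)
            else:
                pred = _back_transform(fitted, self.transform)
            df["pred_ugL"] = pred
            df["sd"] = np.nan
        return df[["wsz_id", "time_cell", "pred_ugL", "sd"]]


def _quarter_index(cell: pd.Period) -> float:
    return cell.year * 4.0 + (cell.quarter - 1)


def fit_haa_model(samples: pd.DataFrame, analyte: str, *,
                  mode: str = "frequentist", time_df: int = 3,
                  exclude_cells: Iterable[pd.Period] = (),
                  n_chains: int = 4, n_burn: int = 500, n_keep: int = 1000,
                  rhat_threshold: float = 1.05, seed: int = 0,
                  smearing: bool = False,
                  raise_on_nonconvergence: bool = True) -> HaaModel:
    """Fit one HAA model on its transformed scale.

    Frequentist mode is a complete-case OLS fit used for model checking;
    Bayesian mode runs a conjugate Gibbs sampler that also imputes missing
    covariate values, and is what drives the published-style quarterly
    surfaces.
    """
    if analyte not in HAA_ANALYTES:
        raise ValueError(f"unknown HAA analyte {analyte!r}; expected one of "
                         f"{HAA_ANALYTES}")
    if mode not in ("frequentist", "bayesian"):
        raise ValueError(f"unknown mode {mode!r}")
    df = samples[samples["analyte"] == analyte].copy()
    if df.empty:
        raise ValueError(f"no monitoring rows for analyte {analyte!r}")
    df["cell"] = _period_of(df["date"], "Q")
    exclude = set(exclude_cells)
    if exclude:
        df = df[~df["cell"].isin(exclude)]
    if (df["value"] <= 0).any():
        raise ValueError("non-positive concentrations; run substitute_half_lod first")

    transform = HAA_TRANSFORM[analyte]
    cov_names = list(HAA_COVARIATES[analyte])
    df["qidx"] = [_quarter_index(c) for c in df["cell"]]
    df["y"] = _transform(df["value"].astype(float).values, transform)

    S_formula = (f"y ~ cr(qidx, df={time_df}, constraints='center')"
                 " + C(wsz_id)")
    y_mat, S = patsy.dmatrices(S_formula, df, return_type="dataframe")
    y = np.asarray(y_mat).ravel()

    Zraw = df[cov_names].astype(float).values
    obs_mask = ~np.isnan(Zraw)
    # an entirely unobserved covariate standardises to the prior N(0, 1)
    cov_mean = np.array([
        Zraw[obs_mask[:, j], j].mean() if obs_mask[:, j].any() else 0.0
        for j in range(Zraw.shape[1])])
    cov_sd = np.array([
        Zraw[obs_mask[:, j], j].std(ddof=1)
        if obs_mask[:, j].sum() > 1 else 1.0
        for j in range(Zraw.shape[1])])
    cov_sd[~np.isfinite(cov_sd) | (cov_sd == 0)] = 1.0
    Z = (Zraw - cov_mean) / cov_sd

    # per-(zone, quarter-of-year) climatology used for grid prediction
    clim = {}
    for j, name in enumerate(cov_names):
        table = {}
        sub = df.assign(v=Zraw[:, j])
        for (zone, cell), grp in sub.groupby(["wsz_id", "cell"]):
            m = grp["v"].mean()
            if not np.isnan(m):
                table[(zone, cell)] = m
        for (zone, qoy), grp in sub.assign(q=[c.quarter for c in sub["cell"]]) \
                                   .groupby(["wsz_id", "q"]):
            m = grp["v"].mean()
            if not np.isnan(m):
                table[(zone, qoy)] = m
        for qoy, grp in sub.assign(q=[c.quarter for c in sub["cell"]]).groupby("q"):
            m = grp["v"].mean()
            if not np.isnan(m):
                table[("__all__", qoy)] = m
        table[("__all__", None)] = cov_mean[j]
        clim[name] = table

    cells = pd.PeriodIndex(sorted(df["cell"].unique()), freq="Q")
    common = dict(analyte=analyte, design_info=S.design_info,
                  cov_names=cov_names, cov_mean=cov_mean, cov_sd=cov_sd,
                  transform=transform, training_cells=cells,
                  cov_climatology=clim, smearing=smearing)

    if mode == "frequentist":
        keep = obs_mask.all(axis=1)
        X = np.hstack([np.asarray(S)[keep], Z[keep]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular HAA design after complete-case filtering")
        res = sm.OLS(y[keep], X).fit()
        return HaaModel(mode="frequentist", result=res, **common)

    beta, sigma = _gibbs_impute(np.asarray(S), Z, obs_mask, y,
                                n_chains=n_chains, n_burn=n_burn,
                                n_keep=n_keep, seed=seed)
    stacked = np.concatenate([beta, sigma[..., None]], axis=2)
    rhat = _split_rhat(stacked)
    converged = bool(np.nanmax(rhat) < rhat_threshold)
    if not converged and raise_on_nonconvergence:
        raise ConvergenceError(
            f"Gibbs sampler for {analyte} failed R-hat < {rhat_threshold} "
            f"(max R-hat {np.nanmax(rhat):.3f})"
        )
    flat_beta = beta.reshape(-1, beta.shape[2])
    flat_sigma = sigma.reshape(-1)
    return HaaModel(mode="bayesian", beta_draws=flat_beta,
                    sigma_draws=flat_sigma, rhat=rhat, converged=converged,
                    **common)


def _gibbs_impute(S, Z, obs_mask, y, *, n_chains, n_burn, n_keep, seed,
                  prior_sd=10.0, a0=2.0, b0=0.5):
    """Conjugate Gibbs sampler for normal linear regression with normal
    imputation of missing standardized covariates.

    Priors: beta ~ N(0, prior_sd^2 I); sigma^2 ~ InvGamma(a0, b0);
    standardized missing covariates ~ N(0, 1) a priori.
    """
    n, ps = S.shape
    pz = Z.shape[1]
    p = ps + pz
    missing_cols = [np.where(~obs_mask[:, j])[0] for j in range(pz)]
    beta_out = np.empty((n_chains, n_keep, p))
    sigma_out = np.empty((n_chains, n_keep))
    rng = np.random.default_rng(seed)
    for c in range(n_chains):
        Zc = np.where(obs_mask, Z, 0.0)
        beta = rng.normal(0, 0.1, size=p)
        sigma2 = float(np.var(y)) or 1.0
        for it in range(n_burn + n_keep):
            X = np.hstack([S, Zc])
            prec = X.T @ X / sigma2 + np.eye(p) / prior_sd ** 2
            cov = np.linalg.inv(prec)
            mean = cov @ (X.T @ y) / sigma2
            beta = rng.multivariate_normal(mean, cov, method="cholesky")
            resid = y - X @ beta
            shape = a0 + n / 2.0
            scale = b0 + 0.5 * float(resid @ resid)
            sigma2 = scale / rng.gamma(shape)
            for j in range(pz):
                rows = missing_cols[j]
                if rows.size == 0:
                    continue
                bj = beta[ps + j]
                partial = y[rows] - (X[rows] @ beta - Zc[rows, j] * bj)
                prec_j = bj ** 2 / sigma2 + 1.0
                mean_j = (bj * partial / sigma2) / prec_j
                Zc[rows, j] = rng.normal(mean_j, np.sqrt(1.0 / prec_j))
            if it >= n_burn:
                beta_out[c, it - n_burn] = beta
                sigma_out[c, it - n_burn] = np.sqrt(sigma2)
    return beta_out, sigma_out


# ---------------------------------------------------------------------------
# surface assembly
# ---------------------------------------------------------------------------

def build_surface(model, zones: Sequence, periods: pd.PeriodIndex, *,
                  exclusions: Iterable[pd.Period] = (),
                  extrapolation: Iterable[pd.Period] = ()) -> ConcentrationSurface:
    """Assemble a complete concentration surface from a fitted model.

    ``exclusions`` are cells that were withheld from training (for example
    a quarter with unreliable laboratory data) and are filled by model
    prediction; ``extrapolation`` cells may sit at most one grid step
    beyond the training window.  Both are flagged in the provenance column.
    """
    exclusions = list(pd.PeriodIndex(list(exclusions), freq=model.freq)) \
        if list(exclusions) else []
    extrapolation = list(pd.PeriodIndex(list(extrapolation), freq=model.freq)) \
        if list(extrapolation) else []
    if model.training_cells is not None and len(extrapolation):
        lo, hi = model.training_cells.min(), model.training_cells.max()
        for cell in extrapolation:
            if not (lo - 1 <= cell <= hi + 1):
                raise ValueError(
                    f"extrapolation cell {cell} is more than one step beyond "
                    f"the training window [{lo}, {hi}]"
                )
    all_cells = pd.PeriodIndex(
        sorted(set(periods) | set(exclusions) | set(extrapolation)),
        freq=model.freq,
    )
    frame = model.predict_cells(zones, all_cells)
    excl, extr = set(exclusions), set(extrapolation)

    def _prov(cell):
        if cell in excl:
            return "gap_filled"
        if cell in extr:
            return "extrapolated"
        return "fitted"

    frame["provenance"] = [_prov(c) for c in frame["time_cell"]]
    return ConcentrationSurface(analyte=model.analyte, freq=model.freq,
                                frame=frame)
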