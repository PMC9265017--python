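"""Agreement and bias statistics for predicted vs observed digestible energy.

The suite follows the standard model-evaluation toolkit of animal
nutrition: precision as the coefficient of determination (R^2) between
observed and predicted values, accuracy as the root mean square error of
prediction (RMSEP), reproducibility as Lin's concordance correlation
coefficient (CCC), mean and linear bias from the regression of residuals
on mean-centered predictions, and the decomposition of the mean square
error of prediction (MSEP) into central-tendency, linear and random
components.

Conventions that matter for signs and identities:

* Residuals are observed - predicted; a positive residual means the
  equation under-predicts.
* CCC and the MSEP decomposition use population (divide-by-n) moments, so
  ECT + ER + ED = MSEP = RMSEP^2 holds as an exact algebraic identity.
* Dataset description (and the SD bands) use the sample (n-1) standard
  deviation, as descriptive statistics conventionally do.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .dataset import Dataset
from .energy import PredictionEquation, predict_dataset

__all__ = [
    "PairedSeries",
    "MomentSummary",
    "BiasRegressionResult",
    "MsepDecomposition",
    "EvaluationResult",
    "SdBandSummary",
    "residuals",
    "pearson",
    "r_squared",
    "rmsep",
    "ccc",
    "bias_regression",
    "msep_decomposition",
    "sd_band_summary",
    "evaluate_equation",
    "residual_nutrient_correlations",
]


@dataclass(frozen=True)
class PairedSeries:
    """Parallel observed/predicted DE vectors (kcal/kg DM) with record ids."""

    observed: np.ndarray
    predicted: np.ndarray
    ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        o = np.asarray(self.observed, dtype=float)
        p = np.asarray(self.predicted, dtype=float)
        object.__setattr__(self, "observed", o)
        object.__setattr__(self, "predicted", p)
        if o.ndim != 1 or p.ndim != 1 or o.shape != p.shape:
            raise ValueError("observed and predicted must be 1-d and equal length")
        if o.size < 3:
            raise ValueError(f"need at least 3 pairs, got {o.size}")
        if not (np.isfinite(o).all() and np.isfinite(p).all()):
            raise ValueError("observed/predicted contain non-finite values")
        if self.ids and len(self.ids) != o.size:
            raise ValueError("ids must parallel the series")

    def __len__(self) -> int:
        return self.observed.size

    @classmethod
    def from_dataset(cls, ds: Dataset, predicted: Sequence[float]) -> "PairedSeries":
        obs = np.array([r.de_observed for r in ds])
        return cls(obs, np.asarray(predicted, dtype=float), tuple(r.id for r in ds))


@dataclass(frozen=True)
class MomentSummary:
    """First and second moments of a paired series (population SDs)."""

    mean_obs: float
    mean_pred: float
    sd_obs_n: float
    sd_pred_n: float
    r: float


def _moments(ps: PairedSeries) -> MomentSummary:
    o, p = ps.observed, ps.predicted
    s_o = float(o.std(ddof=0))
    s_p = float(p.std(ddof=0))
    if s_o == 0 or s_p == 0:
        raise ValueError("zero variance in observed or predicted series")
    cov = float(((o - o.mean()) * (p - p.mean())).mean())
    return MomentSummary(float(o.mean()), float(p.mean()), s_o, s_p, cov / (s_o * s_p))


@dataclass(frozen=True)
class BiasRegressionResult:
    """OLS of residuals on mean-centered predictions.

    The intercept estimates mean bias (kcal/kg DM); the slope estimates
    linear bias (dimensionless). Classical t tests with n - 2 df.
    """

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    t_intercept: float
    t_slope: float
    p_intercept: float
    p_slope: float
    n: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class MsepDecomposition:
    """Additive split of MSEP into interpretable error sources.

    With population moments (mean_obs Obar, mean_pred Pbar, SDs s_O and
    s_P, correlation r):

    * central-tendency error  ECT = (Pbar - Obar)^2  — mean shift;
    * linear error            ER  = (s_P - r s_O)^2  — slope/scale mismatch;
    * random error            ED  = (1 - r^2) s_O^2  — scatter around the
      best linear fit.

    ECT + ER + ED = MSEP exactly. Units (kcal/kg DM)^2; shares in % of MSEP.
    """

    msep: float
    ect: float
    er: float
    ed: float
    pct_ect: Optional[float]
    pct_er: Optional[float]
    pct_ed: Optional[float]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class EvaluationResult:
    """Complete statistics bundle for one equation on one dataset."""

    equation: str
    n: int
    r2: float
    rmsep: float
    rmsep_pct_of_mean: float
    ccc: float
    bias: BiasRegressionResult
    decomposition: MsepDecomposition
    residuals: np.ndarray
    moments: MomentSummary

    def to_dict(self) -> dict:
        d = {
            "equation": self.equation,
            "n": self.n,
            "r2": self.r2,
            "rmsep": self.rmsep,
            "rmsep_pct_of_mean": self.rmsep_pct_of_mean,
            "ccc": self.ccc,
            "bias": self.bias.to_dict(),
            "decomposition": self.decomposition.to_dict(),
            "residuals": [float(x) for x in self.residuals],
        }
        return d

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class SdBandSummary:
    """Percent-error summaries in observed-DE bands around the mean.

    Records are classified by observed DE relative to mean +/- one sample
    (n-1) SD. Per band: count, mean +/- sample SD of the signed percent
    error 100*(pred-obs)/obs (positive = over-prediction) and of the
    absolute percent error.
    """

    lower_edge: float
    upper_edge: float
    bands: dict[str, dict]  # keys: below, within, above

    def to_dict(self) -> dict:
        return {
            "lower_edge": self.lower_edge,
            "upper_edge": self.upper_edge,
            "bands": self.bands,
        }


def residuals(ps: PairedSeries) -> np.ndarray:
    """Element-wise observed - predicted (positive = under-prediction)."""
    return ps.observed - ps.predicted


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with its two-sided p-value (t test, n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def r_squared(ps: PairedSeries) -> float:
    """Squared Pearson correlation of observed and predicted."""
    r, _ = pearson(ps.observed, ps.predicted)
    return r * r


def rmsep(ps: PairedSeries) -> float:
    """Root mean square error of prediction, divide-by-n."""
    e = residuals(ps)
    return float(np.sqrt(np.mean(e * e)))


def ccc(ps: PairedSeries) -> float:
    """Lin's concordance correlation coefficient.

    2*cov / (var_obs + var_pred + (mean_obs - mean_pred)^2) with
    population (n) moments. Penalizes both imprecision (low r) and
    location/scale shift; 1 only for exact agreement.
    """
    o, p = ps.observed, ps.predicted
    var_o = float(o.var(ddof=0))
    var_p = float(p.var(ddof=0))
    if var_o == 0 and var_p == 0:
        raise ValueError("both series constant: CCC undefined")
    cov = float(((o - o.mean()) * (p - p.mean())).mean())
    return 2.0 * cov / (var_o + var_p + (o.mean() - p.mean()) ** 2)


def bias_regression(ps: PairedSeries) -> BiasRegressionResult:
    """Mean/linear bias test: OLS of residuals on centered predictions.

    Fits e_i = a + b (p_i - pbar); a is the mean bias (since the
    regressor is centered, the intercept equals the mean residual) and b
    the linear bias. Classical standard errors; two-sided p-values with
    n - 2 degrees of freedom.
    """
    if len(ps) < 4:
        raise ValueError("bias regression needs at least 4 pairs")
    p_centered = ps.predicted - ps.predicted.mean()
    if p_centered.std() == 0:
        raise ValueError("constant predictions: linear bias undefined")
    e = residuals(ps)
    fit = sm.OLS(e, sm.add_constant(p_centered)).fit()
    return BiasRegressionResult(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        se_intercept=float(fit.bse[0]),
        se_slope=float(fit.bse[1]),
        t_intercept=float(fit.tvalues[0]),
        t_slope=float(fit.tvalues[1]),
        p_intercept=float(fit.pvalues[0]),
        p_slope=float(fit.pvalues[1]),
        n=len(ps),
    )


def msep_decomposition(ps: PairedSeries) -> MsepDecomposition:
    """Split MSEP into central-tendency, linear and random error.

    Uses population moments so that the three components add exactly to
    MSEP = mean squared residual. When MSEP is zero the percentage shares
    are undefined and reported as ``None``.
    """
    o, p = ps.observed, ps.predicted
    e = o - p
    msep = float(np.mean(e * e))
    s_o = float(o.std(ddof=0))
    s_p = float(p.std(ddof=0))
    if s_o > 0 and s_p > 0:
        cov = float(((o - o.mean()) * (p - p.mean())).mean())
        r = cov / (s_o * s_p)
    else:
        r = 0.0
    ect = float((p.mean() - o.mean()) ** 2)
    er = float((s_p - r * s_o) ** 2)
    ed = float((1.0 - r * r) * s_o * s_o)
    if msep > 0:
        pct = (100.0 * ect / msep, 100.0 * er / msep, 100.0 * ed / msep)
    else:
        pct = (None, None, None)
    return MsepDecomposition(msep, ect, er, ed, *pct)


def sd_band_summary(ds: Dataset, predictions: Sequence[float]) -> SdBandSummary:
    """Percent errors grouped by observed DE relative to mean +/- 1 SD."""
    obs = np.array([r.de_observed for r in ds])
    pred = np.asarray(predictions, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predictions must parallel the dataset records")
    mean = obs.mean()
    sd = obs.std(ddof=1) if obs.size > 1 else 0.0
    lo, hi = mean - sd, mean + sd
    pct_err = 100.0 * (pred - obs) / obs

    masks = {
        "below": obs < lo,
        "within": (obs >= lo) & (obs <= hi),
        "above": obs > hi,
    }
    bands = {}
    for label, mask in masks.items():
        ids = [ds[i].id for i in np.flatnonzero(mask)]
        err = pct_err[mask]
        bands[label] = {
            "count": int(mask.sum()),
            "ids": ids,
            "mean_pct_error": float(err.mean()) if err.size else None,
            "sd_pct_error": float(err.std(ddof=1)) if err.size > 1 else None,
            "mean_abs_pct_error": float(np.abs(err).mean()) if err.size else None,
            "sd_abs_pct_error": float(np.abs(err).std(ddof=1)) if err.size > 1 else None,
        }
    return SdBandSummary(float(lo), float(hi), bands)


def evaluate_equation(ds: Dataset, eq: PredictionEquation) -> EvaluationResult:
    """Run the full statistics suite for one equation over a dataset.

    Predictions are always recomputed from the equation coefficients.
    """
    pred = predict_dataset(ds, eq)
    ps = PairedSeries.from_dataset(ds, pred)
    mom = _moments(ps)
    rm = rmsep(ps)
    return EvaluationResult(
        equation=eq.name,
        n=len(ps),
        r2=r_squared(ps),
        rmsep=rm,
        rmsep_pct_of_mean=100.0 * rm / mom.mean_obs,
        ccc=ccc(ps),
        bias=bias_regression(ps),
        decomposition=msep_decomposition(ps),
        residuals=residuals(ps),
        moments=mom,
    )


def residual_nutrient_correlations(
    ds: Dataset, eq: PredictionEquation
) -> list[dict]:
    """Correlation table linking prediction error and composition to fiber.

    Rows (Pearson r with two-sided p):

    * residual (obs - pred) vs each crude nutrient, over all records;
    * crude fiber vs each of DCP, DNFE, DEE, over the records that carry
      digestible fractions.
    """
    pred = predict_dataset(ds, eq)
    ps = PairedSeries.from_dataset(ds, pred)
    e = residuals(ps)
    comp = {
        name: np.array([getattr(r.composition, name) for r in ds])
        for name in ("cp", "cf", "nfe", "ee")
    }
    table: list[dict] = []
    for name, x in comp.items():
        r, p = pearson(e, x)
        table.append({"x": "residual", "y": name, "n": len(ds), "r": r, "p": p})

    complete = ds.complete()
    cf = np.array([r.composition.cf for r in complete])
    for dname in ("dcp", "dnfe", "dee"):
        y = np.array([getattr(r.digestible, dname) for r in complete])
        r, p = pearson(cf, y)
        table.append({"x": "cf", "y": dname, "n": len(complete), "r": r, "p": p})
    return table
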