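"""Correlation screening and the SPAD/LNC calibration models.

The nitrogen-diagnosis regressions relate leaf nitrogen concentration
(LNC, g kg-1) and the SPAD chlorophyll-meter reading to the canopy color
index b* and days after transplanting (DAT):

    Model 1:  LNC  = alpha*SPAD + beta*DAT + gamma
    Model 2:  LNC  = alpha*b*   + beta*DAT + gamma
    Model 3:  SPAD = alpha*b*   + beta*DAT + gamma
    Model 4:  SPAD = alpha*b*   + gamma

Fitting is ordinary least squares (via statsmodels).  The calibration RMSE
uses the divisor n, matching the validation RMSE so the two columns are
comparable.  Validation reports RMSE, R2 (squared Pearson correlation of
predicted vs observed by default; 1 - SSE/SST optionally) and the
normalized mean bias NMB = 100 * sum(pred - obs) / sum(obs), positive when
the model over-predicts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

__all__ = [
    "STAGES",
    "LinearModelSpec",
    "MODEL_SPECS",
    "REFERENCE_FITS",
    "ValidationReport",
    "CorrelationMatrix",
    "NitrogenLinearModel",
    "ZeroVarianceWarning",
    "pearson_matrix",
    "fit_linear_model",
    "predict",
    "validate",
]

#: Rice developmental stages sampled in the study design.
STAGES = ("vegetative", "tillering", "jointing", "booting")


class ZeroVarianceWarning(UserWarning):
    """A requested correlation variable is constant."""


@dataclass(frozen=True)
class LinearModelSpec:
    """One of the four calibration model forms."""

    model_id: int
    response: str
    predictors: tuple[str, ...]

    @property
    def has_dat(self) -> bool:
        return "DAT" in self.predictors


MODEL_SPECS: dict[int, LinearModelSpec] = {
    1: LinearModelSpec(1, "LNC", ("SPAD", "DAT")),
    2: LinearModelSpec(2, "LNC", ("bstar", "DAT")),
    3: LinearModelSpec(3, "SPAD", ("bstar", "DAT")),
    4: LinearModelSpec(4, "SPAD", ("bstar",)),
}

#: Published coefficients (+- SE), calibration RMSE/R2 and validation
#: RMSE/R2/NMB for the four models, estimated on the pooled 2011 rice
#: dataset (n = 240) and validated on the 2010 dataset.  These serve as
#: generating truth for the synthetic study and as recovery references.
REFERENCE_FITS: dict[int, dict[str, float | None]] = {
    1: {
        "alpha": 1.02, "se_alpha": 0.07, "beta": -0.31, "se_beta": 0.01,
        "gamma": 7.01, "se_gamma": 2.95, "rmse": 3.07, "r2": 0.78,
        "val_rmse": 2.43, "val_r2": 0.75, "nmb": 1.19,
    },
    2: {
        "alpha": -0.67, "se_alpha": 0.06, "beta": -0.29, "se_beta": 0.01,
        "gamma": 69.27, "se_gamma": 2.10, "rmse": 3.36, "r2": 0.71,
        "val_rmse": 2.59, "val_r2": 0.62, "nmb": -1.32,
    },
    3: {
        "alpha": -0.60, "se_alpha": 0.04, "beta": 0.024, "se_beta": 0.007,
        "gamma": 59.66, "se_gamma": 1.14, "rmse": 1.62, "r2": 0.55,
        "val_rmse": 2.01, "val_r2": 0.46, "nmb": -1.94,
    },
    4: {
        "alpha": -0.60, "se_alpha": 0.04, "beta": None, "se_beta": None,
        "gamma": 60.70, "se_gamma": 1.12, "rmse": 1.62, "r2": 0.53,
        "val_rmse": 1.89, "val_r2": 0.47, "nmb": -2.00,
    },
}


@dataclass(frozen=True)
class ValidationReport:
    """Out-of-sample performance of a fitted model."""

    rmse: float
    r2: float
    nmb: float
    n: int


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with two-sided p-values."""

    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    n_dropped: int = 0

    def stars(self) -> pd.DataFrame:
        """Significance markers: '**' for p < 0.01, '*' for p < 0.05."""
        def mark(p: float) -> str:
            if not np.isfinite(p):
                return ""
            if p < 0.01:
                return "**"
            if p < 0.05:
                return "*"
            return ""

        return self.p.map(mark)


def pearson_matrix(
    records: pd.DataFrame, variables: Iterable[str] | None = None
) -> CorrelationMatrix:
    """Pearson correlation matrix over the chosen columns.

    Rows with a missing value in any chosen column are dropped listwise
    (count logged).  p-values are two-sided from the t transform with n-2
    degrees of freedom.  A constant column yields NaN correlations for its
    pairs with a :class:`ZeroVarianceWarning`.
    """
    df = pd.DataFrame(records)
    cols = tuple(variables) if variables is not None else tuple(df.columns)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"variables not in the table: {missing}")
    sub = df.loc[:, list(cols)].astype(float)
    n_before = len(sub)
    sub = sub.dropna()
    n_dropped = n_before - len(sub)
    if n_dropped:
        logger.info("pearson_matrix: dropped %d rows with missing values", n_dropped)
    n = len(sub)
    if n < 3:
        raise ValueError(f"need at least 3 complete rows, have {n}")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    constant = [c for c in cols if sub[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"zero-variance variables {constant}: correlations undefined",
            ZeroVarianceWarning,
            stacklevel=2,
        )
    for i in range(k):
        for j in range(i + 1, k):
            if cols[i] in constant or cols[j] in constant:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            ri, pi = sps.pearsonr(sub[cols[i]], sub[cols[j]])
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi
    for i, c in enumerate(cols):
        if c in constant:
            r[i, i] = np.nan
            p[i, i] = np.nan
    rdf = pd.DataFrame(r, index=list(cols), columns=list(cols))
    pdf = pd.DataFrame(p, index=list(cols), columns=list(cols))
    return CorrelationMatrix(cols, rdf, pdf, n=n, n_dropped=n_dropped)


class NitrogenLinearModel(RegressorMixin, BaseEstimator):
    """OLS calibration model for LNC or SPAD (Models 1-4).

    Parameters
    ----------
    model_id:
        1-4, selecting the response and predictors (see :data:`MODEL_SPECS`).
    validation_r2:
        ``"corr"`` (default): validation R2 is the squared Pearson
        correlation of predicted vs observed.  ``"sst"``: 1 - SSE/SST on
        the validation set.

    Attributes (after ``fit``)
    --------------------------
    alpha_, beta_, gamma_ : float
        Slope on the color/meter predictor, slope on DAT (None for
        Model 4), and intercept.
    se_alpha_, se_beta_, se_gamma_ : float
        Their OLS standard errors.
    r2_ : float
        Calibration coefficient of determination.
    rmse_ : float
        Root mean square calibration residual (divisor n).
    n_ : int
        Number of records used (listwise deletion of missing values).
    """

    def __init__(self, model_id: int = 1, validation_r2: str = "corr"):
        self.model_id = model_id
        self.validation_r2 = validation_r2

    @property
    def spec(self) -> LinearModelSpec:
        try:
            return MODEL_SPECS[self.model_id]
        except KeyError:
            raise ValueError(f"model_id must be 1-4, got {self.model_id!r}") from None

    # -- helpers ----------------------------------------------------------
    def _design(self, X, need_response: bool) -> tuple[pd.DataFrame, np.ndarray | None]:
        spec = self.spec
        df = pd.DataFrame(X)
        missing = [c for c in spec.predictors if c not in df.columns]
        if missing:
            raise ValueError(f"missing predictor column(s) {missing} for Model {spec.model_id}")
        cols = list(spec.predictors)
        y = None
        if need_response:
            if spec.response not in df.columns:
                raise ValueError(f"missing response column {spec.response!r}")
            sub = df.loc[:, cols + [spec.response]].astype(float).dropna()
            y = sub[spec.response].to_numpy()
        else:
            sub = df.loc[:, cols].astype(float).dropna()
        dropped = len(df) - len(sub)
        if dropped:
            logger.info("Model %d: dropped %d incomplete rows", spec.model_id, dropped)
        return sub.loc[:, cols], y

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y=None) -> "NitrogenLinearModel":
        """Fit by OLS.  ``X`` is a table holding the predictor columns and,
        when ``y`` is omitted, the response column as well."""
        spec = self.spec
        if y is not None:
            Xd = pd.DataFrame(X)
            if set(spec.predictors) <= set(Xd.columns):
                Xd = Xd.loc[:, list(spec.predictors)]
            else:
                Xd = pd.DataFrame(np.asarray(X, float), columns=list(spec.predictors))
            y = np.asarray(y, dtype=float)
        else:
            Xd, y = self._design(X, need_response=True)
        n, p = len(Xd), len(spec.predictors) + 1
        if n <= p:
            raise ValueError(f"need more than {p} records, have {n}")
        design = np.column_stack([np.ones(n), Xd.to_numpy(dtype=float)])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            corr = np.corrcoef(Xd.to_numpy(dtype=float), rowvar=False)
            pairs = [
                (spec.predictors[i], spec.predictors[j])
                for i in range(len(spec.predictors))
                for j in range(i + 1, len(spec.predictors))
                if abs(corr[i, j]) > 1 - 1e-10
            ] if len(spec.predictors) > 1 else []
            raise ValueError(
                f"design matrix is rank deficient; collinear predictors: "
                f"{pairs or list(spec.predictors)}"
            )
        res = sm.OLS(y, design).fit()
        self.result_ = res
        self.n_ = n
        self.gamma_ = float(res.params[0])
        self.se_gamma_ = float(res.bse[0])
        self.alpha_ = float(res.params[1])
        self.se_alpha_ = float(res.bse[1])
        if spec.has_dat:
            self.beta_ = float(res.params[2])
            self.se_beta_ = float(res.bse[2])
        else:
            self.beta_ = None
            self.se_beta_ = None
        self.r2_ = float(res.rsquared)
        resid = np.asarray(res.resid)
        self.rmse_ = float(np.sqrt(np.mean(resid**2)))
        self.coef_ = np.asarray(res.params[1:])
        self.intercept_ = self.gamma_
        return self

    def predict(self, X) -> np.ndarray:
        """Evaluate the fitted linear form on the predictor columns of X."""
        if not hasattr(self, "alpha_"):
            raise ValueError("model is not fitted")
        spec = self.spec
        Xd, _ = self._design(X, need_response=False)
        yhat = self.gamma_ + self.alpha_ * Xd[spec.predictors[0]].to_numpy()
        if spec.has_dat:
            yhat = yhat + self.beta_ * Xd["DAT"].to_numpy()
        return yhat

    def validate(self, X, y=None) -> ValidationReport:
        """Out-of-sample RMSE, R2 and normalized mean bias (percent)."""
        spec = self.spec
        df = pd.DataFrame(X)
        if y is None:
            if spec.response not in df.columns:
                raise ValueError(f"missing response column {spec.response!r}")
            sub = df.loc[:, list(spec.predictors) + [spec.response]].astype(float).dropna()
            obs = sub[spec.response].to_numpy()
            pred = self.predict(sub)
        else:
            obs = np.asarray(y, dtype=float)
            pred = self.predict(df)
        if len(obs) == 0:
            raise ValueError("empty validation set")
        err = pred - obs
        rmse = float(np.sqrt(np.mean(err**2)))
        if self.validation_r2 == "sst":
            sst = float(np.sum((obs - obs.mean()) ** 2))
            r2 = float(1.0 - np.sum(err**2) / sst) if sst > 0 else float("nan")
        else:
            if len(obs) < 2 or np.std(obs) == 0 or np.std(pred) == 0:
                r2 = 1.0 if np.allclose(pred, obs) else float("nan")
            else:
                r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2)
        nmb = float(100.0 * np.sum(err) / np.sum(obs))
        return ValidationReport(rmse=rmse, r2=r2, nmb=nmb, n=len(obs))

    # -- serialization ----------------------------------------------------
    def to_text(self, extra: Mapping[str, object] | None = None) -> str:
        """Plain-text key=value serialization of spec, coefficients and fit
        statistics; ``extra`` entries (e.g. color-conversion provenance) are
        appended with an ``meta.`` prefix."""
        spec = self.spec
        lines = [
            f"model_id={spec.model_id}",
            f"response={spec.response}",
            f"predictors={','.join(spec.predictors)}",
            f"alpha={self.alpha_!r}",
            f"se_alpha={self.se_alpha_!r}",
            f"beta={'' if self.beta_ is None else repr(self.beta_)}",
            f"se_beta={'' if self.se_beta_ is None else repr(self.se_beta_)}",
            f"gamma={self.gamma_!r}",
            f"se_gamma={self.se_gamma_!r}",
            f"r2={self.r2_!r}",
            f"rmse={self.rmse_!r}",
            f"n={self.n_}",
            f"validation_r2={self.validation_r2}",
        ]
        for key, val in (extra or {}).items():
            lines.append(f"meta.{key}={val}")
        return "\n".join(lines) + "\n"

    def save(self, path, extra: Mapping[str, object] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text(extra))

    @classmethod
    def from_text(cls, text: str) -> "NitrogenLinearModel":
        kv: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, val = line.split("=", 1)
            kv[key] = val
        model = cls(
            model_id=int(kv["model_id"]),
            validation_r2=kv.get("validation_r2", "corr"),
        )
        model.alpha_ = float(kv["alpha"])
        model.se_alpha_ = float(kv["se_alpha"])
        model.beta_ = float(kv["beta"]) if kv.get("beta") else None
        model.se_beta_ = float(kv["se_beta"]) if kv.get("se_beta") else None
        model.gamma_ = float(kv["gamma"])
        model.se_gamma_ = float(kv["se_gamma"])
        model.r2_ = float(kv["r2"])
        model.rmse_ = float(kv["rmse"])
        model.n_ = int(kv["n"])
        model.coef_ = np.array(
            [model.alpha_] + ([model.beta_] if model.beta_ is not None else [])
        )
        model.intercept_ = model.gamma_
        return model

    @classmethod
    def load(cls, path) -> "NitrogenLinearModel":
        with open(path) as fh:
            return cls.from_text(fh.read())


# -- thin functional wrappers ------------------------------------------------

def fit_linear_model(
    records: pd.DataFrame, model_id: int, **kwargs
) -> NitrogenLinearModel:
    """Fit one of Models 1-4 to a sample table (thin estimator wrapper)."""
    return NitrogenLinearModel(model_id=model_id, **kwargs).fit(records)


def predict(fit: NitrogenLinearModel, records: pd.DataFrame) -> np.ndarray:
    """Evaluate a fitted model on a sample table."""
    return fit.predict(records)


def validate(fit: NitrogenLinearModel, records: pd.DataFrame) -> ValidationReport:
    """Validate a fitted model on an independent sample table."""
    return fit.validate(records)
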