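"""Multiple linear regression QSAR models with leave-one-out validation.

The modelling template relates a blood-brain distribution endpoint (log BB,
the base-10 log of the brain-to-blood concentration ratio, or the
alternative estimate log BB*) to four kinds of molecular information::

    log SP = a0 + a1*lipophilicity + a2*d_I + a3*d_II [+ a4*d_III]

where lipophilicity is the micellar descriptor log(k_m/K_AM), d_I is a
polarity descriptor (TPSA or HBA), d_II a size descriptor (polarizability,
parachor or MW) and d_III the optional flexibility descriptor NRB.
Enumerating the template over both endpoints gives models M1-M12; dropping
NRB from the shortlisted models gives the starred variants M5*, M11*, M12*.

Each candidate is fitted by ordinary least squares and judged by the full
validation battery: R2, adjusted R2, predicted R2 from leave-one-out
cross-validation (PRESS), the F statistic, variance inflation factors
(collinearity), and the screening rules max VIF < 5, Q2_LOO > 0.6,
PRESS/SS < 0.4.

The usage pattern mirrors statsmodels::

    model = QSARModel.from_dataframe(table, "log_bb",
                                     ["log_km_over_kam", "hba", "nrb", "parachor_P"],
                                     label="M5")
    res = model.fit()
    res.rsquared, res.press, res.max_vif
    print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _spstats

from .descriptors import DescriptorGrouping
from .errors import (
    DegenerateLeverageError,
    SingularFitError,
    ValidationError,
)

__all__ = [
    "ModelSpec",
    "ModelStats",
    "ScreeningRules",
    "ScreeningResult",
    "QSARModel",
    "QSARResults",
    "PAPER_GROUPS",
    "enumerate_models",
    "fit_mlr",
    "screen_models",
]

#: Canonical group structure of the study descriptors, in enumeration order:
#: polarity (I), size (II), flexibility (III).
PAPER_GROUPS: dict[str, tuple[str, ...]] = {
    "I": ("tpsa", "hba"),
    "II": ("alpha", "parachor_P", "mw"),
    "III": ("nrb",),
}

#: Default starred variants: NRB dropped from the shortlisted models.
DEFAULT_STARRED_BASES = ("M5", "M11", "M12")


@dataclass(frozen=True)
class ModelSpec:
    """A candidate model: response plus an ordered predictor set."""

    label: str
    response: str
    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.predictors)) != len(self.predictors):
            raise ValidationError(f"{self.label}: duplicate predictors")
        if self.response in self.predictors:
            raise ValidationError(f"{self.label}: response cannot be a predictor")


@dataclass
class ModelStats:
    """One row of the validation report for a fitted model."""

    label: str
    response: str
    predictors: tuple[str, ...]
    n: int
    p: int
    r2: float
    r2_adj: float
    r2_pred: float
    press: float
    press_loo: float
    q2_loo: float
    ss: float
    mse: float
    fvalue: float
    p_value: float
    vif: dict[str, float]
    max_vif: float
    press_ss_ratio: float = field(init=False)
    perfect_fit: bool = False
    infinite_vif: bool = False

    def __post_init__(self) -> None:
        self.press_ss_ratio = self.press / self.ss

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "response": self.response,
            "predictors": self.predictors,
            "n": self.n,
            "p": self.p,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "r2_pred": self.r2_pred,
            "press": self.press,
            "press_loo": self.press_loo,
            "q2_loo": self.q2_loo,
            "ss": self.ss,
            "mse": self.mse,
            "fvalue": self.fvalue,
            "p_value": self.p_value,
            "max_vif": self.max_vif,
            "press_ss_ratio": self.press_ss_ratio,
        }
        return d


def enumerate_models(
    grouping: DescriptorGrouping | Mapping[str, Sequence[str]] | None = None,
    responses: Sequence[str] = ("log_bb", "log_bb_star"),
    include_flexibility: str = "with",
    lipophilicity: str = "log_km_over_kam",
    starred_bases: Sequence[str] = DEFAULT_STARRED_BASES,
) -> list[ModelSpec]:
    """Enumerate candidate model specifications from the group template.

    With the flexibility descriptor ("with"): one model per
    response x group-I member x group-II member combination, labelled
    M1, M2, ... in that nesting order.  "without" returns the starred
    variants obtained by dropping the group-III descriptor from the
    models named in ``starred_bases``; "both" concatenates the two.
    """
    if include_flexibility not in ("with", "without", "both"):
        raise ValidationError(f"include_flexibility must be with/without/both, got {include_flexibility!r}")
    if grouping is None:
        groups: Mapping[str, Sequence[str]] = PAPER_GROUPS
    elif isinstance(grouping, DescriptorGrouping):
        groups = {k: list(v) for k, v in grouping.groups.items()}
    else:
        groups = grouping
    for key in ("I", "II", "III"):
        if key not in groups or not groups[key]:
            raise ValidationError(f"grouping must provide a non-empty group {key}")
    g1, g2, g3 = list(groups["I"]), list(groups["II"]), list(groups["III"])
    flex = g3[0]

    full: list[ModelSpec] = []
    i = 1
    for resp in responses:
        for d1 in g1:
            for d2 in g2:
                full.append(
                    ModelSpec(
                        label=f"M{i}",
                        response=resp,
                        predictors=(lipophilicity, d1, flex, d2),
                    )
                )
                i += 1
    if include_flexibility == "with":
        return full

    by_label = {s.label: s for s in full}
    starred = []
    for base in starred_bases:
        if base not in by_label:
            raise ValidationError(f"starred base {base!r} not among enumerated models")
        s = by_label[base]
        starred.append(
            ModelSpec(
                label=f"{base}*",
                response=s.response,
                predictors=tuple(p for p in s.predictors if p != flex),
            )
        )
    if include_flexibility == "without":
        return starred
    return full + starred


class QSARModel:
    """Ordinary least squares QSAR model (with intercept) for one spec.

    Parameters
    ----------
    spec : ModelSpec
    table : pandas.DataFrame
        Descriptor table holding the response and all predictor columns;
        an optional ``compound_id`` column labels the observations.
    """

    def __init__(self, spec: ModelSpec, table: pd.DataFrame):
        missing = [c for c in (spec.response, *spec.predictors) if c not in table.columns]
        if missing:
            raise ValidationError(f"{spec.label}: table lacks column(s) {', '.join(missing)}")
        self.spec = spec
        self.table = table.reset_index(drop=True)
        self.endog = self.table[spec.response].to_numpy(dtype=float)
        self.exog = sm.add_constant(
            self.table[list(spec.predictors)].astype(float), has_constant="add"
        )
        n, p1 = self.exog.shape
        if n <= p1:
            raise ValidationError(
                f"{spec.label}: need more observations ({n}) than parameters ({p1})"
            )
        if np.linalg.matrix_rank(self.exog.to_numpy()) < p1:
            raise SingularFitError(f"{spec.label}: design matrix is rank deficient")
        self.compound_ids = (
            self.table["compound_id"].to_numpy()
            if "compound_id" in self.table.columns
            else np.arange(1, n + 1)
        )

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        response: str,
        predictors: Sequence[str],
        label: str | None = None,
    ) -> "QSARModel":
        spec = ModelSpec(label=label or response, response=response, predictors=tuple(predictors))
        return cls(spec, table)

    def fit(self) -> "QSARResults":
        """Fit by OLS and return a :class:`QSARResults`."""
        res = sm.OLS(self.endog, self.exog).fit()
        return QSARResults(self, res)


def _hat_diagonal(X: np.ndarray) -> np.ndarray:
    """Diagonal of the hat matrix X (X'X)^-1 X' via a thin QR."""
    Q, _ = np.linalg.qr(X)
    return np.einsum("ij,ij->i", Q, Q)


class QSARResults:
    """Fitted QSAR model: coefficients, diagnostics and the validation battery.

    Point estimates and their standard errors come from the OLS fit; the
    cross-validation and collinearity layer (PRESS, predicted R2, VIF,
    leverages, standardized coefficients) is computed here from the hat
    matrix and auxiliary regressions.
    """

    def __init__(self, model: QSARModel, olsres):
        self.model = model
        self.spec = model.spec
        self._ols = olsres
        self.nobs = int(olsres.nobs)
        self.n_predictors = len(model.spec.predictors)
        self.params = olsres.params
        self.bse = olsres.bse
        self.fittedvalues = np.asarray(olsres.fittedvalues, dtype=float)
        self.resid = np.asarray(olsres.resid, dtype=float)
        self.leverages = _hat_diagonal(model.exog.to_numpy(dtype=float))

    # -- goodness of fit ---------------------------------------------------

    @property
    def ss_total(self) -> float:
        """SS: total sum of squared deviations of the response from its mean."""
        y = self.model.endog
        return float(np.sum((y - y.mean()) ** 2))

    @property
    def ss_resid(self) -> float:
        return float(self.resid @ self.resid)

    @property
    def rsquared(self) -> float:
        return 1.0 - self.ss_resid / self.ss_total

    @property
    def rsquared_adj(self) -> float:
        n, p = self.nobs, self.n_predictors
        return 1.0 - (1.0 - self.rsquared) * (n - 1) / (n - p - 1)

    @property
    def df_resid(self) -> int:
        return self.nobs - self.n_predictors - 1

    @property
    def mse(self) -> float:
        """Residual mean square RSS/(n - p - 1)."""
        return self.ss_resid / self.df_resid

    @property
    def fvalue(self) -> float:
        r2, p, dfr = self.rsquared, self.n_predictors, self.df_resid
        if r2 >= 1.0:
            return math.inf
        return (r2 / p) / ((1.0 - r2) / dfr)

    @property
    def f_pvalue(self) -> float:
        if math.isinf(self.fvalue):
            return 0.0
        return float(_spstats.f.sf(self.fvalue, self.n_predictors, self.df_resid))

    # -- leave-one-out cross-validation ------------------------------------

    @property
    def press(self) -> float:
        """Leave-one-out PRESS via the hat-matrix shortcut sum (e_i/(1-h_i))^2.

        Identical to refitting the model n times with one observation
        withheld each time (the algebraic LOO identity for linear models).
        """
        h = self.leverages
        if np.any(h >= 1.0 - 1e-12):
            raise DegenerateLeverageError(
                "a leverage equals 1: leave-one-out residual undefined"
            )
        loo = self.resid / (1.0 - h)
        return float(loo @ loo)

    @property
    def rsquared_pred(self) -> float:
        """Predicted R2 = 1 - PRESS/SS (a.k.a. Q2 of leave-one-out CV)."""
        return 1.0 - self.press / self.ss_total

    q2_loo = rsquared_pred

    def loo_residuals(self) -> np.ndarray:
        """Per-compound leave-one-out prediction residuals e_i/(1-h_i)."""
        return self.resid / (1.0 - self.leverages)

    # -- collinearity -------------------------------------------------------

    def vif(self) -> pd.Series:
        """Variance inflation factor 1/(1 - R2_j) per predictor.

        R2_j is the coefficient of determination of the auxiliary OLS of
        predictor j on the remaining predictors (with intercept).
        Perfectly collinear predictors yield ``inf``.
        """
        preds = list(self.spec.predictors)
        if len(preds) < 2:
            raise ValidationError("VIF requires at least two predictors")
        out = {}
        X = self.model.table[preds].to_numpy(dtype=float)
        n = X.shape[0]
        for j, name in enumerate(preds):
            xj = X[:, j]
            others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
            beta, *_ = np.linalg.lstsq(others, xj, rcond=None)
            resid = xj - others @ beta
            ssj = np.sum((xj - xj.mean()) ** 2)
            r2j = 1.0 - (resid @ resid) / ssj
            out[name] = math.inf if r2j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2j)
        return pd.Series(out, name="VIF")

    @property
    def max_vif(self) -> float:
        return float(self.vif().max())

    # -- effect sizes -------------------------------------------------------

    def standardized_coefficients(self) -> pd.Series:
        """Standardized (beta) coefficients b_j = a_j * sd(x_j)/sd(y).

        Sample standard deviations (n-1 denominator); scale-invariant
        measures of each descriptor's relative influence on the response.
        """
        y_sd = float(self.model.endog.std(ddof=1))
        out = {}
        for name in self.spec.predictors:
            x = self.model.table[name].to_numpy(dtype=float)
            x_sd = float(x.std(ddof=1))
            if x_sd == 0:
                raise ValidationError(f"predictor {name!r} is constant")
            out[name] = float(self.params[name]) * x_sd / y_sd
        return pd.Series(out, name="standardized_coef")

    # -- prediction ---------------------------------------------------------

    def predict(self, record: Mapping[str, float] | pd.Series) -> tuple[float, float, bool]:
        """Predict the response for a new compound record.

        Returns ``(y_hat, leverage, in_domain)`` where the leverage is
        computed against the training design and ``in_domain`` tests it
        against the warning leverage h* = 3(p+1)/n.
        """
        try:
            x = np.array([1.0] + [float(record[p]) for p in self.spec.predictors])
        except KeyError as exc:
            raise ValidationError(f"record lacks predictor {exc.args[0]!r}") from exc
        X = self.model.exog.to_numpy(dtype=float)
        yhat = float(x @ self.params.to_numpy())
        lev = float(x @ np.linalg.solve(X.T @ X, x))
        h_star = 3.0 * (self.n_predictors + 1) / self.nobs
        return yhat, lev, lev <= h_star

    # -- reporting ----------------------------------------------------------

    def stats(self) -> ModelStats:
        """Assemble the full validation-statistic record (one report row)."""
        if self.ss_total == 0:
            raise ValidationError("zero response variance: SS = 0")
        vifs = self.vif().to_dict() if self.n_predictors >= 2 else {}
        max_vif = max(vifs.values()) if vifs else float("nan")
        press = self.press
        return ModelStats(
            label=self.spec.label,
            response=self.spec.response,
            predictors=self.spec.predictors,
            n=self.nobs,
            p=self.n_predictors,
            r2=self.rsquared,
            r2_adj=self.rsquared_adj,
            r2_pred=self.rsquared_pred,
            press=press,
            press_loo=press,
            q2_loo=self.rsquared_pred,
            ss=self.ss_total,
            mse=self.mse,
            fvalue=self.fvalue,
            p_value=self.f_pvalue,
            vif=vifs,
            max_vif=max_vif,
            perfect_fit=self.rsquared >= 1.0 - 1e-14,
            infinite_vif=any(math.isinf(v) for v in vifs.values()),
        )

    def equation(self, decimals: int = 3) -> str:
        """Format the fitted equation with SEs in parentheses."""
        terms = [f"{self.params['const']:.{decimals}f}({self.bse['const']:.{decimals}f})"]
        for name in self.spec.predictors:
            a, se = self.params[name], self.bse[name]
            sign = "-" if a < 0 else "+"
            terms.append(f"{sign} {abs(a):.{decimals}f}({se:.{decimals}f}) {name}")
        return f"{self.spec.label}: {self.spec.response} = " + " ".join(terms)

    def summary(self) -> str:
        """Human-readable summary: equation, fit and validation statistics."""
        s = self.stats()
        lines = [
            self.equation(),
            f"n = {s.n}, predictors = {s.p}",
            f"R2 = {s.r2:.4f}   R2_adj = {s.r2_adj:.4f}   R2_pred = {s.r2_pred:.4f}",
            f"PRESS = {s.press:.4f}   SS = {s.ss:.4f}   PRESS/SS = {s.press_ss_ratio:.4f}",
            f"MSE = {s.mse:.4f}   F({s.p}, {s.n - s.p - 1}) = {s.fvalue:.1f}   p = {s.p_value:.5f}",
            "VIF: " + ", ".join(f"{k} = {v:.1f}" for k, v in s.vif.items()),
        ]
        return "\n".join(lines)


def fit_mlr(spec: ModelSpec, table: pd.DataFrame) -> QSARResults:
    """Fit one candidate model specification on a descriptor table."""
    return QSARModel(spec, table).fit()


@dataclass(frozen=True)
class ScreeningRules:
    """Model screening thresholds.

    ``vif_max`` is compared against the maximum VIF rounded to 1 decimal
    (the precision at which VIFs are reported); a model is excluded when
    the rounded value reaches the threshold.
    """

    vif_max: float = 5.0
    q2_min: float = 0.6
    press_ss_max: float = 0.4


@dataclass
class ScreeningResult:
    excluded: list[str]
    flagged: list[str]
    ranked: list[ModelStats]

    @property
    def shortlist(self) -> list[str]:
        return [s.label for s in self.ranked]


def screen_models(
    stats: Iterable[ModelStats],
    rules: ScreeningRules = ScreeningRules(),
) -> ScreeningResult:
    """Apply the collinearity and predictivity screening rules.

    Models whose (1-decimal rounded) max VIF reaches ``vif_max`` are
    excluded; survivors failing Q2 > q2_min or PRESS/SS < press_ss_max are
    flagged.  Unflagged survivors are ranked by higher predicted R2, then
    lower PRESS.
    """
    stats = list(stats)
    if not stats:
        raise ValidationError("no model statistics to screen")
    excluded, flagged, survivors = [], [], []
    for s in stats:
        vif_reported = round(s.max_vif, 1) if math.isfinite(s.max_vif) else math.inf
        if vif_reported >= rules.vif_max:
            excluded.append(s.label)
            continue
        if not (s.q2_loo > rules.q2_min or s.press_ss_ratio < rules.press_ss_max):
            flagged.append(s.label)
            continue
        survivors.append(s)
    survivors.sort(key=lambda s: (-s.r2_pred, s.press))
    return ScreeningResult(excluded=excluded, flagged=flagged, ranked=survivors)
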