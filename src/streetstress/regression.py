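"""Element–stress multiple linear regression with collinearity and
autocorrelation diagnostics.

The consensus stress score is regressed on the coverage fractions of the
eight most influential visual elements (road, sky, building, vegetation,
sidewalk, auto/car, wall, grass/terrain by default). Reported per predictor:
the raw coefficient, the standardized beta (coefficient scaled by
SD(x)/SD(y), unit-free and comparable across elements), its standard error,
t statistic, two-sided p-value, and variance inflation factor
VIF_j = 1 / (1 - R^2_j) from regressing x_j on the other predictors.
Global diagnostics: R^2, adjusted R^2, and the Durbin–Watson statistic
computed in an explicit case order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .composition import canonical_class

#: Default predictors: the top-eight elements, canonical class names.
DEFAULT_PREDICTORS = ("road", "sky", "building", "vegetation", "sidewalk",
                      "car", "wall", "terrain")


def vif(X) -> np.ndarray:
    """Variance inflation factors via the auxiliary-regression definition.

    For each column j, regress x_j on the remaining columns (with intercept)
    and return 1 / (1 - R^2_j). Perfectly collinear columns give inf.
    """
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        others = sm.add_constant(np.delete(X, j, axis=1)) if p > 1 else np.ones((n, 1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[j] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def durbin_watson(residuals, order=None) -> float:
    """Durbin–Watson statistic sum (e_t - e_{t-1})^2 / sum e_t^2.

    ``order`` is an explicit case ordering (default: the given order, i.e.
    ascending point id when residuals come from an id-sorted fit). All-zero
    residuals leave the statistic undefined.
    """
    e = np.asarray(residuals, float).ravel()
    if len(e) < 2:
        raise ValueError("need at least 2 residuals")
    if order is not None:
        e = e[np.asarray(order)]
    denom = float((e**2).sum())
    if denom == 0:
        raise ValueError("all-zero residuals: Durbin-Watson undefined")
    return float((np.diff(e) ** 2).sum() / denom)


class StressRegression:
    """OLS model of consensus stress on element coverage fractions.

    Parameters
    ----------
    data : DataFrame
        Must contain the response column and every predictor column
        (survey aliases like 'grass' and 'auto' are accepted).
    response : str
        Response column name (default 'score').
    predictors : sequence of str
        Predictor columns; defaults to the top-eight elements.
    """

    def __init__(self, data: pd.DataFrame, response: str = "score",
                 predictors=DEFAULT_PREDICTORS):
        self.predictors = []
        for name in predictors:
            col = name if name in data.columns else canonical_class(name)
            if col not in data.columns:
                raise ValueError(f"predictor column {name!r} not in data")
            self.predictors.append(col)
        if response not in data.columns:
            raise ValueError(f"response column {response!r} not in data")
        self.response = response
        self.data = data
        self.X = data[self.predictors].to_numpy(float)
        self.y = data[response].to_numpy(float)
        n, p = self.X.shape
        if n <= p + 1:
            raise ValueError("need n > p + 1 observations")
        rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), self.X]))
        if rank < p + 1:
            bad = [
                self.predictors[j]
                for j in range(p)
                if np.linalg.matrix_rank(np.column_stack([np.ones(n), np.delete(self.X, j, 1)]))
                == rank
            ]
            raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str = "score",
                       predictors=DEFAULT_PREDICTORS) -> "StressRegression":
        return cls(data, response=response, predictors=predictors)

    def fit(self, dw_order=None) -> "StressRegressionResults":
        ols = sm.OLS(self.y, sm.add_constant(self.X)).fit()
        return StressRegressionResults(self, ols, dw_order=dw_order)


class StressRegressionResults:
    """Fitted element–stress regression.

    Attributes
    ----------
    params, bse, tvalues, pvalues : per-term arrays (intercept first).
    std_beta : standardized betas per predictor (no intercept).
    vif : variance inflation factors per predictor.
    rsquared, rsquared_adj, dw, nobs : global fit statistics.
    """

    def __init__(self, model: StressRegression, ols_results, dw_order=None):
        self.model = model
        self._ols = ols_results
        self.params = np.asarray(ols_results.params)
        self.bse = np.asarray(ols_results.bse)
        self.tvalues = np.asarray(ols_results.tvalues)
        self.pvalues = np.asarray(ols_results.pvalues)
        self.rsquared = float(ols_results.rsquared)
        self.rsquared_adj = float(ols_results.rsquared_adj)
        self.resid = np.asarray(ols_results.resid)
        self.nobs = int(ols_results.nobs)
        sx = model.X.std(axis=0, ddof=0)
        sy = model.y.std(ddof=0)
        self.std_beta = self.params[1:] * sx / sy
        self.vif = vif(model.X)
        self.dw = durbin_watson(self.resid, order=dw_order)

    def coefficient_table(self) -> pd.DataFrame:
        terms = ["intercept", *self.model.predictors]
        table = pd.DataFrame(
            {
                "term": terms,
                "coef": self.params,
                "std_beta": np.concatenate([[np.nan], self.std_beta]),
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "VIF": np.concatenate([[np.nan], self.vif]),
            }
        )
        return table

    def summary(self) -> str:
        lines = [
            "Element-stress multiple linear regression",
            f"  n = {self.nobs}, R^2 = {self.rsquared:.3f}, "
            f"adj R^2 = {self.rsquared_adj:.3f}, D-W = {self.dw:.3f}",
            "",
            f"  {'term':<12}{'coef':>10}{'std beta':>10}{'SE':>9}"
            f"{'t':>9}{'p':>10}{'VIF':>8}",
        ]
        for _, r in self.coefficient_table().iterrows():
            stars = "*" if r["p"] < 0.05 else " "
            sb = f"{r['std_beta']:>10.3f}" if np.isfinite(r["std_beta"]) else " " * 10
            vf = f"{r['VIF']:>8.2f}" if np.isfinite(r["VIF"]) else " " * 8
            lines.append(
                f"  {r['term']:<12}{r['coef']:>10.3f}{sb}{r['se']:>9.3f}"
                f"{r['t']:>9.2f}{r['p']:>10.4f}{vf}{stars}"
            )
        return "\n".join(lines)

    def plot_std_betas(self, ax=None):
        """Horizontal bar chart of standardized betas, signed by effect."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = self.model.predictors
        colors = ["steelblue" if b > 0 else "indianred" for b in self.std_beta]
        ax.barh(names, self.std_beta, color=colors)
        ax.axvline(0, color="k", lw=0.8)
        ax.set_xlabel("standardized beta")
        return ax


def ols_fit(X, y, predictor_names=None) -> StressRegressionResults:
    """Fit from raw arrays; a thin wrapper building the model DataFrame."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    names = list(predictor_names) if predictor_names is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]
    data = pd.DataFrame(X, columns=names)
    data["score"] = np.asarray(y, float)
    return StressRegression(data, response="score", predictors=names).fit()
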