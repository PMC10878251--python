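"""Emergent variables and the standardized multiple-regression suite.

The per-step census counts are converted into percentage-scale emergent
variables (disease prevalence, rate of care, strategy shares, age
structure, reproductive rate).  Endpoint analysis fits ordinary least
squares on the per-combination summary table and reports standardized
coefficients (beta = b * SD(x) / SD(y)), the t and two-sided p values of
the unstandardized fit, and model-level R2 / F.  Alpha is 0.05 throughout;
no multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "STEP_VARIABLES",
    "RegressionResult",
    "compute_step_variables",
    "fit_standardized_ols",
    "regression_suite",
]

STEP_VARIABLES = (
    "prevalence",
    "rate_of_care",
    "pct_acquired",
    "pct_innate",
    "pct_immature",
    "pct_mature",
    "reproductive_rate",
)

ALPHA = 0.05


def compute_step_variables(records: pd.DataFrame) -> pd.DataFrame:
    """Percentage-scale emergent variables from per-step census counts.

    prevalence        : % of living agents infected this step, from the
                        post-transmission census
    rate_of_care      : % of those infected agents that received care;
                        0 when none were infected
    pct_acquired      : % prioritizing the acquired arm (pct_innate mirrors)
    pct_immature      : % aged under 15 (pct_mature mirrors)
    reproductive_rate : % of mature agents that reproduced this step

    Raises ``ValueError`` on any step with an empty population.
    """
    if (records["n_total"] <= 0).any():
        raise ValueError("cannot compute emergent variables for an empty population")
    n_total = records["n_total"].to_numpy(dtype=float)
    n_infected = records["n_infected"].to_numpy(dtype=float)
    n_census = records["n_alive_at_census"].to_numpy(dtype=float)
    n_mature = records["n_mature"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate_of_care = np.where(
            n_infected > 0,
            100.0 * records["n_cared_for"].to_numpy(dtype=float) / n_infected,
            0.0,
        )
        reproductive_rate = np.where(
            n_mature > 0,
            100.0 * records["n_reproduced"].to_numpy(dtype=float) / n_mature,
            0.0,
        )
    out = pd.DataFrame(
        {
            "prevalence": 100.0 * n_infected / np.maximum(n_census, 1.0),
            "rate_of_care": rate_of_care,
            "pct_acquired": 100.0 * records["n_acquired_priority"] / n_total,
            "pct_innate": 100.0 * records["n_innate_priority"] / n_total,
            "pct_immature": 100.0 * records["n_immature"] / n_total,
            "pct_mature": 100.0 * records["n_mature"] / n_total,
            "reproductive_rate": reproductive_rate,
        },
        index=records.index,
    )
    return out


@dataclass
class RegressionResult:
    """One fitted multiple regression with standardized coefficients.

    ``std_coef`` carries the sign; the conventional table prints |beta|
    with the sign shown by t (see :meth:`to_frame`).
    """

    response: str
    predictors: list[str]
    std_coef: pd.Series       # signed standardized coefficients
    coef: pd.Series           # unstandardized coefficients
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n_obs: int
    dropped: list[str] = field(default_factory=list)

    def significant(self, alpha: float = ALPHA) -> pd.Series:
        return self.pvalues < alpha

    def to_frame(self) -> pd.DataFrame:
        """Predictor table: absolute beta, t (carrying the sign), p."""
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "beta": self.std_coef.abs().to_numpy(),
                "t": self.tvalues.to_numpy(),
                "p": self.pvalues.to_numpy(),
                "significant": (self.pvalues < ALPHA).to_numpy(),
            }
        )

    def model_row(self) -> dict:
        return {
            "response": self.response,
            "r_squared": self.r_squared,
            "f_statistic": self.f_statistic,
            "f_pvalue": self.f_pvalue,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "n_obs": self.n_obs,
        }


def fit_standardized_ols(
    table: pd.DataFrame, response: str, predictors: list[str]
) -> RegressionResult:
    """OLS with intercept; coefficients reported on the standardized scale.

    Constant-valued predictors are dropped with a warning.  A
    rank-deficient design raises ``ValueError`` naming the predictors
    involved in the collinearity.
    """
    predictors = list(predictors)
    y = table[response].astype(float)
    X = table[predictors].astype(float)

    constant = [c for c in predictors if X[c].nunique() <= 1]
    if constant:
        warnings.warn(
            f"dropping constant predictor(s): {', '.join(constant)}",
            UserWarning,
            stacklevel=2,
        )
        predictors = [c for c in predictors if c not in constant]
        X = X[predictors]
    if not predictors:
        raise ValueError("no non-constant predictors left to fit")
    if len(table) < len(predictors) + 2:
        raise ValueError(
            f"need at least {len(predictors) + 2} rows to fit "
            f"{len(predictors)} predictors; got {len(table)}"
        )

    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        collinear = _collinear_predictors(X)
        raise ValueError(
            "rank-deficient design; collinear predictor(s): "
            + ", ".join(collinear)
        )

    fit = sm.OLS(y, design).fit()
    sd_y = y.std(ddof=1)
    sd_x = X.std(ddof=1)
    std_coef = fit.params[predictors] * sd_x / sd_y
    return RegressionResult(
        response=response,
        predictors=predictors,
        std_coef=std_coef,
        coef=fit.params[predictors],
        tvalues=fit.tvalues[predictors],
        pvalues=fit.pvalues[predictors],
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n_obs=int(fit.nobs),
        dropped=constant,
    )


def _collinear_predictors(X: pd.DataFrame) -> list[str]:
    """Predictors whose removal does not lower the design rank."""
    full_rank = np.linalg.matrix_rank(X.to_numpy())
    involved = []
    for column in X.columns:
        reduced = X.drop(columns=column).to_numpy()
        if np.linalg.matrix_rank(reduced) == full_rank:
            involved.append(column)
    return involved or list(X.columns)


# predictor blocks used by the endpoint analysis
_BASE = ["transmissibility_pct", "disease_mortality_pct", "extrinsic_mortality_pct"]
PREVALENCE_PREDICTORS = _BASE + ["rate_of_care", "care_intensity"]
STRATEGY_PREDICTORS = _BASE + ["prevalence", "rate_of_care"]
PACE_PREDICTORS = _BASE + ["prevalence", "rate_of_care", "care_intensity"]


def regression_suite(summaries: pd.DataFrame) -> dict[str, RegressionResult]:
    """The full endpoint analysis on a per-combination summary table.

    Fits: (a) disease prevalence on the swept parameters plus rate of care
    over all surviving combinations; (b) the acquired- and innate-priority
    shares on disease characteristics, prevalence and rate of care within
    each care-intensity stratum; (c) the age-structure and reproductive
    rate models over all combinations.
    """
    results: dict[str, RegressionResult] = {}
    results["prevalence"] = fit_standardized_ols(
        summaries, "prevalence", PREVALENCE_PREDICTORS
    )
    for level in sorted(summaries["care_intensity"].unique()):
        stratum = summaries[summaries["care_intensity"] == level]
        for response in ("pct_acquired", "pct_innate"):
            key = f"{response}_care{int(level)}"
            results[key] = fit_standardized_ols(
                stratum, response, STRATEGY_PREDICTORS
            )
    for response in ("pct_immature", "pct_mature", "reproductive_rate"):
        results[response] = fit_standardized_ols(
            summaries, response, PACE_PREDICTORS
        )
    return results
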