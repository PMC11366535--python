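"""Fixed-effects models of carcass unit price.

Two analyses are provided, mirroring standard carcass-pricing practice:

* the full model  UP = date + month-of-age + sex + farm + MQ + IAT + MQxIAT
  with a per-term F table (marginal, full-vs-reduced comparisons), and
* per-meat-quality-grade models  UP = date + month-of-age + sex + IAT
  reporting the standardized partial regression coefficient of the image
  trait, b * SD(IAT) / SD(UP), together with its t statistic (both are
  reported because published tables of "standardized coefficients" for such
  models sometimes carry t-scale magnitudes).

Designs use full dummy coding per factor plus an intercept; rank-deficient
systems are solved by the minimum-norm least-squares solution, so estimable
functions (fitted values, the covariate coefficient, F statistics) do not
depend on reference-level choices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelSpec",
    "FittedModel",
    "fit_fixed_effects_model",
    "anova_f_table",
    "standardized_coefficients",
]


@dataclass
class ModelSpec:
    """Terms of a fixed-effects price model.

    ``factors`` are categorical columns; ``covariate`` the (single)
    continuous image trait; ``interaction_factor`` adds factor-by-covariate
    product terms (the MQ x IAT interaction of the full model).
    """

    response: str = "UP"
    factors: tuple = ("date", "age", "sex", "farm", "MQ")
    covariate: str | None = None
    interaction_factor: str | None = None

    def __post_init__(self) -> None:
        if not self.factors and self.covariate is None:
            raise ValueError("model needs at least one term")
        if self.interaction_factor is not None:
            if self.covariate is None or self.interaction_factor not in self.factors:
                raise ValueError(
                    "interaction needs the covariate and a factor already in the model"
                )

    @property
    def terms(self) -> tuple:
        out = list(self.factors)
        if self.covariate:
            out.append(self.covariate)
        if self.interaction_factor:
            out.append(f"{self.interaction_factor}x{self.covariate}")
        return tuple(out)


@dataclass
class FittedModel:
    """Minimum-norm least-squares fit with design metadata."""

    coefficients: pd.Series
    rss: float
    df_resid: int
    rank: int
    n_obs: int
    response_sd: float
    covariate_sd: float | None
    term_columns: dict = field(repr=False, default_factory=dict)
    xtx_pinv: np.ndarray | None = field(repr=False, default=None)

    @property
    def residual_variance(self) -> float:
        return self.rss / self.df_resid


def _build_design(df: pd.DataFrame, spec: ModelSpec):
    """Design matrix with full per-factor dummy coding and an intercept.

    Returns (X, column labels, {term: column index list}).  Factors with a
    single observed level are dropped with a warning (they are aliased with
    the intercept).
    """
    n = len(df)
    cols = [np.ones(n)]
    labels = ["Intercept"]
    term_cols: dict = {}
    for f in spec.factors:
        cat = pd.Categorical(df[f])
        if len(cat.categories) < 2:
            warnings.warn(f"factor {f!r} has one observed level; term dropped", stacklevel=3)
            continue
        idx = []
        for k, lev in enumerate(cat.categories):
            cols.append((cat.codes == k).astype(float))
            labels.append(f"{f}[{lev}]")
            idx.append(len(labels) - 1)
        term_cols[f] = idx
    if spec.covariate:
        x = df[spec.covariate].to_numpy(dtype=float)
        cols.append(x)
        labels.append(spec.covariate)
        term_cols[spec.covariate] = [len(labels) - 1]
        if spec.interaction_factor:
            # effect-coded (sum-to-zero) contrasts: keeps the covariate main
            # effect estimable as the level-averaged slope
            cat = pd.Categorical(df[spec.interaction_factor])
            levs = cat.categories
            idx = []
            for k, lev in enumerate(levs[:-1]):
                contrast = (cat.codes == k).astype(float)
                contrast -= (cat.codes == len(levs) - 1).astype(float)
                cols.append(contrast * x)
                labels.append(f"{spec.interaction_factor}[{lev}-avg]x{spec.covariate}")
                idx.append(len(labels) - 1)
            term_cols[f"{spec.interaction_factor}x{spec.covariate}"] = idx
    return np.column_stack(cols), labels, term_cols


def _lstsq(x: np.ndarray, y: np.ndarray):
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return coef, float(resid @ resid), int(rank)


def fit_fixed_effects_model(records: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Least-squares fit of the model; minimum-norm under rank deficiency."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    y = records[spec.response].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing response values")
    x, labels, term_cols = _build_design(records, spec)
    coef, rss, rank = _lstsq(x, y)
    if len(y) <= rank:
        raise ValueError("no residual degrees of freedom (n <= design rank)")
    cov_sd = (
        float(np.std(records[spec.covariate].to_numpy(dtype=float), ddof=1))
        if spec.covariate
        else None
    )
    return FittedModel(
        coefficients=pd.Series(coef, index=labels),
        rss=rss,
        df_resid=len(y) - rank,
        rank=rank,
        n_obs=len(y),
        response_sd=float(np.std(y, ddof=1)),
        covariate_sd=cov_sd,
        term_columns=term_cols,
        xtx_pinv=np.linalg.pinv(x.T @ x),
    )


def anova_f_table(records: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Marginal (drop-one-term) F tests for every term of the model.

    Each term's F compares the full model with the model refitted without
    that term's columns; a term whose removal does not change the design
    rank is aliased and reported with NaN.  Significance flags: '*' p<0.05,
    '**' p<0.01 .
    """
    y = records[spec.response].to_numpy(dtype=float)
    x, labels, term_cols = _build_design(records, spec)
    _, rss_full, rank_full = _lstsq(x, y)
    df_resid = len(y) - rank_full
    if df_resid <= 0:
        raise ValueError("model saturates the data; no residual df")
    rows = []
    for term in spec.terms:
        if term not in term_cols:
            continue
        keep = np.ones(x.shape[1], dtype=bool)
        keep[term_cols[term]] = False
        _, rss_red, rank_red = _lstsq(x[:, keep], y)
        df_num = rank_full - rank_red
        if df_num == 0:
            rows.append({"term": term, "df": 0, "F": np.nan, "p": np.nan, "signif": ""})
            continue
        f_val = ((rss_red - rss_full) / df_num) / (rss_full / df_resid)
        p = float(stats.f.sf(f_val, df_num, df_resid))
        flag = "**" if p < 0.01 else ("*" if p < 0.05 else "")
        rows.append({"term": term, "df": df_num, "F": f_val, "p": p, "signif": flag})
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["df_resid"] = df_resid
    return out


def standardized_coefficients(
    records: pd.DataFrame,
    mq: object,
    iat: str,
    response: str = "UP",
    factors: tuple = ("date", "age", "sex"),
    mq_column: str = "MQ",
) -> pd.Series:
    """Standardized partial regression coefficient of one trait, within one MQ.

    Fits  UP = date + age + sex + IAT  on the records of a single meat
    quality grade (farm excluded — per-grade cells are too sparse for farm)
    and returns the coefficient b, the standardized coefficient
    b*SD(IAT)/SD(UP), its t statistic and two-sided p-value.
    """
    sub = records[records[mq_column] == mq]
    if len(sub) == 0:
        raise ValueError(f"no records at {mq_column} == {mq!r}")
    x_sd = float(np.std(sub[iat].to_numpy(dtype=float), ddof=1))
    if x_sd == 0:
        raise ValueError(f"covariate {iat!r} has zero variance in the {mq!r} subset")
    spec = ModelSpec(response=response, factors=factors, covariate=iat)
    fit = fit_fixed_effects_model(sub, spec)
    j = fit.coefficients.index.get_loc(iat)
    b = float(fit.coefficients.iloc[j])
    se = float(np.sqrt(fit.residual_variance * fit.xtx_pinv[j, j]))
    t = b / se
    return pd.Series(
        {
            "n": len(sub),
            "b": b,
            "standardized_coefficient": b * x_sd / fit.response_sd,
            "t": t,
            "p": float(2 * stats.t.sf(abs(t), fit.df_resid)),
        }
    )
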