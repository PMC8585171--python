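"""Statistical linkage between microstructure and mechanics.

Two families of analyses:

* a fixed-effects factorial ANOVA of each microstructure parameter on
  region (SA/SP/IA/IP) x side (left/right) x vertebral level (C2-C7),
  with Type III sums of squares, partial eta-squared effect sizes
  (reported as Eta% = 100 * SS_effect / (SS_effect + SS_error)), a
  Bartlett pre-test of variance homogeneity across cells, and
  simple-effects follow-ups within strata;
* per-pair linear regressions of a mechanical property on a
  microstructure parameter (OLS with adjusted R-squared and the Pearson
  p-value), plus a standardized ridge option for the multi-predictor
  bone-strength question.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "AnovaResult",
    "RegressionResult",
    "SimpleEffect",
    "factorial_anova",
    "simple_effects",
    "regress",
    "ridge_regress",
]

DEFAULT_FACTORS = ("region", "side", "level")


@dataclass
class AnovaResult:
    """Per-term F, p and partial eta-squared of a factorial ANOVA."""

    table: pd.DataFrame  # index = terms; columns F, p, partial_eta_sq, eta_pct, df, sum_sq, significant
    ss_type: int
    alpha: float
    bartlett_stat: float
    bartlett_p: float
    response: str

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    adj_r_squared: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept,
                "r_squared": self.r_squared,
                "adj_r_squared": self.adj_r_squared,
                "p_value": self.p_value, "n": self.n}


@dataclass
class SimpleEffect:
    fixed_factor: str
    at_level: str
    test_factor: str
    f_stat: float
    p_value: float
    p_bonferroni: float
    df_num: int
    df_den: int
    skipped: bool = False
    note: str = ""


def _check_factors(table: pd.DataFrame, factors: Sequence[str],
                   response: str) -> None:
    for f in factors:
        if f not in table.columns:
            raise ValueError(f"factor column {f!r} missing")
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 observed levels")
    if response not in table.columns:
        raise ValueError(f"response column {response!r} missing")


def _bartlett_cells(table: pd.DataFrame, factors: Sequence[str],
                    response: str):
    """Bartlett homogeneity test across design cells with >= 2 obs."""
    groups = [g[response].to_numpy()
              for _, g in table.groupby(list(factors), observed=True)
              if len(g) >= 2 and g[response].var() > 0]
    if len(groups) < 2:
        return float("nan"), float("nan")
    stat, p = sps.bartlett(*groups)
    return float(stat), float(p)


def factorial_anova(table: pd.DataFrame, response: str,
                    factors: Sequence[str] = DEFAULT_FACTORS,
                    alpha: float = 0.05) -> AnovaResult:
    """Three-factor fixed-effects ANOVA with partial eta-squared.

    Type III sums of squares (sum-to-zero contrasts) by default; if the
    design has empty cells the fit falls back to Type II with a warning
    note on the result.  Terms: all main effects, two-way interactions
    and the highest-order interaction.
    """
    _check_factors(table, factors, response)
    if table.groupby(list(factors), observed=True).size().min() < 1:
        raise ValueError("each reported cell needs >= 1 observation")
    n_cells_full = int(np.prod([table[f].nunique() for f in factors]))
    n_cells_obs = table.groupby(list(factors), observed=True).ngroups
    empty_cells = n_cells_obs < n_cells_full
    if len(table) - n_cells_obs <= 0:
        raise ValueError(
            "no residual degrees of freedom: the full factorial model "
            f"has {n_cells_obs} cells for {len(table)} observations; "
            "at least one cell needs replication")

    df = table.copy()
    df["_y"] = df[response].astype(float)
    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    model = smf.ols(f"_y ~ {terms}", data=df).fit()
    ss_type = 2 if empty_cells else 3
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        aov = anova_lm(model, typ=ss_type)

    ss_err = float(aov.loc["Residual", "sum_sq"])
    rows = aov.drop(index="Residual")
    if "Intercept" in rows.index:
        rows = rows.drop(index="Intercept")

    def clean(term: str) -> str:
        return term.replace(", Sum)", ")").replace("C(", "").replace(")", "")

    ss = rows["sum_sq"].astype(float)
    tiny = 1e-12 * max(float(np.abs(df["_y"]).max()) ** 2, 1.0)
    F = rows["F"].astype(float)
    p = rows["PR(>F)"].astype(float)
    with np.errstate(invalid="ignore"):
        eta = ss / (ss + ss_err)
    # a term with no sum of squares has no effect even when the residual
    # variance is also zero (constant response)
    null_terms = ss < tiny
    F = F.where(~null_terms, 0.0)
    p = p.where(~null_terms, 1.0)
    eta = eta.where(~null_terms, 0.0)
    out = pd.DataFrame({
        "df": rows["df"].astype(float),
        "sum_sq": ss,
        "F": F,
        "p": p,
        "partial_eta_sq": eta,
    })
    out.index = [clean(t) for t in rows.index]
    out["eta_pct"] = 100.0 * out["partial_eta_sq"]
    out["significant"] = out["p"] < alpha
    b_stat, b_p = _bartlett_cells(table, factors, response)
    return AnovaResult(table=out, ss_type=ss_type, alpha=alpha,
                       bartlett_stat=b_stat, bartlett_p=b_p,
                       response=response)


def simple_effects(table: pd.DataFrame, fix_factor: str, test_factor: str,
                   response: str, pooled_error: bool = False,
                   factors: Sequence[str] = DEFAULT_FACTORS,
                   alpha: float = 0.05) -> List[SimpleEffect]:
    """One-way ANOVA of ``test_factor`` within each level of
    ``fix_factor`` (the simple-effects follow-up of a significant
    interaction).  ``pooled_error`` replaces the stratum error mean
    square by the full factorial model's.  Bonferroni-adjusted p-values
    (family = the set of strata) are reported alongside the raw ones.
    """
    _check_factors(table, [fix_factor, test_factor], response)
    levels = list(pd.unique(table[fix_factor]))
    n_tests = len(levels)
    mse_pool = df_pool = None
    if pooled_error:
        df = table.copy()
        df["_y"] = df[response].astype(float)
        terms = " * ".join(f"C({f}, Sum)" for f in factors)
        full = smf.ols(f"_y ~ {terms}", data=df).fit()
        df_pool = int(full.df_resid)
        mse_pool = float(full.ssr / full.df_resid)
    out: List[SimpleEffect] = []
    for lev in levels:
        stratum = table[table[fix_factor] == lev]
        groups = [g[response].to_numpy(dtype=float)
                  for _, g in stratum.groupby(test_factor, observed=True)]
        groups = [g for g in groups if g.size > 0]
        if len(groups) < 2 or all(g.size < 2 for g in groups):
            out.append(SimpleEffect(fix_factor, str(lev), test_factor,
                                    float("nan"), float("nan"), float("nan"),
                                    0, 0, skipped=True,
                                    note="fewer than 2 represented levels or "
                                         "single-observation cells"))
            continue
        k = len(groups)
        n = sum(g.size for g in groups)
        gm = np.concatenate(groups).mean()
        ss_b = sum(g.size * (g.mean() - gm) ** 2 for g in groups)
        df_b = k - 1
        if pooled_error and mse_pool is not None:
            ms_e, df_e = mse_pool, df_pool
        else:
            ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
            df_e = n - k
            if df_e <= 0:
                out.append(SimpleEffect(fix_factor, str(lev), test_factor,
                                        float("nan"), float("nan"),
                                        float("nan"), df_b, 0, skipped=True,
                                        note="no within-stratum error df"))
                continue
            ms_e = ss_w / df_e
        F = (ss_b / df_b) / ms_e if ms_e > 0 else float("inf")
        p = float(sps.f.sf(F, df_b, df_e))
        out.append(SimpleEffect(fix_factor, str(lev), test_factor,
                                float(F), p, min(1.0, p * n_tests),
                                df_b, int(df_e)))
    return out


def regress(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Simple OLS of a mechanical property on a microstructure value,
    with adjusted R-squared 1 - (1 - R^2)(n - 1)/(n - 2) and the
    two-sided Pearson p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    res = sps.linregress(x, y)
    r2 = res.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(r2), adj_r_squared=float(adj),
                            p_value=float(res.pvalue), n=n)


def ridge_regress(X: np.ndarray, y: np.ndarray,
                  lam: float = 1.0) -> Dict[str, np.ndarray]:
    """Ridge regression on standardized predictors.

    Solves ``(Z'Z + lam I) b = Z'y_c`` where Z are z-scored columns of X
    and y_c the centred response; at ``lam = 0`` this is exactly OLS on
    the standardized predictors.  Returns the standardized coefficients,
    their back-transformed raw-scale equivalents, and the intercept.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match rows of X")
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant predictor column")
    Z = (X - mu) / sd
    yc = y - y.mean()
    A = Z.T @ Z + lam * np.eye(p)
    beta_std = np.linalg.solve(A, Z.T @ yc)
    beta_raw = beta_std / sd
    intercept = float(y.mean() - beta_raw @ mu)
    return {"coef_standardized": beta_std, "coef": beta_raw,
            "intercept": intercept, "lam": lam}
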