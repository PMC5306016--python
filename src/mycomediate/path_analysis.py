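"""Small recursive path models (partial-correlation SEM) and marginal tests.

The models relate the relative abundance of AM woody plants (predictor) to
the relative abundance of AM herbaceous plants (response) while allowing a
covariate -- an inferred environmental axis or the herb/woody log response
ratio -- to influence both.  With standardized variables and the default
fully recursive structure (covariate -> predictor, covariate -> response,
predictor -> response) the maximum-likelihood path coefficients coincide
with standardized partial regression coefficients, which is what makes the
formulation a literal partial-correlation analysis.

Model fit is judged by chi_square = n * F_ML comparing the implied and
observed covariance (zero for saturated structures) and models are ranked
by AIC from the multivariate-normal log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .stats_core import AssociationTest, aic, kendall_tau

__all__ = [
    "PathModelFit",
    "three_variable_structure",
    "combined_structure",
    "fit_path_model",
    "select_model",
    "marginal_residual_test",
]


def three_variable_structure(covariate: str, predictor: str, response: str):
    """Fully recursive covariate/predictor/response DAG (saturated)."""
    return [
        (covariate, predictor),
        (covariate, response),
        (predictor, response),
    ]


def combined_structure(abiotic: str, biotic: str, predictor: str, response: str):
    """Saturated recursive DAG with one abiotic and one biotic covariate."""
    return [
        (abiotic, predictor),
        (biotic, predictor),
        (abiotic, response),
        (biotic, response),
        (predictor, response),
    ]


@dataclass
class PathModelFit:
    model_id: str
    paths: list  # (from, to, standardized coefficient, p)
    chi_square: float
    df: int
    p_fit: float
    loglik: float
    aic: float
    n: int
    variables: list = field(default_factory=list)


def _topo_order(variables, parents):
    order, seen = [], set()

    def visit(v, stack):
        if v in stack:
            raise ValueError("structure contains a cycle; model not identified")
        if v in seen:
            return
        for u in parents[v]:
            visit(u, stack | {v})
        seen.add(v)
        order.append(v)

    for v in variables:
        visit(v, set())
    return order


def fit_path_model(
    data: pd.DataFrame, structure, model_id: str = "model"
) -> PathModelFit:
    """ML fit of a recursive path model on standardized complete cases.

    ``structure`` is a list of (from, to) directed edges.  Each endogenous
    variable is regressed on its parents (OLS = Gaussian ML for recursive
    systems); exogenous variables keep their free sample (co)variances.
    """
    variables = []
    for f, t in structure:
        for v in (f, t):
            if v not in variables:
                variables.append(v)
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise ValueError(f"variables missing from data: {missing}")
    df_ = data[variables].dropna()
    n = len(df_)
    if n < 10:
        raise ValueError(f"need >= 10 complete cases, got {n}")
    Z = df_.to_numpy(float)
    sd = Z.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        raise ValueError("constant variable; covariance singular")
    Z = (Z - Z.mean(axis=0)) / sd
    p = len(variables)
    idx = {v: i for i, v in enumerate(variables)}
    parents = {v: [f for f, t in structure if t == v] for v in variables}
    _topo_order(variables, parents)  # cycle check

    S = (Z.T @ Z) / n  # ML covariance of standardized data
    B = np.zeros((p, p))
    psi = np.zeros((p, p))
    paths = []
    n_params = 0
    exog = [v for v in variables if not parents[v]]
    for v in variables:
        pa = parents[v]
        i = idx[v]
        if not pa:
            psi[i, i] = S[i, i]
            continue
        cols = [idx[u] for u in pa]
        Xp = Z[:, cols]
        yv = Z[:, i]
        g = Xp.T @ Xp
        try:
            coef = np.linalg.solve(g, Xp.T @ yv)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular covariance among parents") from exc
        resid = yv - Xp @ coef
        rv = float(resid @ resid) / n
        psi[i, i] = rv
        dof = n - len(pa) - 1
        sigma2_u = float(resid @ resid) / max(dof, 1)
        se = np.sqrt(np.diag(sigma2_u * np.linalg.inv(g)))
        for u, c, s_ in zip(pa, coef, se):
            B[i, idx[u]] = c
            tval = c / s_ if s_ > 0 else np.inf
            pval = 2.0 * stats.t.sf(abs(tval), df=max(dof, 1))
            paths.append((u, v, float(c), float(pval)))
        n_params += len(pa) + 1  # paths + residual variance
    # free exogenous (co)variances
    for i, u in enumerate(exog):
        for v in exog[i + 1:]:
            psi[idx[u], idx[v]] = psi[idx[v], idx[u]] = S[idx[u], idx[v]]
    n_params += len(exog) * (len(exog) + 1) // 2

    ib = np.linalg.inv(np.eye(p) - B)
    sigma = ib @ psi @ ib.T
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise ValueError("singular covariance matrix")
    tr = float(np.trace(S @ np.linalg.inv(sigma)))
    f_ml = max(logdet_m + tr - logdet_s - p, 0.0)
    chi_square = n * f_ml
    df_model = p * (p + 1) // 2 - n_params
    if df_model < 0:
        raise ValueError("structure has more parameters than covariance moments")
    p_fit = float(stats.chi2.sf(chi_square, df_model)) if df_model > 0 else 1.0
    loglik = -0.5 * n * (p * np.log(2 * np.pi) + logdet_m + tr)
    return PathModelFit(
        model_id=model_id,
        paths=paths,
        chi_square=float(chi_square),
        df=int(df_model),
        p_fit=p_fit,
        loglik=float(loglik),
        aic=aic(loglik, n_params),
        n=n,
        variables=variables,
    )


def select_model(fits) -> pd.DataFrame:
    """Rank path-model fits by AIC (ascending); deterministic tie-break.

    All fits must share the same n, otherwise likelihoods are not
    comparable and a ValueError is raised.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to rank")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits computed on differing n: {sorted(ns)}")
    rows = pd.DataFrame(
        {
            "model_id": [f.model_id for f in fits],
            "aic": [f.aic for f in fits],
            "chi_square": [f.chi_square for f in fits],
            "df": [f.df for f in fits],
            "n": [f.n for f in fits],
        }
    ).sort_values(["aic", "model_id"], kind="stable").reset_index(drop=True)
    rows["delta_aic"] = rows["aic"] - rows["aic"].iloc[0]
    rows["winner"] = False
    rows.loc[0, "winner"] = True
    return rows


def marginal_residual_test(
    data: pd.DataFrame,
    response: str,
    covariates,
    predictor: str,
    branch: str = "parametric",
) -> AssociationTest:
    """Two-stage marginal test of the predictor after covariate adjustment.

    Stage 1 regresses the response on the covariates (OLS); stage 2 tests
    the association between the stage-1 residuals and the predictor,
    either with a slope t test (``branch="parametric"``) or with Kendall
    tau (``branch="nonparametric"``, the heteroscedasticity-robust route).
    """
    cols = [response, predictor, *covariates]
    df_ = data[cols].dropna()
    if len(df_) < 10:
        raise ValueError(f"need >= 10 complete cases, got {len(df_)}")
    Xc = sm.add_constant(df_[list(covariates)].to_numpy(float))
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("collinear covariates")
    stage1 = sm.OLS(df_[response].to_numpy(float), Xc).fit()
    resid = stage1.resid
    xpred = df_[predictor].to_numpy(float)
    if branch == "parametric":
        stage2 = sm.OLS(resid, sm.add_constant(xpred)).fit()
        return AssociationTest(
            "t_slope", float(stage2.tvalues[1]), float(stage2.pvalues[1]), len(df_)
        )
    if branch == "nonparametric":
        return kendall_tau(xpred, resid)
    raise ValueError(f"unknown branch {branch!r}")
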