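import numpy as np
import pandas as pd
import pytest

from mycomediate.path_analysis import (
    combined_structure,
    fit_path_model,
    marginal_residual_test,
    select_model,
    three_variable_structure,
)
from mycomediate.synthetic_data import make_confounded_triple


def _standardize(df):
    z = df - df.mean()
    return z / z.std(ddof=0)


def test_saturated_model_has_zero_chi_square(rng):
    df = pd.DataFrame(rng.standard_normal((80, 3)), columns=["z", "x", "y"])
    fit = fit_path_model(df, three_variable_structure("z", "x", "y"))
    assert fit.chi_square == pytest.approx(0.0, abs=1e-8)
    assert fit.df == 0
    assert fit.p_fit == 1.0


def test_coefficients_equal_normal_equations_solution(rng):
    df = pd.DataFrame(rng.standard_normal((120, 3)), columns=["z", "x", "y"])
    df["x"] += 0.5 * df["z"]
    df["y"] += 0.4 * df["x"] + 0.3 * df["z"]
    fit = fit_path_model(df, three_variable_structure("z", "x", "y"))
    z = _standardize(df)
    X = z[["z", "x"]].to_numpy()
    coef = np.linalg.solve(X.T @ X, X.T @ z["y"].to_numpy())
    got = {(f, t): c for f, t, c, _ in fit.paths}
    assert got[("z", "y")] == pytest.approx(coef[0], abs=1e-8)
    assert got[("x", "y")] == pytest.approx(coef[1], abs=1e-8)
    # predictor path also equals the partial-correlation regression identity
    slope_zx = float((z["z"] * z["x"]).mean())
    assert got[("z", "x")] == pytest.approx(slope_zx, abs=1e-8)


def test_orthogonal_covariate_leaves_simple_slope(rng):
    n = 4000
    z = rng.standard_normal(n)
    x = rng.standard_normal(n)  # independent of z
    y = 0.5 * x + rng.standard_normal(n)
    df = pd.DataFrame({"z": z, "x": x, "y": y})
    fit = fit_path_model(df, three_variable_structure("z", "x", "y"))
    got = {(f, t): c for f, t, c, _ in fit.paths}
    zs = _standardize(df)
    simple = float((zs["x"] * zs["y"]).mean())
    assert got[("x", "y")] == pytest.approx(simple, abs=0.02)


def test_cyclic_structure_rejected(rng):
    df = pd.DataFrame(rng.standard_normal((50, 2)), columns=["x", "y"])
    with pytest.raises(ValueError, match="cycle"):
        fit_path_model(df, [("x", "y"), ("y", "x")])


def test_combined_structure_is_saturated(rng):
    df = make_confounded_triple(200, seed=3)
    fit = fit_path_model(
        df, combined_structure("e_R", "lrr", "ra_am_woody", "ra_am_herb"), "SEM5"
    )
    assert fit.df == 0
    assert fit.chi_square == pytest.approx(0.0, abs=1e-7)


def test_selection_ties_break_deterministically(rng):
    df = pd.DataFrame(rng.standard_normal((60, 3)), columns=["z", "x", "y"])
    f1 = fit_path_model(df, three_variable_structure("z", "x", "y"), "B_model")
    f2 = fit_path_model(df, three_variable_structure("z", "x", "y"), "A_model")
    ranked = select_model([f1, f2])
    assert ranked["delta_aic"].iloc[1] == pytest.approx(0.0)
    assert ranked["model_id"].iloc[0] == "A_model"


def test_selection_rejects_differing_n(rng):
    d1 = pd.DataFrame(rng.standard_normal((60, 3)), columns=["z", "x", "y"])
    d2 = pd.DataFrame(rng.standard_normal((80, 3)), columns=["z", "x", "y"])
    f1 = fit_path_model(d1, three_variable_structure("z", "x", "y"), "m1")
    f2 = fit_path_model(d2, three_variable_structure("z", "x", "y"), "m2")
    with pytest.raises(ValueError, match="differing n"):
        select_model([f1, f2])


def test_marginal_test_reduces_to_simple_slope_for_orthogonal_predictor(rng):
    import statsmodels.api as sm

    n = 300
    z = rng.standard_normal(n)
    x = rng.standard_normal(n)
    y = 0.4 * x + 0.6 * z + rng.standard_normal(n)
    df = pd.DataFrame({"z": z, "x": x, "y": y})
    res = marginal_residual_test(df, "y", ["z"], "x")
    resid = sm.OLS(y, sm.add_constant(z)).fit().resid
    direct = sm.OLS(resid, sm.add_constant(x)).fit()
    assert res.estimate == pytest.approx(direct.tvalues[1], abs=1e-10)


def test_marginal_test_type_one_error_near_nominal():
    rejections = 0
    reps = 150
    for s in range(reps):
        r = np.random.default_rng(7000 + s)
        z1, z2 = r.standard_normal((2, 120))
        x = r.standard_normal(120)
        y = 0.5 * z1 - 0.3 * z2 + r.standard_normal(120)
        df = pd.DataFrame({"z1": z1, "z2": z2, "x": x, "y": y})
        res = marginal_residual_test(df, "y", ["z1", "z2"], "x")
        rejections += res.p_value < 0.05
    assert 0.005 <= rejections / reps <= 0.12


def test_marginal_test_power_at_moderate_effect():
    rejections = 0
    reps = 100
    for s in range(reps):
        r = np.random.default_rng(8000 + s)
        z = r.standard_normal(150)
        x = 0.4 * z + r.standard_normal(150)
        y = 0.3 * x + 0.5 * z + r.standard_normal(150)
        df = pd.DataFrame({"z": z, "x": x, "y": y})
        res = marginal_residual_test(df, "y", ["z"], "x")
        rejections += res.p_value < 0.05
    assert rejections / reps >= 0.8


def test_collinear_covariates_rejected(rng):
    z = rng.standard_normal(50)
    df = pd.DataFrame({"z1": z, "z2": 2 * z, "x": rng.standard_normal(50),
                       "y": rng.standard_normal(50)})
    with pytest.raises(ValueError, match="collinear"):
        marginal_residual_test(df, "y", ["z1", "z2"], "x")


def test_nonparametric_branch_returns_tau(rng):
    df = make_confounded_triple(120, seed=5)
    res = marginal_residual_test(
        df, "ra_am_herb", ["e_R"], "ra_am_woody", branch="nonparametric"
    )
    assert res.statistic_name == "kendall_tau"
    assert -1 <= res.estimate <= 1
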