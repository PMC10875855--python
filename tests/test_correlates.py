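"""Design matrices and regression fits for score correlates."""

import numpy as np
import pandas as pd
import pytest

from bqindex import (
    adult_model2_spec,
    design_matrix,
    fit_linear,
    fit_multinomial,
)
from bqindex.correlates import ModelSpec


def _frame(n, rng, variables):
    data = {"energy_kcal": rng.normal(2100, 300, size=n)}
    for var, levels, p in variables:
        data[var] = rng.choice(levels, p=p, size=n)
    return pd.DataFrame(data)


def test_design_matrix_treatment_coding():
    frame = pd.DataFrame({"sex": ["woman", "man", "woman"], "energy_kcal": [2000.0, 2100.0, 2200.0]})
    spec = ModelSpec(outcome="bqi_continuous", covariates=(("sex", "woman"),))
    X, meta = design_matrix(frame, spec)
    assert X["sex[man]"].tolist() == [0.0, 1.0, 0.0]
    assert list(X.columns) == ["intercept", "sex[man]", "energy_kcal"]
    assert meta[1]["ref"] == "woman"


def test_design_matrix_level_counts_and_errors():
    rng = np.random.default_rng(2)
    frame = _frame(
        300,
        rng,
        [
            ("education", ["up_to_elementary", "lower_secondary", "upper_secondary", "postsecondary"], [0.25] * 4),
            ("sex", ["woman", "man"], [0.5, 0.5]),
        ],
    )
    spec = ModelSpec(
        outcome="bqi_continuous",
        covariates=(("education", "up_to_elementary"), ("sex", "woman")),
    )
    X, _ = design_matrix(frame, spec)
    # intercept + (4-1) + (2-1) + energy
    assert X.shape[1] == 1 + 3 + 1 + 1

    with pytest.raises(ValueError, match="reference level"):
        design_matrix(frame, ModelSpec(outcome="bqi_continuous", covariates=(("sex", "girls"),)))
    frame["constant"] = "only_level_present"
    frame2 = frame.copy()
    frame2.loc[0, "sex"] = "woman"  # keep sex varying
    # a variable whose single non-reference level never occurs -> constant col
    frame2["flag"] = "no"
    with pytest.raises(ValueError, match="analysis frame lacks"):
        design_matrix(frame2, ModelSpec(outcome="bqi_continuous", covariates=(("absent_var", "x"),)))


def test_full_model2_column_count_on_synthetic_cohort():
    """Columns = sum over covariates of (levels - 1) + intercept + energy."""
    import bqindex as b

    params = b.default_adult_params(n=800, seed=4)
    parts, recall = b.simulate_cohort(params)
    import tempfile, pathlib

    d = pathlib.Path(tempfile.mkdtemp())
    parts.to_csv(d / "p.csv", index=False)
    recall.to_csv(d / "r.csv", index=False)
    cohort = b.read_cohort(d / "r.csv", d / "p.csv", "adult")
    results, _ = b.score_cohort(cohort)
    frame = b.cohort_frame(cohort, results)
    spec = adult_model2_spec()
    X, _ = design_matrix(frame, spec)
    expected = 2  # intercept + energy
    for var, _ref in spec.covariates:
        expected += frame[var].nunique() - 1
    assert X.shape[1] == expected


def test_noiseless_linear_recovery_is_exact():
    x = np.arange(10, dtype=float)
    X = pd.DataFrame({"intercept": np.ones(10), "x": x})
    y = 2 + 3 * x
    fit = fit_linear(y, X)
    assert fit.table.loc["x", "estimate"] == pytest.approx(3.0, abs=1e-10)
    assert fit.table.loc["x", "se"] == pytest.approx(0.0, abs=1e-8)
    assert fit.table.loc["x", "ci_low"] == pytest.approx(3.0, abs=1e-7)


def test_linear_fit_invariant_to_row_permutation():
    rng = np.random.default_rng(8)
    X = pd.DataFrame({"intercept": np.ones(200), "x": rng.normal(size=200)})
    y = 1 + 0.5 * X["x"].to_numpy() + rng.normal(size=200)
    fit1 = fit_linear(y, X)
    perm = rng.permutation(200)
    fit2 = fit_linear(y[perm], X.iloc[perm].reset_index(drop=True))
    assert np.allclose(fit1.table["estimate"], fit2.table["estimate"], atol=1e-12)


def test_linear_matches_normal_equations_and_residual_orthogonality():
    rng = np.random.default_rng(17)
    X = pd.DataFrame(
        {
            "intercept": np.ones(120),
            "a": rng.normal(size=120),
            "b": rng.integers(0, 2, size=120).astype(float),
        }
    )
    y = rng.normal(size=120)
    fit = fit_linear(y, X)
    Xv = X.to_numpy()
    beta = np.linalg.solve(Xv.T @ Xv, Xv.T @ y)
    assert np.allclose(fit.table["estimate"], beta, atol=1e-8)
    resid = y - Xv @ fit.table["estimate"].to_numpy()
    assert np.allclose(Xv.T @ resid, 0, atol=1e-8)


def test_rank_deficiency_names_collinear_columns():
    X = pd.DataFrame({"intercept": np.ones(30), "a": np.arange(30.0), "b": 2 * np.arange(30.0)})
    with pytest.raises(ValueError, match="rank deficient"):
        fit_linear(np.random.default_rng(0).normal(size=30), X)


def test_multinomial_intercept_only_closed_form():
    cats = ["medium"] * 30 + ["low"] * 10
    X = pd.DataFrame({"intercept": np.ones(40)})
    fit = fit_multinomial(cats, X, ref_category="low")
    assert fit.table.loc["intercept", "or"] == pytest.approx(3.0, rel=1e-6)


def test_multinomial_requires_reference_rows():
    X = pd.DataFrame({"intercept": np.ones(20)})
    with pytest.raises(ValueError, match="zero rows"):
        fit_multinomial(["medium"] * 20, X, ref_category="low")


def test_null_covariate_or_near_unity_across_seeds():
    """A covariate independent of the outcome keeps its OR within 10% of 1
    in the vast majority of repeated simulations."""
    hits = 0
    n = 5000
    for seed in range(50):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
        cats = np.where(rng.random(n) < 0.5, "low", "medium")
        fit = fit_multinomial(cats, X, ref_category="low")
        if 0.9 <= fit.table.loc["x", "or"] <= 1.1:
            hits += 1
    assert hits >= 45
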