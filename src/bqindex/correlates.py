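"""Sociodemographic/psychosocial correlates of breakfast quality.

Two model tiers are fitted, mirroring common practice in nutritional
epidemiology: Model 1 adjusts for age group, sex and total daily energy
intake; Model 2 additionally adjusts for geographical area, place of
residence, education, occupation, marital status, smoking, sport activity,
BMI category and disease-history flags.  Continuous scores are analysed by
ordinary least squares (beta with Wald 95% CI); score categories by
multinomial logistic regression with the low category as reference
(odds ratios for medium-vs-low and high-vs-low with Wald 95% CI on the log
scale).  Categorical covariates use treatment (reference-level) coding, so
every coefficient reads "level vs reference".  Analyses are complete-case.

The numerical fitting is delegated to statsmodels (OLS / MNLogit); this
module owns the design-matrix construction, reference-level bookkeeping and
table assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_model import BQIResult, Cohort

__all__ = [
    "ModelSpec",
    "FitResult",
    "adult_model1_spec",
    "adult_model2_spec",
    "child_model1_spec",
    "child_model2_spec",
    "cohort_frame",
    "derive_age_group",
    "design_matrix",
    "fit_linear",
    "fit_multinomial",
    "run_models",
]

Z975 = float(stats.norm.ppf(0.975))

SEPARATION_THRESHOLD = 15.0  # |log-odds| beyond which a term is flagged


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description: outcome, covariates, references.

    ``covariates`` is an ordered list of (variable, reference level);
    total daily energy (kcal/day) always enters as a continuous adjustment.
    """

    outcome: str  # "bqi_continuous" | "bqi_category"
    covariates: tuple[tuple[str, str], ...]
    tier: str = "model2"
    stream: str = "adult"
    include_energy: bool = True


_ADULT_MODEL1: tuple[tuple[str, str], ...] = (
    ("age_group", "20-40"),
    ("sex", "woman"),
)

_ADULT_MODEL2_EXTRA: tuple[tuple[str, str], ...] = (
    ("area", "northern"),
    ("residence", "rural"),
    ("education", "up_to_elementary"),
    ("occupation", "non_manual"),
    ("marital_status", "married"),
    ("smoking", "never"),
    ("sport", "no"),
    ("bmi_category", "normal"),
    ("cvd", "no"),
    ("cancer", "no"),
    ("hypertension", "no"),
    ("hyperlipidaemia", "no"),
    ("diabetes", "no"),
)

_CHILD_MODEL1: tuple[tuple[str, str], ...] = (
    ("age_group", "5-12"),
    ("sex", "woman"),
)

_CHILD_MODEL2_EXTRA: tuple[tuple[str, str], ...] = (
    ("area", "northern"),
    ("residence", "rural"),
    ("education", "up_to_elementary"),
    ("smoking", "never"),
    ("sport", "no"),
    ("bmi_category", "normal"),
)


def adult_model1_spec(outcome: str = "bqi_continuous") -> ModelSpec:
    return ModelSpec(outcome=outcome, covariates=_ADULT_MODEL1, tier="model1", stream="adult")


def adult_model2_spec(
    outcome: str = "bqi_continuous",
    extra: Sequence[tuple[str, str]] = (),
) -> ModelSpec:
    """Model 2; ``extra`` appends further (variable, ref) pairs, e.g. a
    psychosocial exposure analysed on top of the full adjustment set."""
    return ModelSpec(
        outcome=outcome,
        covariates=_ADULT_MODEL1 + _ADULT_MODEL2_EXTRA + tuple(extra),
        tier="model2",
        stream="adult",
    )


def child_model1_spec(outcome: str = "bqi_continuous") -> ModelSpec:
    return ModelSpec(outcome=outcome, covariates=_CHILD_MODEL1, tier="model1", stream="child")


def child_model2_spec(outcome: str = "bqi_continuous") -> ModelSpec:
    return ModelSpec(
        outcome=outcome,
        covariates=_CHILD_MODEL1 + _CHILD_MODEL2_EXTRA,
        tier="model2",
        stream="child",
    )


def derive_age_group(age_years: float, stream: str) -> str:
    if stream == "adult":
        if age_years <= 40:
            return "20-40"
        if age_years <= 65:
            return "41-65"
        return ">65"
    return "5-12" if age_years <= 12 else "13-19"


def cohort_frame(cohort: Cohort, results: Mapping[str, BQIResult]) -> pd.DataFrame:
    """Participant-level analysis frame: covariates, energy, score, category."""
    rows = []
    for pid, p in cohort.participants.items():
        if pid not in results:
            continue
        res = results[pid]
        row = {
            "participant_id": pid,
            "age_years": p.age_years,
            "age_group": derive_age_group(p.age_years, cohort.stream),
            "sex": p.sex,
            "energy_kcal": cohort.days[pid].totals().energy_kcal,
            "bqi": float(res.score),
            "category": res.category,
        }
        row.update(p.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def design_matrix(frame: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, list[dict]]:
    """Treatment-coded design matrix with intercept and column metadata.

    Complete-case: rows with a missing value in any model variable are
    dropped.  Returns (X, meta) where meta records, per column, the source
    variable and level ("" for intercept/continuous terms).
    """
    needed = [v for v, _ in spec.covariates] + (["energy_kcal"] if spec.include_energy else [])
    missing_vars = [v for v in needed if v not in frame.columns]
    if missing_vars:
        raise ValueError(f"analysis frame lacks variable(s): {missing_vars}")
    sub = frame[needed].replace("", np.nan).dropna()

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sub))}
    meta: list[dict] = [{"column": "intercept", "variable": "intercept", "level": ""}]
    for var, ref in spec.covariates:
        values = sub[var].astype(str)
        levels = list(pd.unique(values))
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} absent from variable {var!r}")
        for level in [lv for lv in levels if lv != ref]:
            name = f"{var}[{level}]"
            cols[name] = (values == level).to_numpy(dtype=float)
            meta.append({"column": name, "variable": var, "level": level, "ref": ref})
    if spec.include_energy:
        cols["energy_kcal"] = sub["energy_kcal"].to_numpy(dtype=float)
        meta.append({"column": "energy_kcal", "variable": "energy_kcal", "level": ""})

    X = pd.DataFrame(cols, index=sub.index)
    constant = [
        c for c in X.columns if c != "intercept" and np.ptp(X[c].to_numpy()) == 0
    ]
    if constant:
        raise ValueError(f"constant design column(s): {constant}")
    return X, meta


@dataclass
class FitResult:
    """Coefficient table plus fit metadata.

    For linear fits ``table`` has columns estimate/se/ci_low/ci_high/p per
    term.  For multinomial fits the same columns exist per non-reference
    category, on the odds-ratio scale, with the log-scale estimate kept as
    ``log_or``.
    """

    table: pd.DataFrame
    n: int
    outcome: str
    converged: bool = True
    flags: dict[str, str] = field(default_factory=dict)


def fit_linear(y: np.ndarray | pd.Series, X: pd.DataFrame) -> FitResult:
    """Ordinary least squares with normal-approximation 95% CIs.

    Standard errors use the unbiased residual-variance estimator; confidence
    limits are estimate +/- z_0.975 * SE and p-values are two-tailed normal.
    """
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1]:
        raise ValueError(f"n={len(y)} must exceed number of columns ({X.shape[1]})")
    Xv = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xv)
    if rank < X.shape[1]:
        # identify offending columns via QR pivoting on the correlation structure
        _, r = np.linalg.qr(Xv)
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")

    fit = sm.OLS(y, Xv).fit()
    est = fit.params
    se = fit.bse
    # Perfect fits give se == 0; the normal CI then collapses to the estimate.
    p = 2 * stats.norm.sf(np.abs(np.divide(est, se, out=np.full_like(est, np.inf), where=se > 0)))
    table = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": est - Z975 * se,
            "ci_high": est + Z975 * se,
            "p": p,
        },
        index=X.columns,
    )
    return FitResult(table=table, n=len(y), outcome="bqi_continuous", converged=True)


def fit_multinomial(
    categories: Sequence[str] | pd.Series,
    X: pd.DataFrame,
    ref_category: str = "low",
) -> FitResult:
    """Multinomial logit of the score category with odds-ratio output.

    Maximum likelihood via Newton iterations (|change in log-likelihood|
    < 1e-8 or 100 iterations; the convergence flag records failures).
    Coefficients are reported as ORs vs ``ref_category`` with Wald 95% CIs
    computed on the log scale and exponentiated.  Terms with |log-odds|
    beyond 15 are flagged as likely separation.
    """
    cats = pd.Series(list(categories), index=X.index).astype(str)
    observed = list(pd.unique(cats))
    if ref_category not in observed:
        raise ValueError(f"reference category {ref_category!r} has zero rows")
    if len(observed) < 2:
        raise ValueError("need at least two categories to fit a multinomial model")
    others = [c for c in ("low", "medium", "high") if c in observed and c != ref_category]
    others += [c for c in observed if c not in ("low", "medium", "high") and c != ref_category]
    codes = cats.map({ref_category: 0, **{c: i + 1 for i, c in enumerate(others)}})

    model = sm.MNLogit(codes.to_numpy(dtype=int), X.to_numpy(dtype=float))
    fit = model.fit(method="newton", maxiter=100, tol=1e-8, disp=0)

    frames = []
    flags: dict[str, str] = {}
    params = np.atleast_2d(fit.params)  # (k columns of X) x (categories - 1)
    bse = np.atleast_2d(fit.bse)
    for j, cat in enumerate(others):
        log_or = params[:, j]
        se = bse[:, j]
        p = 2 * stats.norm.sf(np.abs(np.divide(log_or, se, out=np.full_like(log_or, np.inf), where=se > 0)))
        frame = pd.DataFrame(
            {
                "category": cat,
                "log_or": log_or,
                "se": se,
                "or": np.exp(log_or),
                "ci_low": np.exp(log_or - Z975 * se),
                "ci_high": np.exp(log_or + Z975 * se),
                "p": p,
            },
            index=X.columns,
        )
        frames.append(frame)
        for col, b in zip(X.columns, log_or):
            if abs(b) > SEPARATION_THRESHOLD:
                flags[f"{cat}:{col}"] = "possible separation"
    table = pd.concat(frames)
    table.index.name = "term"
    return FitResult(
        table=table,
        n=len(cats),
        outcome="bqi_category",
        converged=bool(fit.mle_retvals.get("converged", True)),
        flags=flags,
    )


def _term_rows(meta: list[dict], fit_table: pd.DataFrame, value_cols: list[str]) -> pd.DataFrame:
    rows = []
    for m in meta:
        if m["variable"] in ("intercept",):
            continue
        row = {"variable": m["variable"], "level": m["level"] or "(continuous)"}
        if m["column"] in fit_table.index:
            for c in value_cols:
                row[c] = fit_table.loc[m["column"], c]
        rows.append(row)
    return pd.DataFrame(rows)


def run_models(
    cohort: Cohort,
    results: Mapping[str, BQIResult],
    tiers: Sequence[str] = ("model1", "model2"),
    extra_covariates: Sequence[tuple[str, str]] = (),
    subset: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Fit linear and multinomial models for the requested tiers.

    Returns a dict of tidy coefficient tables keyed ``linear_<tier>`` and
    ``multinomial_<tier>``; each row is one non-reference covariate level
    (reference rows are implicit in the level/ref metadata).
    ``extra_covariates`` appends exposures to the Model 2 set (e.g. a
    psychosocial variable); ``subset`` is an optional boolean mask on the
    analysis frame (e.g. workers only for stress-at-work models).
    """
    frame = cohort_frame(cohort, results)
    if subset is not None:
        frame = frame[np.asarray(subset, dtype=bool)]
    out: dict[str, pd.DataFrame] = {}
    for tier in tiers:
        if cohort.stream == "adult":
            spec = adult_model1_spec() if tier == "model1" else adult_model2_spec(extra=extra_covariates)
        else:
            spec = child_model1_spec() if tier == "model1" else child_model2_spec()
        X, meta = design_matrix(frame, spec)
        y = frame.loc[X.index, "bqi"]
        lin = fit_linear(y, X)
        out[f"linear_{tier}"] = _term_rows(meta, lin.table, ["estimate", "ci_low", "ci_high", "p"])

        cats = frame.loc[X.index, "category"]
        if cats.nunique() >= 2 and (cats == "low").any():
            mn = fit_multinomial(cats, X, ref_category="low")
            blocks = []
            for cat in mn.table["category"].unique():
                sub_tab = mn.table[mn.table["category"] == cat]
                block = _term_rows(meta, sub_tab, ["or", "ci_low", "ci_high", "p"])
                block.insert(0, "category", cat)
                blocks.append(block)
            out[f"multinomial_{tier}"] = pd.concat(blocks, ignore_index=True)
    return out
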