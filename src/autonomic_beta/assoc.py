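"""Standardized-beta regression ladder linking HRV composites to beta-cell response.

The analysis contract: the outcome and the determinant are z-scored on the
analysis sample, the determinant is multiplied by -1 so coefficients read
"per SD *lower* HRV", and ordinary least squares is run under a cumulative
covariate-adjustment ladder:

* crude — no covariates;
* model 1 — age, sex, educational status (low / middle / high);
* model 2 — model 1 + Matsuda insulin-sensitivity index;
* model 3A — model 2 + total/HDL cholesterol ratio, lipid-modifying
  medication, BMI, smoking status, alcohol consumption status;
* model 3B — model 3A + office systolic blood pressure and use of
  antihypertensive medication.

Every model in the ladder is fitted on the identical complete-case row set
so the ladder is internally comparable.  Effect modification is tested in
the fully adjusted model with determinant-by-modifier and
covariate-by-modifier interaction terms (joint Wald test for >2-level
modifiers); the skewed rate-sensitivity outcome gets a tertile logistic
analysis; stratified ladders re-use the full-sample z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LADDER",
    "DEFAULT_OUTCOMES",
    "DEFAULT_EXPOSURES",
    "ModelSpec",
    "AssociationResult",
    "AssociationLadder",
    "LadderResults",
    "complete_case",
    "standardized_fit",
    "run_ladder",
    "interaction_test",
    "stratified_ladder",
    "tertile_logistic",
]

#: Cumulative covariate sets of the adjustment ladder.
LADDER: Mapping[str, tuple[str, ...]] = {
    "crude": (),
    "m1": ("age", "sex", "education"),
    "m2": ("age", "sex", "education", "matsuda"),
    "m3a": (
        "age", "sex", "education", "matsuda",
        "chol_hdl_ratio", "lipid_med", "bmi", "smoking", "alcohol",
    ),
    "m3b": (
        "age", "sex", "education", "matsuda",
        "chol_hdl_ratio", "lipid_med", "bmi", "smoking", "alcohol",
        "sbp", "antihypertensive_med",
    ),
}

DEFAULT_EXPOSURES = ("hrv_time_z", "hrv_freq_z")
DEFAULT_OUTCOMES = (
    "betacell_composite_z",
    "cpeptidogenic_index",
    "overall_insulin_secretion",
    "glucose_sensitivity",
    "potentiation_ratio",
    "rate_sensitivity",
)

#: Reference levels dropped when indicator-coding categorical covariates.
_REFERENCE_LEVELS = {
    "education": "low",
    "smoking": "never",
    "alcohol": "none",
    "sex": "F",
    "gms": "NGM",
}


@dataclass(frozen=True)
class ModelSpec:
    """Outcome / determinant / ladder definition for one analysis."""

    outcome: str
    determinant: str
    covariate_sets: Mapping[str, tuple[str, ...]] = field(default_factory=lambda: dict(LADDER))
    invert_determinant: bool = True
    complete_case: bool = True


@dataclass(frozen=True)
class AssociationResult:
    """One standardized regression coefficient with its interval."""

    st_beta: float
    ci_lo: float
    ci_hi: float
    p_value: float
    n_used: int
    model_id: str
    outcome: str = ""
    determinant: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.st_beta <= self.ci_hi):
            raise ValueError("confidence interval must bracket the estimate")


def complete_case(cohort: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Rows complete on all listed columns; raises when nothing survives."""
    missing_cols = [c for c in columns if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"columns not in cohort: {missing_cols}")
    out = cohort.dropna(subset=list(columns))
    if out.empty:
        raise ValueError("complete-case filter removed every row")
    return out


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype)


def _encode(cohort: pd.DataFrame, columns: Sequence[str], prefix: str = "") -> pd.DataFrame:
    """Numeric design columns: categoricals indicator-coded against their
    documented reference level, numerics passed through."""
    parts = []
    for col in columns:
        s = cohort[col]
        if _is_categorical(s):
            ref = _REFERENCE_LEVELS.get(col)
            dummies = pd.get_dummies(s, prefix=prefix + col, dtype=float)
            if ref is not None and f"{prefix}{col}_{ref}" in dummies:
                dummies = dummies.drop(columns=f"{prefix}{col}_{ref}")
            else:
                dummies = dummies.iloc[:, 1:]
            parts.append(dummies)
        else:
            parts.append(s.astype(float).rename(prefix + col))
    return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=cohort.index)


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"cannot z-score constant column {s.name!r}")
    return (s - s.mean()) / sd


def standardized_fit(
    cohort: pd.DataFrame,
    outcome: str,
    determinant: str,
    covariates: Sequence[str] = (),
    invert_determinant: bool = True,
    model_id: str = "",
    _prestandardized: pd.DataFrame | None = None,
) -> AssociationResult:
    """OLS of the z-scored outcome on the (inverted) z-scored determinant.

    Both the outcome and the determinant are standardized on the analysis
    sample; with ``invert_determinant`` the coefficient reads per SD *lower*
    determinant.  The 95% CI and p-value come from the usual t distribution.
    """
    if _prestandardized is not None:
        y, x = _prestandardized[outcome], _prestandardized[determinant]
    else:
        y = _zscore(cohort[outcome].astype(float))
        x = _zscore(cohort[determinant].astype(float))
    if invert_determinant:
        x = -x
    X = pd.concat([x.rename("determinant"), _encode(cohort, covariates)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy(float))
    if rank < X.shape[1]:
        raise ValueError(f"collinear design matrix for covariates {list(covariates)}")
    res = sm.OLS(y.to_numpy(float), X.astype(float)).fit()
    ci = res.conf_int().loc["determinant"]
    return AssociationResult(
        st_beta=float(res.params["determinant"]),
        ci_lo=float(ci[0]),
        ci_hi=float(ci[1]),
        p_value=float(res.pvalues["determinant"]),
        n_used=int(res.nobs),
        model_id=model_id,
        outcome=outcome,
        determinant=determinant,
    )


class AssociationLadder:
    """Adjustment-ladder analysis of one outcome against one determinant.

    Applies a single complete-case restriction across the union of all
    ladder covariates (so every model is fitted on the identical rows),
    then fits each ladder model.
    """

    def __init__(self, cohort: pd.DataFrame, spec: ModelSpec) -> None:
        self.spec = spec
        all_cols = {spec.outcome, spec.determinant}
        for cols in spec.covariate_sets.values():
            all_cols.update(cols)
        self.analysis_columns = sorted(all_cols)
        self.cohort = (
            complete_case(cohort, self.analysis_columns) if spec.complete_case else cohort
        )
        self.n_excluded = len(cohort) - len(self.cohort)

    def fit(self) -> "LadderResults":
        spec = self.spec
        results = [
            standardized_fit(
                self.cohort,
                spec.outcome,
                spec.determinant,
                covariates,
                invert_determinant=spec.invert_determinant,
                model_id=model_id,
            )
            for model_id, covariates in spec.covariate_sets.items()
        ]
        return LadderResults(self, results)


class LadderResults:
    """Fitted ladder: ordered :class:`AssociationResult` per model."""

    def __init__(self, model: AssociationLadder, results: list[AssociationResult]) -> None:
        self.model = model
        self.results = {r.model_id: r for r in results}

    def summary(self) -> pd.DataFrame:
        """Long-format table: one row per ladder model."""
        rows = [
            {
                "determinant": r.determinant,
                "outcome": r.outcome,
                "model": r.model_id,
                "st_beta": r.st_beta,
                "ci_lo": r.ci_lo,
                "ci_hi": r.ci_hi,
                "p_value": r.p_value,
                "n": r.n_used,
            }
            for r in self.results.values()
        ]
        return pd.DataFrame(rows)


def run_ladder(
    cohort: pd.DataFrame,
    exposures: Sequence[str] = DEFAULT_EXPOSURES,
    outcomes: Sequence[str] = DEFAULT_OUTCOMES,
    covariate_sets: Mapping[str, tuple[str, ...]] | None = None,
    invert_determinant: bool = True,
) -> pd.DataFrame:
    """Full exposure x outcome x ladder grid, long format.

    With the default two exposures, six outcomes and five ladder models the
    result has 60 rows.  Outcomes absent from the cohort are skipped.
    """
    covariate_sets = dict(LADDER) if covariate_sets is None else dict(covariate_sets)
    frames = []
    for determinant in exposures:
        for outcome in outcomes:
            if outcome not in cohort.columns:
                continue
            spec = ModelSpec(
                outcome=outcome,
                determinant=determinant,
                covariate_sets=covariate_sets,
                invert_determinant=invert_determinant,
            )
            frames.append(AssociationLadder(cohort, spec).fit().summary())
    if not frames:
        raise ValueError("no requested outcome present in the cohort")
    return pd.concat(frames, ignore_index=True)


def interaction_test(
    cohort: pd.DataFrame,
    outcome: str,
    determinant: str,
    modifier: str,
    covariates: Sequence[str] = LADDER["m3b"],
    invert_determinant: bool = True,
) -> float:
    """P-value for effect modification in the fully adjusted model.

    The model adds modifier main effects, modifier-by-determinant and
    modifier-by-covariate interaction terms; the reported p is the (joint,
    for >2-level modifiers) Wald test on the determinant interactions.
    """
    cols = sorted({outcome, determinant, modifier, *covariates})
    df = complete_case(cohort, cols)
    mod_s = df[modifier]
    levels = mod_s.unique()
    if len(levels) < 2:
        raise ValueError(f"modifier {modifier!r} has fewer than 2 levels")
    counts = mod_s.value_counts()
    if (counts < 10).any():
        warnings.warn(f"modifier {modifier!r} has a level with < 10 observations")

    y = _zscore(df[outcome].astype(float))
    x = _zscore(df[determinant].astype(float))
    if invert_determinant:
        x = -x
    base_covs = [c for c in covariates if c != modifier]
    base = _encode(df, base_covs)
    mod_dummies = _encode(df, [modifier])
    inter_det = mod_dummies.mul(x, axis=0)
    inter_det.columns = [f"{c}:determinant" for c in mod_dummies.columns]
    inter_cov = []
    for c in base.columns:
        blk = mod_dummies.mul(base[c], axis=0)
        blk.columns = [f"{m}:{c}" for m in mod_dummies.columns]
        inter_cov.append(blk)
    X = pd.concat(
        [x.rename("determinant"), base, mod_dummies, inter_det, *inter_cov], axis=1
    )
    X = sm.add_constant(X, has_constant="add")
    res = sm.OLS(y.to_numpy(float), X.astype(float)).fit()
    R = np.zeros((inter_det.shape[1], X.shape[1]))
    for i, c in enumerate(inter_det.columns):
        R[i, X.columns.get_loc(c)] = 1.0
    wald = res.wald_test(R, scalar=True, use_f=True)
    return float(wald.pvalue)


def stratified_ladder(
    cohort: pd.DataFrame,
    strata: str = "gms",
    outcome: str = "betacell_composite_z",
    determinant: str = "hrv_time_z",
    covariate_sets: Mapping[str, tuple[str, ...]] | None = None,
    invert_determinant: bool = True,
    min_stratum: int | None = None,
) -> pd.DataFrame:
    """Full ladder within each stratum; z-scoring on the full analysis sample.

    Strata too small to support the largest model are skipped with a
    warning.  Returns the long-format summary with a ``stratum`` column.
    """
    covariate_sets = dict(LADDER) if covariate_sets is None else dict(covariate_sets)
    largest = max(covariate_sets.values(), key=len)
    cols = sorted({outcome, determinant, strata, *largest})
    df = complete_case(cohort, cols)
    # full-sample standardization, then per-stratum OLS without re-scaling
    std = pd.DataFrame(
        {
            outcome: _zscore(df[outcome].astype(float)),
            determinant: _zscore(df[determinant].astype(float)),
        },
        index=df.index,
    )
    if min_stratum is None:
        min_stratum = len(largest) + 4
    frames = []
    for level, sub in df.groupby(strata, observed=True):
        if len(sub) < min_stratum:
            warnings.warn(f"stratum {level!r} too small (n={len(sub)}); skipped")
            continue
        rows = []
        for model_id, covariates in covariate_sets.items():
            rows.append(
                standardized_fit(
                    sub,
                    outcome,
                    determinant,
                    covariates,
                    invert_determinant=invert_determinant,
                    model_id=model_id,
                    _prestandardized=std.loc[sub.index],
                )
            )
        tab = LadderResults(None, rows).summary()
        tab.insert(0, "stratum", level)
        frames.append(tab)
    if not frames:
        raise ValueError("every stratum was too small")
    return pd.concat(frames, ignore_index=True)


def tertile_logistic(
    cohort: pd.DataFrame,
    outcome: str = "rate_sensitivity",
    determinant: str = "hrv_time_z",
    covariates: Sequence[str] = LADDER["m3b"],
    invert_determinant: bool = True,
    contrast: str = "top",
) -> dict:
    """Logistic regression on tertiles of a skewed outcome.

    Tertile cut points sit at the 33.3 / 66.7 sample percentiles; the
    default contrast is top tertile versus the lower two ("bottom" selects
    the bottom tertile versus the upper two).  The determinant is z-scored
    and inverted, so the odds ratio reads per SD lower HRV.
    """
    cols = sorted({outcome, determinant, *covariates})
    df = complete_case(cohort, cols)
    y_raw = df[outcome].astype(float)
    if y_raw.nunique() < 3:
        raise ValueError("need >= 3 distinct outcome values for tertiles")
    q1, q2 = np.percentile(y_raw, [100 / 3, 200 / 3])
    if q1 == q2:
        raise ValueError(f"ties collapse a tertile: cut points ({q1}, {q2})")
    if contrast == "top":
        y = (y_raw > q2).astype(float)
    elif contrast == "bottom":
        y = (y_raw <= q1).astype(float)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    x = _zscore(df[determinant].astype(float))
    if invert_determinant:
        x = -x
    X = pd.concat([x.rename("determinant"), _encode(df, covariates)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    res = sm.Logit(y.to_numpy(float), X.astype(float)).fit(disp=False)
    beta = float(res.params["determinant"])
    lo, hi = res.conf_int().loc["determinant"]
    return {
        "odds_ratio": float(np.exp(beta)),
        "or_ci_lo": float(np.exp(lo)),
        "or_ci_hi": float(np.exp(hi)),
        "p_value": float(res.pvalues["determinant"]),
        "cut_points": (float(q1), float(q2)),
        "n_used": int(res.nobs),
        "contrast": contrast,
    }
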