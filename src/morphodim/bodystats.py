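"""Body-dimorphism statistics.

Levene-gated Student's t-tests, Hedges' g with the small-sample correction,
ANCOVA / MANCOVA sex- and trait-effects with partial eta squared, stepwise
(forward-Wald) logistic and stepwise linear regression, and cubic age
trends.  Ordinary model fits go through statsmodels; the stepwise selection
logic and the effect-size conventions are implemented here.

Sign convention for dimorphism effect sizes: male minus female, so g is
negative whenever the female mean exceeds the male mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SubjectRecord",
    "DimorphismRow",
    "StepwiseModelResult",
    "BODY_PARAMETERS",
    "bmi",
    "ttest_with_levene",
    "hedges_g",
    "dimorphism_table",
    "ancova_sex_effect",
    "mancova_trait_effects",
    "stepwise_logistic",
    "stepwise_linear",
    "cubic_trend",
]

#: canonical body-parameter column names used across the pipeline
BODY_PARAMETERS = (
    "height",
    "weight",
    "bmi",
    "handgrip",
    "wrist_diameter",
    "upper_arm_circ",
    "triceps_skinfold",
    "under_chest_circ",
    "hips_circ",
    "facial_cs",
)


def bmi(weight_kg, height_cm):
    """Body mass index: weight in kg over squared height in meters."""
    return np.asarray(weight_kg, dtype=float) / (np.asarray(height_cm, dtype=float) / 100.0) ** 2


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: sex, age, cohort and the measured body parameters."""

    subject_id: str
    sex: str  # "male" | "female"
    age: float
    cohort: str  # "young" | "mid" | "elderly"
    height: float  # cm
    weight: float  # kg
    bmi: float  # kg/m^2
    handgrip: float  # kg
    wrist_diameter: float  # mm
    upper_arm_circ: float  # cm
    triceps_skinfold: float  # mm
    under_chest_circ: float  # cm
    hips_circ: float  # cm
    facial_cs: float  # cm

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.age < 17:
            raise ValueError("age below the study range (>= 17)")
        expected = self.bmi
        implied = self.weight / (self.height / 100.0) ** 2
        if abs(expected - implied) > 1e-9 * max(1.0, abs(implied)):
            raise ValueError("bmi inconsistent with weight and height")


@dataclass(frozen=True)
class DimorphismRow:
    parameter: str
    male_mean: float
    male_sd: float
    female_mean: float
    female_sd: float
    t: float
    df: float  # non-integer after Welch adjustment
    hedges_g: float
    p: float
    variant: str  # "pooled" | "welch"
    n_male: int
    n_female: int


def ttest_with_levene(x_male, x_female, alpha_levene: float = 0.05):
    """Two-sample t-test gated on Levene's variance-equality test.

    If the (mean-centered) Levene test is non-significant the classical
    pooled-variance t with df = n1 + n2 - 2 is used; otherwise Welch's t
    with Satterthwaite df.  Returns ``(t, df, p, variant)``.
    """
    x = np.asarray(x_male, dtype=float)
    y = np.asarray(x_female, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            raise ValueError("zero variance in both groups with equal means")
    _, p_lev = stats.levene(x, y, center="mean")
    if p_lev >= alpha_levene:
        t, p = stats.ttest_ind(x, y, equal_var=True)
        df = len(x) + len(y) - 2
        variant = "pooled"
    else:
        res = stats.ttest_ind(x, y, equal_var=False)
        t, p = res.statistic, res.pvalue
        df = res.df
        variant = "welch"
    return float(t), float(df), float(p), variant


def hedges_g(x_male, x_female) -> float:
    """Hedges' g (male minus female) with the small-sample correction.

    g = (mean_m - mean_f) / s_pooled * J with J = 1 - 3 / (4 df - 1),
    df = n1 + n2 - 2.
    """
    x = np.asarray(x_male, dtype=float)
    y = np.asarray(x_female, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two observations")
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    s_pooled = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df)
    if s_pooled == 0:
        raise ValueError("pooled standard deviation is zero")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return float((x.mean() - y.mean()) / s_pooled * j)


def dimorphism_table(
    subjects: pd.DataFrame,
    parameters=BODY_PARAMETERS,
    sex_column: str = "sex",
) -> pd.DataFrame:
    """Per-parameter sex comparison (means, SD, Levene-gated t, Hedges' g).

    Missing values are dropped per parameter (complete-case), which is why
    degrees of freedom may differ between rows.
    """
    rows = []
    for param in parameters:
        sub = subjects[[sex_column, param]].dropna()
        x = sub.loc[sub[sex_column] == "male", param].to_numpy()
        y = sub.loc[sub[sex_column] == "female", param].to_numpy()
        t, df, p, variant = ttest_with_levene(x, y)
        rows.append(
            DimorphismRow(
                parameter=param,
                male_mean=float(x.mean()),
                male_sd=float(x.std(ddof=1)),
                female_mean=float(y.mean()),
                female_sd=float(y.std(ddof=1)),
                t=t,
                df=df,
                hedges_g=hedges_g(x, y),
                p=p,
                variant=variant,
                n_male=len(x),
                n_female=len(y),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def _ancova(dv, covariate, factor):
    """dv ~ covariate + factor; Type III F, partial eta^2 and p for the factor."""
    dv = np.asarray(dv, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    fac = np.asarray(factor)
    levels = np.unique(fac)
    if len(levels) < 2:
        raise ValueError("factor is constant")
    dummies = np.zeros((len(fac), len(levels) - 1))
    for j, lev in enumerate(levels[1:]):
        dummies[fac == lev, j] = 1.0
    x_full = sm.add_constant(np.column_stack([cov, dummies]))
    full = sm.OLS(dv, x_full).fit()
    x_red = sm.add_constant(cov)
    reduced = sm.OLS(dv, x_red).fit()
    ss_factor = reduced.ssr - full.ssr  # Type III: factor adjusted for covariate
    ss_res = full.ssr
    df_factor = len(levels) - 1
    df_res = int(full.df_resid)
    f = (ss_factor / df_factor) / (ss_res / df_res)
    partial_eta2 = ss_factor / (ss_factor + ss_res) if (ss_factor + ss_res) > 0 else 0.0
    p = float(stats.f.sf(f, df_factor, df_res))
    return float(f), float(partial_eta2), p


def ancova_sex_effect(dv, bmi_values, sex):
    """Sex effect on a trait after controlling for BMI.

    Linear model ``dv ~ BMI + sex``; the sex effect is the Type III sum of
    squares, partial eta^2 = SS_sex / (SS_sex + SS_residual).  Returns
    ``(F, partial_eta2, p)``.
    """
    return _ancova(dv, bmi_values, sex)


def mancova_trait_effects(
    dvs: pd.DataFrame,
    bmi_values,
    trait,
    trait_name: str = "trait",
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Per-trait univariate ANCOVA of each dependent variable on a predictor.

    Each column of ``dvs`` is modelled as ``dv ~ BMI + trait``; F, partial
    eta^2 and p are reported for the trait (after BMI), with a Bonferroni
    significance flag at alpha / n_tests (n_tests defaults to the number of
    dependent variables, 12 in the facial-index battery).
    """
    if n_tests is None:
        n_tests = dvs.shape[1]
    trait_arr = np.asarray(trait, dtype=float)
    cov = np.asarray(bmi_values, dtype=float)
    rows = []
    for col in dvs.columns:
        dv = dvs[col].to_numpy(dtype=float)
        mask = np.isfinite(dv) & np.isfinite(cov) & np.isfinite(trait_arr)
        d, c, t = dv[mask], cov[mask], trait_arr[mask]
        x_full = sm.add_constant(np.column_stack([c, t]))
        full = sm.OLS(d, x_full).fit()
        reduced = sm.OLS(d, sm.add_constant(c)).fit()
        ss_trait = reduced.ssr - full.ssr
        ss_res = full.ssr
        df_res = int(full.df_resid)
        f = (ss_trait / 1.0) / (ss_res / df_res)
        eta2 = ss_trait / (ss_trait + ss_res)
        p = float(stats.f.sf(f, 1, df_res))
        rows.append(
            {
                "dependent": col,
                "predictor": trait_name,
                "F": float(f),
                "partial_eta2": float(eta2),
                "p": p,
                "bonferroni_significant": p < alpha / n_tests,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class StepwiseModelResult:
    """A stepwise-selected regression model, predictors in entry order."""

    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    coefficient_p: dict[str, float]
    model_p: float
    r2: float  # Nagelkerke pseudo-R^2 for logistic models
    accuracy: float | None = None  # apparent accuracy at 0.5 (logistic only)
    cox_snell_r2: float | None = None
    converged: bool = True
    steps: tuple[str, ...] = ()


def _score_test(x_current: np.ndarray, fitted, candidate: np.ndarray, y: np.ndarray):
    """Rao score (chi^2, 1 df) for adding one column to a fitted logistic model."""
    p = fitted.predict(x_current)
    w = p * (1 - p)
    u = candidate @ (y - p)
    xw = x_current * w[:, None]
    xtwx_inv = np.linalg.pinv(x_current.T @ xw)
    cross = x_current.T @ (candidate * w)
    v = candidate @ (candidate * w) - cross @ xtwx_inv @ cross
    if v <= 0:
        return 0.0, 1.0
    chi2 = u**2 / v
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def stepwise_logistic(
    predictors: pd.DataFrame,
    outcome,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 50,
) -> StepwiseModelResult:
    """Forward-Wald stepwise binary logistic regression.

    Candidates enter by the significance of their Rao score test (smallest
    p first, ties broken by larger statistic then input column order);
    after each entry, included predictors whose Wald p exceeds ``p_remove``
    are removed.  Selection stops when no candidate reaches ``p_enter``.
    Reports coefficients, per-coefficient Wald p, the likelihood-ratio model
    p, Nagelkerke and Cox-Snell pseudo-R^2, and apparent classification
    accuracy at the 0.5 cutoff.
    """
    y = np.asarray(outcome)
    if y.dtype.kind in "OUSb":
        levels = np.unique(y)
        if len(levels) != 2:
            raise ValueError("outcome must be binary")
        y = (y == levels[1]).astype(float)
    else:
        y = y.astype(float)
    if len(predictors) < 2:
        raise ValueError("need at least two candidate predictors")
    names = list(predictors.columns)
    xcols = {c: predictors[c].to_numpy(dtype=float) for c in names}
    n = len(y)

    included: list[str] = []
    steps: list[str] = []
    converged = True

    def design(cols):
        if not cols:
            return np.ones((n, 1))
        return sm.add_constant(np.column_stack([xcols[c] for c in cols]))

    def fit(cols):
        import warnings as _warnings

        with _warnings.catch_warnings():
            # near-separation raises overflow/convergence warnings; the
            # converged flag in the result reports the latter
            _warnings.simplefilter("ignore")
            return sm.Logit(y, design(cols)).fit(disp=0, maxiter=200)

    current = fit(included)
    for _ in range(max_steps):
        # entry: score test per remaining candidate
        best = None
        for j, name in enumerate(c for c in names if c not in included):
            chi2, p = _score_test(design(included), current, xcols[name], y)
            key = (p, -chi2, j)
            if p < p_enter and (best is None or key < best[0]):
                best = (key, name)
        if best is None:
            break
        included.append(best[1])
        steps.append(f"enter:{best[1]}")
        try:
            current = fit(included)
            if not current.mle_retvals.get("converged", True):
                converged = False
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            converged = False
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                current = sm.Logit(y, design(included)).fit_regularized(alpha=1e-6, disp=0)
        # removal: Wald p of included predictors
        removed = True
        while removed and included:
            removed = False
            wald_p = dict(zip(included, current.pvalues[1:]))
            worst = max(included, key=lambda c: wald_p[c])
            if wald_p[worst] > p_remove:
                included.remove(worst)
                steps.append(f"remove:{worst}")
                current = fit(included)
                removed = True

    ll_full = current.llf
    ll_null = sm.Logit(y, np.ones((n, 1))).fit(disp=0).llf
    lr = 2 * (ll_full - ll_null)
    df_model = len(included)
    model_p = float(stats.chi2.sf(lr, df_model)) if df_model else 1.0
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll_null - ll_full))
    nagelkerke = cox_snell / (1.0 - np.exp(2.0 * ll_null / n)) if df_model else 0.0
    pred = current.predict(design(included)) >= 0.5
    accuracy = float(np.mean(pred == (y == 1)))
    coefs = dict(zip(included, np.atleast_1d(current.params)[1:]))
    coef_p = dict(zip(included, np.atleast_1d(current.pvalues)[1:]))
    return StepwiseModelResult(
        predictors=tuple(included),
        coefficients={k: float(v) for k, v in coefs.items()},
        coefficient_p={k: float(v) for k, v in coef_p.items()},
        model_p=model_p,
        r2=float(nagelkerke),
        accuracy=accuracy,
        cox_snell_r2=float(cox_snell),
        converged=converged,
        steps=tuple(steps),
    )


def stepwise_linear(
    predictors: pd.DataFrame,
    response,
    p_enter: float = 0.05,
    max_steps: int = 50,
) -> StepwiseModelResult:
    """Forward stepwise linear regression by F-to-enter.

    At each step the candidate with the most significant partial F enters
    (ties broken by larger F, then input column order); selection stops when
    no candidate reaches ``p_enter``.
    """
    y = np.asarray(response, dtype=float)
    names = list(predictors.columns)
    xcols = {c: predictors[c].to_numpy(dtype=float) for c in names}
    n = len(y)
    included: list[str] = []
    steps: list[str] = []

    def fit(cols):
        x = (
            sm.add_constant(np.column_stack([xcols[c] for c in cols]))
            if cols
            else np.ones((n, 1))
        )
        return sm.OLS(y, x).fit()

    current = fit(included)
    for _ in range(max_steps):
        best = None
        for j, name in enumerate(c for c in names if c not in included):
            trial = fit(included + [name])
            df_res = int(trial.df_resid)
            if df_res <= 0:
                continue
            ss_drop = current.ssr - trial.ssr
            if trial.ssr <= 0:
                f, p = np.inf, 0.0
            else:
                f = ss_drop / (trial.ssr / df_res)
                p = float(stats.f.sf(f, 1, df_res))
            key = (p, -f, j)
            if p < p_enter and (best is None or key < best[0]):
                best = (key, name)
        if best is None:
            break
        included.append(best[1])
        steps.append(f"enter:{best[1]}")
        current = fit(included)

    model_p = float(current.f_pvalue) if included else 1.0
    coefs = dict(zip(included, np.atleast_1d(current.params)[1:]))
    coef_p = dict(zip(included, np.atleast_1d(current.pvalues)[1:]))
    return StepwiseModelResult(
        predictors=tuple(included),
        coefficients={k: float(v) for k, v in coefs.items()},
        coefficient_p={k: float(v) for k, v in coef_p.items()},
        model_p=model_p,
        r2=float(current.rsquared) if included else 0.0,
        steps=tuple(steps),
    )


def cubic_trend(y, age):
    """Least-squares cubic age trend: y ~ age + age^2 + age^3.

    Returns ``(r2, p, coefficients)`` with the overall-model F p-value and
    the coefficients ordered (intercept, age, age^2, age^3).
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(age, dtype=float)
    if len(y) <= 4:
        raise ValueError("cubic trend needs n > 4")
    x = np.column_stack([a, a**2, a**3])
    x = sm.add_constant(x)
    if np.linalg.matrix_rank(x) < 4:
        raise ValueError("age design matrix is collinear")
    fit = sm.OLS(y, x).fit()
    return float(fit.rsquared), float(fit.f_pvalue), fit.params.copy()
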