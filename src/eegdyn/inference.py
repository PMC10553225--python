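"""Statistical layer: EO/EC validation tests, group ANOVAs, dwell-time
regressions, nested-model moderation F-tests and correlation comparisons.

Dwell-times across states sum to one, so regressions on dwell-times drop one
state column (structural multicollinearity): a model on n states has n-1
dwell predictors and each coefficient is interpreted relative to the dropped
state.  Moderation is assessed with the partial F-test for the joint
significance of the dwell x moderator interaction terms,

    F(p-q, n-p-1) = ((SSE_R - SSE_F) / (p - q)) / MSE_F,

where p and q count the predictors of the full model and the interaction
subset.  No multiple-testing correction is applied; raw p-values are
reported together with test counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "welch_t",
    "two_way_anova",
    "RegressionFit",
    "linear_fit",
    "dwell_regression",
    "NestedComparison",
    "nested_f_test",
    "moderation_test",
    "correlation_compare",
    "eo_ec_validation",
]

MARGINAL_P = 0.10  # reporting label threshold for "marginal" effects


def welch_t(x, y, variance_alpha: float = 0.05) -> tuple[float, float, float]:
    """Independent two-sample t-test, pooled or Welch by a variance pre-check.

    An F-ratio test on the two sample variances at ``variance_alpha``
    selects the pooled-variance test when variances are compatible and
    Welch's unequal-variance test (Satterthwaite degrees of freedom)
    otherwise.  Returns (t, df, two-sided p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if np.allclose(x.mean(), y.mean()):
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("both samples are constant with different means")
    # two-sided F-ratio test for variance equality
    f = vx / vy if vy > 0 else np.inf
    dfx, dfy = x.size - 1, y.size - 1
    p_var = 2.0 * min(stats.f.sf(f, dfx, dfy), stats.f.cdf(f, dfx, dfy))
    equal_var = p_var >= variance_alpha
    if equal_var:
        df = float(dfx + dfy)
    else:
        se2x, se2y = vx / x.size, vy / y.size
        df = (se2x + se2y) ** 2 / (se2x**2 / dfx + se2y**2 / dfy)
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(df), float(p)


def two_way_anova(y, factor_a, factor_b) -> pd.DataFrame:
    """2 x 2 factorial ANOVA (effect-coded, Type-III-equivalent sums of squares).

    Returns a tidy frame with one row per effect (A, B, A:B): F, df and p.
    A constant response yields F = 0, p = 1 by convention.
    """
    y = np.asarray(y, float)
    a = pd.Categorical(factor_a)
    b = pd.Categorical(factor_b)
    if len(a.categories) != 2 or len(b.categories) != 2:
        raise ValueError("both factors must have exactly 2 levels")
    df = pd.DataFrame({"y": y, "a": a, "b": b})
    counts = df.groupby(["a", "b"], observed=False).size()
    if (counts == 0).any():
        raise ValueError("every factor cell must be nonempty")
    if np.ptp(y) == 0:
        # constant response: zero effect and zero error sums of squares
        return pd.DataFrame(
            {
                "effect": ["A", "B", "A:B"],
                "F": 0.0,
                "df1": 1.0,
                "df2": float(len(y) - 4),
                "p": 1.0,
            }
        )

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("y ~ C(a, Sum) * C(b, Sum)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    rows = []
    name_map = {
        "C(a, Sum)": "A",
        "C(b, Sum)": "B",
        "C(a, Sum):C(b, Sum)": "A:B",
    }
    for src, label in name_map.items():
        F = tab.loc[src, "F"]
        p = tab.loc[src, "PR(>F)"]
        if not np.isfinite(F):
            # degenerate response: zero effect and zero error sums of squares
            F, p = 0.0, 1.0
        rows.append(
            {
                "effect": label,
                "F": float(F),
                "df1": float(tab.loc[src, "df"]),
                "df2": float(tab.loc["Residual", "df"]),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit summary used by the nested-model comparisons."""

    coefficients: pd.Series
    standard_errors: pd.Series
    sse: float
    r2: float
    overall_f: float
    df1: int
    df2: int
    p_value: float
    n: int
    p_features: int
    residuals: np.ndarray = field(repr=False, default=None)


def linear_fit(X: pd.DataFrame, y) -> RegressionFit:
    """OLS with intercept; X holds named predictor columns (no constant)."""
    y = np.asarray(y, float)
    names = ["intercept", *X.columns]
    M = np.column_stack([np.ones(len(y)), X.to_numpy(float)])
    n, k = M.shape
    p_features = k - 1
    if n <= k:
        raise ValueError("need more observations than parameters")
    beta, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
    if rank < k:
        raise ValueError("singular design matrix")
    resid = y - M @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    df2 = n - p_features - 1
    mse = sse / df2
    cov = mse * np.linalg.inv(M.T @ M)
    se = np.sqrt(np.diag(cov))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    if p_features > 0 and sse > 0:
        f = ((sst - sse) / p_features) / mse
        p = float(stats.f.sf(f, p_features, df2))
    elif p_features > 0 and sst > sse:
        f, p = np.inf, 0.0
    else:
        f, p = 0.0, 1.0
    return RegressionFit(
        pd.Series(beta, index=names),
        pd.Series(se, index=names),
        sse,
        r2,
        float(f),
        p_features,
        df2,
        p,
        n,
        p_features,
        resid,
    )


def dwell_regression(
    dwell: np.ndarray,
    y,
    covariates: pd.DataFrame | None = None,
    drop_state: int = -1,
    state_names: tuple[str, ...] = (),
) -> RegressionFit:
    """OLS predicting a response from dwell-times (one state column dropped).

    Dwell-times lie on the simplex, so one column (default the last
    canonical state) is dropped to break the structural multicollinearity:
    a model on n states has n-1 dwell predictors and one fewer degree of
    freedom than the state count suggests.  The overall F, R^2 and SSE are
    invariant to which column is dropped; coefficients are relative to the
    dropped state.
    """
    dwell = np.asarray(dwell, float)
    if dwell.ndim != 2:
        raise ValueError("dwell must be participants x states")
    if not np.allclose(dwell.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("dwell rows must sum to 1")
    n_states = dwell.shape[1]
    drop = drop_state % n_states
    keep = [s for s in range(n_states) if s != drop]
    if not state_names:
        state_names = tuple(f"state{s + 1}" for s in range(n_states))
    X = pd.DataFrame(
        {state_names[s]: dwell[:, s] for s in keep}
    )
    if covariates is not None:
        for c in covariates.columns:
            X[c] = np.asarray(covariates[c], float)
    return linear_fit(X, y)


@dataclass(frozen=True)
class NestedComparison:
    """Partial F-test result for a nested model pair."""

    F: float
    df1: int
    df2: int
    p_value: float


def nested_f_test(reduced: RegressionFit, full: RegressionFit) -> NestedComparison:
    """Joint significance of the predictors added by the full model.

    F = ((SSE_R - SSE_F)/(p - q)) / (SSE_F/(n - p - 1)) on (p-q, n-p-1)
    degrees of freedom, with p and q the full/reduced predictor counts.
    """
    if full.n != reduced.n:
        raise ValueError("models must be fitted on the same observations")
    p, q = full.p_features, reduced.p_features
    if p <= q:
        raise ValueError("full model must add predictors to the reduced model")
    if full.sse > reduced.sse * (1 + 1e-8) + 1e-10:
        raise ValueError(
            "full-model SSE exceeds reduced-model SSE: models are not nested"
        )
    n = full.n
    df1, df2 = p - q, n - p - 1
    mse_f = full.sse / df2
    F = max((reduced.sse - full.sse) / df1, 0.0) / mse_f
    return NestedComparison(float(F), df1, df2, float(stats.f.sf(F, df1, df2)))


def moderation_test(
    dwell: np.ndarray,
    y,
    moderator,
    drop_state: int = -1,
    state_names: tuple[str, ...] = (),
) -> NestedComparison:
    """Does a binary moderator change the dwell-time/response relation?

    Reduced model: dwell columns + moderator main effect.  Full model adds
    dwell x moderator products.  Returns the partial F-test for the joint
    significance of the interaction terms.
    """
    m = np.asarray(moderator, float)
    levels = np.unique(m)
    if len(levels) != 2 or not np.all(np.isin(levels, [0.0, 1.0])):
        raise ValueError("moderator must be dummy-coded 0/1 with both levels present")
    dwell = np.asarray(dwell, float)
    n_states = dwell.shape[1]
    drop = drop_state % n_states
    keep = [s for s in range(n_states) if s != drop]
    if not state_names:
        state_names = tuple(f"state{s + 1}" for s in range(n_states))
    X_red = pd.DataFrame({state_names[s]: dwell[:, s] for s in keep})
    X_red["moderator"] = m
    X_full = X_red.copy()
    for s in keep:
        X_full[f"{state_names[s]}:moderator"] = dwell[:, s] * m
    return nested_f_test(linear_fit(X_red, y), linear_fit(X_full, y))


def correlation_compare(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided p.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("each sample must have more than 3 observations")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def eo_ec_validation(profiles, n_states: int | None = None) -> pd.DataFrame:
    """Per-state comparison of EO vs EC dwell-times across participants.

    A state tracking genuine physiology should occupy different proportions
    of eyes-open and eyes-closed rest (e.g. the posterior alpha rise with
    eye closure).  Each state's EO and EC dwell vectors across participants
    are compared with :func:`welch_t`; returns a tidy frame (state, t, df,
    p, marginal flag).
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least 2 participants")
    for pr in profiles:
        if "EO" not in pr.by_condition or "EC" not in pr.by_condition:
            raise ValueError("every profile needs both EO and EC dwell vectors")
    if n_states is None:
        n_states = len(profiles[0].overall)
    eo = np.vstack([pr.by_condition["EO"] for pr in profiles])
    ec = np.vstack([pr.by_condition["EC"] for pr in profiles])
    rows = []
    for s in range(n_states):
        t, df, p = welch_t(eo[:, s], ec[:, s])
        rows.append(
            {
                "state": s,
                "t": t,
                "df": df,
                "p": p,
                "marginal": p < MARGINAL_P,
                "significant": p < 0.05,
            }
        )
    return pd.DataFrame(rows)
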