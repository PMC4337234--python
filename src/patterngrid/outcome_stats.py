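"""Statistical layer: paired tests, correlations, hierarchical regression.

Conventions
-----------
* Paired t-tests report Cohen's d as mean difference / SD of the
  difference scores, with a 95% CI for the mean difference.
* The correlation matrix uses pairwise-complete Pearson r with a per-pair
  n; regressions delete listwise within each model.
* Hierarchical regression fits OLS per cumulative step (statsmodels);
  standardized betas rescale B by sd(x)/sd(y); the R-squared-change test is

      dF = (dR2 / q) / ((1 - R2_full) / (n - k_full - 1))

  with q predictors added at the step and k_full predictors in the current
  model, referred to an F(q, n - k_full - 1) distribution.
* Standardized-only regressions can be reconstructed from a printed
  correlation matrix via beta = Rxx^-1 rxy, R2 = beta' rxy.
* Coder agreement is the two-way random-effects, absolute-agreement,
  single-rater ICC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .errors import ContractError, DegenerateDataError


@dataclass(frozen=True)
class PairedTestResult:
    mean_diff: float
    sd_diff: float
    n: int
    t: float
    p: float
    ci_low: float
    ci_high: float
    cohen_d: float

    @property
    def df(self) -> int:
        return self.n - 1

    @classmethod
    def from_stats(cls, mean_diff: float, sd_diff: float, n: int) -> "PairedTestResult":
        """Build the full test result from summary statistics alone."""
        if n < 2:
            raise ContractError("paired t-test needs n >= 2")
        if sd_diff <= 0:
            raise DegenerateDataError("zero-variance difference scores")
        se = sd_diff / np.sqrt(n)
        t = mean_diff / se
        p = 2.0 * st.t.sf(abs(t), n - 1)
        half = st.t.ppf(0.975, n - 1) * se
        return cls(
            mean_diff=float(mean_diff),
            sd_diff=float(sd_diff),
            n=int(n),
            t=float(t),
            p=float(p),
            ci_low=float(mean_diff - half),
            ci_high=float(mean_diff + half),
            cohen_d=float(mean_diff / sd_diff),
        )


def paired_t(pre, post) -> PairedTestResult:
    """Classical paired t-test on (post observations vs pre observations).

    The difference is ``pre - post`` so a positive t reflects a decrease.
    Pairs with a missing value on either side are dropped.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ContractError("pre and post must be paired (equal length)")
    keep = ~(np.isnan(pre) | np.isnan(post))
    diff = pre[keep] - post[keep]
    if diff.size < 2:
        raise ContractError("paired t-test needs n >= 2 complete pairs")
    sd = float(np.std(diff, ddof=1))
    if sd == 0.0:
        if np.all(diff == 0.0):
            return PairedTestResult(0.0, 0.0, diff.size, 0.0, 1.0, 0.0, 0.0, 0.0)
        raise DegenerateDataError("zero-variance difference scores")
    return PairedTestResult.from_stats(float(np.mean(diff)), sd, int(diff.size))


# ---------------------------------------------------------------------------
# correlations


@dataclass(frozen=True)
class CorrelationMatrix:
    variables: tuple[str, ...]
    r: pd.DataFrame
    n: pd.DataFrame
    p: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    degenerate: tuple[str, ...] = ()


def correlation_matrix(
    data: pd.DataFrame, variables: list[str] | None = None
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations with per-pair n and p.

    Constant variables yield NaN r for their pairs and are listed in
    ``degenerate``.
    """
    variables = list(variables or data.columns)
    sub = data.loc[:, variables].astype(float)
    k = len(variables)
    r = np.eye(k)
    pmat = np.zeros((k, k))
    nmat = np.zeros((k, k), dtype=int)
    degenerate = [
        v for v in variables if sub[v].dropna().nunique() <= 1
    ]
    for i in range(k):
        nmat[i, i] = sub[variables[i]].notna().sum()
        for j in range(i + 1, k):
            pair = sub[[variables[i], variables[j]]].dropna()
            nmat[i, j] = nmat[j, i] = len(pair)
            if len(pair) < 3 or variables[i] in degenerate or variables[j] in degenerate:
                r[i, j] = r[j, i] = np.nan
                pmat[i, j] = pmat[j, i] = np.nan
                continue
            x, y = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.nunique() <= 1 or y.nunique() <= 1:
                r[i, j] = r[j, i] = np.nan
                pmat[i, j] = pmat[j, i] = np.nan
                continue
            res = st.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            pmat[i, j] = pmat[j, i] = res.pvalue
    idx = pd.Index(variables)
    return CorrelationMatrix(
        variables=tuple(variables),
        r=pd.DataFrame(r, index=idx, columns=idx),
        n=pd.DataFrame(nmat, index=idx, columns=idx),
        p=pd.DataFrame(pmat, index=idx, columns=idx),
        means=sub.mean(),
        sds=sub.std(ddof=1),
        degenerate=tuple(degenerate),
    )


# ---------------------------------------------------------------------------
# hierarchical regression


@dataclass(frozen=True)
class RegressionStep:
    step: int
    predictors: tuple[str, ...]
    B: pd.Series  # unstandardized coefficients (no intercept)
    se: pd.Series
    beta: pd.Series  # standardized coefficients
    t: pd.Series
    p: pd.Series
    r_squared: float
    delta_r_squared: float
    delta_f: float
    p_delta_f: float
    n: int
    intercept: float | None = None


def hierarchical_regression(
    data: pd.DataFrame,
    outcome: str,
    steps: list[list[str]],
) -> list[RegressionStep]:
    """Ordinary least squares per cumulative step with R-squared-change tests.

    ``steps`` lists the predictors *added* at each step.  Rows are deleted
    listwise over the outcome and all predictors of the final step.
    """
    all_predictors = [p for stage in steps for p in stage]
    if len(set(all_predictors)) != len(all_predictors):
        raise ContractError("a predictor may be entered only once")
    cols = [outcome] + all_predictors
    sub = data.loc[:, cols].dropna().astype(float)
    n = len(sub)
    if n < len(all_predictors) + 2:
        raise ContractError(
            f"need at least {len(all_predictors) + 2} complete rows, have {n}"
        )
    y = sub[outcome]
    sd_y = y.std(ddof=1)
    results: list[RegressionStep] = []
    prev_r2 = 0.0
    entered: list[str] = []
    for i, stage in enumerate(steps, start=1):
        entered = entered + list(stage)
        X = sm.add_constant(sub[entered])
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            raise ContractError(
                f"singular design at step {i}: collinear predictors among {entered}"
            )
        fit = sm.OLS(y, X).fit()
        r2 = float(fit.rsquared)
        q = len(stage)
        k_full = len(entered)
        delta_r2 = r2 - prev_r2
        denom_df = n - k_full - 1
        delta_f = (delta_r2 / q) / ((1.0 - r2) / denom_df)
        p_delta_f = float(st.f.sf(delta_f, q, denom_df))
        B = fit.params.drop("const")
        beta = B * sub[entered].std(ddof=1) / sd_y
        results.append(
            RegressionStep(
                step=i,
                predictors=tuple(entered),
                B=B,
                se=fit.bse.drop("const"),
                beta=beta,
                t=fit.tvalues.drop("const"),
                p=fit.pvalues.drop("const"),
                r_squared=r2,
                delta_r_squared=float(delta_r2),
                delta_f=float(delta_f),
                p_delta_f=p_delta_f,
                n=n,
                intercept=float(fit.params["const"]),
            )
        )
        prev_r2 = r2
    return results


def regression_from_correlations(
    corr: pd.DataFrame,
    outcome: str,
    steps: list[list[str]],
    n: int | None = None,
) -> list[RegressionStep]:
    """Standardized-only hierarchical regression from a correlation matrix.

    ``corr`` is a symmetric correlation matrix (DataFrame labelled by
    variable) that includes the outcome.  Per step, beta = Rxx^-1 rxy and
    R2 = beta' rxy.  No unstandardized quantities are produced; t/p and the
    R-squared-change test are filled only when ``n`` is given.
    """
    entered: list[str] = []
    results = []
    prev_r2 = 0.0
    for i, stage in enumerate(steps, start=1):
        entered = entered + list(stage)
        Rxx = corr.loc[entered, entered].to_numpy(dtype=float)
        rxy = corr.loc[entered, outcome].to_numpy(dtype=float)
        try:
            np.linalg.cholesky(Rxx)
        except np.linalg.LinAlgError as exc:
            raise ContractError(
                f"predictor correlation matrix not positive definite at step {i}"
            ) from exc
        beta = np.linalg.solve(Rxx, rxy)
        r2 = float(beta @ rxy)
        q = len(stage)
        k_full = len(entered)
        delta_r2 = r2 - prev_r2
        if n is not None:
            denom_df = n - k_full - 1
            delta_f = (delta_r2 / q) / ((1.0 - r2) / denom_df)
            p_delta_f = float(st.f.sf(delta_f, q, denom_df))
        else:
            delta_f = p_delta_f = float("nan")
        empty = pd.Series(np.nan, index=entered)
        results.append(
            RegressionStep(
                step=i,
                predictors=tuple(entered),
                B=empty,
                se=empty,
                beta=pd.Series(beta, index=entered),
                t=empty,
                p=empty,
                r_squared=r2,
                delta_r_squared=float(delta_r2),
                delta_f=float(delta_f),
                p_delta_f=float(p_delta_f),
                n=n if n is not None else 0,
            )
        )
        prev_r2 = r2
    return results


def regression_table(steps: list[RegressionStep], outcome: str) -> pd.DataFrame:
    """Flatten RegressionStep results into a printed-table-style frame."""
    rows = []
    for s in steps:
        rows.append(
            {
                "outcome": outcome,
                "step": s.step,
                "term": "(step)",
                "B": np.nan,
                "SE": np.nan,
                "beta": np.nan,
                "t": np.nan,
                "p": np.nan,
                "R2": s.r_squared,
                "dR2": s.delta_r_squared,
                "dF": s.delta_f,
                "p_dF": s.p_delta_f,
                "n": s.n,
            }
        )
        for term in s.predictors:
            rows.append(
                {
                    "outcome": outcome,
                    "step": s.step,
                    "term": term,
                    "B": s.B.get(term, np.nan),
                    "SE": s.se.get(term, np.nan),
                    "beta": s.beta.get(term, np.nan),
                    "t": s.t.get(term, np.nan),
                    "p": s.p.get(term, np.nan),
                    "R2": np.nan,
                    "dR2": np.nan,
                    "dF": np.nan,
                    "p_dF": np.nan,
                    "n": s.n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# coder agreement


@dataclass(frozen=True)
class ICCResult:
    value: float
    form: str
    n: int
    ci_low: float
    ci_high: float
    degenerate: bool = False


def icc_agreement(coder1, coder2) -> ICCResult:
    """Two-way random-effects, absolute-agreement, single-rater ICC.

    ``coder1`` / ``coder2`` are paired rating vectors over the same items
    (sessions x variables flattened is fine).  Computed with
    :func:`pingouin.intraclass_corr` (ICC2).
    """
    import pingouin as pg

    x = np.asarray(coder1, dtype=float)
    y = np.asarray(coder2, dtype=float)
    if x.shape != y.shape:
        raise ContractError("coder rating vectors must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ContractError("ICC needs at least 3 paired ratings")
    form = "ICC2 (two-way random, absolute agreement, single rater)"
    if np.allclose(x, y):
        return ICCResult(1.0, form, int(x.size), 1.0, 1.0)
    between = np.var((x + y) / 2.0, ddof=1)
    if between == 0.0:
        return ICCResult(
            float("nan"), form, int(x.size), float("nan"), float("nan"),
            degenerate=True,
        )
    long = pd.DataFrame(
        {
            "targets": np.tile(np.arange(x.size), 2),
            "raters": np.repeat(["a", "b"], x.size),
            "ratings": np.concatenate([x, y]),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="targets", raters="raters", ratings="ratings"
    ).set_index("Type")
    # pingouin labels the two-way random absolute-agreement single-rater
    # form ICC2 or ICC(A,1) depending on version
    label = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    row = table.loc[label]
    lo, hi = row[ci_col]
    return ICCResult(
        value=float(row["ICC"]),
        form=form,
        n=int(x.size),
        ci_low=float(lo),
        ci_high=float(hi),
    )
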