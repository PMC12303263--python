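"""Association between performance indices and social-reactivity scores.

Implements the full behavioural analysis chain: multiple OLS with
z-scored reactivity predictors and age/sex covariates, influence
diagnostics on externally studentized residuals, a pluggable
residual-distribution screen driving the exclusion rule, Huber
M-estimator robust regression, pairwise partial Pearson correlations
controlling age/sex, and Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: Default predictor order (mirrors the reporting order of the model table).
DEFAULT_INDICES = (
    "machiavellianism",
    "psychopathy",
    "affective_empathy",
    "cognitive_empathy",
)

DELTA_OUTCOMES = ("delta_hostility", "delta_intelligence", "delta_likeability")


class RankDeficiencyError(ValueError):
    """The design matrix is rank deficient; names the collinear term."""


class DegenerateResidualError(ValueError):
    """Residual variance is (numerically) zero where it must not be."""


@dataclass(frozen=True)
class ModelSpec:
    """Regression layout: outcome ~ z(predictors) + covariates (+ intercept)."""

    outcome: str
    predictors: tuple[str, ...] = DEFAULT_INDICES
    covariates: tuple[str, ...] = ("sex", "age")
    include_intercept: bool = True

    def __post_init__(self):
        if not self.predictors:
            raise ValueError("predictors must be non-empty")
        terms = list(self.predictors) + list(self.covariates)
        if len(terms) != len(set(terms)):
            raise ValueError("duplicate terms in model spec")


@dataclass
class ModelResult:
    terms: pd.DataFrame  # columns: term, beta, se, t, p
    r2_adj: float
    fvalue: float
    df_model: int
    df_resid: int
    n_used: int
    excluded_ids: tuple = ()
    method: str = "ols"
    f_pvalue: float = np.nan
    extra: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.terms.set_index("term").loc[term, "se"])


@dataclass
class InfluenceReport:
    table: pd.DataFrame  # id, student_resid, p_uncorrected, p_bonferroni, leverage, cooks_d, flagged
    resid_test_name: str
    resid_test_stat: float
    resid_test_p: float
    flagged_ids: tuple


@dataclass
class PartialCorrResult:
    r: float
    p: float
    n: int
    n_covariates: int
    degenerate: bool = False


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize with sample (ddof=1) standard deviation."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateResidualError("cannot z-score a constant column")
    return (x - x.mean()) / sd


def encode_sex(values) -> np.ndarray:
    """Encode sex as female=0, male=1; numeric 0/1 passes through."""
    out = []
    for v in values:
        if isinstance(v, str):
            s = v.strip().lower()
            if s in ("female", "f"):
                out.append(0.0)
            elif s in ("male", "m"):
                out.append(1.0)
            else:
                raise ValueError(f"unrecognized sex label {v!r}")
        else:
            if v not in (0, 1, 0.0, 1.0):
                raise ValueError(f"numeric sex must be 0/1, got {v!r}")
            out.append(float(v))
    return np.asarray(out)


def _design(
    spec: ModelSpec, data: pd.DataFrame, exclude_ids=()
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
    """Return (y, X, term names, ids) with predictors z-scored on the
    analysis sample (i.e. after exclusion)."""
    df = data.copy()
    if exclude_ids:
        df = df[~df["speaker_id"].isin(exclude_ids)]
    ids = df["speaker_id"].to_numpy()
    y = df[spec.outcome].to_numpy(dtype=float)
    cols = []
    names = []
    if spec.include_intercept:
        cols.append(np.ones(len(df)))
        names.append("intercept")
    for p in spec.predictors:
        cols.append(zscore(df[p].to_numpy(dtype=float)))
        names.append(p)
    for c in spec.covariates:
        if c == "sex":
            cols.append(encode_sex(df[c]))
        else:
            cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate the first column linearly dependent on its predecessors
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                raise RankDeficiencyError(
                    f"design is rank deficient; term {names[j]!r} is collinear"
                )
        raise RankDeficiencyError("design is rank deficient")
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"n_used={X.shape[0]} must exceed number of terms {X.shape[1]}"
        )
    return y, X, names, ids


def fit_ols(spec: ModelSpec, data: pd.DataFrame, exclude_ids=()) -> ModelResult:
    """Least-squares fit with z-scored predictors.

    Overall F uses (k, n - k - 1) degrees of freedom where k counts the
    non-intercept terms.
    """
    y, X, names, _ = _design(spec, data, exclude_ids)
    res = sm.OLS(y, X).fit()
    terms = pd.DataFrame(
        {
            "term": names,
            "beta": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    return ModelResult(
        terms=terms,
        r2_adj=float(res.rsquared_adj),
        fvalue=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        n_used=int(res.nobs),
        excluded_ids=tuple(exclude_ids),
        method="ols",
        f_pvalue=float(res.f_pvalue),
        extra={"r2": float(res.rsquared)},
    )


def influence_diagnostics(
    spec: ModelSpec, data: pd.DataFrame, resid_test: str = "shapiro"
) -> InfluenceReport:
    """Outlier diagnostics on the full-sample OLS fit.

    Externally studentized residuals are tested two-sided against a t
    distribution with n - k - 2 df (k non-intercept terms); Bonferroni
    correction multiplies by n.  The residual-distribution screen is
    Shapiro-Wilk on the OLS residuals by default ("none" disables it).
    """
    if resid_test not in ("shapiro", "none"):
        raise ValueError(f"unknown resid_test {resid_test!r}")
    y, X, names, ids = _design(spec, data)
    n, p = X.shape
    if n - p - 1 <= 0:
        raise ValueError("sample too small for externally studentized residuals")
    res = sm.OLS(y, X).fit()
    scale = max(1.0, float(np.abs(y).max()))
    if np.sqrt(res.ssr / (n - p)) < 1e-10 * scale:
        raise DegenerateResidualError(
            "zero residual variance: studentized residuals undefined"
        )
    infl = res.get_influence()
    student = infl.resid_studentized_external
    df_t = n - p - 1  # = n - k - 2 with k non-intercept terms
    p_unc = 2.0 * stats.t.sf(np.abs(student), df_t)
    p_bonf = np.minimum(1.0, p_unc * n)
    cooks_d = infl.cooks_distance[0]
    table = pd.DataFrame(
        {
            "speaker_id": ids,
            "student_resid": student,
            "p_uncorrected": p_unc,
            "p_bonferroni": p_bonf,
            "leverage": infl.hat_matrix_diag,
            "cooks_d": cooks_d,
            "flagged": p_unc < 0.05,
        }
    )
    if resid_test == "shapiro":
        stat, pval = stats.shapiro(res.resid)
        test_name = "shapiro"
    else:
        stat, pval = np.nan, np.nan
        test_name = "none"
    flagged = tuple(table.loc[table["flagged"], "speaker_id"])
    return InfluenceReport(
        table=table,
        resid_test_name=test_name,
        resid_test_stat=float(stat),
        resid_test_p=float(pval),
        flagged_ids=flagged,
    )


def huber_weight(u: float, c: float = 1.345) -> float:
    """IRLS weight of the Huber loss at standardized residual u (w(0)=1)."""
    u = abs(float(u))
    return 1.0 if u <= c else c / u


def fit_robust(
    spec: ModelSpec,
    data: pd.DataFrame,
    huber_t: float = 1.345,
    tol: float = 1e-8,
    maxiter: int = 200,
) -> ModelResult:
    """Huber M-estimator regression via IRLS on the full sample.

    Scale is the (normalized) median absolute deviation of the
    residuals; convergence is declared when the maximum coefficient
    change falls below ``tol`` (else the result is flagged).
    """
    y, X, names, _ = _design(spec, data)
    model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=huber_t))
    res = model.fit(scale_est="mad", conv="coefs", tol=tol, maxiter=maxiter)
    n_iter = len(res.fit_history.get("params", []))
    converged = n_iter < maxiter
    if not converged:
        logger.warning("robust fit did not converge in %d iterations", maxiter)
    terms = pd.DataFrame(
        {
            "term": names,
            "beta": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    w = res.weights
    resid = y - res.fittedvalues
    ybar_w = np.sum(w * y) / np.sum(w)
    ss_res = np.sum(w * resid**2)
    ss_tot = np.sum(w * (y - ybar_w) ** 2)
    robust_r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else np.nan
    k = X.shape[1]
    rse = float(np.sqrt(ss_res / (len(y) - k)))
    return ModelResult(
        terms=terms,
        r2_adj=np.nan,
        fvalue=np.nan,
        df_model=k - 1,
        df_resid=len(y) - k,
        n_used=len(y),
        method="robust_m",
        extra={
            "robust_r2": robust_r2,
            "rse": rse,
            "scale": float(res.scale),
            "converged": converged,
            "n_iter": n_iter,
        },
    )


def partial_correlation(x, y, covariates=None) -> PartialCorrResult:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [intercept, covariates] by OLS
    and the residuals correlated; p comes from
    t = r * sqrt((n - 2 - g) / (1 - r^2)) with g covariates.  With no
    covariates this reduces to the plain Pearson correlation.  An
    exactly-explained variable yields r = 0 with a warning (degenerate
    flag set) rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
    g = Z.shape[1]
    if n <= g + 2:
        raise ValueError(f"need n > covariates + 2 (n={n}, g={g})")
    C = np.column_stack([np.ones(n), Z])
    rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    scale = max(np.abs(x).max(), np.abs(y).max(), 1.0)
    if rx.std() < 1e-10 * scale or ry.std() < 1e-10 * scale:
        warnings.warn(
            "degenerate residual variance in partial correlation; returning r=0",
            RuntimeWarning,
            stacklevel=2,
        )
        return PartialCorrResult(0.0, 1.0, n, g, degenerate=True)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    df = n - 2 - g
    if abs(r) == 1.0:
        return PartialCorrResult(r, 0.0, n, g)
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return PartialCorrResult(r, float(p), n, g)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class AssociationReport:
    full_ols: ModelResult
    influence: InfluenceReport
    excluded_ids: tuple
    primary_ols: ModelResult
    robust: ModelResult
    partial_table: pd.DataFrame
    followup_ols: ModelResult
    control_partial: PartialCorrResult | None
    log: list


def run_association_suite(
    performance: pd.DataFrame,
    profiles: pd.DataFrame,
    indices: tuple[str, ...] = DEFAULT_INDICES,
    resid_test: str = "shapiro",
    exclusion_alpha: float = 0.001,
    fdr_outcomes: tuple[str, ...] = DELTA_OUTCOMES,
) -> AssociationReport:
    """Run the full association chain on merged per-speaker tables.

    Order of operations: full-sample OLS of the modulation index (ED) on
    the z-scored indices -> influence diagnostics -> exclusion of
    flagged observations only if the residual-distribution screen is
    significant at ``exclusion_alpha`` -> refit OLS -> robust fit on the
    full sample -> partial-correlation table (delta-traits x indices,
    controlling age and sex) with BH-FDR over its cells -> follow-up
    delta-likeability OLS on the full sample -> neutral-voice
    likeability control partial correlation (if the column is present).
    """
    data = performance.merge(profiles, on="speaker_id", validate="one_to_one")
    log: list[str] = []

    spec_ed = ModelSpec(outcome="ed", predictors=tuple(indices))
    full_ols = fit_ols(spec_ed, data)
    infl = influence_diagnostics(spec_ed, data, resid_test=resid_test)
    log.append(
        f"residual-distribution test ({infl.resid_test_name}): "
        f"stat={infl.resid_test_stat:.4f} p={infl.resid_test_p:.4g}"
    )
    if resid_test != "none" and infl.resid_test_p < exclusion_alpha:
        excluded = infl.flagged_ids
        log.append(f"excluding flagged observations: {list(excluded)}")
    else:
        excluded = ()
        log.append("no exclusion (residual screen not significant)")
    primary = fit_ols(spec_ed, data, exclude_ids=excluded)
    robust = fit_robust(spec_ed, data)

    age = data["age"].to_numpy(dtype=float)
    sex = encode_sex(data["sex"])
    Z = np.column_stack([age, sex])
    rows = []
    for outcome in fdr_outcomes:
        for idx in indices:
            pc = partial_correlation(data[outcome], data[idx], Z)
            rows.append(
                {"outcome": outcome, "index": idx, "r_partial": pc.r, "p": pc.p, "n": pc.n}
            )
    partial_table = pd.DataFrame(rows)
    partial_table["p_fdr"] = fdr_adjust(partial_table["p"].to_numpy())

    spec_lik = ModelSpec(outcome="delta_likeability", predictors=tuple(indices))
    followup = fit_ols(spec_lik, data)

    control = None
    if "neutral_likeability" in data.columns and data["neutral_likeability"].notna().all():
        control = partial_correlation(
            data["neutral_likeability"], data["machiavellianism"], Z
        )
        log.append(
            f"neutral-likeability control: r_p={control.r:.3f} p={control.p:.3f}"
        )

    return AssociationReport(
        full_ols=full_ols,
        influence=infl,
        excluded_ids=tuple(excluded),
        primary_ols=primary,
        robust=robust,
        partial_table=partial_table,
        followup_ols=followup,
        control_partial=control,
        log=log,
    )
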