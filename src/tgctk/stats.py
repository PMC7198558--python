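"""Covariate-adjusted association machinery.

Logistic and linear model fitting (maximum likelihood via statsmodels) with
backward stepwise elimination driven by Wald p-values, likelihood-ratio
tests for nested models, permutation-based linear models, unpaired
Wilcoxon rank-sum comparisons with Benjamini-Hochberg adjustment, and
Pearson correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

SEPARATION_COEF = 15.0  # |log-odds| beyond this flags (quasi-)separation


@dataclass
class ModelSpec:
    outcome: str
    family: str  # 'binary' | 'continuous'
    covariates: list[str]

    def __post_init__(self) -> None:
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariates in model spec")
        if self.family not in ("binary", "continuous"):
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.covariates) if self.covariates else "1"
        return f"{self.outcome} ~ {rhs}"


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    log_likelihood: float
    n_obs: int
    n_dropped: int
    converged: bool
    separation_flag: bool
    elimination_trace: list[str] = field(default_factory=list)

    def term_p(self, covariate: str) -> float:
        """Smallest Wald p among the design columns belonging to a covariate."""
        mask = [
            name == covariate or name.startswith(f"{covariate}[")
            for name in self.p_values.index
        ]
        ps = self.p_values[mask]
        if ps.empty:
            raise KeyError(covariate)
        return float(ps.min())


def _complete_cases(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, int]:
    cols = [spec.outcome] + spec.covariates
    sub = data[cols]
    complete = sub.dropna()
    return complete, len(sub) - len(complete)


def fit_glm(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Maximum-likelihood GLM fit with Wald z/t p-values per term.

    Binary outcomes use the binomial family with logit link (IRLS);
    continuous outcomes use ordinary least squares. Rows with missing values
    in any model column are dropped (complete-case, counted). Constant
    covariates raise (singular design); diverging logistic coefficients are
    flagged as separation rather than silently reported.
    """
    complete, n_dropped = _complete_cases(data, spec)
    if spec.family == "binary":
        levels = complete[spec.outcome].nunique()
        if levels != 2:
            raise ValueError(f"binary outcome has {levels} levels")
    for cov in spec.covariates:
        if complete[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant (singular design)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if spec.family == "binary":
            model = smf.glm(spec.formula, complete, family=sm.families.Binomial())
            res = model.fit(maxiter=100)
        else:
            res = smf.ols(spec.formula, complete).fit()
        llf = float(res.llf)  # computed lazily; keep inside the warning guard
    converged = bool(getattr(res, "converged", True))
    if hasattr(res, "mle_retvals"):
        converged = bool(res.mle_retvals.get("converged", converged))
    separation = spec.family == "binary" and bool(
        (res.params.drop("Intercept", errors="ignore").abs() > SEPARATION_COEF).any()
    )
    if separation:
        warnings.warn(f"possible separation in model {spec.formula!r}")
    return FitResult(
        spec=spec,
        coefficients=res.params,
        std_errors=res.bse,
        p_values=res.pvalues,
        log_likelihood=llf,
        n_obs=int(res.nobs),
        n_dropped=n_dropped,
        converged=converged,
        separation_flag=separation,
    )


def stepwise_backward(
    spec: ModelSpec,
    data: pd.DataFrame,
    alpha: float = 0.05,
    protected: list[str] | None = None,
    criterion: str = "wald",
) -> FitResult:
    """Backward elimination: drop the least significant term until all pass.

    At each step the covariate with the largest p >= alpha is removed and
    the model refit; terms in ``protected`` (e.g. the exposure of interest)
    are never removed. ``criterion`` selects the per-term p-value: 'wald'
    (default) or 'lrt' (likelihood-ratio test of dropping the term).
    """
    if criterion not in ("wald", "lrt"):
        raise ValueError("criterion must be 'wald' or 'lrt'")
    protected = set(protected or [])
    current = list(spec.covariates)
    trace: list[str] = []
    while True:
        fit = fit_glm(ModelSpec(spec.outcome, spec.family, current), data)
        candidates = [c for c in current if c not in protected]
        if not candidates:
            break
        if criterion == "wald":
            term_p = fit.term_p
        else:
            def term_p(cov: str) -> float:
                reduced = fit_glm(
                    ModelSpec(spec.outcome, spec.family,
                              [c for c in current if c != cov]),
                    data,
                )
                return likelihood_ratio_test(fit, reduced)[2]

        worst = max(candidates, key=term_p)
        if term_p(worst) < alpha:
            break
        current.remove(worst)
        trace.append(worst)
        if not current:
            fit = fit_glm(ModelSpec(spec.outcome, spec.family, []), data)
            break
    fit.elimination_trace = trace
    return fit


def likelihood_ratio_test(full: FitResult, reduced: FitResult) -> tuple[float, int, float]:
    """Chi-squared LRT of a reduced model nested in the full model.

    Returns (statistic, df, p). df is the difference in estimated
    parameters; models must be nested (reduced covariates a subset).
    """
    if not set(reduced.spec.covariates) <= set(full.spec.covariates):
        raise ValueError("reduced model is not nested in the full model")
    df = len(full.coefficients) - len(reduced.coefficients)
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    stat = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    if df == 0:
        return stat, 0, 1.0
    p = float(sps.chi2.sf(stat, df))
    return stat, df, p


def permutation_lm(
    outcome: np.ndarray,
    design: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Permutation p-values for each linear-model term.

    The outcome is permuted, the OLS |t| statistic of each term recomputed,
    and p = (1 + #{perm >= obs}) / (1 + n_perm) -- an exact,
    distribution-free alternative to normal-theory inference.
    """
    y = np.asarray(outcome, dtype=float)
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    names = ["const"] + list(design.columns)
    rng = np.random.default_rng(seed)

    def tstats(yv: np.ndarray) -> np.ndarray:
        res = sm.OLS(yv, X).fit()
        return np.abs(np.asarray(res.tvalues))

    obs = tstats(y)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        exceed += tstats(rng.permutation(y)) >= obs
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.Series(p, index=names).drop("const")


def group_compare_bh(
    values: np.ndarray,
    groups: np.ndarray,
    comparisons: list[tuple[str, str]],
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests with BH adjustment.

    One unpaired rank-sum test per requested (group_a, group_b) comparison;
    Benjamini-Hochberg adjustment across the comparison family. Comparisons
    with a group of < 2 values are skipped with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    rows = []
    for a, b in comparisons:
        xa, xb = values[groups == a], values[groups == b]
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(f"comparison {a} vs {b}: group with < 2 values; skipped")
            continue
        if np.array_equal(np.sort(xa), np.sort(xb)):
            p = 1.0  # identical groups
        else:
            _, p = sps.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "p": float(p)})
    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Pearson correlation (r, p via the t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
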