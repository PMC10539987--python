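"""Statistical layer: effect sizes, baseline-adjusted treatment contrasts,
score-pain associations, and longitudinal mediation with bootstrap CIs.

Conventions
-----------
* Effect size is Hedges g: the pooled-SD standardized mean difference
  with small-sample correction J = 1 − 3/(4·df − 1), CI from the
  large-sample variance (n1+n2)/(n1·n2) + g²/(2·df).
* Treatment contrasts are OLS of the standardized outcome on arm
  indicators plus standardized covariates (ANCOVA-style): the reported
  β is in outcome-SD units.
* Mediation uses the product-of-coefficients decomposition on
  standardized variables: a from M ~ X + C, b and c′ from
  Y ~ X + M + C, c from Y ~ X + C, indirect = a·b, with a percentile
  bootstrap over participants.  With all-linear models on one sample the
  identity indirect = c − c′ holds to machine precision.
* Missing data: complete cases per analysis, no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


# --------------------------------------------------------------------------
# Hedges g

@dataclass(frozen=True)
class EffectSize:
    g: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int

    def to_dict(self) -> dict:
        return {"g": self.g, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n1": self.n1, "n2": self.n2}


def hedges_g(x, y) -> EffectSize:
    """Bias-corrected standardized mean difference of x minus y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    df = n1 + n2 - 2
    s_pooled = np.sqrt(((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df)
    diff = np.mean(x) - np.mean(y)
    if s_pooled == 0:
        if diff == 0:
            return EffectSize(0.0, 0.0, 0.0, n1, n2)
        g = float(np.sign(diff) * np.inf)
        return EffectSize(g, np.nan, np.nan, n1, n2)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * diff / s_pooled
    var_g = (n1 + n2) / (n1 * n2) + g * g / (2.0 * df)
    half = 1.96 * np.sqrt(var_g)
    return EffectSize(float(g), float(g - half), float(g + half), n1, n2)


# --------------------------------------------------------------------------
# OLS helpers

def _zscore(v: np.ndarray) -> np.ndarray:
    sd = np.std(v, ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize")
    return (v - np.mean(v)) / sd


@dataclass(frozen=True)
class ModelResult:
    beta_standardized: float
    t: float
    df: int
    p: float
    term: str
    covariate_names: tuple[str, ...] = ()
    n: int = 0

    def to_dict(self) -> dict:
        return {"beta_standardized": self.beta_standardized, "t": self.t,
                "df": self.df, "p": self.p, "term": self.term, "n": self.n,
                "covariates": list(self.covariate_names)}


def _fit_standardized_ols(
    data: pd.DataFrame,
    outcome: str,
    terms: list[str],
    covariates: list[str],
    dummy_cols: list[str],
) -> dict[str, ModelResult]:
    """OLS of standardized outcome on terms + covariates.

    Numeric regressors are standardized; columns named in ``dummy_cols``
    (0/1 indicators) enter as-is so their β reads as a group contrast in
    outcome-SD units.
    """
    cols = [outcome] + terms + covariates
    d = data[cols].dropna()
    if len(d) < len(terms) + len(covariates) + 2:
        raise ValueError("too few complete cases for the requested model")
    y = _zscore(d[outcome].to_numpy(dtype=float))
    X = pd.DataFrame(index=d.index)
    for c in terms + covariates:
        v = d[c].to_numpy(dtype=float)
        X[c] = v if c in dummy_cols else _zscore(v)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"collinear design matrix (columns: {list(X.columns)})"
        )
    fit = sm.OLS(y, X).fit()
    out = {}
    for term in terms:
        out[term] = ModelResult(
            beta_standardized=float(fit.params[term]),
            t=float(fit.tvalues[term]),
            df=int(fit.df_resid),
            p=float(fit.pvalues[term]),
            term=term,
            covariate_names=tuple(covariates),
            n=len(d),
        )
    return out


def ancova_effect(
    data: pd.DataFrame,
    outcome: str,
    treatment: str = "arm",
    reference: str | None = None,
    contrasts: list[tuple[str, str]] | None = None,
    covariates: list[str] | None = None,
) -> dict[str, ModelResult]:
    """Baseline-adjusted treatment contrasts on a standardized outcome.

    Either give ``contrasts`` as (level_a, level_b) pairs — each fit on
    the two arms with an indicator for level_a — or a ``reference`` level
    against which every other arm is contrasted within one model.
    Returns a mapping ``"a_vs_b"`` → :class:`ModelResult`.
    """
    covariates = covariates or []
    results: dict[str, ModelResult] = {}
    if contrasts is None:
        if reference is None:
            raise ValueError("give either contrasts or a reference level")
        levels = [lv for lv in pd.unique(data[treatment].dropna()) if lv != reference]
        contrasts = [(lv, reference) for lv in levels]
    for a, b in contrasts:
        sub = data[data[treatment].isin([a, b])].copy()
        ind = f"{a}_vs_{b}"
        sub[ind] = (sub[treatment] == a).astype(float)
        res = _fit_standardized_ols(sub, outcome, [ind], covariates, dummy_cols=[ind])
        results[ind] = res[ind]
    return results


@dataclass(frozen=True)
class PearsonR:
    r: float
    df: int
    p: float

    def to_dict(self) -> dict:
        return {"r": self.r, "df": self.df, "p": self.p}


def pearson_r(x, y) -> PearsonR:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired complete cases")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return PearsonR(float(r), len(x) - 2, float(p))


def association_change_vs_outcome(
    data: pd.DataFrame,
    change_var: str,
    outcome: str,
    baseline: str | None = None,
    condition: str | None = "arm",
) -> tuple[ModelResult, PearsonR]:
    """Association of a change score with an outcome.

    Model-based: standardized outcome ~ condition dummies + standardized
    baseline + standardized change score; plus the simple Pearson r
    (df = n − 2) between change score and outcome on complete cases.
    """
    d = data.copy()
    covariates: list[str] = []
    dummies: list[str] = []
    if condition is not None and condition in d.columns:
        levels = sorted(pd.unique(d[condition].dropna()))
        for lv in levels[1:]:
            col = f"{condition}_{lv}"
            d[col] = (d[condition] == lv).astype(float)
            covariates.append(col)
            dummies.append(col)
    if baseline is not None:
        covariates.append(baseline)
    model = _fit_standardized_ols(d, outcome, [change_var], covariates, dummy_cols=dummies)
    r = pearson_r(d[change_var], d[outcome])
    return model[change_var], r


# --------------------------------------------------------------------------
# Longitudinal mediation

@dataclass(frozen=True)
class MediationResult:
    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    boot_ci_low: float
    boot_ci_high: float
    p_boot: float
    n_boot: int
    seed: int
    n: int
    boot_indirect: np.ndarray = field(repr=False, compare=False, default=None)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "c_prime": self.c_prime,
                "indirect": self.indirect, "boot_ci_low": self.boot_ci_low,
                "boot_ci_high": self.boot_ci_high, "p_boot": self.p_boot,
                "n_boot": self.n_boot, "seed": self.seed, "n": self.n}


def _lstsq_coef(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design")
    return coef


def _paths(x: np.ndarray, m: np.ndarray, y: np.ndarray, C: np.ndarray):
    """a, b, c, c′ on standardized copies of x, m, y (covariates standardized)."""
    def z(v):
        sd = v.std(ddof=1)
        if sd == 0:
            raise np.linalg.LinAlgError("degenerate replicate: zero variance")
        return (v - v.mean()) / sd

    xs, ms, ys = z(x), z(m), z(y)
    Cs = np.column_stack([z(C[:, j]) for j in range(C.shape[1])]) if C.size else np.empty((len(x), 0))
    ones = np.ones((len(x), 1))
    a = _lstsq_coef(np.hstack([ones, xs[:, None], Cs]), ms)[1]
    bc = _lstsq_coef(np.hstack([ones, xs[:, None], ms[:, None], Cs]), ys)
    c_prime, b = bc[1], bc[2]
    c = _lstsq_coef(np.hstack([ones, xs[:, None], Cs]), ys)[1]
    return float(a), float(b), float(c), float(c_prime)


def mediate(
    data: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    covariates: list[str] | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Single-mediator linear mediation with percentile-bootstrap CI.

    ``x`` is the (0/1) treatment indicator, ``m`` the mediator (e.g. the
    pre-to-post change in mind-brain attribution score), ``y`` the distal
    outcome (e.g. 1-year pain intensity).  All variables are standardized
    within each (re)fit, so paths are in SD units.  The CI is the
    percentile bootstrap over participants; the two-sided p is
    2·min(P(indirect ≥ 0), P(indirect ≤ 0)) over bootstrap draws.
    Degenerate bootstrap replicates (a single arm drawn, collinear
    design) are redrawn, up to 10·n_boot attempts.
    """
    covariates = covariates or []
    cols = [x, m, y] + covariates
    d = data[cols].dropna()
    n = len(d)
    if n < len(cols) + 2:
        raise ValueError("too few complete cases for mediation")
    xv = d[x].to_numpy(dtype=float)
    mv = d[m].to_numpy(dtype=float)
    yv = d[y].to_numpy(dtype=float)
    C = d[covariates].to_numpy(dtype=float) if covariates else np.empty((n, 0))

    a, b, c, c_prime = _paths(xv, mv, yv, C)
    indirect = a * b

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    got, attempts = 0, 0
    while got < n_boot:
        if attempts >= 10 * n_boot:
            raise RuntimeError("too many degenerate bootstrap replicates")
        attempts += 1
        idx = rng.integers(0, n, size=n)
        try:
            ab, bb, _, _ = _paths(xv[idx], mv[idx], yv[idx], C[idx])
        except np.linalg.LinAlgError:
            continue
        boots[got] = ab * bb
        got += 1

    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    p = 2.0 * min(np.mean(boots >= 0), np.mean(boots <= 0))
    return MediationResult(
        a=a, b=b, c=c, c_prime=c_prime, indirect=float(indirect),
        boot_ci_low=float(lo), boot_ci_high=float(hi), p_boot=float(min(p, 1.0)),
        n_boot=n_boot, seed=seed, n=n, boot_indirect=boots,
    )
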