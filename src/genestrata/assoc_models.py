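"""Statistical kernel: logistic regression with model ladder, plus the
nonparametric comparisons used throughout the pipeline.

The disease-state model is a binomial GLM with logit link fitted by
iteratively reweighted least squares (IRLS). Candidate predictors follow the
burden-regression convention: de novo variant burden ``D``, rare-variant
burden ``R``, protein length ``L`` (and its natural log ``lnL``), gene
length ``L_g`` (``lnL_g``), gene age in Mya ``T``, and the interaction
``DxlnL``. Gene age stays in raw Mya and lengths are only logged where a
term says so — coefficients are reported on the raw scale, no silent
standardisation.

Model comparison uses the likelihood-ratio test for nested pairs and AIC
otherwise; multicollinearity is screened with variance inflation factors.
No multiple-testing correction is applied anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from genestrata.errors import NumericalError, ValidationError

# ---------------------------------------------------------------------------
# Model specification and term construction
# ---------------------------------------------------------------------------

#: Canonical predictor columns in a cohort frame, keyed by term name.
_TERM_SOURCES = {
    "D": "dnv_burden",
    "R": "rare_burden",
    "L": "protein_length",
    "L_g": "gene_length",
    "T": "age_mya",
}


@dataclass(frozen=True)
class ModelSpec:
    """An ordered, duplicate-free set of predictor terms (logit link)."""

    terms: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValidationError(f"duplicate terms in spec: {self.terms}")

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.terms) < set(other.terms)


def term_column(frame: pd.DataFrame, term: str) -> np.ndarray:
    """Build one predictor column from a cohort frame."""
    if term in _TERM_SOURCES:
        return frame[_TERM_SOURCES[term]].to_numpy(dtype=float)
    if term in ("lnL", "lnL_g"):
        base = "protein_length" if term == "lnL" else "gene_length"
        return np.log(frame[base].to_numpy(dtype=float))
    if term == "DxlnL":
        return term_column(frame, "D") * term_column(frame, "lnL")
    raise ValidationError(f"unknown model term {term!r}")


def design_matrix(frame: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Design matrix with leading intercept column for a spec."""
    cols = [np.ones(len(frame))]
    names = ["intercept"]
    for t in spec.terms:
        cols.append(term_column(frame, t))
        names.append(t)
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# Logistic regression by IRLS
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """A fitted logistic model supporting LRT comparison."""

    spec: ModelSpec
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    df: int
    n_obs: int
    converged: bool
    separated: bool = False
    n_iter: int = 0

    @property
    def aic(self) -> float:
        return 2.0 * self.df - 2.0 * self.loglik

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.coef / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        q = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.coef - q * self.se, self.coef + q * self.se])

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "z": self.z, "p": self.p_values},
            index=self.names,
        )


def fit_logistic(
    design: np.ndarray,
    response: np.ndarray,
    names: Sequence[str] | None = None,
    spec: ModelSpec | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ModelFit:
    """Maximum-likelihood logistic regression via IRLS.

    Converged when the score (log-likelihood gradient) has max-norm below
    ``tol``. Complete or quasi-complete separation is detected and flagged
    on the returned fit instead of raising. A rank-deficient design raises,
    naming the collinear columns.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    n, p = X.shape
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("response must be binary 0/1")
    if n <= p:
        raise ValidationError(f"n_obs ({n}) must exceed number of terms ({p})")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValidationError(
            f"rank-deficient design (rank {rank} < {p}); "
            f"collinear terms among: {_collinear_columns(X, names)}"
        )

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = expit(eta)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        XtW = X.T * w
        try:
            delta = np.linalg.solve(XtW @ X, grad)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"IRLS normal equations singular: {exc}") from exc
        # step-halving on log-likelihood (tolerate float-level decreases)
        ll_old = _loglik(X, y, beta)
        slack = 1e-10 * (1.0 + abs(ll_old))
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            if _loglik(X, y, cand) >= ll_old - slack:
                break
            step *= 0.5
        beta = beta + step * delta

    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = expit(eta)
    # complete separation: fitted probabilities saturate at the data's
    # labels while the coefficients diverge
    saturated = (mu[y == 1] > 1 - 1e-6).all() and (mu[y == 0] < 1e-6).all()
    separated = bool(saturated or (not converged and np.max(np.abs(beta)) > 1e4))
    if separated:
        converged = False
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    fisher = (X.T * w) @ X
    try:
        cov = np.linalg.inv(fisher)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return ModelFit(
        spec=spec or ModelSpec(tuple(names[1:]) if names[0] == "intercept" else tuple(names)),
        names=names,
        coef=beta,
        se=se,
        loglik=_loglik(X, y, beta),
        df=p,
        n_obs=n,
        converged=converged,
        separated=separated,
        n_iter=it,
    )


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -30.0, 30.0)
    # numerically stable Bernoulli log-likelihood
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name columns involved in exact linear dependence (via QR pivoting)."""
    from scipy.linalg import qr

    _, r, piv = qr(X, pivoting=True)
    diag = np.abs(np.diag(r))
    thresh = diag.max() * max(X.shape) * np.finfo(float).eps
    dropped = [names[j] for j in piv[np.sum(diag > thresh):]]
    return dropped or list(names)


def fit_logistic_frame(frame: pd.DataFrame, spec: ModelSpec, **kw) -> ModelFit:
    """Fit a spec on a cohort frame with binary ``is_disease`` response."""
    X, names = design_matrix(frame, spec)
    y = frame["is_disease"].to_numpy(dtype=float)
    return fit_logistic(X, y, names=names, spec=spec, **kw)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    """A test statistic with its p-value and provenance tags."""

    statistic: float
    p_value: float
    method: str
    sidedness: str = "two-sided"
    estimate: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value out of range: {self.p_value}")


def lrt(nested: ModelFit, full: ModelFit) -> TestResult:
    """Likelihood-ratio test of a nested model against a fuller one."""
    if nested.n_obs != full.n_obs:
        raise ValidationError("LRT requires identical observations")
    if not set(nested.spec.terms) < set(full.spec.terms):
        raise ValidationError(
            f"{nested.spec.terms} is not nested in {full.spec.terms}"
        )
    stat = max(0.0, 2.0 * (full.loglik - nested.loglik))
    ddf = full.df - nested.df
    p = float(stats.chi2.sf(stat, ddf)) if ddf > 0 else 1.0
    return TestResult(stat, p, method=f"LRT-chi2(df={ddf})")


def lrt_identical_ok(a: ModelFit, b: ModelFit) -> TestResult:
    """LRT allowing identical specs (statistic 0, p = 1)."""
    if set(a.spec.terms) == set(b.spec.terms):
        return TestResult(0.0, 1.0, method="LRT-chi2(df=0)")
    return lrt(a, b)


@dataclass
class LadderResult:
    """All fitted specs, ranked, with nested LRTs and the selected model."""

    fits: list[ModelFit | None]
    errors: dict[int, str]
    table: pd.DataFrame
    selected: ModelFit
    lrt_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def model_ladder(frame: pd.DataFrame, specs: Sequence[ModelSpec]) -> LadderResult:
    """Fit a ladder of candidate specs and select the preferred model.

    All specs are fitted (per-spec failures annotated, not fatal) and ranked
    by AIC with spec order as a stable tie-break. For nested pairs the LRT
    is reported; selection prefers a significant LRT over a nested rival and
    lower AIC otherwise, which reduces to: the lowest-AIC converged fit.
    """
    if len(specs) < 2:
        raise ValidationError("model ladder needs at least two specs")
    fits: list[ModelFit | None] = []
    errors: dict[int, str] = {}
    for i, spec in enumerate(specs):
        try:
            f = fit_logistic_frame(frame, spec)
            if f.separated:
                errors[i] = "separation"
            fits.append(f)
        except Exception as exc:  # noqa: BLE001 — annotate, keep going
            errors[i] = str(exc)
            fits.append(None)
    rows = []
    for i, (spec, f) in enumerate(zip(specs, fits)):
        rows.append(
            {
                "model": spec.name or f"M{i + 1}",
                "terms": "+".join(spec.terms),
                "df": f.df if f else np.nan,
                "loglik": f.loglik if f else np.nan,
                "aic": f.aic if f else np.nan,
                "converged": bool(f.converged) if f else False,
                "note": errors.get(i, ""),
                "order": i,
            }
        )
    table = pd.DataFrame(rows).sort_values(["aic", "order"], na_position="last")
    ok = [
        (i, f)
        for i, f in enumerate(fits)
        if f is not None and f.converged and not f.separated
    ]
    if not ok:
        raise NumericalError("no spec in the ladder converged")
    sel_i, selected = min(ok, key=lambda t: (t[1].aic, t[0]))
    lrt_rows = []
    for i, fi in ok:
        for j, fj in ok:
            if i != j and fi.spec.is_nested_in(fj.spec):
                r = lrt(fi, fj)
                lrt_rows.append(
                    {
                        "nested": specs[i].name or f"M{i + 1}",
                        "full": specs[j].name or f"M{j + 1}",
                        "statistic": r.statistic,
                        "p": r.p_value,
                    }
                )
    return LadderResult(
        fits=fits,
        errors=errors,
        table=table.reset_index(drop=True),
        selected=selected,
        lrt_table=pd.DataFrame(lrt_rows),
    )


#: Default candidate ladder ending in the optimal term set
#: {D, lnL, T, DxlnL}. The intermediate compositions are a package default.
DEFAULT_LADDER: tuple[ModelSpec, ...] = (
    ModelSpec(("T",), "M1"),
    ModelSpec(("lnL",), "M2"),
    ModelSpec(("D",), "M3"),
    ModelSpec(("R",), "M4"),
    ModelSpec(("T", "lnL"), "M5"),
    ModelSpec(("T", "lnL", "D"), "M6"),
    ModelSpec(("T", "lnL", "R"), "M7"),
    ModelSpec(("T", "lnL", "D", "R"), "M8"),
    ModelSpec(("D", "lnL", "T", "DxlnL"), "M9"),
)


def vif(design: np.ndarray, names: Sequence[str] | None = None) -> pd.Series:
    """Variance inflation factors: VIF_j = 1/(1 - R²_j) regressing each
    predictor on the others (intercept included in the auxiliaries).
    Perfect collinearity is reported as +inf.
    """
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValidationError("VIF needs at least two non-intercept terms")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    out = {}
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coefs, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coefs
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            out[names[j]] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[names[j]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# Nonparametric comparisons and simple regression
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(
    x: Iterable[float], y: Iterable[float], sided: str = "two-sided"
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when min(n) <= 8 with no ties, and the
    tie-corrected normal approximation with continuity correction otherwise;
    the method tag records which path was taken.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return TestResult(
            statistic=float(x.size * y.size / 2.0),
            p_value=1.0,
            method="degenerate",
            sidedness=sided,
            degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(x.size, y.size) <= 8 and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative=sided if sided != "two" else "two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="exact" if exact else "normal-approx",
        sidedness=sided,
    )


def spearman(x: Iterable[float], y: Iterable[float]) -> TestResult:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("spearman needs equal-length vectors, n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return TestResult(np.nan, np.nan, method="undefined", degenerate=True)
    rho, p = stats.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(p),
                      method="t-approx", estimate=float(rho))


@dataclass
class RegressionFit:
    """Ordinary least-squares line with per-point expectations exposed."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    x: np.ndarray
    fitted: np.ndarray

    def predict(self, x_new: Iterable[float]) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(list(x_new), dtype=float)


def ols_fit(x: Iterable[float], y: Iterable[float]) -> RegressionFit:
    """Simple least-squares regression of y on x with predictions exposed
    (the expected values feed the excess-rate computation downstream)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("ols_fit needs equal-length vectors, n >= 3")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in x")
    if np.ptp(y) == 0:
        # constant response: flat line, no explainable variance
        return RegressionFit(0.0, float(y[0]), 0.0, 1.0, x, np.full_like(x, y[0]))
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        x=x,
        fitted=fitted,
    )
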