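"""Pleiotropy summaries, logistic-growth fitting, and the phenotype
enrichment index (PEI).

Pleiotropy of a disease gene is measured as the number of distinct
organ-phenotype (OP) systems its defects affect. Per-stratum medians of
that count rise with gene age and are modelled with a logistic growth
curve

    P(t) = P_max / (1 + ((P_max - P_0)/P_0) * exp(-k t)),

with the floor P_0 and ceiling P_max fixed at empirical medians and only
the growth rate k fitted by nonlinear least squares. Time is measured from
the youngest stratum (t = 0, where the median equals P_0) toward older
strata, in units of 100 Myr; with that convention k is per 100 Myr.

PEI weights each gene's contribution to a system by the reciprocal of the
number of systems it affects ("one gene, many phenotypes" counts less per
phenotype than "one gene, one phenotype") and normalises per stratum to
percentages summing to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from genestrata.core_data import Cohort
from genestrata.errors import NumericalError, ValidationError

#: Conversion from stratum ages (Mya) to the growth-curve time axis.
TIME_UNIT_MYA = 100.0


@dataclass
class PleiotropyCurve:
    """A fitted (or fully specified) logistic growth curve of pleiotropy."""

    P_0: float
    P_max: float
    k: float
    sse: float = np.nan
    p_value: float = np.nan
    se_k: float = np.nan
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (self.P_max > self.P_0 > 0):
            raise ValidationError("require P_max > P_0 > 0")

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        c = (self.P_max - self.P_0) / self.P_0
        out = self.P_max / (1.0 + c * np.exp(-self.k * t))
        return out if out.ndim else float(out)


def reduced_logistic(t: np.ndarray | float, P_max: float, k: float):
    """The reduced conceptual form P(t) = P_max / (1 + exp(-k t)), which
    starts at P_max/2; provided for illustration, not used in fitting."""
    t = np.asarray(t, dtype=float)
    out = P_max / (1.0 + np.exp(-k * t))
    return out if out.ndim else float(out)


def op_counts(
    cohort: Cohort, median_convention: str = "interpolated"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene OP counts and per-stratum medians with growth deltas.

    Returns ``(per_gene, per_stratum)``. ``per_stratum`` is ordered old ->
    young and carries the median OP count (``interpolated`` mean-of-central-
    pair convention by default, ``lower`` optional), the stratum age, and
    the increase rate Δmedian/Δt (per Mya) between adjacent strata going
    from old toward young. Strata without disease genes get a missing
    median, never zero.
    """
    if median_convention not in ("interpolated", "lower"):
        raise ValidationError(f"unknown median convention {median_convention!r}")
    ages = cohort.stratum_ages
    rows = [
        {"gene_id": g.gene_id, "branch": g.branch, "n_op": len(g.op_set)}
        for g in cohort.genes
        if g.is_disease and g.branch
    ]
    per_gene = pd.DataFrame(rows, columns=["gene_id", "branch", "n_op"])
    strata_rows = []
    for s in cohort.phylostrata:
        counts = per_gene.loc[per_gene["branch"] == s.id, "n_op"].to_numpy()
        if counts.size == 0:
            med = np.nan
        elif median_convention == "interpolated":
            med = float(np.median(counts))
        else:
            med = float(np.sort(counts)[(counts.size - 1) // 2])
        strata_rows.append(
            {"stratum": s.id, "age_mya": ages[s.id], "n_disease": counts.size,
             "median_op": med}
        )
    per_stratum = pd.DataFrame(strata_rows)
    # increase rate between adjacent strata: Δmedian over Δage, old -> young
    d_med = -per_stratum["median_op"].diff(-1)   # older minus younger, sign-flipped
    d_age = per_stratum["age_mya"].diff(-1)      # older age minus younger age
    per_stratum["delta_op_per_mya"] = -d_med / d_age
    return per_gene, per_stratum


def growth_times(per_stratum: pd.DataFrame) -> np.ndarray:
    """Map stratum ages to the curve's time axis: t = (age - min age)/100."""
    ages = per_stratum["age_mya"].to_numpy(dtype=float)
    return (ages - ages.min()) / TIME_UNIT_MYA


def fit_logistic_growth(
    times: np.ndarray,
    values: np.ndarray,
    P_0: float,
    P_max: float,
    k_max: float = 50.0,
) -> PleiotropyCurve:
    """Fit the growth rate k (> 0) by least squares with P_0, P_max fixed.

    One-dimensional SSE minimisation bracketed on (0, k_max] to relative
    tolerance 1e-10; significance of k via the NLS linearisation
    t-statistic with n-1 degrees of freedom.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(t) & np.isfinite(v)
    t, v = t[mask], v[mask]
    if t.size < 3:
        raise ValidationError("need at least 3 points to fit the growth curve")
    if (v <= 0).any() or (v > P_max + 1e-9).any():
        warnings.warn("pleiotropy values outside (0, P_max]", stacklevel=2)
    c = (P_max - P_0) / P_0

    def sse(k: float) -> float:
        pred = P_max / (1.0 + c * np.exp(-k * t))
        return float(np.sum((pred - v) ** 2))

    res = optimize.minimize_scalar(
        sse, bounds=(1e-9, k_max), method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise NumericalError(
            f"growth-curve fit failed on bracket (0, {k_max}]: {res.message}"
        )
    k_hat = float(res.x)
    n = t.size
    # linearised standard error of k: sigma^2 / sum (dP/dk)^2
    e = np.exp(-k_hat * t)
    dpdk = P_max * c * t * e / (1.0 + c * e) ** 2
    sse_val = sse(k_hat)
    dof = max(n - 1, 1)
    sigma2 = sse_val / dof
    denom = float(np.sum(dpdk**2))
    se_k = np.sqrt(sigma2 / denom) if denom > 0 else np.nan
    t_stat = k_hat / se_k if se_k and np.isfinite(se_k) else np.nan
    p = float(2.0 * stats.t.sf(abs(t_stat), dof)) if np.isfinite(t_stat) else np.nan
    return PleiotropyCurve(
        P_0=P_0, P_max=P_max, k=k_hat, sse=sse_val, p_value=p,
        se_k=float(se_k), n_points=n,
    )


@dataclass
class PEITable:
    """Stratum x OP matrix of enrichment percentages (rows sum to 100)."""

    table: pd.DataFrame       # index: stratum, columns: OP ids, values: %
    sd: pd.Series             # per-stratum SD across catalogue systems
    empty_strata: list[str]


def pei_table(cohort: Cohort) -> PEITable:
    """Phenotype enrichment index per stratum and OP system.

    For stratum j and system i, each gene g linked to i contributes
    1/|op_set(g)|; the column of summed weights is normalised across all
    systems present in the stratum and scaled to percent. The per-stratum
    SD is taken across all 22 catalogue systems (absent systems count as
    zero enrichment).
    """
    ops = list(cohort.catalog.ids)
    strata = [s.id for s in cohort.phylostrata]
    weights = pd.DataFrame(0.0, index=strata, columns=ops)
    for g in cohort.genes:
        if not g.is_disease or not g.branch:
            continue
        w = 1.0 / len(g.op_set)
        for op in g.op_set:
            weights.at[g.branch, op] += w
    totals = weights.sum(axis=1)
    empty = [s for s in strata if totals[s] == 0]
    pct = weights.divide(totals.replace(0, np.nan), axis=0) * 100.0
    sd = pct.fillna(0.0).std(axis=1, ddof=1)
    sd[empty] = np.nan
    return PEITable(table=pct, sd=sd, empty_strata=empty)
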