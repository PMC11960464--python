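"""Chromosome-level disease-gene statistics and X-region analyses.

Covers the enrichment arithmetic used for sex-chromosome analyses:

- per-chromosome disease-gene counts and proportions;
- expected counts from an autosome-only regression of disease-gene count on
  total dated-gene count, with the excess rate (n - e)/e for each
  chromosome (X and Y are always out-of-sample predictions);
- male:female reproductive disease-gene ratios (alpha) and excess factors;
- ratios of proportions with Katz log confidence intervals (the
  cross-product odds ratio with a Woolf CI is computed alongside, labelled
  distinctly);
- assignment of X-linked genes to pseudoautosomal regions (PARs),
  X-conserved / X-added regions, or evolutionary strata, with per-region
  male-reproductive proportions (PAR genes excluded).

Interval boundaries are closed on both ends, matching the convention of
printed PAR coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from genestrata.assoc_models import RegressionFit, ols_fit
from genestrata.core_data import Cohort, GeneRecord
from genestrata.errors import ConfigurationError, ValidationError

AUTOSOMES = tuple(str(i) for i in range(1, 23))
VALID_CHROMS = AUTOSOMES + ("X", "Y")

#: GRCh38 pseudoautosomal regions on X (1-based inclusive).
GRCH38_X_PARS = (("PAR1", 10_001, 2_781_479), ("PAR2", 155_701_383, 156_030_895))


@dataclass
class ChromStat:
    """Counts for one chromosome, optionally with regression expectation."""

    chromosome: str
    n_total: int
    n_pred: int
    expected: float | None = None

    @property
    def proportion(self) -> float:
        return self.n_pred / self.n_total if self.n_total else 0.0

    @property
    def excess_rate(self) -> float | None:
        """Percent excess (n - e)/e over the regression expectation."""
        if self.expected is None or self.expected <= 0:
            return None
        return 100.0 * (self.n_pred - self.expected) / self.expected


@dataclass(frozen=True)
class AlphaRatio:
    """Male:female reproductive disease-gene ratio."""

    male: int
    female: int

    @property
    def alpha(self) -> float:
        if self.female == 0:
            return np.inf
        return self.male / self.female

    @property
    def excess_factor(self) -> float:
        """(male - female)/female: how many times males outnumber females."""
        if self.female == 0:
            return np.inf
        return (self.male - self.female) / self.female

    @property
    def infinite(self) -> bool:
        return self.female == 0


def alpha_ratio(male: int, female: int) -> AlphaRatio:
    if male < 0 or female < 0:
        raise ValidationError("counts must be non-negative")
    return AlphaRatio(male, female)


@dataclass(frozen=True)
class XInterval:
    name: str
    start: int
    end: int
    region_class: str  # PAR | X-conserved | X-added | stratum-<k>

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"bad interval {self.name}: {self.start}-{self.end}")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end  # closed on both ends


@dataclass
class XRegionMap:
    """Ordered, non-overlapping X intervals under one classification scheme
    (SM: substitutions; SCM: segmentation/clustering; HOS: human-opossum
    synteny)."""

    intervals: list[XInterval]
    scheme: str = "HOS"

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ConfigurationError(
                    f"overlapping intervals in scheme {self.scheme}: "
                    f"{a.name} ({a.start}-{a.end}) and {b.name} ({b.start}-{b.end})"
                )

    def assign(self, position: int) -> str:
        return assign_x_region(position, self)


def read_xregion_table(path, scheme: str | None = None) -> XRegionMap:
    """Read a strata/PAR interval table (TSV: name, chrom, start, end, class
    [, scheme]); keeps only X intervals, optionally one scheme."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("name", "chrom", "start", "end", "class"):
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing column {col!r}")
    if scheme is not None and "scheme" in df.columns:
        df = df[df["scheme"] == scheme]
    df = df[df["chrom"] == "X"]
    ivs = [
        XInterval(str(row["name"]), int(row["start"]), int(row["end"]),
                  str(row["class"]))
        for _, row in df.iterrows()
    ]
    return XRegionMap(ivs, scheme=scheme or "HOS")


def assign_x_region(position: int, region_map: XRegionMap) -> str:
    """Class of the first interval containing the position (closed ends);
    positions outside every interval return "unassigned"."""
    if position < 1:
        raise ValidationError("position must be >= 1")
    for iv in region_map.intervals:
        if iv.contains(position):
            return iv.region_class
    return "unassigned"


# ---------------------------------------------------------------------------
# Per-chromosome tables and regression expectations
# ---------------------------------------------------------------------------


def chrom_table(
    cohort: Cohort, predicate: Callable[[GeneRecord], bool] | None = None
) -> list[ChromStat]:
    """Per-chromosome totals and predicate counts over age-dated genes.

    The default predicate counts disease genes. Chromosomes must be labelled
    1..22, X, Y.
    """
    predicate = predicate or (lambda g: bool(g.is_disease))
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for g in cohort.genes:
        if g.branch is None:
            continue
        c = g.chromosome
        if c not in VALID_CHROMS:
            raise ValidationError(f"unknown chromosome label {c!r}")
        totals[c] = totals.get(c, 0) + 1
        if predicate(g):
            hits[c] = hits.get(c, 0) + 1
    return [
        ChromStat(c, totals.get(c, 0), hits.get(c, 0))
        for c in VALID_CHROMS
        if c in totals
    ]


def autosome_expectation(table: Sequence[ChromStat]) -> tuple[list[ChromStat], RegressionFit]:
    """Fit predicate counts on totals over autosomes; attach expected counts
    and excess rates for every chromosome (X/Y out-of-sample)."""
    autos = [c for c in table if c.chromosome in AUTOSOMES]
    if len(autos) < 3:
        raise ValidationError("need at least 3 autosomes for the regression")
    fit = ols_fit([c.n_total for c in autos], [c.n_pred for c in autos])
    out = [
        ChromStat(c.chromosome, c.n_total, c.n_pred,
                  expected=float(fit.predict([c.n_total])[0]))
        for c in table
    ]
    return out, fit


def excess_rate(observed: float, expected: float) -> float:
    """Percent excess of an observation over its expectation: 100(n-e)/e."""
    if expected <= 0:
        raise ValidationError("expected value must be positive")
    return 100.0 * (observed - expected) / expected


def slope_excess(p_obs: float, slope: float) -> float:
    """Percent excess of an observed proportion over the autosomal slope."""
    if slope <= 0:
        raise ValidationError("slope must be positive")
    return 100.0 * (p_obs - slope) / slope


# ---------------------------------------------------------------------------
# Ratio statistics
# ---------------------------------------------------------------------------


@dataclass
class RatioResult:
    """Ratio of two proportions with Katz log CI; the 2x2 odds ratio with a
    Woolf CI and the Fisher exact p ride along, labelled distinctly."""

    ratio: float
    ci_low: float
    ci_high: float
    odds_ratio: float | None = None
    or_ci: tuple[float, float] | None = None
    fisher_p: float | None = None
    degenerate: bool = False


def proportion_ratio(
    a: tuple[int, int],
    b: tuple[int, int],
    level: float = 0.95,
    fisher: bool = True,
) -> RatioResult:
    """Ratio of proportions (a_num/a_den)/(b_num/b_den) with Katz log CI.

    ``a`` and ``b`` are (numerator, denominator) count pairs. With a zero
    numerator the CI degenerates and is flagged.
    """
    (x1, n1), (x2, n2) = a, b
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("denominators must be positive")
    p1, p2 = x1 / n1, x2 / n2
    if p2 == 0:
        raise ValidationError("reference proportion is zero")
    ratio = p1 / p2
    z = stats.norm.ppf(0.5 + level / 2.0)
    degenerate = x1 == 0 or x2 == 0
    if degenerate:
        ci = (np.nan, np.nan)
    else:
        se = np.sqrt(1 / x1 - 1 / n1 + 1 / x2 - 1 / n2)
        ci = (ratio * np.exp(-z * se), ratio * np.exp(z * se))
    odds_ratio = or_ci = fisher_p = None
    y1, y2 = n1 - x1, n2 - x2
    if fisher:
        fisher_p = float(stats.fisher_exact([[x1, y1], [x2, y2]])[1])
    if min(x1, y1, x2, y2) > 0:
        odds_ratio = (x1 * y2) / (y1 * x2)
        se_or = np.sqrt(1 / x1 + 1 / y1 + 1 / x2 + 1 / y2)
        or_ci = (odds_ratio * np.exp(-z * se_or), odds_ratio * np.exp(z * se_or))
    return RatioResult(
        ratio=ratio, ci_low=ci[0], ci_high=ci[1],
        odds_ratio=odds_ratio, or_ci=or_ci, fisher_p=fisher_p,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# X-region proportions and OP specificity
# ---------------------------------------------------------------------------


@dataclass
class RegionProportion:
    region: str
    m: int          # predicate count
    b: int          # background dated count
    empty: bool = False

    @property
    def percent(self) -> float:
        return 100.0 * self.m / self.b if self.b else np.nan


def region_proportions(
    cohort: Cohort,
    region_map: XRegionMap,
    predicate: Callable[[GeneRecord], bool] | None = None,
) -> list[RegionProportion]:
    """Per-X-region predicate proportions over dated X-linked genes.

    A gene's region is assigned from its start coordinate. PAR genes are
    excluded from both numerator and background, reflecting their
    non-hemizygous inheritance. Default predicate: male-specific
    reproductive disease genes.
    """
    predicate = predicate or (
        lambda g: g.is_disease == 1 and g.repro_class == "male"
    )
    counts: dict[str, list[int]] = {}
    for g in cohort.genes:
        if g.chromosome != "X" or g.branch is None:
            continue
        region = assign_x_region(g.start, region_map)
        if region == "PAR":
            continue
        m, b = counts.setdefault(region, [0, 0])
        counts[region] = [m + int(predicate(g)), b + 1]
    order = []
    for iv in region_map.intervals:
        if iv.region_class not in order and iv.region_class != "PAR":
            order.append(iv.region_class)
    if "unassigned" in counts:
        order.append("unassigned")
    return [
        RegionProportion(r, *counts.get(r, [0, 0]), empty=counts.get(r, [0, 0])[1] == 0)
        for r in order
    ]


@dataclass
class SpecificitySummary:
    """Single- vs multi-system disease-gene fractions with per-system tally."""

    n_disease: int
    n_single: int
    n_multi: int
    per_system: pd.Series = field(default_factory=pd.Series)

    @property
    def single_percent(self) -> float:
        return 100.0 * self.n_single / self.n_disease if self.n_disease else np.nan

    @property
    def multi_percent(self) -> float:
        return 100.0 * self.n_multi / self.n_disease if self.n_disease else np.nan


def op_specificity_summary(cohort: Cohort) -> SpecificitySummary:
    """Fractions of disease genes specific to one OP system vs pleiotropic,
    with the per-system tally of system-specific genes."""
    disease = [g for g in cohort.genes if g.is_disease]
    single = [g for g in disease if len(g.op_set) == 1]
    tally: dict[str, int] = {}
    for g in single:
        (op,) = g.op_set
        tally[op] = tally.get(op, 0) + 1
    per_system = pd.Series(tally, dtype=float).sort_values(ascending=False)
    if len(single):
        per_system = per_system / len(single) * 100.0
    return SpecificitySummary(
        n_disease=len(disease),
        n_single=len(single),
        n_multi=len(disease) - len(single),
        per_system=per_system,
    )
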