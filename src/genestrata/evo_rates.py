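"""Disease-gene emergence rates per stratum and the per-generation derivation.

For each phylostratum *i* the emergence rate is

    r_i = O_i / (A_i * T_i)

where O_i is the number of disease genes in the stratum, A_i the number of
age-dated genes, and T_i the stratum's divergence time in Mya (node age from
the branch-age table). r_i is the fraction of the stratum's dated genes that
are disease genes, per million years.

Scaling a near-constant r (in percent per Mya) by genome gene count G and
generation time g (years) yields the expected number of disease-causing
genes arising per individual per generation, mu_d = G * g * r_year, and the
implied rare-disease prevalence per 10,000 births, r_RD = 10,000 * mu_d.
All internal computation is in fractions; percent appears only in labelled
report fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from genestrata.core_data import Cohort
from genestrata.errors import ConfigurationError, ValidationError


@dataclass(frozen=True)
class EmergenceRate:
    """Per-stratum disease-gene emergence rate."""

    stratum: str
    O: int
    A: int
    T: float
    r: float  # per Mya, as a fraction

    @property
    def r_percent(self) -> float:
        return 100.0 * self.r


@dataclass(frozen=True)
class GenerationRate:
    """Per-generation causal-gene rate and implied prevalence."""

    G: int
    g: float
    r_year: float          # per gene per year (fraction)
    mu_d: float            # causal genes per individual per generation
    r_RD: float            # prevalence per 10,000
    r_RD_rounded: int      # nearest-integer "per 10,000" display


def emergence_rate(O: int, A: int, T: float) -> EmergenceRate:
    """Rate r = O/(A*T) for one stratum; validates 0 <= O <= A, A,T > 0."""
    if A <= 0:
        raise ValidationError("A (dated gene count) must be positive")
    if T <= 0:
        raise ValidationError("T (stratum time, Mya) must be positive")
    if not 0 <= O <= A:
        raise ValidationError(f"O must satisfy 0 <= O <= A (got O={O}, A={A})")
    return EmergenceRate(stratum="", O=O, A=A, T=T, r=(O / A) / T)


def per_generation_rate(G: int, g: float, r_percent_per_mya: float) -> GenerationRate:
    """Scale a percent-per-Mya emergence rate to per-generation units.

    r_year = (r%/100)/1e6 per year; mu_d = G*g*r_year; r_RD = 1e4*mu_d.
    """
    if G <= 0 or g <= 0 or r_percent_per_mya < 0:
        raise ValidationError("G, g must be positive and r non-negative")
    r_year = (r_percent_per_mya / 100.0) / 1e6
    mu_d = G * g * r_year
    r_rd = 1e4 * mu_d
    return GenerationRate(
        G=G, g=g, r_year=r_year, mu_d=mu_d, r_RD=r_rd,
        r_RD_rounded=int(round(r_rd)),
    )


def stratum_rates(
    cohort: Cohort, times: Mapping[str, float] | None = None
) -> list[EmergenceRate]:
    """Per-stratum emergence rates over the cohort's (possibly merged) strata.

    O and A count only age-dated genes (branch present); ``times`` overrides
    the strata's own node ages.
    """
    times = dict(times) if times is not None else cohort.stratum_ages
    out = []
    for s in cohort.phylostrata:
        if s.id not in times:
            raise ConfigurationError(f"stratum {s.id} has no time span configured")
        dated = [g for g in cohort.genes if g.branch == s.id]
        A = len(dated)
        O = sum(g.is_disease for g in dated)
        if A == 0:
            continue
        base = emergence_rate(O, A, times[s.id])
        out.append(EmergenceRate(s.id, base.O, base.A, base.T, base.r))
    return out
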