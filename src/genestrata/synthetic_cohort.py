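"""Synthetic cohorts with the statistical structure the analyses assume.

The generator emulates the joint structure of an age-dated human gene table
crossed with organ-phenotype disease annotations and variant-burden scores:

1. branches br0..br6 assigned by configurable proportions (old-heavy, as in
   real phylostratigraphies);
2. protein lengths drawn log-normally; gene lengths as a log-normal
   multiple of coding length;
3. de novo (D) and rare-variant (R) burdens drawn from negative binomial
   distributions whose means increase exp-linearly with ln(L) and with gene
   age T — reproducing the positive age-burden correlation;
4. disease state by Bernoulli with
   logit = b0 + bD*D + blnL*ln(L) + bT*T + bDxlnL*D*ln(L),
   the intercept solved so the expected prevalence hits a target;
5. for disease genes, an organ-phenotype set whose per-branch median count
   follows the logistic growth curve P(t) = P_max/(1 + ((P_max-P_0)/P_0)
   e^(-k t)); counts are drawn as 1 + Poisson(median-1) truncated to
   [1, 22], then that many distinct systems are sampled by weight;
6. chromosome placement by weight, with reproductive disease genes
   (op set containing OP7) tagged male/female to hit a target male:female
   ratio (alpha) per chromosome class in expectation;
7. pairwise Ka/Ks in (0, 1) with mean decreasing in age and lower for
   disease genes.

One master seed is split into per-step child streams, so adding a step
never perturbs earlier draws. The generator records ground truth (latent
probabilities, realized prevalence, per-branch target medians, realized
alpha) for downstream recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import optimize
from scipy.special import expit

import yaml

from genestrata.core_data import (
    DEFAULT_PHYLOSTRATA,
    Cohort,
    GeneRecord,
    OPCatalog,
    Phylostratum,
)
from genestrata.errors import ConfigurationError, NumericalError
from genestrata.pleiotropy_pei import TIME_UNIT_MYA, PleiotropyCurve


def _default_branch_weights() -> dict[str, float]:
    # old-heavy, echoing real phylostratigraphies where most genes predate
    # the tetrapod split
    return {
        "br0": 0.55, "br1": 0.07, "br2": 0.08, "br3": 0.08,
        "br4": 0.06, "br5": 0.09, "br6": 0.07,
    }


def _default_chromosome_weights() -> dict[str, float]:
    w = {str(i): 0.9 / 22 for i in range(1, 23)}
    w["X"] = 0.085
    w["Y"] = 0.015
    return w


@dataclass
class BurdenModel:
    """Exp-linear mean model for a negative binomial burden count."""

    intercept: float
    beta_lnL: float
    beta_T: float
    dispersion: float = 3.0  # NB size parameter; smaller = more overdispersed

    def mean(self, lnL: np.ndarray, T: np.ndarray) -> np.ndarray:
        return np.exp(self.intercept + self.beta_lnL * lnL + self.beta_T * T)


@dataclass
class DiseaseModel:
    """Logit coefficients for the Bernoulli disease assignment.

    Defaults are the optimal burden-regression estimates used as generator
    truth: D 0.29, ln L 0.22, T 0.0041 per Mya, D x ln L -0.027.
    """

    beta0: float | None = None   # solved for target_prevalence when None
    beta_D: float = 0.29
    beta_lnL: float = 0.22
    beta_T: float = 0.0041
    beta_DxlnL: float = -0.027

    def linear_predictor(self, D, lnL, T) -> np.ndarray:
        return (
            self.beta_D * D + self.beta_lnL * lnL + self.beta_T * T
            + self.beta_DxlnL * D * lnL
        )


@dataclass
class CohortConfig:
    """Full parameterisation of the generator; defaults are the study
    conditions the analyses assume."""

    n_genes: int = 20_000
    branch_weights: dict[str, float] = field(default_factory=_default_branch_weights)
    phylostrata: tuple[Phylostratum, ...] = DEFAULT_PHYLOSTRATA
    length_log_mean: float = 6.1   # ln(aa); median protein ~ 446 aa
    length_log_sd: float = 0.6
    dnv_model: BurdenModel = field(
        default_factory=lambda: BurdenModel(-1.6, 0.3, 0.002)
    )
    rare_model: BurdenModel = field(
        default_factory=lambda: BurdenModel(-0.5, 0.35, 0.0025, dispersion=5.0)
    )
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    target_prevalence: float = 0.25
    pleiotropy_curve: PleiotropyCurve = field(
        default_factory=lambda: PleiotropyCurve(P_0=4.0, P_max=10.0, k=1.66)
    )
    op_weights: dict[str, float] | None = None  # default: OP1-heavy, OP7 raised
    chromosome_weights: dict[str, float] = field(
        default_factory=_default_chromosome_weights
    )
    alpha_by_class: dict[str, float] = field(
        default_factory=lambda: {"autosome": 1.81, "X": 8.89, "Y": 17.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.branch_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"branch_weights sum to {total}, not 1")
        ids = {s.id for s in self.phylostrata}
        if set(self.branch_weights) != ids:
            raise ConfigurationError("branch_weights keys must match phylostrata ids")
        for name, a in self.alpha_by_class.items():
            if a < 0:
                raise ConfigurationError(f"alpha for {name} must be >= 0")
        if not 0 < self.target_prevalence < 1:
            raise ConfigurationError("target_prevalence must lie in (0, 1)")


@dataclass
class TruthRecord:
    """Ground truth recorded at generation time."""

    disease_prob: np.ndarray
    realized_prevalence: float
    branch_median_target: dict[str, float]
    branch_median_realized: dict[str, float]
    alpha_realized: dict[str, float]
    beta0: float
    seed: int

    def summary(self) -> dict:
        return {
            "realized_prevalence": self.realized_prevalence,
            "branch_median_target": self.branch_median_target,
            "branch_median_realized": self.branch_median_realized,
            "alpha_realized": self.alpha_realized,
            "beta0": self.beta0,
            "seed": self.seed,
            "mean_disease_prob": float(np.mean(self.disease_prob)),
        }


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _draw_covariates(config: CohortConfig, rng_branch, rng_len, rng_burden):
    strata_ids = [s.id for s in config.phylostrata]
    ages = {s.id: s.age_mya for s in config.phylostrata}
    probs = np.array([config.branch_weights[b] for b in strata_ids])
    branch_idx = rng_branch.choice(len(strata_ids), size=config.n_genes, p=probs)
    branch = np.array(strata_ids)[branch_idx]
    T = np.array([ages[b] for b in branch])
    lnL = rng_len.normal(config.length_log_mean, config.length_log_sd,
                         size=config.n_genes)
    L = np.exp(lnL)
    mu_d = config.dnv_model.mean(lnL, T)
    size_d = config.dnv_model.dispersion
    D = rng_burden.negative_binomial(size_d, size_d / (size_d + mu_d)).astype(float)
    mu_r = config.rare_model.mean(lnL, T)
    size_r = config.rare_model.dispersion
    R = rng_burden.negative_binomial(size_r, size_r / (size_r + mu_r)).astype(float)
    return branch, T, L, lnL, D, R


def solve_intercept(
    config: CohortConfig, target_prevalence: float | None = None
) -> float:
    """Solve the disease-model intercept so that the expected prevalence
    under the generator's covariate distribution equals the target.

    The expectation is evaluated over a covariate sample drawn with the
    config's seed (monotone in b0, solved by Brent's method to 1e-10)."""
    target = (
        config.target_prevalence if target_prevalence is None else target_prevalence
    )
    if not 0 < target < 1:
        raise ConfigurationError(f"target prevalence {target} not in (0, 1)")
    rngs = _streams(config.seed, 8)
    _, T, _, lnL, D, _ = _draw_covariates(config, rngs[0], rngs[1], rngs[2])
    eta = config.disease_model.linear_predictor(D, lnL, T)

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + eta))) - target

    lo, hi = -60.0, 60.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise NumericalError(
            f"no intercept root in [{lo}, {hi}] for target {target}; "
            f"gap({lo})={gap(lo):.4g}, gap({hi})={gap(hi):.4g}"
        )
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def _op_probs(config: CohortConfig, catalog: OPCatalog) -> np.ndarray:
    if config.op_weights is not None:
        w = np.array([config.op_weights.get(op, 0.0) for op in catalog.ids])
    else:
        w = np.ones(len(catalog.ids))
        w[0] = 4.0   # OP1 nervous system dominates real annotations
        w[6] = 2.5   # OP7 genitourinary well represented
        w[1] = 2.0
    if w.sum() <= 0:
        raise ConfigurationError("OP weights must have positive mass")
    return w / w.sum()


def generate_cohort(config: CohortConfig) -> tuple[Cohort, TruthRecord]:
    """Generate a cohort plus its ground truth; deterministic given seed."""
    catalog = OPCatalog()
    rngs = _streams(config.seed, 8)
    (rng_branch, rng_len, rng_burden, rng_disease,
     rng_op, rng_chrom, rng_sex, rng_kaks) = rngs

    branch, T, L, lnL, D, R = _draw_covariates(
        config, rng_branch, rng_len, rng_burden
    )
    beta0 = (
        config.disease_model.beta0
        if config.disease_model.beta0 is not None
        else solve_intercept(config)
    )
    prob = expit(beta0 + config.disease_model.linear_predictor(D, lnL, T))
    is_disease = (rng_disease.random(config.n_genes) < prob).astype(int)

    # organ-phenotype sets: per-branch median target from the growth curve
    ages = {s.id: s.age_mya for s in config.phylostrata}
    min_age = min(ages.values())
    curve = config.pleiotropy_curve
    med_target = {
        b: float(curve.predict((age - min_age) / TIME_UNIT_MYA))
        for b, age in ages.items()
    }
    op_p = _op_probs(config, catalog)
    n_ops = len(catalog.ids)
    lam = np.array([max(med_target[b] - 1.0, 0.0) for b in branch])
    counts = 1 + rng_op.poisson(lam)
    counts = np.clip(counts, 1, n_ops)
    op_ids = np.array(catalog.ids)
    op_sets: list[frozenset[str]] = []
    for i in range(config.n_genes):
        if not is_disease[i]:
            op_sets.append(frozenset())
            continue
        chosen = rng_op.choice(n_ops, size=int(counts[i]), replace=False, p=op_p)
        op_sets.append(frozenset(op_ids[chosen]))

    # chromosome placement
    chroms = list(config.chromosome_weights)
    cw = np.array([config.chromosome_weights[c] for c in chroms], dtype=float)
    cw = cw / cw.sum()
    chrom = np.array(chroms)[rng_chrom.choice(len(chroms), size=config.n_genes, p=cw)]

    # reproductive tagging: OP7 disease genes, male with prob alpha/(1+alpha)
    def chrom_class(c: str) -> str:
        return c if c in ("X", "Y") else "autosome"

    repro = np.array(["none"] * config.n_genes, dtype=object)
    for i in range(config.n_genes):
        if is_disease[i] and "OP7" in op_sets[i]:
            a = config.alpha_by_class.get(chrom_class(chrom[i]), 1.0)
            p_male = 1.0 if np.isinf(a) else a / (1.0 + a)
            repro[i] = "male" if rng_sex.random() < p_male else "female"

    # Ka/Ks: beta-distributed, mean decreasing in age, lower for disease genes
    kaks_mean = np.clip(0.42 - 0.0004 * T - 0.06 * is_disease, 0.02, 0.95)
    kappa = 8.0
    kaks = rng_kaks.beta(kaks_mean * kappa, (1.0 - kaks_mean) * kappa)

    gene_len = np.round(L * 3.0 * rng_len.lognormal(2.0, 0.5, config.n_genes))
    pos = rng_chrom.integers(1, 150_000_000, size=config.n_genes)

    genes = []
    for i in range(config.n_genes):
        genes.append(
            GeneRecord(
                gene_id=f"G{i:06d}",
                symbol=f"SYN{i:06d}",
                chromosome=str(chrom[i]),
                start=int(pos[i]),
                end=int(pos[i] + gene_len[i]),
                protein_length=float(np.round(L[i])),
                gene_length=float(gene_len[i]),
                branch=str(branch[i]),
                dnv_burden=float(D[i]),
                rare_burden=float(R[i]),
                plof_burden=float(np.round(kaks[i] * D[i], 4)),
                kaks={"chimp": float(np.round(kaks[i], 4))},
                is_disease=int(is_disease[i]),
                op_set=op_sets[i],
                repro_class=str(repro[i]),
            )
        )
    cohort = Cohort(genes, phylostrata=config.phylostrata, catalog=catalog)

    med_real = {}
    for s in config.phylostrata:
        vals = [len(op_sets[i]) for i in range(config.n_genes)
                if branch[i] == s.id and is_disease[i]]
        med_real[s.id] = float(np.median(vals)) if vals else float("nan")
    alpha_real = {}
    for cls in ("autosome", "X", "Y"):
        m = sum(1 for i in range(config.n_genes)
                if repro[i] == "male" and chrom_class(chrom[i]) == cls)
        f = sum(1 for i in range(config.n_genes)
                if repro[i] == "female" and chrom_class(chrom[i]) == cls)
        alpha_real[cls] = m / f if f else float("inf")
    truth = TruthRecord(
        disease_prob=prob,
        realized_prevalence=float(np.mean(is_disease)),
        branch_median_target=med_target,
        branch_median_realized=med_real,
        alpha_realized=alpha_real,
        beta0=float(beta0),
        seed=config.seed,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Config file loading and simulation outputs
# ---------------------------------------------------------------------------


def load_config(path: str | Path, seed: int | None = None) -> CohortConfig:
    """Load a CohortConfig from a YAML file; flat or nested keys mirror the
    dataclass fields. A seed argument overrides the file's seed."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for key in ("n_genes", "branch_weights", "length_log_mean", "length_log_sd",
                "target_prevalence", "op_weights", "chromosome_weights",
                "alpha_by_class", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "phylostrata" in raw:
        kwargs["phylostrata"] = tuple(
            Phylostratum(d["id"], d.get("name", d["id"]), float(d["age_mya"]))
            for d in raw["phylostrata"]
        )
    for key, cls in (("dnv_model", BurdenModel), ("rare_model", BurdenModel),
                     ("disease_model", DiseaseModel)):
        if key in raw:
            kwargs[key] = cls(**raw[key])
    if "pleiotropy_curve" in raw:
        kwargs["pleiotropy_curve"] = PleiotropyCurve(**raw["pleiotropy_curve"])
    if seed is not None:
        kwargs["seed"] = seed
    return CohortConfig(**kwargs)


def write_simulation(
    cohort: Cohort, truth: TruthRecord, out_dir: str | Path
) -> dict[str, str]:
    """Write gene table, annotation table, term->OP mapping, and truth JSON."""
    from genestrata.core_data import write_gene_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gene_path = out / "genes.tsv"
    write_gene_table(cohort, gene_path)

    # synthetic phenotype terms: one per OP system, with sexed reproductive
    # terms for OP7 so keyword classification is exercisable
    ann_path = out / "phenotype_to_genes.tsv"
    map_path = out / "term_to_op.tsv"
    rows = ["hpo_id\thpo_name\tgene_id\tgene_symbol"]
    mapping = ["hpo_id\top_system"]
    term_of = {op: f"HP:{9000000 + i + 1}" for i, op in enumerate(cohort.catalog.ids)}
    male_term, female_term = "HP:9100001", "HP:9100002"
    for op, tid in term_of.items():
        mapping.append(f"{tid}\t{op}")
    mapping.append(f"{male_term}\tOP7")
    mapping.append(f"{female_term}\tOP7")
    for g in cohort.genes:
        for op in sorted(g.op_set, key=lambda o: int(o[2:])):
            if op == "OP7" and g.repro_class in ("male", "female"):
                tid = male_term if g.repro_class == "male" else female_term
                name = (
                    "Male reproductive system abnormality (synthetic)"
                    if g.repro_class == "male"
                    else "Abnormal female reproductive system physiology (synthetic)"
                )
            else:
                tid = term_of[op]
                name = f"Abnormality of the {cohort.catalog.label(op)} (synthetic)"
            rows.append(f"{tid}\t{name}\t{g.gene_id}\t{g.symbol}")
    ann_path.write_text("\n".join(rows) + "\n")
    map_path.write_text("\n".join(mapping) + "\n")

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth.summary(), indent=2, sort_keys=True))
    return {
        "genes": str(gene_path),
        "annotations": str(ann_path),
        "mapping": str(map_path),
        "truth": str(truth_path),
    }
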