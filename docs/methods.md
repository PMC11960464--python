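# Methods

## Data model

Every analysis consumes a `Cohort`: a list of gene records joined to a set
of phylostrata and an organ-phenotype (OP) catalogue. A gene carries
1-based inclusive coordinates (Ensembl convention; all interval inputs must
share one assembly), a phylostratum id, protein and gene length, burden
scores (de novo variant burden D, rare-variant burden R, ultrarare pLOF
burden), optional pairwise Ka/Ks values, a binary disease state, the set of
OP systems its defects affect (nonempty exactly when the gene is a disease
gene), a reproductive class, and exclusion flags. The OP catalogue fixes
22 systems, OP1 = nervous system, OP7 = genitourinary (reproductive)
system; the remaining order is a package default and carries no meaning
beyond display.

Branch ages ship as TimeTree-style node ages (br0 Euteleostomi 435 Mya …
br6 Primate 74 Mya). These are package defaults, user-overridable via a
strata table, because the downstream statistics need *some* T_i and users
will generally want their own dating. T_i is treated as the node age of
the branch, not the branch length; this is a configuration choice and any
stratum→time map can be supplied instead.

### Cleaning and regrouping

`apply_exclusion_filters` drops mitochondrial, unplaced, RNA, and
neoplasm-only genes (counts logged per flag). `regroup_branches` merges any
stratum with fewer than 100 genes into its adjacent older stratum,
iterating youngest-first until stable; the merged stratum keeps the older
stratum's identity and age. Youngest-first iteration is a tie-break choice
(the merge order is otherwise underdetermined); the operation is
idempotent. `collapse_to_major_strata` relabels the seven branches into
four major phylostrata (Euteleostomi, Tetrapoda, Amniota, Eutheria by
default) and conserves counts.

### Reproductive classification

Genes are classed male/female/both by case-insensitive substring matching
of phenotype-term names against "reproduct", "male", "female", after
removing neoplasm terms. Because "male" is a suffix of "female", a naive
grep assigns male to every female term; we therefore match "male" only
when it is not the tail of "female" (regex `(?<!fe)male`). The guard is
configurable (`male_in_female_guard=False` restores the naive behaviour)
since either reading of a plain grep is defensible. "reproduct" alone
assigns both sexes; a gene matched in both sexes is "both".

## Emergence rates

r_i = O_i/(A_i·T_i) with O_i disease genes among A_i dated genes and T_i
in Mya. Internal arithmetic is kept in fractions; percent appears only in
explicitly labelled fields (this avoids silent 100× errors). The
per-generation scaling is r_year = (r%/100)/10⁶, μ_d = G·g·r_year,
r_RD = 10⁴·μ_d, with the "per 10,000" figure additionally reported rounded
to the nearest integer. No confidence intervals are attached to r.

## Pleiotropy and PEI

Pleiotropy of a disease gene is |op_set|. Per-stratum medians use the
interpolated (mean-of-central-pair) convention by default with a "lower"
option — integer medians in small strata do not disambiguate the
convention, so both are exposed. A stratum with no disease genes reports a
missing median, never zero. Increase rates between adjacent strata are
Δmedian/Δage in units per Mya.

The growth curve P(t) = P_max/(1 + ((P_max−P_0)/P_0)e^(−kt)) satisfies
P(0) = P_0 and P(∞) = P_max. P_0 and P_max are fixed at the empirical
extreme medians (defaults 4 and 10); only k is free. The time axis is
t = (stratum age − youngest stratum age)/100, i.e. units of 100 Myr with
t = 0 at the youngest stratum, so the curve starts at the youngest
stratum's median — with ages in raw Mya any plausible k collapses to ~0.01
and the curve degenerates numerically. k is found by bounded 1-D SSE
minimisation on (0, 50] with xatol 1e-12; its significance comes from the
NLS linearisation t-statistic (σ² = SSE/(n−1), se_k = σ/√Σ(∂P/∂k)², n−1
df). A reduced form P(t) = P_max/(1+e^(−kt)) is provided for illustration
only and never used in fitting.

PEI(i,j) for system i in stratum j sums 1/m_g over genes g in j annotated
to i (m_g = |op_set(g)|) and normalises across the stratum's systems to
percentages summing to 100. The per-stratum SD is taken across all 22
catalogue systems, counting absent systems as zero — the SD is meant to
capture how concentrated a stratum's enrichment is, and dropping empty
systems would overstate the spread of sparsely annotated strata.

## Logistic regression and model comparison

The disease-state model is a binomial GLM with logit link, fitted by IRLS
with step-halving; convergence requires the score max-norm < 1e-8 (max 100
iterations, both configurable). Standard errors come from the inverse
Fisher information at the optimum. Complete separation is detected (fitted
probabilities saturating at the labels / diverging coefficients) and
flagged on the result rather than raised; rank-deficient designs raise an
error naming the collinear terms. The implementation is cross-checked in
the test suite against statsmodels' independent GLM fit.

Predictors stay on their natural scales: T in Mya, lengths logged only in
ln-terms. No standardisation, so coefficients are directly interpretable
(e.g. per-Mya log-odds). The default ladder is nine nested specs ending in
the term set {D, lnL, T, D×lnL}; the intermediate compositions are a
package default since only the endpoint is canonical. Ranking is by AIC
with spec order as tie-break; nested pairs additionally get LRTs; a
per-spec failure (e.g. separation) is annotated without aborting the
ladder. No multiple-testing correction is applied anywhere.

Wilcoxon rank-sum uses the exact null distribution when min(n) ≤ 8 with no
ties, otherwise the tie-corrected normal approximation with continuity
correction; the result records which path ran. All comparisons are
two-sided by default. Spearman uses mid-ranks with the t-approximation;
degenerate inputs (constant ranks) are flagged, not raised. Proportion
ratios carry Katz log-scale CIs; the cross-product odds ratio with a Woolf
CI and Fisher's exact p are computed alongside under distinct labels,
because the two statistics are routinely conflated and differ materially
at these table margins.

## Chromosomal analyses

Expected disease-gene counts come from an OLS fit of predicate count on
total dated count over autosomes only; X and Y are always out-of-sample.
Excess rate is 100(n−e)/e. "Outnumbered by a factor" is reported as the
excess factor (m−f)/f, with the plain quotient m/f also available as α.
X intervals are closed on both ends; PAR genes (GRCh38 defaults
X:10001–2,781,479 and X:155,701,383–156,030,895) are excluded from both
numerator and background of X-region proportions, since PARs recombine and
escape hemizygosity. A gene's region is assigned from its start
coordinate. Overlapping intervals within one scheme are rejected at load.

## Synthetic cohorts

The generator emulates the statistical relations the analyses test — not
real human chromosome architecture or term frequencies. Steps draw from
independent child streams of one master seed (adding a step never perturbs
earlier draws). Defaults, chosen once as the study conditions:

- 20,000 genes; branch weights old-heavy (br0 0.55 … br6 0.07), mirroring
  the dominance of ancient genes in real phylostratigraphies.
- Protein length log-normal, ln-mean 6.1 (median ≈ 446 aa), ln-sd 0.6;
  gene length a log-normal multiple of coding length.
- Burdens are negative binomial (overdispersed, as real gene-wise burdens
  are; dispersion 3 for D, 5 for R) with exp-linear means in ln L and T,
  giving D a mean of ~2 per gene and a positive age–burden rank
  correlation.
- Disease assignment: logit = β0 + 0.29·D + 0.22·lnL + 0.0041·T −
  0.027·D·lnL, the canonical burden-model estimates used as ground truth;
  β0 is solved by Brent root-finding so the expected prevalence over the
  drawn covariates hits the target (default 0.25, the genome-wide
  disease-gene fraction scale).
- OP-set sizes: 1 + Poisson(median−1), truncated to [1, 22], with the
  per-branch median target taken from the growth curve (defaults P_0 = 4,
  P_max = 10, k = 1.66 per 100 Myr). The shifted-truncated-Poisson family
  is a documented choice — only the medians are constrained — and its
  realized medians track the targets within ±1 once a stratum holds
  thousands of disease genes.
- OP sampling weights favour OP1 and OP7; reproductive tagging assigns
  male with probability α/(1+α) per chromosome class (defaults α = 1.81
  autosomes, 8.89 X, 17 Y).
- Ka/Ks ~ Beta with mean decreasing in age and 0.06 lower for disease
  genes, reproducing stronger purifying selection on old and disease
  genes.

Because the generator draws from exactly the model family the regression
fits, passing recovery tests demonstrates correctness of the estimation
machinery, not realism of the model for real cohorts; real data add
ascertainment bias, annotation noise, and between-gene dependence that the
generator deliberately omits.

## Problem sizes and numerical choices

The test and acceptance runs use: 20 replicates of 20,000-gene cohorts for
coefficient and model-selection recovery (coverage ≥ 18/20 per
coefficient, selection ≥ 16/20); 2,000 null replicates at n = 400 for LRT
p-value uniformity (KS); 200 noisy replicates (σ = 0.5) for growth-rate
recovery; a 40,000-gene cohort (~10⁴ disease genes) for distributional
checks. These sizes make every check complete in seconds on a single core
while keeping Monte-Carlo error well inside the asserted tolerances.

Known limitations: no confidence intervals on emergence rates; the PEI SD
convention (zeros included) is one of several defensible definitions; the
ladder's intermediate models are a default, not canonical; exact Wilcoxon
is limited to tie-free small samples by construction.
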