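# Methods

This note documents the statistical procedures implemented in `mirimpact`,
the modeling assumptions behind them, the defaults and why they were chosen,
and what the synthetic-data tests do and do not establish about real data.

## Scope and data contract

The pipeline starts from *already normalized* expression matrices on the
log2 scale (features × samples, TSV) with a two-group sample sheet
(`case`/`control`). Probe-level normalization (RMA/PLIER and kin) is out of
scope by design: scale is a declared input contract, and readers validate
but never transform. Target predictions and gene-set annotations are
consumed as GMT files; the prediction algorithms themselves are not
implemented.

## Differential expression

### Detection filter (small-RNA path)

A probe is kept iff its detection fraction is **strictly greater than 0.5
within the case group and within the control group**. The per-group reading
is the stricter of the two natural interpretations of "detected in more
than 50% of the patients and controls"; a pooled-cohort variant can be
applied by the caller but is deliberately not the default, since per-group
detection guards against a probe detected only in one arm.

### Ordinary and moderated t

Both tests are equal-variance (pooled) two-sample t-tests, two-sided. The
moderated variant shrinks each feature's sample variance toward a prior:

    s~²_g = (d0·s0² + df·s²_g) / (d0 + df)
    t_g   = (mean_case − mean_control) / sqrt(s~²_g (1/n1 + 1/n2)),  df_total = d0 + df

under the hierarchical model s²_g | σ²_g ~ σ²_g·χ²(df)/df with
σ²_g ~ s0²·d0/χ²(d0) (scaled inverse chi-square). Hyperparameters are
estimated by method of moments on e_g = log s²_g − ψ(df/2) + log(df/2):
the excess of var(e) over mean ψ′(df/2) identifies d0 through the inverse
trigamma (solved by bracketed root-finding to 1e-12), and mean(e) identifies
s0². When the observed spread does not exceed sampling noise the prior is
degenerate: d0 = ∞ and every gene uses s0² (normal reference). d0 = 0 is
also accepted and reduces exactly to the ordinary t — this limit is
exercised as an equivalence test. The full moderated path is additionally
cross-checked in the test suite against an independent linear-model
implementation (limma's `eBayes`, run through Rscript), which agrees with
this implementation to ~1e-13 on hyperparameters, t and p.

Degenerate features (zero pooled variance) are retained: equal means give
t = 0, p = 1; separated means are flagged `degenerate` with t = ±∞, since a
p-value has no finite-sample meaning there.

Fold change is the geometric-mean ratio 2^(Δ of log2 means). Log-scale array
data make the geometric mean the standard choice; an arithmetic-mean ratio
is available behind the `arithmetic_ratio` flag for comparison with
linear-scale summaries.

### Storey q-values

q-values use the single-point π₀ estimate π₀ = min(1, #{p > λ}/(m(1−λ)))
with **λ = 0.5 fixed** (exposed as a parameter), then the cumulative-minimum
construction q_(i) = min_{j≥i} π₀·m·p_(j)/j. The single-point estimate was
chosen over the spline smoother for determinism and transparency; with
π₀ = 1 (λ = 0) the procedure is exactly Benjamini–Hochberg, which the test
suite asserts against statsmodels.

## KS target-impact test

For each miRNA and each prediction source, the log2 fold changes of the
predicted targets present in the analyzed universe are compared against the
background = universe \ targets (recomputed per miRNA) with a two-sample,
two-sided KS test. The universe is the post-filter mRNA results table, not
the whole genome, because fold changes only exist for analyzed genes.

The p-value uses the asymptotic Kolmogorov distribution
Q(λ) = 2Σ(−1)^{j−1}e^{−2j²λ²} evaluated at
λ = (√n_e + 0.12 + 0.11/√n_e)·D, n_e = n_x n_y/(n_x+n_y) (Stephens'
small-sample factor). **Known limitation:** this is a large-sample
approximation. It agrees with the exact two-sample null distribution to
~0.01 at n ≈ 60–80 per side (unit-tested against an exact enumeration), but
for very small samples (effective size n_e below ~4, e.g. both sides ≤ 6) it
can differ from the exhaustive permutation p by far more than 0.05 — at
n_x = n_y = 1 the permutation p is exactly 1 while the formula gives 0.29.
In the intended application the two sides are hundreds of targets vs
thousands of background genes, where the approximation is excellent. Callers
with tiny target sets should use an exact or permutation procedure instead.

Design choices: the test is two-sided (a shift in either direction counts as
impact), with the direction of the median shift reported separately;
p-values are not multiplicity-corrected, matching the per-miRNA reporting
convention of the published table the fixtures mirror. Classification of a
miRNA as "affecting its targets" requires a numeric p < 0.05 (strict) from
at least one prediction source; the NA state (no predictions available) and
the NS state (present only in the published fixture: computed but not
printed) never qualify.

## Reporter-algorithm enrichment

Per-gene significance values (q-values by default, raw p behind a flag —
the default follows the upstream choice of overlaying q-values on GO) are
transformed by z = Φ⁻¹(1 − p), with p clipped to [1e-15, 1−1e-15] to keep
the quantile finite. A term of size k scores z_raw = Σz/√k, and is
standardized against the empirical mean and sd of the same score over
random k-subsets of the universe sampled **without replacement**
(default 10,000 subsets; background moments are cached per set size within
one run, so equal-size terms share one background). p_enrichment is the
normal upper tail of the standardized score.

Directionality uses two one-sided runs per term: members restricted to
up-regulated genes (sign of log2 fold change ≥ 0) with p halved, scored
against the up-restricted universe, and symmetrically for down-regulated
members. The more significant class wins (ties resolve to "over") and sets
the sign of the reported score ±(−log₁₀ p). Two classes suffice for an
over/under heatmap; the finer five-class directional schemes of gene-set
packages are intentionally not reproduced. A term equal to its whole class
universe is uninformative and scores (z_adj = 0, p = 0.5) by definition.
Terms with fewer than 3 members in the universe are dropped.

## Integration

A gene enters the integrated table iff it is differentially expressed and is
a predicted target — **union over the prediction sources** — of at least one
DE miRNA. Union, not intersection, because a miRNA covered by a single
database still counts as impactful in the per-source classification. Top
tables rank by fold change (> 1 descending; < 1 ascending) with q-value and
then gene ID as deterministic tie-breaks; fold change exactly 1 joins
neither list. Functional-module enrichment is implemented as hypergeometric
over-representation of the integrated genes in each module against the
analyzed universe, p = P(X ≥ x) — an interpretation chosen here, as the
usual over-representation reading of "module enrichment", not a
re-implementation of any specific published module method. The bipartite
graph carries `kind` and `direction` node attributes and is serialized as an
edge-list TSV plus a node-attribute TSV; no layout is computed.

## qPCR statistics

ΔCt = Ct(target) − Ct(reference gene) per sample; ΔΔCt centers on the
**arithmetic mean ΔCt of the reference group** (the geometric mean on the
linear scale, per the standard comparative-Ct method), so the geometric mean
of reference-group RQ is exactly 1. RQ = 2^−ΔΔCt; summaries are mean ± SEM.
Technical replicates are expected to be averaged on the Ct scale before
entry. Group differences use the same pooled t-test as the array path
(asserted identical in the tests). Values below an assay detection limit,
when present, should be floored at the limit before analysis; the package
does not guess a treatment.

## Synthetic-data generator

`generate_study` draws everything from one seeded generator in a fixed
order, so a config reproduces a study bit-for-bit. Defaults describe the
emulated two-platform design:

| parameter | default | meaning |
|---|---|---|
| n_case / n_control | 11 / 9 | small-RNA arm cohort |
| n_case_mrna / n_control_mrna | 10 / 9 | mRNA arm cohort (overlapping but non-identical participants; noise is independent between arms) |
| n_mirna / n_gene | 1,000 / 20,000 | platform sizes |
| n_de_mirna | 21 | planted down-regulated miRNAs |
| mirna_log2fc_range | (−2.8, −0.6) | planted shifts, spanning fold changes ≈ 0.14–0.66 |
| targets_per_mirna_mean | 200 | Poisson mean of target-set sizes (truncated ≥ 5) |
| repression_transfer_max | 0.5 | β_max; target g of miRNA m is shifted by −β·δ_m, β ~ U(0, β_max) |
| prior_df / prior_scale | 4 / 0.05 | scaled-inverse-χ² variance prior (d0, s0²) |
| gene baselines | Normal(7, 1.5) | log2 intensities |
| n_de_gene_independent | 200 | DE genes not explained by miRNAs, effects ±U(0.5, 2) |
| detection_prob | 0.9 | Bernoulli detection per cell; planted miRNAs forced detected |
| map2_resample_fraction / map2_absent_fraction | 0.3 / 0.2 | second prediction source: partial overlap, some miRNAs absent |
| n_go_terms, sizes, n_enriched_terms | 100, U(10,100), 5 | annotation; enriched terms seeded with ~50% strongly up-regulated planted genes |

Down-regulated miRNA ⇒ **up**-shifted targets (de-repression) is the
default, matching canonical miRNA biology; the sign is configurable.
Effect sizes for mRNA shifts have no published counterpart, so the defaults
were chosen once for testability (planted effects detectable at the given
cohort sizes), not as estimates of any real dataset.

What the generator does *not* emulate: probe-level effects, batch and
spatial artifacts, cross-hybridization, correlated co-expression beyond the
planted regulatory structure, and annotation bias in GO. Passing recovery
tests therefore demonstrates the statistical machinery is correct and
calibrated under the stated model — not that the pipeline is robust to
real-array artifacts.

## Numerical choices

* Kolmogorov series summed with alternating terms to 1e-12 relative
  convergence, capped at 100 terms (tiny λ returns the limit 1).
* Inverse trigamma by Brent bracketing, tolerance 1e-12; verified to round
  trip to 1e-8 over [1e-4, 10].
* p-values clipped to (tiny, 1]; reporter inputs clipped at 1e-15.
* Background subset sampling is chunked to ≈2e7 doubles of workspace.
* All tie-breaks (top tables, direction ties, GMT writing) are
  deterministic; two runs of the full pipeline with one seed are
  byte-identical, which the acceptance suite asserts.

## Test problem sizes

Stochastic suites run at desk scale chosen as the package's own test
design: null calibration at 2,000 genes × 200 miRNAs × 20 seeds; variance
prior recovery at 2,000 genes × 20 seeds; KS power at 5,000 genes with
~200 targets per miRNA × 20 seeds; reporter calibration at 200 terms × 10
seeds with 1,000 background subsets per size (the API default is 10,000).
The published cohort-scale counts (thousands of DE genes, the specific
920/100/21 integration counts) depend on the original arrays and 2011-era
prediction snapshots and are not reproduction targets of this package.
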