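# Methods

This note documents the models, numerical conventions and design choices
behind `slepipe`, and what the synthetic-data tests do and do not establish
about behaviour on real data.

## Synthetic cohorts

**LD model.** SNPs are partitioned into blocks laid round-robin over 22
autosomes (5 kb SNP spacing inside a block, 1 Mb gaps between blocks, so
blocks are effectively unlinked while the ±300 kb cis window and ±100 kb
pooled-support window span a whole block). Each block carries a finite pool
of haplotypes; a subject's two haplotypes per block are uniform draws with
replacement from the pool, and genotype = haplotype sum. Within a block the
pool is generated by a first-order Markov chain whose adjacent-SNP allele
correlation is `block_ld_rho` (joint cell probability
`p11 = p_i p_j + rho*sqrt(p_i q_i p_j q_j)`, clamped to the Fréchet
bounds); allele-1 frequencies are uniform on `maf_range` (default
0.05–0.5). The finite pool makes LD oracles exact: r² and D′ can be
recomputed by direct haplotype counting on the emitted draws. The default
pool size is 200 haplotypes per block; a much smaller pool (e.g. 20)
injects spurious background LD of order 1/(pool−1) ≈ 0.05 between unlinked
SNPs, which defeats null-LD checks, so 200 is the default and the size is
a config field for users who want strong finite-pool drift.

**Disease model and ascertainment.** Disease risk is additive on the
logit: `logit P(case) = b0 + Σ log(allele_or) · dosage` over the configured
risk SNPs. `b0` is solved by Brent root-finding (tolerance 1e-8) so that
the population prevalence matches `prevalence` (default 0.01, a plausible
order for a chronic autoimmune disease study design); the genetic-score
distribution entering that solve is computed exactly by enumerating pool
haplotype pairs per block and convolving across blocks. Cases and controls
are ascertained by rejection sampling: candidate subjects are drawn as
block-pool indices (cheap), status is Bernoulli from the liability, and
full genotypes are materialised only for subjects kept to fill the
`n_cases`/`n_controls` quotas exactly. Missingness is applied afterwards,
completely at random at `missing_rate` (default 0.2%). Replication cohorts
reuse the same haplotype pools (same marker panel and allele frequencies)
with independent subject-level random streams.

**Expression.** The first `n_expr_samples` subjects (default 90, a
HapMap-scale lymphoblastoid panel) form the expression panel. Each risk SNP
with an `eqtl_beta` receives one causal probe placed uniformly within
±250 kb (safely inside the ±300 kb cis window) with expression
`beta · dosage + N(0, expr_noise_sd)`, plus local decoy probes; every
block additionally receives `probes_per_region` pure-noise decoy probes
(default 5, matching the ~4.9 probes per SNP of genome-scale arrays) so
that non-causal SNPs are genuinely tested downstream.

**Pooled scan.** Scores are standard normal; SNPs within 100 kb of a
causal locus get a mean shift of `pooled_enrichment` (default 4.0) decayed
exponentially with distance (50 kb scale), then scores are converted to
rank-based P = rank/N. The real pooled-DNA scoring procedure is not
reconstructed — only the statistical shape the selection step consumes
(uniform null ranks, inflated signals near causal loci). Note the
granularity constraint: rank-based P cannot fall below 1/N, so a scan of
fewer than ~200 SNPs can never satisfy the strict `rank_p < 0.01` support
rule; synthetic scenarios exercising pooled support use ≥200 SNPs.

**qPCR/ASTQ.** Ct = offset − log₂(template amount) + channel shift +
N(0, `noise_sd_ct`). The VIC channel carries a probe-specific shift
(default +0.4 cycles) absorbed by the standard curve's intercept; each
sample has a random total input amount which cancels in ΔCt. The mixture
series is the conventional 2:8 … 8:2 genomic-DNA ladder.

## Statistical procedures

* **HWE exact test** — conditional on allele counts, heterozygote counts
  follow the classical urn distribution; log-probabilities are computed
  via `gammaln` and normalised by `logsumexp`; the two-sided P sums all
  heterozygote counts no more probable than observed, with a 1e-12
  log-scale tolerance for float ties. Monomorphic tables return 1.
* **Cochran–Armitage trend** — scores (0,1,2);
  `chi2 = N (N·Σw r − R·Σw n)² / (R (N−R) (N·Σw² n − (Σw n)²))`; this
  equals the logistic score test of slope = 0 (the identity the test suite
  exploits as an independent oracle). Zero score variance → chi2 0, P 1.
* **Allelic OR** — allele counts from subject counts and frequencies use
  round-half-away-from-zero (printed frequencies are rounded, and this
  convention reproduces published table arithmetic); Woolf (log-OR normal)
  95% CI; a zero cell triggers the 0.5 continuity correction and a flag.
* **Mantel–Haenszel** — OR_MH = ΣR_i/ΣS_i with R_i = a_i d_i/N_i,
  S_i = b_i c_i/N_i; CI from the Robins–Breslow–Greenland variance; the
  combined P is the 1-df MH chi-square without continuity correction
  (cross-checked against `statsmodels.StratifiedTable` in tests). Strata
  with N ≤ 1 are skipped; all-degenerate input is an error.
* **eQTL mapping** — expression is rank-based inverse-normal transformed
  per probe (Blom offset (r−3/8)/(n+1/4); ties get average ranks; constant
  probes become zeros and are flagged); cis pairing intersects the probe
  interval with the SNP-centred window, boundaries inclusive, converting
  BED half-open coordinates at that boundary only; OLS slope with
  two-sided t P; one global BH family across all tested pairs (the
  conservative reading of a study-wide FDR screen; a per-SNP family is a
  caller-side regrouping of the same table).
* **LD (r², D′)** — EM over the four haplotype frequencies from unphased
  two-SNP genotype tables; only the double heterozygote is ambiguous;
  convergence when the largest frequency change is < 1e-10, max 1000
  iterations (non-convergence is an error carrying the iteration count).
* **IBD** — PLINK-style method of moments: expected IBS-class
  probabilities given IBD state are accumulated from sample allele
  frequencies; (z0,z1,z2) solved sequentially, truncated to [0,1] and
  renormalised; pairs with < 100 informative SNPs are flagged
  low-information. The related-pair removal is greedy in descending π̂,
  dropping the lower-call-rate member (tie: lexicographically larger id) —
  deterministic, and guaranteed to break every flagged pair.
* **PCA ancestry** — mean-imputed standardised genotypes, SVD; a study
  sample is an outlier when its distance from the study-cluster median on
  PCs 1–2, in per-PC SD units, exceeds `pca_outlier_sd` (default 6). LD
  pruning before PCA/IBD: sliding window 50 SNPs, step 5, r² > 0.2.
  Without a reference panel the PCA runs on the study alone with a
  warning. The 6-SD rule and pruning parameters are conventional
  reconstructions, configurable.
* **QC orchestration** — sample call-rate and SNP filters alternate to a
  fixed point (each removal can shift the other axis' statistics), which
  makes the full battery idempotent; every exclusion carries exactly one
  primary reason code, assigned in the fixed order call_rate → maf → hwe →
  non_autosomal → not_shared. All QC comparisons are strict `<`, so values
  exactly at a threshold are retained.
* **Selection** — thresholds are pure configuration
  (`SelectionThresholds`); the compound rule's boundaries are exactly as
  stated (P = 1e-4 falls in the mid band and needs eQTL positivity).
  Clumping is greedy by ascending P (ties: smaller position, then id) with
  a ±500 kb locus window; known-locus exclusion uses ±200 kb. Neither
  radius has a canonical published value; both are documented defaults and
  config fields. Pooled support is SNP-to-SNP (distance to the pooled
  marker itself, not to a signal region); when LD against a pooled marker
  cannot be computed (marker absent from the genotype panel) the distance
  criterion alone applies and the decision is annotated.
* **Replication gates** — Mantel–Haenszel over discovery + replication 1,
  gate P < 1e-6; then all three stages, final P < 5e-8. Allele orientation
  across stages is reconciled by letter matching with strand-flip
  tolerance for non-ambiguous SNPs; A/T and G/C SNPs without orientation
  metadata are an error. Missing stage tables for a candidate are an
  error, never a silent skip.
* **ASTQ** — replicates are averaged on the Ct scale before curve fitting;
  the curve regresses mean ΔCt = Ct(VIC)−Ct(FAM) on log₂(mixture ratio)
  (ΔCt = −log₂ ratio + intercept under perfect efficiency — more template
  means a *lower* Ct, which fixes the sign convention throughout);
  |slope| < 0.2 is rejected as uninformative. Ratios invert through
  `2^((ΔCt − intercept)/slope)` with first-order error propagation of the
  replicate SE. Each line's cDNA ratio is normalised by its *own*
  genomic-DNA ratio (per-line pairing), and imbalance is a paired
  two-sided t-test on log₂ ratios with geometric means reported;
  identically-zero differences return P = 1.

## Problem sizes used by the test and acceptance runs

Simulation-backed checks run at the discovery-stage subject counts
(891 cases / 3,384 controls) but a reduced marker panel: 5 SNPs for OR
coverage (100 seeds), 200 SNPs in 40 blocks with 90 expression samples for
the 200-seed selection-rule comparison, a 10,000-SNP independent null
panel for type-I error and λ_GC, and 100 seeds of the 17-line ASTQ design.
These sizes give the reported rates sampling errors well inside the
asserted bands while keeping a full run in minutes.

## What the synthetic tests do and do not show

The generator reproduces the *statistical* structure the pipeline assumes:
blockwise LD, additive logistic risk, additive cis-eQTL effects with
Gaussian noise, uniform null rank-P, and the log₂ Ct law. It does not
emulate genotyping-batch artefacts, population stratification (beyond a
single divergent-sample injection helper for the PCA test), differential
missingness, probe cross-hybridisation, or qPCR efficiency drift — so
green tests certify the arithmetic and the decision logic, not robustness
to those real-data pathologies. The packaged table of 26 known
susceptibility loci is transcribed summary data (P-values, eQTL flags,
discovery-population marks) and is checksum-guarded; its replication and
positivity rates are desk-scale arithmetic, not re-analyses. Genotype
imputation, pooled-array score computation, probe remapping and X-linked
markers are out of scope by design.
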