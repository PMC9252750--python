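# Methods

This note documents the statistical model, the tunable parameters, the
synthetic study the tests rely on, and the numerical and design choices
made where the published description of the approach leaves the details
open.

## Model and procedure

The pipeline assumes that the genes driving a phenotype tend to be
selectively expressed in its driver tissues and cell types. It couples
three estimators:

1. **Effective chi-square (ECS) gene test.** Per-variant P-values
   inside a gene window (gene span ± flank) are converted to 1-df
   chi-square quantiles and summed; the sum is referred to a scaled
   chi-square null whose first two moments match those implied by the
   LD matrix of the reference panel, using cov(q_i, q_j) ≈ 2 r_ij².
   The original ECS software is published separately and its internals
   are not restated in the description this package follows; the
   moment-matching construction here is a deliberate, deterministic
   reconstruction of its stated purpose (removing redundant
   associations among correlated variants). Its exact contracts — the
   single-variant reduction, the collapse of r = 1 duplicates, and the
   identity-LD reduction to χ²_m — are enforced by tests.

2. **Robust-regression Z (REZ) selective expression.** For each column,
   log2(CPM+1) is regressed on the per-gene leave-one-out median of
   log2(CPM+1) over the remaining columns. The leave-one-out baseline
   prevents the focal column from pulling its own reference; the Huber
   fit prevents the genuinely selective genes from tilting the trend.
   The regression design of the original REZ formulation likewise lives
   in a separate publication; the reconstruction here (simple
   regression on the leave-one-out median, Huber IRLS, MAD scale) is
   flagged as such and validated against an OLS oracle on clean
   Gaussian panels, where the two must coincide.

3. **Iterative conditional estimation.** Each pass (i) ranks all panel
   columns by a one-sided Wilcoxon rank-sum test of the current
   associated genes' z against the rest, (ii) orders the associated
   (retained) genes by z in the top column — ties by smaller p, then
   symbol — and (iii) re-tests every other gene after shrinking each of
   its variant chi-squares by (1 − min(r²_cap, max r²)) against
   retained-gene variants on the same chromosome within a window.
   Because the calibration (a, d) is kept and chi-squares only shrink,
   conditional P-values are never smaller than unconditional ones. The
   loop stops when the associated set repeats; the trace then ends with
   two identical gene sets.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| gene window flank | 5 kb | symmetric, conservative window for assigning variants to genes; configurable |
| UMI floor | 300 | cells with fewer total UMIs are dropped (strict `<`) |
| cluster floor | 15 cells | pooled clusters below this are dropped (after same-label merging) |
| top fraction | 0.10 | per pooled cluster, ceil(0.10 n) highest-depth cells are averaged |
| TMM trims | 30% of M, 5% of A | canonical doubly-trimmed mean; unweighted (only the trims are prescribed); factors rescaled to geometric mean 1 |
| Huber constant | 1.345 | standard 95%-efficiency tuning; IRLS max 50 iterations, tol 1e-8 |
| association rule | BH-FDR < 0.05, floor 10 | the floor keeps the Wilcoxon groups defined when few genes pass |
| r² cap | 0.95 | avoids total erasure of a candidate by near-duplicate variants; the uncapped behaviour (full overlap ⇒ conditional p = 1) is available at cap 1.0 |
| conditioning window | 10 Mb | same-chromosome LD horizon; cross-chromosome r² = 0 |
| max iterations | 10 | convergence is exact set equality of consecutive associated sets |
| tissue significance | FDR < 0.05 | defines the organ set for the hierarchical cell-type stage (Bonferroni also reported) |

## Synthetic study conditions

The generator plants an exactly known truth: 20 tissues (one organ
each, 3 cell types per organ), 1,000 genes, 40 causal genes boosted by
+2 log2 units in a single driver column, one 5-variant LD block per
gene (latent AR(1) ρ = 0.5 thresholded at allele frequency 0.3,
500 diploid reference samples), and GWAS P-values that are Uniform(0,1)
for null variants and noncentral-χ²(1, ncp = 30) for causal-gene
variants. Association is injected at the P-value level because
P-values are all the downstream method consumes; this isolates the
tested contracts from phenotype-model assumptions.

What the generator does **not** emulate: realistic human LD maps and
cross-gene LD (blocks are independent), population structure, allele
frequency spectra, polygenic background, expression correlation between
tissues of the same organ system, batch effects, and dropout noise
beyond Poisson sampling. Passing recovery tests therefore shows the
estimators are correct and well calibrated under their own model, not
that real GWAS-to-cell-type inference is this clean.

The single-cell fixture is designed so that every panel-construction
rule fires at least once (a shallow-depth cluster for the UMI floor, a
14-cell cluster, an UNKNOWN label, a diseased sample, a same-label pair
that must merge), and the surviving column set is known by
construction.

Problem sizes in the test-suite and acceptance script (50 replicates
for driver recovery, 20 for the reported recovery rate, 1,000 and 400
null column tests, 2,000 null genes, exhaustive hypergeometric
enumeration to N = 30/25) were chosen as the smallest runs whose
binomial/KS noise is well inside the asserted bands.

## Numerical choices and edge cases

- P-values of exactly 0 in summary files are clamped to 1e-300 with a
  warning; genome-wide files routinely underflow. Computed tail
  probabilities are floored at the same value, keeping them in (0, 1].
- Missing genotypes are mean-imputed per site before correlation;
  monomorphic and non-biallelic-SNV records are excluded with counts.
- Wilcoxon enrichment uses full enumeration of labelings over midranks
  when both groups have ≤ 8 members (ties handled exactly; an all-tied
  column gives p = 1) and the tie- and continuity-corrected normal
  approximation otherwise, with a zero-variance guard returning 1.
- The hypergeometric tail is computed as the upper sum of log-gamma
  binomial terms (logsumexp), equal to 1 − the lower sum but stable for
  corpus-scale N.
- REZ scale: 1.4826 × MAD of residuals. When the MAD underflows
  (more than half the residuals numerically zero) the residual SD is
  used instead, so a lone selective gene on an otherwise noise-free
  panel still scores; only a fully perfect fit yields z = 0 (with a
  warning). A perfect OLS pre-fit short-circuits the IRLS, which cannot
  iterate on a zero scale.
- "Top 10% highly expressed cells" is interpreted as cells ranked by
  total UMI, taking ceil(0.10 n); merging of same-labeled clusters
  happens before that selection, on the pooled cells. Both choices are
  exposed as parameters.
- Homolog mapping keeps strictly one-to-one pairs; many-to-one and
  one-to-many mappings are dropped (logged) to avoid double counting.
  Column totals are not re-normalized after gene removal; the fact is
  recorded in column provenance.
- A pooled cluster is treated as diseased if any of its cells carries
  the abnormal flag; the flag is curation input, never inferred from
  free-text metadata.
- Gzip output members are written with a zeroed timestamp so repeated
  runs are byte-identical.
- Tie-breaks are deterministic everywhere: column ranking by (p-value,
  column id), retained-gene order by (−z, p, symbol), similarity
  ranking by (−jaccard, phenotype id).

## Design decisions taken where the design was open

- Conditioning operates at the variant level (residual chi-squares),
  not on gene statistics; the re-test keeps the original gene LD
  calibration, which guarantees monotonicity of conditional P-values.
- The iteration re-estimates the retained order from the single
  top-ranked column each pass (not a pool of top columns); configurable
  by re-running with a manual organ list.
- If every gene would be "associated" (degenerate Wilcoxon), the
  largest-p gene is excluded to keep a proper subset; if fewer than 10
  pass, the 10 smallest-p genes are used.
- The hierarchical stage falls back to all cell types (with a warning)
  when no tissue is significant, and accepts a manual organ list that
  bypasses the automatic selection.

## Known limitations

- The ECS and REZ internals are reconstructions (see above); numerical
  agreement with the original software is not claimed, only the
  documented contracts.
- The moment-matched null is an approximation to the true distribution
  of correlated chi-square sums; its calibration is verified under
  identity LD and by the null-uniformity tests, not proved in general.
- Cross-gene conditioning ignores LD beyond the 10 Mb window.
- TMM factors are computed but panel aggregation consumes CPM columns;
  composition correction matters only for strongly unbalanced bulk
  libraries.
- The landscape significance convention (what defines N) is
  input-driven: the table the user supplies defines the universe of
  tests.
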