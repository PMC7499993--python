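# Methods

## Response binarization

Multi-level clinical response annotations are collapsed to responder (R) /
non-responder (NR) through named, dataset-family-specific rules
(`coremarkers.response.RESPONSE_RULES`):

| rule | R | NR | used by |
| --- | --- | --- | --- |
| `breast_cr_pr` | complete + partial response | residual + progressive disease | all breast-cancer cohorts |
| `stable_as_responder` | complete + partial response + stable disease | progressive disease | TCGA cohorts, tipifarnib AML |
| `myeloma_gse9782` | complete + partial response | no change + progressive disease | bortezomib myeloma |
| `myeloma_vgpr` | complete, near-complete, very good partial | partial, minor, worse | remaining myeloma cohorts |
| `target_survival` | — (survival threshold) | — | pediatric TARGET cohorts |

Categories are canonicalized (lowercase, hyphens and whitespace runs
collapsed) before lookup, because public annotations spell the same group
inconsistently. An unknown category is an error naming the category and the
rule; nothing is ever guessed.

## Survival-threshold split

TARGET cohorts are annotated only with event-free survival (EFS) in days,
whose distribution shows a short-survival mode (progression/relapse) and a
long-survival mode. The split works on log EFS time:

1. Fit a two-component Gaussian mixture by EM, 10 starts (one initialized at
   the 25%/75% quantiles of log time, nine random restarts under a fixed
   seed), keeping the best log-likelihood.
2. Declare the split defensible only if (a) BIC prefers two components over
   a single-Gaussian fit, and (b) the separation |μ₂ − μ₁| / σ_pooled, with
   σ_pooled² the weight-averaged component variance, is at least
   `min_separation` (default 1.0). Otherwise raise the *unimodal* error: no
   responder split should be manufactured from a unimodal cohort.
3. The threshold is the equal-posterior point between the component means
   (solved by bracketed root finding on the posterior log-odds), mapped back
   to days. Samples with EFS time ≥ threshold are responders (the boundary
   is closed on the responder side).

The BIC gate is the load-bearing part of the degeneracy check: a
two-component EM fit on genuinely unimodal data usually splits the bulk and
a tail into components roughly 1–2.5 pooled sd apart, so a separation floor
alone almost never triggers. Measured over 200 seeds of a single lognormal
(log-sd 0.3, n = 100–120), BIC + separation refuses in ≈ 98–99% of seeds
while accepting a well-separated two-mode mixture (medians 200/1500 days,
log-sd 0.3) in 200/200 seeds, with the threshold always between the true
component medians. For equal weights and equal log-sd the equal-posterior
point is the geometric mean of the medians, √(200·1500) ≈ 548 d, and the
fitted threshold's median across seeds lands within a few days of it.

Censoring and event indicators are not modeled — raw EFS time only. The
fit is performed in the log domain, so rescaling all times by c > 0 scales
the threshold by c.

## Per-gene AUC and ranking

For one gene, AUC = (pairs where a responder exceeds a non-responder + half
the tied pairs) / (|R|·|NR|), computed from midranks:
U = ranksum_R − |R|(|R|+1)/2, AUC = U / (|R|·|NR|). U is a half-integer and
exact in double precision; the oriented score is computed as
max(U, D − U)/D with D = |R|·|NR| so that swapping class labels gives a
bit-identical ranking (computing max(AUC, 1 − AUC) in floating point is
asymmetric by one ulp, enough to flip a tie at a rank boundary). Ranking
order is (oriented AUC descending, gene id ascending) — total and
deterministic; ties at the top-Q boundary keep the lexicographically
smaller gene id. Missing or non-finite expression values are rejected, not
imputed. The conventional 0.7 biomarker-quality threshold is carried as an
annotation flag only, never used as a filter.

## Leave-one-out core extraction

For each sample i, the top-Q list is computed on the matrix without sample
i, and the core set is the intersection over all N folds exactly — no
"present in ≥ x% of folds" relaxation. Folds are keyed by the left-out
sample id, so results do not depend on column order. Q defaults to 30 and
must stay below N (enforced); cohorts below 40 cases trigger a coded
SMALL_N warning but still run. With the deterministic tie-break the top-Q
lists are nested in Q, so the core set is monotone in Q, and intersecting
any additional fold can only shrink it — both properties are tested.

Rather than re-ranking each of the N folds from scratch
(O(G·N²·log N)), the implementation computes each fold's Mann–Whitney
numerator incrementally from the full-data numerator: removing responder i
subtracts that sample's win/tie count against all non-responders, obtainable
from one sorted search per gene, giving O(G·N·log N) overall. All
corrections are half-integers, so the fast path is bit-identical to naive
re-ranking; unit tests verify fold-by-fold agreement against an exact
rational-arithmetic oracle on tie-rich data.

Suitability: a cohort is judged able to support classifier training when
the core set holds at least `min_core_genes` genes (default 7, the lower
end of what well-balanced public cohorts yield; cohorts judged unusable
yielded 2–3). The suitability report carries the per-fold list sizes and
the class balance min(|R|,|NR|)/N as diagnostics.

## Synthetic cohorts

The generator (`coremarkers.simulate`) draws what the analysis assumes and
nothing more:

- **microarray_gaussian** — per-gene baseline means ~ N(7, 1) on the
  log-intensity scale, unit-variance noise; the first `n_markers` genes are
  shifted by `effect_size` sd in the responder class, sign drawn per marker
  so both up- and down-regulated markers occur.
- **rnaseq_negbin** — negative-binomial counts (dispersion 0.2 by default)
  with per-gene lognormal base means, per-sample library sizes log-uniform
  within a factor of 4, then log2 CPM with a 0.5 pseudocount. Marker shifts
  are applied on the log scale in units of each gene's approximate log-count
  sd √(dispersion + 1/mean), keeping the meaning of `effect_size` aligned
  across families. The true library sizes are retained on the dataset for
  normalization diagnostics (a null gene's AUC is uncorrelated with the
  library-size split after CPM, |r| < 0.1 over 100 seeds).
- **survival** — a two-component lognormal mixture (defaults: equal
  weights, medians 200/1500 days, log-sd 0.3) with true component
  membership retained for recovery scoring.

Defaults (G = 1000 genes, 40+40 samples, 10 markers at 3 sd, Q = 30) are a
desk-scale stand-in for the public cohorts (~20k genes, 41–508 cases): large
enough to exhibit the ranking and stability behavior, small enough that
hundreds of replicate cohorts run in seconds. Everything derives from one
integer seed; identical seeds give bit-identical cohorts.

What the generator deliberately omits — batch effects, platform differences,
correlated co-expression blocks, annotation noise, censoring — bounds what
green tests mean: they demonstrate the selection machinery behaves as
specified under its own assumptions, not that real cohorts are this clean.

## Measured behavior of the procedure

- **Recovery**: with 10 planted markers at 3 sd (G = 1000, N = 80 balanced,
  Q = 30), all ten markers land in the core set in ≥ 95 of 100 seeds
  (measured: 100/100).
- **Imbalance degradation**: at fixed N = 80 and effect 3 sd, the mean core
  size over 100 seeds per level falls monotonically as the minority-class
  fraction drops — ≈ 21.2 / 18.6 / 15.4 / 12.4 genes at fractions
  0.5 / 0.25 / 0.1 / 0.05 — mirroring the small cores of the imbalanced
  public cohorts.
- **Null behavior (a known limitation)**: on pure-noise cohorts (effect 0,
  same geometry) the core set does *not* collapse: measured mean ≈ 18 genes
  (range 13–22 over 100 seeds). The N leave-one-out folds share N − 2
  samples, so their top-30 lists are strongly correlated, and every gene
  whose null AUC margin exceeds a one-sample perturbation survives the full
  intersection. The intersection therefore measures *stability under single-
  case removal*, not signal strength: a pure-noise cohort still clears the
  7-gene suitability bar essentially always. Interpreting |S| ≥ 7 as
  evidence of biological signal would be a mistake; the verdict separates
  stable cohorts (balanced) from unstable ones (imbalanced), and a
  label-permutation control is the appropriate companion check when signal
  itself is in question.

## Numerical and design choices

- Orientation of AUC (max(AUC, 1 − AUC)) is used throughout so that
  down-regulated markers are not silently discarded; one-sided ranking is a
  trivial restriction if ever needed.
- Tie handling follows the standard 0.5-per-tied-pair Mann–Whitney
  convention.
- The catalog fixture transcribes its source table verbatim, including three
  rows whose printed R/NR split does not sum to N; `validate_rn_split`
  reports them and summaries use the N column only. Dataset-id uniqueness is
  not an invariant (one accession legitimately appears twice under different
  therapy arms).
- `balance_ratio` is min(|R|,|NR|)/(|R|+|NR|), robust to the one catalog row
  whose printed split exceeds its N.
- Degenerate inputs fail loudly with typed errors (exit code 3 for data
  contract violations, 4 for statistically degenerate situations) rather
  than producing a number.
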