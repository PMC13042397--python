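# Methods

This note documents the models and procedures implemented in `dnbpipe`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic benchmark does and does not establish.

## Data model and preprocessing

The substrate is a proteins × samples intensity matrix (raw or log2) with
missing values, plus an ordered stage vocabulary (default
ESO < MID < MOD < SED < ESCC) and a compartment label per sample (lesion `L`
vs adjacent non-lesion `N`). Core principles:

* **Missing values are never imputed** at the data layer. Each downstream
  operation declares its own policy: DE and signature scoring use available
  values per group/sample, DNB statistics are pairwise-complete, the panel
  classifier defaults to complete-case features (with an optional explicit
  median fill). Imputation would contaminate exactly the variance and
  correlation statistics the DNB method depends on.
* **Median normalization** shifts (log2) or rescales (raw) each sample so its
  median equals the global median of pre-normalization column medians. The
  non-zero target keeps values on the interpretable intensity scale. The
  operation is idempotent and commutes with column permutation.
* **Completeness filter**: retain proteins observed in ≥ `min_frac` (default
  0.5) of the samples of at least one (stage, compartment) group. The default
  is this package's choice — typical of DIA practice, surfaced in config —
  since the minimum-observation rule of such studies is usually unreported.
* `"NA"`, `"NaN"` and empty cells all parse as missing (common TSV dialects).
  Values round-trip bitwise through the writers (17-significant-digit output,
  correctly rounded parsing).

## DNB composite index and tipping-stage call

Assumption: approaching a critical transition, a small *dominant group* of
molecules exhibits (i) inflated within-group variance, (ii) inflated
within-group correlation and (iii) reduced correlation with the remainder of
the system. Per stage *s* and candidate module *M*:

```
SD_in(s, M)  = mean over M of the within-stage SD (ddof = 1)
PCC_in(s, M) = mean |Pearson r| over member pairs   (pairwise-complete)
PCC_out(s, M)= mean |Pearson r| over member × non-member pairs
CI(s, M)     = SD_in · PCC_in / max(PCC_out, ε),   ε = 0.01
```

The tipping stage is the argmax over stages of the best module's CI. Details
and choices:

* **Absolute** correlations throughout: DNB theory concerns coupling
  strength, not sign.
* **Pairwise-complete correlation with a defined-pair floor**: pairs with
  fewer than `min_pairs` (default 3) shared observations are *undefined* and
  excluded from the means — never zeroed, which would bias PCC downward.
* **ε floor** prevents division blow-up for perfectly decoupled modules; it
  is config-exposed and logged in results.
* **Candidate discovery**: average-linkage hierarchical clustering on the
  distance 1 − |PCC| (undefined pairs → distance 1), flat cut at 0.5, modules
  of size ≥ 5. The tree is built over the proteins above the 0.90
  within-stage SD quantile. This variance pre-selection is the package's
  resolution of a genuinely open design point: with thousands of flat noise
  proteins and a dozen usable samples per stage, small-overlap correlation
  estimates are noisy enough that chance high-|r| neighbors scatter a real
  module across the tree; restricting discovery to high-SD proteins — the
  leading DNB signal itself — removes that failure mode. CI statistics
  (including PCC_out) always use the full retained universe, and
  `sd_quantile = 0` restores unfiltered discovery.
* **Tie-breaks** are fully deterministic: within a stage, higher CI, then
  larger module, then lexicographically smallest member set; across stages,
  the earliest stage rank.
* **Invariances** (asserted in tests): scaling all values by a > 0 scales
  every CI by exactly a without moving the tipping call; adding per-protein
  constants changes nothing.
* **Permutation significance**: sample-to-stage assignments are shuffled
  within the compartment (group sizes preserved), the per-stage best CI is
  recomputed, and `p(stage) = (1 + #{null CI ≥ observed}) / (B + 1)`. This
  conditions on the compartment's sample pool and is exact in the
  randomization sense; note the argmax stage's p is selection-biased low, so
  per-stage p-values should be read jointly.
* The tipping stage closes the *pre* phase: pre = stages with rank ≤
  tipping rank, post = the rest (the first post stage is the first
  "irreversible" one). The pipeline uses the L-compartment call by default
  and exposes an override, since a real analysis may triangulate both
  compartments and biology.

## Fuzzy c-means trend clustering

Per-stage mean trajectories (proteins missing an entire stage are excluded
with reasons) are row-standardized and clustered with fuzzy c-means:
memberships `u_ic = 1 / Σ_k (d_ic/d_ik)^(2/(m−1))`, centers the
`u^m`-weighted means, Euclidean distance. Coincident points receive full
membership at their center. The objective `Σ u^m d²` is asserted
non-increasing at every iteration and membership rows are asserted normalized
at every iteration.

* `c = 4` by default (the four canonical trend shapes: rising, falling,
  mid-peaked, late/tipping-peaked); configurable.
* Fuzzifier `m = 1.25`: standardized 5-point trajectories are
  low-dimensional; larger m (e.g. the textbook 2.0) drives memberships toward
  uniform on such data. The estimator-based defaults of existing soft
  clustering packages are not reproduced bit-for-bit.
* Best of 5 seeded restarts (centers initialized from distinct data rows;
  restart seeds derived from the master seed) — init sensitivity without
  losing determinism.
* Cluster labels are arbitrary: quality is measured by best-matching metrics
  (adjusted Rand index) only.
* Reporting threshold for "core" cluster membership defaults to 0.5.

## Differential expression

Per protein, groups A vs B on log2 data (≥ 3 non-missing values per group,
otherwise skipped with a reason):

* **Normality gate**: Shapiro–Wilk at α = 0.05 in *both* groups → Welch's
  t test; otherwise Wilcoxon rank-sum (exact null when min(n) ≤ 10 with no
  ties, asymptotic with tie correction otherwise). Welch rather than pooled
  variance because group sizes like 19 vs 11 make pooled estimates fragile.
* **Effect**: `FC = 2^(mean_A − mean_B)` of log2 means; the convention is
  recorded in the output.
* **Calls**: `p < 0.05` *and* `FC > 1.20` (up) or `FC < 0.83` (down), all
  strict inequalities. No multiple-testing correction enters the calls —
  this reproduces the operational definition used in staged-proteomics
  practice — but a Benjamini–Hochberg column is emitted for information.
* Stage-specific proteins use a presence rule: observed in ≥ `presence_frac`
  (default 0.6) of one stage's samples and below that fraction in every other
  stage of the compartment.

## EMT score

Per sample: mean of non-missing mesenchymal-set values minus mean of
non-missing epithelial-set values (log2 units). A sample with an entirely
missing set is undefined with a reason; set coverage is reported. The score
is exactly invariant to sample-wide additive shifts. Signature sets are
user-supplied GMT; the bundled epithelial/mesenchymal file is illustrative
and non-canonical. The phase comparison reuses the normality-gated two-sided
test on the score vectors.

## Biomarker panel

Labels are the two phases (post = positive). AUC is computed by the
Mann–Whitney rank identity with midranks for ties. Steps:

* **Benchmark**: 5 learners by default (linear SVM, RBF SVM, logistic
  regression, random forest, k-NN), all evaluated on identical stratified
  fold assignments, features standardized inside training folds only. The
  harness is the contribution; the roster is config-extensible.
* **SVM-RFE**: linear SVM (C = 1, fixed — standard RFE practice; optional
  tuning is out of scope), rank features by squared weight, drop the weakest
  `⌈0.1 · surviving⌉` per round; the reversed elimination order is the
  importance ranking.
* **Panel size**: `fixed_k` (default k = 7) or `one_se` (smallest size whose
  mean CV AUC is within one SD of the best). The AUC-by-size curve re-runs
  RFE inside each training fold, so selection never sees held-out samples —
  verified by a pure-noise test whose CV AUC stays in the null band.
* Missing data: complete-case features by default; the pipeline uses
  ≥ 80 %-observed features with a per-protein median fill (a pragmatic
  choice; the fill is computed across analyzed samples and is the one
  deliberate departure from strict fold isolation, affecting only feature
  availability, not labels).

## Ligand–receptor crosstalk

At one stage (default MOD), a protein is "expressed" in a compartment if
observed in ≥ 50 % of the group's samples. For each annotated pair with the
ligand expressed in the source compartment and the receptor in the target,
the score is the product of their within-compartment mean-expression ranks
rescaled to (0, 1]. Both directions (L→N, N→L) are ranked; ties break
lexicographically. This is a deliberately scale-free, deterministic stand-in
for interaction-ranking tools: it reproduces the *ranking role* of such
networks, not any particular tool's internals, and is labelled accordingly.

## Synthetic cohort generator

Per protein p and sample j in stage s (all effects planted in the L
compartment; N is baseline + noise and serves as a negative control):

```
x_pj = b_p + t_p(s) + Δ·[p ∈ panel]·[post] + γ·rank(s)·(±1 for mes/epi)
       + m_j + e_pj
b_p ~ N(μ_b, σ_b²)        baseline (μ_b = 20, σ_b = 2, log2 DIA scale)
t_p(s)                     trend template scaled to δ (= 1.0 log2 units)
m_j ~ N(0, 0.3²)           per-sample offset (removed by normalization)
e_pj ~ N(0, σ_p²),  σ_p ~ U(0.2, 0.6)
```

DNB members use a shared-factor construction
`e = κ·σ_p·(√ρ z_j + √(1−ρ) w_pj)` with ρ = ρ* = 0.8 and κ = 3 at the
tipping stage (default MID), ρ = 0.1 and κ = 1 elsewhere — O(d) per sample
with the exact target equicorrelation in expectation, unlike a Cholesky
factor. Trend templates over the five stage ranks: up (0, .25, .5, .75, 1),
down (reversed), mid-peaked (0, .5, 1, .5, 0), tipping-peaked (indicator at
the tipping rank). Missingness is intensity-dependent: dropout probability
∝ logistic(−steepness·(x − median)), rescaled to a 20 % expected overall
rate. Planted sets (15 DNB, 7 panel, 4 × 50 trend, 10 + 10 EMT) are disjoint
by construction. Outputs are bitwise-deterministic given the seed.

Default effect sizes are calibration choices, not estimates from any cohort:
they produce comfortably detectable but non-trivial signal at the design's
group sizes (e.g. within-module correlation estimated from ~12
pairwise-complete samples at 20 % missingness spans 0.6–0.9 across seeds).

**What the generator does not emulate**: peptide-level structure, batch
effects, subject pairing between L and N, heavy-tailed intensity noise,
biologically correlated pathways outside the planted sets. Passing recovery
tests therefore demonstrates that the implementations detect the structures
they claim to detect at realistic sample sizes — not that any particular
real cohort has those structures.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run: composite-index oracle
agreement on 100 random instances plus full enumeration of all ≤ 5-member
modules in a 12-protein block; tipping recovery on the full default design
(2000 proteins, L groups 10/19/11/14/10, 20 % missingness) over 50 seeds;
trend and DE checks at 300–2000 proteins; permutation calibration at 300
proteins with B = 99 over 20 seeds (the permutation layer recomputes the
entire per-stage module search ~100× per cohort, so a compact universe keeps
the calibration study a single-CPU job); panel recovery at 7 informative of
300 features, n = 64, over 20 seeds with a genuinely held-out second draw.

## Known limitations

* Module discovery below ~8 usable samples per stage is unreliable; the
  smallest default group (ESCC_N, 5 samples) passes the hard minimum of 3
  but its correlation estimates are weak.
* The permutation test reports per-stage p-values; family-wise control
  across stages is left to the reader (the argmax stage's p is biased low).
* The DE rule deliberately mirrors uncorrected practice; use the emitted BH
  column for FDR-aware interpretation.
* CI is computed on normalized log2 data without reference-stage
  standardization; a flag for first-stage standardization is exposed but both
  variants share the same discovery recipe.
* The crosstalk scorer is a ranking device only; it attaches no statistical
  significance to edges.
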