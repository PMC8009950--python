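# Methods

This note documents the models and procedures implemented in `feedeval`,
the numerical choices behind them, what the synthetic generators emulate,
and the known limitations.

## Data model and censoring

A `NutrientPanel` holds replicate measurements of many analytes for one
substrate and category (amino acids, fatty acids, vitamins, minerals,
proximate).  Analytical panels are left-censored in two distinct ways and
the distinction matters downstream:

- **ND (not detected)** — the assay ran and found nothing.  Carried as a
  censored measurement with numeric value 0.
- **"<x" (below limit of quantification)** — the assay ran; the value is
  somewhere below x.  Carried with the limit retained for reporting; the
  numeric value used by statistics is 0, matching the source study's
  convention of treating undetectable concentrations as zero.  This is a
  deliberate simplification: substitution at 0 (rather than x/2 or a
  maximum-likelihood censored estimate) biases means downward, but it is
  the convention the bundled tables were produced under, and the win-count
  comparisons below only need the ordering of means.
- **absent** — a parameter with no measurement record at all for a
  substrate (e.g. a fatty acid never detected there).  Absence is not a
  measurement; it only matters to comparability filtering.

Replicate summaries are mean ± t-based 95 % half-width,
hw = t(0.975, n−1)·sd/√n, the convention of the bundled tables (n = 3
throughout the study, t = 4.3027).  The inverse map
sd = hw·√n/t(0.975, n−1) is provided to rebuild demonstration replicates
from printed summaries; such reconstructions are surrogates with the right
first two moments, never data.

Amino-acid analyte names are normalised to 3-letter codes through a synonym
map; unknown analytes pass through verbatim with a warning, so user panels
are not silently corrupted.

## Protein-quality scoring

Contents printed as g/100 g dry weight are multiplied by 62.5 to give mg
per g nitrogen (the nitrogen-to-protein factor 6.25 × 10).  The conversion
is applied to the printed contents directly, without renormalising by crude
protein — this reproduces every printed score and keeps the fixtures equal
to the published table.

Scoring uses the 8 pooled categories Ile, Leu, Lys, Thr, Val, Trp, Met+Cys,
Phe+Tyr, pooling *before* conversion.  The EAAI is the geometric mean of
100·(sample/egg) over those categories.  The textbook definition counts
n = 9 separate essential amino acids; only the 8-pooled-category variant
reproduces the published indices (34.13/45.16/55.93), so 8 pooled is the
default and the category list is an explicit parameter for anyone wanting
the unpooled variant.  His and Arg (conditionally essential) are excluded
from scoring by default, matching the reference patterns bundled.

A zero content in any category drives the EAAI to 0 (geometric mean with a
zero factor); scores are reported unrounded, with half-up 2-decimal
rounding for display only.  The limiting category is the argmin of CS;
ties are reported as co-limiting in alphabetical order.

The ΣEAA/ΣNEAA/ΣFAA sums are recomputed from the essential/flavor flags.
The published aggregate rows do not exactly equal the sum of their flagged
rows (e.g. isopod ΣEAA prints 19.57 vs 19.41 recomputed); fixtures store
the printed aggregates verbatim and `aa_summaries` recomputes from flags —
the two are kept side by side, never reconciled.  Taurine carries the
flavor flag (and no essential flag) by default; a switch drops it from the
flavor totals for the stricter convention.

## Growth kinetics

The juvenile growth model is allometric: BW = a·t^b with multiplicative
error, fitted by OLS on (ln t, ln BW).  r² is reported on the transformed
scale — the convention of spreadsheet power trendlines, which the source
analysis used — with the original-units 1 − SSE/SST also computed for
reference.  t = 0 (birth weight) is excluded from the fit (log undefined)
but anchors WGR and SGR; non-positive weights are excluded with a warning;
at least 3 usable points are required.

SGR is exactly additive over a partition of the trial when weighted by
segment duration, which the tests assert.  The residual normality check is
Shapiro–Wilk on the standardized log-scale residuals; an (numerically)
exact fit has no variance to test and raises a degenerate-input error
rather than returning a meaningless p-value.

Note the published trendline (a = 0.1479, b = 1.8022, r² = 0.9466) was
fitted to all 15 weighing check points; only 6 means are published, and the
log-log fit to the 5 positive-age published means gives b ≈ 2.21,
r² ≈ 0.974.  The published parameters are therefore reference metadata, not
a reproduction target.

## Group comparison pipeline

Per analyte, for k substrates in triplicate:

1. Shapiro–Wilk on raw replicates (3 ≤ n ≤ 5000).
2. Levene's test, mean-centered variant, for variance homogeneity.
3. Levene p ≥ α: classical one-way ANOVA; post hoc Duncan's multiple range
   test.  Levene p < α: Welch's ANOVA; post hoc Dunnett's T3.  The gate is
   overridable.
4. Fisher's LSD (pooled-MSE t comparisons of a designated control substrate
   against the others) is available as a cross-check, mirroring the study's
   use of isopod meal as control.

**Duncan's MRT.**  Means are ordered; a span of p means has least
significant range R_p = q(1 − α_p; p, df)·√(MSE/n_h) with the protection
level α_p = 1 − (1 − α)^(p−1), studentized-range quantiles from scipy, df
and MSE from the ANOVA, and n_h the harmonic mean group size (a warning
flags unbalanced designs).  A pair differs iff its own range and every
containing range exceed their critical values.  Quantiles are cached by
(p, df, α), which keeps the 2000-replicate simulations fast.

**Compact letter display.**  Letters are the maximal cliques of the
"not significantly different" graph (Bron–Kerbosch), ordered by smallest
clique mean.  This construction makes letter sharing *equivalent* to
pairwise non-significance — the soundness property the tests verify against
a brute-force oracle.  Default orientation gives 'a' to the smallest mean,
matching the bundled tables (two printed rows are inconsistent with their
own convention; fixtures keep the printed letters untouched).

**Welch + Dunnett T3.**  Welch's F uses the standard closed form with
Satterthwaite df (cross-checked against pingouin).  T3 compares each pair
with its own Welch df; the critical point is the studentized maximum
modulus over r = k(k−1)/2 comparisons, computed through the Šidák relation
|t| at level 1 − (1 − α)^(1/r) — exact under independence and a close,
slightly conservative approximation otherwise (simulated familywise error
under unequal variances stays below α).  A zero-variance pair is decided by
the limit rule (significant iff the means differ) and flagged.

**Error rates.**  Duncan's protection level is designed to control the
*comparison-wise* error rate; its familywise rate under the complete null
with k groups is by construction ≈ 1 − (1 − α)^(k−1) (9.75 % at k = 3,
which the simulations reproduce).  The pipeline's simulated comparison-wise
rate on null triplicate data is ≈ 4 %, bounded at 0.07 in the acceptance
checks.  Simulation sizes (2000 null replicates, 500 random letter
instances) were chosen to give stable rates while keeping the default suite
fast.

## AHP engine

Judgment matrices are validated as reciprocal with entries in [1/9, 9].
Priorities are the principal right eigenvector computed by power iteration
from a uniform start to a 1e-12 sup-norm tolerance — deterministic and
platform-stable, and agreeing with a dense eigensolver to better than 1e-8
on random near-consistent matrices.  λ_max is the Rayleigh mean of (Aw)/w;
CI = (λ_max − n)/(n − 1), CR = CI/RI with Saaty's random-index table
(0, 0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49); 2×2 matrices are
always consistent (CR = 0).  The YAAHP software used in the source study
may use slightly different RI values; this engine documents Saaty's.

Group aggregation averages per-expert *priority vectors* arithmetically
(equal expert weights by default, overridable).  The published phrasing is
ambiguous between averaging vectors and averaging matrix elements; vector
averaging always yields a valid priority vector, so it is the default, with
the element-wise geometric matrix mean (the aggregation that preserves
reciprocity) available as an option.  Synthesis is the standard weighted
sum over criteria; any matrix with CR ≥ 0.1 blocks synthesis unless
explicitly overridden.

The study's three expert matrices are unpublished, so the published global
weights (fish 0.5407, isopod 0.2015 — forcing krill to 0.2578 by
normalization) cannot be recomputed; the engine is instead validated by
construction (consistent matrices built from known weights are recovered
exactly) and by cross-solver agreement.

## Comparability filtering and radar scores

A category parameter is comparable across substrates when it survives three
rules, all configurable:

- not censored in every substrate (an all-ND/all-"<x" row carries no
  ranking information);
- absent (no measurement record) in at most one substrate;
- not reported in an excluded unit — by default "%", which removes bulk
  percentage entries (total phosphorus) from categories otherwise measured
  as trace mg/kg concentrations.

These defaults reproduce the source study's comparable-parameter counts
(9 minerals, 8 vitamins) and win counts (isopod 6/krill 2/fish 1 and
5/2/1); the exclusion list is inferred, not stated in the source, and is
recorded as configuration precisely so it can be changed.

Win counts award each parameter to the substrate with the strictly highest
mean (censored = 0); ties split the credit equally so counts always sum to
the number of parameters.  Rank scores map count order onto 50/40/30; tied
counts share the mean of the scores their ranks span (e.g. two tied at the
bottom get 35 each) and the tie is flagged.  The rank-score total across
substrates is always 120.  The radar *table* is the tested artifact; the
polar plot is a thin optional rendering.

## Synthetic generators

- `gen_panel`: replicates ~ Normal(mean, sd) truncated at 0 — composition
  replicates at the study's noise levels are well approximated as normal
  (the study's own normality checks pass), and triplicate design is the
  default.  Draws below an analyte's quantification limit are emitted as
  "<limit".  Not modelled: inter-analyte correlation, between-batch
  variation, seasonal composition shifts — so passing tests demonstrate
  correctness of the machinery, not robustness to those real-data features.
- `gen_growth`: BW = a·t^b·exp(ε), ε ~ Normal(0, σ²) per replicate group;
  multiplicative noise keeps weights positive and makes variance grow with
  size, as juvenile weighing data do.  Defaults follow the study design
  (check points every 5 days to day 70, 3 groups, published a and b,
  σ = 0.1).
- `gen_expert_matrices`: upper-triangle entries (w_j/w_k)·exp(δ),
  δ ~ Normal(0, jitter²), reciprocals filled exactly, entries clipped to
  [1/9, 9].  Jitter 0 gives CR = 0 and exact recovery; jitter ≈ 0.1 keeps
  ≥ 95 % of matrices under the CR < 0.1 gate.

All generators are driven by a single integer seed through numpy's
`default_rng`; identical spec + seed gives identical output.

## Known limitations

- No digestibility-corrected protein scores (PDCAAS/DIAAS), no
  nitrogen-factor estimation, no wet/dry conversion beyond a user-supplied
  factor.
- Censored values substitute 0 rather than being modelled; fine for
  ordering-based comparisons, biased for means near the detection limit.
- Dunnett T3 critical points are Šidák-based, not exact SMM table values;
  differences are at the third decimal of the critical point and
  conservative in direction.
- No multiplicity correction across analytes (each analyte is tested
  marginally, as in the source study) and no two-way or repeated-measures
  designs.
- The AHP engine handles complete matrices only (no fuzzy/interval AHP, no
  incomplete-matrix completion).
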