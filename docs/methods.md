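# Methods

## Model and procedure

The package treats a case-control genotype panel as an `n × m` matrix of
three-level categorical variables (genotypes 0/1/2) plus a binary class
`C`. Association is measured purely information-theoretically:

- **Main effect** of SNP `A`: `I(A;C) = H(C) − H(C|A)`, with entropies over
  the empirical (plug-in) frequencies. `I(A;C)` is non-negative and bounded
  by `H(C)`.
- **Pairwise interaction** of SNPs `A, B`:
  `IG(A;B;C) = I(A,B;C) − I(A;C) − I(B;C)`, where the joint term uses the
  9-level genotype of the ordered pair. `IG` is symmetric in `A` and `B`,
  positive for synergy, negative for redundancy, and bounded below by
  `−min(I(A;C), I(B;C))`.

No pseudocounts or bias corrections are applied: the weights are the raw
plug-in statistics, and cells with zero probability contribute zero to every
entropy sum. Tiny negative rounding residues (> −1e−12) on quantities that
are non-negative by theory are clamped to zero.

Networks `G_t` contain an edge for every pair with `IG ≥ t` (ties at exactly
`t` included) and only vertices with at least one incident edge. As `t`
decreases the graphs nest, so a single descending sweep (one sort of the
pair weights plus an incremental union-find) reproduces what an independent
per-threshold construction would give; this equivalence is asserted in the
tests. The filtered graph `Ĝ_t` keeps edges whose permutation p-value is at
or below the edge significance level.

### Permutation null

Each replicate shuffles the phenotype labels uniformly (class counts
preserved exactly) and recomputes all pair weights and per-threshold network
summaries. Replicate `r` uses seed `seed + r`, so replicates are independent
of execution order. Per-pair p-values are **matched by pair**: the fraction
of replicates whose weight *for that same pair* strictly exceeds the
observed weight. This is the literal permutation estimator; a non-strict
variant and the add-one estimator `(b+1)/(R+1)` (which cannot return exactly
zero) are provided, and a pooled-across-pairs variant exists for sensitivity
analyses but is off by default. **No multiple-testing correction is applied
across the ~m²/2 pairs** — the edge filter is the raw per-pair p-value, and
users should interpret single-edge significance accordingly; the
network-level permutation comparisons (edge count, vertex count, largest
component vs. the null ensemble) are the quantity-of-interest guards.

Per-replicate full weight tables are needed for matched-pair p-values and
are kept only while `R × n_pairs` fits the storage budget (default 5·10⁷
floats ≈ 400 MB); beyond that the null degrades gracefully to per-threshold
summaries and the CLI warns that per-pair p-values are unavailable.

### Degree-distribution models

Two generative null shapes are compared on the degree distribution of a
candidate network:

- **Power law** `p(d) = c·d^−γ`, fitted by least squares. Two protocols are
  shipped because "least squares on the points (d, p(d))" underdetermines
  the procedure: `nonlinear_lsq_with_zeros` (default) minimizes the
  untransformed sum of squares over *every* degree 1..d_max, counting
  degrees with p(d) = 0; `loglog_linear_regression` is OLS of log p on
  log d over the nonzero points. Reports always name the protocol. On the
  reported bladder-cancer degree distribution the nonlinear protocol
  recovers the reported exponent (γ = 2.012 vs 2.01 printed) while the
  log-log protocol's KS outcome matches the reported test result
  (p ≈ 0.38 vs 0.366 printed) — i.e. the two reported numbers appear to
  come from different conventions, which is exactly why both are exposed.
- **Zero-truncated Poisson** `P0(d) = λ^d e^−λ / (k·d!)`, `k = 1 − e^−λ`,
  the degree law of a randomly wired graph after removing isolated
  vertices. The rate is `λ = 2|E| / m_total` with the *all-SNPs*
  denominator: edges are imagined attached to all `m_total` SNPs before
  zero-degree removal, so the mean is over every SNP, not the surviving
  vertices. (For the reported network this gives λ = 2·255/1422 = 0.3587;
  a slightly different value appears in print, but the formula is the
  construction-consistent choice.)

Goodness of fit uses the sup-norm distance between the empirical degree CDF
and the model CDF. Because degrees are discrete and parameters are estimated
from the same data, p-values come from a **parametric bootstrap** (default
1000 replicates): sample `n_vertices` degrees from the fitted model, refit
with the same protocol (power law) or from the resampled degree sum
(Poisson), recompute the statistic, and report the fraction of bootstrap
statistics at or above the observed one. The asymptotic continuous-case
p-value is reported alongside for reference only. Bootstraps are
reproducible given `(n_boot, seed)`. The Poisson bootstrap conditions on the
observed vertex count rather than re-randomizing it; for the m_total values
of interest this is a second-order simplification.

### Threshold report

For each threshold on the grid the report lists network size, the three
property p-values, and the degree-model verdicts, then raises three flags:
properties significant (all three p ≤ 0.01), dominant component (LCC at
least twice the second-largest), and scale-free (power law not rejected,
Poisson rejected, both at α = 0.05). `n_flags` counts them; no scalar
"best-threshold" score is invented — ranking is left to the reader. When
pair p-values are available the degree fits run on `Ĝ_t`, since the weakest
edges are the likeliest to be chance inclusions.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| log base | 2 (bits) | unit of every weight and threshold; `e` supported, results scale by ln 2 |
| threshold grid | 0.02 → 0, step 0.001 | sweep range in weight units; grid points snap to 1e−12 so the endpoint is never dropped |
| permutations R | 1000 | null-ensemble size; smallest nonzero p is 1/R |
| edge alpha | 0.01 | per-edge cutoff defining `Ĝ_t` and the property-significance flag |
| topology alpha | 0.05 | level for the degree-model flags |
| n_boot | 1000 (200 in the per-threshold report) | KS bootstrap replicates |
| null storage budget | 5·10⁷ floats | above this the null keeps summaries only |

## Synthetic data: what it emulates and what it does not

The generator emulates a candidate-gene case-control panel: background SNPs
draw genotypes from Hardy-Weinberg frequencies (MAF uniform on 0.05–0.5 by
default) independently of each other and of the phenotype; planted two-SNP
penetrance models (optionally arranged into line or star motifs via shared
slots) define `P(case | genotype pair)`; disease risk across several planted
models combines as independent causes,
`P(case) = 1 − (1 − baseline) · Π(1 − f_k)`. Sampling is retrospective:
individuals are drawn from the population until the case and control quotas
(defaults mirror the study scale, 491/791 over 1,422 SNPs; the test suite
uses a reduced scale of 100 SNPs, 200/300) are filled, bounded at 10⁷ draws.
Named presets cover parity-XOR, pure epistasis (XOR at MAF 0.5, whose
marginal penetrance is exactly constant — hub SNPs need no main effects) and
a main-effect-only model. For any planted pair, `expected_ig` evaluates the
exact population information gain under retrospective sampling by
enumerating the 9 genotype cells; finite-sample weights converge to it.

Deliberately **not** emulated: linkage disequilibrium (the scoring makes no
LD adjustment, so independence is the honest null; a block-correlated
background would be a robustness study, not a default), covariates,
genotyping error, population stratification, and missingness mechanisms
beyond completely-at-random. Passing tests therefore demonstrate
correctness of the machinery and detectability of planted effects under
clean conditions, not robustness to confounding in real cohorts.

## Numerical and design choices

- Missing genotypes are imputed with the SNP's modal genotype over the
  pooled population (cases + controls); mode ties break toward the lowest
  genotype code — a fixed, reproducible rule. Imputation is idempotent.
- Pair scoring is chunked one anchor SNP at a time (a single `bincount`
  per anchor covers all its partners), so memory is O(pairs) for the
  weights and never O(pairs × individuals); the full 1,422-SNP enumeration
  (1,010,331 pairs) runs in under a second on one core.
- Degenerate inputs are refused loudly: single-class phenotypes, all-zero
  contingency tables, entirely missing SNP columns, inconsistent count
  marginals, sub-3-support degree distributions, `m_total` smaller than the
  vertex count.
- Component-size ties in component listings break by lexicographically
  smallest member; condensed pair storage uses the standard `i·m − i(i+1)/2
  + (j − i − 1)` indexing with symmetric access.
- The null-calibration check pools p-values over 10 independent null
  datasets (each m=20, n=200, R=200): one dataset yields only 190 p-values,
  whose KS distance to uniform exceeds 0.05 more often than not by pure
  sampling noise, so pooling is required to actually measure uniformity.
- Test and acceptance problem sizes (reduced-scale generator, R in the
  tens-to-hundreds for unit tests, 1000-replicate bootstraps where the
  result is asserted) are the package's chosen trade-off between statistical
  resolution and a test suite that runs in seconds.

## Known limitations

- Plug-in information estimates are biased upward by O(cells / n); with
  ~10⁶ pairs and no multiple-testing correction, individual edges at
  moderate thresholds include false positives by design — the permutation
  comparisons operate at the network level.
- Only pairwise interactions are scored; higher-order epistasis without
  pairwise footprint is invisible (connected components are a heuristic
  guide, not a test, for it).
- The power-law/Poisson comparison is a goodness-of-fit contrast between
  two simple families, not a model-selection procedure; no tail-cutoff
  (x_min) estimation or likelihood-ratio machinery is attempted.
- Isolated SNPs are not graph vertices; all vertex counts and degree
  distributions follow that convention.
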