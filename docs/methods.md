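# Methods

## Model

The package implements the analytic hierarchy process (AHP) for
reaction-condition selection. A decision hierarchy consists of a goal,
criteria $c = 1..m$ with weights $w_c$, and per-criterion alternatives
with priorities $p_c(\cdot)$. Both levels derive from positive reciprocal
judgment matrices on Saaty's scale (the 17 admissible values
$1/9, 1/8, \dots, 1/2, 1, 2, \dots, 9$), or are supplied directly when
only the priorities are known.

Two priority-derivation methods are implemented and recorded in outputs:

- **Principal eigenvector** (default): the Perron vector of the positive
  matrix, normalized to sum 1. This is the canonical AHP procedure.
- **Normalized column average**: each column divided by its sum, rows
  averaged. Equal to the eigenvector exactly on consistent matrices
  (those with $a_{ij} a_{jk} = a_{ik}$), which is the regime the packaged
  fixtures occupy; on inconsistent matrices the two differ and the choice
  matters, which is why it is an explicit, logged parameter.

Consistency uses Saaty's $CI = (\lambda_{\max}-n)/(n-1)$ and
$CR = CI/RI(n)$ with the standard random-index table
(0, 0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49 for $n = 1..10$)
and the conventional acceptance threshold 0.1; both the threshold and the
derivation method are configurable, since the source study states
neither. $n > 10$ is rejected rather than extrapolated.

Global scores are additive: $S(x) = \sum_c w_c\, p_c(x_c)$. Additivity
makes the ranking separable — the top combination is the tuple of
per-criterion argmaxes — and scale-invariant in the criteria weights.
Interaction terms (e.g. solvent × duration synergies) are deliberately
out of scope; the concordance report is the tool for noticing when the
additive assumption strains against data.

## Numerical choices

- Eigenvectors by power iteration from the uniform vector, relative-change
  tolerance $10^{-12}$, cap 10,000 iterations; failure raises with the
  last residual. Positive matrices have a simple dominant eigenvalue, so
  convergence is guaranteed in practice; tests cross-check against a
  dense eigendecomposition to $10^{-8}$ on matrices up to $n = 6$.
  $\lambda_{\max}$ is read off as $\mathbf{1}^\top A v$ for the
  sum-normalized $v$. A $CI$ within $10^{-9}$ below zero (floating-point
  noise on consistent matrices) is clamped to 0.
- Saaty rounding maps each upper-triangle entry to the nearest admissible
  value, ties resolved toward the value nearer 1 (the less extreme
  judgment — conservative elicitation); the lower triangle is rebuilt by
  reciprocity, so rounded matrices are always strict-Saaty valid.
- Inverse fitting (`fit_saaty_matrix`) minimizes the L2 distance between
  derived and target priorities. For $n = 3$ with budget $\ge 17^3$ the
  upper triangle is enumerated exhaustively (global optimum); the search
  is seeded with the Saaty-rounded consistent matrix so residual ties —
  e.g. a maximally inconsistent cyclic matrix that also reproduces a
  uniform target — resolve toward the consistent candidate. For
  $4 \le n \le 6$ a deterministic greedy single-cell descent refines the
  same start within an evaluation budget (default 20,000); $17^{n(n-1)/2}$
  enumeration is infeasible beyond $n = 3$. The 4-criterion target
  33.1/33.1/23.7/10.1 is not representable on the scale (33.1/23.7 ≈ 1.40
  sits between 1 and 2) and retains a residual of ≈ 0.017.
- Hierarchy configs accept priorities summing to 1 within 0.005 (printed
  values are rounded to three decimals) and renormalize; larger deviations
  are config errors. Fraction strings ("1/9") are accepted everywhere a
  number is.
- Ties in ranking break by enumeration order (criteria in declaration
  order, alternatives in declaration order); sorts are stable, so equal
  scores keep that order and identical configs yield byte-identical
  rankings.

## The packaged study fixture

The porphyrin-metalation hierarchy ships with the priorities the study
reported: criteria 33.1/33.1/23.7/10.1 (%); metal salts Pd(acac)₂ 43.7,
Pd(OAc)₂ 25.1, PdCl₂ 17.3, Pt(acac)₂ 5.0; solvents NMP 40.4, PhCN 21.9;
durations 1 day 67.2, 45 min 14.2, 30 min 14.2, 15 min 4.3. The
underlying judgment matrices were never published; the mole-ratio
criterion is the one exception where the printed 81.8/9.1/9.1 is exactly
the eigenvector of a unique consistent strict-Saaty matrix
([[1,9,9],[1/9,1,1],[1/9,1,1]]), which is therefore reconstructed and
stored as a matrix. Priorities never printed for individual alternatives
(PtCl₂ and K₂PtCl₄; acetic acid, pyridine and chloroform–methanol) share
their category's leftover mass evenly and carry an `imputed` flag that
reports surface as footnotes — an even split is the least-informative completion and
keeps the category sums faithful. The criteria weights themselves are
treated as inputs, not re-derived: no single strict integer-scale matrix
reproduces them (see the fitting residual above).

Temperature is not an independent criterion in the main fixture: the
study's hierarchy weighted four criteria, with each solvent implying its
working temperature. A five-criterion variant config (three temperature
set points, uniform imputed priorities) is included for analyses of the
full 6×3×5×3×4 = 1080-combination space.

The 25-experiment yield table is stored in the canonical CSV dialect
(`index,metal_salt,mole_ratio,solvent,temperature,duration,heating_mode,yield_percent`).
Parsing accepts decimal commas, normalizes durations to minutes
(1 day = 24 h = 1440) and keeps "RT" symbolic, mapping it to 25 °C only
where a numeric temperature is required.

## Concordance statistic

The study checked its estimates against experiments but named no
statistic. We use Kendall's $\tau_b$ (tie-corrected), implemented by
direct $O(n^2)$ pair counting, because mean yields contain many ties
(multiple all-zero alternatives). Pair counts are pooled across criteria
— concordant, discordant and tied pairs are accumulated within each
criterion and the $\tau_b$ formula applied to the totals — so priorities
on different criteria, which live on different simplices, are never
compared with each other. Alternatives with no experimental records are
excluded; a criterion with fewer than two populated alternatives makes
the correlation undefined and is reported as an error rather than
silently dropped. `scipy.stats.kendalltau` serves as the independent
oracle in the test suite, never as the implementation.

## Synthetic-data generator

The generator emulates the two things the study did not publish: the
elicited judgments and further experiments. Ground truth is an additive
utility model (criteria weights plus per-alternative utilities).

- **Judgments**: $a_{ij} = (w_i/w_j)\,e^{\varepsilon_{ij}}$,
  $\varepsilon_{ij} \sim N(0, \sigma^2)$ i.i.d. over the upper triangle
  (row-major), reciprocals exact, optional Saaty rounding. Log-normal
  multiplicative noise is the standard perturbation that preserves
  positivity and reciprocity. Defaults: $\sigma = 0.05$, a careful-expert
  noise level at which ratios are typically off by ~5%.
- **Yield tables**: conditions sampled uniformly from the design space;
  yield = clip to [0, 100] of `yield_scale` × summed utility + Gaussian
  noise (default sd 5 percentage points, a typical isolated-yield
  repeatability), rounded to whole percent. With utilities set to the
  study priorities, `yield_scale` = 40 puts the best combination's
  noiseless yield in the low 90s — above the best observed 81% but inside
  the clip, so the optimum remains identifiable. The default table size
  is 25 rows, matching the study's experimental budget.
- **Recovery experiment**: per replicate, regenerate all matrices with
  fresh seeds (one spawned stream per matrix from a root seed), re-derive
  priorities, re-rank, and compare the top-1 combination to the true
  per-criterion argmax; also the mean L1 distance between derived and
  true priority vectors. Everything is deterministic given the spec's
  seed.

What the generator does *not* emulate: temperature/solvent interactions,
reaction kinetics, heteroscedastic or censored yields, and systematic
expert bias (noise is zero-mean). Passing recovery tests therefore show
the pipeline's statistical machinery is sound under its own additive
assumptions — not that AHP predictions transfer to chemistry where those
assumptions fail.

## Problem sizes and determinism

The test suite and acceptance checks run at the study's native scales:
the full 360- and 1080-combination enumerations, the complete 25-row
yield table, 1000 random consistency-theorem round-trips, 200
eigensolver cross-checks, 500 tau-b oracle comparisons and 200
recovery replicates (the whole suite completes in well under a minute on
one CPU). All stochastic components take explicit integer seeds;
reference-run pins recorded in the tests (the greedy fitting residual,
the mean CR of 200 low-noise matrices, the pooled fixture tau-b) are
exact reruns of the shipped generator, not externally sourced numbers.

## Known limitations

- Single-judge matrices only: no geometric-mean aggregation of multiple
  experts, no fuzzy AHP/ANP, and no consistency "repair" beyond
  reporting.
- The additive synthesis cannot express interactions; a combination's
  score is blind to, e.g., a solvent that only works under microwave
  heating.
- The greedy matrix fit is locally optimal for $n \ge 4$; only the
  $n = 3$ search certifies global optimality.
- Imputed fixture priorities are conventions, not data; concordance
  involving imputed alternatives should be read accordingly.
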