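# Methods

This note documents the models, conventions and design decisions behind
`mutualnet`, in the order the pipeline runs them.

## Data model

Interaction data are visit counts: an event is one bird landing on a fruiting
plant and eating at least one fruit. The central object is an integer matrix
`w` with plants as rows and birds as columns; `r_i` and `c_j` denote row and
column totals, `m = Σ w_ij`, `L` the number of nonzero cells. Every metric in
the package is documented against this orientation. Events carry an optional
season tag (rainy/dry); a seasonal slice drops species with no interactions
in that season by default (so per-season richness reflects the season, as in
published seasonal tables), with a flag to retain them. Labels sort
lexicographically unless an explicit order is supplied, which together with
explicit seeds makes every stochastic step reproducible.

## Network-level metrics

**Connectance** is `C = L/(A_p·A_b)` with `L` the count of distinct realized
links, so `C ∈ [0, 1]` and 1 means every pair interacts. (Counting total
events instead of links would leave the ratio unbounded, so the link reading
is the only one consistent with the stated range.)

**Weighted NODF.** Rows and columns are sorted by decreasing marginal totals
(ties broken stably by label). An ordered pair (u above v) contributes 0 when
v's total is ≥ u's (the "decreasing fill" condition, which makes ties
contribute nothing), otherwise `100 · #{k: 0 < w_vk < w_uk} / #{k: w_vk > 0}`.
The score averages contributions over all row pairs and column pairs. The
implementation is certified against a literal brute-force transcription of
this definition on random small matrices.

**H2′ specialization.** `H2 = −Σ p_ij ln p_ij` with `p_ij = w_ij/m` (natural
logarithms throughout, as in the Shannon family). The extremes under the
observed marginals are computed by documented heuristics:

- `H2max` (most even): floor of the independence expectation `r_i c_j / m`,
  then each remaining unit goes to the emptiest cell whose row and column
  still have a deficit, tie-broken by largest fractional remainder;
- `H2min` (most concentrated): repeatedly place
  `min(remaining r_i, remaining c_j)` into the cell pairing the largest
  remaining row and column totals.

`H2′ = (H2max − H2)/(H2max − H2min)`, clamped to [0, 1], defined as 0 when
the extremes coincide. The heuristics are certified against exhaustive
enumeration of all integer matrices for several small marginal families
(within 2% of the attainable range); no claim of exact optimality is made for
large matrices.

**Barber modularity.** `Q = (1/m) Σ_ij [w_ij − r_i c_j/m] δ(g_i, g_j)` over a
joint module assignment of plants and birds. The optimizer runs seeded label
propagation — random initial plant partition, then alternating best-module
reassignment of each side against the modularity matrix `B = w − r cᵀ/m`,
nodes whose best attainable sum is negative getting fresh singleton modules —
followed by exhaustive pairwise module merging, best of `n_restarts`
(default 20). On matrices up to 4×4 the optimizer provably reaches the
exhaustive optimum in the test suite (row set-partitions × independently
optimal column assignment); on larger matrices it is a stochastic maximizer
whose reported Q always equals the direct evaluation of Barber's formula on
the returned partition. A planted-partition anchor (generator blocks with
boost γ = 3 at study-scale m) checks that the optimizer is within 10% of a
known good partition.

## Species-level metrics

Degree is the partner count. Strength of bird j is `Σ_i w_ij / r_i` (the sum
of the plants' dependencies on it); strengths on one side sum exactly to the
other side's richness, which the tests assert to machine precision.

`d′` rescales `d_j = Σ_i p'_ij ln(p'_ij / q_i)` — the KL divergence of the
species' partner-use distribution `p'_ij = w_ij/c_j` from availability
`q_i = r_i/m` — between `d_min` and `d_max = ln(m/c_j)`. `d_min` starts from
the largest-remainder integer allocation of `c_j` events proportional to
availability and then applies single-unit exchange descent; since the
divergence is convex this reaches the integer minimum (certified
exhaustively on small cases; the plain largest-remainder start alone can be
off by more than 2% of the range, which motivated the descent step). Species
with zero interactions are reported as missing rather than 0.

## Null models

The null family is the uniform distribution over nonnegative integer
matrices with the observed marginals. The sampler writes the m events as a
multiset of row tokens and a multiset of column tokens, shuffles one and
pairs positionally — equivalent to a uniformly random bipartite matching,
which induces the multivariate-hypergeometric (Fisher/r2dtable) distribution.
This is simpler to verify than a sequential conditional sampler; a χ² test
against the exact 2×2 hypergeometric pmf (2000 draws) and an independent
cross-check against R's `r2dtable` certify the distribution, and marginal
conservation is asserted on every draw.

`z = (obs − mean_null)/sd_null`. The published convention computes p as the
share of null draws scoring *at least* the observed value; that rule yields
p ≈ 1 for metrics that sit *below* the null (connectance in specialized
webs), so the package always reports both tails plus a two-sided summary and
labels which tail is significant, rather than guessing a convention.
`sd_null = 0` (e.g. for marginal-conserved quantities) reports z as undefined
with a diagnostic instead of dividing by zero. Default N = 1000, overridable.

## Extinction robustness

Removal order is fixed from the *initial* degrees (degrees are not
recomputed after each removal — the convention of the standard
implementations of this curve); ties break by strength in the scenario's
direction, then label, so ordered scenarios are deterministic. After each
primary removal, opposite-side species whose remaining interaction total is
zero go secondarily extinct (for this all-partners-lost rule, weighted and
binary readings coincide). The curve starts at (0, 1), ends at (1, 0), and
`R` is its trapezoidal area. "R for birds" means birds are removed and R
integrates plant survival; both orientations are always computed since the
phrase is ambiguous in field reports.

The familiar ordering `R(hubs first) ≤ R(random) ≤ R(hubs last)` is a
property of nested, hub-dominated webs, not a theorem: in strongly
assortative webs where specialists pair with specialists, removing
low-degree species first kills their exclusive partners immediately and the
ordering can invert. The generator's default regime sits in the nested
regime (see below) and the suite asserts the ordering there; the inversion
is a real phenomenon, not a bug.

## Sample coverage

Chao's abundance-based estimator
`Ĉ = 1 − (f1/n)·[(n−1)f1/((n−1)f1 + 2f2)]`, with `Ĉ = 1` when `f1 = 0` and
`Ĉ = 0` for the degenerate single-singleton sample. Link coverage uses the
nonzero cell values as abundances; side coverage uses the marginal totals of
that side (the documented assumption — field reports rarely state the side
treatment). Full rarefaction/extrapolation curves are out of scope; only the
coverage at the observed sample size is computed.

## Trait → role models

All numeric responses and predictors are log10-transformed. Zeros (a
proportional generalist has d′ = 0) are replaced per column by half the
smallest positive observed value before the log — a documented, switchable
offset; categorical fruit-color codes pass through untransformed. A
Kolmogorov–Smirnov normality diagnostic is attached per variable but never
gates the fit.

Every predictor subset (≤ 8 predictors, ≤ 256 subsets) is fit by OLS. AIC
uses the Gaussian maximum-likelihood convention
`n·ln(RSS/n) + n·ln(2π) + n + 2k` with k counting intercept, slopes and the
residual variance — constant-consistent across subsets, so Akaike weights
`w_k ∝ exp(−Δ_k/2)` depend only on fit and size. Coefficients are averaged
in **full** mode by default (a model without the predictor contributes 0;
conditional averaging is available), with the unconditional standard error
`se = Σ_k w_k √(se_k² + (β_k − β̄)²)`, `z = |β̄|/se`, and a standard-normal
p-value. Relative importance is the summed weight of models containing the
predictor. Rank-deficient subsets are skipped with a warning.

## Synthetic data generator

The generator emulates a year-round visitation survey of a species-poor
subtropical web: defaults 14 plants × 18 birds, exactly m = 4446 events
(multinomial total-sum conditioning, matching how a survey fixes its observed
event count), ~52% of events tagged rainy.

Cell probabilities are
`P_ij ∝ λ_i λ_j · exp(−(u_i − v_j)²/(2σ_j²)) · (1 + γ·1[same block])`:

- `λ` — lognormal species propensities (abundance/activity), sd 1.0;
- `u, v` — niche positions on a latent trait axis, laid out as jittered
  normal quantile grids so the community tiles the axis and no species is
  accidentally unreachable;
- `σ_j` — per-bird niche breadth: base `match_sd`, optional lognormal
  breadth heterogeneity (`width_sd`), and an optional multiplicative
  body-mass coupling;
- `γ` — planted-module boost over `block_count` random blocks.

`match_sd` defaults to 0.8, which keeps the default web in the nested,
hub-dominated regime where the extinction-scenario ordering holds on every
seed tested; strongly specialized webs (`match_sd ≈ 0.2`, H2′ ≈ 0.5–0.7) are
one knob away and are what the null-model sign-structure and specialization
experiments use explicitly. Matrices with an empty row/column trigger a
bounded regeneration (new latents and counts) and error out after 25
attempts.

Trait tables: bird body mass is lognormal around 30 g; the remaining bird
morphology scales allometrically with an independent size factor. Plant
fruit morphology is lognormal; the fruit abundance index is assigned from
the plant's visit total via the ordinal decade scale (0 = none, 1 = 1–10, …,
5 > 10,000), so FAI is causally coupled to degree/strength as in real crops.
Causal trait couplings enter through the probability structure itself, not
post-hoc relabeling: the study-like preset `STUDY_TRAIT_EFFECTS` sends body
mass into `λ` (negative → heavier birds visit less, hence lower degree and
strength) and into niche breadth (positive → heavier birds are more
selective, hence higher d′). The sign-recovery experiment runs at 40 birds ×
20 plants, m = 8000, `match_sd = 0.4` — sizes chosen so each bird has enough
events for a stable d′ while remaining a desk-scale computation — and
recovers both signs in ≥ 90% of 100 replicates.

What the generator does **not** emulate: observation effort and detectability
(no per-transect or per-hour bookkeeping), phenology (seasons only reweight
event tags, they do not move species in and out of fruiting), within-season
temporal autocorrelation, and spatial structure. Tests passing on generator
output therefore certify the *estimators and their stated invariants*, not
the field-data idiosyncrasies those features would introduce.

## Published reference tables

The species-level table (degree, strength, d′ for 18 birds and 14 plants),
per-season network summaries (richness, links, events, z-scores), robustness
values and coverage percentages printed by the karst frugivory survey ship
as plain CSV (`mutualnet.reference`). The survey's raw visit matrix is
archived externally and is not redistributed here, so checks against those
tables are consistency checks (degree means, strength sums, the 52.25% rainy
share, ordering and sign structure), not recomputations from the raw field
data.

## Numerical conventions and scales

- Natural logs in all entropies/divergences; log10 only in the regression
  transformation (a base change that rescales coefficients, not fits).
- Seeds: every stochastic routine takes an explicit seed or Generator;
  multi-stage runs fan out one master seed via `SeedSequence` so stages are
  independent but reproducible; derived seeds stay below 2³¹.
- Default problem sizes in the test and acceptance runs (null N = 200–1000,
  200–1000 random removal orders, 100 regression replicates, small-instance
  oracle suites up to 4×4 with totals ≤ 8) were chosen as desk-scale
  renderings of the full analysis; all are config-overridable.
- Degenerate inputs: all-zero matrices are rejected; zero-interaction
  species are dropped or reported missing; `sd_null = 0` and `H2max = H2min`
  return defined, documented values instead of NaN surprises.

## Known limitations

- The H2 extreme fills are certified heuristics, not proven optima, for
  matrices beyond the exhaustively enumerated families.
- The modularity optimizer is stochastic; restarts make inter-run variance
  negligible at study scale, but Q on large matrices is a lower bound.
- Exact numeric parity with any particular legacy implementation's H2′/d′
  values is not promised (those depend on unstated internal defaults); the
  definitions and their certified properties are the contract.
- Conditional (as opposed to full) model averaging changes coefficient
  magnitudes; both are provided, and comparisons across publications should
  match the mode.
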