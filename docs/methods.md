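# Methods

## Model

The pipeline turns two surveys into a weighted aspiration-gap report.

**Direct influence.** Each of `H` experts fills an `n × n` matrix `Eʰ` of
pairwise direct influence on an integer scale (default 0–4); diagonals are
fixed at 0 and are a validation error if nonzero (explicit beats silent
mutation). The panel average `A = (1/H) Σ Eʰ` is the working matrix. In the
hierarchical design the survey is split into one block over the `D`
dimensions and one block per dimension over its `n_d` criteria, which cuts
the item count from `n(n−1)` to `D(D−1) + Σ n_d(n_d−1)` — a strict reduction
for every hierarchy with at least two dimensions.

**Panel consensus.** The consistency index compares the mean over all `H`
experts with the mean over the first `H−1` (input order — the convention is
otherwise undefined, so the input order is the contract), entrywise relative
to the full mean, averaged over the `n(n−1)` off-diagonal cells and
expressed in percent. Cells whose full mean is zero contribute nothing but
the denominator stays `n(n−1)`. Default threshold 5 %, policy configurable
(warn or abort). Pre-averaged matrices (H = 1 panels with real entries) skip
the check.

**Total influence.** `A` is scaled by
`u = min(1/max row sum, 1/max column sum)` so that every row and column sum
of `N = uA` is ≤ 1, which keeps the spectral radius below 1 on any
irreducible instance; the radius is checked explicitly and a non-convergent
series raises. The direct-plus-indirect influence is the Neumann series
summed in closed form, `T = N(I − N)⁻¹`, computed by a linear solve against
`(I − N)` rather than explicit inversion. The truncated series is kept as a
test oracle only (closed form agrees within 1e−9 at spectral radius
≤ 0.95). Because `u` is a pure rescaling, multiplying `A` by any `c ∈ (0,1]`
leaves `N` and hence `T` unchanged: the questionnaire's unit is removed.

The min-over-row-and-column rule matters: the row-sum-only variant does not
reproduce the reference dimension-level matrix, whose normalisation constant
is its maximum *column* sum (9.3).

**Influence map.** With `o` the row sums and `r` the column sums of `T`,
each factor sits at `(o+r, o−r)`; `o−r > 0` is a cause, `< 0` a receiver,
and `|o−r| < 1e−12` is reported neutral (no epsilon band beyond guarding
exact round-off). Each unordered pair gets one arrow from the stronger
direction (`t_ij > t_ji` ⇒ i → j); an exact tie — a measure-zero event,
defined for testability — is exported as a bidirectional edge.

**Influential weights.** `T` is row-normalised to the row-stochastic `Tᵅ`
and transposed; the limiting power of that column-stochastic matrix has the
stationary distribution `π` (with `π Tᵅ = π`, `Σπ = 1`) in every column.
One published formulation prints an inverse where its prose says
"transpose"; a row-stochastic matrix's inverse is not its transpose, and
only the transpose reproduces the reference weight table, so the transpose
is used. `π` is found by power iteration from the uniform vector
(tolerance 1e−10 in max-abs difference of successive iterates, cap 10⁴
iterations) and always cross-checked against a direct least-squares solve of
the stationary equations; a disagreement above 1e−8 raises. Strictly
positive `T` (guaranteed when `A` is irreducible) makes the chain ergodic,
so oscillation handling is unnecessary. A zero row in `T` (a factor exerting
no influence) makes the weights undefined and raises.

Hierarchical mode runs this once per block and composes
`w^g_c = w^l_D(d(c)) · w^l_{D_c}(c)`; local vectors each sum to 1, hence so
do the globals. Classic mode runs one full criterion-level matrix, takes the
stationary vector as the global weights directly, and *derives* dimension
weights as within-dimension sums of globals with locals renormalised inside
each dimension — the reference description reverses the order but gives no
formula, so this interpretation is documented rather than asserted.

**Aspiration gaps.** Scores are judged against a fixed aspiration level
`f^aspired` (by convention the top of the survey scale; the worst level
`f^worst` is the bottom — both configurable, since narrative defaults of
0–10 and case studies on 1–7 Likert scales coexist). Two dialects:

- `raw`: `f^aspired − f_kj`, in survey units — matches published gap tables;
- `normalized`: `|f^aspired − f_kj| / |f^aspired − f^worst|` ∈ [0, 1].

The library default is `normalized` (the formula); the CLI and the bundled
case default to `raw` (the published table). Normalised `S_k` equals raw
`S_k` divided by the scale span, always.

Rollup: dimension performance is the local-criterion-weighted mean of its
criteria's scores; overall performance the local-dimension-weighted mean of
dimension performances; gaps identically in the chosen dialect. This
weighting is inferred from, and numerically confirmed by, the reference
table — the rollup formula is never stated there. In the raw dialect,
normalised weights force `overall gap + overall performance = f^aspired`
exactly, and the dimension-rollup total gap coincides with `S_k` over global
weights because composition is multiplicative; both paths are computed and
asserted equal. Only mean group utility is implemented from the VIKOR
family; maximal-regret and compromise indices (R, Q, the coefficient v) are
out of scope for the aspiration-level variant.

## Bundled case fixture

`xingshisi` packages a 4-dimension / 26-criterion quality-of-life hierarchy
(blocks of 7, 6, 4 and 9 criteria), five pre-averaged influence matrices at
their published precision (one decimal), and a single-alternative village
satisfaction survey (1–7 Likert means, three decimals) with
`f^aspired = 7`, `f^worst = 0`. Report rounding defaults to 3 decimals to
mirror the published layout; full-precision values always accompany the JSON
summary. Reproduction tolerances account for the fixture's printed rounding
(±0.001 on weights, ±0.01 on rolled-up performance/gap pairs).

One fixture anomaly is documented in the test suite: the published
total-influence matrix of the 4-criterion social-relations block does not
follow from its own average matrix under the stated normalisation
(`u = 1/8.6`) but is reproduced exactly under the dimension block's factor
(`u = 1/9.3`), evidently a carry-over error in the source table. Weights
and cause/receiver signs are identical under both factors, so every
downstream number is unaffected.

## Synthetic data

The generator emulates the two surveys such a study rests on. Experts: the
ground-truth matrix is rounded to the integer scale and each off-diagonal
entry is independently shifted by ±step (uniform in 1..max_step, default 1)
with probability `flip_probability` (default 0.3 — moderate disagreement on
a 5-point scale), then clipped into scale. Clipping biases entries at the
scale ends inward; that is accepted and the concentration tests restrict to
interior entries. Respondents: Gaussian noise (default sd 1.0, about one
Likert step) added to true scores, clipped, averaged over `respondents`
(default 50, the order of a village survey). Default panel size H = 10
matches a typical expert panel.

One shared seed expands into per-block substreams by stable (SHA-256)
hashing of block ids, so adding a block never reshuffles another block's
draws, and identical specs are bit-reproducible.

What the generator does not model: expert psychology (anchoring, halo
effects), correlated respondent error, and item non-response. Passing
recovery tests therefore show that the numerics are consistent — noise
averages out at the rate the binomial/CLT arithmetic predicts (global weight
deviation < 0.03 at H = 50, flip 0.2) — not that any real panel of ten
experts is this well behaved.

## Numerical choices and limitations

- Matrix sizes in the intended regime are ≤ ~30; everything is dense
  `float64` linear algebra, milliseconds per block.
- The stationary solve uses least squares on the rank-augmented system
  (stationarity rows plus the normalisation row), robust to the rank-1
  deficiency of `P − I`.
- Degenerate inputs raise with a named cause: all-zero direct matrix,
  spectral radius ≥ 1, zero row in `T`, aspiration equal to worst,
  coverage mismatches between weights and gaps.
- Recovery experiments at small H can fail a block's 5 % consensus check by
  construction; the experiment suppresses the warning, and real analyses
  should not.
- Test problem sizes (panels of up to 200 experts, 500 respondents, ~10
  seeded replicates per property) were chosen so the full suite runs in a
  few seconds while keeping Monte-Carlo assertions comfortably away from
  their thresholds.
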