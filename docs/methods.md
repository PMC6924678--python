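# Methods

## The question and the instrument

Reserve selection under the *maximal coverage* target fixes the number of
cells to protect and asks which cells cover the most species. With real
data the answer can never be validated, because the true distributions are
unknown. `nichesim` therefore builds communities whose truth is known by
construction, surveys them imperfectly on purpose, and measures — via the
effectiveness index — whether prioritizing on modelled presence
probabilities covers more true species than prioritizing on the raw
records.

## Community generation

A community is a binary species × site matrix on a 1-D gradient with
`e_i = i/(n_sites − 1)`. The unit interval is an arbitrary but numerically
convenient scale; only the ratio `(e − c)/w` enters the model.

Three constraints hold simultaneously:

1. **Rank-abundance curve** (exact row sums). Families: `log_linear`
   (abundance at rank r is `max_abundance·exp(−decay·r)`), `log_normal`
   (i.i.d. `exp(Normal(μ, σ))`), or a user-supplied `empirical_table`
   (two-column value/frequency text, sampled with replacement). Values are
   rounded half-up and clamped to `[1, n_sites]`: every species exists
   somewhere, and a spec in which more than 10% of species overflow the
   grid is rejected as infeasible rather than silently truncated.
2. **Richness pattern** (exact column sums), drawn i.i.d. per site —
   spatially and environmentally unstructured by design — from a
   `log_linear` frequency family (`P(k) ∝ exp(−rate·k)`) or an empirical
   table.
3. **Unimodal preference.** Suitability `expit(h − ((e − c_s)/w_s)²)` with
   optimum `c_s ~ Uniform(0, 1)` and width
   `w_s = w0 + w1 · abundance_s/n_sites`. Defaults `h = 2` (peak
   suitability ≈ 0.88), `w0 = 0.05`, `w1 = 0.5`. Width *increases* with
   abundance because a species that must occupy many cells of a single
   gradient cannot do so with a narrow niche; with the default rule the
   rarest species get niches spanning ~5% of the gradient and the most
   common ~55%.

The two margin totals are equalized before assignment by unit adjustments
to the richness vector at uniformly chosen sites (abundance carries the
rank-abundance signal and is left untouched), and the adjusted pair is
certified realizable by the Gale–Ryser inequalities.

**Assignment and refinement.** A first matrix with the exact margins is
built by the Gale–Ryser constructive fill and randomized by curveball
trades (5 × n_species trades), which mix toward the uniform distribution
over margin-preserving matrices while leaving both margins fixed. The
refinement stage then repeatedly proposes two random sites and one
movable species in each direction, and applies the exchange iff it
strictly increases `Σ log S` over occupied cells — equivalent to
comparing suitability products, and a checkerboard swap, so margins are
conserved exactly throughout. When random proposals stall (10 × n_sites
consecutive rejections), systematic best-improvement sweeps over all site
pairs finish the job until a full sweep finds no improving exchange: the
returned matrix is certified locally optimal under the swap move set
("no more swapping improves consistency"), which random proposals alone
can only approach asymptotically. On small instances this local optimum
coincides with the exhaustive-search global optimum in ≳90% of seeds;
pair swaps do admit occasional non-global fixed points.

**Default community shape.** `default_community_spec` scales the full
1000 × 1000 reference setting to any grid: the most abundant species occupies half
the sites, the log-linear decay reaches single-site occupancy at the last
rank, and the richness rate is matched so both margin totals agree in
expectation (reconciliation absorbs the sampling residual). A third
default type exercises the empirical-table path with a synthetic
heavy-tailed table (`P(k) ∝ k^−1.6`) standing in for tables extracted from
real survey reports.

## Virtual survey

The grid is divided into N equal blocks; each block receives
`n_sites·R/N` consecutive cells at a uniform random offset (indivisible
remainders go one-each to randomly chosen blocks). Bias levels: strong
N = 2, weak N = 5; "no bias" is implemented as simple random sampling —
the many-blocks limit of the block design and the spatially most even
choice. Surveys are error-free: no detection error or misidentification
is modelled. Because richness is placed at random, the expected number of
presence records at fixed R is the same at every bias level; bias changes
*which* species are seen (few species, many records each), not how many
records exist.

## Niche models

One model per species on the surveyed cells, predicting over all cells:

- **GLM** — binomial, logit link, linear + quadratic environment: exactly
  the generating functional form, i.e. a correctly specified model. On
  IRLS failure (typically complete separation) the fit is retried with a
  small ridge penalty (10⁻⁴); a constant-prevalence predictor is the last
  resort, logged in `fit_meta`.
- **GAM** — binomial, logit link, penalized cubic B-spline with basis
  dimension `min(10, n_distinct_env − 1)` and a fixed light penalty
  `alpha = 10⁻³` (chosen so that a textbook unimodal response at n = 500
  is reproduced essentially unpenalized while near-separation remains
  stabilized; larger defaults visibly flatten the response). Below 5
  distinct surveyed environment values a spline basis is unsupportable and
  the quadratic GLM stands in. Predictions outside the surveyed
  environmental range — routine under blocked surveys — hold the boundary
  value constant, a deliberately conservative extrapolation.
- **RF** — random-forest classification on the single predictor;
  probabilities are vote fractions. 500 trees by default; minimum leaf
  size tuned over {1, 5, 10, 25} by out-of-bag error (skipped when the
  grid has one entry).

Species never observed in the survey are excluded — no model can exist for
them — and re-enter only through the truth-based coverage scoring. Species
observed everywhere in the survey have no absences to contrast and receive
a constant predictor (probability 1), flagged `degenerate_constant` but
not excluded. AUC diagnostics are rank-based with midrank ties, computed
against the true distribution over **all** cells (surveyed included), and
undefined for species whose truth is constant.

## Prioritization

Both greedies break ties toward the lowest cell index, making selections
deterministic given their inputs.

- **Raw-data approach:** greedy complementarity on the observed records
  (first pick = the surveyed cell with the largest observed richness),
  stopping when the target is reached or every recorded species is
  covered; remaining slots are filled with uniformly random unsurveyed
  cells (falling back to leftover surveyed cells only when the unsurveyed
  range is exhausted).
- **ENM approach:** greedy on expected coverage with residual
  probabilities `r_s = Π(1 − p_si)` updated after each pick. Fitted
  probabilities are clipped to `[10⁻⁹, 1 − 10⁻⁹]` first so that a
  numerically exact 1.0 (an RF unanimous vote) cannot freeze a species'
  residual at zero. The implementation uses lazy gain evaluation on a
  priority queue; submodularity makes it pick-identical to naive full
  recomputation, which is asserted in the tests.

If the survey records no species at all, the ENM reserve degrades to a
seeded uniform random selection — the approach has nothing to model, and
failing the run would discard a legitimate (if extreme) factorial cell.

## Evaluation and the sweep

`effectiveness = covered_enm/covered_raw − 1`, with coverage judged
against the truth. A raw coverage of zero makes the ratio undefined: the
record carries NaN, is excluded from percentage denominators, and is
counted separately (at full scale raw coverage is always positive).
Rare-species metrics repeat the calculation for species under a threshold
of true presence records — 20 on the 1000-cell grid, scaled
proportionally (e.g. 4 at 200 cells) so "rare" keeps meaning 2% occupancy.

The sweep crosses community types × replicates × R × bias × target ×
algorithm. Replicate communities are generated once per (type, replicate)
and reused across all other factors; model fits are shared across target
sizes, which only affect selection. Both approaches consume the identical
observation within a record (paired design). Every stage derives its own
sub-seed by hashing (master seed, stage name, factor tuple), so any single
cell reproduces in isolation; records are therefore identical whether a
cell is run alone, in a sweep, or after a resume.

## Problem sizes and what the tests show

The package defaults give the full-scale design (1000 × 1000 grid, 19
R values, 3 biases, 5 targets, 3 algorithms, 10 replicates = 25,650 runs;
the planner enumerates exactly this). The test suite and the acceptance
script exercise the pipeline at 200 × 200 with 5 replicates, 3 R values,
2 biases, 2 targets and 50-tree forests with a fixed leaf size — sizes
chosen so a complete verification runs in minutes on one CPU. At that
scale the *directional* findings hold (model-based prioritization is
beneficial more often under strong bias, narrow range and small targets,
and covers no more rare species than the raw approach), but the absolute
percentages of beneficial cases are smaller than at full scale: with 200
species the surveyed pool saturates quickly and the raw approach is
harder to beat. Passing tests therefore certify mechanics and directions,
not the full-scale percentages.

What the generator deliberately does not emulate: detection error, 2-D
space, multiple environmental variables, and spatially or environmentally
structured richness. Conclusions about real landscapes with strong
richness gradients are outside what these simulations can support.

## Numerical notes

- Swap acceptance requires improvement > 10⁻¹² to keep floating-point
  no-ops from looping.
- `round(x)` ties are resolved half-up everywhere margins are built, via
  `floor(x + 0.5)`.
- All randomness flows through `numpy.random.Generator`; identical spec +
  seed gives bit-identical communities and records.
- Degenerate inputs (single species, empty surveys, all-presence
  responses, constant truth rows) are handled explicitly and tested.
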