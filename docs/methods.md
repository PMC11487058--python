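# Methods

## The interference length

Crossover interference is quantified per chromosome from the per-sample CO
counts `N` and positions `x_i ∈ [0, L]`. The statistic is the difference
between a distance representative of the observed pattern and the distance
expected without interference,

    L_int = d_int − d_noInt.

**Null model.** "No interference" means COs placed independently along the
chromosome with Poisson-distributed counts of the same mean `⟨N⟩`.
`d_noInt` is the mean distance over all pairs of *distinct* entries in the
pooled position multiset (all samples pooled, same-sample pairs included —
with-replacement sampling would differ only at `O(1/M)` for `M` pooled
positions). Pooling preserves the empirical CO density, so a non-uniform
recombination landscape alone does not register as interference.

**Observed side.** `d_obs` is the mean distance over all observed
same-sample pairs, each *pair* weighted equally (samples with more COs
contribute more pairs). Interference also narrows the count distribution: a
sample with `N` COs has `N(N−1)/2` pairs, so the mean observed pair count
`N̄_obs^pair` falls below the Poisson value `N̄_noInt^pair = ⟨N⟩²/2` even at
identical `⟨N⟩`. The missing pairs `N̄_mis^pair = N̄_noInt^pair − N̄_obs^pair`
are assigned the largest observable distance, `d_mis = L`, and `d_int` is the
pair-count-weighted average of `d_obs` and `d_mis`. With
`φ = N̄_obs^pair/N̄_noInt^pair` this collapses to the operative formula

    L_int = φ·(d_obs − d_noInt) + (1 − φ)·(L − d_noInt),

which is what `interference_length` evaluates (the `d_obs` term is dropped
when `φ = 0` and no pair exists). Closed-form anchors:

| configuration | L_int |
|---|---|
| Poisson counts, independent positions (any density) | 0 |
| one CO per sample, uniform positions ("complete interference") | 2/3·L |
| one CO per sample at a fixed position | L (exactly) |
| N evenly spaced COs, uniform phase ("regular placement") | L·(1/N − 1/(3N²)) |
| maximal-interference reference for mean count N ≥ 2 | 4/3·L/N (reference curve only) |

The maximal-interference curve is exposed as a reference value, not asserted
against a simulator: the CO configuration achieving it is not constructed
here. A related edge case: for *exactly two COs at opposite chromosome ends*
direct evaluation of the formula gives `L/2` (`φ = 1/2`, `d_obs = L`,
`d_noInt → L/2`), not the `2/3·L` sometimes quoted for that scenario from a
different derivation; the package reports what the formula gives and does not
special-case this configuration.

**Properties** (each verified by a test): scale equivariance (positions and
`L` in different units rescale `L_int` exactly, leaving `φ` and `L_int^norm`
unchanged); invariance in expectation under binomial thinning of COs
(random detection loss, e.g. genetic data seeing half the bivalent's COs);
`L_int ≤ L − d_noInt` whenever `φ ∈ [0, 1]`, with equality iff `φ = 0`.

**Clustering.** If COs cluster (more pairs than the Poisson null),
`N̄_mis^pair < 0` and the two-term formula can return `L_int < 0`. The value
is reported together with a `ClusteringWarning`; clamping would hide real
negative interference. The `d_int` field of `PairStatistics` is left unset in
this regime because its weighted-average form has a negative weight.

**Normalization.** `L_int^norm = L_int·⟨N⟩/L` removes the `L/⟨N⟩` scaling
expected under strong interference and measures placement regularity. `⟨N⟩`
should count COs per bivalent; genetic (gamete) counts are roughly half of
that, so `interference_length(..., bivalent_correction=True)` doubles `⟨N⟩`
in the normalization. The correction is never applied silently — the caller
knows the detection modality, the data do not.

**Mixed-class variant.** To ask whether class I COs interfere with class II
COs, `mixed_interference_length` counts observed cross-class pairs
(`N_a·N_b` per sample) against the independence expectation `⟨N_a⟩·⟨N_b⟩`,
uses the cross-class analogues of `d_obs`/`d_noInt`, and evaluates the same
two-term formula. Under independence of the two processes it is 0 in
expectation. Unlabeled COs are excluded; calling it with both classes equal
falls back to the single-class estimator restricted to that class.

## Classical measures

**CoC curve.** The chromosome is cut into `bin_count` equal bins (default
15 — the choice is the user's; no binning is privileged). For bins `i ≠ j`,
observed co-occurrence `f_ij` is the fraction of samples with at least one
CO in *both* bins (presence/absence, not counts); expected is `f_i·f_j`.
All bin pairs at the same center separation are aggregated as a ratio of
sums `Σf_ij / Σf_i·f_j`, which remains stable when individual expected
frequencies are tiny; separations with zero expected sum are dropped. The
interference distance `d_CoC` is the linearly interpolated first upward
crossing of 0.5; a curve starting at or above 0.5 yields 0 by convention,
one that never reaches 0.5 has no `d_CoC`. Note the first resolvable
separation is one bin width: weak interference can be invisible at coarse
binning (`d_CoC = 0`), which is the known resolution/data trade-off of the
measure — tests that compare interference strengths use 25 bins.

**Gamma shape.** Adjacent CO distances pooled over samples with ≥ 2 COs are
fitted by a two-parameter gamma MLE (`scipy.stats.gamma.fit`, location fixed
at 0); at least 10 distances are required. `ν = 1` is exponential spacing
(no interference). Zero distances (coincident foci at resolution limits) are
replaced by `10⁻⁹·L` to keep the likelihood finite. Distances are **not**
corrected for censoring at chromosome ends; with few COs per chromosome the
complete-interval selection biases `ν` (for a Poisson process the fit stays
within ~0.15 of 1 only once a chromosome holds ~20 COs — the tests use that
regime).

## Resampling inference

The exchangeable unit is the sample (cell/gamete). Three procedures, all
pure functions of (data, seed, replicates) with at least 100 replicates:

- `bootstrap_sem` — nonparametric bootstrap over whole samples; SEM is the
  standard deviation of replicate estimates. Degenerate replicates are
  redrawn, up to 10× the requested number of draws.
- `test_two_sample` — permutation test: samples pooled and reassigned to
  groups of the original sizes; statistic `|estimate(a) − estimate(b)|`
  (two-sided by construction).
- `test_vs_null` — parametric bootstrap from the fitted no-interference
  null: Poisson counts with the observed mean, positions i.i.d. from the
  pooled observed positions. One-sided (interference inflates the
  estimator).

p-values use the add-one rule `(k+1)/(B+1)` and cannot be exactly zero. No
multiple-testing correction is applied; callers comparing many chromosomes
must correct downstream. Calibration at nominal α = 0.05 is verified by
simulation (400 replications of each test on its own null) in the test
suite.

## Simulators

`simulate(SimulationConfig(...))` generates per-chromosome datasets under
five placement models (see module docstring for the list). Defaults emulate
the analysis conditions used throughout the tests: unit chromosome length,
uniform positional density, mean counts of 1–5. The gamma renewal model is
*stationary*: inter-CO distances are gamma(ν₀, scale `L/(ν₀⟨N⟩)`) and the
first CO is drawn from the equilibrium forward-recurrence distribution via
the length-bias construction `U·Gamma(ν₀+1)`, so the expected count on the
window is exactly `⟨N⟩` and ν₀ = 1 reproduces the Poisson process exactly.
`subsample` applies independent binomial thinning per CO.

What the simulators do **not** emulate about real data: non-uniform
chromatin compaction (DNA↔SC conversion is linear), per-cell SC length
variation, centromere effects or CO maturation biases, and any mechanistic
interference model (no HEI10-coarsening or beam-film dynamics). Passing
tests therefore demonstrate correctness of the estimators under the stated
point-process models, not biological fidelity of any particular species'
landscape.

## Numerical choices and problem sizes

- Pair distances use exact prefix-sum identities (`O(M log M)`), verified
  against brute-force enumeration to 10⁻¹² relative tolerance.
- Closed-form recoveries are tested at 5·10⁴–2·10⁵ samples, where the Monte
  Carlo error is well below the asserted tolerances (±0.01 absolute, or 3
  bootstrap SEs); calibration checks use 400 outer replications of tests
  with 100 inner replicates on 100–120 samples. These sizes were chosen so
  each check resolves its tolerance with comfortable margin.
- Chromosome length always comes from the length table, never from the
  maximum observed position (which would bias `L_int` downward).
- Zero-CO samples must be declared in input files via manifest rows (empty
  position field); silently omitting them would bias `⟨N⟩` and `φ` upward.

## Known limitations

- The class-II contamination correction for `L_int` (when a fraction of
  detected COs is non-interfering) is not implemented.
- `d_CoC` inherits the binning resolution limit described above.
- The gamma fit is end-censoring-biased for chromosomes with few COs.
- Published cross-species datasets are not re-analyzed here; doing so
  requires the original data and their study-specific preprocessing
  (merging genetic/cytological sets, averaging SC lengths across cells).
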