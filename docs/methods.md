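# Methods

## The segmentation model

A time-course experiment is a profile of |G| genes at |T| ordered time
points. The method assumes regulation acts in *periods*: maximal intervals
of time points over which the set of active regulations is constant. The
model is a binary activity matrix `Act` (genes × time points) whose rows
are constant within each period, together with the break set `Tra` of
period boundaries (break j means one period ends at the j-th point and the
next begins at the (j+1)-th), scored against a regulation-intensity matrix
`M` by

    Score(Act) = Σ_ij M_ij·Act_ij − c·|B|·ln(|G|·|T|).

Positive `M_ij` is evidence the regulation of gene i is active at time j,
so the first term rewards switching a gene on exactly where the evidence is
positive; the second is a Bayesian-information-criterion style penalty per
break. Two conventions are supported for the penalized break count |B|:

* **declared** (default): |B| is the number of breaks the search currently
  entertains, even if a break is not used by any gene — this is what the
  k-loop of the search procedure charges;
* **effective**: |B| counts only the transitions actually realized by
  `Act`, which is the score function read literally.

At the exhaustive optimum the two coincide: an unused declared break can be
dropped at no cost in fit, strictly improving the declared score, so every
optimal break is realized by at least one gene (asserted in the test
suite). The penalty coefficient `c` defaults to 2, the factor the search
procedure subtracts per break; `c = 1` gives the plain score. `|G|` in the
penalty is the number of rows of M; a different effective gene count can be
supplied (`penalty_genes`) when M rows are a subset of a larger system.

### Search

For a fixed break set, the optimum decomposes: each gene independently
activates each period iff the period's intensity sum is strictly positive
(exact zeros stay inactive — the sparser model), contributing
`Σ_periods max(0, period sum)`. Two searches over break sets are provided.

`search_exhaustive` enumerates all break sets of size k for k = 0, 1, …,
keeping the per-k best (ties broken toward the lexicographically smallest
break set, and toward smaller k across sizes, for reproducibility). Its
`early_stop` flag (on by default) implements the stopping rule of the
original procedure: quit as soon as score_k fails to improve on
score_{k−1}. This rule is not globally optimal — the micro-instance
M = [[5, −5, 5]] at c = 1 scores 5, 5 − ln 3, 10 − 2·ln 3 for k = 0, 1, 2,
so the stopper returns the flat k = 0 model while the true optimum has two
breaks — which the result records honestly (`stopped_early`), and a few
break counts past the stop are still tabulated in a separate `reference`
field so score-vs-period tables can show the neighborhood of the optimum.

`search_dp` solves the same problem exactly by dynamic programming. Segment
gains `gain(a, b) = Σ_g max(0, Σ_{j=a..b} M_gj)` are precomputed from
per-gene prefix sums (the memoized gene-and-period sub-scores); the best
m-segment cover of the suffix starting at column a satisfies
`S(m, a) = max_e gain(a, e) + S(m−1, e+1)`, and
`score_k = S(k+1, 0) − c·k·ln(|G|·|T|)`. Backtracking always takes the
smallest optimal segment end first, recovering the lexicographically
smallest optimal break set. The DP is O(|G|·|T|² + K·|T|²) and reproduces
the exhaustive per-k scores to 1e−9 on 200 random instances in the
acceptance suite; it has no early stopping (all k up to `max_breaks`,
default |T|−1, are reported).

### Conventions and degenerate inputs

Break indices are 1-based; reported breakpoint labels use the time value of
the last point of the earlier period (the convention a reader needs to
interpret "the shift happened at 878 min"), with both flanking time values
also emitted, since period-end vs period-start labeling is otherwise
ambiguous. |T| = 1 admits only the empty break set. An empty M is an error.
All-zero rows of M contribute nothing but still count in |G|. Scores are
plain float64 sums; ties at exactly 0 in a period sum deactivate the
period.

## The intensity estimator

The segmentation consumes M from any source; `read_intensity` ingests
externally computed matrices (e.g. from the tacs R package, the canonical
route for published real-data analyses). The in-package estimator
`loo_intensity` is this package's own reference construction of the
leave-one-out idea: each time point is scored by how well the profile with
that point omitted predicts it.

For gene g with parent set P(g) (self-loops excluded — a gene cannot
explain itself) and time point j:

1. Fit g's expression on its parents' expression over all points except j.
   The core is ordinary least squares with intercept
   (`fit_parent_model`; residual scale `sqrt(RSS/(n−rank−1))`,
   rank-deficient designs solved by pseudo-inverse on the centered design
   and flagged degenerate). The fit is made robust by least-trimmed-squares
   style concentration steps: refit on the h = ⌊n/2⌋+1 points with the
   smallest residuals until the subset stabilizes, from several starting
   subsets, keeping the converged solution with the smallest
   noise-to-signal ratio (trimmed residual scale over fitted-value sd), and
   finally refitting by OLS on all points within 2.5 corrected standard
   deviations. Robustness is not a luxury here: regulation that is active
   in only part of the time course is the phenomenon under study, and a
   pooled OLS over both regimes produces a compromise slope that inverts
   the active/inactive contrast. Start subsets are blocks of points sorted
   by the child's and each parent's *values* — never by time, never at
   random — so the estimator is deterministic and permuting time points
   permutes M's columns identically. Selecting by noise-to-signal ratio
   rather than trimmed RSS matters for autocorrelated profiles, where a
   low-spread stretch of data can be fit spuriously tightly while
   explaining no signal.
2. Form the held-out residual r_j = y_j − ŷ_j and standardize it at the
   row level: s_r is the 0.4-quantile of the gene's |r| divided by the
   matching Gaussian quantile (the cleanest 40% of points are taken to
   represent the locked-on regime), floored at `sigma_floor`; s_j is the
   sd of the j-th fit's fitted values (the scale of signal the parents
   explain), also floored. Then

       ρ_j² = r_j² · (1/s_r² + 1/s_j²),   M_gj = λ − min(ρ_j², ρ_cap).

The three standardization ingredients each carry one property. The
row-level robust scale makes E[ρ²] ≈ 1 for points that follow the fitted
regime, absorbing the small-sample biases of trimmed fitting, so active
regulation with signal ≫ noise scores about λ − 1 > 0 and an exactly
explained child scores exactly λ (residuals vanish). The explained-signal
term makes a *no-signal* fit unable to claim any point: a child decoupled
from its parents leaves the regression with fitted-value sd near zero, ρ²
blows up, and the gene scores strongly negative — a plain standardized LOO
residual cannot deliver this, because it is self-normalizing (E[ρ²] ≈ 1
regardless of R²). The cap ρ_cap = 9 (a 3σ discrepancy) bounds the
influence of any single time point so that one outlier can never, by
itself, out-weigh a break penalty downstream. ρ is invariant to affine
rescaling of the child (all three scales transform together), up to the
`sigma_floor` regime.

Defaults: λ = 2 (a well-explained point then scores ≈ +1 under the
unit-mean χ² of a standardized residual), `sigma_floor` = 1e−8,
`robust = True`, ρ_cap = 9. The estimator needs |T| ≥ max parent count + 3
so each leave-one-out fit keeps two residual degrees of freedom. Individual
points of a genuinely regulated gene can still dip negative (ρ² has the
spread of a χ²); it is the period *sums* the segmentation consumes that
separate regimes.

Signed edges are carried as metadata only; the score never uses them.

## Synthetic data

The generators exist so every stage is testable without downloads; their
defaults are the study conditions of the test and acceptance suites.

`generate_intensity` plants period structure directly in M:
`M_gj ~ Normal(μ_act, σ)` where a binary gene × period plan marks the gene
active, `Normal(μ_inact, σ)` otherwise, with μ_act = +1, μ_inact = −1,
σ = 0.3 — evidence well separated from zero at the per-point level, the
regime the score model assumes. `planted_truth` draws the plan uniformly
and then guarantees identifiability in two ways: every break flips at least
one gene (an unflipped break is undetectable by construction), and breaks
are by default placed evenly with ±1 jitter (`placement="spread"`), since a
break flanked by a one-or-two-point period carries raw support below the
break penalty at these sizes and is unidentifiable by design rather than by
noise (`placement="uniform"` is available for studying exactly that
regime).

`generate_network` samples a random DAG (edges respect a random topological
order), so expression can be generated parent-first; cyclic input networks
are rejected with the offending cycle named.

`generate_expression` drives root genes with a chosen signal and makes each
regulated gene follow the mean of its parents plus `Normal(0, σ_expr)`
noise in its active periods, and an *independent* signal draw plus noise in
inactive periods. The default driver is a sine of amplitude `signal_scale`
= 3 (ten times the default noise sd — a strongly regulated pathway) with
frequency drawn from U(1.5, 4) cycles per course. The amplitude choice
guarantees a strong, range ≫ noise parent signal in every draw (a random
walk's realized range can collapse to the noise scale); the frequency floor
makes independently drawn signals decorrelate within half the course —
below ~1 visible cycle, two independent smooth signals are near-collinear
over a 10-point window, and an inactive gene is then *genuinely* linearly
explained by its parent, a situation no estimator could or should reject.
Ramp and random-walk drivers are provided for sensitivity studies.

What the generators do **not** emulate: mechanistic transcription dynamics
(no ODEs, no lags — a child responds to its parents at the same time
point), nonlinear regulation, edge-sign constraints, measurement-platform
artifacts, or unequal time spacing effects (the estimator ignores spacing
by design). Passing tests therefore demonstrate that the optimization and
the estimator behave as specified under their own model assumptions, not
that those assumptions hold for any particular real dataset.

## Problem sizes and determinism

The acceptance suite runs the sizes the method targets: DP-vs-brute
equivalence on 200 instances with |G| ≤ 6, |T| ≤ 8 (brute force enumerates
all 2^{|T|−1} break sets); break recovery on 100 replicates at
|G| = |T| = 20 with three planted breaks; the end-to-end pipeline on 100
replicates of ten parent→child pairs over 20 points with one planted
boundary, counted as localized when the best model places a break within ±1
point of it. In that pipeline the best model occasionally (about a quarter
of replicates) contains an additional boundary beyond the planted one:
stretches where an independently drawn signal happens to track the parent
are classified as regulated, and the boundary delimiting such a stretch is
real structure in the generated instance as seen by any
explained-vs-not-explained criterion. One integer seed drives each
generator; identical seeds give identical outputs (IEEE-754 double
arithmetic, NumPy default generator).

## Known limitations

* The intensity estimator is a reference construction of the leave-one-out
  idea, not a numerical replication of the tacs package; published
  real-data tables should be reproduced by ingesting tacs output.
* Robust fitting has a breakdown point at 50% contamination: regulation
  active in well under half the time course is estimated against the
  majority regime, weakening (not flipping) the contrast.
* All genes share one break set by construction — the model detects
  network-level transitions, not per-gene change points; a gene whose
  activity changes where no break is placed is averaged over the period.
* Breaks supported by less raw evidence than `c·ln(|G|·|T|)` are
  (correctly, under the model) pruned; very short periods are therefore
  undetectable at small |G|.
* The estimator treats time points as exchangeable; irregular spacing is
  preserved in labels and reports but carries no weight in the fit.
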