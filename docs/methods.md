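# Methods

## Model and objective

ibkit works with two discrete random variables X and Y with joint pmf
p(x, y), either estimated from paired observations by plug-in counting or
supplied directly as a matrix. The object being optimized is an *encoder*
q(m|x): a stochastic map from X to a bottleneck variable M with
`m_cardinality` states, under the Markov constraint
p(x, m, y) = p(x) q(m|x) p(y|x) — M touches Y only through X.

For a trade-off multiplier β ≥ 0 and interpolation parameter α ≥ 0 the
solver minimizes the generalized bottleneck objective

    L(q) = H(M) − α·H(M|X) − β·I(M:Y)     (all terms in bits).

α = 1 gives the standard Information Bottleneck, L = I(M:X) − β·I(M:Y),
because I(M:X) = H(M) − H(M|X). α = 0 gives the Deterministic Information
Bottleneck: the row-wise minimizer of a linear functional over the simplex
is a vertex, so optimal encoders are hard assignments with H(M|X) = 0.

## The fixed-point iteration

One iteration recomputes, from the current encoder,

1. the cluster marginal q(m) = Σₓ p(x) q(m|x),
2. the decoder q(y|m) = Σₓ p(x,y) q(m|x) / q(m) for q(m) > 0,
3. the per-pair distortion d(x,m) = KL(p(y|x) ‖ q(y|m)),
4. the new rows: for α > 0,
   q(m|x) ∝ exp((ln q(m) − β·d(x,m)) / α); for α = 0 all mass goes to
   argmaxₘ (ln q(m) − β·d(x,m)), ties to the lowest cluster index.

Descent is guaranteed for every α ≥ 0, not only for the classic α = 1
case: the three quantities above are the exact block minimizers of a
variational functional that differs from L by the constant β·I(X:Y) and is
convex in each block (linear plus, for α > 0, the convex α·Σ q ln q term),
so the objective evaluated at the self-consistent (q(m), q(y|m)) never
increases across iterations. The test suite checks this to 1e-10 for
α ∈ {0, 0.5, 1, 2}.

Numerical choices:

* All scores are computed in log space; natural logs internally, bits on
  every reported quantity. The update is base-invariant (2^(s/ln 2) = eˢ),
  and the α = 1 iteration is verified to agree with the directly coded
  classic update q(m|x) ∝ q(m)·2^(−β·d) to 1e-12.
* 0·log 0 = 0 everywhere, implemented by masking zero entries — never by
  pseudocounts. A pair with p(y|x) > 0 but q(y|m) = 0 gets score −∞ for
  that (x, m); at least one admissible cluster always exists for each x.
* β = 0 zeroes the distortion term exactly (the score reduces to ln q(m)),
  avoiding the 0·∞ ambiguity.
* Clusters whose marginal hits zero stay empty as structural zeros, which
  keeps the descent property exact; `reseed_empty_clusters=True` instead
  moves the worst-fit x one-hot onto the emptied cluster (a restart-like
  heuristic that can increase the objective; off by default).
* DIB argmax ties break to the lowest cluster index — deterministic and
  seed-independent. At α = 0, β = 0 this makes the solver return the
  all-to-cluster-0 map among the equivalent single-cluster optima.

## Restarts, seeding, sweeps

The objective is non-convex, so `solve_fixed_beta` runs `n_restarts`
independent optimizations and keeps the lowest final objective. Initial
encoders are rows drawn uniformly on the simplex (Dirichlet(1,…,1)) for
α > 0 and uniformly random one-hot rows for α = 0. Every restart's
generator is seeded by the triple (master seed, β index, restart index),
so a sweep's result is bit-identical however the β grid is chunked across
processes (`n_processes` is purely a speed knob; chunking uses joblib).

Defaults: `tol` = 1e-9 bits on the change of the objective,
`max_iter` = 10 000, `n_restarts` = 3, `m_cardinality` = size of the
x support (enough clusters to realize the optimal frontier). The default
β grid is 30 geometrically spaced points on [0.1, 100], which spans the
knee of every shipped fixture; β = 0 can be added as an explicit anchor.
Each β is solved independently by default; `warm_start=True` feeds each β
the previous winner as an extra candidate (sequential only).

Curve cleaning removes points dominated in the information plane (another
point with I(M:X) at most as large and I(M:Y) at least as large, strictly
better in one, tolerance 1e-9 bits) and near-duplicates, then sorts by
I(M:X). Failed β points are recorded on the curve rather than aborting
the sweep; only an all-β failure raises.

## Estimation and preprocessing

`estimate_joint` is the plug-in maximum-likelihood estimator: normalized
co-occurrence counts, no smoothing (smoothing is deliberately left to the
caller). Alphabets are the sorted unique symbols, so runs are reproducible
regardless of input order. x values with zero marginal mass are flagged
and excluded from the solver support — p(y|x) is undefined there — but
retained in the joint for reporting. Inputs claiming to be pmfs must be
normalized to 1e-12; only `joint_from_matrix` rescales arbitrary
non-negative matrices.

Past-future preprocessing slides a window over a single sequence: X is the
`past_len` symbols ending at t, Y the `future_len` symbols starting at
t + 1 (adjacent, non-overlapping; successive pairs overlap by one step),
giving exactly len − past − future + 1 pairs. Length-1 windows stay bare
symbols; longer windows become tuples, ordered lexicographically in the
derived alphabets.

## Synthetic fixtures: what they do and do not show

The generators provide systems with known information content:

* `binary_symmetric_joint(p)` — uniform binary X through a binary
  symmetric channel; I(X:Y) = 1 − H₂(p) in closed form.
* `k_symbol_noisy_joint(k, p)` — the k-ary symmetric channel;
  I(X:Y) = log₂k − H(1−p, p/(k−1), …).
* `near_uniform_dib_joint(n_x, n_y, concentration, seed)` — a large system
  (default 128×32) with p(x) uniform up to ±10% jitter and p(y|x) built
  from max(2, n_y/4) prototype profiles drawn from a symmetric
  Dirichlet(concentration = 0.2 by default), each row mixing in 10% fresh
  Dirichlet(1) noise to keep full support. The grouped predictive profiles
  give hard clusterings real structure to exploit, which is what makes the
  deterministic regime visibly cheaper in H(M) than the stochastic one at
  matched I(M:Y). The low concentration sharpens the prototypes; both
  values were fixed once as the demonstration conditions.
* `random_joint` / `sample_observations` — seeded random joints and i.i.d.
  paired draws for property tests.

These fixtures emulate stationary discrete channels with exactly known
pmfs. They do not emulate finite-sample estimation error in the curve
(the plug-in estimator is biased upward in MI at small n), non-stationary
time series, or continuous observables — passing tests say the solver and
functionals are correct on known discrete systems, not that a curve from
scarce empirical data is unbiased.

## Problem sizes used in the checks

The shipped verification runs use the 2×2 and 4×4 channel fixtures on the
full 30-point default grid, the 128×32 system on an 8-point grid over
[0.1, 20] with 2 restarts for the deterministic-vs-stochastic comparison,
and exhaustive encoder enumeration on 2×2 and 3×3 systems (at most
27 hard encoders). These sizes trace the full frontier of each fixture;
larger alphabets change runtime, not behaviour, since one iteration is
O(|X|·|M|·|Y|) dense linear algebra.

## Known limitations

* Plug-in estimation only; no bias correction or smoothing of empirical
  pmfs, so curves from small samples overestimate information.
* Each β is solved to a local optimum; restarts make misses rare on small
  systems (the enumeration tests confirm this) but global optimality is
  not guaranteed in general.
* No annealing/continuation in β by default, matching the independent
  per-β architecture; `warm_start` is available but changes nothing about
  the returned guarantees.
* Discrete, finite alphabets only; no continuous or kernel estimators.
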