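# Model and methods

## The direction chain

A cell extends exactly one pseudopod per time step, along one of six
lattice directions θₙ = (n−1)π/3 (counterclockwise from a fixed x-axis).
Repeating the current direction is forbidden.  The ordered pair
Xₜ = (θₜ₋₁, θₜ) of consecutive directions is a Markov chain on the
30 admissible pairs; we fix the lexicographic order on (prev, curr) as
the canonical state order for all matrices and vectors.

The homogeneous transition rule is generative: from pair (m, n),

* with probability `p` the next pseudopod is *de novo* — uniform over
  the three directions at least 2π/3 away from n (p/3 each),
  regardless of how (m, n) itself arose;
* otherwise the pseudopod *splits* to n±1 (a ±π/3 turn).  If the move
  m→n was itself a split, the same handedness continues with weight
  `alpha` and alternates with weight `beta` (α+β = 1); after a de novo
  move the two split targets are equally likely.

Each row of the 30×30 matrix P⁰ then has exactly five nonzero entries
and sums to one by construction.  The rule is equivalent, case by case,
to the four two-step scenarios (split–split, split–de novo,
de novo–split, de novo–de novo) written as Kronecker-delta products;
the test suite checks that equivalence entry-by-entry against a literal
delta-product evaluator.  A naive additive reading of the
de novo–de novo case as a *sum* of two indicator blocks would
double-count and break row stochasticity, which is why the generative
formulation is the one implemented.

Conventions: index +1 = +π/3 = counterclockwise = "L"; the model is
mirror-symmetric, so the naming only labels outputs.  Defaults
`p = 1/7` (splitting observed about seven times more often than
de novo) and `alpha = 0.25, beta = 0.75` (alternating LR/RL sequences
about three times more common than LL/RR) reproduce the observed
pseudopod statistics; both are configurable.

## Stationary state

`solve_stationary` computes the left unit eigenvector of P (via
`scipy.linalg.eig` on the transpose), normalizes it to a probability
vector (L1, nonnegativity enforced within 1e−12, residual
‖ωP − ω‖∞ < 1e−10) and refuses degenerate cases: if more than one
eigenvalue has modulus above 1 − 1e−8 the chain is reducible (e.g.
p = 0 with α = 1 decomposes into rotation cycles) and no branch is
silently picked.  For the homogeneous chain the result has the closed
form ω₀ = (1−p)/12 on the twelve adjacent pairs and p/18 on the
eighteen wide pairs — independent of α, β; `closed_form_stationary`
builds it directly and the two agree to 1e−10 over a p-grid.  Direction
marginals (summing out the previous direction) are uniform, 1/6.

## Gradient coupling

The gradient adds ε·(ĝ·n̂ⱼ) to every structurally allowed transition
except the back-step (target opposite the current direction, at the
cell posterior), which keeps its unbiased value.  This back-step
exclusion is what makes the bias mass-conserving *identically*: the
remaining four targets pair up as opposite unit vectors, so each row of
the bias matrix Δ sums to exactly zero and P = P⁰ + εΔ needs no
renormalization.  Mirror symmetry about the gradient axis is preserved.

ε is dimensionless, ε = γ L |∇C| / C with cell size L (default 10 µm);
only the relative steepness ∇C/C enters.  ε is held constant over a
run (constant relative gradient).  The weak-coupling validity bound —
the largest ε keeping every entry of P in [0, 1] — is computed from the
actual matrix by scanning all biased entries; at the defaults
(p = 1/7, gradient +y) the binding entry is a de novo probability
p/3 = 1/21 against the maximal coupling √3/2, giving
ε_max = 2/(21√3) ≈ 0.0550.  The bound shrinks with p (the de novo
entries vanish first) and is exposed as a function, not a constant.

First-order perturbation theory solves ω₁(𝕀 − P⁰) = ω₀Δ on the
zero-sum subspace (minimum-norm least squares plus the zero-sum
condition, which fixes the homogeneous ω₀-direction freedom) and
returns ω ≈ ω₀ + εω₁.  Against the exact eigen-solution of P the error
scales as ε² (measured log-log slope 2.00 over ε ∈ [0.005, 0.04]), and
the stationary alignment ⟨cos φ⟩ = Σ ω(s) ĝ·n̂(curr(s)) grows linearly
in ε throughout the valid range.

## Simulation

Each sampled direction moves the centroid by a full fixed step
(6 µm per 20-s step).  Real protrusion statistics are messier — only
part of the extensions translocate the body, and step sizes vary — but
the fixed-step idealization is the model under study.  Initial pairs
are drawn from ω₀ by default so ensemble statistics carry no
initialization transient (`init_mode="uniform"` is retained for
sensitivity checks).  Cell k of a run with seed s uses the dedicated
substream `numpy.random.default_rng([s, k])`, making ensembles
bit-reproducible and order-independent; the chain itself is advanced by
a vectorized inverse-CDF draw over the 30 states (cumulative row sums
closed to exactly 1 to absorb roundoff at the top bin).

## Statistics

* **MSD** is a pure realization average of squared displacement from
  the origin (no time-lag averaging), so the first grid point is
  exactly the squared step length, 36 µm².
* **D(t) = MSD/4t** rises over the first minutes and plateaus at the
  long-time diffusion coefficient.
* **Fürth fit**: nonlinear least squares of
  ⟨r²⟩ = 2v²[τt − τ²(1 − e^(−t/τ))] with positivity bounds and a
  deterministic initializer (v₀ from the first grid point, τ₀ = 1 min).
  The default weighting is σ ∝ √MSD: ensemble-MSD noise grows roughly
  like MSD/√N, and uniform weighting would let the noisiest large-time
  points dominate a fit whose parameters are nearly degenerate there
  (only the product v²τ is identified at large t), inflating the
  variance of τ several-fold; the square-root compromise keeps both
  regimes informative while changing the noise-free fit values by less
  than 2%.  `uniform` and `relative` weightings and an explicit fit
  window remain available.  Standard errors come from the fit
  covariance and inherit its assumptions (independent residuals —
  optimistic for correlated MSD noise).
* **Alignment and chemotaxis index**: ⟨cos φ⟩(t) averages ĝ·n̂ over
  cells per step; the CI is its time average after discarding a 2-min
  transient (the series plateaus within a couple of minutes), and the
  CI spread is the standard deviation over cells of each cell's own
  time-averaged cos φ.
* **Turn statistics** count same-handed vs alternating handedness among
  consecutive split-split pairs; the ratio is undefined (reported as
  `None`) when no same-handed pair occurred.

## Problem sizes and reproducibility

The reference ensemble is 10,000 cells × 180 steps (one hour), which
runs in about a second; the chemotaxis scans use 2,000 cells per
coupling value, chosen so the Monte-Carlo error of the CI
(≈ 0.1/√2000 ≈ 0.002) is two orders of magnitude below the CI range
being resolved.  `scripts/acceptance.py` averages the Fürth persistence
time over eight replicate reference ensembles, reducing the fit's
Monte-Carlo error to ≈ 0.02 min without changing what is estimated.

## Known limitations

* The fitted (v, τ) of the default model are 16.3 µm/min and 0.71 min;
  ballistic speed is bounded by the raw path speed 18 µm/min, so
  reported experimental speeds near 10 µm/min can only be matched by
  relaxing the fixed-step idealization (partial translocation,
  variable step sizes), which is out of scope here.
* The Fürth form is an approximation to the chain's true MSD; different
  fit weightings therefore target slightly different effective (v, τ).
* Only the weak-coupling regime is covered: the linear bias breaks down
  (entries leave [0, 1]) beyond ε_max, and no strong-coupling theory is
  attempted.
* The model is point-like with six discrete directions: no cell shape,
  no pseudopod bending toward the gradient, no variable number of
  simultaneous protrusions, no cell–cell signalling.
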