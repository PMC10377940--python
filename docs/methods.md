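# Methods

## Model

A PID problem is a finite joint distribution p(t, y₁, …, yₙ).  All measures
here satisfy the (*) assumption: they depend on the joint only through the
target marginal p(t) and the marginal channels K⁽ⁱ⁾[t, y] = p(yᵢ | t), so the
library's core functions take `(p_t, channels)`; joints are a convenience
layer on top (`channel_from_joint`, `tuple_channel`, `compute_measure`).
Target outcomes with zero probability are dropped from channel inputs when a
channel is extracted from a joint — every measure is insensitive to
zero-mass rows, and dropping them avoids imputing arbitrary conditionals.
All information quantities are in bits; the gate tables (0.311, 0.5, 1)
pin the base-2 convention.  Outcome labels are ordered lexicographically so
that every matrix is bit-for-bit reproducible.

Specific information uses the Williams–Beer form
I(Y; T=t) = Σ_y p(y|t)[log₂ p(t|y) − log₂ p(t)], whose p(t)-expectation is
I(T;Y); the literature this package follows cites specific information
without defining it, so the choice is recorded here.

## Order decision procedures

* **Degradation** `W ⪯d V`: solved as a linear program minimizing the
  entrywise ∞-norm residual ‖W − V·K_U‖∞ over row-stochastic K_U (HiGHS via
  scipy).  HOLDS iff the optimum ≤ `tol` (default 1e-7); the K_U certificate
  is returned and re-verifiable.  The residual formulation is robust to
  floating-point degeneracy compared with a pure feasibility phase.
* **Supermodularity** `W ⪯s V`: breadth-first enumeration of all JoinMeet
  rewrites of V.  The reachable set is finite because the operator permutes
  entries within rows; ties in the exploration order are broken by
  lexicographic column pairs so certificates are reproducible.  A node cap
  (default 10 000) turns overflow into UNKNOWN.
* **Degradation/supermodularity** `W ⪯ds V`: no complete decision condition
  is known, so the checker is sound but incomplete: it searches chains up to
  the configured depth (default 2: `⪯d`, `⪯s`, and `W ⪯d U ⪯s V` over
  closure members U) and answers HOLDS or UNKNOWN, never VIOLATED.
* **Less noisy / more capable**: both are defined by quantification over a
  continuum, so a finite test can only certify *violation*.  The less-noisy
  test evaluates the χ² contraction inequality χ²(pV‖qV) ≥ χ²(pW‖qW) on all
  ordered pairs of grid distributions (entries in multiples of `grid_step`,
  default 0.1 — the protocol used for the published tables); the
  more-capable test evaluates I(p;V) − I(p;W) on the same grid, optionally
  polished by a local SLSQP descent from the worst grid point (polish can
  only expose violations, never hide one).  Non-violation is reported as
  `NO_VIOLATION_AT_RESOLUTION`, deliberately not `HOLDS`.  Refining the grid
  only adds witness pairs, so a VIOLATED verdict can never revert at a finer
  step.  χ² uses the conventions 0²/0 := 0 and (>0)/0 := +∞; an infinite
  value on the stronger channel's side satisfies the inequality.

## The degradation measure (exact path)

I∩d maximizes the convex function I(Q;T) over the polytope
{(K_U⁽¹⁾, …, K_U⁽ⁿ⁾) : K⁽¹⁾K_U⁽¹⁾ = K⁽ⁱ⁾K_U⁽ⁱ⁾ ∀i, K_U⁽ⁱ⁾ row-stochastic},
so the optimum sits at a vertex.  Vertices are enumerated as basic feasible
solutions: every subset of `rank(A)` columns of the equality system is
solved and kept if non-negative and consistent.  Enumeration runs whenever
the binomial count C(n_vars, rank) ≤ 200 000 — a cap on the actual subset
count rather than on the variable count, since the latter does not bound
the work.  All published examples (2–4 target outcomes, binary sources)
fall far below the cap and are therefore solved *exactly*.

Above the cap a seeded multistart Frank–Wolfe ascent takes over: from each
start, repeatedly move to the vertex maximizing the linearized objective
(one LP per step) until no ascent remains.  Starts are the constant
channels, each source channel that is a degradation of all others (found by
feasibility LPs, guaranteeing the printed table equalities like Q = Y₂ are
found deterministically), and random vertices from random-objective LPs.
The result is then labelled a LOWER_BOUND with the MMI value as the upper
companion.

Q's output alphabet is capped at Σᵢ|S_Yᵢ| − n + 1, which is provably
sufficient for the degradation measure.  The same default cap is applied to
the less-noisy/more-capable solvers, where no such sufficiency proof exists;
the cap is configurable (`SolverOptions.q_support_cap`) for that reason.

## The sampled-constraint measures (bracket path)

For `ln` and `mc` the defining constraints range over the whole target
simplex, which is not finitely checkable.  Both measures therefore return a
**bracket** [lower, upper], collapsing to EXACT only when the endpoints meet
within `collapse_tol` (1e-4):

* **Lower bound** (certified feasible): the best I(T;Yⱼ) over sources Yⱼ
  that pass the corresponding order check against every other source (such
  a Yⱼ is itself an admissible Q); the deterministic common part when the
  joint is supplied (a function of every source is below every source in
  all orders used here); else 0 via the constant channel.  The bound is
  clamped by the MMI cap, which every measure obeys.  Caveat: a
  passing-source certificate relies on a grid non-violation, which is
  itself resolution-limited.
* **Upper bound**: the best local optimum of the sampled-constraint
  relaxation — maximize I(Q;T) over row-stochastic K_Q subject to the
  order's inequality at a finite constraint sample — clamped by MMI and
  never below the lower bound.  The constraint sample is the full simplex
  grid at `grid_step` plus `n_dirichlet` (default 500) seeded flat-Dirichlet
  draws.  Constraints whose right-hand side is numerically zero are imposed
  *structurally*: a zero mutual-information cap forces the corresponding
  rows of K_Q to coincide (rows are merged by union–find and the problem is
  re-parameterized on row groups); a zero χ² cap at a pair (p, q) forces
  (p−q)·K_Q = 0 (unit-vector pairs again merge rows; other pairs become
  linear equalities).  This makes the structurally-forced part of the
  optimum exact — it is why copy targets with independent sources come out
  at exactly 0 (the independent-identity property).  Of the remaining
  constraints only the `max_kept_constraints` tightest (smallest right-hand
  side) are kept for the SLSQP stage, which runs from each projected source
  channel, the constant channel and `sampled_restarts` Dirichlet starts.
  When the MMI cap already meets the certified lower bound within
  `collapse_tol` the SLSQP stage is skipped — the bracket cannot tighten.

Honesty note: a local maximum of the sampled relaxation is a heuristic
stand-in for the relaxation's global optimum; the relaxation itself
over-relaxes the true feasible set.  The reported upper bound is therefore
"best effort plus the always-valid MMI cap", matching the protocol used to
produce the published tables, and the bracket label keeps the uncertainty
explicit rather than collapsing it to a midpoint.  Grid refinement
monotonically shrinks the relaxed feasible set but is not known to converge
to the true measure.

`ds` brackets between max(degradation value, best source certified by the
sound `⪯ds` chain search) and the more-capable upper bound (the ds order
implies more capable).  For the printed 3×2 pair the single JoinMeet
certificate makes the bracket collapse at I(T;Y₄); for the 2×2
counterexample pair it remains an honest [I∩d, I∩mc] interval, mirroring
the open status of that entry.

## Deterministic measures

The common part of the sources is computed as the connected components of
the n-partite graph joining source outcomes that co-occur with positive
probability (networkx).  The component index is the maximal variable that
is a deterministic function of every source; its entropy is the Gács–Körner
common information, and I(component; T) is the deterministic II measure
(exact by maximality plus data processing).  With a single source the
maximal function is the source itself, giving self-redundancy I(T;Y₁).

## PID assembly

`pid_bivariate` derives U₁, U₂, S from the redundancy via the standard
identities.  A bracketed redundancy propagates as intervals on all four
components (U decreasing in R, S increasing in R); midpoints are never
taken.  Components are clamped at 0 against roundoff.

## Synthetic inputs and what the tests show

The worked examples are generated exactly: gate joints with iid uniform
binary inputs and rational masses, and the two printed channel pairs stored
as their printed numeric matrices (the parametric construction behind the
2×2 pair lives in cited prior work and is deliberately not
reverse-engineered).  Randomized suites use flat-Dirichlet channels and
joints with fixed seeds; these are full-support, generic-position inputs,
so the property tests exercise the generic case but not adversarial
boundary geometry (near-singular channels, vanishing masses) beyond the
explicit degenerate-input unit tests.  Conclusions about real biological
data pipelines (estimation error from finite samples, alphabet inference)
are out of scope: inputs are exact distributions.

Problem sizes: the randomized acceptance suites run 50 joints for the
Williams–Beer axioms, 100 joints for the measure chain and 200 seeded
constructions for the order-implication chain, all on binary alphabets with
reduced solver effort (40 Dirichlet constraint draws, 2 extra restarts, 120
kept constraints); the worked-example tests and the acceptance script use
the package defaults stated above.  The brute-force cross-check of the
degradation optimizer grids a two-letter Q at step 0.002 on binary-target
instances (a two-letter Q empirically attains the three-letter optimum
there) with exact inverse-based feasibility, restricted to channels with
|det| ≥ 0.05 so the inverse test is well-conditioned.

## Numerical conventions and limitations

* Input tolerance: distributions accepted if |Σp − 1| ≤ 1e-6 and
  renormalized; internal consistency asserted at 1e-9.  Degradation LP
  tolerance 1e-7; grid-violation margin 1e-9; bracket collapse 1e-4.
* 0·log 0 := 0 throughout; χ² zero conventions as above.
* The `ds` checker and measure are sound but incomplete by construction —
  a deeper chain search could in principle raise a lower bound; no known
  algorithm closes the gap.
* Less-noisy/more-capable brackets are only as tight as the constraint
  sample and the local solver; they are guaranteed valid only up to the
  caveats above (the MMI clamp and certified lower bounds are always
  valid).
* Exact degradation results depend on enumerating up to 200k basis subsets;
  for large alphabets the Frank–Wolfe path yields certified lower bounds
  only.
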