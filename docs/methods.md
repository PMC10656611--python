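# Methods

## Model and scope

`linframe` treats a finite, simple, directed graph with labelled edges as
the infinitesimal generator of a finite-state, time-homogeneous,
continuous-time Markov process. Vertices are molecular states; an edge
i → j with label ℓ(i → j) is a transition with that rate, dimensionally
(time)⁻¹. Labels are formal products of positive parameter symbols and may
include concentration symbols for ligands assumed to sit in reservoirs, so
labels are constants over the dynamics; time-varying rates, parallel edges,
self-loops and countably infinite state spaces are out of scope.

The Laplacian convention is column-based: `L[i, j] = ℓ(j → i)` for i ≠ j
and diagonal entries minus the column's off-diagonal sum, so `1·L = 0`
exactly and `du/dt = L u` conserves probability. The row-convention
generator used by the linear-algebra engines is the transpose, restricted
to non-target vertices where appropriate; this is asserted by a closed-form
unit test on the two-state graph.

## Forest enumeration

All headline quantities are ratios of rooted spanning-forest weight sums.
Enumeration assigns one outgoing edge to every non-root vertex by
depth-first search, pruning as soon as a choice closes a cycle; in a forest
each non-root vertex has exactly one outgoing edge, so following the chain
of out-edges from any vertex identifies the unique root of its tree, which
gives path constraints (`Φ_{U: j⇝r}`) for free. A single enumeration per
root set is shared across all path constraints by grouping forests by the
root each vertex reaches. Worst-case cost is the product of out-degrees;
that is exact and comfortably fast at the intended desk scale (≲ 10
vertices), but forest enumeration is fundamentally subject to combinatorial
explosion and this package makes no attempt to push past it. A brute-force
filter over raw edge subsets (guarded to ≤ 20 edges) serves as an
equivalence oracle in the tests, never as the implementation.

Weight polynomials are *manifestly positive*: hash maps from sorted atom
multisets to positive integer coefficients, with the zero polynomial (empty
map) distinct from the constant 1. Rational results are ordered
numerator/denominator pairs and are **never cancelled** — each monomial
stays in one-to-one correspondence with a forest, which is the point of the
representation. Numeric edge labels (the grammar admits a positive decimal
literal) are carried as literal atoms inside monomials so coefficients stay
integral; the pipeline expansion Δ(j, N) is likewise expressed over formal
ratio atoms `q_u/p_{u+1}` mirroring its printed form, resolved only at
evaluation time. Canonical ordering (atoms sorted within monomials,
monomials sorted lexicographically) makes all serialized output
reproducible.

## First-passage machinery

`prepare_targets` deletes every outgoing edge of each requested target —
this cannot change the FPT distribution, because trajectories stop on
arrival — then verifies via the SCC condensation that every terminal SCC is
a (singleton) target, so absorption is certain and all mean FPTs are
finite. Non-singleton terminal SCCs among the targets are rejected rather
than collapsed; callers must contract them first.

The kth-moment formula sums over k-tuples of non-target vertices; it is
evaluated by dynamic programming over the matrix of doubly-rooted,
path-constrained forest sums, making the cost quadratic in the number of
non-target states per moment order. Moments are capped at order 4 by
default (`max_order` overrides) because the symbolic objects grow quickly.
The start-equals-target case returns the zero distribution (trivial-path
convention) rather than an error. Conditional FPTs are provided for the
mean only; higher conditional moments have no forest formula here and are
accessible through the stochastic simulator instead. Splitting
probabilities and conditional means are returned uncancelled, so tests
compare them numerically rather than symbolically.

`n_min`, the squared mean over the variance of the FPT, is evaluated
numerically from the first two moments. It is strictly less than the vertex
count for every graph — a bound the test-suite checks on every fixture and
random graph — and whether n_min is itself manifestly positive is an open
question the code deliberately does not assume.

## Pipelines

`PipelineSpec` describes a nearest-neighbour chain: forward labels p_i
(times x at binding sites), backward labels q_i with `None` marking
irreversible transitions, the final catalytic step always irreversible.
Binding must occur on reversible transitions, which excludes the final
step. For a single reversible block the denominator of the mean FPT is the
unique all-forward spanning tree and the numerator is indexed by the gap
position, giving the closed form Σ_j Δ(j, N)/p_j; the package checks this
identity against the general forest formula numerically. The concentration
profile collects an FPT rational function by powers of x, requiring the
pipeline shape (denominator a monomial in x, numerator of no higher
degree); s = 1 is the reciprocal Michaelis–Menten form. Multi-block chains
decompose at irreversible transitions; block FPTs are independent because
every irreversible transition is taken exactly once, so means add and
second moments add with the cross terms 2·Σ_{i<j} τ_i⁽¹⁾τ_j⁽¹⁾. The
conjecture that the kth moment has x-degree k·s is exercised on fixtures
(k ≤ 2) but never assumed by the code.

## Independent oracles

Four engines, none of which touch the forest machinery, back every
formula: SVD null-space solves for the stationary distribution;
absorbed-chain recursions `(−A)·m⁽ᵏ⁾ = k·m⁽ᵏ⁻¹⁾` for FPT moments;
first-step linear systems for hitting probabilities and the products
π·χ; and `scipy.linalg.expm` for transient propagation. A seedable
Gillespie simulator (exponential waiting times, categorical jumps, 10⁶-jump
guard per trajectory, numpy `default_rng`) provides empirical moments and
splitting frequencies with standard errors; its agreement tolerance in the
tests is four standard errors at 10⁴ trajectories, chosen so that a correct
implementation fails with probability well below 10⁻³ per check.

The cross-validation sweep (`linframe check`, also an acceptance test) runs
100 seeded random strongly connected graphs — Hamiltonian-cycle backbone on
3–7 vertices plus 1 to n+1 extra edges, capped by the simple-graph capacity
— times three positive assignments drawn uniformly from [0.2, 3], and
requires relative agreement ≤ 1e-9 for the stationary distribution, moments
k ≤ 3, splitting probabilities and conditional/unconditional means. In the
sweep the forest sums are evaluated to floats before the moment dynamic
programme (a pure evaluation shortcut); the unit suite pins the symbolic
route to the numeric route on the worked examples, so the dual-route
argument — forest formulas versus linear algebra — is preserved. These
problem sizes keep the whole sweep around a second while exercising graphs
up to the size where hand-checking stops being possible.

What the random-graph generator does not emulate: real biochemical networks
are sparse, structured, and often nearly reversible, whereas these graphs
are small dense digraphs with i.i.d. rates; passing the sweep demonstrates
algebraic correctness of the formulas, not biological realism of any
particular model.

## Worked-example graphs

The two larger teaching graphs (the five-vertex strongly connected example
and the six-vertex two-target example) are transcribed from drawings, so
`fixture()` validates them at build time against independently known
counts — 20 spanning trees rooted at vertex 5 and a unique tree rooted at
vertex 3; 24 doubly-rooted forests after making vertex 5 absorbing; 18
forests rooted at {5, 6}, 6 of them containing a path 1⇝5 — and raises
rather than silently proceeding if a transcription ever drifts. The
absorbing variant is *derived* (outgoing edges of vertex 5 removed), not
separately transcribed.

## Numerical choices and degenerate inputs

* Detailed-balance check: cycle basis of the underlying undirected graph
  (ratio products are multiplicative over a basis); default `rel_tol` 1e-9;
  irreversible graphs report `reversible=False` rather than erroring.
* Null-space oracle: SVD with a rank tolerance scaled to the leading
  singular value; a kernel dimension other than 1 is an error.
* Splitting degeneracies follow the trivial-path convention: π = 1 for
  i = q or a single target, π = 0 from a different target, both emerging
  from the enumeration itself rather than special-case code.
* Zero FPT variance (degenerate for n_min) raises instead of returning
  infinity.
* Evaluation under non-positive or missing parameter values raises
  immediately; positivity of every manifestly positive denominator under a
  positive assignment is asserted, not assumed.

## Limitations

Enumeration cost grows with the product of out-degrees; recurrence times,
set-to-set FPTs, full FPT distributions (densities, Laplace transforms) and
kernel bases for non-strongly-connected graphs are not provided. Higher
moments of *conditional* FPTs are simulation-only. Fitting to experimental
data is out of scope; the pipeline results give the parametric forms such
fits would use.
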