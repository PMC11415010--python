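# Methods

## Model

The package works with the uniform random walk on an undirected, simple,
connected graph: P(i,j) = 1/deg(i) for neighbors, 0 otherwise. For a proper
target set A, ordering vertices as (A, A^c) partitions P into an identity
block on A, the substochastic block P_A on A^c × A^c, and the coupling block
R_A = I − P_A (row-sum complement) on A^c × A. Three quantities drive
everything:

* **mean hitting times** t_i = E_i[T_A], the unique solution of
  (I − P_A) t = 1 on A^c (zero on A); the matrix is invertible because the
  graph is connected, so every walk is absorbed with probability 1;
* **the objective** F(A) = Σ_i t_i, the summed expected arrival time; it is
  sandwiched between max_i t_i and (|V|−|A|)·max_i t_i, decreases when a
  vertex is added to A, and is bounded below by the farness
  C(A) = Σ_{v∉A} d(A, v) (a walk needs at least d(A,v) steps to reach A);
* **the consensus link**: with leaders A clamped at value c and followers
  updated by x_{n+1} = P_A x_n + c R_A 1 from x_0 = 0, the iterates equal
  c(I − P_A^n)1 and the ℓ₁ gap to the consensus vector c·1 equals
  c·Σ_{i∈A^c} P_i[T_A > n]. The tail obeys
  P_µ[T_A > n] ≤ exp(−⌊n/⌈e·t*⌉⌋) for µ uniform on A^c, with
  t* = max_i t_i.

The standard walk is periodic on bipartite graphs, but hitting times are
finite regardless, so the solver uses it by default; the lazy walk
(I + P)/2 is available as an option and exactly doubles all hitting times
(every off-diagonal rate is halved).

Distances are hop counts; weighted or directed inputs are out of scope
(directed files are symmetrized on load, which is a modeling choice the
loader makes explicit in its documentation, not a silent coercion of edge
semantics).

## Monte Carlo estimator

One realization ω^j launches an independent walk from every i ∈ A^c and
records H(ω^j, A) = Σ_i T_A^i(ω^j). The estimator
F_M = (1/M) Σ_j H(ω^j, A) is unbiased; since the H_j are i.i.d. with
exponential tails, the Student-t interval
F_M ± s·t_{α}/√M (s² the sample variance with M−1 degrees of freedom) is
asymptotically calibrated, and the sample size needed for half-width δ is
M = ⌈(s·t_α/δ)²⌉.

Implementation: all M·|A^c| walks advance in lock-step through a CSR
adjacency; each active walk draws one uniform variate per step to pick a
neighbor. A single seeded `numpy` generator is consumed in step-major order,
so a fixed seed yields a bit-identical estimate. (Per-walk child streams
would give the same estimator law at much higher cost; common random numbers
across candidate sets can be had by reusing one seed, which stabilizes
rankings even though the step-major coupling is not exact path-by-path.)
Walks are capped at 50·n² steps — a crude cover-time scale at which
surviving mass is astronomically small on a connected graph — and a capped
walk is a *censored observation*: it raises in the single-walk API and
poisons the batch estimate (`valid = False`, a RuntimeWarning), never a
silent truncation.

## Heuristics

Both searches restrict candidates to the h highest-degree vertices, ties
broken by ascending vertex index, as are all argmax/argmin ties — every
stage is deterministic given parameters and seed.

**Combinatorial** (small k): enumerate all C(h,k) hub subsets; keep the b
with the largest p-neighborhood coverage |N^p[S]| (disjoint hubs beat
overlapping ones); keep the q of those with the smallest farness (valid
because C ≤ F); rank the q by a cheap Monte Carlo pass F_{M1}; re-rank the
best ⌈q/2⌉ with the larger budget F_{M2} and return the argmin. The number
surviving the preliminary ranking is not pinned down by the outline this
follows; half of q keeps the cheap pass meaningful while still letting the
expensive pass overturn close calls. With h = |V|, b = q = C(h,k) and exact
final ranking the search degenerates to exhaustive enumeration — the
configuration the tests use to verify it against the brute-force optimum.

**Semi-greedy** (larger k): seed with the hub *pair* maximizing joint
coverage over all C(h,2) pairs — starting from a pair rather than the top
hub avoids the local minimum of two adjacent big hubs — then repeatedly add
the hub with the largest marginal coverage gain until |A| = k. k = 1
degenerates to the best-covering single hub. The result reports C(Â) and
F_M(Â) (or exact F on request). No farness screen is applied: the greedy
trajectory produces a single set.

**Fallback**: on some dense-core networks the plain top-k-hub set beats the
coverage-driven pick; `hub_fallback` evaluates both (exact F when available,
otherwise a matched Monte Carlo budget) and returns the better.

Defaults: p = 1 (p = 2 can help below ~100 vertices), h = 10k capped at
|V|, b = q = 5, M1 = 10², M2 = 10⁴. These are the practical-compromise
settings the package adopts throughout its own evaluation harness.

## Evaluation harness

On graphs where C(|V|, k) is enumerable (a configurable budget, default
10⁵ sets, refuses larger sweeps — the 297-vertex case at k = 3 alone is
4,322,340 linear solves and belongs offline), `exhaustive_optimum` gives
the true minimizer. Otherwise the baseline is L uniform k-subsets sampled
with replacement (L = 1000 by default; L ≥ 30 enforced for the CLT-based
standard error σ/√L): E_L[F_k] is what a random guess buys, M_L[F_k] the
best of L guesses, and the ratios E_L[F_k]/F(Â), M_L[F_k]/F(Â) measure the
heuristic's advantage. Two empirical regularities the tests check as trends:
the E-ratio decreases with k (a single vertex matters less in a bigger set)
and increases with the degree ratio Δ/⟨d⟩ (heavier tails give hubs more
leverage).

For lower-tail threshold estimation, the largest F value among the final
candidates of a run estimates the η-quantile threshold c with
n = ⌈η·C(|V|,k)⌉ final sets; averaging over T independent replications has
Chebyshev confidence 1 − Var(c)/(T·ε²), so
T = ⌈Var(c)/((1−conf)·ε²)⌉ replications suffice for half-width ε. (The
inequality is implemented from this confidence expression; writing it with
the variance of the un-normalized sum would be dimensionally inconsistent
with it.)

## Synthetic data

Deterministic families (path, cycle, star, complete, barbell) come with
closed-form hitting profiles used as analytic oracles for the solver:
path with endpoint target, t_i = i(2n−i−2); cycle, t = d(n−d) at hop
distance d; star center, t ≡ 1 on leaves; complete, t ≡ n−1. Random
families emulate the heavy-tailed regime: Barabási–Albert preferential
attachment, and a configuration-model draw from a discrete power law on
[2, n−1] (inverse-CDF sampling; minimum degree 2 keeps the giant component
near size n), simplified and reduced to the largest connected component.
Simplification distorts the drawn degree sequence at the high end — the
family targets a qualitative regime (Δ/⟨d⟩ ≫ 1, typically > 5 at n = 2000,
γ = 2.3), not a specific degree sequence.

What the generator does **not** emulate: community structure, degree
correlations, clustering, and the label conventions of any real network
archive. Passing tests therefore demonstrate correctness of the machinery
and the qualitative hub-heuristic story, not performance claims about any
particular real network.

## Numerical choices

* Linear systems: dense `numpy.linalg.solve` below 500 free vertices
  (faster at small sizes and bit-stable), sparse LU (`spsolve`) above.
* Tolerances: solver cross-checks at 1e−10..1e−8; consensus/tail identity
  asserted at 1e−10; transition row sums at 1e−12.
* Tie-breaks: lexicographic on sorted member indices, everywhere.
* Tail-bound typography: the exponent is read as ⌊n/⌈e·t*⌉⌋ by default (the
  always-valid integer-part form); the tighter un-floored ratio is behind a
  flag since the two readings differ for n below the mixing scale.
* Vertex labels are mapped once to dense indices 0..n−1 in sorted-label
  order; every matrix and every tie-break uses that ordering, and reports
  translate back to original labels.
* Seeds: every stochastic routine takes an explicit seed; heuristic stages
  derive per-candidate child seeds deterministically from it.

## Problem sizes in the standard runs

The test suite and `scripts/acceptance.py` run entirely on synthetic
graphs: solver oracles on 4–8 vertices, identity and doubling sweeps on
≤ 30, heuristic-vs-exhaustive on ≤ 20 vertices with k ≤ 3 (50 instances),
Monte Carlo calibration on 3–6-vertex fixtures with M = 10⁴ over 500
replications, and improvement ratios on 200–300-vertex heavy-tailed graphs
with L = 1000 sampled baselines. These sizes make every expected value
exactly checkable while exercising the same code paths a large-graph run
uses; scaling beyond them is a matter of budget, not of different code.

## Known limitations

* Exhaustive validation is inherently limited to small graphs; on large
  ones the harness bounds quality only relative to sampled baselines.
* The estimator's confidence interval is asymptotic in M; at very small M
  on highly skewed H distributions coverage can dip below nominal.
* Directed and weighted walks, spectral convergence-rate analysis, and
  supermodularity-based exact solvers are out of scope.
* The semi-greedy variant optimizes coverage, not F directly; the fallback
  and the Monte Carlo final ranking mitigate, but adversarial graphs can
  defeat a pure coverage proxy.
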