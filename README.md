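# firsthit

Find the *k* vertices of a network that a random walker reaches fastest —
effective influencer (leader) sets for consensus and spreading processes.

## The problem

Let 𝒢 = (V, ℰ) be an undirected, connected, simple graph and let X_t be the
uniform random walk on it, P(i,j) = 1/deg(i) for j ~ i. For a target set
A ⊆ V the first hitting time is T_A = min{t ≥ 0 : X_t ∈ A}, and the quality
of A as an influencer set is measured by the summed expected arrival time

    F(A) = Σ_{i∈V} E_i[T_A].

Small F(A) means a consensus process in which the vertices of A hold a fixed
value drives the whole network to that value quickly: the ℓ₁ gap to consensus
after n steps equals the survival probability Σ_{i∈A^c} P_i[T_A > n], whose
decay rate is governed by the hitting times. The optimization problem is

    min F(A)   subject to   A ⊆ V, |A| = k,

which is combinatorial (C(|V|, k) candidate sets) and intractable by
enumeration beyond tiny graphs. This package provides:

* **exact machinery** — F(A) and the per-vertex profile E_i[T_A] from the
  absorbing-chain linear system (I − P_A) t = 1, consensus trajectories,
  survival probabilities, and the exponential tail bound;
* **Monte Carlo machinery** — an unbiased estimator F_M of F(A) from M
  simulated walk realizations, with a Student-t confidence interval and the
  sample-size rule M = ⌈(s·t_α/δ)²⌉;
* **two hub heuristics** — a combinatorial search over the k-subsets of the
  h highest-degree vertices, screened by p-neighborhood coverage and by the
  farness lower bound C(A) ≤ F(A), then ranked by F_M; and a semi-greedy
  variant that grows A from the best-covering hub pair. A fallback compares
  the result against the plain top-k-hub set;
* **an evaluation harness** — exhaustive optima on small graphs, the sampled
  baseline E_L[F_k] and best-of-L value M_L[F_k] over random k-subsets,
  improvement ratios, and Chebyshev planning of replications for lower-tail
  threshold estimates;
* **synthetic networks** — closed-form toy families (path, cycle, star,
  complete, barbell) that double as analytic oracles, and seeded heavy-tailed
  families (preferential attachment, power-law configuration model) in the
  high max-degree/mean-degree regime where hub heuristics pay off.

## Worked example

Generate a 300-vertex preferential-attachment network, find a 3-vertex
influencer set, and compare it with random guessing:

```sh
$ firsthit gen --family preferential_attachment --n 300 --seed 7 --out pa300.edgelist
{"family": "preferential_attachment", "n": 300, "m_edges": 596, "degree_ratio": 9.060402684563758, "out": "pa300.edgelist"}

$ firsthit find pa300.edgelist --k 3 --seed 1 --exact-final
{"method": "semi_greedy", "A": ["0", "1", "28"], "k": 3, "C": 596.0, "F_M": null,
 "F_exact": 6473.3976168633535, "stages": [["hub_pool", 30], ["seed_pair", 1],
 ["greedy_grow", 1], ["exact_final", 1]]}

$ firsthit evaluate pa300.edgelist --k 3 --l 1000 --seed 1
{"k": 3, "L": 1000, "mean_F": 50439.52243009864, "std_F": 17309.99821417243,
 "se": 547.3902065023201, "min_F": 10894.032865668094, "argmin": ["1", "48", "277"]}
```

Reading the numbers: the graph is heavy-tailed (max degree 9.1× the mean).
The semi-greedy heuristic picks hubs {0, 1, 28} with farness C = 596 (a lower
bound on F) and exact objective F(Â) ≈ 6.47×10³ summed walk steps. A random
3-subset averages E_L[F₃] ≈ 5.04×10⁴ — about 7.8× worse — and even the best
of 1,000 random samples (1.09×10⁴) is ~1.7× worse than the heuristic's pick.
The exact profile for any set is available too:

```sh
$ firsthit hit pa300.edgelist --targets "0,1,2"
{"A": ["0", "1", "2"], "F": 8144.335038294128, "t_star": 34.735642245787865, "C": 629.0}
```

The same functionality is available as a library:

```python
import firsthit as fh

net = fh.load_graph("pa300.edgelist")
prof = fh.mean_hitting_times(net, fh.VertexSet.from_labels(net, [0, 1, 28]))
est = fh.estimate_F(net, (0, 1, 28), fh.WalkConfig(M=10_000, seed=0))
```

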