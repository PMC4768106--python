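# Methods

## Problem and model

A signed network `G = (V, E)` has edges `eᵢⱼ ∈ {+1, −1}` (or nonzero
real weights `wᵢⱼ` in weighted mode). Given a division of the nodes into
two alliances, encoded as spins `vᵢ ∈ {+1, −1}`, an edge is a *conflict*
when `vᵢ eᵢⱼ vⱼ < 0` — a negative edge inside an alliance or a positive
edge across. The frustration index (number of structural conflicts) is
the minimum over all divisions of the conflict count, or of the total
absolute conflict weight in weighted mode. It is zero exactly when the
network is structurally balanced (every cycle has an even number of
negative edges), and computing it in general is NP-hard — this package's
heuristic trades the guarantee of optimality for linear scaling,
validated against an exhaustive oracle on small instances.

For gene-regulatory and signaling networks the quantity has a concrete
reading: a balanced interaction graph corresponds to a monotone
dynamical system, and the frustration index measures how many
activating/inhibiting relations contradict a globally consistent
two-module sign structure.

### Fitness

Each node's payoff sums its edge satisfactions:

- undirected, unweighted: `fᵢ = Σ_{j∈Nᵢ} vᵢ eᵢⱼ vⱼ`
- weighted: `fᵢ = Σ_{j∈Nᵢ} vᵢ wᵢⱼ vⱼ`
- directed: `fᵢ = Σⱼ vᵢ (eᵢⱼ + eⱼᵢ) vⱼ`

The undirected network fitness is `H(V) = Σᵢ fᵢ` — each edge counted
once from each endpoint, so `H = 2|E|` iff the division is conflict-free
— which gives the exact identity used throughout the package and its
tests:

```
s = (2·total − H) / 4,     total = |E|  (or Σ|wᵢⱼ|).
```

Flipping node *i* negates `fᵢ` and changes `H` by `−4fᵢ`.

**Directed networks.** A one-sided payoff `Σⱼ vᵢ eᵢⱼ vⱼ` makes the
per-node and network objectives inconsistent: for mutually incompatible
pairs (i likes j, j dislikes i) a node can raise its own payoff only by
lowering another's, and the naive update dynamics absorbs into a
periodic orbit. We therefore symmetrize: the directed payoff uses the
coefficient `eᵢⱼ + eⱼᵢ` per neighbor pair, which makes `Σᵢ fᵢ` a global
objective again (`Σfᵢ = 2·H_dir` with `H_dir` the once-per-edge sum) and
assigns incompatible pairs a net coefficient of zero — on a triangle of
three mutual like/dislike pairs every assignment has `H = 0`, every node
sits at its aspiration level, and the dynamics is stationary instead of
periodic. Conflict counting is still per directed edge, so
`s = (total − H_dir)/2`, and each antiparallel pair with contradictory
signs contributes exactly one unavoidable conflict. The symmetrization
is isolated in the adjacency construction
(`SignedNetwork.adjacency_csr`) so an alternative directed payoff can be
swapped in.

## The game dynamics

One **sweep** visits every node exactly once in a fresh uniformly random
permutation (a fixed visiting order would imprint order artifacts on the
final division). Each visited node with payoff `fᵢ < 0` — below the
aspiration level of zero — deterministically switches alliance. A node
with `fᵢ ≥ 0` *explores*: with probability `R` it adopts a strategy
drawn uniformly from `{+1, −1}` (an effective flip probability of
`R/2`); ties at `fᵢ = 0` explore rather than switch. After a flip the
node's cached payoff is negated and each neighbor's payoff is adjusted
by `2 vᵢ (coefficient) vⱼ`, so a sweep costs `O(|V| + |E|)`; a debug
mode re-derives all payoffs from scratch and asserts agreement, and a
property test exercises it.

The exploration probability anneals geometrically,

```
R(t) = min(1, T₀ · a^⌊t/K⌋),
```

with initial temperature `T₀ > 0`, damping coefficient `0 < a < 1`, and
damping period `K` sweeps; sweeps continue while `R(t) ≥ R_min`, so the
scheduled sweep count is `K·⌈log_a(R_min/T₀)⌉` — a constant of the
schedule, independent of the network. `R(t)` is the same for every node:
a payoff-dependent exploration probability would make the termination
time depend on the network state, breaking the constant-work property.
The schedule is the method's simulated-annealing analogue: early, large
`R` shakes the population across fitness barriers; late, vanishing `R`
lets pure aspiration lock in a high-fitness division.

### Best-recall and settling

Aspiration-only dynamics is monotone (every flip has `fᵢ < 0`, hence
`ΔH = −4fᵢ > 0`), but exploration is not, and the sparse-benchmark
experiments expose a structural limitation of reporting the state at
termination: a small cluster tied internally by strong edges and tied to
the rest of the network by a few low-weight edges has *both* of its
configurations (aligned and misaligned with its surroundings) as
aspiration fixed points, and because exploration ignores payoffs, the
transition rates between the two are symmetric — the terminal
configuration is close to a coin flip however slowly the schedule cools.
The run therefore tracks the best end-of-sweep assignment seen (the
standard keep-the-best practice for annealed searches), recalls it after
the last scheduled sweep, and then *settles*: pure-aspiration sweeps
(`R = 0`, recorded with temperature 0) run until one makes no flip. The
returned division is thus a stable equilibrium of the game — every node
at or above aspiration — at least as fit as every state the trajectory
visited. A schedule whose very first probability is already below
`R_min` runs zero sweeps and reports the initial all-`+1` state
unmodified.

### Defaults

| parameter | default | meaning |
|-----------|---------|---------|
| `T₀`      | 0.5     | initial exploration probability; half the population explores per early sweep |
| `a`       | 0.98    | geometric damping per period |
| `K`       | 100     | sweeps per temperature step |
| `R_min`   | 10⁻³    | exploration floor; termination threshold |

These give 30,800 scheduled sweeps, the same order as the trajectories
the method needs on thousand-node regulatory networks (tens of
thousands of steps). On the 200-node benchmarks used in the acceptance
suite a run takes well under 0.1 s (the sweep loop is a numba kernel);
faster cooling (`a = 0.95`, 12,200 sweeps) still solves the unweighted
benchmarks but leaves low-weight tethered clusters unresolved on a few
percent of weighted instances, which is why the slower default was
chosen.

### Reproducibility

All randomness comes from one `numpy.random.Generator` seeded by the
caller and consumed in a fixed, documented order: per sweep, a
Fisher–Yates shuffle drawing `⌊rng.random()·(i+1)⌋` for `i = n−1…1`,
then per visited node with `fᵢ ≥ 0` one uniform draw (made even when
`R = 0`, so the stream does not depend on the schedule), plus a second
draw for the random strategy only when exploration triggers. Only
`Generator.random()` is ever consumed, which keeps the compiled numba
kernel and the pure-Python reference sweep on an identical bit stream —
a property test asserts the two engines produce byte-identical
trajectories, and identical `(network, schedule, seed)` triples replay
exactly.

## Exact components

**Balance test.** Sign-constrained 2-coloring by breadth-first search:
positive edges constrain endpoints to equal colors, negative edges to
opposite colors; a violated constraint is returned as a witness edge
closing an odd-negative cycle, otherwise the coloring is a zero-conflict
partition. Directed networks are tested on the underlying undirected
sign pattern, with an antiparallel pair of contradictory signs itself a
witness. `O(|V| + |E|)`.

**Exhaustive oracle.** The global flip `v → −v` preserves conflicts, so
node 0 is pinned and `2^(|V|−1)` assignments are enumerated in Gray-code
order, updating the conflict count in `O(degree)` per step. The default
cap of 22 nodes (~2M assignments) runs in seconds; the test suite
validates the heuristic against it on 12-node instances and validates
the oracle itself against naive full enumeration on still smaller ones.

## Benchmark generators

`generate_planted` reproduces the designated-network construction used
to evaluate the heuristic: `2N` nodes in two equal parts, `M₁` positive
edges sampled without replacement inside each part, `M₂` negative edges
between the parts — a balanced network whose planted partition is a
ground truth — then `s` edges sampled without replacement from the full
edge set get their signs reversed. Under the planted partition exactly
those `s` edges are conflicts, so `s` is a pre-established upper bound
on the frustration index; the true minimum can be slightly smaller
(reversals can partially cancel), which is why benchmark assertions are
`found ≤ planted`, with equality expected only at `s = 0`. Weighted mode
draws `|w| ~ Uniform(0,1)` per edge (zeros redrawn; a zero weight is no
edge) before the reversals, and the planted bound becomes the total
absolute weight of the reversed edges. Directed mode samples ordered
pairs, both orientations independently.

The acceptance-scale benchmark fixes `2N = 200`, `2M₁ = 300`,
`M₂ = 150` with designated conflicts spaced uniformly over 0…150 across
31 instances — sizes chosen so the full three-variant suite (unweighted,
weighted, directed) runs in seconds while keeping the mean degree (4.5)
low enough that the hard sparse structures (tethered clusters, isolated
components) actually occur.

What the generators deliberately do not emulate: realistic degree
distributions (the construction is Erdős–Rényi within/between parts),
clustering, more than two planted factions, or the preprocessing that
turns raw directed biological interaction data into the undirected
networks summarized in the real-network table. Passing the planted
benchmarks therefore demonstrates the optimizer's behavior under the
construction's assumptions, not performance on scale-free or
empirically structured networks.

## Numerical choices

- Spins and payoffs are float64 even in unweighted mode; all quantities
  there are small exact integers, so comparisons are exact.
- An edge is a conflict iff `vᵢwᵢⱼvⱼ < 0` exactly; weights are nonzero
  by construction, so the sign test is exact in floating point.
- Incremental `H` maintenance can drift by ~1e-12 per flip in weighted
  mode; the run re-derives the final fitness from scratch and asserts
  the `s = (2·total − H)/4` identity to a tolerance scaled by the total
  weight.
- `conflicts_from_fitness` refuses negative results and, for unweighted
  inputs, non-integer results (tolerance 1e-9) — these indicate an
  inconsistent `(total, H)` pair rather than a representable state.
- The sweep-count closed form is evaluated by walking the (short)
  geometric sequence rather than via `log`, so it agrees bit-for-bit
  with the run loop's `R(t) ≥ R_min` test at period boundaries.

## Limitations

- The heuristic offers no approximation guarantee; on adversarial
  instances the returned equilibrium can exceed the optimum. The oracle
  comparison (best of 20 seeds matches the exact minimum on ≥95% of
  random 12-node instances) characterizes typical, not worst-case,
  behavior.
- The directed payoff is a reconstruction choice (symmetrization); other
  resolutions of the incompatible-pair problem exist and would change
  `H_dir` but not the per-edge conflict definition.
- Edge lists are fully materialized in memory; candidate-pair arrays in
  the generators are `O(N²)`, fine at benchmark scale but not for
  million-node networks.
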