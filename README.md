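# signedgame

Structural conflicts in signed networks, determined by evolutionary game
dynamics.

Signed networks — graphs whose edges carry `+`/`−` labels or signed
weights — model friendly/hostile social ties and activating/inhibiting
interactions in gene-regulatory and signaling networks. A signed network
is *structurally balanced* when every cycle contains an even number of
negative edges; equivalently, its nodes split into two alliances with
positive edges inside each alliance and negative edges across. Real
networks are rarely balanced, and the natural question is *how far* from
balance they are: the minimum number (or total weight) of edges whose
deletion restores balance, known as the **frustration index** or number
of **structural conflicts**. Deciding balance is linear-time; computing
the frustration index is NP-hard.

`signedgame` implements a distributed heuristic for this optimization,
phrased as an evolutionary game. Each node *i* holds a strategy
(alliance) `vᵢ ∈ {+1, −1}` and receives the payoff

```
fᵢ = Σ_{j∈Nᵢ} vᵢ eᵢⱼ vⱼ            (undirected; wᵢⱼ replaces eᵢⱼ when weighted,
                                    eᵢⱼ + eⱼᵢ when directed)
```

so that satisfied edges pay `+1` (or `+|w|`) and conflict edges pay the
negative. The network fitness `H(V) = Σᵢ fᵢ` then determines the number
of conflicts exactly: for an undirected network with `|E|` edges,
`s = (2|E| − H)/4`. Nodes update by **aspiration** — a node with
negative payoff deterministically defects to the other alliance — plus
annealed **exploration**: with probability `R(t) = min(1, T₀·a^⌊t/K⌋)` a
satisfied node adopts a random strategy, where the temperature `T₀`, the
damping coefficient `a`, and the damping period `K` play the same role
as a simulated-annealing cooling schedule. The run keeps the best
division it visits, recalls it when the exploration floor `R_min` is
reached, and settles it with pure aspiration sweeps, returning a stable
equilibrium of the game. The sweep count is a constant of the schedule,
so total work scales linearly with network size.

The package handles undirected or directed, unweighted or weighted
networks, and ships with:

- an exact linear-time balance test with certificate (partition or
  witness edge),
- planted-conflict benchmark generators (balanced two-faction
  construction with a designated number of sign reversals, giving a
  pre-established upper bound on the frustration index),
- a brute-force exact oracle (Gray-code enumeration, ≲22 nodes) for
  validation,
- a `signedgame` command-line tool.

## Worked example

Generate a designated benchmark — 100 nodes in two factions, 240
positive within-faction edges, 80 negative cross edges, then 12 random
sign reversals — and solve it:

```sh
$ signedgame generate --kind planted -n 50 --m1 120 --m2 80 --s 12 --seed 42 --out demo.tsv
{"kind": "planted", "n_nodes": 100, "n_edges": 320, "planted_bound": 12.0, "seed": 42}

$ signedgame solve demo.tsv --seed 1
{"seed": 1, "t0": 0.5, "damping": 0.98, "period": 100, "rmin": 0.001, "n_nodes": 100,
 "n_edges": 320, "total_weight": 320.0, "sweeps": 30801, "scheduled_sweeps": 30800,
 "fitness": 592.0, "conflicts": 12.0}
best conflicts: 12 (fitness 592)
```

The solver reports 12 structural conflicts — exactly the planted bound —
and the fitness identity checks out: `(2·320 − 592)/4 = 12`. The
benchmark is indeed unbalanced, with a witness edge closing an
odd-negative cycle:

```sh
$ signedgame balance demo.tsv
unbalanced	witness edge: b40 -- b44 (1)
```

Small networks can be solved exactly; the unbalanced triangle
(`+1, +1, −1`) needs one deletion:

```sh
$ printf 'a b 1\nb c 1\na c -1\n' > tri.tsv
$ signedgame oracle tri.tsv
{"minimum_conflicts": 1.0, "n_nodes": 3, "n_edges": 3, "fitness": 2.0}
```

The same operations are available as library functions
(`signedgame.run`, `is_balanced`, `exact_min_conflicts`,
`generate_planted`, ...); `solve` accepts `--weighted`, `--directed`,
schedule flags, `--restarts`, and writes partition/conflict-edge/
trajectory files on request.

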