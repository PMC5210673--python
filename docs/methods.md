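# Methods

## Model

A group of `n` agents occupies a connected k-regular graph: every agent has
exactly `k` social ties, and connectivity guarantees that information can in
principle reach everyone.  Graphs are drawn by configuration-model pairing
(via networkx) with rejection of disconnected outcomes and a bounded retry
count (default 1000); this is approximately uniform over the set of connected
k-regular graphs on `n` nodes.  The sampling measure over that set is a
modelling choice, not a claim — no construction algorithm is canonical for
this model.

**Synchronization event.**  Headings are degrees on a half-open dial
`[0, 360)`; initial headings are i.i.d. uniform.  An event is `T = τn/2`
sequential meetings (τ exchanges per agent on average; `T` is rounded to the
nearest integer when `τn` is odd).  Each meeting is an independent uniform
draw over the edges — ties are sampled with replacement and every tie is
equally likely.  Within a meeting both agents update *simultaneously* from
the pre-meeting headings: agent `a` moves to the shorter-arc midpoint of its
own heading and the partner's heading perturbed by `ν_a ∈ {−ε_a, +ε_a}`
(fair coin, redrawn independently at every meeting).  Antipodal headings
(difference exactly 180°) take the plain average of the two values.  The
circle, rather than a line, prevents agents from short-cutting the consensus:
no single exchange reveals where the group will converge.

**Distances and payoffs.**  At the end of an event, `d_i` is agent i's mean
shorter-arc distance to the other `n−1` agents and `d̄` the mean of the
`d_i`; both lie in `[0, 180]`.  The raw payoffs are `H = C − D·d̄` (group,
`D > 0`) and `H_i = H/n − A·d_i − B·(180 − ε_i)` (individual).  Because only
the ε-ranking of payoffs matters to both the best response and the
evolutionary dynamics, the package works with the normalised form
`h_i = −d̄ − α·d_i − β·(180 − ε_i)`, `α = nA/D`, `β = nB/D`; the
normalisation identity and the invariance of the argmax to `C, D` are
property-tested.  With a survival threshold `λ` the group payoff becomes
all-or-nothing: `c = C` if `d̄ ≤ λ` (boundary inclusive) else `0`.

**Evolution.**  Each step scores every agent by its mean `h_i` over
`payoff_reps` independent events (fresh graph and fresh headings per event),
then replaces the worst scorer's ε with `U((1−θ)ε_top, (1+θ)ε_top)` clamped
to `[0, 180]`.  Ties in the ranking go to the lowest agent id; if one agent
is simultaneously worst and best it self-copies with mutation.  Only the ε
value is inherited — network positions are fixed.  The dynamics use ranking
only, so no positivity assumption on payoffs is needed.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| `n`, `k` | group size, ties per agent | 10, 4 | reference setting of all experiments |
| `τ` | exchanges per agent per event | 40 | enough meetings for near-convergence at low noise |
| `ε` range | reception noise | `[0, 180]`° | 180° is maximal confusion on a dial |
| `α` | cost of own misalignment | 1.0 | reference unit |
| `β` | cost of precision | 0.1 | cheap-precision regime (`β/α = 0.1`) |
| `θ` | copying error (mutation width) | 0.05 | small multiplicative error; no canonical value exists, so it is an explicit config knob |
| `ε₀` | initial common noise | 10 | evolutionary runs start from modest noise |
| `S` | evolutionary steps | 2000 | both regimes reach their terminal state well within this horizon at n=10 |
| `λ` | survival threshold on `d̄` | 30° | an explicitly arbitrary scale, same magnitude as the reference group noise; always overridable |
| `payoff_reps` | events averaged per evolutionary score | 1 (library), 10 (regime experiments) | see below |
| best-response grid | candidate ε levels | 0–180 step 5, 100 repeats | grid resolution vs Monte-Carlo cost |

**Scoring replicates (`payoff_reps`).**  With single-event scoring the payoff
ranking is dominated by event-level randomness: selection for low noise at
`β/α = 0.1` is weak (a few tenths of a degree of expected `d_i` per degree of
ε) while one event's `d_i` varies by several degrees.  Under that noise the
efficient-communication state is not held — the population drifts and
eventually escapes into the high-noise basin, which *is* stable because a
chaotic group makes individual precision worthless.  Averaging 10 events per
step restores a reliable ranking: all oracle runs then descend (final mean
ε < 3° by step ~500–1300).  The bistability and speed experiments therefore
score with `payoff_reps = 10`; the library default stays 1, the most literal
single-event reading, and the knob is explicit.

**Two basins of the best response.**  At `α = 1, β = 0.1` the focal agent's
best response is below the group's level only while the group is moderately
coordinated (others' ε ≲ 90).  Against a very noisy group, own precision
buys almost no alignment and the β saving dominates, so the optimum flips to
high ε.  Iterated best response from a very noisy start therefore stays
noisy; the slow-descent experiment (`fig3b_slow`) starts at ε = 60, inside
the efficient basin, and walks down to 0.  The descent is gradual near the
bottom — the best response to a group at ε = 10–20 is a modestly lower
value, not 0 — which is the model's expression of "no point being fluent
while everyone else is a beginner".

## Determinism

One master seed; every replicate, grid cell and pipeline stage draws from a
`SeedSequence` substream keyed by a counter, so runs are independently
replayable.  Best-response curves use common random numbers: the same
per-replicate event seeds are reused for every candidate ε, so curve
differences reflect the candidate alone (a variance-reduction choice, not
part of the model).  Experiments write a JSON manifest (resolved parameters,
master seed, substream count, SHA-256 checksums); re-running from a manifest
reproduces the CSVs byte-for-byte.

## Numerical notes

* Angles are kept in degrees throughout and wrapped with `x mod 360`; the
  rare float case where `x mod 360` rounds to exactly 360.0 is mapped to 0.
* `d̄` equals the mean of the off-diagonal pairwise distance matrix; this
  equivalence is property-tested.
* Best-response ties go to the smallest candidate ε.
* Steps-to-threshold statistics censor non-reaching runs at `S + 1`.

## Problem sizes used in the shipped checks

The automated checks run the reference setting at desk scale: 100 replicates
for event-level statistics and best-response curves, 20 evolutionary
replicates per cost regime at `S = 2000` with `payoff_reps = 10`, 50
replicates per group size in the `n_max` searches (cap `n = 40`), chosen as
the smallest sizes at which the qualitative results are stable across seeds.
The acceptance script uses 10 evolutionary replicates per regime.

## What the generator emulates — and what it does not

All inputs are synthetic by construction: the model *is* the data-generating
process (uniform initial headings, two-point reception noise, uniform edge
meetings).  Passing checks show the implementation reproduces the model's
internal logic and its qualitative regimes; they say nothing about real
social groups — real interaction networks are not regular, communication
errors are not two-point symmetric, and payoffs are not linear in angular
distances.  The two-point noise set follows the model's definition; a
continuous uniform perturbation on `[−ε, ε]` would be a natural variant but
is deliberately not the default.

## Known limitations

* Rejection sampling of connected graphs is only approximately uniform over
  the target set, and becomes slow for sparse graphs near the connectivity
  threshold (k = 2 at large n).
* `n_max` reported at the search cap is labelled censored rather than
  extrapolated.
* The evolutionary dynamics replace exactly one agent per step; population
  size and network degree never evolve.
* No parallelism: runs are single-process to keep replay exact.
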