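# Methods

This note records the model as implemented, the defaults and why they hold,
the conventions chosen where the design was genuinely open, and what the
test suite does and does not establish.

## Task and environments

Each environment is a 20×20 lattice MDP. Obstacle cells are deleted from
the state graph (no edges in or out); an action into an obstacle or off the
grid returns the current state, which also creates the self-loops in the
random-walk transition matrix at walls and corners. Coordinates are (x, y),
0-indexed, y increasing upward; the action order is Down (0,−1), Up (0,+1),
Left (−1,0), Right (+1,0) everywhere — memory value slots, policies, and
the cardinal-direction matrix all share it.

Layouts are coordinate data in `gridworld.py`:

- **open_field** — no obstacles (400 available states).
- **separated_field** — a vertical wall at x = 10 spanning y = 0..13 with a
  gap along the top (386 states, one bottleneck region).
- **four_rooms** — full cross walls at x = 10 and y = 10 minus four
  single-cell doorways at (5,10), (15,10), (10,5), (10,15): 35 obstacles,
  365 states. The doorway count and positions are constrained by the
  365-state total; their centring within each wall arm is this package's
  choice.
- **tunnel** — wall segments at y = 9 and y = 11 for x = 2..17, leaving a
  one-row corridor at y = 10 open at both ends (368 states).

Only the four-rooms obstacle count is externally pinned; the separated
field and tunnel are best-effort reconstructions of the pictured mazes.
The default reward state is (14, 14) in every layout (off-centre, never on
an obstacle, reachable); it is configurable.

**Reward-receipt convention.** At each timestep the agent receives R(s_t)
for its current state *before* acting; the episode ends when s_t = s\* or
at the 250th receipt. This is the only convention under which a fully
failed episode scores exactly 250 × (−0.01) = −2.5 and an optimal path of
geodesic length d scores 10 − 0.01 d, which the normalization anchors
require. Starts are uniform over available states excluding s\* (a start on
the reward would be a zero-length episode).

**λ and R\*.** λ is the mean geodesic (BFS) distance of available states
to s\*, excluding s\* itself to match the start distribution; including it
shifts λ by under 1% on these grids (tested). R\* = 10 − 0.01 λ.

## Memory

- **Capacity**: floor(fraction × n_available), computed with a 1e−9 guard
  against binary round-off on exact products. Fraction 1 means every state
  fits and nothing is ever overwritten.
- **Timestamps** are refreshed on *write* only (least-recently-updated
  forgetting). Stamping on retrieval instead is available as
  `forget_on='access'` because the two readings of "least recently
  accessed" differ; the default is the operationally defined write-time
  stamp.
- **Unvisited action slots** hold 0.0 so the softmax always has four
  finite inputs. Consequence: one large observed return dominates the
  policy, which is the mechanism behind low-entropy policies near the
  reward.
- **Nearest-key ties** go to the lowest storage index (`tie_break='first'`,
  deterministic). This matters enormously for onehot keys, where every
  non-exact candidate ties at distance 1; a `tie_break='random'` option
  exists and measurably changes restricted-capacity onehot behaviour.
- **Exact match** means Chebyshev distance exactly 0 — safe because
  queries and keys are drawn bitwise-identically from one precomputed
  table.
- The softmax uses max-subtraction (exact by shift invariance).

## Encodings

- **onehot**: identity rows.
- **random**: i.i.d. uniform [0,1) rows; dimension set to n_available so
  all encodings share key dimensionality (not externally constrained).
- **place cells**: one unit per available state (no units on obstacles),
  centres at grid coordinates divided by 20, σ = 0.05 = one cell. The
  Gaussian exponent is the standard isotropic −[(x−x_i)²+(y−y_i)²]/(2σ²).
  Activity depends only on Euclidean offset, so cross-wall key distances
  equal same-side distances exactly (tested as equality).
- **successor representation**: M solved from (I − γT) M = I (linear
  solve, not an explicit inverse), T the uniform random-walk transition
  matrix of the obstacle-pruned graph, γ = 0.98 throughout. Rows sum to
  1/(1−γ) = 50.

## Simulation protocol

One `numpy` Generator per run, seeded once; start states, action sampling
and random-rule victim selection draw from it in a fixed order, so runs are
bitwise reproducible. Defaults: 5000 episodes per seed, 6 seeds per
condition, capacity ladder {1.0, 0.9, 0.75, 0.6, 0.5, 0.25}. Storage is
end-of-episode; within an episode the bank is frozen, so per-state recalls
are cached (skipped under `forget_on='access'`, where each recall must
touch a timestamp). Memory snapshots are taken every episode over the final
dense window (default 400 episodes, the policy-map averaging window) and
every 50th episode before that; snapshotting never touches the RNG, so
cadence cannot perturb dynamics (tested).

## Analyses

- Normalized performance: 100 × (mean raw + 2.5)/(R\* + 2.5).
- Policy maps query the bank at *every* available state with the same
  nearest-key recall as behaviour — states absent from memory are not
  special-cased.
- Policy entropy uses the natural log (range [0, ln 4] nats); the log base
  is a convention and only scales the measure.
- Preferred directions z_s = π_s · D; the neighbourhood-coherence summary
  is the mean cosine similarity of z over graph-adjacent state pairs.
- Match statistics are computed per recall *event* (memory is queried every
  timestep), grouped by episode outcome; a group with no events reports
  NaN, never zero.
- Trajectory sampling rebuilds a frozen controller per snapshot and draws
  read-only episodes (default 5 per snapshot over a 200-snapshot window,
  i.e. 1000 samples).
- Forgetting incidence: per-run per-state forget counts normalized to
  frequencies (sum 1), averaged within condition, and differenced
  oldest − random; the difference field sums to 0 by construction.
- Welch's t-test is computed directly (Welch–Satterthwaite df, p from the
  t distribution, Bonferroni min(1, m·p)); zero variance with equal means
  returns t = 0, p = 1 by convention.

## What the synthetic world does and does not establish

All data are generated by the simulator itself; there is no external
dataset. The reduced-scale batteries in the test suite (1000 episodes × 5
or 6 seeds instead of 5000 × 6) reproduce the qualitative phenomena: no
encoding difference at unbounded capacity; a successor-over-onehot
advantage at 75% capacity; rising policy coherence and falling near-reward
entropy under moderate forgetting with structured keys; and the oldest-rule
preservation of doorway and near-reward states relative to random
forgetting. Green tests establish these *orderings and signs* at desk
scale, not exact per-condition effect magnitudes at full scale.

One quantitative expectation is knowingly not met and its test left
failing: in the *open field* at 25% capacity, the onehot agent lands ~25
normalized points above the random-walk baseline rather than within 10.
The open field is the most forgiving layout (no bottlenecks), the ~100
exactly-matched stored states still carry confident reward-directed
returns, and deterministic tie-breaking turns non-match onehot recalls into
a mild persistent drift that beats a diffusive walk. The documented
tie-break alternative widens, not narrows, the gap.

## Known limitations

- Transitions are deterministic; no stochastic dynamics, moving rewards or
  multi-reward foraging.
- Returns are Monte-Carlo only (no TD bootstrapping); the SR is the
  analytic random-walk SR, never learned online.
- Forgetting is recency- or chance-based; no salience weighting.
- Retrieval is an exact linear scan (no approximate nearest-neighbour
  index) — adequate at these scales, O(N·D) per query.
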