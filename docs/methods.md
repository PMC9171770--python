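# Methods

## Model and assumptions

The simulator implements the Conscious Turing Machine as a synchronous
discrete-time system. One global clock drives a fixed intra-tick phase
order — sensors, processor steps and submissions, tree advance, broadcast
and link deliveries, actuators — which is part of the machine definition
here, not an implementation detail: every trace is totally ordered by
(tick, phase, origin).

Chunks are immutable six-tuples. The identity quadruple (address, t,
gist, weight) is frozen at submission; intensity and mood are the only
fields rewritten as chunks merge upward, always by pairwise summation.
The invariant |mood| ≤ intensity holds at submission (|w| vs w) and is
preserved by summation via the triangle inequality; constructors assert
it with a 1e-9 relative tolerance to absorb float rounding in long sums.

Gists are opaque: a bounded token sequence plus modality tags drawn from
a small fixed vocabulary (speech, vision, tactile, command, query,
answer, empty). The simulator never interprets payloads — scenarios
attach meaning. Gist equality is byte-wise on a canonical serialization
(sorted tags + payload as compact JSON), making it total; the
`origin_note` field is deliberately outside the canonical form so that
provenance annotations (e.g. inner- vs outer-speech) do not break
equality-based comparisons like change detection.

## The competition

Each internal tree node selects its left child with probability
f(L)/(f(L)+f(R)), or 1/2 when the denominator is zero; a node consumes
exactly one uniform draw whether or not the outcome is forced, so replay
alignment is input-independent. Non-power-of-two N is padded with null
chunks (empty gist, zero weight). With an additive f a padded leaf can
never beat a positive-f chunk, so the proportional-share result over the
real leaves is unaffected; in an all-zero competition a null chunk —
possibly a padded one — reaches the root and an empty gist is broadcast,
matching the coin-flip rule rather than special-casing silence.

Floating-point ties receive no epsilon handling: the coin flip itself is
the tie-breaker.

### Exact win-probability oracle

`exact_win_probabilities` is a bottom-up dynamic program. The chunk at
any node is (some surviving leaf identity, subtree intensity sum,
subtree mood sum), and the sums are winner-independent. The DP therefore
tracks, per node, the probability distribution over surviving leaf
identities; an internal node combines its children's distributions
through the pairwise coin-flip matrix built from per-identity f-values
evaluated at the fixed subtree sums. This is exact for arbitrary
competition functions (including the non-additive |mood|), costs
O(n²) per level pair rather than an exponential enumeration of winner
sets, and at desk scale runs in microseconds. For additive f it
reproduces f/Σf to below 1e-12, which the suite asserts.

### Monte-Carlo fast path

`monte_carlo_win_frequencies` vectorises whole tournaments across runs.
It is valid only for additive f, where every node's f-value is the fixed
sum of its subtree's leaf f-values; a unit test pins it against the
generic chunk-level tournament so the two routes cannot silently
diverge. The generic route (`run_competition`) remains the machine's
actual mechanism.

## Randomness and replay

All randomness descends from one master seed through numpy
`SeedSequence` spawn keys: one stream per processor, and one stream per
competition keyed by its submission tick, consumed in a fixed node
traversal order (level by level, left to right). Two runs with the same
config and seed produce byte-identical JSON-lines traces; this seeded
mode is the default and only mode — the machine is deterministic given
its seed, which is itself a statement the model is committed to (a
pseudorandom machine loses none of the architecture's properties).

## Timing

Pipelined mode (default): the competition submitted at tick t advances
one level per tick, its root enters STM at t+h, and all processors
receive the broadcast at t+h+1 — the moment of conscious awareness. h
competitions are in flight at once; after warm-up exactly one broadcast
is emitted per tick. A collapsed mode (root within the submission tick,
reception at t+1) exists for unit tests. Broadcast reception one tick
after root arrival is the committed reading of the awareness timing; the
alternative (same-tick reception) was considered and not implemented as
a flag because nothing downstream depends on it at desk scale.

Sleeping-Experts feedback and link acknowledgments reference the
submission tick carried inside each chunk (its t field), so pipeline
latency never misattributes outcomes.

## Learning (Sleeping Experts)

The scale a processor applies to its emitted weight magnitudes is
updated multiplicatively — the canonical choice for sleeping-experts
style updates, where the model itself fixes only the directions
(embolden/hush):

- embolden: lost, and own value > broadcast value → scale ← min(hi, β·scale)
- hush: won, and own value < the best losing value → scale ← max(lo, scale/β)

Defaults: β = 2, bounds [0.01, 100]. Valuations come from a
scenario-supplied evaluator; the best-loser value is computed by the
machine from the per-tick submission record it retains until the
corresponding broadcast resolves. Embolden compares against the
broadcast and hush against the best loser — an interpretive choice where
the model's text does not pin the comparison set down; it makes both
rules triggerable from information the machine demonstrably has.

In the two-expert toy (a reliable expert starting at the minimum scale
vs an unreliable one at scale 1) the reliable expert's scale doubles per
lost tick while the unreliable one halves per won tick, so parity is
reached in ~3–4 ticks from the worst case and a strict broadcast
majority within 200 ticks is essentially certain; the suite checks ≥95
of 100 seeds.

## Links

"Usefulness" is operationalized as explicit acknowledgment messages:
k_link = 3 acks within a W_link = 50-tick sliding window form (or
strengthen) a bidirectional edge, and the window is consumed on each
formation. Strength is monotone non-decreasing — the model describes
strengthening only, so no decay or pruning is implemented. Link
deliveries take one tick, matching broadcast latency, to keep a single
global time semantics. Repeated broadcasts without acknowledgment never
form links.

## Memory, predictions, salience

Per tick each processor archives its submission, the broadcast it
received, and the single largest-|weight| link/input chunk (bounded
memory per tick); surprising ticks are flagged. Predictions default to
0/1 gist equality; any positive error is a surprise and marks the
entry salient. Pruning keeps entries with |weight| above threshold or
flagged surprising, never reordering.

## Scenarios: what the synthetic fixtures emulate

All scenarios run from a single seed with no external data, in well
under a second at their default sizes. They emulate the *structure* of
the phenomena — competition asymmetries, gist-encoding coarseness,
intensity gating — not their content: there is no video, audio or
language processing anywhere, so passing scenarios verify the model's
internal logic, not claims about human vision or sleep.

- **Blindsight** (N=8): vision processors are lesioned
  (`competition_enabled=False`, so they submit only null chunks) but
  keep a pre-formed link to the walk processor. Background "hum"
  processors submit positive weights every tick, so a null chunk — hence
  any vision-address chunk — can never win; vision-origin broadcasts are
  structurally zero while link-driven fetches succeed.
- **Inattentional blindness** (15 task processors at weight r, one
  "gorilla" at weight 1): the oracle share is 1/(15r+1) ≈ 0.66% at
  r=10. The 10⁵-competition statistic uses the vectorised tournament
  runner over the configured intensities — the same selection process
  the machine runs — alongside a short full-machine trace.
- **Change blindness** (N=6): a scene morphs behind cutaways; the
  camera's gist-encoder is the experimental knob. The coarse encoder
  yields byte-identical gists for the before/after scenes, so the
  comparison processor (which reports when consecutive scene gists
  differ) stays silent; the fine encoder includes the swapped props and
  triggers.
- **Sleep/dream** (N=8): need rises 1 per awake tick and falls 5 per
  sleep/dream tick, with thresholds 100/40/10 — a schedule chosen to
  give a ~100-tick day, a 12-tick dreamless phase and a 6-tick dream in
  a 150-tick run; the model fixes the mechanism (intensity domination),
  not the schedule. Asleep, the Sleep processor submits the empty gist
  at weight 10⁹ and fades linearly with remaining need toward the dream
  threshold; sensors are gated to zero (ears excepted) and actuators
  blocked. A loud noise (weight 10¹²) relayed by the ungated noise
  detector out-competes the Sleep chunk. In the dream phase the Dream
  Creator (weight 100) submits kernels sampled seed-deterministically
  from the most salient awake-phase submissions; the Inner Speech
  processor re-routes speech-tagged broadcasts to the outer-speech
  recipient over a pre-formed link, dreamed and outer speech arriving by
  the same path.

Self attribution uses a consecutive-success counter per (command gist,
entity): k_self = 5 consecutive command→action pairings (action exactly
one tick after the broadcast, matching actuator latency) tag the entity
self; a miss resets the run; entities observed k_self times with zero
pairings are not-self; tags are sticky — evidence monotonicity means a
later miss never demotes self.

## Sizes, tolerances, limitations

Defaults are desk scale: N = 16, h = 4, runs of 10²–10³ ticks, 10⁵-draw
Monte-Carlo checks — chosen because every property asserted is
scale-free, so nothing is learned from larger N that is not visible at
16 leaves. The model's own magnitudes (N > 10⁷ processors, lifetimes
~10¹⁰ ticks) are configuration-legal but pointless on one core.
Exactness tolerances: 1e-12 for oracle-vs-closed-form, 1e-9 for
float-sum conservation, 3 binomial standard errors for Monte-Carlo
agreement. Known limitations: gists carry no semantics; link capacity is
unbounded per tick (only chunk size is bounded); single sleep cycles
only (non-REM/REM alternation is a physiological claim, out of scope);
and nothing here bears on whether any of this *feels* like anything.
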