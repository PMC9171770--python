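# ctmsim

A discrete-time simulator of the **Conscious Turing Machine (CTM)** — a
formal, substrate-independent Global-Workspace architecture for studying
consciousness-related phenomena computationally. It is aimed at
researchers in computational cognitive science and theoretical computer
science who want the model's dynamics as runnable, assertable code rather
than prose.

## The model

The machine is a seven-tuple **⟨STM, LTM, Up Tree, Down Tree, Links,
Input, Output⟩** evolving in discrete ticks *t = 0, 1, …, T*:

- **LTM** is a collection of *N* autonomous processors. Every tick, every
  processor submits one *chunk* ⟨address, t, gist, weight, intensity,
  mood⟩: a bounded multimodal payload (the *gist*) with a signed valence
  *weight*; at submission intensity = |weight| and mood = weight.
- **The Up Tree** is a binary tournament tree of height *h* over the N
  leaves. Each internal node holds a *coin-flip neuron* that picks its
  left child's chunk with probability *f(L)/(f(L)+f(R))* (a fair coin
  when both scores are zero), where *f* is a non-negative *competition
  function* — the bundled family is *f = intensity + c·mood*, |c| ≤ 1.
  The chunk moved up keeps the winner's identity but carries the *summed*
  intensity and mood of both children.
- **STM** holds exactly one chunk — the tournament's root, the machine's
  conscious content. For *additive* f, each submission reaches STM with
  probability exactly *f(chunk)/Σ f(all chunks)*, independent of the
  leaf assignment; `exact_win_probabilities` computes this distribution
  for arbitrary f by dynamic programming.
- **The Down Tree** broadcasts the STM chunk to all N processors one tick
  later — that reception is *conscious awareness*; the broadcast sequence
  is the stream of consciousness. The broadcast chunk's mood equals the
  sum of all moods submitted h ticks earlier, so mood/N reads out the
  machine's average valence.
- **Links** form between processors that repeatedly acknowledge each
  other's answers as useful (k acks within a sliding window) and carry
  chunks directly — *unconscious* communication that never touches STM.
- Processors calibrate their submitted weights with a **Sleeping-Experts**
  rule: embolden (scale × β) a processor whose losing chunk was more
  valuable than the broadcast, hush (scale ÷ β) one whose winning chunk
  was less valuable than some loser.

Scenarios turn the model's qualitative predictions into experiments:
**blindsight** (lesioned vision still drives action over links),
**inattentional blindness** (a low-intensity "gorilla" gist wins its
exactly-proportional, near-zero share), **change blindness** (a coarse
gist-encoder maps the before/after scenes to the same gist), and
**sleep/dream** (a Sleep processor floods the competition with an empty
gist, then yields to a Dream Creator).

## Worked example

Verify the proportional-share theorem on an 8-leaf instance with
f-values (3, 1, 2, 2, 0, 4, 1, 3):

```
$ ctm verify-theorem --leaves 3,1,2,2,0,4,1,3 --runs 20000
leaf  f      exact       empirical   z
   0  3      0.187500    0.187150    -0.13
   1  1      0.062500    0.063650    +0.67
   2  2      0.125000    0.122800    -0.94
   3  2      0.125000    0.128050    +1.30
   4  0      0.000000    0.000000    +0.00
   5  4      0.250000    0.252200    +0.72
   6  1      0.062500    0.061150    -0.79
   7  3      0.187500    0.185000    -0.91
max |z| = 1.30 over 20000 runs
```

The `exact` column is the dynamic-programming oracle, which for additive
f equals f/Σf to machine precision (leaf 5: 4/16 = 0.25); the empirical
tournament frequencies agree within Monte-Carlo error (|z| ≲ 3).

Run the sleep/dream scenario:

```
$ ctm scenario sleep_dream --seed 0
sleep_broadcasts: 12
sleep_empty_broadcasts: 11
sleep_noise_broadcasts: 1
dream_broadcasts: 6
dream_creator_broadcasts: 6
inner_speech_dream_routings: 2
```

During the 12-tick sleep phase every broadcast holds the empty gist
(the machine is barely conscious) except one: an injected loud noise
that breaks through the Sleep processor's domination. All 6 dream-phase
broadcasts originate from the Dream Creator, and its speech-tagged dream
gists are re-routed to the outer-speech recipient by the Inner Speech
processor.

Other entry points: `ctm run --config cfg.yaml --ticks K --out
trace.jsonl` (replayable JSON-lines trace), `ctm mood --trace
trace.jsonl` (valence readout), and the Python API (`ctmsim.Machine`,
`ctmsim.scenario_*`, `ctmsim.exact_win_probabilities`).

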