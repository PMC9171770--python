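"""Executable scenarios: the model's qualitative predictions as experiments.

Each scenario builds a small machine around a synthetic environment and a
cast of special processors, runs it from a single seed with no external
data, and returns a result object whose fields make the prediction
assertable:

* **blindsight** — vision processors are lesioned out of the competition
  (their chunks never reach the broadcast slot) yet still feed the walk
  processor over a link, so the machine acts on what it cannot
  "consciously" see.
* **inattentional blindness** — one low-intensity "gorilla" submission
  among many high-intensity task submissions wins the broadcast at exactly
  its proportional share, which is nearly never.
* **change blindness** — a scene morphs behind cutaways, but a coarse
  gist-encoder yields identical gists for the before/after scenes, so the
  comparison processor never reports a change; a finer encoder does.
* **sleep/dream** — a Sleep processor accumulates need, floods the
  competition with an overwhelming empty-gist chunk (dreamless sleep,
  interruptible by a loud noise), then yields to a Dream Creator whose
  gists — recirculated through inner-speech routing — dominate the dream
  phase until waking.

The module also houses the Model-of-the-World self/not-self attribution
rule and inner-speech routing, which the sleep scenario exercises.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .core import (
    Chunk,
    ContractViolation,
    EMPTY_GIST,
    Gist,
    MachineConfig,
    make_submission_chunk,
)
from .machine import Environment, Machine, Trace
from .processors import Emission, Inbox, ProcessorState, register_behaviour
from .uptree import exact_win_probabilities, monte_carlo_win_frequencies

__all__ = [
    "SleepState",
    "SelfModel",
    "self_attribution",
    "inner_speech_route",
    "scenario_blindsight",
    "scenario_inattentional",
    "scenario_change_blindness",
    "scenario_sleep_dream",
    "SCENARIOS",
    "run_scenario",
]


# ---------------------------------------------------------------------------
# Model-of-the-World self attribution
# ---------------------------------------------------------------------------


@dataclass
class SelfModel:
    """Self/not-self tagging from thought→action co-occurrence.

    A broadcast command gist immediately (one tick later) followed by an
    actuator action, consistently for ``k_self`` consecutive occurrences,
    tags that actuator as part of *self*.  A command occurring without the
    action resets the run.  Entities whose actions never co-occur with any
    command are *not self*; everything in between stays *unknown*.  Tags
    are monotone in evidence: once self, always self.
    """

    k_self: int = 5
    consecutive: dict[tuple[str, str], int] = field(
        default_factory=lambda: defaultdict(int)
    )
    pairings: dict[str, int] = field(default_factory=lambda: defaultdict(int))
    observations: dict[str, int] = field(default_factory=lambda: defaultdict(int))
    self_entities: set[str] = field(default_factory=set)

    def tag(self, entity: str) -> str:
        if entity in self.self_entities:
            return "self"
        if self.observations[entity] >= self.k_self and self.pairings[entity] == 0:
            return "not_self"
        return "unknown"


def self_attribution(
    model: SelfModel,
    command_gist: Gist,
    entity: str,
    action_followed: bool,
    tick: int,
) -> SelfModel:
    """Record one broadcast-command occurrence for ``entity``.

    ``action_followed`` states whether the entity's actuator carried out
    the commanded action on the next tick.
    """
    key = (command_gist.payload, entity)
    model.observations[entity] += 1
    if action_followed:
        model.consecutive[key] += 1
        model.pairings[entity] += 1
        if model.consecutive[key] >= model.k_self:
            model.self_entities.add(entity)
    else:
        model.consecutive[key] = 0
    return model


# ---------------------------------------------------------------------------
# Inner generalized speech
# ---------------------------------------------------------------------------


def inner_speech_route(
    broadcast_chunk: Chunk,
    outer_speech_targets: tuple[int, ...],
) -> list[tuple[int, Gist]]:
    """Re-deliver the speech content of a broadcast to the processors that
    receive *outer* speech, marked as inner-origin.

    No-op when the broadcast gist carries no speech modality.  The same
    routing runs while dreaming, which is why dreamed speech "sounds like"
    outer speech.
    """
    if "speech" not in broadcast_chunk.gist.modality_tags:
        return []
    inner = Gist(
        modality_tags=frozenset({"speech"}),
        payload=broadcast_chunk.gist.payload,
        origin_note="inner-speech",
    )
    return [(target, inner) for target in outer_speech_targets]


# ---------------------------------------------------------------------------
# Shared simple behaviours
# ---------------------------------------------------------------------------


@register_behaviour("hum")
class HumBehaviour:
    """Background activity: submits a constant low-weight gist every tick."""

    def __init__(self, weight: float = 1.0, payload: str = "hum") -> None:
        self.weight = weight
        self.payload = payload

    def emit(self, proc, inbox, tick, rng):
        return Emission(
            gist=Gist(frozenset({"tactile"}), self.payload), weight=self.weight
        )


@register_behaviour("silent")
class SilentBehaviour:
    """Submits the null chunk every tick."""

    def emit(self, proc, inbox, tick, rng):
        return None


# ---------------------------------------------------------------------------
# Blindsight
# ---------------------------------------------------------------------------

_BS_VISION = (1, 2)
_BS_WALK = 3


class _BlindsightEnv(Environment):
    """An object sits at one of four positions, moving every 20 ticks; the
    leg actuator's fetch succeeds when aimed at the current position."""

    sensor_targets = {"eyes": _BS_VISION}
    actuator_sources = {"legs": (_BS_WALK,)}

    def __init__(self, rng: np.random.Generator) -> None:
        self.positions = [int(rng.integers(0, 4)) for _ in range(50)]
        self.fetch_successes = 0
        self.fetch_attempts = 0

    def object_position(self, tick: int) -> int:
        return self.positions[(tick // 20) % len(self.positions)]

    def sense(self, tick):
        pos = self.object_position(tick)
        gist = Gist(frozenset({"vision"}), f"obj@{pos}")
        return [("eyes", target, gist, 5.0) for target in _BS_VISION]

    def act(self, actuator, address, command, tick):
        kind, pos = command
        assert kind == "fetch"
        self.fetch_attempts += 1
        success = pos == self.object_position(tick)
        self.fetch_successes += int(success)
        return {"success": success}


class _VisionBehaviour:
    """Relays what the eyes deliver: submits it to the competition (when
    not lesioned, that submission can win) and forwards it over the link
    to the walk processor."""

    def emit(self, proc, inbox, tick, rng):
        if not inbox.inputs:
            return None
        seen = inbox.inputs[-1]
        return Emission(
            gist=seen.gist,
            weight=seen.weight,
            link_messages=[(_BS_WALK, seen.gist, 2.0)],
        )


class _WalkBehaviour:
    """Fetches toward the last position received over the vision link."""

    def emit(self, proc, inbox, tick, rng):
        if not inbox.links:
            return None
        pos = int(inbox.links[-1].gist.payload.split("@")[1])
        return Emission(
            gist=Gist(frozenset({"command"}), f"fetch@{pos}"),
            weight=0.5,
            env_commands=[("fetch", pos)],
        )


@dataclass
class BlindsightResult:
    trace: Trace
    vision_broadcasts: int
    fetch_successes: int
    fetch_attempts: int
    lesioned: bool

    def summary(self) -> dict:
        return {
            "vision_broadcasts": self.vision_broadcasts,
            "fetch_successes": self.fetch_successes,
            "fetch_attempts": self.fetch_attempts,
            "lesioned": self.lesioned,
        }


def scenario_blindsight(
    seed: int, *, lesioned: bool = True, ticks: int = 200
) -> BlindsightResult:
    """Vision severed from the competition but not from its links.

    With the lesion active, no vision-origin chunk is ever broadcast, yet
    fetch actions driven by link-borne visual chunks still succeed.  The
    control run (``lesioned=False``) shows vision chunks winning
    broadcasts as usual.
    """
    config = MachineConfig(N=8, master_seed=seed, T=max(ticks, 8))
    rng = np.random.default_rng(seed)
    env = _BlindsightEnv(rng)
    behaviours = [HumBehaviour(1.0) for _ in range(8)]
    for v in _BS_VISION:
        behaviours[v] = _VisionBehaviour()
    behaviours[_BS_WALK] = _WalkBehaviour()
    machine = Machine(config, behaviours, environment=env)
    # the useful exchanges have already happened: pre-form the links the
    # walk processor built up by acknowledging the vision feed
    for v in _BS_VISION:
        for k in range(config.k_link):
            machine.link_graph.record_acknowledgment(_BS_WALK, v, k)
    if lesioned:
        for v in _BS_VISION:
            machine.processors[v].competition_enabled = False
    trace = machine.run(ticks)
    vision_broadcasts = sum(
        1
        for e in trace.broadcasts()
        if e.payload["chunk"]["address"] in _BS_VISION
    )
    return BlindsightResult(
        trace=trace,
        vision_broadcasts=vision_broadcasts,
        fetch_successes=env.fetch_successes,
        fetch_attempts=env.fetch_attempts,
        lesioned=lesioned,
    )


# ---------------------------------------------------------------------------
# Inattentional blindness
# ---------------------------------------------------------------------------


@dataclass
class InattentionalResult:
    oracle_share: float
    mc_share: float
    mc_runs: int
    binomial_se: float
    trace: Trace

    def summary(self) -> dict:
        return {
            "oracle_share": self.oracle_share,
            "mc_share": self.mc_share,
            "mc_runs": self.mc_runs,
            "binomial_se": self.binomial_se,
        }


class _ClassBehaviour:
    def __init__(self, payload: str, weight: float) -> None:
        self.payload = payload
        self.weight = weight

    def emit(self, proc, inbox, tick, rng):
        return Emission(
            gist=Gist(frozenset({"vision"}), self.payload), weight=self.weight
        )


def scenario_inattentional(
    seed: int,
    intensity_ratio: float = 10.0,
    *,
    n_task: int = 15,
    mc_runs: int = 100_000,
    trace_ticks: int = 100,
) -> InattentionalResult:
    """One unattended "gorilla" gist among ``n_task`` attended task gists.

    Task processors submit at ``intensity_ratio`` times the gorilla's
    weight, so by the proportional-share theorem the gorilla's broadcast
    share is ``1 / (n_task * ratio + 1)`` — about 0.66% at the default
    15-vs-1, ratio 10 setup.  The empirical share over ``mc_runs``
    simulated competitions is returned next to the analytic oracle share,
    plus a short full-machine trace of the same cast.
    """
    n = n_task + 1
    weights = [intensity_ratio] * n_task + [1.0]
    config = MachineConfig(N=n, master_seed=seed, T=max(trace_ticks, 8))
    chunks = [
        make_submission_chunk(i, 0, Gist(frozenset({"vision"}),
                                         "white-shirt" if i < n_task else "gorilla"),
                              w)
        for i, w in enumerate(weights)
    ]
    table = exact_win_probabilities(chunks, config.competition_function)
    oracle_share = table[n - 1]
    rng = np.random.default_rng(seed)
    f_values = [config.competition_function(ch) for ch in chunks]
    freqs = monte_carlo_win_frequencies(f_values, mc_runs, rng)
    mc_share = float(freqs[n - 1])
    se = float(np.sqrt(oracle_share * (1 - oracle_share) / mc_runs))

    behaviours = [
        _ClassBehaviour("white-shirt" if i < n_task else "gorilla", w)
        for i, w in enumerate(weights)
    ]
    trace = Machine(config, behaviours).run(trace_ticks)
    return InattentionalResult(
        oracle_share=oracle_share,
        mc_share=mc_share,
        mc_runs=mc_runs,
        binomial_se=se,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Change blindness
# ---------------------------------------------------------------------------

_CB_ENCODER = 1
_CB_COMPARER = 2

_SCENE_A = {"room": "mansion", "coat": "dark", "prop": "bear"}
_SCENE_A2 = {"room": "mansion", "coat": "white", "prop": "armor"}


def _coarse_encoder(scene: dict) -> str:
    # the same gist describes the before and after scenes equally well
    return f"scene:{scene['room']} with detective, maid, butler, body"


def _fine_encoder(scene: dict) -> str:
    return f"scene:{scene['room']} coat={scene['coat']} prop={scene['prop']}"


class _ChangeBlindnessEnv(Environment):
    """Scene A, cutaways to the suspects, then the morphed scene A'."""

    sensor_targets = {"camera": (_CB_ENCODER, _CB_COMPARER)}
    actuator_sources = {"voice": (_CB_COMPARER,)}

    def __init__(self, encoder, second_scene: dict) -> None:
        self.encoder = encoder
        self.second_scene = second_scene
        self.change_reports = 0

    def frame(self, tick: int):
        if tick < 10:
            return ("scene", _SCENE_A)
        if tick < 15:
            return ("cutaway", {"closeup": "maid"})
        return ("scene", self.second_scene)

    def sense(self, tick):
        kind, content = self.frame(tick)
        if kind == "scene":
            payload = self.encoder(content)
        else:
            payload = f"cutaway:{content['closeup']}"
        gist = Gist(frozenset({"vision"}), payload)
        return [("camera", t, gist, 3.0) for t in self.sensor_targets["camera"]]

    def act(self, actuator, address, command, tick):
        if command[0] == "report_change":
            self.change_reports += 1
        return {}


class _ComparerBehaviour:
    """Reports a change when consecutive scene gists differ (cutaways are
    not scenes and are skipped)."""

    def __init__(self) -> None:
        self.last_scene: Gist | None = None

    def emit(self, proc, inbox, tick, rng):
        for ch in inbox.inputs:
            if ch.gist.payload.startswith("scene:"):
                if self.last_scene is not None and ch.gist != self.last_scene:
                    self.last_scene = ch.gist
                    return Emission(
                        gist=Gist(frozenset({"speech"}), "something changed!"),
                        weight=4.0,
                        env_commands=[("report_change", tick)],
                    )
                self.last_scene = ch.gist
        return None


class _EncoderBehaviour:
    def emit(self, proc, inbox, tick, rng):
        if not inbox.inputs:
            return None
        seen = inbox.inputs[-1]
        return Emission(gist=seen.gist, weight=2.0)


@dataclass
class ChangeBlindnessResult:
    trace: Trace
    change_reports: int
    encoder: str

    def summary(self) -> dict:
        return {"change_reports": self.change_reports, "encoder": self.encoder}


def scenario_change_blindness(
    seed: int, *, encoder: str = "coarse", identical_scenes: bool = False,
    ticks: int = 30
) -> ChangeBlindnessResult:
    """Scene morph behind cutaways, watched through a gist-encoder.

    Under the coarse encoder the before/after gists are equal, so no
    change is ever reported; the fine encoder includes the swapped props
    and triggers at least one report.  Identical scenes produce no report
    under any encoder.
    """
    if encoder not in ("coarse", "fine"):
        raise ContractViolation(f"unknown encoder {encoder!r}")
    enc = _coarse_encoder if encoder == "coarse" else _fine_encoder
    second = _SCENE_A if identical_scenes else _SCENE_A2
    config = MachineConfig(N=6, h=3, master_seed=seed, T=max(ticks, 8))
    env = _ChangeBlindnessEnv(enc, second)
    behaviours = [HumBehaviour(0.2) for _ in range(6)]
    behaviours[_CB_ENCODER] = _EncoderBehaviour()
    behaviours[_CB_COMPARER] = _ComparerBehaviour()
    trace = Machine(config, behaviours, environment=env).run(ticks)
    return ChangeBlindnessResult(
        trace=trace, change_reports=env.change_reports, encoder=encoder
    )


# ---------------------------------------------------------------------------
# Sleep and dream creation
# ---------------------------------------------------------------------------


@dataclass
class SleepState:
    """Sleep-need state machine: awake → sleep → dream → awake.

    Need rises by 1 per awake tick and falls by 5 per sleep/dream tick;
    the phase advances as need crosses θ_sleep upward and then θ_dream and
    θ_wake downward.
    """

    phase: str = "awake"
    need: float = 0.0
    theta_sleep: float = 100.0
    theta_dream: float = 40.0
    theta_wake: float = 10.0

    def __post_init__(self) -> None:
        if not self.theta_sleep > self.theta_dream > self.theta_wake:
            raise ContractViolation(
                "thresholds must satisfy θ_sleep > θ_dream > θ_wake"
            )

    def advance(self) -> str | None:
        """One tick of need dynamics; returns the new phase on transition."""
        if self.phase == "awake":
            self.need += 1.0
            if self.need >= self.theta_sleep:
                self.phase = "sleep"
                return "sleep"
        else:
            self.need -= 5.0
            if self.phase == "sleep" and self.need <= self.theta_dream:
                self.phase = "dream"
                return "dream"
            if self.phase == "dream" and self.need <= self.theta_wake:
                self.phase = "awake"
                return "awake"
        return None


_SD_SLEEP = 0
_SD_DREAMER = 1
_SD_INNER_SPEECH = 2
_SD_OUTER_SPEECH = 3
_SD_NOISE = 4

#: Weight of the Sleep processor's empty-gist chunk while asleep — large
#: enough to crowd out every ordinary submission, small enough that an
#: especially loud noise still wins.
_SLEEP_WEIGHT = 1e9
_NOISE_WEIGHT = 1e12
_DREAM_WEIGHT = 100.0


class _SleepBehaviour:
    """Floods the competition with an empty gist while asleep; fades
    proportionally to the remaining need as the dream phase nears."""

    def __init__(self, state: SleepState) -> None:
        self.state = state

    def emit(self, proc, inbox, tick, rng):
        if self.state.phase == "awake":
            return None
        frac = (self.state.need - self.state.theta_dream) / (
            self.state.theta_sleep - self.state.theta_dream
        )
        weight = _SLEEP_WEIGHT * max(0.0, frac)
        if weight <= 0:
            return None
        return Emission(gist=EMPTY_GIST, weight=weight)


class _DreamCreatorBehaviour:
    """Active only while dreaming: submits kernels sampled from the most
    salient archived gists of the awake phase."""

    def __init__(self, state: SleepState) -> None:
        self.state = state
        self.kernels: list[Gist] = []

    def emit(self, proc, inbox, tick, rng):
        if self.state.phase != "dream" or not self.kernels:
            return None
        kernel = self.kernels[int(rng.integers(0, len(self.kernels)))]
        dream_gist = Gist(
            modality_tags=frozenset({"speech", "vision"}),
            payload=f"dream:{kernel.payload}",
            origin_note="dream-creator",
        )
        return Emission(gist=dream_gist, weight=_DREAM_WEIGHT)


class _InnerSpeechBehaviour:
    """Re-routes the speech content of each broadcast to the outer-speech
    recipients (over pre-formed links)."""

    def emit(self, proc, inbox, tick, rng):
        if inbox.broadcast is None:
            return None
        routed = inner_speech_route(inbox.broadcast, (_SD_OUTER_SPEECH,))
        return Emission(
            link_messages=[(t, g, 1.0) for t, g in routed]
        )


class _NoiseDetectorBehaviour:
    """Relays especially loud noises at their full (enormous) weight."""

    def emit(self, proc, inbox, tick, rng):
        if not inbox.inputs:
            return None
        loudest = max(inbox.inputs, key=lambda ch: ch.weight)
        return Emission(gist=loudest.gist, weight=loudest.weight)


class _SleepDreamEnv(Environment):
    sensor_targets = {"eyes": (5,), "ears": (_SD_NOISE,)}
    actuator_sources = {}

    def __init__(self, noise_tick: int | None) -> None:
        self.noise_tick = noise_tick

    def sense(self, tick):
        readings = [
            ("eyes", 5, Gist(frozenset({"vision"}), f"daylight@{tick}"), 1.0)
        ]
        if tick == self.noise_tick:
            readings.append(
                ("ears", _SD_NOISE, Gist(frozenset({"speech"}), "BANG"),
                 _NOISE_WEIGHT)
            )
        return readings


@dataclass
class SleepDreamResult:
    trace: Trace
    phase_by_tick: dict[int, str]
    sleep_broadcasts: int
    sleep_empty_broadcasts: int
    sleep_noise_broadcasts: int
    dream_broadcasts: int
    dream_creator_broadcasts: int
    inner_speech_dream_routings: int

    def summary(self) -> dict:
        return {
            "sleep_broadcasts": self.sleep_broadcasts,
            "sleep_empty_broadcasts": self.sleep_empty_broadcasts,
            "sleep_noise_broadcasts": self.sleep_noise_broadcasts,
            "dream_broadcasts": self.dream_broadcasts,
            "dream_creator_broadcasts": self.dream_creator_broadcasts,
            "inner_speech_dream_routings": self.inner_speech_dream_routings,
        }


def scenario_sleep_dream(
    seed: int,
    *,
    ticks: int = 150,
    noise: bool = True,
    theta_sleep: float = 100.0,
    theta_dream: float = 40.0,
    theta_wake: float = 10.0,
) -> SleepDreamResult:
    """One full awake → sleep → dream → awake cycle.

    During dreamless sleep every broadcast originating in that phase holds
    the empty gist, except the loud-noise override when ``noise`` is on.
    During the dream phase the Dream Creator's recirculated kernels
    dominate the broadcasts while sensors are gated to zero and actuators
    are blocked.
    """
    state = SleepState(theta_sleep=theta_sleep, theta_dream=theta_dream,
                       theta_wake=theta_wake)
    config = MachineConfig(N=8, master_seed=seed, T=max(ticks, 8))
    # noise arrives a few ticks into the sleep phase
    noise_tick = int(theta_sleep) + 2 if noise else None
    env = _SleepDreamEnv(noise_tick)
    dreamer = _DreamCreatorBehaviour(state)
    behaviours = [
        _SleepBehaviour(state),
        dreamer,
        _InnerSpeechBehaviour(),
        HumBehaviour(0.5, "listening"),
        _NoiseDetectorBehaviour(),
        HumBehaviour(0.5, "looking"),
        HumBehaviour(0.5, "working"),
        HumBehaviour(0.5, "worrying"),
    ]
    phase_by_tick: dict[int, str] = {}

    def on_tick(machine: Machine, tick: int) -> None:
        transition = state.advance()
        phase_by_tick[tick] = state.phase
        if transition == "sleep":
            machine.input_gain = 0.0
            machine.ungated_sensors = {"ears"}
            machine.actuators_enabled = False
            # dream kernels: the most salient awake submissions so far
            dreamer.kernels = _salient_kernels(machine.processors)
            machine.log_state_change(tick, _SD_SLEEP, {"phase": "sleep"})
        elif transition == "dream":
            machine.log_state_change(tick, _SD_SLEEP, {"phase": "dream"})
        elif transition == "awake":
            machine.input_gain = 1.0
            machine.ungated_sensors = set()
            machine.actuators_enabled = True
            machine.log_state_change(tick, _SD_SLEEP, {"phase": "awake"})

    machine = Machine(config, behaviours, environment=env,
                      tick_callback=on_tick)
    # the inner-speech processor talks to the outer-speech recipient over a
    # link formed during the awake phase
    for k in range(config.k_link):
        machine.link_graph.record_acknowledgment(
            _SD_OUTER_SPEECH, _SD_INNER_SPEECH, k
        )
    trace = machine.run(ticks)

    sleep_b = empty_b = noise_b = dream_b = creator_b = 0
    for e in trace.broadcasts():
        chunk = e.payload["chunk"]
        phase = phase_by_tick.get(chunk["t"], "awake")
        if phase == "sleep":
            sleep_b += 1
            if chunk["gist_tags"] == ["empty"] and chunk["gist_payload"] == "":
                empty_b += 1
            elif chunk["address"] == _SD_NOISE:
                noise_b += 1
        elif phase == "dream":
            dream_b += 1
            if chunk["address"] == _SD_DREAMER:
                creator_b += 1
    routings = sum(
        1
        for e in trace.of_kind("link_msg")
        if e.origin == _SD_INNER_SPEECH
        and phase_by_tick.get(e.tick, "awake") == "dream"
    )
    return SleepDreamResult(
        trace=trace,
        phase_by_tick=phase_by_tick,
        sleep_broadcasts=sleep_b,
        sleep_empty_broadcasts=empty_b,
        sleep_noise_broadcasts=noise_b,
        dream_broadcasts=dream_b,
        dream_creator_broadcasts=creator_b,
        inner_speech_dream_routings=routings,
    )


def _salient_kernels(processors: list[ProcessorState],
                     top_k: int = 8) -> list[Gist]:
    entries = []
    for proc in processors:
        for e in proc.memory:
            if e.submitted["gist_payload"]:
                entries.append(e)
    entries.sort(key=lambda e: (-abs(e.submitted["weight"]), e.tick,
                                e.submitted["address"]))
    kernels = []
    seen = set()
    for e in entries:
        payload = e.submitted["gist_payload"]
        if payload not in seen:
            seen.add(payload)
            kernels.append(Gist(frozenset(e.submitted["gist_tags"]), payload))
        if len(kernels) >= top_k:
            break
    return kernels


# ---------------------------------------------------------------------------
# Scenario registry (CLI entry point)
# ---------------------------------------------------------------------------

SCENARIOS = {
    "blindsight": scenario_blindsight,
    "inattentional": scenario_inattentional,
    "change_blindness": scenario_change_blindness,
    "sleep_dream": scenario_sleep_dream,
}


def run_scenario(name: str, seed: int, **kwargs):
    if name not in SCENARIOS:
        raise ContractViolation(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    return SCENARIOS[name](seed, **kwargs)
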