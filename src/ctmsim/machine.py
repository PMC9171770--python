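"""The assembled machine and its clock loop.

The machine is the seven-tuple <STM, LTM, Up Tree, Down Tree, Links,
Input, Output>: a single-chunk short-term memory fed by the tournament
tree over N long-term-memory processors, a depth-1 broadcast back to all
of them, a link graph for unconscious traffic, and input/output maps
touching a synthetic environment.

Timing (pipelined mode, the default): at every tick sensors deliver input
chunks, every processor submits, and each in-flight competition advances
one tree level, so the competition submitted at tick ``t`` produces its
root chunk at ``t + h``; that chunk is broadcast at ``t + h`` and received
by all processors at ``t + h + 1`` — the moment of conscious awareness.
``h`` competitions are in flight at once and, once the pipeline is warm,
exactly one broadcast is emitted per tick.  A collapsed mode (competition
resolved within the tick, reception at ``t + 1``) exists for unit tests.

Every event is logged to a replayable JSON-lines trace — the machine's
stream of consciousness plus its unconscious traffic.  Identical config
and master seed reproduce the trace byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import (
    Chunk,
    ContractViolation,
    Gist,
    MachineConfig,
    make_submission_chunk,
)
from .links import Broadcast, LinkGraph, broadcast as make_broadcast
from .processors import (
    Behaviour,
    Emission,
    Inbox,
    ProcessorState,
    SEAOutcome,
    sea_update,
    step,
)
from .uptree import assign_leaves, run_competition

__all__ = [
    "EVENT_KINDS",
    "TraceEvent",
    "Trace",
    "MoodReadout",
    "mood_readout",
    "Environment",
    "Wiring",
    "WiringError",
    "attach_io",
    "Machine",
    "run",
]

#: Fixed intra-tick phase order; the index is the sort key within a tick.
EVENT_KINDS = (
    "state_change",
    "env_input",
    "submission",
    "local_win",
    "broadcast",
    "link_msg",
    "ack",
    "env_action",
)


@dataclass(frozen=True)
class TraceEvent:
    tick: int
    kind: str
    origin: int | str
    payload: dict

    def sort_key(self) -> tuple:
        return (self.tick, EVENT_KINDS.index(self.kind), str(self.origin))

    def to_record(self) -> dict:
        return {
            "tick": self.tick,
            "kind": self.kind,
            "origin": self.origin,
            "payload": self.payload,
        }


@dataclass
class Trace:
    """The replayable event stream plus the config that produced it."""

    config: dict
    events: list[TraceEvent] = field(default_factory=list)

    def append(self, event: TraceEvent) -> None:
        self.events.append(event)

    def of_kind(self, kind: str) -> list[TraceEvent]:
        return [e for e in self.events if e.kind == kind]

    def broadcasts(self) -> list[TraceEvent]:
        return self.of_kind("broadcast")

    def submissions_at(self, tick: int) -> list[Chunk]:
        return [
            Chunk.from_record(e.payload["chunk"])
            for e in self.events
            if e.kind == "submission" and e.tick == tick
        ]

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"config": self.config},
                                separators=(",", ":"), sort_keys=True) + "\n")
            for ev in self.events:
                fh.write(json.dumps(ev.to_record(), separators=(",", ":")) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "Trace":
        with open(path) as fh:
            header = json.loads(fh.readline())
            trace = cls(config=header["config"])
            for line in fh:
                rec = json.loads(line)
                trace.append(TraceEvent(rec["tick"], rec["kind"],
                                        rec["origin"], rec["payload"]))
        return trace


@dataclass(frozen=True)
class MoodReadout:
    """The machine's valence summary at one broadcast tick.

    ``mood`` is the broadcast chunk's mood — by construction the sum of
    the moods submitted ``h`` ticks earlier — so ``mood / N`` is the
    average submitted mood: positive reads as optimism/happiness, negative
    as pessimism/sadness.  ``intensity`` summarizes energy/enthusiasm.
    """

    tick: int
    mood: float
    intensity: float
    average_mood: float


def mood_readout(trace: Trace, tick: int) -> MoodReadout:
    """Extract the mood readout at ``tick``, cross-checking it against the
    submissions it aggregates.

    Raises during warm-up (no broadcast yet at ``tick``).
    """
    matches = [e for e in trace.broadcasts() if e.tick == tick]
    if not matches:
        raise ContractViolation(
            f"no broadcast at tick {tick} (pipeline warm-up or out of range)"
        )
    chunk = Chunk.from_record(matches[0].payload["chunk"])
    h = trace.config["h"] if trace.config.get("pipelined", True) else 0
    submitted = trace.submissions_at(tick - h)
    if submitted:
        total_mood = sum(ch.mood for ch in submitted)
        if abs(total_mood - chunk.mood) > 1e-9 * max(1.0, abs(total_mood)):
            raise ContractViolation(
                f"broadcast mood {chunk.mood} disagrees with the sum of "
                f"submitted moods {total_mood} at tick {tick - h}"
            )
    return MoodReadout(
        tick=tick,
        mood=chunk.mood,
        intensity=chunk.intensity,
        average_mood=chunk.mood / trace.config["N"],
    )


class WiringError(ContractViolation):
    """An input/output map violates the connection architecture."""


#: Sentinel a sensor/actuator declaration might (illegally) name as its endpoint.
STM = "STM"


@dataclass(frozen=True)
class Wiring:
    """Audit record of the machine's five connection kinds.

    The only paths are Env→LTM (sensors), LTM→STM (Up Tree), STM→LTM
    (Down Tree), LTM↔LTM (links), and LTM→Env (actuators).  Inputs and
    outputs go directly to and from processors, never through STM.
    """

    n_processors: int
    sensor_targets: dict[str, tuple[int, ...]]
    actuator_sources: dict[str, tuple[int, ...]]

    def connection_kinds(self) -> set[str]:
        kinds = {"LTM->STM", "STM->LTM", "LTM<->LTM"}
        if self.sensor_targets:
            kinds.add("Env->LTM")
        if self.actuator_sources:
            kinds.add("LTM->Env")
        return kinds

    def actuator_for(self, address: int) -> str | None:
        for name, sources in self.actuator_sources.items():
            if address in sources:
                return name
        return None


def attach_io(
    config: MachineConfig,
    sensor_specs: dict[str, Sequence[int | str]] | None = None,
    actuator_specs: dict[str, Sequence[int | str]] | None = None,
) -> Wiring:
    """Validate and freeze the input/output wiring.

    Each sensor names the processor addresses that receive its chunks;
    each actuator names the processors allowed to command it.  Wiring a
    sensor or actuator to STM is rejected: the competition is the only
    road into STM.  A machine with no sensors or actuators is valid (a
    closed box, still capable of dreaming).
    """
    sensor_specs = sensor_specs or {}
    actuator_specs = actuator_specs or {}
    for kind, specs in (("sensor", sensor_specs), ("actuator", actuator_specs)):
        for name, targets in specs.items():
            for t in targets:
                if t == STM:
                    raise WiringError(
                        f"{kind} {name!r} may not touch STM; inputs and "
                        "outputs connect directly to LTM processors"
                    )
                if not isinstance(t, int) or not 0 <= t < config.N:
                    raise WiringError(
                        f"{kind} {name!r} names invalid processor {t!r} "
                        f"(valid: 0..{config.N - 1})"
                    )
    return Wiring(
        n_processors=config.N,
        sensor_targets={k: tuple(v) for k, v in sensor_specs.items()},  # type: ignore[arg-type]
        actuator_sources={k: tuple(v) for k, v in actuator_specs.items()},  # type: ignore[arg-type]
    )


class Environment:
    """Synthetic environment base: a per-tick state vector plus I/O maps.

    Subclasses override :meth:`sense` (produce ``(sensor_name, target
    address, gist, weight)`` tuples), :meth:`act` (apply a processor's
    command, returning an optional result payload for the trace), and
    :meth:`advance` (evolve the state by one tick).
    """

    sensor_targets: dict[str, tuple[int, ...]] = {}
    actuator_sources: dict[str, tuple[int, ...]] = {}

    def sense(self, tick: int) -> list[tuple[str, int, Gist, float]]:
        return []

    def act(self, actuator: str, address: int, command: object, tick: int) -> dict:
        return {}

    def advance(self, tick: int) -> None:
        pass


def _stream(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=master_seed, spawn_key=key))
    )


class Machine:
    """The assembled seven-tuple plus its synthetic environment."""

    def __init__(
        self,
        config: MachineConfig,
        behaviours: Sequence[Behaviour | None],
        environment: Environment | None = None,
        value_fn: Callable[[Chunk], float] | None = None,
        tick_callback: Callable[["Machine", int], None] | None = None,
        log_local_wins: bool = False,
    ) -> None:
        if len(behaviours) != config.N:
            raise ContractViolation(
                f"scenario provides {len(behaviours)} behaviours but the "
                f"config declares N = {config.N} processors"
            )
        self.config = config
        self.f = config.competition_function
        self.tree = assign_leaves(config.N, h=config.h)
        self.processors = [
            ProcessorState(
                address=i,
                behaviour=b,
                scale_bounds=config.scale_bounds,
            )
            for i, b in enumerate(behaviours)
        ]
        self.link_graph = LinkGraph(k_link=config.k_link, W_link=config.W_link)
        self.environment = environment
        self.wiring = attach_io(
            config,
            environment.sensor_targets if environment else None,
            environment.actuator_sources if environment else None,
        )
        self.value_fn = value_fn
        self.tick_callback = tick_callback
        self.log_local_wins = log_local_wins

        # scenario-controllable gates (used by the sleep state machine)
        self.input_gain: float = 1.0
        self.ungated_sensors: set[str] = set()
        self.actuators_enabled: bool = True

        self.stm: Chunk | None = None
        self.trace = Trace(config=config.to_dict())
        self._proc_rngs = [
            _stream(config.master_seed, 1, i) for i in range(config.N)
        ]
        self._inbox: list[Inbox] = [Inbox() for _ in range(config.N)]
        self._next_inbox: list[Inbox] = [Inbox() for _ in range(config.N)]
        self._pending_submissions: dict[int, list[Chunk]] = {}
        self._tick = 0

    # -- helpers ---------------------------------------------------------

    def _log(self, tick: int, kind: str, origin, payload: dict) -> None:
        self.trace.append(TraceEvent(tick, kind, origin, payload))

    def log_state_change(self, tick: int, origin, payload: dict) -> None:
        """Scenario hook: record a labelled state transition in the trace."""
        self._log(tick, "state_change", origin, payload)

    @property
    def delay(self) -> int:
        return self.config.h if self.config.pipelined else 0

    # -- the clock loop --------------------------------------------------

    def run(self, ticks: int) -> Trace:
        for _ in range(ticks):
            self._do_tick(self._tick)
            self._tick += 1
        return self.trace

    def _do_tick(self, t: int) -> None:
        cfg = self.config
        if self.tick_callback is not None:
            self.tick_callback(self, t)

        # phase 1: sensors convert environment state into input chunks
        if self.environment is not None:
            for sensor, target, gist, weight in self.environment.sense(t):
                if target not in self.wiring.sensor_targets.get(sensor, ()):
                    raise WiringError(
                        f"sensor {sensor!r} delivered to undeclared processor {target}"
                    )
                gain = 1.0 if sensor in self.ungated_sensors else self.input_gain
                chunk = make_submission_chunk(
                    target, t, gist, weight * gain, gist_bound=cfg.B_gist
                )
                self._inbox[target].inputs.append(chunk)
                self._log(t, "env_input", sensor,
                          {"target": target, "chunk": chunk.to_record()})

        # phase 2: every processor steps and submits exactly one chunk
        submissions: list[Chunk] = []
        emissions: list[Emission] = []
        for proc, inbox, rng in zip(self.processors, self._inbox, self._proc_rngs):
            chunk, emission = step(proc, inbox, t, rng, gist_bound=cfg.B_gist)
            submissions.append(chunk)
            emissions.append(emission)
            self._log(t, "submission", proc.address, {"chunk": chunk.to_record()})
        self._pending_submissions[t] = submissions

        # phase 3: the tree advances; the competition submitted at
        # t - delay completes now and its root chunk enters STM
        completing = t - self.delay
        if completing in self._pending_submissions:
            leaf_chunks = self.tree.arrange(self._pending_submissions[completing])
            rng = _stream(cfg.master_seed, 2, completing)
            on_win = None
            if self.log_local_wins:
                def on_win(level, node, chunk, _sub=completing):
                    self._log(_sub + level, "local_win", f"L{level}N{node}",
                              {"chunk": chunk.to_record()})
            root = run_competition(leaf_chunks, self.f, rng,
                                   h=cfg.h, on_local_win=on_win)
            self.stm = root
            broadcast_obj = make_broadcast(root, t, cfg.N)
            self._log(t, "broadcast", "STM", {"chunk": root.to_record()})
            for addr in broadcast_obj.recipients:
                self._next_inbox[addr].broadcast = root
            self._apply_sea(completing, root)

        # phase 4: link messages and acknowledgments (delivered next tick)
        for proc, emission in zip(self.processors, emissions):
            for to, gist, weight in emission.link_messages:
                self.link_graph.require_edge(proc.address, to)
                msg = make_submission_chunk(proc.address, t, gist, weight,
                                            gist_bound=cfg.B_gist)
                self._next_inbox[to].links.append(msg)
                self._log(t, "link_msg", proc.address,
                          {"to": to, "chunk": msg.to_record()})
            for to in emission.acks:
                self.link_graph.record_acknowledgment(proc.address, to, t)
                self._log(t, "ack", proc.address,
                          {"about": to,
                           "strength": self.link_graph.strength(proc.address, to)})

        # phase 5: actuators act on the environment, which then evolves
        if self.environment is not None:
            for proc, emission in zip(self.processors, emissions):
                for command in emission.env_commands:
                    actuator = self.wiring.actuator_for(proc.address)
                    if actuator is None:
                        raise WiringError(
                            f"processor {proc.address} has no actuator"
                        )
                    if not self.actuators_enabled:
                        continue
                    result = self.environment.act(actuator, proc.address,
                                                  command, t)
                    self._log(t, "env_action", proc.address,
                              {"actuator": actuator, "command": command,
                               "result": result})
            self.environment.advance(t)

        # rotate inboxes; drop submission records once SEA no longer needs them
        self._inbox = self._next_inbox
        self._next_inbox = [Inbox() for _ in range(cfg.N)]
        self._pending_submissions.pop(completing, None)

    def _apply_sea(self, sub_tick: int, root: Chunk) -> None:
        if self.value_fn is None:
            return
        submissions = self._pending_submissions.get(sub_tick)
        if submissions is None:
            return
        values = [self.value_fn(ch) for ch in submissions]
        winner_addr = root.address
        loser_values = [
            v for ch, v in zip(submissions, values) if ch.address != winner_addr
        ]
        best_loser = max(loser_values) if loser_values else None
        broadcast_value = self.value_fn(root)
        for proc, own in zip(self.processors, values):
            outcome = SEAOutcome(
                tick=sub_tick,
                won=(proc.address == winner_addr),
                own_value=own,
                broadcast_value=broadcast_value,
                best_loser_value=best_loser,
            )
            sea_update(proc, outcome, beta=self.config.beta_sea)


def run(
    config: MachineConfig,
    behaviours: Sequence[Behaviour | None],
    ticks: int,
    *,
    environment: Environment | None = None,
    value_fn: Callable[[Chunk], float] | None = None,
    tick_callback: Callable[[Machine, int], None] | None = None,
) -> Trace:
    """Build a machine from a scenario and run it for ``ticks`` ticks."""
    machine = Machine(config, behaviours, environment=environment,
                      value_fn=value_fn, tick_callback=tick_callback)
    return machine.run(ticks)
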