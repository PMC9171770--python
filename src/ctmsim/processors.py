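"""Long-term-memory processors.

Each processor is an autonomous module with a scenario-supplied behaviour.
Every tick it must submit exactly one chunk to the competition (the null
chunk when it has nothing to say), and it receives every broadcast.  Around
that duty this module implements:

* the *memory archive* — the time-ordered record of what the processor
  submitted, what it received by broadcast, and a select subset of link and
  sensory chunks; the processor's "high-level story";
* the prediction/feedback cycle — registered gist predictions scored
  against observations, with surprises flagged salient;
* Sleeping-Experts weight adaptation — a multiplicative scale on the
  magnitude of the processor's emitted weights, raised ("embolden") when
  its losing submission was more valuable than the broadcast and lowered
  ("hush") when its winning submission was less valuable than some loser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np

from .core import Chunk, ContractViolation, Gist, make_submission_chunk, null_chunk

__all__ = [
    "Emission",
    "Behaviour",
    "MemoryEntry",
    "ProcessorState",
    "SEAOutcome",
    "step",
    "sea_update",
    "predict_and_score",
    "prune_memory",
    "BEHAVIOUR_REGISTRY",
    "register_behaviour",
]


@dataclass
class Emission:
    """What a behaviour produces in one tick.

    ``gist``/``weight`` form the competition submission (``gist=None``
    means submit the null chunk).  ``link_messages`` are direct sends
    ``(to, gist, weight)`` over existing links; ``acks`` are usefulness
    acknowledgments about other processors; ``env_commands`` go to this
    processor's actuator, if any; ``prediction`` registers an expected
    gist for the next broadcast.
    """

    gist: Gist | None = None
    weight: float = 0.0
    link_messages: list[tuple[int, Gist, float]] = field(default_factory=list)
    acks: list[int] = field(default_factory=list)
    env_commands: list[object] = field(default_factory=list)
    prediction: Gist | None = None


@dataclass
class Inbox:
    """Chunks available to a processor at the start of a tick."""

    broadcast: Chunk | None = None
    links: list[Chunk] = field(default_factory=list)
    inputs: list[Chunk] = field(default_factory=list)


class Behaviour(Protocol):
    def emit(self, proc: "ProcessorState", inbox: Inbox, tick: int,
             rng: np.random.Generator) -> Emission | None: ...


@dataclass
class MemoryEntry:
    tick: int
    submitted: dict
    broadcast_received: dict | None
    received: list[dict]
    surprising: bool = False

    def to_record(self) -> dict:
        return {
            "tick": self.tick,
            "submitted": self.submitted,
            "broadcast_received": self.broadcast_received,
            "received": self.received,
            "surprising": self.surprising,
        }


@dataclass
class ProcessorState:
    """One LTM processor: identity, behaviour, learning scale, archive."""

    address: int
    behaviour: Behaviour | None = None
    sea_scale: float = 1.0
    scale_bounds: tuple[float, float] = (0.01, 100.0)
    competition_enabled: bool = True
    memory: list[MemoryEntry] = field(default_factory=list)
    pending_predictions: dict[int, Gist] = field(default_factory=dict)
    surprise_log: list[tuple[int, float]] = field(default_factory=list)

    def archive(self, entry: MemoryEntry) -> None:
        if self.memory and entry.tick <= self.memory[-1].tick:
            raise ContractViolation("memory archive must be strictly increasing in t")
        self.memory.append(entry)

    def memory_to_jsonl(self, path) -> None:
        import json

        with open(path, "w") as fh:
            for entry in self.memory:
                fh.write(json.dumps(entry.to_record(), separators=(",", ":")) + "\n")


@dataclass(frozen=True)
class SEAOutcome:
    """One broadcast's feedback for one processor.

    ``won`` — this processor's submission was the broadcast; ``own_value``
    and ``broadcast_value`` are the scenario evaluator's valuations;
    ``best_loser_value`` is the highest valuation among the submissions
    that failed to reach STM (needed for the hush condition).
    """

    tick: int
    won: bool
    own_value: float
    broadcast_value: float
    best_loser_value: float | None = None


def step(
    proc: ProcessorState,
    inbox: Inbox,
    tick: int,
    rng: np.random.Generator,
    *,
    gist_bound: int | None = None,
) -> tuple[Chunk, Emission]:
    """Run one processor tick: behaviour emits, SEA scale applied, archived.

    The emitted weight magnitude is multiplied by ``sea_scale`` (sign
    preserved) before the chunk is built.  A behaviour that emits nothing
    submits the null chunk — submission is mandatory.  A lesioned processor
    (``competition_enabled=False``) always submits the null chunk but its
    behaviour still runs (it can, e.g., talk over links).
    """
    emission = proc.behaviour.emit(proc, inbox, tick, rng) if proc.behaviour else None
    if emission is None:
        emission = Emission()
    if emission.gist is None or not proc.competition_enabled:
        chunk = null_chunk(proc.address, tick)
    else:
        chunk = make_submission_chunk(
            proc.address, tick, emission.gist,
            emission.weight * proc.sea_scale, gist_bound=gist_bound,
        )
    if emission.prediction is not None:
        proc.pending_predictions[tick + 1] = emission.prediction

    received = _select_received(inbox)
    proc.archive(
        MemoryEntry(
            tick=tick,
            submitted=chunk.to_record(),
            broadcast_received=(
                inbox.broadcast.to_record() if inbox.broadcast else None
            ),
            received=[ch.to_record() for ch in received],
        )
    )
    return chunk, emission


def _select_received(inbox: Inbox) -> list[Chunk]:
    # archive a bounded subset: the single largest-|weight| link/input chunk
    # per tick (bounded memory); surprising chunks are flagged separately
    extras = inbox.links + inbox.inputs
    if not extras:
        return []
    return [max(extras, key=lambda ch: abs(ch.weight))]


def sea_update(
    proc: ProcessorState,
    outcome: SEAOutcome,
    beta: float = 2.0,
) -> float:
    """Sleeping-Experts multiplicative update of the processor's scale.

    Embolden (scale × beta, capped) when the processor lost but its
    information was more valuable than the broadcast; hush (scale ÷ beta,
    floored) when it won but some losing submission was more valuable.
    Otherwise unchanged.  Returns the new scale.
    """
    lo, hi = proc.scale_bounds
    if not outcome.won and outcome.own_value > outcome.broadcast_value:
        proc.sea_scale = min(hi, proc.sea_scale * beta)
    elif (
        outcome.won
        and outcome.best_loser_value is not None
        and outcome.own_value < outcome.best_loser_value
    ):
        proc.sea_scale = max(lo, proc.sea_scale / beta)
    return proc.sea_scale


def predict_and_score(
    proc: ProcessorState,
    tick: int,
    observed: Gist,
    *,
    metric: Callable[[Gist, Gist], float] | None = None,
) -> tuple[bool, float]:
    """Score a registered prediction against the observed gist.

    Default metric is 0/1 gist equality; scenarios may pass a bounded real
    metric.  A positive error raises the surprise flag and the event is
    logged (surprises mark archive entries salient).
    """
    if tick not in proc.pending_predictions:
        raise ContractViolation(
            f"processor {proc.address} has no prediction registered for tick {tick}"
        )
    predicted = proc.pending_predictions.pop(tick)
    if metric is None:
        error = 0.0 if predicted == observed else 1.0
    else:
        error = float(metric(predicted, observed))
    surprise = error > 0
    if surprise:
        proc.surprise_log.append((tick, error))
        for entry in reversed(proc.memory):
            if entry.tick == tick:
                entry.surprising = True
                break
    return surprise, error


def prune_memory(proc: ProcessorState, salience_threshold: float) -> list[MemoryEntry]:
    """Keep only salient archive entries, preserving order.

    An entry survives iff its submitted |weight| meets the threshold or it
    was flagged surprising (terrible/wonderful/unexpected events stay).
    """
    if salience_threshold < 0:
        raise ContractViolation("salience threshold must be non-negative")
    proc.memory = [
        e
        for e in proc.memory
        if abs(e.submitted["weight"]) >= salience_threshold or e.surprising
    ]
    return proc.memory


#: Named behaviour registry so scenario configs can refer to behaviours by
#: key (populated by the scenarios module and by user code).
BEHAVIOUR_REGISTRY: dict[str, Callable[..., Behaviour]] = {}


def register_behaviour(name: str):
    def deco(factory):
        BEHAVIOUR_REGISTRY[name] = factory
        return factory

    return deco
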