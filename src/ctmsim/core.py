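"""Core data types of the Conscious Turing Machine.

The universal message unit is the *chunk*, a six-tuple
``<address, t, gist, weight, intensity, mood>``.  A processor at leaf
``address`` submits, at tick ``t``, a *gist* (a bounded multimodal payload —
the stand-in for the machine's inner language) to which it attaches a signed
valence ``weight``.  At submission the chunk's ``intensity`` is ``|weight|``
and its ``mood`` is ``weight``; as chunks merge on their way up the
tournament tree these two fields accumulate the subtree sums while the
identity fields (address, t, gist, weight) stay frozen.

Local competitions are driven by a *competition function* ``f`` mapping
chunks to non-negative reals.  The bundled linear-additive family is
``f(chunk) = intensity + c·mood`` for a coefficient ``c`` in ``[-1, +1]``;
because ``|mood| ≤ intensity`` always holds, these values are non-negative.
A function is *additive* when ``f`` of a merged chunk equals the sum of
``f`` over its parts — the property under which each submission's chance of
reaching the broadcast slot is exactly proportional to its ``f`` value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

__all__ = [
    "MODALITY_TAGS",
    "Gist",
    "EMPTY_GIST",
    "Chunk",
    "null_chunk",
    "make_submission_chunk",
    "merge_chunks",
    "CompetitionFunction",
    "evaluate_f",
    "is_additive",
    "MachineConfig",
    "ContractViolation",
    "GistTooLargeError",
]

MODALITY_TAGS = frozenset(
    {"speech", "vision", "tactile", "command", "query", "answer", "empty"}
)

#: Tolerance used when asserting ``|mood| <= intensity`` on merged chunks;
#: pairwise float summation can overshoot by a few ulps.
_MOOD_TOL = 1e-9


class ContractViolation(ValueError):
    """A value breached one of the model's structural contracts."""


class GistTooLargeError(ContractViolation):
    """A gist exceeded the configured serialized-size bound."""


@dataclass(frozen=True)
class Gist:
    """Bounded multimodal payload carried inside a chunk.

    The payload is an opaque token sequence; the core never interprets it.
    Scenarios attach whatever meaning they need.  Equality is byte-wise on
    the canonical serialization, which makes it total and well defined.
    """

    modality_tags: frozenset[str]
    payload: str = ""
    origin_note: str | None = None

    def __post_init__(self) -> None:
        tags = frozenset(self.modality_tags)
        object.__setattr__(self, "modality_tags", tags)
        unknown = tags - MODALITY_TAGS
        if unknown:
            raise ContractViolation(
                f"unknown modality tags {sorted(unknown)}; "
                f"allowed: {sorted(MODALITY_TAGS)}"
            )
        if not tags:
            raise ContractViolation("a gist needs at least one modality tag")

    def serialize(self) -> bytes:
        """Canonical byte serialization (sorted tags, then payload)."""
        return json.dumps(
            [sorted(self.modality_tags), self.payload],
            separators=(",", ":"),
            ensure_ascii=False,
        ).encode("utf-8")

    @property
    def size(self) -> int:
        return len(self.serialize())

    def check_size(self, bound: int) -> "Gist":
        if self.size > bound:
            raise GistTooLargeError(
                f"gist serializes to {self.size} bytes, exceeding the "
                f"configured bound of {bound} bytes"
            )
        return self

    @property
    def is_empty(self) -> bool:
        return self.modality_tags == frozenset({"empty"}) and self.payload == ""

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Gist):
            return NotImplemented
        return self.serialize() == other.serialize()

    def __hash__(self) -> int:
        return hash(self.serialize())


#: The distinguished empty gist broadcast while nothing contentful wins
#: (e.g. during dreamless sleep).
EMPTY_GIST = Gist(modality_tags=frozenset({"empty"}), payload="")


@dataclass(frozen=True)
class Chunk:
    """The six-tuple message unit.

    ``address``, ``t``, ``gist`` and ``weight`` identify the originating
    submission and never change once submitted; ``intensity`` and ``mood``
    are the only fields updated (by pairwise summation) as the chunk climbs
    the tree.  The invariant ``|mood| ≤ intensity`` holds at every level —
    true at submission (``|weight|`` vs ``weight``) and preserved by
    summation via the triangle inequality.
    """

    address: int
    t: int
    gist: Gist
    weight: float
    intensity: float
    mood: float

    def __post_init__(self) -> None:
        if self.address < 0:
            raise ContractViolation("address must be a non-negative leaf index")
        if self.t < 0:
            raise ContractViolation("submission tick must be non-negative")
        for name in ("weight", "intensity", "mood"):
            if not math.isfinite(getattr(self, name)):
                raise ContractViolation(f"chunk {name} must be finite")
        if self.intensity < 0:
            raise ContractViolation("intensity must be non-negative")
        if abs(self.mood) > self.intensity + _MOOD_TOL * max(1.0, self.intensity):
            raise ContractViolation(
                f"|mood| = {abs(self.mood)} exceeds intensity = {self.intensity}"
            )

    def identity(self) -> tuple[int, int, Gist, float]:
        """The immutable quadruple preserved up the tree."""
        return (self.address, self.t, self.gist, self.weight)

    def to_record(self) -> dict:
        """Flat record with fixed field order for JSON-lines traces."""
        return {
            "address": self.address,
            "t": self.t,
            "gist_tags": sorted(self.gist.modality_tags),
            "gist_payload": self.gist.payload,
            "weight": self.weight,
            "intensity": self.intensity,
            "mood": self.mood,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Chunk":
        return cls(
            address=rec["address"],
            t=rec["t"],
            gist=Gist(frozenset(rec["gist_tags"]), rec["gist_payload"]),
            weight=rec["weight"],
            intensity=rec["intensity"],
            mood=rec["mood"],
        )


def null_chunk(address: int, t: int) -> Chunk:
    """The empty submission: EMPTY gist, zero weight/intensity/mood.

    Used both for padded tree leaves and for processors with nothing to say
    (every processor must submit every tick).
    """
    return Chunk(address=address, t=t, gist=EMPTY_GIST, weight=0.0,
                 intensity=0.0, mood=0.0)


def make_submission_chunk(
    address: int,
    t: int,
    gist: Gist,
    weight: float,
    *,
    gist_bound: int | None = None,
) -> Chunk:
    """Build a level-0 chunk: ``intensity = |weight|``, ``mood = weight``.

    Raises :class:`ContractViolation` for a non-finite weight and
    :class:`GistTooLargeError` when ``gist_bound`` is given and exceeded.
    """
    if not math.isfinite(weight):
        raise ContractViolation("submission weight must be finite")
    if gist_bound is not None:
        gist.check_size(gist_bound)
    return Chunk(address=address, t=t, gist=gist, weight=weight,
                 intensity=abs(weight), mood=weight)


def merge_chunks(winner: Chunk, left: Chunk, right: Chunk) -> Chunk:
    """Chunk placed at a parent node: winner's identity, summed aggregates."""
    return Chunk(
        address=winner.address,
        t=winner.t,
        gist=winner.gist,
        weight=winner.weight,
        intensity=left.intensity + right.intensity,
        mood=left.mood + right.mood,
    )


@dataclass(frozen=True)
class CompetitionFunction:
    """Non-negative chunk score driving local competitions.

    ``linear_additive`` instances score ``intensity + c·mood``; custom
    evaluators receive the whole chunk but must return a finite
    non-negative real (checked at every call).
    """

    c: float = 0.0
    form: str = "linear_additive"
    evaluator: Callable[[Chunk], float] | None = None

    def __post_init__(self) -> None:
        if self.form == "linear_additive":
            if not -1.0 <= self.c <= 1.0:
                raise ContractViolation(
                    f"linear-additive coefficient c must lie in [-1, 1], got {self.c}"
                )
        elif self.form == "custom":
            if self.evaluator is None:
                raise ContractViolation("custom competition function needs an evaluator")
        else:
            raise ContractViolation(f"unknown competition-function form {self.form!r}")

    @classmethod
    def linear(cls, c: float = 0.0) -> "CompetitionFunction":
        return cls(c=c, form="linear_additive")

    @classmethod
    def custom(cls, evaluator: Callable[[Chunk], float]) -> "CompetitionFunction":
        return cls(form="custom", evaluator=evaluator)

    def __call__(self, chunk: Chunk) -> float:
        return evaluate_f(self, chunk)

    def describe(self) -> str:
        if self.form == "linear_additive":
            return f"intensity + {self.c}*mood"
        return f"custom:{getattr(self.evaluator, '__name__', 'evaluator')}"


def evaluate_f(f: CompetitionFunction, chunk: Chunk) -> float:
    """Evaluate a competition function, enforcing its output contract."""
    if f.form == "linear_additive":
        value = chunk.intensity + f.c * chunk.mood
        # |c| <= 1 and |mood| <= intensity guarantee >= 0 up to rounding
        return max(0.0, value)
    value = float(f.evaluator(chunk))  # type: ignore[misc]
    if not math.isfinite(value) or value < 0:
        raise ContractViolation(
            f"competition function returned {value!r}; must be a finite "
            "non-negative real"
        )
    return value


def _random_chunk_pair(rng: np.random.Generator) -> tuple[Chunk, Chunk]:
    chunks = []
    for addr in (0, 1):
        weight = float(rng.uniform(-10.0, 10.0))
        chunks.append(make_submission_chunk(addr, 0, EMPTY_GIST, weight))
    return chunks[0], chunks[1]


def is_additive(
    f: CompetitionFunction,
    trials: int = 64,
    rng: np.random.Generator | None = None,
) -> bool:
    """Randomized necessary-condition test for additivity.

    Draws ``trials`` random chunk pairs and checks
    ``f(merged) == f(left) + f(right)`` within 1e-9, where the merged chunk
    carries summed intensity and mood.  Exact for linear forms; a
    non-additive function such as ``|mood|`` fails with probability
    approaching 1 as ``trials`` grows (any opposite-sign mood pair is a
    witness).
    """
    if trials < 1:
        raise ContractViolation("trials must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    for _ in range(trials):
        left, right = _random_chunk_pair(rng)
        merged = merge_chunks(left, left, right)
        if abs(evaluate_f(f, merged) - (evaluate_f(f, left) + evaluate_f(f, right))) > 1e-9:
            return False
    return True


@dataclass(frozen=True)
class MachineConfig:
    """Machine-level configuration.

    Defaults are desk scale (N=16 processors, tree height 4); the
    architecture is scale-free, so every structural property checked at this
    size holds at any size.

    Parameters
    ----------
    N : number of long-term-memory processors (leaves of the Up Tree).
    h : tree height; ``2**h >= N`` (non-powers of two are padded with null
        leaves).
    T : lifetime in ticks.
    c : coefficient of the bundled linear-additive competition function.
    B_gist : serialized gist size bound in bytes.
    master_seed : root of every random stream in the machine.
    k_link, W_link : a link forms when one processor acknowledges another's
        chunks as useful ``k_link`` times within a ``W_link``-tick window.
    beta_sea : multiplicative Sleeping-Experts factor (> 1) applied to a
        processor's emitted-weight scale on embolden/hush events.
    scale_bounds : clipping interval for the Sleeping-Experts scale.
    pipelined : one tree level per tick (the faithful mode) versus
        collapsed within-tick competitions (debug mode).
    """

    N: int = 16
    h: int | None = None
    T: int = 10_000
    c: float = 0.0
    B_gist: int = 256
    master_seed: int = 0
    k_link: int = 3
    W_link: int = 50
    beta_sea: float = 2.0
    scale_bounds: tuple[float, float] = (0.01, 100.0)
    pipelined: bool = True

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ContractViolation("N must be >= 1")
        h = self.h if self.h is not None else max(1, math.ceil(math.log2(self.N)))
        object.__setattr__(self, "h", h)
        if 2 ** h < self.N:
            raise ContractViolation(f"2^h = {2**h} < N = {self.N}")
        if self.T < h:
            raise ContractViolation("lifetime T must be at least the tree height h")
        if self.beta_sea <= 1.0:
            raise ContractViolation("beta_sea must exceed 1")
        lo, hi = self.scale_bounds
        if not (0 < lo <= 1.0 <= hi):
            raise ContractViolation("scale bounds must satisfy 0 < lo <= 1 <= hi")
        if self.B_gist < len(EMPTY_GIST.serialize()):
            raise ContractViolation("B_gist too small to hold even the empty gist")

    @property
    def competition_function(self) -> CompetitionFunction:
        return CompetitionFunction.linear(self.c)

    def to_dict(self) -> dict:
        d = {
            "N": self.N, "h": self.h, "T": self.T, "c": self.c,
            "B_gist": self.B_gist, "master_seed": self.master_seed,
            "k_link": self.k_link, "W_link": self.W_link,
            "beta_sea": self.beta_sea,
            "scale_bounds": list(self.scale_bounds),
            "pipelined": self.pipelined,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MachineConfig":
        d = dict(d)
        if "scale_bounds" in d:
            d["scale_bounds"] = tuple(d["scale_bounds"])
        return cls(**d)
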