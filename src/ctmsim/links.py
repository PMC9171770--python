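"""Down-Tree broadcast and inter-processor links.

The Down Tree is a depth-1 fan-out: the single chunk in short-term memory
is delivered, identically, to every processor one tick after it reaches the
root — that reception *is* conscious awareness in this model.

Links are the unconscious channel.  When processor A repeatedly finds
processor B's broadcast answers useful — operationalized here as A emitting
explicit acknowledgments, ``k_link`` of them within a ``W_link``-tick
window — a bidirectional edge forms between A and B, over which chunks can
then travel directly without ever entering the competition.  Repeats of the
same criterion strengthen the edge; strength never decreases.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Iterable

from .core import Chunk, ContractViolation

__all__ = ["Broadcast", "broadcast", "LinkGraph", "MissingLinkError"]


class MissingLinkError(ContractViolation):
    """A direct send was attempted between unlinked processors."""


@dataclass(frozen=True)
class Broadcast:
    """One tick's global broadcast: the conscious content and its audience."""

    tick: int
    chunk: Chunk
    recipients: tuple[int, ...]


def broadcast(stm_chunk: Chunk, tick: int, n_processors: int) -> Broadcast:
    """Emit the STM chunk at ``tick``; every processor receives it at
    ``tick + 1`` (the machine performs the deliveries)."""
    return Broadcast(tick=tick, chunk=stm_chunk,
                     recipients=tuple(range(n_processors)))


def _edge_key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


@dataclass
class LinkGraph:
    """Undirected link edges with integer strengths plus pending ack windows.

    ``record_acknowledgment(a, b, tick)`` appends a timestamped ack from
    ``a`` about ``b``; when the acks inside the trailing window reach the
    threshold, the edge (a, b) is created at strength 1 — or strengthened —
    and the window is consumed.  Strength is symmetric and monotone
    non-decreasing.
    """

    k_link: int = 3
    W_link: int = 50
    strengths: dict[tuple[int, int], int] = field(default_factory=dict)
    pending_acks: dict[tuple[int, int], deque] = field(
        default_factory=lambda: defaultdict(deque)
    )

    def has_edge(self, a: int, b: int) -> bool:
        return _edge_key(a, b) in self.strengths

    def strength(self, a: int, b: int) -> int:
        return self.strengths.get(_edge_key(a, b), 0)

    def record_acknowledgment(self, frm: int, to: int, tick: int) -> None:
        """A ``frm`` → about-``to`` usefulness acknowledgment at ``tick``."""
        if frm == to:
            raise ContractViolation("a processor cannot acknowledge itself")
        window = self.pending_acks[(frm, to)]
        window.append(tick)
        while window and window[0] <= tick - self.W_link:
            window.popleft()
        if len(window) >= self.k_link:
            key = _edge_key(frm, to)
            self.strengths[key] = self.strengths.get(key, 0) + 1
            window.clear()

    def require_edge(self, frm: int, to: int) -> None:
        if not self.has_edge(frm, to):
            raise MissingLinkError(
                f"no link between processors {frm} and {to}; conscious "
                "communication (via the competition) is the only channel"
            )

    def edges(self) -> Iterable[tuple[int, int, int]]:
        for (a, b), s in sorted(self.strengths.items()):
            yield a, b, s

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("from\tto\tstrength\n")
            for a, b, s in self.edges():
                fh.write(f"{a}\t{b}\t{s}\n")
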