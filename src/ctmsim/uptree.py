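"""The probabilistic Up-Tree competition.

Every tick each of the N processors submits one chunk at its leaf of a full
binary tree of height h.  Each internal node runs a *local competition*
between the chunks of its two children: a coin-flip neuron picks the left
chunk with probability ``f(L) / (f(L) + f(R))`` (a fair coin when both
scores are zero), and the chunk moved up carries the winner's identity
fields with the *summed* intensity and mood of both children.  The root
chunk — the machine's conscious content for that tick — therefore carries
one submission's identity together with the global intensity and mood sums.

For an additive competition function the chance that a given submission
reaches the root is exactly ``f(chunk) / Σ f(all chunks)``, independent of
how processors are assigned to leaves.  :func:`exact_win_probabilities`
computes the root-reaching distribution for *any* competition function by
dynamic programming, which serves as the analytic oracle against which the
simulated tournament is checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import (
    Chunk,
    CompetitionFunction,
    ContractViolation,
    evaluate_f,
    merge_chunks,
    null_chunk,
)

__all__ = [
    "coin_flip_select",
    "local_compete",
    "UpTree",
    "run_competition",
    "WinProbabilityTable",
    "exact_win_probabilities",
    "assign_leaves",
    "monte_carlo_win_frequencies",
]


def coin_flip_select(a: float, b: float, rng: np.random.Generator) -> int:
    """The coin-flip neuron: return 0 (first) with probability ``a/(a+b)``.

    When both inputs are zero the choice is a fair coin.  Exactly one draw
    is consumed from ``rng`` in every case, so replay alignment never
    depends on the inputs.
    """
    if a < 0 or b < 0 or not (np.isfinite(a) and np.isfinite(b)):
        raise ContractViolation(
            f"coin-flip neuron inputs must be finite and non-negative, got ({a}, {b})"
        )
    u = rng.random()
    total = a + b
    p_first = a / total if total > 0 else 0.5
    return 0 if u < p_first else 1


def local_compete(
    left: Chunk,
    right: Chunk,
    f: CompetitionFunction,
    rng: np.random.Generator,
) -> Chunk:
    """One node's local competition: pick a winner, merge the aggregates.

    The returned chunk carries the winner's (address, t, gist, weight) and
    intensity/mood equal to the sums over both children.
    """
    choice = coin_flip_select(evaluate_f(f, left), evaluate_f(f, right), rng)
    winner = left if choice == 0 else right
    return merge_chunks(winner, left, right)


def _padded(leaf_chunks: Sequence[Chunk], h: int, t: int) -> list[Chunk]:
    M = 2 ** h
    padded = list(leaf_chunks)
    padded.extend(null_chunk(addr, t) for addr in range(len(leaf_chunks), M))
    return padded


def _height_for(n: int) -> int:
    h = 0
    while 2 ** h < n:
        h += 1
    return max(1, h)


@dataclass
class UpTree:
    """A full binary tournament tree over N processor leaves.

    ``permutation[i]`` gives the processor address assigned to leaf slot
    ``i``; padded slots (``>= N``) always hold the null chunk.
    """

    N: int
    h: int
    permutation: tuple[int, ...]

    @property
    def n_slots(self) -> int:
        return 2 ** self.h

    def arrange(self, chunks_by_address: Sequence[Chunk]) -> list[Chunk]:
        """Order one chunk per processor (indexed by address) onto leaves."""
        if len(chunks_by_address) != self.N:
            raise ContractViolation(
                f"expected exactly {self.N} submissions (one per processor), "
                f"got {len(chunks_by_address)}"
            )
        return [chunks_by_address[p] for p in self.permutation]


def assign_leaves(n_processors: int, permutation: Sequence[int] | None = None,
                  h: int | None = None) -> UpTree:
    """Build an UpTree with processors placed on leaves per ``permutation``.

    The permutation must be a bijection on ``{0..N-1}``; identity by
    default.  For an additive competition function the leaf assignment has
    no effect on root-reaching probabilities (the tournament theorem's
    corollary); a non-additive function can break that invariance.
    """
    if permutation is None:
        permutation = tuple(range(n_processors))
    perm = tuple(int(p) for p in permutation)
    if sorted(perm) != list(range(n_processors)):
        raise ContractViolation(
            f"permutation must be a bijection on 0..{n_processors - 1}"
        )
    if h is None:
        h = _height_for(n_processors)
    if 2 ** h < n_processors:
        raise ContractViolation(f"2^h = {2**h} < N = {n_processors}")
    return UpTree(N=n_processors, h=h, permutation=perm)


def run_competition(
    leaf_chunks: Sequence[Chunk],
    f: CompetitionFunction,
    rng: np.random.Generator,
    *,
    h: int | None = None,
    on_local_win: Callable[[int, int, Chunk], None] | None = None,
) -> Chunk:
    """Run one full tournament and return the root chunk.

    Nodes are resolved level by level, left to right, each consuming one
    draw from ``rng`` — a fixed traversal order so traces replay exactly.
    ``on_local_win(level, node_index, chunk)`` is invoked per internal node
    when supplied (used by the machine to log local-win events).

    The root chunk's identity equals one submission's identity and its
    intensity/mood are the sums over all submissions.
    """
    if not leaf_chunks:
        raise ContractViolation("at least one leaf chunk required")
    if h is None:
        h = _height_for(len(leaf_chunks))
    t = leaf_chunks[0].t
    level = _padded(leaf_chunks, h, t)
    for s in range(1, h + 1):
        nxt = []
        for i in range(0, len(level), 2):
            node = local_compete(level[i], level[i + 1], f, rng)
            if on_local_win is not None:
                on_local_win(s, i // 2, node)
            nxt.append(node)
        level = nxt
    return level[0]


@dataclass
class WinProbabilityTable:
    """Per-leaf probability of reaching the root, with its f metadata."""

    probabilities: np.ndarray
    f_values: np.ndarray
    f_description: str

    def __post_init__(self) -> None:
        total = float(np.sum(self.probabilities))
        if abs(total - 1.0) > 1e-12:
            raise ContractViolation(
                f"win probabilities sum to {total}, not 1 (±1e-12)"
            )

    def __getitem__(self, leaf: int) -> float:
        return float(self.probabilities[leaf])

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("leaf_index,f_value,probability\n")
            for i, (fv, p) in enumerate(zip(self.f_values, self.probabilities)):
                fh.write(f"{i},{fv!r},{p!r}\n")


def exact_win_probabilities(
    leaf_chunks: Sequence[Chunk],
    f: CompetitionFunction,
    *,
    h: int | None = None,
) -> WinProbabilityTable:
    """Exact root-reaching distribution by bottom-up dynamic programming.

    The chunk occupying any node is (identity of one leaf in its subtree,
    subtree intensity sum, subtree mood sum); the sums are fixed regardless
    of who won below, so per-node f-values depend only on which leaf
    identity survived.  The DP therefore tracks, per node, the distribution
    over surviving leaf identities and composes sibling distributions
    through the coin-flip rule — exact for arbitrary competition functions,
    with no enumeration over winner sets.
    """
    if not leaf_chunks:
        raise ContractViolation("at least one leaf chunk required")
    if h is None:
        h = _height_for(len(leaf_chunks))
    t = leaf_chunks[0].t
    leaves = _padded(leaf_chunks, h, t)
    M = len(leaves)

    # Per node: (leaf indices that can occupy it, their probabilities,
    # subtree intensity sum, subtree mood sum).
    nodes = [
        (np.array([i]), np.array([1.0]), leaves[i].intensity, leaves[i].mood)
        for i in range(M)
    ]
    leaf_f = np.array([evaluate_f(f, ch) for ch in leaves])

    def node_f(ids: np.ndarray, isum: float, msum: float) -> np.ndarray:
        return np.array([
            evaluate_f(
                f,
                Chunk(
                    address=leaves[i].address,
                    t=leaves[i].t,
                    gist=leaves[i].gist,
                    weight=leaves[i].weight,
                    intensity=isum,
                    mood=msum,
                ),
            )
            for i in ids
        ])

    for _level in range(h):
        nxt = []
        for k in range(0, len(nodes), 2):
            ids_l, p_l, i_l, m_l = nodes[k]
            ids_r, p_r, i_r, m_r = nodes[k + 1]
            f_l = node_f(ids_l, i_l, m_l)
            f_r = node_f(ids_r, i_r, m_r)
            # pairwise left-win probability via the coin-flip rule
            tot = f_l[:, None] + f_r[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                w_left = np.where(tot > 0, f_l[:, None] / np.where(tot > 0, tot, 1.0), 0.5)
            p_up_l = p_l * (w_left @ p_r)
            p_up_r = p_r * ((1.0 - w_left).T @ p_l)
            nxt.append(
                (
                    np.concatenate([ids_l, ids_r]),
                    np.concatenate([p_up_l, p_up_r]),
                    i_l + i_r,
                    m_l + m_r,
                )
            )
        nodes = nxt

    ids, probs, _, _ = nodes[0]
    table = np.zeros(M)
    table[ids] = probs
    return WinProbabilityTable(
        probabilities=table,
        f_values=leaf_f,
        f_description=f.describe(),
    )


def monte_carlo_win_frequencies(
    f_values: Sequence[float],
    runs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Empirical root-winning frequencies over many simulated tournaments.

    Vectorised across runs.  Valid for *additive* competition functions
    only: additivity makes every internal node's f-value the fixed sum of
    its subtree's leaf f-values, independent of which identity survived, so
    the whole bracket reduces to identity bookkeeping over precomputable
    weights.  (A unit test pins this fast path to the generic chunk-level
    tournament.)
    """
    fv = np.asarray(f_values, dtype=float)
    if np.any(fv < 0) or not np.all(np.isfinite(fv)):
        raise ContractViolation("f-values must be finite and non-negative")
    h = _height_for(len(fv))
    M = 2 ** h
    weights = np.zeros(M)
    weights[: len(fv)] = fv

    ids = np.broadcast_to(np.arange(M), (runs, M)).copy()
    w = weights
    while ids.shape[1] > 1:
        a, b = w[0::2], w[1::2]
        tot = a + b
        p_first = np.where(tot > 0, np.divide(a, np.where(tot > 0, tot, 1.0)), 0.5)
        take_first = rng.random((runs, a.size)) < p_first
        ids = np.where(take_first, ids[:, 0::2], ids[:, 1::2])
        w = tot
    counts = np.bincount(ids[:, 0], minlength=M)
    return counts / runs
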