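"""Single stochastic Prisoner's Dilemma moves between two players.

Moves are encoded as integers, ``C = 0`` and ``D = 1``.  A joint outcome is a
code ``o = 2 * own_move + opponent_move``, i.e. 0 = CC, 1 = CD, 2 = DC,
3 = DD with the focal player's move first.  The two endpoints of a pairing
see mirror-image histories: outcome CD for one player is DC for the other.

Both players move simultaneously, each consulting the gene selected by the
joint history accumulated with this specific partner: the unconditional gene
on a fresh pairing, the depth-``h`` conditional block after ``h < k`` shared
rounds, and the memory-``k`` block thereafter.

:func:`stationary_play_distribution` provides an exact oracle for the
long-run play statistics of two fixed memory-one strategies: their repeated
play is a Markov chain on the four joint outcomes, and the stationary
distribution of that chain is what lifetime play fractions converge to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import AXELROD, PayoffMatrix, StrategyGenome, gene_block_start

__all__ = [
    "C",
    "D",
    "MOVE_NAMES",
    "OUTCOME_NAMES",
    "mirror_outcome",
    "gene_index",
    "PairState",
    "PlayCounts",
    "decide",
    "payoff",
    "play_edge",
    "simulate_pair",
    "stationary_play_distribution",
]

C: int = 0
D: int = 1
MOVE_NAMES = ("C", "D")
OUTCOME_NAMES = ("CC", "CD", "DC", "DD")


def mirror_outcome(o: int) -> int:
    """Swap whose move comes first in an outcome code (CD <-> DC)."""
    return ((o & 1) << 1) | (o >> 1)


def gene_index(k: int, history: list[int]) -> int:
    """Index of the gene a memory-``k`` player consults.

    ``history`` holds joint-outcome codes from the deciding player's own
    perspective, oldest first.  With ``h = min(len(history), k)`` rounds
    available, the index lies in the depth-``h`` block, offset by the last
    ``h`` outcomes read as a base-4 number (oldest outcome most significant).
    """
    h = min(len(history), k)
    if h == 0:
        return 0
    off = 0
    for o in history[-h:]:
        off = off * 4 + o
    return gene_block_start(h) + off


@dataclass
class PairState:
    """Shared play history on one edge, stored from endpoint 0's perspective.

    ``history`` keeps at most ``memory_order`` joint-outcome codes, oldest
    first.  An empty history marks a fresh pairing (either endpoint newborn
    or the partner just replaced), on which both players consult their
    unconditional gene.
    """

    memory_order: int
    history: list[int] = field(default_factory=list)

    @property
    def fresh(self) -> bool:
        return not self.history

    def view(self, endpoint: int) -> list[int]:
        """History from the perspective of endpoint 0 or 1."""
        if endpoint == 0:
            return list(self.history)
        return [mirror_outcome(o) for o in self.history]

    def push(self, outcome_from_0: int) -> None:
        self.history.append(outcome_from_0)
        if len(self.history) > self.memory_order:
            del self.history[0]

    def reset(self) -> None:
        """Void the history (partner replacement or birth)."""
        self.history.clear()


@dataclass
class PlayCounts:
    """Lifetime joint-outcome counts of one player, own move first."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def fractions(self) -> np.ndarray:
        """Play statistics (pi_CC, pi_CD, pi_DC, pi_DD); NaN if no games."""
        t = self.total
        if t == 0:
            return np.full(4, np.nan)
        return self.counts / t


def decide(g: StrategyGenome, history: list[int], rng: np.random.Generator) -> int:
    """One move: cooperate with the probability of the gene selected by
    ``history`` (the deciding player's own perspective)."""
    p = g.genes[gene_index(g.memory_order, history)]
    return C if rng.random() < p else D


def payoff(a: int, b: int, M: PayoffMatrix = AXELROD) -> tuple[float, float]:
    """Scores awarded to the two players for one round."""
    pay = ((M.R, M.R), (M.S, M.T), (M.T, M.S), (M.P, M.P))
    return pay[2 * a + b]


def play_edge(
    gA: StrategyGenome,
    gB: StrategyGenome,
    s: PairState,
    M: PayoffMatrix = AXELROD,
    rng: np.random.Generator | None = None,
    counts_a: PlayCounts | None = None,
    counts_b: PlayCounts | None = None,
) -> tuple[float, float, int, PairState]:
    """One simultaneous round on an edge; A is endpoint 0 of ``s``.

    Both players decide from the pre-round state.  Returns the two scores,
    the joint-outcome code from A's perspective, and the updated state
    (mutated in place).  If ``PlayCounts`` are supplied they are incremented.
    """
    if rng is None:
        rng = np.random.default_rng()
    ma = decide(gA, s.view(0), rng)
    mb = decide(gB, s.view(1), rng)
    sa, sb = payoff(ma, mb, M)
    oa = 2 * ma + mb
    s.push(oa)
    if counts_a is not None:
        counts_a.counts[oa] += 1
    if counts_b is not None:
        counts_b.counts[mirror_outcome(oa)] += 1
    return sa, sb, oa, s


def simulate_pair(
    gA: StrategyGenome,
    gB: StrategyGenome,
    n_rounds: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Joint-outcome counts (A's perspective) over ``n_rounds`` of repeated
    play starting from a fresh pairing.

    Memory-one fast path used for comparing empirical play frequencies with
    :func:`stationary_play_distribution`.
    """
    counts = np.zeros(4, dtype=np.int64)
    if gA.memory_order == 1 and gB.memory_order == 1:
        ga = gA.genes
        gb = gB.genes
        u = rng.random(size=(n_rounds, 2))
        ia, ib = 0, 0
        for t in range(n_rounds):
            ma = 0 if u[t, 0] < ga[ia] else 1
            mb = 0 if u[t, 1] < gb[ib] else 1
            oa = 2 * ma + mb
            counts[oa] += 1
            ia = 1 + oa
            ib = 1 + 2 * mb + ma
        return counts
    s = PairState(max(gA.memory_order, gB.memory_order))
    ca, cb = PlayCounts(), PlayCounts()
    for _ in range(n_rounds):
        play_edge(gA, gB, s, AXELROD, rng, ca, cb)
    return ca.counts


def stationary_play_distribution(
    gA: StrategyGenome,
    gB: StrategyGenome,
    eps: float = 1e-9,
) -> np.ndarray:
    """Exact stationary distribution (pi_CC, pi_CD, pi_DC, pi_DD) of the
    joint-outcome Markov chain of two memory-one strategies, from A's
    perspective.

    From state ``(X, Y)`` A cooperates with probability ``P_XY`` of A and B
    with probability ``P_YX`` of B, so the transition matrix is the product
    of the two players' conditional genes.  Strictly deterministic genes can
    make the chain reducible or periodic; each gene is therefore mixed with
    ``eps`` toward 0.5, which makes the chain ergodic and the stationary
    vector unique and continuous in the genes.
    """
    if gA.memory_order != 1 or gB.memory_order != 1:
        raise ValueError("the Markov oracle is defined for memory-one strategies")
    pa = (1 - eps) * gA.genes[1:5] + eps * 0.5
    pb_mirrored = (1 - eps) * gB.genes[1:5][[0, 2, 1, 3]] + eps * 0.5
    # P[s, s'] with s' = 2*ma + mb
    P = np.empty((4, 4))
    for s in range(4):
        for ma in (0, 1):
            for mb in (0, 1):
                qa = pa[s] if ma == 0 else 1 - pa[s]
                qb = pb_mirrored[s] if mb == 0 else 1 - pb_mirrored[s]
                P[s, 2 * ma + mb] = qa * qb
    # solve pi P = pi, sum(pi) = 1
    A = np.vstack([P.T - np.eye(4), np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()
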