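"""Stochastic memory-k strategy genomes on a coarse-grained allele lattice.

A strategy genome is a vector of cooperation probabilities.  Gene 0 is the
unconditional probability ``P_C`` of cooperating against a partner with whom
no joint history exists.  For memory order ``k``, the genes consulted after
``h`` rounds of shared history (``1 <= h <= k``) form a block of ``4**h``
conditional probabilities indexed by the last ``h`` joint outcomes, each
outcome one of CC, CD, DC, DD with the player's own move written first.
The total genome length is therefore ``L(k) = (4**(k+1) - 1) / 3``:
5 genes for memory one, 21 for memory two, 85 for memory three.

Mutation replaces a gene with a uniformly drawn allele from a finite lattice
of ``2**b`` equally spaced probabilities (``b`` = resolution in bits); at one
bit per gene the strategy space collapses to the deterministic strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PayoffMatrix",
    "AXELROD",
    "StrategyGenome",
    "genome_length",
    "gene_block_start",
    "seed_genome",
    "allele_lattice",
    "mutate",
    "landmark_genome",
    "LANDMARKS",
    "genomes_to_table",
    "table_to_genomes",
]

MAX_MEMORY = 3
MAX_BITS = 15


@dataclass(frozen=True)
class PayoffMatrix:
    """Single-round Prisoner's Dilemma payoffs.

    ``T`` (temptation) > ``R`` (reward) > ``P`` (punishment) > ``S`` (sucker),
    with ``R > (S + T) / 2`` so that alternating exploitation does not beat
    mutual cooperation.
    """

    T: float = 5.0
    R: float = 3.0
    P: float = 1.0
    S: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T > self.R > self.P > self.S):
            raise ValueError("payoffs must satisfy T > R > P > S")
        if not (self.R > (self.S + self.T) / 2):
            raise ValueError("payoffs must satisfy R > (S + T)/2")

    def as_outcome_array(self) -> np.ndarray:
        """Payoff to a focal player for each joint outcome (CC, CD, DC, DD),
        own move first."""
        return np.array([self.R, self.S, self.T, self.P], dtype=np.float64)


#: Axelrod's canonical payoffs, used throughout.
AXELROD = PayoffMatrix(T=5.0, R=3.0, P=1.0, S=0.0)


def genome_length(k: int) -> int:
    """Number of genes of a memory-``k`` strategy: ``(4**(k+1) - 1) / 3``.

    One unconditional gene plus one block of ``4**h`` conditional genes for
    each history depth ``h = 1..k``.
    """
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise ValueError(f"memory order must be an integer, got {k!r}")
    if k < 1:
        raise ValueError(f"memory order must be >= 1, got {k}")
    return (4 ** (k + 1) - 1) // 3


def gene_block_start(h: int) -> int:
    """Index of the first gene of the depth-``h`` conditional block.

    Depth 0 is the unconditional gene (index 0); depth ``h >= 1`` starts at
    ``(4**h - 1) / 3`` (1, 5, 21, ...).
    """
    if h < 0:
        raise ValueError("history depth must be >= 0")
    return (4**h - 1) // 3


def _validate_kb(k: int, b: int) -> None:
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool) or k < 1 or k > MAX_MEMORY:
        raise ValueError(f"memory order must be an integer in [1, {MAX_MEMORY}], got {k!r}")
    if not isinstance(b, (int, np.integer)) or isinstance(b, bool) or b < 1 or b > MAX_BITS:
        raise ValueError(f"resolution must be an integer in [1, {MAX_BITS}] bits, got {b!r}")


@dataclass(frozen=True)
class StrategyGenome:
    """A memory-``k`` stochastic strategy: cooperation probabilities per
    history context, on a ``2**b``-allele lattice (mutations only; stored
    values may lie off-lattice, e.g. the 0.5 seed)."""

    memory_order: int
    resolution_bits: int
    genes: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        _validate_kb(self.memory_order, self.resolution_bits)
        genes = np.asarray(self.genes, dtype=np.float64)
        if genes.ndim != 1 or genes.shape[0] != genome_length(self.memory_order):
            raise ValueError(
                f"memory-{self.memory_order} genome needs "
                f"{genome_length(self.memory_order)} genes, got shape {genes.shape}"
            )
        if np.any(genes < 0.0) or np.any(genes > 1.0):
            raise ValueError("gene values must lie in [0, 1]")
        genes = genes.copy()
        genes.setflags(write=False)
        object.__setattr__(self, "genes", genes)

    def __len__(self) -> int:
        return self.genes.shape[0]

    @property
    def first_move(self) -> float:
        """Unconditional cooperation probability ``P_C`` (gene 0)."""
        return float(self.genes[0])

    @property
    def conditional(self) -> np.ndarray:
        """Memory-1 conditional genes ``(P_CC, P_CD, P_DC, P_DD)``."""
        return self.genes[1:5].copy()


def seed_genome(k: int = 1, b: int = MAX_BITS) -> StrategyGenome:
    """The 'random' founder genotype: every gene exactly 0.5.

    Seeding is exempt from the allele lattice; coarse-graining constrains
    only alleles that arise by mutation.
    """
    _validate_kb(k, b)
    return StrategyGenome(k, b, np.full(genome_length(k), 0.5))


def allele_lattice(b: int) -> np.ndarray:
    """The ``2**b`` admissible mutant alleles ``i / (2**b - 1)``.

    The lattice spans [0, 1] inclusive, so 1-bit genes are exactly the
    deterministic strategies {0, 1}.
    """
    if not isinstance(b, (int, np.integer)) or isinstance(b, bool) or b < 1 or b > MAX_BITS:
        raise ValueError(f"resolution must be an integer in [1, {MAX_BITS}] bits, got {b!r}")
    n = 2**b
    return np.arange(n, dtype=np.float64) / (n - 1)


def mutate(g: StrategyGenome, mu: float, rng: np.random.Generator) -> StrategyGenome:
    """Return a mutated copy of ``g``.

    Each gene independently receives a Poisson(``mu``)-distributed number of
    mutation events; a gene hit at least once is replaced by a uniform draw
    from :func:`allele_lattice`.  Repeated hits on one gene collapse to a
    single redraw (the last draw would overwrite the earlier ones).  ``mu``
    is thus the mean number of mutations per gene per replication event.
    """
    if mu < 0:
        raise ValueError(f"mutation rate must be >= 0, got {mu}")
    if mu == 0:
        return g
    n_events = rng.poisson(mu, size=len(g))
    hit = n_events >= 1
    genes = np.array(g.genes)
    if hit.any():
        n_alleles = 2**g.resolution_bits
        idx = rng.integers(0, n_alleles, size=int(hit.sum()))
        genes[hit] = idx / (n_alleles - 1)
    return StrategyGenome(g.memory_order, g.resolution_bits, genes)


#: Landmark memory-one strategies, ``(P_C, P_CC, P_CD, P_DC, P_DD)``.
#: The conditional genes are the textbook definitions; the opening move is a
#: convention (these strategies are analysis fixtures whose first gene is
#: consulted only on fresh pairings, where it drifts neutrally anyway).
LANDMARKS: dict[str, tuple[float, float, float, float, float]] = {
    "TFT": (1.0, 1.0, 0.0, 1.0, 0.0),
    "ALLC": (1.0, 1.0, 1.0, 1.0, 1.0),
    "ALLD": (0.0, 0.0, 0.0, 0.0, 0.0),
    "WSLS": (1.0, 1.0, 0.0, 0.0, 1.0),
    "GTFT": (1.0, 1.0, 0.333, 1.0, 0.0),
    "START": (0.5, 0.5, 0.5, 0.5, 0.5),
}


def landmark_genome(name: str, b: int = MAX_BITS) -> StrategyGenome:
    """A named memory-one reference strategy (TFT, ALLC, ALLD, WSLS, GTFT,
    or the random START genotype)."""
    try:
        genes = LANDMARKS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown landmark strategy {name!r}; choose from {sorted(LANDMARKS)}"
        ) from None
    return StrategyGenome(1, b, np.array(genes))


def genomes_to_table(genomes: list[StrategyGenome]) -> str:
    """Serialize genomes to tab-separated text, one row per genome:
    memory order, resolution bits, then genes at 17 significant digits."""
    lines = []
    for g in genomes:
        vals = "\t".join(format(x, ".17g") for x in g.genes)
        lines.append(f"{g.memory_order}\t{g.resolution_bits}\t{vals}")
    return "\n".join(lines) + "\n"


def table_to_genomes(text: str) -> list[StrategyGenome]:
    """Inverse of :func:`genomes_to_table` (lossless round trip)."""
    out = []
    for line in text.strip().splitlines():
        parts = line.split("\t")
        k, b = int(parts[0]), int(parts[1])
        out.append(StrategyGenome(k, b, np.array([float(x) for x in parts[2:]])))
    return out
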