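"""Evolutionary dynamics of stochastic IPD strategies on a toroidal lattice.

A population of ``side x side`` players lives on a torus; every update each
player plays one simultaneous PD round against each of its 8 Moore
neighbours (``4N`` games per update), then a replacement phase removes every
player independently with probability ``r`` and refills each vacancy with a
mutated, fitness-proportionally chosen copy from the candidate pool — the
vacancy's 8 neighbours for spatially structured populations, or all ``N - 1``
other players for well-mixed ones (the dying player is never its own
candidate, and players marked dead in the same update are excluded).  The
overlapping generations make this a Moran-like process in which the
replacement rate sets the expected length of the play history shared by two
neighbours.

Fitness is the lifetime accumulated score; newborns start at zero, with
fresh pair states on all incident edges, and first play in the following
update.  The full ancestry (parent, birth update, genome, and lifetime play
counts of every organism that ever lived) is logged so that lines of
descent can be traced afterwards.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import _kernels
from .genome import AXELROD, PayoffMatrix, genome_length, seed_genome

__all__ = [
    "ExperimentConfig",
    "Population",
    "AncestryLog",
    "RunResult",
    "moore_neighbors",
    "build_edges",
    "games_per_update",
    "replacement_pool_size",
    "init_population",
    "play_phase",
    "replacement_phase",
    "run",
    "run_replicates",
    "replicate_rng",
]

STRUCTURES = ("spatial", "well_mixed")
SEED_PARENT = -1


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete description of one evolution experiment.

    ``mu`` is the per-gene mutation rate applied at replication; a
    ``mu_schedule`` of ``(start_update, mu)`` pairs can be given instead, in
    which case the rate in force at update ``t`` is the entry with the
    largest ``start_update <= t`` (taking effect at that update's
    replacement phase).  ``r`` is the per-update, per-player replacement
    probability.
    """

    side: int = 32
    structure: str = "spatial"
    mu: float = 0.005
    mu_schedule: tuple[tuple[int, float], ...] | None = None
    r: float = 0.01
    memory_order: int = 1
    resolution_bits: int = 15
    payoffs: PayoffMatrix = AXELROD
    total_updates: int = 500_000
    n_replicates: int = 80
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.side < 3:
            raise ValueError("grid side must be >= 3 (Moore neighbourhoods must not wrap onto themselves)")
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}, got {self.structure!r}")
        if not (0.0 < self.r <= 1.0):
            raise ValueError(f"replacement rate must be in (0, 1], got {self.r}")
        if self.total_updates < 0:
            raise ValueError("total_updates must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.mu_schedule is not None:
            sched = tuple((int(t), float(m)) for t, m in self.mu_schedule)
            if not sched:
                raise ValueError("mu_schedule must not be empty")
            if any(m < 0 for _, m in sched):
                raise ValueError("scheduled mutation rates must be >= 0")
            if list(sched) != sorted(sched, key=lambda e: e[0]):
                raise ValueError("mu_schedule must be sorted by start update")
            if sched[0][0] > 1:
                raise ValueError("mu_schedule must cover the run from update 1")
            object.__setattr__(self, "mu_schedule", sched)
        elif self.mu < 0:
            raise ValueError(f"mutation rate must be >= 0, got {self.mu}")
        genome_length(self.memory_order)  # validates k
        if not (1 <= self.resolution_bits <= 15):
            raise ValueError("resolution must be 1..15 bits")

    @property
    def n_players(self) -> int:
        return self.side * self.side

    def mu_at(self, update: int) -> float:
        """Mutation rate in force at ``update`` (1-based)."""
        if self.mu_schedule is None:
            return self.mu
        current = self.mu_schedule[0][1]
        for start, m in self.mu_schedule:
            if start <= update:
                current = m
            else:
                break
        return current

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["payoffs"] = {"T": self.payoffs.T, "R": self.payoffs.R, "P": self.payoffs.P, "S": self.payoffs.S}
        if self.mu_schedule is not None:
            d["mu_schedule"] = [list(e) for e in self.mu_schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "payoffs" in d and isinstance(d["payoffs"], dict):
            d["payoffs"] = PayoffMatrix(**d["payoffs"])
        if d.get("mu_schedule") is not None:
            d["mu_schedule"] = tuple(tuple(e) for e in d["mu_schedule"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def moore_neighbors(side: int) -> np.ndarray:
    """(N, 8) site indices of the Moore neighbourhood on the torus."""
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    rows, cols = np.divmod(np.arange(side * side), side)
    nbrs = np.empty((side * side, 8), dtype=np.int64)
    for j, (dr, dc) in enumerate(offs):
        nbrs[:, j] = ((rows + dr) % side) * side + (cols + dc) % side
    return nbrs


def build_edges(side: int) -> tuple[np.ndarray, np.ndarray]:
    """Undirected play edges of the torus and each site's incident edges.

    Every site pairs once with its E, SE, S and SW neighbours, giving the
    ``4N`` unique Moore edges; returns ``(edges, incident_edges)`` with
    shapes (4N, 2) and (N, 8).
    """
    offs = [(0, 1), (1, 1), (1, 0), (1, -1)]
    rows, cols = np.divmod(np.arange(side * side), side)
    edges = np.empty((4 * side * side, 2), dtype=np.int64)
    for j, (dr, dc) in enumerate(offs):
        other = ((rows + dr) % side) * side + (cols + dc) % side
        edges[j::4, 0] = np.arange(side * side)
        edges[j::4, 1] = other
    incident: list[list[int]] = [[] for _ in range(side * side)]
    for e in range(edges.shape[0]):
        incident[edges[e, 0]].append(e)
        incident[edges[e, 1]].append(e)
    inc = np.array(incident, dtype=np.int64)
    assert inc.shape == (side * side, 8)
    return edges, inc


def games_per_update(side: int) -> int:
    """Games per update: 8 neighbours each, shared, so ``4 N``."""
    return 4 * side * side


def replacement_pool_size(cfg: ExperimentConfig) -> int:
    """Candidate pool for one vacancy before dead-player exclusion: the 8
    neighbours (spatial) or all other players (well-mixed)."""
    return 8 if cfg.structure == "spatial" else cfg.n_players - 1


class Population:
    """Mutable state of one evolving population plus its ancestry log."""

    def __init__(self, cfg: ExperimentConfig):
        self.cfg = cfg
        N, L = cfg.n_players, genome_length(cfg.memory_order)
        seed = seed_genome(cfg.memory_order, cfg.resolution_bits)
        self.genes = np.tile(seed.genes, (N, 1))
        self.scores = np.zeros(N, dtype=np.float64)
        self.counts = np.zeros((N, 4), dtype=np.int64)
        self.neighbors = moore_neighbors(cfg.side)
        self.edges, self.incident_edges = build_edges(cfg.side)
        self.hist = np.zeros((self.edges.shape[0], cfg.memory_order), dtype=np.int8)
        self.hlen = np.zeros(self.edges.shape[0], dtype=np.int8)
        self.org_of_site = np.arange(N, dtype=np.int64)
        self.update_counter = 0
        # ancestry: seed organisms 0..N-1
        self._org_parent: list[np.ndarray] = [np.full(N, SEED_PARENT, dtype=np.int64)]
        self._org_birth: list[np.ndarray] = [np.zeros(N, dtype=np.int64)]
        self._org_genes: list[np.ndarray] = [self.genes.copy()]
        self._death_org: list[np.ndarray] = []
        self._death_counts: list[np.ndarray] = []
        self.n_orgs = N
        # reusable per-update buffers
        self._b_site = np.empty(N, dtype=np.int64)
        self._b_parent = np.empty(N, dtype=np.int64)
        self._b_genes = np.empty((N, L), dtype=np.float64)
        self._d_org = np.empty(N, dtype=np.int64)
        self._d_counts = np.empty((N, 4), dtype=np.int64)

    @property
    def n_players(self) -> int:
        return self.genes.shape[0]

    def finalize_log(self, rng: np.random.Generator) -> "AncestryLog":
        """Assemble the ancestry log, closing the books on still-living
        organisms (their lifetime counts are the counts at run end) and
        sampling the terminal player whose line of descent is traced."""
        parent = np.concatenate(self._org_parent)
        birth = np.concatenate(self._org_birth)
        genomes = np.concatenate(self._org_genes, axis=0)
        play_counts = np.zeros((self.n_orgs, 4), dtype=np.int64)
        if self._death_org:
            play_counts[np.concatenate(self._death_org)] = np.concatenate(self._death_counts, axis=0)
        play_counts[self.org_of_site] = self.counts
        alive = np.zeros(self.n_orgs, dtype=bool)
        alive[self.org_of_site] = True
        sampled = int(self.org_of_site[rng.integers(self.n_players)])
        return AncestryLog(
            parent_id=parent,
            birth_update=birth,
            genomes=genomes,
            play_counts=play_counts,
            alive=alive,
            terminal_ids=np.sort(self.org_of_site),
            sampled_terminal=sampled,
            side=self.cfg.side,
            memory_order=self.cfg.memory_order,
            resolution_bits=self.cfg.resolution_bits,
            total_updates=self.update_counter,
        )


@dataclass
class AncestryLog:
    """Genealogy of a finished run: one row per organism that ever lived.

    Seed organisms have ``parent_id == -1`` and ``birth_update == 0``;
    every other organism has exactly one parent, so the log is a forest
    rooted in the seed generation.  ``play_counts`` are lifetime joint-
    outcome counts (own move first) frozen at death or run end.
    """

    parent_id: np.ndarray
    birth_update: np.ndarray
    genomes: np.ndarray
    play_counts: np.ndarray
    alive: np.ndarray
    terminal_ids: np.ndarray
    sampled_terminal: int
    side: int
    memory_order: int
    resolution_bits: int
    total_updates: int

    @property
    def n_organisms(self) -> int:
        return self.parent_id.shape[0]

    @property
    def n_seed(self) -> int:
        return int((self.parent_id == SEED_PARENT).sum())

    def to_frame(self) -> pd.DataFrame:
        L = self.genomes.shape[1]
        data = {
            "child_id": np.arange(self.n_organisms),
            "parent_id": self.parent_id,
            "birth_update": self.birth_update,
            "alive": self.alive.astype(int),
            "n_CC": self.play_counts[:, 0],
            "n_CD": self.play_counts[:, 1],
            "n_DC": self.play_counts[:, 2],
            "n_DD": self.play_counts[:, 3],
        }
        for g in range(L):
            data[f"gene_{g}"] = self.genomes[:, g]
        return pd.DataFrame(data)

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "format": "ipdevo-ancestry-v1",
            "side": self.side,
            "memory_order": self.memory_order,
            "resolution_bits": self.resolution_bits,
            "total_updates": self.total_updates,
            "sampled_terminal": self.sampled_terminal,
        }
        with path.open("w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AncestryLog":
        path = Path(path)
        meta = {}
        with path.open() as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                k, _, v = line[1:].partition(":")
                meta[k.strip()] = v.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        gene_cols = [c for c in df.columns if c.startswith("gene_")]
        alive = df["alive"].to_numpy().astype(bool)
        return cls(
            parent_id=df["parent_id"].to_numpy(np.int64),
            birth_update=df["birth_update"].to_numpy(np.int64),
            genomes=df[gene_cols].to_numpy(np.float64),
            play_counts=df[["n_CC", "n_CD", "n_DC", "n_DD"]].to_numpy(np.int64),
            alive=alive,
            terminal_ids=np.flatnonzero(alive),
            sampled_terminal=int(meta["sampled_terminal"]),
            side=int(meta["side"]),
            memory_order=int(meta["memory_order"]),
            resolution_bits=int(meta["resolution_bits"]),
            total_updates=int(meta["total_updates"]),
        )


@dataclass
class RunResult:
    """Outcome of one replicate: the ancestry log and optional per-update
    summaries (mean lifetime score, fraction of C moves)."""

    log: AncestryLog
    config: ExperimentConfig
    replicate: int
    summaries: pd.DataFrame | None = None


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """The dedicated random stream of one replicate, derived from the master
    seed by spawn key so replicate sets are reproducible and independent."""
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(replicate,)))


def init_population(cfg: ExperimentConfig, rng: np.random.Generator | None = None) -> Population:
    """Seeded population: every player carries the all-0.5 founder genome,
    zero score, fresh pair states everywhere."""
    return Population(cfg)


def play_phase(pop: Population, M: PayoffMatrix | None = None, rng: np.random.Generator | None = None) -> int:
    """Execute one synchronous play phase (every edge plays once).

    Returns the number of C moves made this update.
    """
    M = M or pop.cfg.payoffs
    if rng is None:
        rng = np.random.default_rng()
    return int(
        _kernels.play_phase(
            pop.genes,
            pop.scores,
            pop.counts,
            pop.edges,
            pop.hist,
            pop.hlen,
            pop.cfg.memory_order,
            M.as_outcome_array(),
            rng,
        )
    )


def replacement_phase(
    pop: Population,
    cfg: ExperimentConfig | None = None,
    rng: np.random.Generator | None = None,
    mu: float | None = None,
) -> int:
    """Execute one replacement phase; returns the number of replacements.

    Deaths are Bernoulli(``r``) per player; vacancies are refilled
    fitness-proportionally from the surviving candidate pool and the child
    genome is the parent's with each gene redrawn from the allele lattice
    with probability ``1 - exp(-mu)`` (at least one Poisson mutation event).
    Ancestry and death records are appended to the population's log.
    """
    cfg = cfg or pop.cfg
    if rng is None:
        rng = np.random.default_rng()
    if mu is None:
        mu = cfg.mu_at(pop.update_counter if pop.update_counter >= 1 else 1)
    p_mut = -np.expm1(-mu)
    nb = int(
        _kernels.replacement_phase(
            pop.genes,
            pop.scores,
            pop.counts,
            pop.neighbors,
            pop.incident_edges,
            pop.hlen,
            pop.org_of_site,
            cfg.structure == "well_mixed",
            cfg.r,
            p_mut,
            2**cfg.resolution_bits,
            pop.n_orgs,
            rng,
            pop._b_site,
            pop._b_parent,
            pop._b_genes,
            pop._d_org,
            pop._d_counts,
        )
    )
    if nb:
        t = pop.update_counter if pop.update_counter >= 1 else 1
        pop._org_parent.append(pop._b_parent[:nb].copy())
        pop._org_birth.append(np.full(nb, t, dtype=np.int64))
        pop._org_genes.append(pop._b_genes[:nb].copy())
        pop._death_org.append(pop._d_org[:nb].copy())
        pop._death_counts.append(pop._d_counts[:nb].copy())
        pop.n_orgs += nb
    return nb


def run(
    cfg: ExperimentConfig,
    replicate: int = 0,
    record_summaries: bool = False,
    summary_every: int = 1000,
    log_progress=None,
) -> RunResult:
    """Run one replicate for ``cfg.total_updates`` updates.

    Each update is a play phase followed by a replacement phase, with the
    mutation rate taken from the schedule in force at that update.  The run
    is a pure function of ``(cfg, replicate)``: the replicate's random
    stream is derived from the master seed, and kernel draw order is fixed.
    """
    rng = replicate_rng(cfg.master_seed, replicate)
    pop = init_population(cfg, rng)
    rows = []
    for t in range(1, cfg.total_updates + 1):
        pop.update_counter = t
        n_coop = play_phase(pop, cfg.payoffs, rng)
        replacement_phase(pop, cfg, rng, mu=cfg.mu_at(t))
        if record_summaries and (t % summary_every == 0 or t == cfg.total_updates):
            rows.append(
                {
                    "update": t,
                    "mean_score": float(pop.scores.mean()),
                    "frac_coop": n_coop / (2 * games_per_update(cfg.side)),
                    "mu": cfg.mu_at(t),
                }
            )
            if log_progress is not None:
                log_progress(rows[-1])
    log = pop.finalize_log(rng)
    summaries = pd.DataFrame(rows) if record_summaries else None
    return RunResult(log=log, config=cfg, replicate=replicate, summaries=summaries)


def run_replicates(
    cfg: ExperimentConfig,
    replicates: Sequence[int] | None = None,
    **kwargs,
) -> Iterable[RunResult]:
    """Run (lazily) each requested replicate of the experiment."""
    if replicates is None:
        replicates = range(cfg.n_replicates)
    for i in replicates:
        yield run(cfg, replicate=i, **kwargs)
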