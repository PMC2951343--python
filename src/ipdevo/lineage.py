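"""Line-of-descent (LOD) analysis of ancestry logs.

The LOD of a run is the chain of direct ancestors of one player sampled
from the terminal population, followed back to the founding genotype.  It
is the standard way to read an evolutionary trajectory out of an
agent-based run: unlike population averages, the LOD records exactly the
genotypes that left descendants.  Because all terminal players' lineages
coalesce at the most recent common ancestor (MRCA), the stretch of the LOD
past the MRCA reflects a single arbitrary surviving family rather than the
equilibrated dynamics — which is why consensus genotypes discard the tail
of the record.

Per-update attribution is birth-inclusive: the organism "at update t" is
the one with ``birth_update <= t`` and whose successor on the LOD (its
child) was born later than ``t``.  Averaging the genomes and lifetime play
statistics of the update-t organisms across replicates yields the average
LOD; averaging the average LOD over the equilibrated window yields the
consensus genotype, the empirical fixed point of the dynamics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .population import SEED_PARENT, AncestryLog

__all__ = [
    "LOD",
    "AverageLOD",
    "ConsensusGenotype",
    "trace_lod",
    "lod_at_update",
    "expand_lod",
    "average_lod",
    "consensus_window",
    "consensus_genotype",
    "mrca_index",
]


@dataclass
class LOD:
    """One line of descent, seed organism first.

    ``pi`` holds the lifetime play statistics (pi_CC, pi_CD, pi_DC, pi_DD)
    of each organism on the chain; a row is NaN for an organism that never
    played (born during the final update).
    """

    org_ids: np.ndarray
    birth_update: np.ndarray
    genomes: np.ndarray
    play_counts: np.ndarray
    total_updates: int

    def __len__(self) -> int:
        return self.org_ids.shape[0]

    @property
    def pi(self) -> np.ndarray:
        totals = self.play_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.play_counts / totals
        out[totals[:, 0] == 0] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        L = self.genomes.shape[1]
        data = {"org_id": self.org_ids, "birth_update": self.birth_update}
        for g in range(L):
            data[f"gene_{g}"] = self.genomes[:, g]
        pi = self.pi
        for q, name in enumerate(("pi_CC", "pi_CD", "pi_DC", "pi_DD")):
            data[name] = pi[:, q]
        return pd.DataFrame(data)


def trace_lod(log: AncestryLog, end_player_id: int | None = None) -> LOD:
    """Ancestor chain from the seed genotype to a terminal player.

    ``end_player_id`` is an organism id from the terminal population; by
    default the player the run itself sampled uniformly at its end.
    """
    if end_player_id is None:
        end_player_id = log.sampled_terminal
    if not (0 <= end_player_id < log.n_organisms) or not log.alive[end_player_id]:
        raise KeyError(f"organism {end_player_id} is not in the terminal population")
    chain = [end_player_id]
    while log.parent_id[chain[-1]] != SEED_PARENT:
        chain.append(int(log.parent_id[chain[-1]]))
    ids = np.array(chain[::-1], dtype=np.int64)
    return LOD(
        org_ids=ids,
        birth_update=log.birth_update[ids],
        genomes=log.genomes[ids],
        play_counts=log.play_counts[ids],
        total_updates=log.total_updates,
    )


def lod_at_update(lod: LOD, t: int) -> int:
    """Index into ``lod`` of the organism attributed to update ``t``
    (birth-inclusive, successor-birth-exclusive)."""
    if not (1 <= t <= lod.total_updates):
        raise ValueError(f"update {t} outside 1..{lod.total_updates}")
    return int(np.searchsorted(lod.birth_update, t, side="right") - 1)


def expand_lod(lod: LOD) -> tuple[np.ndarray, np.ndarray]:
    """Per-update genome matrix (T, L) and play-statistics matrix (T, 4)
    of the LOD, row ``i`` describing update ``i + 1``."""
    T = lod.total_updates
    idx = np.searchsorted(lod.birth_update, np.arange(1, T + 1), side="right") - 1
    return lod.genomes[idx], lod.pi[idx]


@dataclass
class AverageLOD:
    """Per-update mean genome and mean play statistics across replicates.

    Row ``i`` is update ``i + 1``.  Organisms with undefined play
    statistics (zero lifetime games) are excluded from the play-statistics
    mean at their updates, never imputed.
    """

    genes: np.ndarray
    pi: np.ndarray
    n_replicates: int

    @property
    def total_updates(self) -> int:
        return self.genes.shape[0]

    def to_frame(self) -> pd.DataFrame:
        L = self.genes.shape[1]
        data = {"update": np.arange(1, self.total_updates + 1)}
        for g in range(L):
            data[f"gene_{g}"] = self.genes[:, g]
        for q, name in enumerate(("pi_CC", "pi_CD", "pi_DC", "pi_DD")):
            data[name] = self.pi[:, q]
        return pd.DataFrame(data)

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"# n_replicates: {self.n_replicates}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "AverageLOD":
        with Path(path).open() as fh:
            first = fh.readline()
            n_rep = int(first.partition(":")[2]) if first.startswith("#") else 1
            if not first.startswith("#"):
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        gene_cols = [c for c in df.columns if c.startswith("gene_")]
        pi_cols = ["pi_CC", "pi_CD", "pi_DC", "pi_DD"]
        return cls(df[gene_cols].to_numpy(np.float64), df[pi_cols].to_numpy(np.float64), n_rep)


def average_lod(lods: list[LOD]) -> AverageLOD:
    """Pointwise (per-update) mean of genomes and play statistics over
    replicate LODs, which must share the same run length."""
    if not lods:
        raise ValueError("need at least one LOD")
    T = lods[0].total_updates
    if any(l.total_updates != T for l in lods):
        raise ValueError("replicate LODs have different run lengths")
    genes = np.stack([expand_lod(l)[0] for l in lods])
    pis = np.stack([expand_lod(l)[1] for l in lods])
    with warnings.catch_warnings():
        # an update where every replicate's organism never played stays NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean_pi = np.nanmean(pis, axis=0)
    return AverageLOD(genes.mean(axis=0), mean_pi, len(lods))


def consensus_window(T: int, tail_discard: int | None = None) -> tuple[int, int]:
    """Equilibrated window ``[T/2, T - tail_discard]`` (inclusive updates).

    The default discard is ``T // 10``: its purpose is to drop the stretch
    of the LOD past the MRCA, whose expected length scales with the
    coalescence time of the run rather than being an absolute constant.
    """
    if tail_discard is None:
        tail_discard = T // 10
    lo, hi = T // 2, T - tail_discard
    if lo < 1 or hi < lo:
        raise ValueError(f"empty consensus window [{lo}, {hi}] for T={T}, tail_discard={tail_discard}")
    return lo, hi


@dataclass
class ConsensusGenotype:
    """Per-gene mean and variance of the average LOD over the consensus
    window — the empirical evolutionary fixed point of the experiment."""

    mean: np.ndarray
    variance: np.ndarray
    window: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": np.arange(self.mean.shape[0]), "mean": self.mean, "variance": self.variance}
        )


def consensus_genotype(avg: AverageLOD, tail_discard: int | None = None) -> ConsensusGenotype:
    """Average the second half of the average genetic LOD, minus the tail
    discard, to obtain the consensus genotype."""
    lo, hi = consensus_window(avg.total_updates, tail_discard)
    block = avg.genes[lo - 1 : hi]
    return ConsensusGenotype(block.mean(axis=0), block.var(axis=0), (lo, hi))


def mrca_index(log: AncestryLog) -> int | None:
    """Organism id of the most recent common ancestor of the terminal
    population, or ``None`` if the terminal lineages have not coalesced."""
    ancestries = []
    for tid in log.terminal_ids:
        chain = [int(tid)]
        while log.parent_id[chain[-1]] != SEED_PARENT:
            chain.append(int(log.parent_id[chain[-1]]))
        ancestries.append(chain[::-1])
    mrca = None
    for depth in range(min(len(a) for a in ancestries)):
        first = ancestries[0][depth]
        if all(a[depth] == first for a in ancestries):
            mrca = first
        else:
            break
    return mrca
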