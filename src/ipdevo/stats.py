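"""Order parameter, phase diagrams and PCA trajectories.

The character of the evolved attractor is summarised by the order
parameter ``m = (pi_CC - pi_DD) / (pi_CC + pi_DD)``: the normalised
difference between the equilibrated frequencies of mutual cooperation and
mutual defection along the (average) line of descent.  ``m = +1`` means all
equilibrated play is mutual cooperation, ``m = -1`` all mutual defection,
and the sign flips when CC and DD play are exchanged.  A population is
classified cooperative for ``m > 0.2``, defective for ``m < -0.2`` and in
the transition regime otherwise.

Sweeping ``m`` over a mutation-rate / replacement-rate grid produces a
phase diagram; along a mutation-rate slice the zero crossing of ``m``
locates the critical mutation rate at which cooperation gives way to
defection.

Strategy space is visualised by projecting the four conditional genes
(P_CC, P_CD, P_DC, P_DD) of the average LOD onto the two leading principal
components fitted once on a low-mutation-rate reference trajectory; keeping
the components fixed lets trajectories at other mutation rates and the
landmark strategies (TFT, WSLS, ...) be drawn in the same coordinates.  The
unconditional gene is excluded: it is consulted only on fresh pairings and
drifts neutrally.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import LANDMARKS, StrategyGenome
from .lineage import LOD, AverageLOD, average_lod, consensus_window, expand_lod, trace_lod
from .population import ExperimentConfig, run

__all__ = [
    "order_parameter",
    "order_parameter_per_replicate",
    "classify_phase",
    "run_experiment_lods",
    "phase_sweep",
    "CriticalPoint",
    "critical_mu",
    "PCAModel",
    "fit_pca",
    "project",
    "landmark_projections",
]

#: |m| band within which a population counts as neither cooperative nor
#: defective.
TRANSITION_BAND = 0.2

M_FORMULAS = ("cc_dd", "all")


def _window_pi(pi: np.ndarray, window: tuple[int, int] | None) -> np.ndarray:
    T = pi.shape[0]
    lo, hi = window if window is not None else consensus_window(T)
    if not (1 <= lo <= hi <= T):
        raise ValueError(f"window [{lo}, {hi}] outside 1..{T}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(pi[lo - 1 : hi], axis=0)


def _m_from_pibar(pibar: np.ndarray, formula: str) -> float:
    if formula not in M_FORMULAS:
        raise ValueError(f"formula must be one of {M_FORMULAS}")
    num = pibar[0] - pibar[3]
    den = pibar[0] + pibar[3] if formula == "cc_dd" else pibar.sum()
    if not np.isfinite(den) or den == 0:
        return float("nan")
    return float(num / den)


def order_parameter(
    avg: AverageLOD | np.ndarray,
    window: tuple[int, int] | None = None,
    formula: str = "cc_dd",
) -> float:
    """Order parameter from window-averaged play statistics.

    ``avg`` is an :class:`AverageLOD` (or a raw (T, 4) play-statistics
    matrix); the window defaults to the consensus window, i.e. the
    equilibrated stretch ``[T/2, T - T/10]``.  Returns NaN when no CC or DD
    play occurred in the window (the parameter is then undefined).

    The default ``cc_dd`` formula normalises by mutual play only,
    ``(pi_CC - pi_DD) / (pi_CC + pi_DD)``; the ``all`` variant divides by
    the total of all four play frequencies instead.
    """
    pi = avg.pi if isinstance(avg, AverageLOD) else np.asarray(avg, dtype=float)
    return _m_from_pibar(_window_pi(pi, window), formula)


def order_parameter_per_replicate(
    lods: Sequence[LOD],
    window: tuple[int, int] | None = None,
    formula: str = "cc_dd",
) -> np.ndarray:
    """One order parameter per replicate LOD (each replicate's own
    window-averaged play statistics)."""
    return np.array([_m_from_pibar(_window_pi(expand_lod(l)[1], window), formula) for l in lods])


def classify_phase(m: float, band: float = TRANSITION_BAND) -> str:
    if np.isnan(m):
        return "undefined"
    if m > band:
        return "cooperation"
    if m < -band:
        return "defection"
    return "transition"


def run_experiment_lods(cfg: ExperimentConfig) -> tuple[list[LOD], AverageLOD]:
    """Run all replicates of ``cfg`` and trace each replicate's LOD.

    Returns the per-replicate LODs and their average.
    """
    lods = [trace_lod(run(cfg, replicate=i).log) for i in range(cfg.n_replicates)]
    return lods, average_lod(lods)


def phase_sweep(
    base_cfg: ExperimentConfig,
    mus: Sequence[float],
    rs: Sequence[float] | None = None,
    formula: str = "cc_dd",
    progress=None,
) -> pd.DataFrame:
    """Order-parameter table over a mutation-rate x replacement-rate grid.

    Each grid cell runs the full pipeline (``base_cfg.n_replicates``
    replicates, LOD tracing, windowed play statistics) with an independent
    master seed derived from the base seed, so cells can be computed — or
    recomputed — independently.  Reports the replicate mean of ``m``, two
    standard errors, and the phase classification at the +-0.2 band.
    """
    rs = list(rs) if rs is not None else [base_cfg.r]
    cells = [(mu, r) for r in rs for mu in mus]
    seeds = np.random.SeedSequence(base_cfg.master_seed).generate_state(len(cells)) & 0x7FFFFFFF
    rows = []
    for (mu, r), seed in zip(cells, seeds):
        cfg = dataclasses.replace(base_cfg, mu=mu, mu_schedule=None, r=r, master_seed=int(seed))
        lods, _ = run_experiment_lods(cfg)
        ms = order_parameter_per_replicate(lods, formula=formula)
        ms = ms[np.isfinite(ms)]
        n = ms.size
        mean_m = float(ms.mean()) if n else float("nan")
        two_se = float(2 * ms.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        rows.append(
            {
                "structure": cfg.structure,
                "mu": mu,
                "r": r,
                "mean_m": mean_m,
                "two_se": two_se,
                "n_replicates": n,
                "phase": classify_phase(mean_m),
            }
        )
        if progress is not None:
            progress(rows[-1])
    return pd.DataFrame(rows)


@dataclass
class CriticalPoint:
    """Zero crossing of the order-parameter curve m(mu).

    ``mu_star`` is the linearly interpolated crossing; ``bracket`` the grid
    interval containing it.  ``crossed`` is False when the curve never
    changes sign (no transition in the scanned range) — not an error.
    """

    mu_star: float | None
    bracket: tuple[float, float] | None
    crossed: bool


def critical_mu(mus: Sequence[float], ms: Sequence[float]) -> CriticalPoint:
    """Locate the cooperation-to-defection transition on an m(mu) curve by
    linear interpolation between the first sign-changing grid points."""
    order = np.argsort(mus)
    mu_arr = np.asarray(mus, dtype=float)[order]
    m_arr = np.asarray(ms, dtype=float)[order]
    if np.any(~np.isfinite(m_arr)):
        raise ValueError("order-parameter curve contains undefined values")
    for i in range(len(mu_arr) - 1):
        a, b = m_arr[i], m_arr[i + 1]
        if a == 0.0:
            return CriticalPoint(float(mu_arr[i]), (float(mu_arr[i]), float(mu_arr[i])), True)
        if a * b < 0:
            mu_star = mu_arr[i] + (mu_arr[i + 1] - mu_arr[i]) * a / (a - b)
            return CriticalPoint(float(mu_star), (float(mu_arr[i]), float(mu_arr[i + 1])), True)
    if m_arr[-1] == 0.0:
        return CriticalPoint(float(mu_arr[-1]), (float(mu_arr[-1]), float(mu_arr[-1])), True)
    return CriticalPoint(None, None, False)


@dataclass
class PCAModel:
    """Fixed two-component PCA basis over the conditional genes.

    ``mean_`` is the centring vector, ``components`` the (2, 4) orthonormal
    loadings over (P_CC, P_CD, P_DC, P_DD) and ``explained_variance_ratio``
    the fraction of total variance each component carries.  Signs follow
    the convention: PC1's P_CC loading <= 0, PC2's P_DD loading >= 0.
    """

    mean_: np.ndarray
    components: np.ndarray
    explained_variance_ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.components, columns=["P_CC", "P_CD", "P_DC", "P_DD"], index=["PC1", "PC2"]
        )
        df["explained_variance_ratio"] = self.explained_variance_ratio
        return df


def fit_pca(avg: AverageLOD | np.ndarray) -> PCAModel:
    """Covariance PCA of the conditional genes along an average LOD.

    The input rows are the per-update mean conditional genes (the
    unconditional gene is excluded as neutral); the model keeps the top two
    eigenvectors of the sample covariance.
    """
    X = avg.genes[:, 1:5] if isinstance(avg, AverageLOD) else np.asarray(avg, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise ValueError("expected a (T, 4) matrix of conditional genes")
    if X.shape[0] < 2:
        raise ValueError("need at least two updates to fit a PCA")
    mean = X.mean(axis=0)
    cov = np.cov(X - mean, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise ValueError("degenerate input: conditional genes have zero variance")
    comps = evecs[:, :2].T.copy()
    if comps[0, 0] > 0:
        comps[0] = -comps[0]
    if comps[1, 3] < 0:
        comps[1] = -comps[1]
    return PCAModel(mean, comps, np.clip(evals[:2] / total, 0.0, 1.0))


def _conditional_matrix(genotypes) -> np.ndarray:
    if isinstance(genotypes, np.ndarray):
        X = np.atleast_2d(np.asarray(genotypes, dtype=float))
    else:
        rows = []
        for g in genotypes:
            rows.append(g.conditional if isinstance(g, StrategyGenome) else np.asarray(g, dtype=float))
        X = np.vstack(rows)
    if X.shape[1] != 4:
        raise ValueError("conditional-gene vectors must have length 4")
    return X


def project(model: PCAModel, genotypes) -> np.ndarray:
    """Project conditional-gene vectors (or memory-one genomes) into the
    model's fixed two-component plane; the centring mean maps to (0, 0)."""
    X = _conditional_matrix(genotypes)
    return (X - model.mean_) @ model.components.T


def landmark_projections(model: PCAModel) -> pd.DataFrame:
    """Coordinates of the landmark strategies in the model's plane, for
    annotating trajectory plots."""
    names = sorted(LANDMARKS)
    X = np.array([LANDMARKS[n][1:5] for n in names])
    coords = project(model, X)
    return pd.DataFrame({"name": names, "pc1": coords[:, 0], "pc2": coords[:, 1]})
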