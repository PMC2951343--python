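# ipdevo

Agent-based evolution of **genetically encoded stochastic iterated
Prisoner's Dilemma strategies** in finite spatial and well-mixed
populations, with the line-of-descent toolkit used to characterise the
transition between cooperative and defective evolutionary attractors.

## The problem

Whether cooperation can evolve by natural selection depends on how
reliably a player can predict its opponents. Here each player's strategy
is a genome of cooperation probabilities: an unconditional opening gene
`P_C` plus conditional genes `P_XY` — the probability of cooperating given
that the player's last move against this partner was `X` and the
opponent's reply was `Y` (memory one: `P_C, P_CC, P_CD, P_DC, P_DD`;
memory `k` has `(4^(k+1)−1)/3` genes). Alleles live on a coarse-grained
lattice of `2^b` values (`b ≤ 15` bits; `b = 1` gives the deterministic
strategies).

Players occupy a toroidal grid and play one simultaneous PD round per
update against each of their 8 neighbours, with Axelrod's payoffs
`T, R, P, S = 5, 3, 1, 0`. Each update every player dies with probability
`r` and is replaced by a mutated offspring of a neighbour (spatial) or of
any player (well-mixed), chosen in proportion to lifetime accumulated
score — a Moran-like process with overlapping generations. Mutation hits
each gene as a Poisson process with rate `μ` per replication, redrawing
the allele uniformly from the lattice.

Evolution is read off the **line of descent (LOD)**: the ancestor chain
of a random terminal player back to the all-0.5 founder. Averaging LODs
over replicates and time-averaging the equilibrated window
`[T/2, T − T/10]` yields the **consensus genotype** (the empirical fixed
point) and the **order parameter**

```
m = (π̄_CC − π̄_DD) / (π̄_CC + π̄_DD)
```

the normalised difference of equilibrated mutual-cooperation and
mutual-defection play frequencies. `m > 0.2` marks the cooperative phase,
`m < −0.2` the defective one; `m(μ)` crosses zero at a critical mutation
rate, and low `μ` together with low `r` (long, predictable pairings)
favours cooperation. PCA of the conditional genes along the average LOD,
with components fixed by a low-μ reference trajectory, maps trajectories
and the landmark strategies (TFT, ALLC, ALLD, WSLS, GTFT) into a common
2-D strategy space.

## Worked example

```python
import numpy as np
import ipdevo as ip

# exact long-run play statistics of WSLS against itself
wsls = ip.landmark_genome("WSLS")
print("WSLS vs WSLS stationary play:", np.round(ip.stationary_play_distribution(wsls, wsls), 3))

# a small evolution experiment: 8x8 torus, mu = 2%, r = 2%
cfg = ip.ExperimentConfig(side=8, total_updates=20_000, n_replicates=5,
                          mu=0.02, r=0.02, master_seed=7)
lods, avg = ip.run_experiment_lods(cfg)
cons = ip.consensus_genotype(avg)
m = ip.order_parameter(avg)
print("consensus genotype:", np.round(cons.mean, 3))
print("order parameter m =", round(m, 3), "->", ip.classify_phase(m))
```

prints

```
WSLS vs WSLS stationary play: [1. 0. 0. 0.]
consensus genotype: [0.372 0.269 0.327 0.366 0.38 ]
order parameter m = -0.478 -> defection
```

Two Win-Stay-Lose-Shift players lock into permanent mutual cooperation
(all play mass on CC). The evolution run, by contrast, sits at a 2%
mutation rate on a small grid — an uncertain environment — so the
consensus genotype keeps all cooperation probabilities well below ½ and
the equilibrated line of descent plays far more mutual defection than
mutual cooperation (`m < −0.2`: the defective attractor).

## Command line

```sh
ipdevo run --out runs/coop --side 16 --updates 50000 --replicates 10 \
           --mu 0.005 --r 0.01 --seed 1
ipdevo sweep --out runs/sweep --mus 0.04,0.07,0.10,0.13,0.16 \
             --side 16 --updates 50000 --replicates 10 --bits 1 --seed 3
ipdevo analyze runs/coop --pca-reference runs/coop
```

`run` persists one ancestry log per replicate plus all derived tables
(per-replicate LODs, average LOD, consensus genotype, order parameter in
both normalisations, PCA model/trajectory/landmarks, manifest); `analyze`
recomputes every derived table from stored ancestry logs without
re-simulating. The full published scale (32×32, 500,000 updates, 80
replicates) is available behind `--paper-scale`.

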