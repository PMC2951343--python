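# Methods

## Model

`ipdevo` simulates Darwinian evolution of stochastic iterated Prisoner's
Dilemma (IPD) strategies in a finite population with overlapping
generations.

**Strategies as genomes.** A memory-`k` strategy is a genome of
`L(k) = (4^(k+1) − 1)/3` cooperation probabilities: one unconditional gene
`P_C` consulted when a player has no joint history with the current
partner, and, for each history depth `h = 1..k`, a block of `4^h`
conditional genes indexed by the last `h` joint outcomes (CC, CD, DC, DD,
own move first). Memory one has the five genes
`(P_C, P_CC, P_CD, P_DC, P_DD)`; memory two has 21, memory three 85.
Allele values are coarse-grained to a lattice of `2^b` equally spaced
probabilities `i/(2^b − 1)`, `b ∈ [1, 15]` bits; the lattice includes 0 and
1 exactly, so `b = 1` recovers the deterministic strategies. The endpoints
are a design choice — the alternative lattice `(i + 1/2)/2^b` would exclude
the deterministic corner strategies that the 1-bit limit is meant to
reach. The founder ("random") genotype has every gene exactly 0.5, stored
as-is even when off-lattice: coarse-graining constrains mutant alleles,
not the seed.

**Game.** Players sit on a `side × side` torus (default 32, so
N = 1024) and each update play one simultaneous PD round with each of
their 8 Moore neighbours — `4N` games per update, every edge exactly once.
Payoffs are Axelrod's `T, R, P, S = 5, 3, 1, 0` (temptation, reward,
punishment, sucker), satisfying `T > R > P > S` and `R > (S + T)/2`. Both
endpoints of an edge decide from the pre-round pair state, so the edge
evaluation order is irrelevant. Each player's lifetime joint-outcome
counts are its phenotype; normalised they are the play statistics
`π_CC, π_CD, π_DC, π_DD`.

**Selection (Moran-like).** After the play phase each player is
independently marked dead with probability `r` (the replacement rate;
default 1% per update). Each vacancy is refilled by an offspring of a
parent drawn with probability proportional to lifetime accumulated score
from the candidate pool: the vacancy's 8 neighbours (spatial structure) or
all `N − 1` other players (well-mixed — note play remains local in both
structures; only the parental pool differs). Players marked dead in the
same update are never candidates; if a vacancy's whole spatial pool is
dead (probability ≪ 1e−8 at r = 1%) the parent is drawn uniformly from all
survivors, and if no one survives the site is left untouched. When every
candidate's score is zero the draw is uniform. Newborns start with score
0, empty play counts, fresh pair states on all 8 incident edges (both the
newborn *and* the surviving incumbent greet each other through the
unconditional gene — the model's reading of partner replacement), and
first play in the following update.

**Mutation.** At replication each gene independently receives a
Poisson(`μ`)-distributed number of mutation events; a gene hit at least
once is replaced by a uniform draw from the allele lattice. Because later
draws on the same gene overwrite earlier ones, the net effect is a single
redraw with probability `1 − exp(−μ)`, which is exactly how the simulation
kernel implements it; the stand-alone `mutate()` operation draws true
Poisson counts. A μ-schedule (list of `(start_update, μ)` pairs) switches
the rate at the replacement phase of the named update.

**Expected pairing length.** An edge's history survives while both
endpoints do, so pairings last `≈ 1/(2r)` rounds (50 at r = 1%); `r` is
therefore the knob that controls how much information neighbours can
gather about each other, and the unconditional gene is consulted so rarely
that it drifts neutrally (uniform limit: mean 1/2, variance 1/12).

## Line-of-descent analysis

Each run logs every organism that ever lived (parent, birth update,
genome, lifetime play counts). The line of descent (LOD) is the ancestor
chain of one terminal player sampled uniformly by the run's own random
stream. Per-update attribution is birth-inclusive: the organism "at
update t" is the one on the chain with `birth_update ≤ t` before its
successor's birth. Averaging genomes and play statistics per update
across replicate LODs gives the average LOD; organisms that never played
(born in the final update) have undefined play statistics and are excluded
from the average, not imputed.

The consensus genotype is the per-gene mean (and variance) of the average
LOD over the window `[T/2, T − T/10]`. The tail discard generalises the
fixed 50,000-update discard used at T = 500,000 proportionally, because
its purpose is to drop the stretch of the LOD past the most recent common
ancestor, whose expected length scales with the run's coalescence time
rather than being an absolute constant.

## Order parameter and phase diagrams

The attractor's character is summarised by
`m = (π̄_CC − π̄_DD)/(π̄_CC + π̄_DD)`, the normalised difference between
window-averaged mutual-cooperation and mutual-defection frequencies on the
average LOD (window = consensus window by default). `m ∈ [−1, 1]`,
antisymmetric under CC↔DD exchange, undefined (NaN) when no mutual play
occurred. A variant normalising by all four play frequencies is available
(`formula="all"`); the default normalises by mutual play only, which keeps
the full `[−1, 1]` range. Phase classification uses the bands m > 0.2
(cooperation), m < −0.2 (defection), transition between.

`phase_sweep` runs the full pipeline per (μ, r) grid cell with an
independent derived master seed per cell and reports the replicate mean of
m with two standard errors (each replicate's m computed from its own LOD's
windowed play statistics — the mean of per-replicate ratios, whereas the
headline `order_parameter` is the ratio of window means on the average
LOD; both are exposed). `critical_mu` locates the zero crossing of m(μ)
by linear interpolation between the first sign-changing grid points and
reports the bracketing interval; a curve with no sign change returns a
no-crossing result rather than raising.

## PCA trajectories

Strategy-space trajectories project the four conditional genes of the
average LOD onto the two leading eigenvectors of their sample covariance
(`P_C` excluded as neutral). Components are kept fixed from a reference
(low-mutation-rate) trajectory so that trajectories at other rates and the
landmark strategies — TFT (1,0,1,0), ALLC, ALLD, WSLS (1,0,0,1), GTFT
(1,0.333,1,0), START (0.5,…) — occupy stable positions. Sign convention:
PC1's `P_CC` loading ≤ 0, PC2's `P_DD` loading ≥ 0. Landmark opening
moves (`P_C`) are a convention (1 for TFT/ALLC/WSLS/GTFT, 0 for ALLD, 0.5
for START); they are analysis fixtures whose first gene is neutral anyway.

## Numerical choices

* **Markov oracle.** Two memory-one strategies induce a Markov chain on
  the four joint outcomes whose transition probabilities are products of
  the players' conditional genes; `stationary_play_distribution` solves
  `πP = π` by least squares after mixing each gene with `ε = 1e−9` toward
  0.5, which makes strictly deterministic (reducible/periodic) chains
  ergodic and the stationary vector unique and continuous in the genes.
* **Memory-`k` warm-up.** With `h < k` rounds of shared history the
  depth-`h` gene block is consulted, using all information available.
* **Determinism.** Each replicate uses
  `SeedSequence(master_seed, spawn_key=(replicate,))`; the kernels draw
  from the generator in a fixed order, so `(config, replicate)` determines
  every output bit. Sweep cells derive independent 31-bit master seeds
  from the base seed.
* **Statistical tests.** Consecutive rounds of a pair are autocorrelated,
  so oracle-vs-simulation comparisons use batch-means standard errors
  (100 × 1000-round batches), not multinomial ones. The neutral-drift
  uniform law is checked on the distribution pooled across replicates:
  within one replicate the coalesced terminal population under-disperses
  (observed within-replicate variance ≈ 0.04 at desk scale), while the
  pooled second moment about 1/2 approaches 1/12.
* **Performance.** The per-update play and replacement loops are
  numba-compiled; a 16×16 run executes ~50,000 updates in a few seconds,
  which is what makes replicate sweeps practical on one CPU.

## Study scales and what they show

Default configuration mirrors the full experiment (32×32, 500,000
updates, 80 replicates, r = 1%, 15 bits, memory one); the CLI refuses it
without `--paper-scale` because it takes hours. The test suite and the
acceptance script use a desk scale: 16×16, 50,000 updates, 10 replicates.

The desk scale reproduces the model's bookkeeping, neutral drift, the
defective regime, the 1-bit deterministic transition (zero crossing of
m(μ) near μ = 10%), and μ-regime tracking. It does **not** reach the
cooperative attractor at μ = 0.5%: the attractor exists — at 32×32 ×
250,000 updates this implementation measures consensus `P_CC = 0.993`,
m = +0.83 — but the time to nucleate cooperation from the random founder
is governed by the mutation supply `N·r·μ`, which shrinks with population
size, so at 16×16 most replicates are still in the defective-leaning
transient at update 50,000 (≈0.5 gene-redraws per gene per lineage) and
only become predominantly cooperative by ~100,000 updates. Desk-scale
numbers for the cooperative consensus and its PCA structure therefore
understate the equilibrated values, and the acceptance script reports
them as computed. The μ-schedule experiment (5% → 0.5% at mid-run) keeps
the full 32×32 grid — regime tracking is driven by the mutation supply
`N·r·μ`, and at 16×16 the invasion of cooperation into an adapted
defective background is too slow and too stochastic to resolve — scaling
down only the run length (200,000 updates) and replicate count (10); m is
windowed over the last quarter of each half.

## Limitations

* The simulator models exactly the published process: square torus, Moore
  play neighbourhood, Bernoulli removal, fitness = lifetime score.
  Arbitrary graphs, payoff noise, recombination, windowed fitness and
  memory > 3 are out of scope.
* The exact form of the order parameter was adopted from its verbal
  definition (normalised difference of mutual-play frequencies); the
  all-plays normalisation is provided as a variant.
* Whether the surviving incumbent of a replaced pair should keep
  consulting its conditional gene on the stale history is ambiguous in the
  source description; this implementation voids the history for both
  endpoints.
* Small populations are strongly bistable near the transition: replicate
  order parameters of ±0.8 at the same parameters are common at 16×16, so
  phase boundaries at desk scale carry wide error bars.
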