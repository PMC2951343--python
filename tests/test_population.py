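import dataclasses

import numpy as np
import pytest

import ipdevo as ip
from ipdevo.population import (
    ExperimentConfig,
    build_edges,
    games_per_update,
    init_population,
    moore_neighbors,
    play_phase,
    replacement_phase,
    replacement_pool_size,
    replicate_rng,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(side=2),
            dict(structure="hexagonal"),
            dict(r=0.0),
            dict(r=1.5),
            dict(mu=-0.1),
            dict(memory_order=0),
            dict(resolution_bits=16),
            dict(mu_schedule=((1, 0.05), (0, 0.01))),  # unsorted
            dict(mu_schedule=((10, 0.05),)),  # does not cover the start
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        base = dict(side=8, total_updates=10)
        base.update(kw)
        with pytest.raises(ValueError):
            ExperimentConfig(**base)

    def test_mu_schedule_lookup(self):
        cfg = ExperimentConfig(
            side=8, total_updates=100, mu_schedule=((1, 0.05), (50, 0.005), (80, 0.2))
        )
        assert cfg.mu_at(1) == 0.05
        assert cfg.mu_at(49) == 0.05
        assert cfg.mu_at(50) == 0.005  # takes effect at its start update
        assert cfg.mu_at(100) == 0.2

    def test_yaml_round_trip(self, tmp_path):
        cfg = ExperimentConfig(side=8, structure="well_mixed", mu=0.02, total_updates=50,
                               n_replicates=3, master_seed=99)
        cfg.to_yaml(tmp_path / "c.yaml")
        assert ExperimentConfig.from_yaml(tmp_path / "c.yaml") == cfg


class TestGeometry:
    def test_eight_distinct_wrapping_neighbors(self):
        nbrs = moore_neighbors(4)
        assert nbrs.shape == (16, 8)
        for i in range(16):
            assert len(set(nbrs[i])) == 8
            assert i not in nbrs[i]
        # symmetry: j neighbor of i <=> i neighbor of j
        for i in range(16):
            for j in nbrs[i]:
                assert i in nbrs[j]

    def test_edge_count_and_incidence(self):
        edges, inc = build_edges(4)
        assert edges.shape == (64, 2)  # 8 * 16 / 2
        assert inc.shape == (16, 8)
        # every edge appears in both endpoints' incidence lists
        for e, (a, b) in enumerate(edges):
            assert e in inc[a] and e in inc[b]

    def test_games_and_pools(self):
        assert games_per_update(32) == 4096
        cfg = ExperimentConfig(side=32, total_updates=1)
        assert replacement_pool_size(cfg) == 8
        wm = dataclasses.replace(cfg, structure="well_mixed")
        assert replacement_pool_size(wm) == 1023


class TestInitPopulation:
    def test_seeded_with_random_genotype(self):
        cfg = ExperimentConfig(side=4, total_updates=1)
        pop = init_population(cfg)
        assert pop.n_players == 16
        assert np.all(pop.genes == 0.5)
        assert np.all(pop.scores == 0)
        assert np.all(pop.hlen == 0)


class TestPlayPhase:
    def _homogeneous(self, genes, side=4):
        cfg = ExperimentConfig(side=side, total_updates=1, mu=0.0)
        pop = init_population(cfg)
        pop.genes[:] = genes
        return cfg, pop

    def test_all_defect_gains_8P_per_update(self, rng):
        cfg, pop = self._homogeneous(np.zeros(5))
        play_phase(pop, cfg.payoffs, rng)
        assert np.all(pop.scores == 8.0)  # 8 games x P = 1
        assert np.all(pop.counts[:, 3] == 8)

    def test_all_cooperate_gains_8R_per_update(self, rng):
        cfg, pop = self._homogeneous(np.ones(5))
        for _ in range(3):
            play_phase(pop, cfg.payoffs, rng)
        assert np.all(pop.scores == 3 * 24.0)  # 8 games x R = 3 per update
        assert np.all(pop.counts[:, 0] == 24)

    def test_memory_two_consults_deepest_available_block(self, rng):
        # genome: open with C; after one shared round cooperate only on CC;
        # after two rounds defect always.  Homogeneous population:
        # update 1 all CC (gene 0), update 2 all CC (memory-1 block),
        # update 3 onward all DD (memory-2 block) -> scores 24, 24, 8, 8.
        cfg = ExperimentConfig(side=4, total_updates=1, memory_order=2, mu=0.0)
        pop = init_population(cfg)
        genes = np.zeros(21)
        genes[0] = 1.0
        genes[1] = 1.0  # P_CC of the memory-1 block
        pop.genes[:] = genes
        expected = [24.0, 48.0, 56.0, 64.0]
        for total in expected:
            play_phase(pop, cfg.payoffs, rng)
            assert np.all(pop.scores == total)

    def test_score_conservation_matches_play_counts(self, rng):
        cfg = ExperimentConfig(side=5, total_updates=1)
        pop = init_population(cfg)
        pop.genes[:] = rng.random(pop.genes.shape)
        play_phase(pop, cfg.payoffs, rng)
        # each player logs one outcome per game: totals are 8 per player
        assert np.all(pop.counts.sum(axis=1) == 8)
        cc_games = pop.counts[:, 0].sum() / 2
        mixed_games = pop.counts[:, 1].sum()  # one CD entry per mixed game
        dd_games = pop.counts[:, 3].sum() / 2
        assert cc_games + mixed_games + dd_games == games_per_update(5)
        assert pop.scores.sum() == 6 * cc_games + 5 * mixed_games + 2 * dd_games


class TestReplacementPhase:
    def test_no_mutation_keeps_homogeneous_composition(self, rng):
        cfg = ExperimentConfig(side=4, total_updates=1, mu=0.0, r=0.5)
        pop = init_population(cfg)
        pop.genes[:] = np.array([1.0, 1.0, 0.0, 1.0, 0.0])
        play_phase(pop, cfg.payoffs, rng)
        for _ in range(20):
            replacement_phase(pop, cfg, rng)
        assert np.all(pop.genes == np.array([1.0, 1.0, 0.0, 1.0, 0.0]))

    def test_newborns_reset_scores_counts_and_edges(self, rng):
        cfg = ExperimentConfig(side=4, total_updates=1, mu=0.0, r=0.3)
        pop = init_population(cfg)
        play_phase(pop, cfg.payoffs, rng)
        before = pop.org_of_site.copy()
        nb = replacement_phase(pop, cfg, rng)
        born = pop.org_of_site != before
        assert nb == born.sum()
        assert np.all(pop.scores[born] == 0)
        assert np.all(pop.counts[born] == 0)
        for v in np.flatnonzero(born):
            assert np.all(pop.hlen[pop.incident_edges[v]] == 0)

    def test_uniform_choice_when_all_scores_zero(self, rng):
        # before any play everyone has score 0: replacement must still work
        cfg = ExperimentConfig(side=4, total_updates=1, mu=0.0, r=0.5)
        pop = init_population(cfg)
        nb = replacement_phase(pop, cfg, rng)
        assert nb > 0


class TestRun:
    def test_zero_updates_logs_only_seeds(self):
        cfg = ExperimentConfig(side=4, total_updates=0, n_replicates=1)
        log = ip.run(cfg).log
        assert log.n_organisms == log.n_seed == 16
        assert np.all(log.alive)

    def test_bit_identical_reruns(self):
        cfg = ExperimentConfig(side=5, total_updates=150, mu=0.05, r=0.05, master_seed=17)
        a, b = ip.run(cfg), ip.run(cfg)
        assert np.array_equal(a.log.genomes, b.log.genomes)
        assert np.array_equal(a.log.parent_id, b.log.parent_id)
        assert np.array_equal(a.log.play_counts, b.log.play_counts)
        assert a.log.sampled_terminal == b.log.sampled_terminal

    def test_replicates_differ(self):
        cfg = ExperimentConfig(side=5, total_updates=150, mu=0.05, r=0.05, master_seed=17)
        a = ip.run(cfg, replicate=0)
        b = ip.run(cfg, replicate=1)
        assert not np.array_equal(a.log.genomes, b.log.genomes)

    def test_population_size_constant_and_parents_valid(self, tiny_run):
        cfg, results = tiny_run
        log = results[0].log
        assert log.terminal_ids.shape == (cfg.n_players,)
        non_seed = log.parent_id >= 0
        # every parent was born strictly before its child
        assert np.all(
            log.birth_update[log.parent_id[non_seed]] < log.birth_update[non_seed]
        )

    def test_lifetime_play_counts_of_survivors(self, tiny_run):
        cfg, results = tiny_run
        log = results[0].log
        # a terminal organism born at update t first plays at t+1: 8 games
        # per surviving update
        totals = log.play_counts[log.terminal_ids].sum(axis=1)
        expected = 8 * (cfg.total_updates - log.birth_update[log.terminal_ids])
        assert np.array_equal(totals, expected)

    def test_mu_schedule_gates_mutation(self):
        cfg = ExperimentConfig(
            side=5, total_updates=120, mu_schedule=((1, 0.0), (61, 2.0)), r=0.2,
            master_seed=3,
        )
        log = ip.run(cfg).log
        early = (log.birth_update > 0) & (log.birth_update <= 60)
        late = log.birth_update > 60
        assert np.all(log.genomes[early] == 0.5)  # mu = 0: perfect copies
        assert np.any(log.genomes[late] != 0.5)

    def test_well_mixed_structure_runs(self):
        cfg = ExperimentConfig(
            side=5, structure="well_mixed", total_updates=100, mu=0.05, r=0.1,
            master_seed=4,
        )
        log = ip.run(cfg).log
        assert log.n_organisms > log.n_seed

    def test_summaries_do_not_alter_results(self):
        cfg = ExperimentConfig(side=5, total_updates=100, mu=0.05, r=0.05, master_seed=6)
        plain = ip.run(cfg)
        with_sum = ip.run(cfg, record_summaries=True, summary_every=10)
        assert np.array_equal(plain.log.genomes, with_sum.log.genomes)
        assert len(with_sum.summaries) == 10
        assert (with_sum.summaries["frac_coop"].between(0, 1)).all()


def test_ancestry_log_tsv_round_trip(tmp_path, tiny_run):
    _, results = tiny_run
    log = results[0].log
    log.write_tsv(tmp_path / "log.tsv")
    back = ip.AncestryLog.read_tsv(tmp_path / "log.tsv")
    assert np.array_equal(back.parent_id, log.parent_id)
    assert np.array_equal(back.genomes, log.genomes)
    assert np.array_equal(back.play_counts, log.play_counts)
    assert np.array_equal(back.terminal_ids, log.terminal_ids)
    assert back.sampled_terminal == log.sampled_terminal
    assert back.total_updates == log.total_updates


def test_replicate_rng_streams_are_stable():
    a = replicate_rng(42, 3).random(4)
    b = replicate_rng(42, 3).random(4)
    c = replicate_rng(42, 4).random(4)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_neutral_first_gene_drifts_uniform():
    """The unconditional gene is consulted only on fresh pairings, so it
    should drift: pooled across replicates its distribution approaches a
    uniform on [0, 1] (mean 1/2, variance 1/12)."""
    vals = []
    for i in range(6):
        cfg = ExperimentConfig(side=8, total_updates=4000, mu=0.2, r=0.05, master_seed=88)
        log = ip.run(cfg, replicate=i).log
        vals.append(log.genomes[log.terminal_ids, 0])
    pooled = np.concatenate(vals)
    rep_means = np.array([v.mean() for v in vals])
    se_mean = rep_means.std(ddof=1) / np.sqrt(len(vals))
    assert abs(pooled.mean() - 0.5) < 3 * se_mean + 0.02
    rep_sq = np.array([((v - 0.5) ** 2).mean() for v in vals])
    se_var = rep_sq.std(ddof=1) / np.sqrt(len(vals))
    assert abs(((pooled - 0.5) ** 2).mean() - 1 / 12) < 3 * se_var + 0.01
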