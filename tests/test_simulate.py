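"""Coalescent simulator behaviour: split-time bounds, closed-form
expectations, determinism, and an independent msprime cross-check."""

import numpy as np
import pytest

from straitpop import IMModel, LocusSpec, simulate_dataset
from straitpop import diversity as dv
from straitpop import simulate as sim


def one_deme_model(ne=1000.0, mu=1e-6):
    """Panmictic reduction: all samples in HS, splits far in the past."""
    return IMModel(ne_hs=ne, ne_c=ne, ne_ti=ne, t0=1e12, t1=2e12, mu=mu)


class TestGenealogy:
    def test_single_leaf_no_coalescence(self):
        g = sim.simulate_genealogy(IMModel(), LocusSpec("x", 100), (1, 0, 0), 1)
        assert g.n_nodes == 1
        assert g.total_branch_length() == 0.0

    def test_cross_deme_tmrca_bounded_by_split(self):
        model = IMModel()
        spec = LocusSpec("x", 100)
        for seed in range(20):
            g = sim.simulate_genealogy(model, spec, (0, 1, 1), seed)
            assert g.tmrca() >= model.t0 / model.generation_time

    def test_hs_vs_c_tmrca_bounded_by_t1(self):
        model = IMModel()
        g = sim.simulate_genealogy(model, LocusSpec("x", 100), (1, 1, 0), 5)
        assert g.tmrca() >= model.t1 / model.generation_time

    def test_identical_seed_identical_genealogy(self):
        model = IMModel()
        spec = LocusSpec("x", 100)
        g1 = sim.simulate_genealogy(model, spec, (3, 3, 3), 42)
        g2 = sim.simulate_genealogy(model, spec, (3, 3, 3), 42)
        assert np.array_equal(g1.parent, g2.parent)
        assert np.array_equal(g1.time, g2.time)

    def test_zero_samples_error(self):
        with pytest.raises(ValueError):
            sim.simulate_genealogy(IMModel(), LocusSpec("x", 10), (0, 0, 0), 1)

    def test_panmictic_pairwise_coalescence_mean(self, rng):
        # E[T2] = 2N generations for a sample of two
        N = 500.0
        model = one_deme_model(ne=N)
        spec = LocusSpec("x", 10)
        times = [
            sim.simulate_genealogy(model, spec, (2, 0, 0), rng).tmrca()
            for _ in range(2000)
        ]
        se = np.std(times) / np.sqrt(len(times))
        assert abs(np.mean(times) - 2 * N) < 3 * se

    def test_inheritance_scale_shrinks_coalescence_times(self, rng):
        N = 1000.0
        model = one_deme_model(ne=N)
        nuc = LocusSpec("nuc", 10, inheritance_scale=1.0)
        cp = LocusSpec("cp", 10, inheritance_scale=0.25)
        t_nuc = np.mean([
            sim.simulate_genealogy(model, nuc, (2, 0, 0), rng).tmrca()
            for _ in range(500)
        ])
        t_cp = np.mean([
            sim.simulate_genealogy(model, cp, (2, 0, 0), rng).tmrca()
            for _ in range(500)
        ])
        assert t_cp < t_nuc

    def test_migration_allows_pre_split_coalescence(self, rng):
        # with strong C<->TI migration some pairs coalesce before t0
        model = IMModel(migration={("C", "TI"): 20.0, ("TI", "C"): 20.0},
                        ne_c=1e4, ne_ti=1e4, t0=1e6, t1=2e6)
        spec = LocusSpec("x", 10)
        tm = [sim.simulate_genealogy(model, spec, (0, 1, 1), rng).tmrca()
              for _ in range(50)]
        assert min(tm) < model.t0


class TestMutations:
    def test_zero_rate_identical_sequences(self):
        g = sim.simulate_genealogy(IMModel(), LocusSpec("x", 50), (2, 2, 2), 3)
        aln = sim.drop_mutations(g, LocusSpec("x", 50), mu=0.0, seed=4)
        assert len(set(aln.sequences)) == 1

    def test_single_branch_poisson_mean(self, rng):
        # two leaves in one deme: S ~ Poisson(2 * tmrca * mu * L)
        model = one_deme_model(ne=200.0)
        spec = LocusSpec("x", 200)
        mu = 5e-6
        exp_counts, obs_counts = [], []
        for _ in range(2000):
            g = sim.simulate_genealogy(model, spec, (2, 0, 0), rng)
            aln = sim.drop_mutations(g, spec, mu, rng)
            obs_counts.append(dv.diversity(aln).S)
            exp_counts.append(2 * g.tmrca() * mu * spec.length)
        se = np.std(obs_counts) / np.sqrt(len(obs_counts))
        assert abs(np.mean(obs_counts) - np.mean(exp_counts)) < 3 * se

    def test_saturation_raises(self):
        model = one_deme_model(ne=5000.0, mu=1e-2)
        spec = LocusSpec("x", 5)
        with pytest.raises(sim.SaturationError):
            for seed in range(20):
                g = sim.simulate_genealogy(model, spec, (5, 0, 0), seed)
                sim.drop_mutations(g, spec, model.mu, seed)

    def test_jukes_cantor_runs_and_matches_alphabet(self, rng):
        model = one_deme_model(ne=800.0)
        spec = LocusSpec("x", 100, mutation_model="jukes_cantor")
        g = sim.simulate_genealogy(model, spec, (4, 0, 0), rng)
        aln = sim.drop_mutations(g, spec, 1e-5, rng)
        assert set("".join(aln.sequences)) <= set("ACGT")

    def test_indels_leave_gap_runs(self, rng):
        model = one_deme_model(ne=800.0)
        spec = LocusSpec("x", 200, indel_rate=2e-5)
        g = sim.simulate_genealogy(model, spec, (4, 0, 0), rng)
        aln = sim.drop_mutations(g, spec, 1e-6, rng)
        assert "-" in "".join(aln.sequences)


class TestDataset:
    def test_seed_reproducibility_byte_identical(self, tmp_path):
        from straitpop.alignment import write_fasta_alignment
        model = IMModel()
        loci = [LocusSpec("l1", 300), LocusSpec("cp", 300, inheritance_scale=0.25)]
        outs = []
        for run in range(2):
            alns, _ = simulate_dataset(model, loci, (3, 3, 3), seed=99)
            p = tmp_path / f"run{run}.fasta"
            write_fasta_alignment(alns[0], p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_population_map_matches_samples(self):
        alns, pmap = simulate_dataset(
            IMModel(), [LocusSpec("l1", 100)], (4, 2, 2), seed=7,
            populations_per_deme=2,
        )
        assert set(pmap.sample_ids) == set(alns[0].sample_ids)
        assert set(pmap.groups()) == {"HS", "C", "TI"}
        assert len([p for p in pmap.populations() if p.startswith("HS")]) == 2

    def test_locus_genealogies_independent(self, rng):
        model = one_deme_model(ne=300.0, mu=5e-6)
        loci = [LocusSpec("a", 400), LocusSpec("b", 400)]
        alns, _ = simulate_dataset(model, loci, (6, 0, 0), seed=11)
        assert alns[0].sequences != alns[1].sequences

    def test_cpdna_less_diverse_than_nuclear(self, rng):
        model = one_deme_model(ne=400.0, mu=2e-6)
        pis = {"nuc": [], "cp": []}
        for _ in range(300):
            alns, _ = simulate_dataset(
                model,
                [LocusSpec("nuc", 300), LocusSpec("cp", 300, inheritance_scale=0.25)],
                (6, 0, 0), seed=rng,
            )
            pis["nuc"].append(dv.diversity(alns[0]).pi)
            pis["cp"].append(dv.diversity(alns[1]).pi)
        assert np.mean(pis["cp"]) < np.mean(pis["nuc"])


class TestNullMachinery:
    def test_batched_and_tree_nulls_agree(self, rng):
        n, theta = 12, 4.0
        kbar_b, S_b = sim.neutral_pi_s(n, theta, 4000, rng)
        tree = [sim.neutral_tree_stats(n, theta, rng) for _ in range(4000)]
        kbar_t = [t[0] for t in tree]
        S_t = [t[1] for t in tree]
        se = np.std(S_b) / np.sqrt(len(S_b)) + np.std(S_t) / np.sqrt(len(S_t))
        assert abs(np.mean(S_b) - np.mean(S_t)) < 3 * se
        se_k = np.std(kbar_b) / np.sqrt(len(kbar_b)) + np.std(kbar_t) / np.sqrt(len(kbar_t))
        assert abs(np.mean(kbar_b) - np.mean(kbar_t)) < 3 * se_k

    def test_expected_segregating_sites(self, rng):
        n, theta = 10, 5.0
        _, S = sim.neutral_pi_s(n, theta, 4000, rng)
        want = theta * dv.a1_of(n)
        se = np.std(S) / np.sqrt(len(S))
        assert abs(np.mean(S) - want) < 3 * se


class TestMsprimeCrossCheck:
    """Independent oracle: the same IM history configured in msprime."""

    def test_mean_tmrca_matches_msprime(self, rng):
        msprime = pytest.importorskip("msprime")
        model = IMModel(ne_hs=2000, ne_c=1000, ne_ti=1500, t0=4000.0, t1=8000.0)
        spec = LocusSpec("x", 10)
        reps = 400
        ours = np.array([
            sim.simulate_genealogy(model, spec, (2, 2, 2), rng).tmrca()
            for _ in range(reps)
        ])

        dem = msprime.Demography()
        sizes = model.size_of
        dem.add_population(name="HS", initial_size=model.ne_hs)
        dem.add_population(name="C", initial_size=model.ne_c)
        dem.add_population(name="TI", initial_size=model.ne_ti)
        dem.add_population(name="A1", initial_size=sizes["A1"])
        dem.add_population(name="A2", initial_size=sizes["A2"])
        dem.add_population_split(time=model.t0, derived=["C", "TI"], ancestral="A1")
        dem.add_population_split(time=model.t1, derived=["HS", "A1"], ancestral="A2")
        theirs = []
        for ts in msprime.sim_ancestry(
            samples={"HS": 1, "C": 1, "TI": 1}, demography=dem, ploidy=2,
            num_replicates=reps, random_seed=1234,
        ):
            theirs.append(ts.first().time(ts.first().root))
        theirs = np.array(theirs)
        se = ours.std() / np.sqrt(reps) + theirs.std() / np.sqrt(reps)
        assert abs(ours.mean() - theirs.mean()) < 3 * se
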