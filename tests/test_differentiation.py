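"""AMOVA, pairwise Phi-ST and divergence summaries against brute-force
oracles and exchangeability properties."""

import itertools
import math

import numpy as np
import pytest

from straitpop import LocusAlignment, PopulationMap
from straitpop import differentiation as df
from tests.conftest import grouped_alignment, random_alignment


def oracle_amova(d2, pop_labels, group_labels):
    """Independent AMOVA implementation: explicit double-loop sums of
    squared distances and the standard normal equations solved with
    numpy.linalg.solve."""
    n = d2.shape[0]
    pops = sorted(set(pop_labels))
    groups = sorted(set(group_labels))
    grp_of_pop = {}
    for p, g in zip(pop_labels, group_labels):
        grp_of_pop[p] = g

    def ssd(indices_sets):
        total = 0.0
        for idx in indices_sets:
            s = 0.0
            for i, j in itertools.combinations(idx, 2):
                s += d2[i, j]
            total += s / len(idx)
        return total

    all_idx = [list(range(n))]
    pop_idx = [[i for i in range(n) if pop_labels[i] == p] for p in pops]
    grp_idx = [[i for i in range(n) if group_labels[i] == g] for g in groups]
    ssd_t = ssd(all_idx)
    ssd_wp = ssd(pop_idx)
    ssd_wg = ssd(grp_idx)
    ss = np.array([ssd_t - ssd_wg, ssd_wg - ssd_wp, ssd_wp])
    P, G = len(pops), len(groups)
    dfree = np.array([G - 1, P - G, n - P], dtype=float)
    ms = ss / dfree
    n_p = {p: pop_labels.count(p) for p in pops}
    n_g = {g: group_labels.count(g) for g in groups}
    sum_np2_over_ng = sum(
        sum(n_p[p] ** 2 for p in pops if grp_of_pop[p] == g) / n_g[g]
        for g in groups
    )
    n1 = (n - sum_np2_over_ng) / (P - G)
    n2 = (sum_np2_over_ng - sum(v ** 2 for v in n_p.values()) / n) / (G - 1)
    n3 = (n - sum(v ** 2 for v in n_g.values()) / n) / (G - 1)
    # E[MS] = A @ sigma2  with sigma2 = (a, b, c)
    A = np.array([
        [n3, n2, 1.0],
        [0.0, n1, 1.0],
        [0.0, 0.0, 1.0],
    ])
    return np.linalg.solve(A, ms)


class TestDistanceMatrix:
    def test_two_sequences(self):
        aln = LocusAlignment.from_pairs("x", [("a", "AAAA"), ("b", "AATT")])
        d, L = df.pairwise_distance_matrix(aln)
        assert d[0, 1] == 2 and L == 4

    def test_identical_gives_zero_matrix(self):
        aln = LocusAlignment.from_pairs("x", [(f"s{i}", "ACGT") for i in range(4)])
        d, _ = df.pairwise_distance_matrix(aln)
        assert not d.any()

    def test_matches_brute_force_recount(self, rng):
        for _ in range(50):
            aln = random_alignment(rng, int(rng.integers(2, 10)),
                                   int(rng.integers(4, 25)), alphabet="ACGT-N")
            try:
                d, _ = df.pairwise_distance_matrix(aln)
            except ValueError:
                continue
            cols = [j for j in range(aln.length)
                    if all(s[j] not in "-N" for s in aln.sequences)]
            for i, j in itertools.combinations(range(aln.n), 2):
                want = sum(aln.sequences[i][c] != aln.sequences[j][c] for c in cols)
                assert d[i, j] == want
            assert np.array_equal(d, d.T)


class TestAmova:
    def test_fixed_difference_phist_one(self):
        aln = LocusAlignment.from_pairs(
            "x", [("a1", "AA"), ("a2", "AA"), ("b1", "TT"), ("b2", "TT")]
        )
        pmap = PopulationMap.from_records([
            ("a1", "P1", "G1", 0, 0), ("a2", "P1", "G1", 0, 0),
            ("b1", "P2", "G2", 1, 1), ("b2", "P2", "G2", 1, 1),
        ])
        res = df.amova(aln, pmap, permutations=50, seed=0)
        assert res.phi_st == pytest.approx(1.0)

    def test_identical_groups_give_null_phi_ct(self, rng):
        # two groups with identical composition: no among-group signal
        seqs = [("".join(rng.choice(list("ACGT"), size=20))) for _ in range(4)]
        records, pairs = [], []
        for g in ("G1", "G2"):
            for p in (1, 2):
                for k, s in enumerate(seqs):
                    sid = f"{g}_{p}_{k}"
                    records.append((sid, f"{g}P{p}", g, 0, 0))
                    pairs.append((sid, s))
        aln = LocusAlignment.from_pairs("x", pairs)
        pmap = PopulationMap.from_records(records)
        res = df.amova(aln, pmap, permutations=200, seed=1)
        assert abs(res.phi_ct) < 1e-9
        assert res.p_ct > 0.05

    def test_components_match_independent_oracle(self, rng, three_group_pmap):
        for _ in range(50):
            aln = grouped_alignment(rng, three_group_pmap)
            res = df.amova(aln, three_group_pmap, permutations=1, seed=0)
            d, _ = df.pairwise_distance_matrix(aln)
            pop_of = three_group_pmap.population_of()
            grp_of = three_group_pmap.group_of()
            want = oracle_amova(
                d.astype(float),
                [pop_of[s] for s in aln.sample_ids],
                [grp_of[s] for s in aln.sample_ids],
            )
            assert np.allclose(res.sigma2, want, rtol=1e-9, atol=1e-12)

    def test_percentages_sum_and_df(self, rng, three_group_pmap):
        aln = grouped_alignment(rng, three_group_pmap)
        res = df.amova(aln, three_group_pmap, permutations=10, seed=0)
        assert sum(res.percent) == pytest.approx(100.0, abs=0.01)
        assert sum(res.df) == aln.n - 1

    def test_strong_structure_significant(self, rng, three_group_pmap):
        aln = grouped_alignment(rng, three_group_pmap, divergence=0.3)
        res = df.amova(aln, three_group_pmap, permutations=500, seed=2)
        assert res.phi_st > 0.5
        assert res.p_st < 0.01

    def test_exhaustive_ct_flag_with_few_populations(self, rng, three_group_pmap):
        # 6 populations in 3 groups of 2: only 90 distinct reassignments
        aln = grouped_alignment(rng, three_group_pmap)
        res = df.amova(aln, three_group_pmap, permutations=10_000, seed=0)
        assert res.exhaustive_ct


class TestPairwisePhist:
    def test_reciprocally_fixed_pair(self):
        aln = LocusAlignment.from_pairs(
            "x", [("a1", "AAAA"), ("a2", "AAAA"), ("b1", "TTTT"), ("b2", "TTTT")]
        )
        pmap = PopulationMap.from_records([
            ("a1", "P1", "G1", 0, 0), ("a2", "P1", "G1", 0, 0),
            ("b1", "P2", "G2", 1, 1), ("b2", "P2", "G2", 1, 1),
        ])
        units, phi, pv = df.pairwise_phist(aln, pmap, permutations=50, seed=0)
        assert phi[0, 1] == pytest.approx(1.0)

    def test_identical_composition_pair_near_zero(self, rng):
        seqs = [("".join(rng.choice(list("ACGT"), size=30))) for _ in range(5)]
        records, pairs = [], []
        for g in ("G1", "G2"):
            for k, s in enumerate(seqs):
                sid = f"{g}_{k}"
                records.append((sid, g, g, 0, 0))
                pairs.append((sid, s))
        aln = LocusAlignment.from_pairs("x", pairs)
        pmap = PopulationMap.from_records(records)
        _, phi, pv = df.pairwise_phist(aln, pmap, permutations=200, seed=3)
        # matched composition: no positive differentiation, never significant
        assert phi[0, 1] <= 0.0
        assert pv[0, 1] > 0.05

    def test_symmetric_and_bounded(self, rng, three_group_pmap):
        aln = grouped_alignment(rng, three_group_pmap)
        _, phi, _ = df.pairwise_phist(aln, three_group_pmap, permutations=20, seed=0)
        assert np.allclose(phi, phi.T, equal_nan=True)
        finite = phi[np.isfinite(phi)]
        assert (finite <= 1.0 + 1e-12).all()
        assert (finite >= -0.5).all()

    def test_consistent_with_single_level_oracle(self, rng, three_group_pmap):
        """Two-unit Phi-ST equals an independently coded one-level
        variance decomposition on the restricted dataset."""
        for _ in range(20):
            aln = grouped_alignment(rng, three_group_pmap)
            units, phi, _ = df.pairwise_phist(
                aln, three_group_pmap, permutations=1, seed=0)
            d, _ = df.pairwise_distance_matrix(aln)
            grp_of = three_group_pmap.group_of()
            labels = [grp_of[s] for s in aln.sample_ids]
            for a, b in itertools.combinations(range(len(units)), 2):
                ia = [i for i, l in enumerate(labels) if l == units[a]]
                ib = [i for i, l in enumerate(labels) if l == units[b]]
                idx = ia + ib
                sub = d[np.ix_(idx, idx)].astype(float)
                # one-level oracle: treat the two units as two "groups" of
                # one population each in the hierarchical formulas
                n = len(idx)
                na = len(ia)
                ssd_t = sum(sub[i, j] for i in range(n) for j in range(i + 1, n)) / n
                ssd_w = (sum(sub[i, j] for i in range(na) for j in range(i + 1, na)) / na
                         + sum(sub[i, j] for i in range(na, n)
                               for j in range(i + 1, n) if i >= na) / (n - na))
                ms_a = (ssd_t - ssd_w) / 1
                sigma_w = ssd_w / (n - 2)
                n0 = (n - (na ** 2 + (n - na) ** 2) / n) / 1
                sigma_a = (ms_a - sigma_w) / n0
                want = sigma_a / (sigma_a + sigma_w)
                assert phi[a, b] == pytest.approx(want, rel=1e-9)


class TestDivergence:
    def test_fixed_difference_pair(self):
        aln = LocusAlignment.from_pairs(
            "x", [("a1", "AA"), ("a2", "AA"), ("b1", "TT"), ("b2", "TT")]
        )
        pmap = PopulationMap.from_records([
            ("a1", "A", "A", 0, 0), ("a2", "A", "A", 0, 0),
            ("b1", "B", "B", 1, 1), ("b2", "B", "B", 1, 1),
        ])
        out = df.divergence_summary(aln, pmap, mu=3.7e-9)
        assert out[0].dxy == pytest.approx(1.0)
        assert out[0].da == pytest.approx(1.0)

    def test_time_arithmetic(self):
        # Da per site 0.00222 at the reference rate -> 300 kyr
        assert 0.00222 / (2 * 3.7e-9) == pytest.approx(300_000, rel=1e-6)

    def test_negative_da_flagged_nan(self, rng):
        seqs = [("".join(rng.choice(list("ACGT"), size=30))) for _ in range(6)]
        records, pairs = [], []
        for u, g in (("A", "A"), ("B", "B")):
            for k in range(3):
                sid = f"{u}{k}"
                records.append((sid, u, g, 0, 0))
                pairs.append((sid, seqs[k]))  # same pool: dxy < within pi possible
        aln = LocusAlignment.from_pairs("x", pairs)
        pmap = PopulationMap.from_records(records)
        out = df.divergence_summary(aln, pmap, mu=3.7e-9)
        if out[0].da < 0:
            assert math.isnan(out[0].t_hat_years)

    def test_between_group_distance_single_fixed_site(self):
        a = "A" * 100
        b = "T" + "A" * 99
        aln = LocusAlignment.from_pairs(
            "x", [("a1", a), ("a2", a), ("b1", b), ("b2", b)]
        )
        pmap = PopulationMap.from_records([
            ("a1", "A", "A", 0, 0), ("a2", "A", "A", 0, 0),
            ("b1", "B", "B", 1, 1), ("b2", "B", "B", 1, 1),
        ])
        units, mat = df.between_group_distance(aln, pmap)
        assert mat[0, 1] == pytest.approx(0.01)

    def test_between_group_distance_invariant_within_group_shuffle(self, rng, three_group_pmap):
        aln = grouped_alignment(rng, three_group_pmap)
        _, mat1 = df.between_group_distance(aln, three_group_pmap)
        # shuffle sample order within groups
        grp_of = three_group_pmap.group_of()
        by_group = {}
        for sid in aln.sample_ids:
            by_group.setdefault(grp_of[sid], []).append(sid)
        new_order = []
        for g, members in by_group.items():
            new_order.extend(rng.permutation(members))
        shuffled = aln.take(new_order)
        _, mat2 = df.between_group_distance(shuffled, three_group_pmap)
        assert np.allclose(mat1, mat2)
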