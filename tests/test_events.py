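import numpy as np
import pytest
from scipy import stats

from mitoqc import (
    Mitochondrion,
    Subcompartment,
    execute_fission,
    execute_fusion,
    execute_mitophagy,
    execute_replication,
)
from .conftest import make_cell


class TestMitophagyEvent:
    def test_removes_whole_mitochondrion(self, small_cell):
        target = small_cell.mitochondria[0]  # (W=3, M=1)
        execute_mitophagy(small_cell, target)
        assert small_cell.n_mitochondria == 1
        assert small_cell.n_nucleoids == 4
        assert small_cell.M == 0  # the only mutant-bearing mitochondrion is gone

    def test_removing_last_mitochondrion_flags_termination(self):
        cell = make_cell(([(2, 0)], 0))
        execute_mitophagy(cell, cell.mitochondria[0])
        assert cell.terminated_empty
        assert cell.n_mitochondria == 0


class TestReplicationEvent:
    def test_increments_one_identity_in_place(self, small_cell):
        m = small_cell.mitochondria[0]
        execute_replication(small_cell, m, 0, is_mutant=False)
        assert (m.W, m.M) == (4, 1)
        execute_replication(small_cell, m, 0, is_mutant=True)
        assert (m.W, m.M) == (4, 2)

    def test_total_increases_by_exactly_one(self, small_cell):
        before = small_cell.n_nucleoids
        execute_replication(small_cell, small_cell.mitochondria[1], 0, False)
        assert small_cell.n_nucleoids == before + 1

    def test_cannot_replicate_absent_identity(self, small_cell):
        with pytest.raises(ValueError):
            execute_replication(small_cell, small_cell.mitochondria[1], 0, True)


class TestFusionEvent:
    def test_chains_concatenate_with_new_junction_site(self, rng):
        cell = make_cell(([(1, 0)], 0), ([(2, 0), (0, 3)], 1))
        a, b = cell.mitochondria
        execute_fusion(cell, a, b, rng)
        assert cell.n_mitochondria == 1
        fused = cell.mitochondria[0]
        assert fused.n_fission_sites == 2  # both internal sites survive
        assert fused.total == 6
        chains = [(s.W, s.M) for s in fused.chain]
        assert sorted(chains) == sorted([(1, 0), (2, 0), (0, 3)])

    def test_nucleoids_conserved_and_compartment_is_acceptors(self, rng):
        for seed in range(8):
            cell = make_cell(([(3, 1)], 0), ([(4, 0)], 2))
            before = cell.n_nucleoids
            execute_fusion(cell, *cell.mitochondria, np.random.default_rng(seed))
            assert cell.n_nucleoids == before
            assert cell.mitochondria[0].compartment in (0, 2)

    def test_self_and_infeasible_pairs_rejected(self, rng):
        cell = make_cell(([(2, 0)], 0), ([(2, 0)], 8))
        with pytest.raises(ValueError):
            execute_fusion(cell, cell.mitochondria[0], cell.mitochondria[0], rng)
        with pytest.raises(ValueError):
            execute_fusion(cell, cell.mitochondria[0], cell.mitochondria[1], rng)


class TestFissionEvent:
    def test_chain_cut_conserves_and_respects_minimum(self, rng):
        for seed in range(20):
            cell = make_cell(([(3, 0), (2, 0)], 0))
            execute_fission(cell, cell.mitochondria[0], np.random.default_rng(seed))
            assert cell.n_mitochondria == 2
            assert cell.n_nucleoids == 5
            assert all(m.total >= 1 for m in cell.mitochondria)

    def test_single_subcompartment_split(self, rng):
        cell = make_cell(([(2, 2)], 0))
        execute_fission(cell, cell.mitochondria[0], rng)
        assert cell.n_mitochondria == 2
        assert cell.n_nucleoids == 4
        assert all(len(m.chain) == 1 for m in cell.mitochondria)
        assert all(m.total >= 1 for m in cell.mitochondria)

    def test_too_few_nucleoids_rejected(self, rng):
        cell = make_cell(([(1, 0)], 0))
        with pytest.raises(ValueError):
            execute_fission(cell, cell.mitochondria[0], rng)

    def test_daughter_placement_original_or_neighbor(self, rng):
        graph_seen = set()
        for seed in range(40):
            cell = make_cell(([(4, 4)], 5))
            execute_fission(cell, cell.mitochondria[0], np.random.default_rng(seed))
            allowed = {5, *cell.graph.neighbors[5]}
            comps = [m.compartment for m in cell.mitochondria]
            assert 5 in comps  # one daughter stays home
            assert set(comps) <= allowed
            graph_seen.update(comps)
        assert len(graph_seen) > 1  # displacement does occur

    def test_degenerate_sites_are_avoided(self):
        # chain (0,0),(0,0),(2,0): the first site pools two empty
        # subcompartments with an empty left side — no exchange can leave a
        # nucleoid there, so only the second site is viable
        for seed in range(10):
            c = make_cell(([(0, 0), (0, 0), (2, 0)], 0))
            execute_fission(c, c.mitochondria[0], np.random.default_rng(seed))
            assert all(m.total >= 1 for m in c.mitochondria)

    def test_mean_mutant_split_is_symmetric(self):
        # (W=2, M=2): by symmetry each daughter carries 1 mutant on average
        rng = np.random.default_rng(7)
        mutants = []
        for _ in range(20000):
            cell = make_cell(([(2, 2)], 0))
            execute_fission(cell, cell.mitochondria[0], rng)
            mutants.append(cell.mitochondria[1].M)
        assert np.mean(mutants) == pytest.approx(1.0, abs=0.02)

    def test_identity_blind_exchange_is_hypergeometric(self):
        # conditioned on the daughter size k, the mutant count must follow
        # Hypergeom(N=6, K=3, k) — fission must not prefer either identity
        rng = np.random.default_rng(11)
        by_k = {}
        for _ in range(30000):
            cell = make_cell(([(3, 3)], 0))
            execute_fission(cell, cell.mitochondria[0], rng)
            d = cell.mitochondria[1]
            by_k.setdefault(d.total, []).append(d.M)
        for k, ms in by_k.items():
            counts = np.bincount(ms, minlength=k + 1)
            expected = stats.hypergeom(6, 3, k).pmf(np.arange(k + 1)) * len(ms)
            keep = expected > 5
            chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
            dof = keep.sum() - 1
            assert chi2 < stats.chi2(dof).ppf(0.999)


class TestEventDeltas:
    def test_population_and_nucleoid_deltas(self, rng):
        cell = make_cell(([(3, 1)], 0), ([(4, 0)], 1), ([(2, 2)], 1))
        n0, t0 = cell.n_mitochondria, cell.n_nucleoids
        execute_replication(cell, cell.mitochondria[0], 0, False)
        assert (cell.n_mitochondria, cell.n_nucleoids) == (n0, t0 + 1)
        execute_fission(cell, cell.mitochondria[2], rng)
        assert (cell.n_mitochondria, cell.n_nucleoids) == (n0 + 1, t0 + 1)
        execute_fusion(cell, cell.mitochondria[0], cell.mitochondria[1], rng)
        assert (cell.n_mitochondria, cell.n_nucleoids) == (n0, t0 + 1)
        removed = cell.mitochondria[-1]
        execute_mitophagy(cell, removed)
        assert cell.n_mitochondria == n0 - 1
        assert cell.n_nucleoids == t0 + 1 - removed.total

    def test_fusion_then_fission_at_junction_redistributes_junction_contents(self):
        # fuse [A] + [B], then cut at the only site: the two junction
        # subcompartments pool and redistribute; totals are conserved
        for seed in range(10):
            rng = np.random.default_rng(seed)
            cell = make_cell(([(4, 0)], 0), ([(0, 4)], 0))
            execute_fusion(cell, *cell.mitochondria, rng)
            fused = cell.mitochondria[0]
            assert fused.n_fission_sites == 1
            execute_fission(cell, fused, rng)
            assert cell.n_mitochondria == 2
            assert cell.n_nucleoids == 8
            assert all(m.total >= 1 for m in cell.mitochondria)
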