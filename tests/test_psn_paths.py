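"""Interaction matrices, network construction, DCC and path search."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from allopath import psn_paths as pp
from allopath import structure_io as sio
from allopath import synthetic_data as sd
from conftest import make_topology


def brute_force_best_path(g, source, sink):
    """Exhaustive simple-path search under the tie rules: minimum hops,
    then maximum summed edge weight, then lexicographic order."""
    best = None
    for path in nx.all_simple_paths(g, source, sink):
        w = sum(g[u][v].get("weight", 0.0) for u, v in zip(path, path[1:]))
        key = (len(path), -w, tuple(path))
        if best is None or key < best:
            best = key
    return best if best is None else best[2]


def random_weighted_graph(rng, n_nodes, p_edge=0.4):
    g = nx.Graph()
    nodes = [("A", i, "") for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for u, v in itertools.combinations(nodes, 2):
        if rng.random() < p_edge:
            # coarse weights force frequent sum ties
            g.add_edge(u, v, weight=float(rng.integers(1, 4)))
    return g, nodes


class TestInteractionMatrix:
    def _two_residue_ensemble(self, separation):
        """Two 3-atom side chains whose tips sit `separation` apart."""
        top = make_topology(1, atoms=("CA", "CB", "CG", "CD"), chain="A") + \
            make_topology(1, atoms=("CA", "CB", "CG", "CD"), chain="B")
        xyz = np.zeros((1, 8, 3))
        xyz[0, 1:4, 0] = [0.0, 0.3, 0.6]           # chain A side chain
        xyz[0, 5:8, 0] = separation + np.array([0.0, 0.3, 0.6])
        xyz[0, 4:, 1] = 0.0
        return sio.Ensemble(top, xyz)

    def test_far_apart_zero(self):
        ens = self._two_residue_ensemble(20.0)
        im = pp.interaction_matrix(ens, 0)
        assert im.i.max() == 0.0 and im.n.max() == 0

    def test_pair_count_matches_brute_force(self):
        rng = np.random.default_rng(0)
        top = make_topology(4, atoms=("N", "CA", "C", "O", "CB", "CG"))
        # spread residues so that some but not all pairs touch
        xyz = rng.normal(scale=4.0, size=(1, len(top), 3))
        ens = sio.Ensemble(top, xyz)
        cfg = pp.PSNConfig(include_adjacent=True)
        im = pp.interaction_matrix(ens, 0, cfg)
        sidechain = {r: [i for i, rec in enumerate(top)
                         if rec.residue_number == r
                         and rec.atom_name in ("CB", "CG")]
                     for r in range(1, 5)}
        for r1, r2 in itertools.combinations(range(1, 5), 2):
            n = sum(np.linalg.norm(xyz[0, a] - xyz[0, b]) <= 4.5
                    for a in sidechain[r1] for b in sidechain[r2])
            k1, k2 = ("A", r1, ""), ("A", r2, "")
            assert im.n[im.index(k1), im.index(k2)] == n
            # uniform normalization: I equals the raw pair count
            assert im.i[im.index(k1), im.index(k2)] == pytest.approx(float(n))

    def test_uniform_vs_table_normalization(self):
        ens = self._two_residue_ensemble(4.0)
        uniform = pp.interaction_matrix(ens, 0, pp.PSNConfig())
        table = pp.interaction_matrix(ens, 0, pp.PSNConfig(
            normalization_mode="table", normalization_table={"ALA": 25.0}))
        # sqrt form: N=25 quadruples I relative to N=100
        assert np.allclose(table.i, uniform.i * 4.0)
        product = pp.interaction_matrix(ens, 0, pp.PSNConfig(
            normalization="product"))
        assert np.allclose(product.i, uniform.i / 100.0)

    def test_missing_normalization_entry(self):
        ens = self._two_residue_ensemble(4.0)
        with pytest.raises(KeyError, match="ALA"):
            pp.interaction_matrix(ens, 0, pp.PSNConfig(
                normalization_mode="table", normalization_table={"GLY": 10.0}))

    def test_sequence_adjacent_excluded_by_default(self):
        top = make_topology(2, atoms=("CA", "CB"))
        xyz = np.zeros((1, 4, 3))
        xyz[0, 3, 0] = 3.0   # CB of residue 2 close to CB of residue 1
        ens = sio.Ensemble(top, xyz)
        default = pp.interaction_matrix(ens, 0)
        assert default.n.max() == 0
        included = pp.interaction_matrix(ens, 0, pp.PSNConfig(include_adjacent=True))
        assert included.n.max() == 1

    def test_glycine_uses_calpha(self):
        top = make_topology(1, atoms=("N", "CA", "C", "O"), resname="GLY") + \
            make_topology(1, atoms=("N", "CA", "C", "O", "CB"), chain="B")
        xyz = np.zeros((1, 9, 3))
        xyz[0, 8, 0] = 2.0    # B's CB near GLY's CA
        ens = sio.Ensemble(top, xyz)
        im = pp.interaction_matrix(ens, 0)
        assert im.n[im.index(("A", 1, "")), im.index(("B", 1, ""))] == 1


class TestBuildPsn:
    def test_contact_free_frame_edgeless(self):
        residues = [("A", i, "") for i in range(3)]
        im = pp.InteractionMatrix(residues, np.zeros((3, 3)), np.zeros((3, 3), int))
        assert pp.build_psn(im).number_of_edges() == 0

    def test_threshold_oracle(self):
        residues = [("A", i, "") for i in range(4)]
        i_mat = np.zeros((4, 4))
        n_mat = np.zeros((4, 4), int)
        for (a, b), val in {(0, 1): 3.1, (1, 2): 1.2, (2, 3): 5.0}.items():
            i_mat[a, b] = i_mat[b, a] = val
            n_mat[a, b] = n_mat[b, a] = 2
        g = pp.build_psn(pp.InteractionMatrix(residues, i_mat, n_mat),
                         pp.PSNConfig(i_min=2.0))
        assert set(g.edges) == {(residues[0], residues[1]),
                                (residues[2], residues[3])}

    def test_zero_imin_still_requires_contact(self):
        residues = [("A", 0, ""), ("A", 2, "")]
        i_mat = np.array([[0.0, 1.0], [1.0, 0.0]])
        n_mat = np.zeros((2, 2), int)   # I > 0 but no actual atom pairs
        g = pp.build_psn(pp.InteractionMatrix(residues, i_mat, n_mat),
                         pp.PSNConfig(i_min=0.0))
        assert g.number_of_edges() == 0

    def test_transpose_invariance(self):
        rng = np.random.default_rng(4)
        residues = [("A", i, "") for i in range(6)]
        n_mat = rng.integers(0, 5, size=(6, 6))
        n_mat = np.triu(n_mat, 1) + np.triu(n_mat, 1).T
        i_mat = n_mat.astype(float)
        g1 = pp.build_psn(pp.InteractionMatrix(residues, i_mat, n_mat))
        g2 = pp.build_psn(pp.InteractionMatrix(residues, i_mat.T, n_mat.T))
        assert set(g1.edges) == set(g2.edges)

    def test_raising_imin_monotone(self):
        rng = np.random.default_rng(5)
        residues = [("A", i, "") for i in range(8)]
        n_mat = rng.integers(0, 6, size=(8, 8))
        n_mat = np.triu(n_mat, 1) + np.triu(n_mat, 1).T
        i_mat = n_mat.astype(float)
        im = pp.InteractionMatrix(residues, i_mat, n_mat)
        counts = [pp.build_psn(im, pp.PSNConfig(i_min=t)).number_of_edges()
                  for t in (0.0, 1.0, 2.0, 4.0)]
        assert counts == sorted(counts, reverse=True)


class TestDcc:
    def _ensemble_from_displacements(self, disp):
        """disp: (n_frames, n_atoms, 3) displacements around fixed sites."""
        n_frames, n_atoms, _ = disp.shape
        base = np.arange(n_atoms)[:, None] * np.array([10.0, 0.0, 0.0])
        top = make_topology(n_atoms, atoms=("CA",))
        return sio.Ensemble(top, base[None] + disp)

    def test_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        ens = self._ensemble_from_displacements(rng.normal(size=(50, 4, 3)))
        d = pp.dcc_matrix(ens, np.arange(4), superpose=False)
        assert np.allclose(np.diag(d.c), 1.0)

    def test_parallel_and_antiparallel_motion(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=(40, 1, 3))
        disp = np.concatenate([t, t, -t], axis=1)
        d = pp.dcc_matrix(self._ensemble_from_displacements(disp),
                          np.arange(3), superpose=False)
        assert d.c[0, 1] == pytest.approx(1.0)
        assert d.c[0, 2] == pytest.approx(-1.0)

    def test_identical_frames_flagged(self):
        ens = self._ensemble_from_displacements(np.zeros((5, 3, 3)))
        with pytest.warns(UserWarning, match="zero displacement"):
            d = pp.dcc_matrix(ens, np.arange(3), superpose=False)
        assert d.flagged.all() and np.allclose(d.c, 0.0)

    def test_bounded(self, gnm_small):
        _, ens, _ = gnm_small
        d = pp.dcc_matrix(ens, np.arange(ens.n_atoms), superpose=False)
        assert np.abs(d.c).max() <= 1.0

    def test_global_rotation_invariance_with_superposition(self, gnm_small):
        _, ens, _ = gnm_small
        sub = ens.subset_frames(np.arange(40))
        d1 = pp.dcc_matrix(sub, np.arange(ens.n_atoms), superpose=True)
        rot = Rotation.random(random_state=3).as_matrix()
        rotated = sio.Ensemble(sub.topology,
                               np.einsum("fnx,yx->fny", sub.coords, rot))
        d2 = pp.dcc_matrix(rotated, np.arange(ens.n_atoms), superpose=True)
        assert np.allclose(d1.c, d2.c, atol=1e-6)


class TestShortestPath:
    def test_source_equals_sink(self):
        g = nx.Graph()
        g.add_node(("A", 1, ""))
        p = pp.shortest_path(g, None, ("A", 1, ""), ("A", 1, ""), corr_min=0.0)
        assert p.hops == 0 and p.residues == (("A", 1, ""),)

    def test_missing_node_raises(self):
        g = nx.Graph()
        g.add_node(("A", 1, ""))
        with pytest.raises(KeyError):
            pp.shortest_path(g, None, ("A", 1, ""), ("A", 9, ""), corr_min=0.0)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(123)
        checked = 0
        for _ in range(150):
            g, nodes = random_weighted_graph(rng, int(rng.integers(4, 9)))
            s, t = nodes[0], nodes[-1]
            expected = brute_force_best_path(g, s, t)
            got = pp.shortest_path(g, None, s, t, corr_min=0.0)
            if expected is None:
                assert got is None
            else:
                assert got.residues == expected
                checked += 1
        assert checked > 50

    def test_correlation_filter_reroutes(self):
        # two 2-hop routes A-B-D and A-C-D; DCC excludes the B route's edge
        nodes = [("A", i, "") for i in range(4)]
        a, b, c, d = nodes
        g = nx.Graph()
        g.add_edge(a, b, weight=9.0)
        g.add_edge(b, d, weight=9.0)
        g.add_edge(a, c, weight=1.0)
        g.add_edge(c, d, weight=1.0)
        corr = np.ones((4, 4))
        unfiltered = pp.shortest_path(g, None, a, d, corr_min=0.0)
        assert unfiltered.residues == (a, b, d)   # higher summed weight
        corr[1, 3] = corr[3, 1] = 0.05            # kill edge B-D
        dcc = pp.DCCMatrix(nodes, corr, np.zeros(4, bool))
        filtered = pp.shortest_path(g, dcc, a, d, corr_min=0.3)
        assert filtered.residues == (a, c, d)

    def test_raising_corrmin_monotone_in_reachability(self):
        rng = np.random.default_rng(9)
        g, nodes = random_weighted_graph(rng, 8, p_edge=0.5)
        corr = rng.uniform(-1, 1, size=(8, 8))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        dcc = pp.DCCMatrix(nodes, corr, np.zeros(8, bool))
        reachable = []
        for corr_min in (0.0, 0.2, 0.4, 0.6, 0.8):
            found = sum(
                pp.shortest_path(g, dcc, s, t, corr_min=corr_min) is not None
                for s, t in itertools.combinations(nodes, 2))
            reachable.append(found)
        assert reachable == sorted(reachable, reverse=True)


class TestTallyPaths:
    def test_planted_path_found_at_full_persistence(self, planted_dimer):
        spec, ens, truth = planted_dimer
        cfg = pp.PSNConfig()
        graphs = pp.frame_graphs(ens, cfg)
        all_res = sio.ResidueSelection.from_residue_keys(
            [(c, n) for c, n, _ in sio.residue_keys(ens.topology)])
        ca = sio.select_residues(ens.topology, all_res, atoms="calpha")
        dcc = pp.dcc_matrix(ens, ca, superpose=True)
        tally = pp.tally_paths(graphs, dcc, spec.source_pocket, spec.sink_pocket)
        expected = tuple((c, n, "") for c, n in spec.planted_chain)
        assert tally.top == expected
        assert tally.frequencies[expected] == pytest.approx(1.0)
        assert tally.n_frequent == 1

    def test_zero_persistence_empty_tally(self):
        spec = sd.default_planted_spec(persistence=0.0)
        ens, _ = sd.make_planted_path_dimer(spec, 5, seed=2)
        graphs = pp.frame_graphs(ens, pp.PSNConfig())
        tally = pp.tally_paths(graphs, None, spec.source_pocket,
                               spec.sink_pocket, corr_min=0.0)
        assert tally.frequencies == {} and tally.n_frequent == 0
        assert tally.top is None

    def test_partial_persistence_frequency(self):
        spec = sd.default_planted_spec(persistence=0.5)
        ens, truth = sd.make_planted_path_dimer(spec, 40, seed=8)
        graphs = pp.frame_graphs(ens, pp.PSNConfig())
        tally = pp.tally_paths(graphs, None, spec.source_pocket,
                               spec.sink_pocket, corr_min=0.0)
        expected = tuple((c, n, "") for c, n in spec.planted_chain)
        assert tally.frequencies[expected] == pytest.approx(
            truth["persistence_exact"])

    def test_empty_pocket_rejected(self, planted_dimer):
        spec, ens, _ = planted_dimer
        graphs = pp.frame_graphs(ens.subset_frames([0]), pp.PSNConfig())
        with pytest.raises(ValueError, match="nonempty"):
            pp.tally_paths(graphs, None, sio.ResidueSelection([]),
                           spec.sink_pocket)

    def test_raising_freqmin_monotone(self):
        spec = sd.default_planted_spec(persistence=0.5)
        ens, _ = sd.make_planted_path_dimer(spec, 20, seed=3)
        graphs = pp.frame_graphs(ens, pp.PSNConfig())
        counts = [pp.tally_paths(graphs, None, spec.source_pocket,
                                 spec.sink_pocket, corr_min=0.0,
                                 freq_min=f).n_frequent
                  for f in (0.1, 0.4, 0.6)]
        assert counts == sorted(counts, reverse=True)
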