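import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agbt.algebraic_graph import (
    AGConfig,
    DEFAULT_KERNELS,
    ElementPair,
    ElementPairGraph,
    KernelSpec,
    adjacency,
    ag_fingerprint,
    build_subgraph,
    connected_component_count,
    kernel_value,
    laplacian,
    rigidity_index,
    spectral_statistics,
)
from agbt.chem_io import Atom, Molecule

EXP = KernelSpec("exponential", eta=2.0, power=2.0)
LOR = KernelSpec("lorentz", eta=2.0, power=3.0)


def two_atom_mol(e1, e2, d):
    return Molecule("m", [Atom.of(e1, (0, 0, 0)), Atom.of(e2, (0, 0, d))])


class TestKernel:
    def test_exponential_at_eta(self):
        spec = KernelSpec("exponential", eta=3.0, power=1.0)
        assert kernel_value(3.0, spec) == pytest.approx(np.exp(-1), abs=1e-12)

    @pytest.mark.parametrize("nu", [1.0, 2.0, 5.5])
    def test_lorentz_at_eta_is_half(self, nu):
        assert kernel_value(2.0, KernelSpec("lorentz", 2.0, nu)) == pytest.approx(0.5)

    @pytest.mark.parametrize("spec", [EXP, LOR])
    def test_zero_distance_is_one(self, spec):
        assert kernel_value(0.0, spec) == 1.0

    def test_negative_distance_raises(self):
        with pytest.raises(ValueError):
            kernel_value(-0.1, EXP)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(d1=st.floats(0, 20), delta=st.floats(1e-6, 10),
           family=st.sampled_from(["exponential", "lorentz"]),
           eta=st.floats(0.5, 10), power=st.floats(0.5, 5))
    def test_strictly_decreasing_and_bounded(self, d1, delta, family, eta, power):
        spec = KernelSpec(family, eta, power)
        w1, w2 = kernel_value(d1, spec), kernel_value(d1 + delta, spec)
        assert 0.0 <= w2 <= w1 <= 1.0
        # strict decrease wherever double precision can resolve it
        # (both tails saturate: exp underflow at large d, 1.0 at tiny d)
        if 1e-12 < w2 < 1.0 - 1e-12:
            assert w2 < w1


class TestBuildSubgraph:
    def test_noncovalent_pair_gets_edge(self):
        # C-O at 2.8 Å: cutoff 0.76 + 0.66 = 1.42 < 2.8
        g = build_subgraph(two_atom_mol("C", "O", 2.8), ElementPair("C", "O"), EXP, 0.0)
        assert len(g.edges) == 1
        assert g.edges[0][2] == pytest.approx(kernel_value(2.8, EXP))

    def test_covalent_contact_excluded(self):
        g = build_subgraph(two_atom_mol("C", "O", 1.20), ElementPair("C", "O"), EXP, 0.0)
        assert g.edges == []

    def test_missing_element_gives_empty_graph(self):
        g = build_subgraph(two_atom_mol("C", "O", 2.8), ElementPair("N", "N"), EXP, 0.0)
        assert g.n_vertices == 0 and g.edges == []

    def test_sigma_widens_exclusion(self):
        pair = ElementPair("C", "O")
        assert build_subgraph(two_atom_mol("C", "O", 1.5), pair, EXP, 0.0).edges
        assert not build_subgraph(two_atom_mol("C", "O", 1.5), pair, EXP, 0.2).edges

    def test_cross_element_edges_only(self):
        mol = Molecule("m", [Atom.of("C", (0, 0, 0)), Atom.of("C", (0, 0, 4.0)),
                             Atom.of("O", (0, 3.0, 0))])
        g = build_subgraph(mol, ElementPair("C", "O"), EXP, 0.0)
        # C-C at 4.0 Å is beyond cutoff but is not a C-O pair
        assert len(g.edges) == 2
        labels = {frozenset((g.vertices[i], g.vertices[j])) for i, j, _ in g.edges}
        assert labels == {frozenset((0, 2)), frozenset((1, 2))}


class TestRigidityAndMatrices:
    def test_single_edge_counts_both_endpoints(self):
        g = ElementPairGraph(ElementPair("C", "O"), EXP, [0, 1], [(0, 1, 0.3)])
        assert rigidity_index(g) == pytest.approx(0.6)

    def test_empty_graph_zero(self):
        g = ElementPairGraph(ElementPair("C", "O"), EXP, [], [])
        assert rigidity_index(g) == 0.0
        assert laplacian(g).shape == (0, 0)

    def test_trace_identity_on_fixtures(self, random_subgraphs):
        for g in random_subgraphs:
            tr = np.trace(laplacian(g))
            assert abs(rigidity_index(g) - tr) <= 1e-12 * max(1.0, abs(tr))

    def test_k2_laplacian_closed_form(self):
        g = ElementPairGraph(ElementPair("C", "O"), EXP, [0, 1], [(0, 1, 0.5)])
        L = laplacian(g)
        np.testing.assert_allclose(L, [[0.5, -0.5], [-0.5, 0.5]])
        np.testing.assert_allclose(np.linalg.eigvalsh(L), [0.0, 1.0], atol=1e-12)

    def test_laplacian_psd_zero_rowsum_on_fixtures(self, random_subgraphs):
        for g in random_subgraphs:
            L = laplacian(g)
            np.testing.assert_allclose(L.sum(1), 0.0, atol=1e-12)
            assert np.linalg.eigvalsh(L).min() >= -1e-10

    def test_path_matches_dense_eigensolver(self):
        g = ElementPairGraph(ElementPair("C", "C"), EXP, [0, 1, 2],
                             [(0, 1, 0.2), (1, 2, 0.4)])
        L = laplacian(g)
        dense = np.array([[0.2, -0.2, 0.0], [-0.2, 0.6, -0.4], [0.0, -0.4, 0.4]])
        np.testing.assert_allclose(np.linalg.eigvalsh(L), np.linalg.eigvalsh(dense),
                                   atol=1e-10)

    def test_k2_adjacency_spectrum(self):
        g = ElementPairGraph(ElementPair("C", "O"), EXP, [0, 1], [(0, 1, 0.5)])
        np.testing.assert_allclose(np.linalg.eigvalsh(adjacency(g)), [-0.5, 0.5])

    def test_adjacency_eigenvalues_sum_to_zero(self, random_subgraphs):
        for g in random_subgraphs:
            assert abs(np.linalg.eigvalsh(adjacency(g)).sum()) <= 1e-10

    def test_zero_modes_count_components(self, random_subgraphs):
        for g in random_subgraphs[:50]:
            L = laplacian(g)
            eig = np.linalg.eigvalsh(L)
            tau = 1e-10 * max(1.0, eig.max(initial=0.0))
            assert (eig < tau).sum() == connected_component_count(g)

    def test_isolated_vertices_are_components(self):
        g = ElementPairGraph(ElementPair("C", "C"), EXP, [0, 1, 2], [])
        assert connected_component_count(g) == 3


class TestSpectralStatistics:
    def test_k2_laplacian_stats(self):
        L = np.array([[0.5, -0.5], [-0.5, 0.5]])
        np.testing.assert_allclose(spectral_statistics(L, "laplacian"),
                                   [1.0, 1.0, 1.0, 1.0, 0.0], atol=1e-12)

    def test_k2_adjacency_stats_positive_only(self):
        A = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(spectral_statistics(A, "adjacency"),
                                   [0.5, 0.5, 0.5, 0.5, 0.0], atol=1e-12)

    def test_empty_matrix_convention(self):
        np.testing.assert_array_equal(spectral_statistics(np.zeros((0, 0)), "laplacian"),
                                      np.zeros(5))

    def test_asymmetric_raises(self):
        with pytest.raises(ValueError, match="symmetric"):
            spectral_statistics(np.array([[0.0, 1.0], [0.0, 0.0]]), "laplacian")


class TestAGFingerprint:
    def test_default_length_1800(self, toy_molecules, toy_sigma):
        fp = ag_fingerprint(toy_molecules[0], AGConfig(), toy_sigma)
        assert len(fp.values) == 1800
        assert len(fp.names) == 1800
        assert len(set(fp.names)) == 1800

    def test_single_hydrogen_all_zero(self):
        mol = Molecule("h", [Atom.of("H", (0, 0, 0))])
        fp = ag_fingerprint(mol, AGConfig(), 0.0)
        assert np.all(fp.values == 0)

    def test_rigid_motion_and_permutation_invariance(self, toy_molecules, toy_sigma):
        rng = np.random.default_rng(0)
        config = AGConfig()
        for mol in toy_molecules[:10]:
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            coords = mol.coordinates @ q.T + rng.uniform(-3, 3, 3)
            perm = rng.permutation(len(mol))
            moved = Molecule(mol.id, [Atom.of(mol.elements[i], coords[i]) for i in perm])
            diff = ag_fingerprint(moved, config, toy_sigma).values - \
                ag_fingerprint(mol, config, toy_sigma).values
            assert np.abs(diff).max() <= 1e-8

    def test_monotone_in_distance(self):
        pair = ElementPair("C", "C")
        prev = np.inf
        for d in [2.0, 3.0, 5.0, 9.0]:
            ri = rigidity_index(build_subgraph(two_atom_mol("C", "C", d), pair, EXP, 0.0))
            assert ri <= prev
            prev = ri

    def test_far_scale_decays_to_zero(self):
        mol = two_atom_mol("C", "C", 5000.0)
        fp = ag_fingerprint(mol, AGConfig(), 0.0)
        assert np.abs(fp.values).max() < 1e-8
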