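"""Elastic network, normal modes, entropy profiles and delta-G contracts.

Independent oracles: exhaustive O(N^2) pair scan for spring building,
central finite differences of the spring energy for the Hessian,
numpy.linalg.eigh as a second eigensolver, and the Moore-Penrose
pseudo-inverse for the entropy profile.
"""

import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import make_nodes
from nmvar.catalog import VariantRecord
from nmvar.enm import (DeltaGProfile, EnmError, EnmParams, build_network,
                       delta_g, entropy_profile, hessian, normal_modes,
                       uniform_weight_table, variant_delta_g)
from nmvar.structure import CoarseStructure, Node, assign_subunits


def profile_of(structure, params):
    return entropy_profile(
        normal_modes(hessian(build_network(structure, params)), params)
    )


class TestBuildNetwork:
    def test_two_nodes_within_cutoff(self, two_node_structure, uniform_params):
        net = build_network(two_node_structure, uniform_params)
        assert len(net.springs) == 1
        i, j, rest, k = net.springs[0]
        assert (i, j) == (0, 1)
        assert rest == pytest.approx(5.0)

    def test_far_nodes_disconnected_flagged(self, uniform_params):
        nodes = (
            Node(chain_id="A", residue_index=1, residue_type="ALA",
                 coords=(0.0, 0.0, 0.0)),
            Node(chain_id="B", residue_index=1, residue_type="ALA",
                 coords=(20.0, 0.0, 0.0)),
        )
        s = CoarseStructure(nodes=nodes)
        net = build_network(s, uniform_params, on_disconnected="keep")
        assert net.springs == ()
        assert not net.connected
        with pytest.raises(EnmError, match="disconnected"):
            build_network(s, uniform_params)

    def test_springs_match_brute_force_scan(self, random_cloud_structure):
        params = EnmParams(cutoff_radius=6.0)
        net = build_network(random_cloud_structure, params,
                            on_disconnected="keep")
        # oracle: exhaustive O(N^2) scan applying the spring rule directly
        nodes = random_cloud_structure.nodes
        coords = random_cloud_structure.coords
        expected = set()
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                sequential = (
                    nodes[i].chain_id == nodes[j].chain_id
                    and nodes[j].residue_index - nodes[i].residue_index == 1
                )
                r = float(np.linalg.norm(coords[j] - coords[i]))
                if sequential:
                    expected.add((i, j, round(r, 9), params.k_backbone))
                elif r <= params.cutoff_radius:
                    w = params.pair_weight(nodes[i].residue_type,
                                           nodes[j].residue_type)
                    expected.add((i, j, round(r, 9),
                                  params.epsilon_nonbonded * w))
        got = {(i, j, round(r, 9), k) for i, j, r, k in net.springs}
        assert got == expected

    def test_backbone_stiffer_than_nonbonded(self, small_complex):
        net = build_network(small_complex, EnmParams())
        ks = {}
        for i, j, _r, k in net.springs:
            a, b = net.structure.nodes[i], net.structure.nodes[j]
            seq = a.chain_id == b.chain_id and b.residue_index - a.residue_index == 1
            ks.setdefault(seq, []).append(k)
        assert min(ks[True]) > max(ks[False])

    def test_single_node_rejected(self):
        s = CoarseStructure(nodes=make_nodes([(0, 0, 0)]))
        with pytest.raises(EnmError):
            build_network(s)


class TestHessian:
    def test_single_spring_closed_form(self, two_node_structure, uniform_params):
        # spring along x with k=1: +/-1 at the xx entries, zero elsewhere
        H = hessian(build_network(two_node_structure, uniform_params))
        expected = np.zeros((6, 6))
        for a, b, v in [(0, 0, 1), (0, 3, -1), (3, 0, -1), (3, 3, 1)]:
            expected[a, b] = v
        np.testing.assert_allclose(H, expected, atol=1e-12)

    def test_translation_invariance(self, random_cloud_structure):
        H = hessian(build_network(random_cloud_structure,
                                  EnmParams(), on_disconnected="keep"))
        n = H.shape[0] // 3
        for axis in range(3):
            t = np.zeros(3 * n)
            t[axis::3] = 1.0
            np.testing.assert_allclose(H @ t, 0.0, atol=1e-9)

    def test_rotation_invariance_about_centroid(self, random_cloud_structure):
        net = build_network(random_cloud_structure, EnmParams(),
                            on_disconnected="keep")
        H = hessian(net)
        X = net.structure.coords - net.structure.coords.mean(axis=0)
        for axis in np.eye(3):
            rot = np.cross(np.tile(axis, (len(X), 1)), X).ravel()
            np.testing.assert_allclose(H @ rot, 0.0, atol=1e-8)

    def test_matches_finite_difference_oracle(self, uniform_params):
        s = CoarseStructure(nodes=make_nodes(
            [(0, 0, 0), (3.8, 0.5, 0), (6.0, 3.0, 1.0)]
        ))
        net = build_network(s, uniform_params)
        H = hessian(net)

        def energy(x):
            x = x.reshape(-1, 3)
            e = 0.0
            for i, j, rest, k in net.springs:
                e += 0.5 * k * (np.linalg.norm(x[j] - x[i]) - rest) ** 2
            return e

        x0 = s.coords.ravel()
        h = 1e-5
        n = x0.size
        H_fd = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                xpp = x0.copy(); xpp[a] += h; xpp[b] += h
                xpm = x0.copy(); xpm[a] += h; xpm[b] -= h
                xmp = x0.copy(); xmp[a] -= h; xmp[b] += h
                xmm = x0.copy(); xmm[a] -= h; xmm[b] -= h
                H_fd[a, b] = (energy(xpp) - energy(xpm) - energy(xmp)
                              + energy(xmm)) / (4 * h * h)
        np.testing.assert_allclose(H, H_fd, atol=1e-5)

    def test_coincident_nodes_rejected(self):
        nodes = make_nodes([(0, 0, 0), (0, 0, 0)])
        s = CoarseStructure(nodes=nodes)
        net = build_network(s, EnmParams(), on_disconnected="keep")
        with pytest.raises(EnmError, match="coincident"):
            hessian(net)


class TestNormalModes:
    @pytest.mark.parametrize("k", [1.0, 2.5])
    def test_two_body_analytic_spectrum(self, two_node_structure, k):
        # relative coordinate of two unit masses: lambda = 2k; 5 rigid modes
        params = EnmParams(weight_table=uniform_weight_table(),
                           epsilon_nonbonded=k, k_backbone=100 * k)
        net = build_network(two_node_structure, params)
        modes = normal_modes(hessian(net), params)
        assert modes.n_rigid == 5
        assert modes.eigenvalues[-1] == pytest.approx(2.0 * k, rel=1e-12)

    def test_connected_noncollinear_network_has_six_zero_modes(self):
        rng = np.random.default_rng(2)
        s = CoarseStructure(nodes=make_nodes(rng.uniform(0, 7, size=(8, 3))))
        modes = normal_modes(hessian(build_network(s, EnmParams())))
        assert modes.n_rigid == 6

    def test_eigenpairs_match_independent_solver(self, random_cloud_structure):
        params = EnmParams()
        H = hessian(build_network(random_cloud_structure, params,
                                  on_disconnected="keep"))
        modes = normal_modes(H, params)
        lam_oracle = np.linalg.eigh(H)[0]  # independent solver
        scale = max(1.0, float(np.abs(lam_oracle).max()))
        np.testing.assert_allclose(modes.eigenvalues, lam_oracle,
                                   atol=1e-8 * scale)
        # residuals |Hv - lambda v| and orthonormality
        V, lam = modes.eigenvectors, modes.eigenvalues
        np.testing.assert_allclose(H @ V, V * lam, atol=1e-8 * scale)
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)

    def test_non_symmetric_rejected(self):
        with pytest.raises(EnmError, match="symmetric"):
            normal_modes(np.array([[0.0, 1.0], [0.0, 0.0]]))


class TestEntropyProfile:
    def test_two_node_symmetry(self, two_node_structure, uniform_params):
        prof = profile_of(two_node_structure, uniform_params)
        assert prof.per_node[0] == pytest.approx(prof.per_node[1])

    def test_stiffness_scaling_inverts_profile(self, random_cloud_structure):
        c = 4.0
        p1 = EnmParams()
        p2 = EnmParams(epsilon_nonbonded=c * p1.epsilon_nonbonded,
                       k_backbone=c * p1.k_backbone)
        prof1 = profile_of(random_cloud_structure, p1)
        prof2 = profile_of(random_cloud_structure, p2)
        np.testing.assert_allclose(prof2.per_node, prof1.per_node / c,
                                   rtol=1e-9)

    def test_matches_pseudo_inverse_oracle(self, uniform_params):
        rng = np.random.default_rng(3)
        s = CoarseStructure(nodes=make_nodes(rng.uniform(0, 6, size=(5, 3))))
        H = hessian(build_network(s, uniform_params))
        prof = entropy_profile(normal_modes(H, uniform_params))
        diag = np.diag(np.linalg.pinv(H, hermitian=True))
        np.testing.assert_allclose(prof.per_node, diag.reshape(-1, 3).sum(1),
                                   rtol=1e-8, atol=1e-12)

    def test_rigid_rotation_invariance(self, random_cloud_structure):
        params = EnmParams()
        prof = profile_of(random_cloud_structure, params)
        # random rotation + translation of every coordinate
        rng = np.random.default_rng(4)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        moved = CoarseStructure(nodes=tuple(
            Node(chain_id=nd.chain_id, residue_index=nd.residue_index,
                 residue_type=nd.residue_type,
                 coords=tuple(Q @ np.array(nd.coords) + [10.0, -3.0, 7.0]))
            for nd in random_cloud_structure.nodes
        ))
        prof_moved = profile_of(moved, params)
        np.testing.assert_allclose(prof_moved.per_node, prof.per_node,
                                   atol=1e-10 * max(prof.per_node))


class TestDeltaG:
    def test_wild_type_against_itself_is_zero(self, small_complex):
        params = EnmParams()
        prof = profile_of(small_complex, params)
        dg = delta_g(prof, prof, small_complex)
        for vec in dg.per_subunit.values():
            np.testing.assert_array_equal(vec, 0.0)

    def test_swapping_profiles_negates(self, small_complex, small_panel):
        params = small_panel.enm_params
        wt = profile_of(small_complex, params)
        v = small_panel.variants[0]
        from nmvar.structure import apply_point_mutation
        mut_struct = apply_point_mutation(
            small_complex, "B", v.position, v.ref_aa, v.alt_aa
        )
        mut = profile_of(mut_struct, params)
        fwd = delta_g(wt, mut, small_complex, v)
        rev = delta_g(mut, wt, small_complex, v)
        for s in fwd.subunits:
            np.testing.assert_allclose(rev.per_subunit[s],
                                       -fwd.per_subunit[s], rtol=1e-12)

    def test_weight_neutral_substitution_gives_zero(self, small_complex,
                                                    uniform_params):
        # under a uniform weight table every type is interchangeable
        ref = small_complex.nodes[small_complex.node_index("B", 5)].residue_type
        alt = "Trp" if ref != "TRP" else "Tyr"
        rec = VariantRecord.from_protein_change(
            f"p.{ref.capitalize()}5{alt}", phenotype_group="1", patient_count=1,
        )
        dg = variant_delta_g(small_complex, rec, uniform_params)
        for vec in dg.per_subunit.values():
            np.testing.assert_array_equal(vec, 0.0)

    def test_determinism_bit_identical(self, small_complex, small_panel):
        v = small_panel.variants[0]
        a = variant_delta_g(small_complex, v, small_panel.enm_params)
        b = variant_delta_g(small_complex, v, small_panel.enm_params)
        for s in a.subunits:
            np.testing.assert_array_equal(a.per_subunit[s], b.per_subunit[s])

    def test_node_count_mismatch_rejected(self, small_complex):
        from nmvar.enm import EntropyProfile
        a = EntropyProfile(per_node=np.zeros(5), scalar_pseudo_entropy=0.0)
        b = EntropyProfile(per_node=np.zeros(6), scalar_pseudo_entropy=0.0)
        with pytest.raises(EnmError, match="mismatch"):
            delta_g(a, b, small_complex)

    def test_panel_matches_monolithic_oracle(self, small_complex, small_panel):
        """End-to-end oracle: recompute 3 variant profiles from scratch with
        an independent pseudo-inverse route (no ModeSpectrum machinery)."""
        from nmvar.structure import apply_point_mutation
        params = small_panel.enm_params

        def oracle_profile(structure):
            H = hessian(build_network(structure, params))
            diag = np.diag(np.linalg.pinv(H, hermitian=True))
            return diag.reshape(-1, 3).sum(1)

        wt_oracle = oracle_profile(small_complex)
        for v in small_panel.variants[:3]:
            dg = variant_delta_g(small_complex, v, params)
            mut = apply_point_mutation(small_complex, "B", v.position,
                                       v.ref_aa, v.alt_aa)
            diff_oracle = oracle_profile(mut) - wt_oracle
            for label, idxs in small_complex.subunit_map.items():
                np.testing.assert_allclose(
                    dg.per_subunit[label], diff_oracle[list(idxs)],
                    atol=1e-9 * max(1.0, np.abs(wt_oracle).max()),
                )

    def test_localization_decays_with_hop_distance(self, uniform_params):
        """Perturbing one site's interactions: |dG| should shrink with
        network distance from the perturbation on a lattice chain."""
        import networkx as nx
        from nmvar.enm import WeightTable
        from nmvar.synthetic import ToyComplexSpec, make_toy_complex

        s = make_toy_complex(ToyComplexSpec(
            n_chains=2, residues_per_chain=30, geometry="lattice",
            ligand_nodes=0, rng_seed=9,
        ))
        s = assign_subunits(s, "B", "K")
        params = EnmParams(weight_table=WeightTable(
            {("TRP", t): 5.0 for t in
             ["ALA", "GLY", "TRP", "LYS", "SER", "CYS", "PHE", "ASP", "GLU",
              "VAL", "LEU", "ILE", "MET", "TYR", "HIS", "ARG", "ASN", "GLN",
              "PRO", "THR"]}
        ))
        site = s.node_index("B", 15)
        ref = s.nodes[site].residue_type
        alt = "TRP" if ref != "TRP" else "TYR"
        rec = VariantRecord.from_protein_change(
            f"p.{ref.capitalize()}15{alt.capitalize()}",
            phenotype_group="1", patient_count=1,
        )
        dg = variant_delta_g(s, rec, params)
        net = build_network(s, params)
        g = nx.Graph((i, j) for i, j, _r, _k in net.springs)
        hops = nx.single_source_shortest_path_length(g, site)
        mags, dists = [], []
        idxs = s.subunit_map["A"]
        for pos, value in zip(idxs, dg.per_subunit["A"]):
            mags.append(abs(value))
            dists.append(hops[pos])
        rho = spearmanr(mags, dists).statistic
        assert rho < 0
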