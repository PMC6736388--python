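"""Entropy/ΔRMSF coupling, distance matrices, dendrograms, projections."""

import math

import numpy as np
import pytest
from scipy import stats

import famdyn as fd
from famdyn.analysis import DistanceMatrix, dendrogram, tm_score


class TestShannonEntropy:
    def _entropy_of_columns(self, cols):
        from famdyn.ensemble import FamilyEnsemble, Structure
        n = len(cols[0])
        m = len(cols)
        structures = []
        ens = FamilyEnsemble.__new__(FamilyEnsemble)
        ens.aligned_seqs = cols
        ens.core_columns = np.arange(n)
        return fd.shannon_entropy(ens)

    def test_conserved_column_zero(self):
        h = self._entropy_of_columns(["A", "A", "A", "A"])
        assert h[0] == pytest.approx(0.0)

    def test_two_state_column_ln2(self):
        h = self._entropy_of_columns(["A", "A", "G", "G"])
        assert h[0] == pytest.approx(math.log(2))

    def test_uniform_twenty_states_ln20(self):
        cols = [aa for aa in "ACDEFGHIKLMNPQRSTVWY"]
        h = self._entropy_of_columns(cols)
        assert h[0] == pytest.approx(math.log(20))

    def test_gaps_excluded_allgap_nan(self):
        # column 0: A, A, G among non-gaps -> H = -(⅔ln⅔ + ⅓ln⅓)
        h = self._entropy_of_columns(["A-", "A-", "G-", "--"])
        expect = -(2 / 3 * math.log(2 / 3) + 1 / 3 * math.log(1 / 3))
        assert h[0] == pytest.approx(expect)
        assert np.isnan(h[1])

    def test_bounds_on_family(self, ensemble):
        h = fd.shannon_entropy(ensemble)
        ok = np.isfinite(h)
        assert np.all(h[ok] >= 0.0)
        assert np.all(h[ok] <= math.log(20) + 1e-12)


class TestDeltaRmsf:
    def test_identical_members_zero(self, default_family):
        from famdyn.ensemble import Structure
        a = default_family.structures[0]
        members = [Structure(f"c{i}", a.residue_labels, a.ca_coords.copy(),
                             a.sequence) for i in range(3)]
        ens = fd.build_ensemble(members,
                                {m.member_id: m.sequence for m in members})
        dr = fd.delta_rmsf(fd.build_mode_ensemble(ens), (1, 20))
        assert np.allclose(dr, 0.0, atol=1e-9)

    def test_two_members_closed_form(self, default_family):
        from famdyn.ensemble import Structure
        a, b = default_family.structures[:2]
        ens = fd.build_ensemble(
            [a, b], {a.member_id: a.sequence, b.member_id: b.sequence})
        me = fd.build_mode_ensemble(ens)
        dr = fd.delta_rmsf(me, (1, 20))
        prof = fd.signature_msf(me, (1, 20), as_rmsf=True)
        expect = np.abs(prof.per_member[0] - prof.per_member[1]) / math.sqrt(2)
        assert np.allclose(dr, expect, atol=1e-12)

    def test_window_beyond_k_clipped_with_warning(self, gnm_ensemble):
        with pytest.warns(UserWarning, match="clipped"):
            dr = fd.delta_rmsf(gnm_ensemble, (61, 10 ** 6))
        assert np.all(np.isfinite(dr[np.isfinite(dr)]))

    def test_positive_entropy_flexibility_coupling(self, ensemble,
                                                   gnm_ensemble):
        """Mobility-proportional substitution ⇒ Spearman(H, ΔRMSF) > 0."""
        h = fd.shannon_entropy(ensemble)
        dr = fd.delta_rmsf(gnm_ensemble)
        ok = np.isfinite(h) & np.isfinite(dr)
        rho = stats.spearmanr(h[ok], dr[ok]).statistic
        assert rho > 0


class TestEntropyBinnedDivergence:
    def test_lognormal_parameter_recovery(self):
        """MLE on n=5000 lognormal entropies recovers (μ, σ) within 5%."""
        rng = np.random.default_rng(27)
        mu, sigma = 0.6, 0.35
        h = rng.lognormal(mu, sigma, size=5000)
        d = rng.uniform(0.5, 1.5, size=5000)
        curve = fd.entropy_binned_divergence(h, d)
        assert curve.lognorm_mu == pytest.approx(mu, rel=0.05)
        assert curve.lognorm_sigma == pytest.approx(sigma, rel=0.05)
        assert curve.pearson_r > 0.95

    def test_constant_divergence_flat_curve(self):
        rng = np.random.default_rng(28)
        h = rng.lognormal(0.5, 0.3, 200)
        curve = fd.entropy_binned_divergence(h, np.full(200, 2.5))
        assert np.allclose(curve.mean_divergence, 2.5)

    def test_small_bins_dropped(self):
        h = np.concatenate([np.full(10, 0.2), [2.9]])
        d = np.ones(11)
        curve = fd.entropy_binned_divergence(h, d)
        assert len(curve.bin_centers) == 1

    def test_degenerate_entropy_rejected(self):
        with pytest.raises(ValueError):
            fd.entropy_binned_divergence(np.zeros(50), np.ones(50))


class TestDistanceMatrices:
    def test_hamming_values(self, ensemble):
        dm = fd.sequence_distance_matrix(ensemble)
        assert dm.metric == "hamming"
        assert np.allclose(np.diag(dm.matrix), 0.0)
        assert dm.matrix.max() <= 1.0
        # spot-check one pair against a direct count
        a, b = ensemble.aligned_seqs[0], ensemble.aligned_seqs[1]
        both = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
        expect = 1.0 - sum(x == y for x, y in both) / len(both)
        assert dm.matrix[0, 1] == pytest.approx(expect)

    def test_relabeling_invariance(self, gnm_ensemble):
        d = fd.pairwise_spectral_distances(gnm_ensemble, (1, 3))
        order = np.random.default_rng(29).permutation(len(d))
        assert np.allclose(d[np.ix_(order, order)],
                           d[np.ix_(order, order)].T)

    def test_all_matrices_nonnegative_symmetric(self, ensemble,
                                                gnm_ensemble):
        for dm in (fd.sequence_distance_matrix(ensemble),
                   fd.rmsd_distance_matrix(ensemble),
                   fd.tm_distance_matrix(ensemble),
                   fd.spectral_distance_matrix(gnm_ensemble, (1, 3))):
            assert np.allclose(dm.matrix, dm.matrix.T)
            assert np.all(dm.matrix >= -1e-12)
            assert np.allclose(np.diag(dm.matrix), 0.0, atol=1e-12)


class TestTmScore:
    def test_identical_structures_one(self, ensemble):
        c = ensemble.coords[0]
        assert tm_score(c, c, l_norm=ensemble.n_core) == pytest.approx(1.0)

    def test_d0_arithmetic(self):
        # L = 100: d0 = 1.24·85^⅓ − 1.8 ≈ 3.652
        d0 = 1.24 * 85 ** (1 / 3) - 1.8
        assert d0 == pytest.approx(3.652, abs=5e-3)
        a = np.zeros((100, 3))
        b = a.copy()
        b[0, 0] = d0  # one residue displaced by exactly d0 -> term = 1/2
        assert tm_score(a, b, l_norm=100) == pytest.approx(99.5 / 100)

    def test_l_norm_validation(self):
        with pytest.raises(ValueError):
            tm_score(np.zeros((5, 3)), np.zeros((5, 3)), l_norm=0)


class TestSubfamilyDistances:
    def test_constructed_subfamilies(self, default_family):
        from famdyn.ensemble import Structure
        # two subfamilies of identical members; subfamilies differ
        a = default_family.structures[0]
        b = default_family.structures[1]
        members, labels = [], {}
        for i in range(4):
            src = a if i < 2 else b
            s = Structure(f"x{i}", src.residue_labels, src.ca_coords.copy(),
                          src.sequence)
            members.append(s)
            labels[f"x{i}"] = "p" if i < 2 else "q"
        ens = fd.build_ensemble(members,
                                {m.member_id: m.sequence for m in members})
        me = fd.build_mode_ensemble(ens)
        sub = fd.subfamily_distances(me, [labels[m] for m in ens.member_ids],
                                     (1, 10), min_size=2)
        # arccos amplifies float noise near SO = 1, hence the loose floor
        assert np.allclose(np.diag(sub.matrix), 0.0, atol=1e-3)
        assert sub.matrix[0, 1] > 0.05

    def test_matches_bruteforce_pair_loop(self, gnm_ensemble, ensemble):
        labels = ensemble.subfamily_labels
        sub = fd.subfamily_distances(gnm_ensemble, labels, (21, 60))
        dmat = fd.pairwise_spectral_distances(gnm_ensemble, (21, 60))
        names = sub.labels
        for p, gp in enumerate(names):
            for s, gs in enumerate(names):
                vals = []
                for i in range(len(labels)):
                    for j in range(len(labels)):
                        if i >= j:
                            continue
                        li, lj = labels[i], labels[j]
                        if {li, lj} == {gp, gs} or \
                                (gp == gs and li == lj == gp):
                            vals.append(dmat[i, j])
                assert sub.matrix[p, s] == pytest.approx(np.mean(vals))

    def test_small_subfamilies_excluded(self, gnm_ensemble, ensemble):
        labels = list(ensemble.subfamily_labels)
        labels[0] = "tiny"
        sub = fd.subfamily_distances(gnm_ensemble, labels, (21, 60),
                                     min_size=4)
        assert "tiny" in sub.excluded

    def test_too_few_subfamilies_rejected(self, gnm_ensemble, ensemble):
        with pytest.raises(ValueError):
            fd.subfamily_distances(gnm_ensemble,
                                   ["one"] * gnm_ensemble.n_members,
                                   (21, 60))


class TestDendrogram:
    def test_hand_upgma_three_leaves(self):
        m = np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
        dm = DistanceMatrix(["A", "B", "C"], m, "hamming")
        newick, order, _ = dendrogram(dm)
        assert newick == "((A:0.5,B:0.5):1.5,C:2);"
        assert order.index("C") in (0, 2)

    def test_ultrametric_reconstruction(self):
        # generating tree: ((A,B):h1, (C,D):h2) with known heights
        m = np.zeros((4, 4))
        ab, cd, root = 1.0, 2.0, 6.0
        m[0, 1] = m[1, 0] = ab
        m[2, 3] = m[3, 2] = cd
        for i in (0, 1):
            for j in (2, 3):
                m[i, j] = m[j, i] = root
        dm = DistanceMatrix(list("ABCD"), m, "rmsd")
        _, _, z = dendrogram(dm)
        assert sorted(np.round(z[:, 2], 9)) == [ab, cd, root]

    def test_two_leaves_cherry(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 3.0], [3.0, 0.0]]),
                            "rmsd")
        newick, _, _ = dendrogram(dm)
        assert newick == "(A:1.5,B:1.5);"

    def test_leaf_order_covers_all_members(self, ensemble, gnm_ensemble):
        dm = fd.spectral_distance_matrix(gnm_ensemble, (1, 3))
        _, order, _ = dendrogram(dm)
        assert sorted(order) == sorted(ensemble.member_ids)


class TestStructurePca:
    def test_rank_one_construction(self, default_family):
        from famdyn.ensemble import Structure
        rng = np.random.default_rng(30)
        a = default_family.structures[0]
        direction = rng.normal(size=a.ca_coords.shape)
        direction /= np.linalg.norm(direction)
        amps = [-2.0, -1.0, 0.5, 2.5]
        members = [Structure(f"p{i}", a.residue_labels,
                             a.ca_coords + amp * direction, a.sequence)
                   for i, amp in enumerate(amps)]
        ens = fd.build_ensemble(members,
                                {m.member_id: m.sequence for m in members})
        pca = fd.structure_pca(ens)
        # superposition leaks a sliver of variance into higher components
        assert pca.variance_fractions[0] == pytest.approx(1.0, abs=1e-4)
        # projections recover amplitudes up to sign/centering
        proj = pca.projections[:, 0]
        centered = np.array(amps) - np.mean(amps)
        ratio = proj / centered
        assert np.allclose(np.abs(ratio), np.abs(ratio[0]), rtol=1e-4)

    def test_projection_columns_centered(self, ensemble):
        pca = fd.structure_pca(ensemble)
        assert np.allclose(pca.projections.mean(axis=0), 0.0, atol=1e-9)

    def test_identical_members_flagged(self, default_family):
        from famdyn.ensemble import Structure
        a = default_family.structures[0]
        members = [Structure(f"i{i}", a.residue_labels, a.ca_coords.copy(),
                             a.sequence) for i in range(3)]
        ens = fd.build_ensemble(members,
                                {m.member_id: m.sequence for m in members})
        with pytest.warns(UserWarning, match="degenerate"):
            pca = fd.structure_pca(ens)
        assert pca.degenerate
        assert np.allclose(pca.projections, 0.0)


class TestSignatureProjection:
    def test_member_along_signature_mode(self, ensemble, anm_ensemble):
        proj = fd.project_on_signature_modes(anm_ensemble, ensemble)
        assert proj.shape == (ensemble.n_members, 2)
        # reconstruct projection independently from definition
        s1 = anm_ensemble.vectors[:, :, 0].mean(axis=0)
        s1 /= np.linalg.norm(s1)
        dr0 = np.nan_to_num(
            ensemble.coords[0].ravel() - ensemble.mean_coords().ravel())
        assert proj[0, 0] == pytest.approx(dr0 @ s1)

    def test_gnm_ensemble_rejected(self, ensemble, gnm_ensemble):
        with pytest.raises(ValueError, match="ANM"):
            fd.project_on_signature_modes(gnm_ensemble, ensemble)
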