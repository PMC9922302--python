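"""Ensemble-comparison metric suite: zeros, oracles, invariances."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from disgen.cg import KB
from disgen.ensembles_io import Conformation, ConformationalEnsemble, ResidueSequence
from disgen.metrics import (
    ContactMap,
    akld_d,
    contact_map,
    drmsd,
    emd_drmsd,
    histogram_kld,
    kld_r,
    median_energy_difference,
    memorization_search,
    metric_report,
    mse_c,
    mse_d,
    pca_pmf,
    radius_of_gyration,
)


def random_ensemble(L=6, n=20, seed=0, spread=0.4):
    rng = np.random.default_rng(seed)
    xyz = np.cumsum(rng.normal(scale=spread, size=(n, L, 3)), axis=1)
    return ConformationalEnsemble(ResidueSequence("r", "A" * L), xyz)


class TestContactMap:
    def test_counting(self):
        seq = ResidueSequence("t", "AAA")
        frames = np.zeros((2, 3, 3))
        frames[0, 2, 0] = 0.5   # pair (0,2) at 0.5 nm in frame 0
        frames[1, 2, 0] = 0.9   # and 0.9 nm in frame 1
        frames[:, 1, 1] = 0.3
        cm = contact_map(ConformationalEnsemble(seq, frames))
        assert cm.frequencies[0, 2] == pytest.approx(0.5)
        assert cm.frequencies[2, 0] == pytest.approx(0.5)

    @pytest.mark.parametrize("d,expected", [(0.5, 1.0), (0.9, 0.0)])
    def test_always_or_never(self, d, expected):
        seq = ResidueSequence("t", "AAA")
        frames = np.zeros((4, 3, 3))
        frames[:, 1, 1] = 0.3
        frames[:, 2, 0] = d
        cm = contact_map(ConformationalEnsemble(seq, frames))
        assert cm.frequencies[0, 2] == expected

    def test_mse_c_hand_value(self):
        """One pair ref 0.5 vs gen 0 (pseudo-count 0.01), others equal:
        (ln 50)^2 / 6."""
        L = 4
        ref = np.full((L, L), 0.3)
        gen = ref.copy()
        ref[0, 1] = ref[1, 0] = 0.5
        gen[0, 1] = gen[1, 0] = 0.0
        val = mse_c(ContactMap(ref), ContactMap(gen))
        assert val == pytest.approx(np.log(50.0) ** 2 / 6, rel=1e-12)

    def test_mse_c_symmetric_in_arguments(self):
        a = contact_map(random_ensemble(seed=1))
        b = contact_map(random_ensemble(seed=2))
        assert mse_c(a, b) == pytest.approx(mse_c(b, a), rel=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            mse_c(ContactMap(np.zeros((3, 3))), ContactMap(np.zeros((4, 4))))


class TestMseD:
    def test_constant_shift(self):
        """All mean pairwise distances differing by 0.1 nm -> 0.01 nm^2."""
        seq = ResidueSequence("t", "AAA")
        a = np.zeros((1, 3, 3)); a[0, :, 0] = [0, 1, 2]
        b = np.zeros((1, 3, 3)); b[0, :, 0] = [0, 1.1, 2.2]
        # pairs: (01)=1 vs 1.1, (02)=2 vs 2.2, (12)=1 vs 1.1 -> not all 0.1
        ens_a = ConformationalEnsemble(seq, a)
        ens_b = ConformationalEnsemble(seq, b)
        expected = np.mean([0.1**2, 0.2**2, 0.1**2])
        assert mse_d(ens_a, ens_b) == pytest.approx(expected, rel=1e-12)

    def test_two_frame_hand_arithmetic(self):
        seq = ResidueSequence("d", "AA")
        a = np.zeros((2, 2, 3)); a[0, 1, 0] = 1.0; a[1, 1, 0] = 3.0   # mean 2.0
        b = np.zeros((2, 2, 3)); b[0, 1, 0] = 2.0; b[1, 1, 0] = 4.0   # mean 3.0
        assert mse_d(ConformationalEnsemble(seq, a),
                     ConformationalEnsemble(seq, b)) == pytest.approx(1.0)


class TestHistogramKld:
    def test_identical_samples_zero(self):
        x = np.random.default_rng(0).normal(size=500)
        assert histogram_kld(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_closed_form(self):
        """P=(1/2,1/2), Q=(1/4,3/4) with 2 bins: 0.5 ln2 + 0.5 ln(2/3)."""
        ref = np.array([0.0] * 2 + [1.0] * 2)
        gen = np.array([0.0] * 1 + [1.0] * 3)
        expected = 0.5 * np.log(2) + 0.5 * np.log(2 / 3)
        assert histogram_kld(ref, gen, n_bins=2) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_range_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert histogram_kld(np.ones(5), np.ones(7)) == 0.0

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = rng.normal(loc=rng.uniform(-1, 1), scale=rng.uniform(0.5, 2), size=300)
            b = rng.normal(loc=rng.uniform(-1, 1), scale=rng.uniform(0.5, 2), size=300)
            assert histogram_kld(a, b) >= 0.0


class TestRadiusOfGyration:
    def test_single_point(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_points(self):
        assert radius_of_gyration(np.array([[0, 0, 0], [2.0, 0, 0]])) == pytest.approx(1.0)

    def test_equilateral_triangle(self):
        s = 1.7
        tri = np.array([[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]])
        assert radius_of_gyration(tri) == pytest.approx(s / np.sqrt(3), rel=1e-12)


class TestDrmsd:
    def test_identical_zero(self):
        a = random_ensemble(seed=3)[0]
        assert drmsd(a, a) == 0.0

    def test_mirror_images_zero(self):
        a = random_ensemble(seed=4)[0]
        b = Conformation(a.coords * np.array([1.0, 1.0, -1.0]))
        assert drmsd(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_triangle_vs_collinear_hand_value(self):
        """Equilateral side-1 triangle vs collinear (1,1,2) distances: sqrt(1/3)."""
        tri = Conformation([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        line = Conformation([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        assert drmsd(tri, line) == pytest.approx(np.sqrt(1 / 3), rel=1e-12)


class TestEmdDrmsd:
    def test_self_is_zero(self):
        ens = random_ensemble(n=15, seed=5)
        assert emd_drmsd(ens, ens, max_n=15, seed=0) == pytest.approx(0.0, abs=1e-6)

    def test_frame_permutation_is_zero(self):
        ens = random_ensemble(n=12, seed=6)
        perm = ConformationalEnsemble(ens.sequence, ens.xyz[::-1].copy())
        assert emd_drmsd(ens, perm, max_n=12, seed=0) == pytest.approx(0.0, abs=1e-6)

    def test_matches_exhaustive_permutation_oracle(self):
        """Hungarian result equals brute-force minimum over all n! pairings."""
        from disgen.gan.features import distance_features

        rng = np.random.default_rng(9)
        for trial in range(50):
            n = int(rng.integers(2, 7))
            a = random_ensemble(L=5, n=n, seed=100 + trial)
            b = random_ensemble(L=5, n=n, seed=200 + trial)
            got = emd_drmsd(a, b, max_n=n, seed=0)
            fa = distance_features(a.xyz)
            fb = distance_features(b.xyz)
            P = fa.shape[1]
            cost = np.sqrt(((fa[:, None] - fb[None]) ** 2).mean(axis=2))
            best = min(np.mean([cost[i, p[i]] for i in range(n)])
                       for p in itertools.permutations(range(n)))
            assert got == pytest.approx(best, rel=1e-9)


class TestMed:
    def test_identical_zero(self, ff):
        ens = random_ensemble(L=5, n=9, seed=7)
        assert median_energy_difference(ens, ens, ens.sequence, ff) == 0.0

    def test_clash_direction_positive(self, ff):
        ens = random_ensemble(L=5, n=9, seed=8, spread=0.5)
        squeezed = ConformationalEnsemble(ens.sequence, ens.xyz * 0.25)
        assert median_energy_difference(ens, squeezed, ens.sequence, ff) > 0

    def test_three_frame_hand_medians(self, ff):
        from disgen.cg import cg_energy

        seq = ResidueSequence("d", "AA")
        lengths_a, lengths_b = [0.36, 0.38, 0.40], [0.38, 0.42, 0.44]
        xa = np.zeros((3, 2, 3)); xa[:, 1, 0] = lengths_a
        xb = np.zeros((3, 2, 3)); xb[:, 1, 0] = lengths_b
        med = median_energy_difference(ConformationalEnsemble(seq, xa),
                                       ConformationalEnsemble(seq, xb), seq, ff)
        e = lambda l: cg_energy(Conformation([[0, 0, 0], [l, 0, 0]]), seq, ff).total
        expected = np.median([e(l) for l in lengths_b]) - np.median([e(l) for l in lengths_a])
        assert med == pytest.approx(expected, rel=1e-12)


class TestMetricZeroSuite:
    def test_all_metrics_zero_on_identical_ensembles(self, ff):
        ens = random_ensemble(L=6, n=30, seed=10)
        rep = metric_report(ens, ens, ens.sequence, ff, emd_max_n=30)
        assert rep.mse_c == 0.0
        assert rep.mse_d == 0.0
        assert rep.akld_d == pytest.approx(0.0, abs=1e-12)
        assert rep.emd_drmsd == pytest.approx(0.0, abs=1e-6)
        assert rep.kld_r == pytest.approx(0.0, abs=1e-12)
        assert rep.med == 0.0

    def test_metrics_invariant_under_rigid_motion_and_reflection(self, ff):
        ens = random_ensemble(L=6, n=25, seed=11)
        rng = np.random.default_rng(1)
        moved = np.empty_like(ens.xyz)
        for i in range(len(ens)):
            R = Rotation.random(random_state=i).as_matrix()
            refl = np.diag([1.0, 1.0, -1.0]) if i % 2 else np.eye(3)
            moved[i] = ens.xyz[i] @ (R @ refl).T + rng.normal(size=3)
        ens2 = ConformationalEnsemble(ens.sequence, moved)
        rep = metric_report(ens, ens2, ens.sequence, ff, emd_max_n=25)
        assert rep.mse_c == pytest.approx(0.0, abs=1e-6)
        assert rep.mse_d == pytest.approx(0.0, abs=1e-12)
        assert rep.akld_d == pytest.approx(0.0, abs=1e-6)
        assert rep.emd_drmsd == pytest.approx(0.0, abs=1e-6)
        assert rep.kld_r == pytest.approx(0.0, abs=1e-6)
        assert abs(rep.med) < 1e-6


class TestPcaPmf:
    def test_query_equals_reference_identical_maps(self):
        ens = random_ensemble(L=6, n=300, seed=12)
        ref_map, q_map = pca_pmf(ens, ens, bins=10)
        assert np.allclose(np.nan_to_num(ref_map.free_energy),
                           np.nan_to_num(q_map.free_energy))

    def test_component_variance_ordering(self):
        from disgen.gan.features import distance_features
        from sklearn.decomposition import PCA

        ens = random_ensemble(L=6, n=200, seed=13)
        pca = PCA(n_components=2).fit(distance_features(ens.xyz))
        assert pca.explained_variance_[0] >= pca.explained_variance_[1]

    def test_gaussian_features_give_quadratic_bowl(self):
        """Gaussian projections: PMF = kT z_i^2 / (2 var_i) + const per component.

        A regression of the binned free energy on (z1^2, z2^2) over
        well-populated cells must recover the analytic curvatures.
        """
        from sklearn.decomposition import PCA

        from disgen.gan.features import distance_features

        rng = np.random.default_rng(14)
        n = 40000
        xyz = np.zeros((n, 3, 3))
        xyz[:, 1, 0] = rng.normal(2.0, 0.15, size=n)
        xyz[:, 2, 1] = rng.normal(3.0, 0.15, size=n)
        ens = ConformationalEnsemble(ResidueSequence("t", "AAA"), xyz)
        ref_map, _ = pca_pmf(ens, ens, bins=25)
        kT = KB * 298.0
        proj = PCA(n_components=2).fit_transform(distance_features(ens.xyz))
        var1, var2 = proj.var(axis=0)
        xc = (ref_map.xedges[:-1] + ref_map.xedges[1:]) / 2
        yc = (ref_map.yedges[:-1] + ref_map.yedges[1:]) / 2
        X, Y = np.meshgrid(xc, yc, indexing="ij")
        fe = ref_map.free_energy
        ok = np.isfinite(fe) & (fe - np.nanmin(fe) < 2.5 * kT)
        A = np.column_stack([X[ok] ** 2, Y[ok] ** 2, np.ones(ok.sum())])
        coef, *_ = np.linalg.lstsq(A, fe[ok], rcond=None)
        assert coef[0] == pytest.approx(kT / (2 * var1), rel=0.15)
        assert coef[1] == pytest.approx(kT / (2 * var2), rel=0.15)

    def test_rank_deficient_reference_errors(self):
        xyz = np.zeros((50, 3, 3))
        xyz[:, 1, 0] = 1.0
        xyz[:, 2, 0] = 2.0
        ens = ConformationalEnsemble(ResidueSequence("t", "AAA"), xyz)
        with pytest.raises(ValueError):
            pca_pmf(ens, ens)


class TestMemorization:
    def test_training_copy_has_zero_neighbor(self):
        train = random_ensemble(L=5, n=20, seed=15)
        gen = ConformationalEnsemble(train.sequence, train.xyz[3:4].copy(), "generated")
        d = memorization_search(gen, [train])
        assert d.shape == (1,) and d[0] == pytest.approx(0.0, abs=1e-12)

    def test_output_length_matches_generated(self):
        train = random_ensemble(L=5, n=10, seed=16)
        gen = random_ensemble(L=5, n=7, seed=17)
        assert memorization_search(gen, [train]).shape == (7,)

    def test_disjoint_rigid_shapes_positive(self):
        seq = ResidueSequence("t", "AAA")
        tri = np.array([[[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]]])
        line = np.array([[[0, 0, 0], [1, 0, 0], [2, 0, 0]]])
        gen = ConformationalEnsemble(seq, tri, "generated")
        train = ConformationalEnsemble(seq, line)
        assert memorization_search(gen, [train])[0] == pytest.approx(np.sqrt(1 / 3), rel=1e-9)

    def test_empty_pool_errors(self):
        gen = random_ensemble(seed=18)
        with pytest.raises(ValueError):
            memorization_search(gen, [])
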