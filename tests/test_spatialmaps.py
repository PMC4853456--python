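import numpy as np
import pytest

from tractmvpa.classify import ClassifierSpec
from tractmvpa.cohort import EffectSpec, NoiseSpec, simulate_dti_cohort
from tractmvpa.skeletons import make_skeleton
from tractmvpa.spatialmaps import (TFCEParams, VoxelMap,
                                   bootstrap_coefficient_map,
                                   coef_covariance_diagnostics,
                                   group_covariance_map, tfce,
                                   tfce_permutation_fwe)

from _oracles import tfce_chain_oracle


class TestCovarianceMap:
    def test_hand_value(self, chain_skeleton):
        X = np.array([[2.0, 0, 0, 0], [2.0, 0, 0, 0],
                      [0.0, 0, 0, 0], [0.0, 0, 0, 0]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        m = group_covariance_map(X, y, chain_skeleton)
        assert m.values[0] == pytest.approx(4.0 / 3.0)

    def test_mirrored_values_give_exact_zero(self, chain_skeleton):
        X = np.array([[1.0], [-1.0], [1.0], [-1.0]]) @ np.ones((1, 4))
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert group_covariance_map(X, y, chain_skeleton).values[0] == 0.0

    def test_label_flip_antisymmetry_exact(self, small_cohort):
        X = small_cohort.metric("MD")
        y = small_cohort.y
        a = group_covariance_map(X, y, small_cohort.skeleton).values
        b = group_covariance_map(X, -y, small_cohort.skeleton).values
        assert np.array_equal(a, -b)

    def test_sign_pattern_recovered_in_end_regions(self):
        sk = make_skeleton(n_voxels=300, seed=13)
        noise = NoiseSpec()
        c = simulate_dti_cohort(sk, n_pos=200, n_neg=200,
                                effect=EffectSpec(metric="MD",
                                                  amplitude=3 * noise.total_voxel_sd),
                                noise=noise, behaviour=False, seed=14)
        cov = group_covariance_map(c.metric("MD"), c.y, sk).values
        fro = sk.region_indices("frontal")
        tem = sk.region_indices("temporal")
        agree = np.concatenate([np.sign(cov[fro]) == 1, np.sign(cov[tem]) == -1])
        assert agree.mean() >= 0.95

    def test_constant_labels_rejected(self, chain_skeleton):
        with pytest.raises(ValueError):
            group_covariance_map(np.zeros((3, 4)), np.ones(3), chain_skeleton)


class TestTFCE:
    def test_all_zero_map(self, chain_skeleton):
        out = tfce(VoxelMap(np.zeros(4), chain_skeleton), TFCEParams(dh=1.0))
        assert np.array_equal(out.values, np.zeros(4))

    def test_chain_hand_oracle(self, chain_skeleton):
        """(0,2,2,0) with E=0.5, H=2, dh=1: middle voxels collect
        sqrt(2)*(1+4) ~ 7.071, ends 0."""
        vals = np.array([0.0, 2.0, 2.0, 0.0])
        out = tfce(VoxelMap(vals, chain_skeleton),
                   TFCEParams(E=0.5, H=2.0, dh=1.0))
        assert out.values[1] == pytest.approx(np.sqrt(2) * 5.0)
        assert out.values[0] == 0.0
        expected = tfce_chain_oracle(vals, 0.5, 2.0, 1.0)
        assert np.allclose(out.values, expected)

    def test_matches_chain_oracle_on_random_maps(self, chain_skeleton):
        rng = np.random.default_rng(1)
        coords = np.array([[i, 0, 0] for i in range(12)])
        edges = np.array([[i, i + 1] for i in range(11)])
        sk_type = type(chain_skeleton)
        sk = sk_type(coords, edges, np.array(["mid"] * 12, dtype=object),
                     np.linspace(0, 1, 12))
        for _ in range(20):
            vals = np.round(rng.random(12) * 4, 2)
            out = tfce(VoxelMap(vals, sk), TFCEParams(E=0.5, H=2.0, dh=0.25))
            assert np.allclose(out.values, tfce_chain_oracle(vals, 0.5, 2.0, 0.25))

    def test_negative_values_enhanced_and_resigned(self, chain_skeleton):
        vals = np.array([0.0, -2.0, -2.0, 0.0])
        out = tfce(VoxelMap(vals, chain_skeleton), TFCEParams(E=0.5, H=2.0, dh=1.0))
        assert out.values[1] == pytest.approx(-np.sqrt(2) * 5.0)

    def test_monotone_in_input(self, small_skeleton):
        """Pointwise raising the map never lowers any TFCE value."""
        rng = np.random.default_rng(2)
        params = TFCEParams(E=0.5, H=2.0, dh=0.05)
        for _ in range(25):
            base = rng.random(small_skeleton.n_voxels)
            bump = base + rng.random(small_skeleton.n_voxels) * 0.5
            t_base = tfce(VoxelMap(base, small_skeleton), params).values
            t_bump = tfce(VoxelMap(bump, small_skeleton), params).values
            assert (t_bump >= t_base - 1e-9).all()

    def test_riemann_refinement_converges(self, small_skeleton):
        rng = np.random.default_rng(3)
        vals = np.abs(rng.normal(size=small_skeleton.n_voxels))
        a = tfce(VoxelMap(vals, small_skeleton), TFCEParams(dh=0.01)).values
        b = tfce(VoxelMap(vals, small_skeleton), TFCEParams(dh=0.005)).values
        denom = np.abs(b).max()
        assert np.abs(a - b).max() / denom < 0.01

    def test_oversized_dh_warns_single_step(self, chain_skeleton):
        vals = np.array([0.0, 1.0, 1.0, 0.0])
        with pytest.warns(UserWarning, match="single step"):
            out = tfce(VoxelMap(vals, chain_skeleton), TFCEParams(dh=5.0))
        assert out.values[1] > 0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TFCEParams(E=-1)
        with pytest.raises(ValueError):
            TFCEParams(dh=0.0)


class TestTFCEPermutation:
    def test_implanted_effect_detected(self):
        sk = make_skeleton(n_voxels=150, seed=21)
        noise = NoiseSpec()
        c = simulate_dti_cohort(sk, n_pos=50, n_neg=50,
                                effect=EffectSpec(metric="MD",
                                                  amplitude=5 * noise.total_voxel_sd),
                                noise=noise, behaviour=False, seed=22)
        res = tfce_permutation_fwe(c.metric("MD"), c.y, sk, n_perm=200, seed=23)
        p = res["p_fwe"].values
        ends = np.r_[sk.region_indices("frontal"), sk.region_indices("temporal")]
        assert p[ends].min() <= 0.05

    def test_p_bounds_and_monotonicity(self, null_cohort):
        res = tfce_permutation_fwe(null_cohort.metric("MD"), null_cohort.y,
                                   null_cohort.skeleton, n_perm=50, seed=24)
        p = res["p_fwe"].values
        assert (p >= 1 / 50 - 1e-12).all() and (p <= 1.0).all()
        # p non-increasing in |TFCE|
        order = np.argsort(np.abs(res["tfce"].values))
        assert (p[order][:-1] >= p[order][1:] - 1e-12).all()

    def test_null_rejection_rate_controlled(self):
        sk = make_skeleton(n_voxels=60, seed=25)
        rej = 0
        n_rep = 20
        for r in range(n_rep):
            c = simulate_dti_cohort(sk, n_pos=12, n_neg=12,
                                    effect=EffectSpec(amplitude=0.0),
                                    noise=NoiseSpec(), behaviour=False,
                                    seed=2500 + r)
            res = tfce_permutation_fwe(c.metric("MD"), c.y, sk, n_perm=50,
                                       seed=3500 + r)
            rej += res["p_fwe"].values.min() <= 0.05
        # exact binomial 95% band around 0.05 for 20 replicates: [0, 3]
        assert rej <= 3


class TestBootstrapMap:
    SPEC = ClassifierSpec(family="enet_lrc", lambda1=0.05, alpha=0.5)

    def test_identity_resample_equals_single_fit(self, small_cohort):
        from tractmvpa.classify import train_enet_lrc
        X = small_cohort.metric("MD")
        y = small_cohort.y
        boot = bootstrap_coefficient_map(
            X, y, small_cohort.skeleton, self.SPEC, n_boot=1,
            _resample_hook=lambda b: np.arange(len(y)))
        ref = train_enet_lrc(X, y, self.SPEC)
        assert np.allclose(boot["coef"].values, ref.coefficient_map())

    def test_same_seed_reproduces_map(self, small_cohort):
        X = small_cohort.metric("MD")
        kw = dict(spec=self.SPEC, n_boot=10, seed=6)
        a = bootstrap_coefficient_map(X, small_cohort.y,
                                      small_cohort.skeleton, **kw)
        b = bootstrap_coefficient_map(X, small_cohort.y,
                                      small_cohort.skeleton, **kw)
        assert np.array_equal(a["coef"].values, b["coef"].values)

    def test_signs_match_covariance_under_strong_signal(self, small_cohort):
        X = small_cohort.metric("MD")
        y = small_cohort.y
        boot = bootstrap_coefficient_map(X, y, small_cohort.skeleton,
                                         self.SPEC, n_boot=40, seed=7)
        cov = group_covariance_map(X, y, small_cohort.skeleton)
        diag = coef_covariance_diagnostics(boot["coef"], cov)
        assert diag.n_nonzero > 0
        assert diag.sign_agreement >= 0.95

    def test_nonlinear_family_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            bootstrap_coefficient_map(small_cohort.metric("MD"), small_cohort.y,
                                      small_cohort.skeleton,
                                      ClassifierSpec(family="svm"), n_boot=1)


class TestDiagnostics:
    def test_identity_and_antisymmetry(self, chain_skeleton):
        vals = np.array([0.5, -1.0, 0.0, 2.0])
        a = VoxelMap(vals.copy(), chain_skeleton, semantics="coefficient")
        b = VoxelMap(vals.copy(), chain_skeleton)
        d = coef_covariance_diagnostics(a, b)
        assert d.sign_agreement == 1.0 and d.pearson_r == pytest.approx(1.0)
        assert d.n_nonzero == 3
        neg = VoxelMap(-vals, chain_skeleton)
        d2 = coef_covariance_diagnostics(a, neg)
        assert d2.sign_agreement == 0.0 and d2.pearson_r == pytest.approx(-1.0)

    def test_hand_pearson_on_toy_maps(self):
        coords = np.array([[i, 0, 0] for i in range(5)])
        edges = np.array([[i, i + 1] for i in range(4)])
        from tractmvpa.skeletons import TractSkeleton
        sk = TractSkeleton(coords, edges, np.array(["mid"] * 5, dtype=object),
                           np.linspace(0, 1, 5))
        c = np.array([1.0, 2.0, 0.0, -1.0, 3.0])
        v = np.array([0.5, 1.0, 9.0, -2.0, 2.5])
        d = coef_covariance_diagnostics(VoxelMap(c, sk), VoxelMap(v, sk))
        mask = c != 0
        expected = np.corrcoef(c[mask], v[mask])[0, 1]
        assert d.pearson_r == pytest.approx(expected, abs=1e-12)

    def test_all_zero_coefficients_explicit_empty(self, chain_skeleton):
        d = coef_covariance_diagnostics(VoxelMap(np.zeros(4), chain_skeleton),
                                        VoxelMap(np.ones(4), chain_skeleton))
        assert d.n_nonzero == 0
        assert d.sign_agreement is None and d.pearson_r is None
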