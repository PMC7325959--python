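"""Temporal cleaning, PCA/MDL, group ICA, back-reconstruction, Z-maps and
template matching."""

import numpy as np
import pytest
from scipy import signal as spsignal

from effconn import extraction
from effconn.extraction import (
    GroupICA,
    amari_index,
    back_reconstruct,
    estimate_order_mdl,
    match_templates,
    mean_active_z,
    pca_reduce,
    preprocess_timecourses,
    run_group_ica,
    zscore_and_mask,
)

TR = 2.0


def band_power(x, fs, lo, hi):
    f, p = spsignal.periodogram(x, fs=fs)
    return float(p[(f >= lo) & (f <= hi)].sum())


class TestPreprocess:
    def test_self_regression_leaves_nothing(self, rng):
        Y = rng.normal(size=(200, 3))
        out = preprocess_timecourses(Y, TR, nuisance=Y)
        assert np.max(np.abs(out)) < 1e-8

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(512) * TR
        x = np.sin(2 * np.pi * 0.005 * t)
        out = preprocess_timecourses(x, TR)
        before = band_power(x, 1 / TR, 0.003, 0.007)
        after = band_power(out[:, 0], 1 / TR, 0.003, 0.007)
        assert after < 0.1 * before

    def test_passband_sinusoid_preserved(self):
        t = np.arange(512) * TR
        x = np.sin(2 * np.pi * 0.05 * t)
        out = preprocess_timecourses(x, TR)
        amp = out[:, 0][100:-100].std() * np.sqrt(2)
        assert amp == pytest.approx(1.0, rel=0.10)

    def test_output_columns_are_centred(self, rng):
        Y = rng.normal(size=(300, 4)) + 5.0
        out = preprocess_timecourses(Y, TR, nuisance=rng.normal(size=(300, 2)))
        assert np.max(np.abs(out.mean(axis=0))) < 1e-10

    def test_band_outside_nyquist_rejected(self, rng):
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess_timecourses(rng.normal(size=(100, 2)), TR,
                                   band=(0.01, 0.3))

    def test_rank_deficient_nuisance_reported(self, rng):
        n1 = rng.normal(size=(200, 1))
        nuis = np.hstack([n1, n1])  # duplicated column
        with pytest.warns(UserWarning, match="rank deficient"):
            preprocess_timecourses(rng.normal(size=(200, 2)), TR,
                                   nuisance=nuis)


class TestPcaReduce:
    def test_rank2_data_reconstructs_exactly(self, rng):
        X = rng.normal(size=(50, 2)) @ rng.normal(size=(2, 40))
        reduced, basis, frac = pca_reduce(X, 2)
        recon = basis @ reduced + X.mean(axis=0)
        assert np.allclose(recon, X, atol=1e-8)
        assert frac == pytest.approx(1.0)

    def test_white_noise_spectrum_is_flat(self, rng):
        X = rng.normal(size=(2000, 20))
        _, _, frac10 = pca_reduce(X, 10)
        # 10 of 20 equal-variance directions: close to half the variance
        assert frac10 == pytest.approx(0.5, abs=0.1)

    def test_components_ordered_by_variance(self, rng):
        X = rng.normal(size=(100, 30)) * np.linspace(5, 0.1, 30)
        reduced, _, _ = pca_reduce(X, 10)
        var = (reduced**2).sum(axis=1)
        assert np.all(np.diff(var) <= 1e-9)

    def test_target_above_rank_names_maximum(self, rng):
        X = rng.normal(size=(50, 2)) @ rng.normal(size=(2, 40))
        with pytest.raises(ValueError, match="achievable maximum is 2"):
            pca_reduce(X, 5)

    def test_forty_dims_on_synthetic_concat(self, voxel_setup):
        cohort, _, volumes = voxel_setup
        vols = [volumes[s.subject_id] for s in cohort.subjects]
        mask = extraction.compute_mask(vols)
        concat = np.vstack(extraction.flatten_volumes(vols, mask))
        reduced, basis, _ = pca_reduce(concat, 40)
        assert reduced.shape == (40, mask.sum())
        assert basis.shape == (concat.shape[0], 40)


class TestMdl:
    def test_five_planted_sources_recovered(self, rng):
        S = rng.normal(size=(400, 5))
        M = np.linalg.qr(rng.normal(size=(50, 5)))[0]
        X = S @ M.T * 3 + rng.normal(size=(400, 50)) * 0.05
        assert estimate_order_mdl(X) == 5

    def test_pure_noise_gives_small_count(self, rng):
        assert estimate_order_mdl(rng.normal(size=(500, 30))) <= 2

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_order_mdl(np.zeros((100, 5)))

    def test_ten_sources_in_volumes(self, rng):
        from effconn import synthetic

        gts = synthetic.default_ground_truths(seed=3)
        cohort = synthetic.simulate_cohort(
            gts, group_sizes={g: 3 for g in gts}, T=120, seed=3)
        mix = synthetic.make_mixing_model(grid_shape=(12, 12, 8),
                                          n_signal=10, n_noise=0,
                                          voxel_noise_sd=0.5, seed=3)
        vols = synthetic.simulate_voxel_volumes(cohort, mix, seed=3)
        vlist = [vols[s.subject_id] for s in cohort.subjects]
        mask = extraction.compute_mask(vlist)
        concat = np.vstack(extraction.flatten_volumes(vlist, mask))
        reduced, _, _ = pca_reduce(concat, 20)
        assert abs(estimate_order_mdl(reduced.T) - 10) <= 1


class TestGroupICA:
    def test_noiseless_orthogonal_sources_recovered(self, rng):
        n, V = 6, 900
        S = rng.laplace(size=(n, V))  # non-Gaussian spatial sources
        A = rng.normal(size=(n, n))
        X = A @ S  # n x V mixed observations
        res = run_group_ica(X, n, seed=0)
        # unmixing implied by estimated maps: W = S_est pinv(S) A^{-1}...
        # score recovery directly via correlation-based Amari index
        C = np.corrcoef(res.group_maps, S)[:n, n:]
        assert amari_index(C, np.eye(n)) < 0.05

    def test_same_seed_identical_maps(self, rng):
        X = np.random.default_rng(5).laplace(size=(5, 500))
        a = run_group_ica(X, 5, seed=3)
        b = run_group_ica(X, 5, seed=3)
        assert np.array_equal(a.group_maps, b.group_maps)

    def test_components_within_reduction_accepted(self, rng):
        X = rng.laplace(size=(40, 800))
        res = run_group_ica(X, 25, seed=0, max_iter=2000, tol=1e-4)
        assert res.n_components == 25

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            run_group_ica(rng.normal(size=(5, 100)), 8)

    def test_z_maps_standardized_and_masks_consistent(self, rng):
        X = rng.laplace(size=(6, 700))
        res = run_group_ica(X, 6, seed=1)
        assert np.allclose(res.z_maps.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(res.z_maps.std(axis=1), 1, atol=1e-10)
        assert np.array_equal(res.active_masks,
                              np.abs(res.z_maps) > res.threshold)


class TestBackReconstruct:
    def test_exact_model_recovers_time_courses(self, rng):
        K, V, T = 4, 300, 80
        maps = rng.normal(size=(K, V))
        tcs = rng.normal(size=(T, K))
        res = extraction.ICAResult(
            group_maps=maps, group_timecourses=tcs,
            z_maps=maps, active_masks=np.abs(maps) > 1.5, threshold=1.5,
        )
        sub_tcs, sub_maps = back_reconstruct(res, [tcs @ maps])
        assert np.allclose(sub_tcs[0], tcs, atol=1e-8)
        assert np.allclose(sub_maps[0], maps, atol=1e-6)

    def test_orthonormal_maps_reduce_to_projection(self, rng):
        K, V, T = 3, 200, 50
        maps = np.linalg.qr(rng.normal(size=(V, K)))[0].T  # orthonormal rows
        Y = rng.normal(size=(T, V))
        res = extraction.ICAResult(
            group_maps=maps, group_timecourses=np.zeros((T, K)),
            z_maps=maps, active_masks=np.abs(maps) > 1.5, threshold=1.5,
        )
        sub_tcs, _ = back_reconstruct(res, [Y])
        assert np.allclose(sub_tcs[0], Y @ maps.T, atol=1e-8)

    def test_grid_mismatch_rejected(self, rng):
        maps = rng.normal(size=(3, 100))
        res = extraction.ICAResult(
            group_maps=maps, group_timecourses=np.zeros((10, 3)),
            z_maps=maps, active_masks=np.abs(maps) > 1.5, threshold=1.5,
        )
        with pytest.raises(ValueError, match="do not match"):
            back_reconstruct(res, [rng.normal(size=(10, 99))])


class TestZscoreAndMask:
    def test_standardized_input_unchanged(self, rng):
        m = rng.normal(size=5000)
        m = (m - m.mean()) / m.std()
        z, _ = zscore_and_mask(m)
        assert np.allclose(z, m, atol=1e-12)

    def test_idempotent(self, rng):
        m = rng.normal(3.0, 7.0, size=2000)
        z1, a1 = zscore_and_mask(m)
        z2, a2 = zscore_and_mask(z1)
        assert np.allclose(z1, z2)
        assert np.array_equal(a1, a2)

    def test_gaussian_active_fraction_matches_tail(self, rng):
        m = rng.normal(size=10_000)
        _, active = zscore_and_mask(m, threshold=1.5)
        from scipy.stats import norm

        assert active.mean() == pytest.approx(2 * norm.cdf(-1.5), abs=0.02)

    def test_threshold_is_strict(self):
        # mean-0, SD-1 map whose extreme voxels sit at exactly |z| = 1.5
        x = np.sqrt((10 - 2 * 1.5**2) / 8)  # filler keeping the variance at 1
        m = np.array([1.5, -1.5] + [x, -x] * 4)
        assert m.mean() == 0 and np.isclose(m.std(), 1.0)
        z, active = zscore_and_mask(m, threshold=1.5)
        at_threshold = np.isclose(np.abs(z), 1.5, atol=1e-12)
        assert at_threshold.any()
        assert not np.any(active[at_threshold])

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_and_mask(np.ones(100))


class TestMatchTemplates:
    def test_identity_when_templates_equal_maps(self, rng):
        maps = rng.normal(size=(5, 300))
        labels = list("abcde")
        asg = match_templates(maps, maps, labels)
        assert {lab: idx for lab, (idx, _) in asg.items()} == \
            {lab: i for i, lab in enumerate(labels)}
        assert all(c == pytest.approx(1.0) for _, c in asg.values())

    def test_permuted_templates_recover_inverse_permutation(self, rng):
        maps = rng.normal(size=(6, 400))
        perm = np.array([3, 0, 5, 1, 4, 2])
        labels = list("abcdef")
        asg = match_templates(maps[perm], maps, labels)
        inv = np.argsort(perm)  # component j holds template perm[j]
        for i, lab in enumerate(labels):
            assert asg[lab][0] == inv[i]

    def test_permutation_equivariance(self, rng):
        maps = rng.normal(size=(5, 200))
        templates = rng.normal(size=(3, 200))
        labels = ["x", "y", "z"]
        base = match_templates(maps, templates, labels)
        perm = np.array([4, 2, 0, 3, 1])
        permuted = match_templates(maps[perm], templates, labels)
        inv = np.argsort(perm)
        for lab in labels:
            assert permuted[lab][0] == inv[base[lab][0]]
            assert permuted[lab][1] == pytest.approx(base[lab][1])

    def test_assignment_is_injective(self, rng):
        maps = rng.normal(size=(25, 500))
        templates = rng.normal(size=(10, 500))
        labels = [f"n{i}" for i in range(10)]
        asg = match_templates(maps, templates, labels)
        comps = [idx for idx, _ in asg.values()]
        assert len(set(comps)) == 10

    def test_shortfall_reported(self, rng):
        with pytest.raises(ValueError, match="short by 2"):
            match_templates(rng.normal(size=(3, 100)),
                            rng.normal(size=(5, 100)),
                            list("abcde"))


class TestMeanActiveZ:
    def test_uniform_active_voxels(self):
        z = np.full(100, 2.0)
        mask = np.ones(100, dtype=bool)
        assert mean_active_z(z, mask) == pytest.approx(2.0)

    def test_mixed_signs_use_magnitude(self):
        z = np.array([2.0] * 50 + [-2.0] * 50)
        assert mean_active_z(z, np.ones(100, dtype=bool)) == pytest.approx(2.0)

    def test_always_exceeds_threshold_on_real_masks(self, rng):
        m = rng.normal(size=5000)
        z, active = zscore_and_mask(m, threshold=1.5)
        assert mean_active_z(z, active) > 1.5

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_active_z(np.ones(10), np.zeros(10, dtype=bool))


def test_end_to_end_timecourse_recovery(voxel_setup):
    """Volumes -> ICA -> dual regression -> template matching recovers
    the generating network time courses up to sign (|r| >= 0.8)."""
    cohort, mixing, volumes = voxel_setup
    vols = [volumes[s.subject_id] for s in cohort.subjects]
    mask = extraction.compute_mask(vols)
    flat = extraction.flatten_volumes(vols, mask)
    ica = GroupICA(n_components=12, pca_dims=20, random_state=0)
    tcs = ica.fit_transform(flat)
    templates = mixing.flat_maps()[:10][:, mask.ravel()]
    asg = match_templates(ica.z_maps_, templates,
                          list(cohort.node_labels))
    for s, tc in zip(cohort.subjects, tcs):
        for ni, lab in enumerate(cohort.node_labels):
            ci, _ = asg[lab]
            r = np.corrcoef(s.timeseries[:, ni], tc[:, ci])[0, 1]
            assert abs(r) >= 0.8

    # subject maps correlate with the generating maps
    for smaps in ica.subject_maps_[:3]:
        for ni, lab in enumerate(cohort.node_labels):
            ci, _ = asg[lab]
            r = np.corrcoef(templates[ni], smaps[ci])[0, 1]
            assert abs(r) >= 0.8


def test_group_ica_pipeline_is_reproducible(voxel_setup):
    cohort, _, volumes = voxel_setup
    vols = [volumes[s.subject_id] for s in cohort.subjects]
    mask = extraction.compute_mask(vols)
    flat = extraction.flatten_volumes(vols, mask)
    a = GroupICA(n_components=12, pca_dims=20, random_state=1).fit(flat)
    b = GroupICA(n_components=12, pca_dims=20, random_state=1).fit(flat)
    assert np.array_equal(a.group_maps_, b.group_maps_)
    assert np.array_equal(a.z_maps_, b.z_maps_)
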