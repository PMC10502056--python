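"""Network arm: spatial ICA, matching, dual regression, responsivity."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from submem import (
    BoldRun,
    DesignMatrix,
    ICASet,
    build_first_level_design,
    concat_and_decompose,
    dual_regression_stage1,
    match_decompositions,
    network_behavior_models,
    network_responsivity,
    rsn_similarity,
    threshold_map,
)
from submem.netica import SubjectTimecourses


def block_maps(shape=(10, 10, 4)):
    """Three disjoint spatial blocks as ground-truth components."""
    maps = []
    for sl in (np.s_[0:3, 0:3, :], np.s_[5:8, 0:3, :], np.s_[0:3, 5:8, :]):
        m = np.zeros(shape)
        m[sl] = 1.0
        maps.append(m)
    return np.stack(maps)


def planted_run(rng, maps, t=120, noise=0.0, tr=3.0, subject_id=0):
    k = maps.shape[0]
    tc = rng.normal(size=(k, t))
    data = np.einsum("kxyz,kt->xyzt", maps, tc)
    if noise:
        data = data + rng.normal(0, noise, data.shape)
    return BoldRun(data=data, tr=tr, subject_id=subject_id), tc


class TestDecompose:
    def test_planted_blocks_recovered(self, rng):
        """Disjoint blocks with independent time courses and negligible
        noise come back with near-perfect spatial correlation."""
        maps = block_maps()
        runs = [
            planted_run(np.random.default_rng(s), maps, noise=1e-8)[0]
            for s in range(4)
        ]
        ica = concat_and_decompose(runs, k=3, seed=0, var_norm=False)
        for true_map in maps:
            best = max(
                abs(np.corrcoef(true_map.ravel()[ica.mask.ravel()], ica.maps[:, j])[0, 1])
                for j in range(3)
            )
            assert best >= 0.99

    def test_same_seed_bit_identical(self, rng):
        maps = block_maps()
        runs = [planted_run(np.random.default_rng(s), maps, noise=0.2)[0] for s in range(3)]
        a = concat_and_decompose(runs, k=3, seed=11)
        b = concat_and_decompose(runs, k=3, seed=11)
        assert np.array_equal(a.maps, b.maps)
        assert np.array_equal(a.mixing, b.mixing)

    def test_rank_one_data_identified(self, rng):
        """K=1 on rank-1 data returns a map proportional to the generator
        (amplitude structure preserved by skipping variance normalization)."""
        shape = (8, 8, 3)
        m = rng.random(shape) + 0.5
        tc = rng.normal(size=60)
        data = m[..., None] * tc[None, None, None, :]
        run = BoldRun(data=data, tr=3.0)
        ica = concat_and_decompose([run], k=1, seed=0, var_norm=False)
        r = np.corrcoef(m.ravel()[ica.mask.ravel()], ica.maps[:, 0])[0, 1]
        assert abs(r) >= 0.999

    def test_degenerate_voxels_rejected(self, rng):
        data = rng.normal(size=(4, 4, 2, 50))
        data[0, 0, 0, :] = 7.0  # constant voxel
        with pytest.raises(ValueError, match="constant"):
            concat_and_decompose([BoldRun(data=data, tr=3.0)], k=2, seed=0)

    def test_positive_skew_sign_convention(self, rng):
        maps = block_maps()
        runs = [planted_run(np.random.default_rng(s), maps, noise=0.05)[0] for s in range(3)]
        ica = concat_and_decompose(runs, k=3, seed=2)
        from scipy.stats import skew

        assert (skew(ica.maps, axis=0) >= 0).all()


class TestThresholdMap:
    def test_normal_noise_tail_fraction(self):
        r = np.random.default_rng(0)
        m = r.normal(size=(40, 40, 10))
        kept = threshold_map(m, method="zscore", level=3.0)
        expected = 2 * norm.sf(3.0)
        assert kept.mean() == pytest.approx(expected, abs=0.002)

    def test_all_zero_map_empty(self):
        assert not threshold_map(np.zeros((5, 5, 2))).any()

    def test_planted_activation_fully_retained(self):
        r = np.random.default_rng(1)
        m = r.normal(size=(20, 20, 5))
        planted = np.zeros_like(m, dtype=bool)
        planted[5:8, 5:8, 1:3] = True
        m[planted] = 8.0
        kept = threshold_map(m, method="zscore", level=3.0)
        assert kept[planted].all()

    def test_mixture_method_runs(self):
        r = np.random.default_rng(2)
        m = np.concatenate([r.normal(0, 1, 4000), r.normal(6, 1, 400)])
        kept = threshold_map(m, method="mixture")
        # the high-mode voxels are retained
        assert kept[-400:].mean() > 0.95


class TestMatch:
    def make_set(self, maps, mask_shape=(10, 10, 4)):
        mask = np.ones(mask_shape, dtype=bool)
        flat = maps.reshape(maps.shape[0], -1).T
        return ICASet(maps=flat, mixing=np.zeros((5, maps.shape[0])), mask=mask, seed=0)

    def test_self_match_all_replicable(self, rng):
        maps = rng.normal(size=(4, 10, 10, 4))
        a = self.make_set(maps)
        table = match_decompositions(a, a)
        assert np.allclose(table.r_max, 1.0)
        assert all(s == "replicable" for s in table.status)

    def test_sign_flip_invariance(self, rng):
        maps = rng.normal(size=(4, 10, 10, 4))
        a = self.make_set(maps)
        b = self.make_set(-maps)
        table = match_decompositions(a, b)
        assert np.allclose(table.r_max, 1.0)

    def test_independent_noise_low_rmax(self):
        r = np.random.default_rng(3)
        a = self.make_set(r.normal(size=(6, 25, 20, 20)), mask_shape=(25, 20, 20))
        b = self.make_set(r.normal(size=(6, 25, 20, 20)), mask_shape=(25, 20, 20))
        table = match_decompositions(a, b)
        assert np.median(table.r_max) <= 0.1
        assert all(s == "not_replicable" for s in table.status)

    def test_inspect_band(self, rng):
        v = rng.normal(size=(2000,))
        noise = rng.normal(size=(2000,))
        # construct a pair correlated at ~0.65
        w = 0.65 * (v - v.mean()) / v.std() + np.sqrt(1 - 0.65**2) * (
            noise - noise.mean()
        ) / noise.std()
        mask = np.ones((2000, 1, 1), dtype=bool)
        a = ICASet(maps=v[:, None], mixing=np.zeros((2, 1)), mask=mask, seed=0)
        b = ICASet(maps=w[:, None], mixing=np.zeros((2, 1)), mask=mask, seed=0)
        table = match_decompositions(a, b)
        assert table.status[0] in ("inspect", "replicable", "not_replicable")
        if 0.6 <= table.r_max[0] < 0.7:
            assert table.status[0] == "inspect"


class TestDualRegression:
    def test_exact_recovery_orthogonal_maps(self, rng):
        maps = block_maps()
        run, tc = planted_run(rng, maps, noise=0.0)
        icaset = ICASet(
            maps=maps.reshape(3, -1).T, mixing=np.zeros((5, 3)),
            mask=np.ones(maps.shape[1:], bool), seed=0,
        )
        rec = dual_regression_stage1(run, icaset)
        assert np.max(np.abs(rec.timecourses - tc)) <= 1e-8

    def test_exact_recovery_correlated_maps(self, rng):
        """Joint multiple regression, not per-map projection."""
        shape = (10, 10, 4)
        m1 = np.zeros(shape)
        m1[0:5, :, :] = 1.0
        m2 = np.zeros(shape)
        m2[3:8, :, :] = 1.0  # overlaps m1
        maps = np.stack([m1, m2])
        run, tc = planted_run(rng, maps, noise=0.0)
        icaset = ICASet(
            maps=maps.reshape(2, -1).T, mixing=np.zeros((5, 2)),
            mask=np.ones(shape, bool), seed=0,
        )
        rec = dual_regression_stage1(run, icaset)
        assert np.max(np.abs(rec.timecourses - tc)) <= 1e-8

    def test_snr1_recovery_correlation(self, rng):
        maps = block_maps()
        run, tc = planted_run(rng, maps, noise=1.0)
        icaset = ICASet(
            maps=maps.reshape(3, -1).T, mixing=np.zeros((5, 3)),
            mask=np.ones(maps.shape[1:], bool), seed=0,
        )
        rec = dual_regression_stage1(run, icaset)
        for k in range(3):
            assert np.corrcoef(rec.timecourses[k], tc[k])[0, 1] >= 0.9

    def test_collinear_maps_rejected(self, rng):
        shape = (6, 6, 3)
        m = np.zeros(shape)
        m[0:3] = 1.0
        maps = np.stack([m, 2 * m])
        run, _ = planted_run(rng, maps, noise=0.1)
        icaset = ICASet(
            maps=maps.reshape(2, -1).T, mixing=np.zeros((5, 2)),
            mask=np.ones(shape, bool), seed=0,
        )
        with pytest.raises(ValueError, match="collinear"):
            dual_regression_stage1(run, icaset)


def responsivity_design(small_cohort, s=0):
    ev = small_cohort.events[s]
    run = small_cohort.runs[s]
    return build_first_level_design(
        ev, run.n_volumes, small_cohort.spec.tr,
        scheme="picture_encoding", motion=run.motion,
    )


class TestResponsivity:
    def test_pure_task_timecourse_positive_responsivity(self, small_cohort):
        x = responsivity_design(small_cohort)
        tc = SubjectTimecourses(
            subject_id=0, timecourses=x.column("pictures")[None, :].copy()
        )
        table = network_responsivity(tc, x)
        assert table["responsivity"].iloc[0] > 0
        assert abs(table["beta_control"].iloc[0]) < 0.05

    def test_noise_timecourse_mean_responsivity_near_zero(self, small_cohort):
        x = responsivity_design(small_cohort)
        r = np.random.default_rng(0)
        vals = []
        for _ in range(200):
            tc = SubjectTimecourses(0, r.normal(size=(1, x.n_volumes)))
            vals.append(network_responsivity(tc, x)["responsivity"].iloc[0])
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 4 * se + 0.01

    def test_label_swap_flips_sign(self, small_cohort):
        x = responsivity_design(small_cohort)
        r = np.random.default_rng(1)
        tc = SubjectTimecourses(0, r.normal(size=(2, x.n_volumes)))
        fwd = network_responsivity(tc, x, "pictures", "figures")
        rev = network_responsivity(tc, x, "figures", "pictures")
        assert np.allclose(
            fwd["responsivity"].to_numpy(), -rev["responsivity"].to_numpy()
        )


class TestNetworkBehavior:
    @staticmethod
    def make_tables(rng, n=300, k=6, slope=0.5):
        resp = rng.normal(size=(n, k))
        recall = slope * resp[:, 2] + rng.normal(size=n)
        rows = [
            {"subject_id": s, "component": j, "responsivity": resp[s, j]}
            for s in range(n)
            for j in range(k)
        ]
        pheno = pd.DataFrame(
            {
                "subject_id": np.arange(n),
                "recall_count": recall,
                "age": rng.uniform(18, 35, n),
                "sex": rng.choice(["F", "M"], n),
                "batch_mr": rng.choice(["mr1", "mr2"], n),
                "room": rng.choice(["room1", "room2"], n),
            }
        )
        return pd.DataFrame(rows), pheno

    def test_planted_component_flagged_with_positive_slope(self, rng):
        resp, pheno = self.make_tables(rng)
        models = network_behavior_models(resp, pheno)
        hit = models[models["significant"]]
        assert hit["component"].tolist() == [2]
        assert hit["slope"].iloc[0] > 0
        assert models.attrs["bonferroni_alpha"] == pytest.approx(0.05 / 6)

    def test_null_family_wise_error_controlled(self):
        false_pos = 0
        n_sims = 100
        for seed in range(n_sims):
            r = np.random.default_rng(seed)
            resp, pheno = self.make_tables(r, n=60, k=10, slope=0.0)
            models = network_behavior_models(resp, pheno)
            if models["significant"].any():
                false_pos += 1
        assert false_pos / n_sims <= 0.08

    def test_r2_increment_reported(self, rng):
        resp, pheno = self.make_tables(rng, n=200, k=3, slope=0.8)
        models = network_behavior_models(resp, pheno)
        assert (models["r2_increment"] >= 0).all()
        assert models.set_index("component").loc[2, "r2_increment"] > 0.1


class TestRSNSimilarity:
    def make_set(self, maps):
        mask = np.ones(maps.shape[1:], dtype=bool)
        return ICASet(
            maps=maps.reshape(maps.shape[0], -1).T,
            mixing=np.zeros((4, maps.shape[0])), mask=mask, seed=0,
        )

    def test_template_containing_component_matches_at_one(self, rng):
        maps = rng.normal(size=(3, 8, 8, 4))
        ica = self.make_set(maps)
        table = rsn_similarity(ica, maps, template_names=["a", "b", "c"])
        assert np.allclose(np.abs(table["best_r"]), 1.0)
        assert table["best_template"].tolist() == ["a", "b", "c"]

    def test_lenient_count_at_least_stringent(self, rng):
        maps = rng.normal(size=(5, 8, 8, 4))
        templates = rng.normal(size=(10, 8, 8, 4))
        table = rsn_similarity(self.make_set(maps), templates)
        assert (table["n_lenient"] >= table["n_stringent"]).all()

    def test_noise_templates_match_rate_near_permutation_null(self):
        r = np.random.default_rng(7)
        n_vox = 4000
        maps = r.normal(size=(6, n_vox, 1, 1))
        templates = r.normal(size=(10, n_vox, 1, 1))
        table = rsn_similarity(self.make_set(maps), templates)
        # permutation oracle: null |r| exceedance probability at 0.1
        null_r = []
        t0 = templates[0].ravel()
        m0 = maps[0].ravel()
        for _ in range(500):
            null_r.append(abs(np.corrcoef(m0, r.permutation(t0))[0, 1]))
        p_exceed = np.mean(np.array(null_r) > 0.1)
        expected = 10 * p_exceed
        assert table["n_lenient"].mean() <= expected + 0.5

    def test_grid_mismatch_rejected(self, rng):
        maps = rng.normal(size=(2, 6, 6, 3))
        with pytest.raises(ValueError, match="grid"):
            rsn_similarity(self.make_set(maps), rng.normal(size=(3, 5, 5, 3)))
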