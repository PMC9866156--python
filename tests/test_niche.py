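"""Niche-space construction, occupancy grids, Schoener's D, COUE indices
and the permutation tests."""

import numpy as np
import pandas as pd
import pytest

import nichekit as nk
from nichekit.niche import (
    NicheSpace,
    OccupancyGrid,
    coue,
    equivalency_test,
    occupancy,
    pca_env,
    pno_profile,
    schoener_d,
    similarity_test,
)


def toy_space(R=10, lo=-4.0, hi=4.0):
    return NicheSpace(
        loadings=np.eye(2), mean=np.zeros(2), scale=np.ones(2),
        variables=["x", "y"], explained=np.array([0.5, 0.5]),
        xmin=lo, xmax=hi, ymin=lo, ymax=hi, resolution=R,
    )


def grid_from_z(z, support=None):
    z = np.asarray(z, dtype=float)
    if support is None:
        support = z > 0
    return OccupancyGrid(
        z=z, occ_density=z, bg_density=np.ones_like(z), support=support,
        space=toy_space(R=z.shape[0]), support_floor=0.0,
    )


class TestPcaEnv:
    def test_isotropic_background_splits_variance(self):
        rng = np.random.default_rng(0)
        bg1 = pd.DataFrame(rng.normal(size=(4000, 2)), columns=["a", "b"])
        bg2 = pd.DataFrame(rng.normal(size=(4000, 2)), columns=["a", "b"])
        occ = bg1.head(10)
        space, _ = pca_env(bg1, bg2, occ, occ)
        assert space.explained[0] == pytest.approx(0.5, abs=0.05)

    def test_duplicating_background_preserves_axes(self):
        rng = np.random.default_rng(1)
        bg = pd.DataFrame(rng.normal(size=(500, 3)), columns=["a", "b", "c"])
        occ = bg.head(10)
        s1, _ = pca_env(bg, bg, occ, occ)
        s2, _ = pca_env(pd.concat([bg, bg]), pd.concat([bg, bg]), occ, occ)
        np.testing.assert_allclose(np.abs(s1.loadings), np.abs(s2.loadings), atol=1e-9)

    def test_identical_occurrences_identical_scores(self, range_pair):
        space, scores = pca_env(
            range_pair["bg_native"], range_pair["bg_invasive"],
            range_pair["env_native"], range_pair["env_native"],
        )
        np.testing.assert_array_equal(scores["native_occ"], scores["invasive_occ"])

    def test_constant_variable_dropped(self):
        rng = np.random.default_rng(2)
        bg = pd.DataFrame(rng.normal(size=(100, 3)), columns=["a", "b", "c"])
        bg["c"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            space, _ = pca_env(bg, bg, bg.head(5), bg.head(5))
        assert space.variables == ["a", "b"]


class TestOccupancy:
    def test_background_distributed_occurrences_give_flat_z(self):
        rng = np.random.default_rng(3)
        bg = rng.normal(size=(10_000, 2))
        occ = rng.normal(size=(10_000, 2))  # same distribution as background
        space = toy_space(R=100)
        z = occupancy(occ, bg, space)
        sup = z.support
        uniform = sup / sup.sum()
        tv = 0.5 * np.abs(z.z - uniform).sum()
        assert tv < 0.15

    def test_tight_cluster_peaks_at_cluster(self):
        rng = np.random.default_rng(4)
        bg = rng.uniform(-4, 4, size=(5000, 2))
        occ = rng.normal(loc=[1.0, -1.0], scale=0.1, size=(200, 2))
        space = toy_space(R=40)
        z = occupancy(occ, bg, space)
        iy, ix = np.unravel_index(np.argmax(z.z), z.z.shape)
        xs, ys = space.grid_centers()
        assert abs(xs[ix] - 1.0) < 0.3 and abs(ys[iy] + 1.0) < 0.3

    def test_weight_doubling_invariance(self):
        # duplicating every occurrence leaves z unchanged once the n-dependent
        # Silverman factor is held fixed (multiplier 2^(1/6) compensates)
        rng = np.random.default_rng(5)
        bg = rng.uniform(-4, 4, size=(3000, 2))
        occ = rng.normal(size=(300, 2))
        space = toy_space(R=50)
        z1 = occupancy(occ, bg, space)
        z2 = occupancy(
            np.vstack([occ, occ]), None, space, bandwidth=2 ** (1 / 6), background=z1
        )
        assert schoener_d(z1, z2) > 0.999

    def test_z_normalized_and_zero_off_support(self):
        rng = np.random.default_rng(6)
        bg = rng.normal(size=(2000, 2))
        occ = rng.normal(size=(200, 2))
        z = occupancy(occ, bg, toy_space(R=50))
        assert z.z.sum() == pytest.approx(1.0)
        assert np.all(z.z[~z.support] == 0)

    def test_too_few_occurrences(self):
        with pytest.raises(ValueError, match="5 occurrence"):
            occupancy(np.zeros((3, 2)), np.zeros((10, 2)), toy_space())


class TestSchoenerD:
    def test_identical_grids(self):
        z = np.full((5, 5), 1 / 25)
        assert schoener_d(z, z) == 1.0

    def test_disjoint_supports(self):
        z1 = np.zeros((2, 2))
        z1[0, 0] = 1.0
        z2 = np.zeros((2, 2))
        z2[1, 1] = 1.0
        assert schoener_d(z1, z2) == 0.0

    def test_three_cell_worked_example(self):
        z1 = np.array([[0.5, 0.5, 0.0]])
        z2 = np.array([[0.0, 0.5, 0.5]])
        assert schoener_d(z1, z2) == 0.5

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        a = rng.random((20, 20))
        a /= a.sum()
        b = rng.random((20, 20))
        b /= b.sum()
        assert schoener_d(a, b) == schoener_d(b, a)

    def test_grid_mismatch(self):
        with pytest.raises(ValueError, match="shapes"):
            schoener_d(np.zeros((2, 2)), np.zeros((3, 3)))


class TestCOUE:
    def test_identical_niches(self):
        z = np.array([[0.25, 0.25], [0.25, 0.25]])
        g = grid_from_z(z, support=np.ones((2, 2), bool))
        e, s, u = coue(g, g)
        assert (e, s, u) == (0.0, 1.0, 0.0)

    def test_abc_worked_example(self):
        # native mass on cells {A,B}, invasive on {B,C}, all analog
        sup = np.ones((1, 3), bool)
        zn = grid_from_z(np.array([[0.5, 0.5, 0.0]]), support=sup)
        zi = grid_from_z(np.array([[0.0, 0.5, 0.5]]), support=sup)
        e, s, u = coue(zn, zi)
        assert (e, s, u) == (0.5, 0.5, 0.5)

    def test_subset_support_no_expansion(self):
        sup = np.ones((1, 4), bool)
        zn = grid_from_z(np.array([[0.25, 0.25, 0.25, 0.25]]), support=sup)
        zi = grid_from_z(np.array([[0.0, 0.5, 0.5, 0.0]]), support=sup)
        e, s, u = coue(zn, zi)
        assert e == 0.0 and s == 1.0 and u == pytest.approx(0.5)

    def test_expansion_plus_stability_is_one(self, range_pair):
        res = nk.compare_niches(
            range_pair["bg_native"], range_pair["bg_invasive"],
            range_pair["env_native"], range_pair["env_invasive"], run_tests=False,
        )
        assert res.expansion + res.stability == 1.0
        assert 0 <= res.expansion <= 1 and 0 <= res.unfilling <= 1

    def test_empty_analog_mask(self):
        zn = grid_from_z(np.array([[1.0, 0.0]]), support=np.array([[True, False]]))
        zi = grid_from_z(np.array([[0.0, 1.0]]), support=np.array([[False, True]]))
        with pytest.raises(ValueError, match="analog"):
            coue(zn, zi)


class TestPermutationTests:
    def test_identical_occurrences_equivalent(self, range_pair):
        space, scores = pca_env(
            range_pair["bg_native"], range_pair["bg_invasive"],
            range_pair["env_native"], range_pair["env_native"],
        )
        z1 = occupancy(scores["native_occ"], scores["native_bg"], space)
        z2 = occupancy(scores["invasive_occ"], scores["invasive_bg"], space)
        obs, nulls, p_lo, p_hi = equivalency_test(
            scores["native_occ"], scores["invasive_occ"], z1, z2, reps=19, seed=0
        )
        # same point set on each side: observed overlap can only tie or beat nulls
        assert p_lo > 0.5

    def test_p_never_zero(self, range_pair):
        space, scores = pca_env(
            range_pair["bg_native"], range_pair["bg_invasive"],
            range_pair["env_native"], range_pair["env_invasive"],
        )
        z1 = occupancy(scores["native_occ"], scores["native_bg"], space)
        z2 = occupancy(scores["invasive_occ"], scores["invasive_bg"], space)
        _, _, p_lo, p_hi = equivalency_test(
            scores["native_occ"], scores["invasive_occ"], z1, z2, reps=19, seed=1
        )
        assert p_lo >= 1 / 20 and p_hi >= 1 / 20

    def test_similarity_single_rep_p_values(self, range_pair):
        space, scores = pca_env(
            range_pair["bg_native"], range_pair["bg_invasive"],
            range_pair["env_native"], range_pair["env_invasive"],
        )
        z1 = occupancy(scores["native_occ"], scores["native_bg"], space)
        z2 = occupancy(scores["invasive_occ"], scores["invasive_bg"], space)
        _, _, p = similarity_test(scores["invasive_occ"], z2, z1, reps=1, seed=2)
        assert p in (0.5, 1.0)

    def test_similar_niches_significant_similarity(self, range_pair):
        res = nk.compare_niches(
            range_pair["bg_native"], range_pair["bg_invasive"],
            range_pair["env_native"], range_pair["env_invasive"],
            reps=99, seed=3,
        )
        assert res.p_similarity_nat_inv <= 0.05
        assert res.p_similarity_inv_nat <= 0.05


class TestPNOProfile:
    def test_uniform_weights_flat_variable(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(0, 1, 20_000)
        prof = pno_profile(np.ones_like(v), v, n_bins=10)
        assert prof["mass"].sum() == pytest.approx(1.0)
        assert prof["mass"].max() - prof["mass"].min() < 0.02

    def test_sums_to_one_any_input(self):
        rng = np.random.default_rng(9)
        prof = pno_profile(rng.random(500), rng.normal(size=500), n_bins=7)
        assert prof["mass"].sum() == pytest.approx(1.0)

    def test_mode_recovers_optimum(self, range_pair, species):
        # suitability-weighted profile of the driving variable peaks at its optimum
        stack = range_pair["stack_native"]
        sp = nk.default_species(nuisance=())
        surf = nk.suitability_surface(sp, stack)
        prof = pno_profile(surf.ravel(), stack.layers["env1"].ravel(), n_bins=20)
        mode = prof.loc[prof["mass"].idxmax(), "bin_center"]
        bin_width = prof["bin_center"].iloc[1] - prof["bin_center"].iloc[0]
        assert abs(mode - 0.0) <= bin_width
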