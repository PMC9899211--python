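import numpy as np
import pytest

from arterial_atlas import (
    OVERLAP,
    UNDEFINED,
    BinaryVolume,
    ClaimMap,
    LabelScheme,
    LabelVolume,
    VolumeGrid,
    claim_threshold,
    claim_voxels,
    merge_to_level2,
    resolve_overlaps,
    sharp_atlas_from_prob,
    smooth_labels,
    subdivide_by_anatomy,
    territory_scheme,
    water_spread,
)
from arterial_atlas.assign import is_claimed
from arterial_atlas.average_maps import ProbMapSet
from arterial_atlas.bmm import BMMFit, clip_rates
from arterial_atlas.core_io import TERRITORY_LABELS


def fit_with_mu(grid, territory, mu_volumes, n=100):
    mu = clip_rates(np.stack(mu_volumes))
    K = len(mu_volumes)
    return BMMFit(
        territory=territory, grid=grid, K=K, pi=np.ones(K) / K, mu=mu,
        responsibilities=np.ones((n, K)) / K, loglik_trace=np.array([0.0]),
        n_subjects=n, seed=0, n_restarts=1, tol=1e-6, max_iter=1,
    )


def full_brain(grid):
    return BinaryVolume(grid, np.ones(grid.shape, dtype=np.uint8))


class TestClaimingRule:
    def test_rate_one_claimed_any_alpha(self):
        for alpha in (0.0, 1.0, 3.0, 10.0):
            assert is_claimed(np.array([1.0]), alpha)[0]

    def test_boundary_rate_point_one_at_alpha_three(self):
        # 0.1 + 3*sqrt(0.09) = 1.0 exactly: claimed
        assert is_claimed(np.array([0.1]), 3.0)[0]

    def test_just_below_boundary_not_claimed(self):
        # 0.09 + 3*sqrt(0.09*0.91) ~ 0.949 < 1
        assert not is_claimed(np.array([0.09]), 3.0)[0]

    def test_closed_form_threshold_equivalence(self):
        mus = np.linspace(0.0, 1.0, 100_001)
        for alpha in (0.5, 1.0, 2.0, 3.0):
            assert np.array_equal(is_claimed(mus, alpha), mus >= claim_threshold(alpha))

    def test_alpha_three_threshold_exact(self):
        assert claim_threshold(3.0) == pytest.approx(0.1, abs=1e-15)

    def test_claimed_set_grows_with_alpha(self, grid16):
        rng = np.random.default_rng(0)
        mu = rng.random(grid16.shape)
        prev = None
        for alpha in (0.0, 1.0, 2.0, 3.0, 4.0):
            claimed = is_claimed(mu, alpha)
            if prev is not None:
                assert np.all(claimed[prev])  # previously claimed stays claimed
            prev = claimed


class TestClaimVoxels:
    def test_codes_and_overlap_and_undefined(self, grid16):
        mu_a = np.zeros(grid16.shape)
        mu_b = np.zeros(grid16.shape)
        mu_a[2, 2, 2] = 0.9           # claimed by MCA only
        mu_a[5, 5, 5] = 0.5           # claimed by both
        mu_b[5, 5, 5] = 0.6
        fits = {
            "MCA": fit_with_mu(grid16, "MCA", [mu_a]),
            "PCA": fit_with_mu(grid16, "PCA", [mu_b]),
        }
        claim = claim_voxels(fits, full_brain(grid16), alpha=3.0)
        assert claim.data[2, 2, 2] == TERRITORY_LABELS["MCA"]
        assert claim.data[5, 5, 5] == OVERLAP
        assert claim.data[0, 0, 0] == UNDEFINED

    def test_any_cluster_suffices(self, grid16):
        lo = np.zeros(grid16.shape)
        hi = np.zeros(grid16.shape)
        hi[3, 3, 3] = 0.4
        fits = {"VB": fit_with_mu(grid16, "VB", [lo, hi])}
        claim = claim_voxels(fits, full_brain(grid16), alpha=3.0)
        assert claim.data[3, 3, 3] == TERRITORY_LABELS["VB"]

    def test_matches_mu_max_thresholding(self, cohort16, phantom16):
        from arterial_atlas import fit_cohort, mu_max_map

        fits = fit_cohort(cohort16, k_per_territory={"ACA": 1, "MCA": 1, "PCA": 2},
                          seed=0, n_restarts=2)
        alpha = 3.0
        claim = claim_voxels(fits, phantom16.brain_mask, alpha)
        thr = claim_threshold(alpha)
        brain = phantom16.brain_mask.data > 0
        # reconstruct the full claim map by plain thresholding of mu_max at
        # 1/(1+alpha^2) and compare voxelwise
        claimed = {t: (mu_max_map(f) >= thr) & brain for t, f in fits.items()}
        n_claims = sum(c.astype(int) for c in claimed.values())
        expected = np.zeros(claim.grid.shape, dtype=np.int32)
        expected[brain] = UNDEFINED
        for t, c in claimed.items():
            expected[c & (n_claims == 1)] = TERRITORY_LABELS[t]
        expected[n_claims > 1] = OVERLAP
        assert np.array_equal(claim.data, expected)


class TestResolveOverlaps:
    def test_argmax_wins(self, grid16):
        mu_m = np.zeros(grid16.shape)
        mu_p = np.zeros(grid16.shape)
        mu_m[4, 4, 4], mu_p[4, 4, 4] = 0.9, 0.4
        fits = {"MCA": fit_with_mu(grid16, "MCA", [mu_m]),
                "PCA": fit_with_mu(grid16, "PCA", [mu_p])}
        claim = claim_voxels(fits, full_brain(grid16), alpha=3.0)
        assert claim.data[4, 4, 4] == OVERLAP
        resolved = resolve_overlaps(claim, fits)
        assert resolved.data[4, 4, 4] == TERRITORY_LABELS["MCA"]
        assert not np.any(resolved.data == OVERLAP)

    def test_exact_tie_uses_priority(self, grid16):
        mu = np.zeros(grid16.shape)
        mu[4, 4, 4] = 0.5
        fits = {"ACA": fit_with_mu(grid16, "ACA", [mu.copy()]),
                "PCA": fit_with_mu(grid16, "PCA", [mu.copy()])}
        claim = claim_voxels(fits, full_brain(grid16), alpha=3.0)
        first = resolve_overlaps(claim, fits)
        second = resolve_overlaps(claim, fits)
        assert first.data[4, 4, 4] == TERRITORY_LABELS["PCA"]  # PCA > ACA
        assert np.array_equal(first.data, second.data)

    def test_no_overlaps_identity(self, grid16):
        mu = np.zeros(grid16.shape)
        mu[1, 1, 1] = 0.9
        fits = {"VB": fit_with_mu(grid16, "VB", [mu])}
        claim = claim_voxels(fits, full_brain(grid16), alpha=3.0)
        assert np.array_equal(resolve_overlaps(claim, fits).data, claim.data)


def brute_force_nearest_label(data, brain, voxel_size, priority_rank):
    """Oracle: per unlabeled brain voxel, scan all labeled voxels for the
    metric-nearest; ties by priority rank."""
    out = data.copy()
    labeled = np.argwhere(data > 0)
    vs = np.asarray(voxel_size)
    for idx in np.argwhere(brain & (data == 0)):
        d2 = ((labeled - idx) * vs) ** 2
        dists = d2.sum(axis=1)
        best = dists.min()
        cands = {int(data[tuple(v)]) for v, d in zip(labeled, dists) if d == best}
        out[tuple(idx)] = min(cands, key=priority_rank)
    return out


class TestWaterSpread:
    def test_no_undefined_identity(self, grid16):
        data = np.ones(grid16.shape, dtype=int) * 2
        vol = LabelVolume(grid16, data, territory_scheme())
        out = water_spread(vol, full_brain(grid16))
        assert np.array_equal(out.data, data)

    def test_face_adjacent_neighbor(self):
        grid = VolumeGrid((5, 5, 5))
        data = np.zeros(grid.shape, dtype=int)
        data[2, 2, 2] = 0  # undefined, surrounded by MCA
        data[1, 2, 2] = data[3, 2, 2] = data[2, 1, 2] = data[2, 3, 2] = 2
        brain = np.zeros(grid.shape, dtype=np.uint8)
        brain[1:4, 1:4, 2] = 1
        out = water_spread(LabelVolume(grid, data, territory_scheme()),
                           BinaryVolume(grid, brain))
        assert out.data[2, 2, 2] == 2

    def test_equidistant_tie_priority_stable(self):
        grid = VolumeGrid((5, 5, 5))
        data = np.zeros(grid.shape, dtype=int)
        data[1, 2, 2] = TERRITORY_LABELS["ACA"]
        data[3, 2, 2] = TERRITORY_LABELS["PCA"]
        brain = np.zeros(grid.shape, dtype=np.uint8)
        brain[1:4, 2, 2] = 1
        vol = LabelVolume(grid, data, territory_scheme())
        outs = [water_spread(vol, BinaryVolume(grid, brain)) for _ in range(3)]
        # voxel (2,2,2) is at distance 1 from both; PCA outranks ACA
        assert all(o.data[2, 2, 2] == TERRITORY_LABELS["PCA"] for o in outs)

    def test_matches_brute_force_oracle(self, phantom16):
        rng = np.random.default_rng(1)
        brain = phantom16.brain_mask.data > 0
        data = np.where(brain & (rng.random(phantom16.grid.shape) < 0.1),
                        phantom16.true_labels.data, 0)
        if not data.any():
            pytest.skip("no seeds drawn")
        vol = LabelVolume(phantom16.grid, data, territory_scheme())
        out = water_spread(vol, phantom16.brain_mask)
        from arterial_atlas.assign import _priority_rank_for_label

        oracle = brute_force_nearest_label(data, brain, phantom16.grid.voxel_size,
                                           _priority_rank_for_label)
        assert np.array_equal(out.data, oracle)

    def test_no_labels_errors(self, grid16):
        vol = LabelVolume(grid16, np.zeros(grid16.shape, dtype=int), territory_scheme())
        with pytest.raises(ValueError):
            water_spread(vol, full_brain(grid16))


class TestSharpAtlasFromProb:
    def test_argmax_assignment(self, grid16):
        maps = {t: np.zeros(grid16.shape) for t in ("MCA", "PCA", "VB")}
        maps["MCA"][2, 2, 2] = 0.3
        maps["PCA"][2, 2, 2] = 0.1
        maps["VB"][8, 8, 8] = 0.2
        pm = ProbMapSet(grid16, maps, {t: 10 for t in maps})
        atlas = sharp_atlas_from_prob(pm, full_brain(grid16))
        assert atlas.data[2, 2, 2] == TERRITORY_LABELS["MCA"]
        assert atlas.data[8, 8, 8] == TERRITORY_LABELS["VB"]

    def test_partitions_brain(self, cohort16, phantom16):
        from arterial_atlas import average_prob_maps

        atlas = sharp_atlas_from_prob(average_prob_maps(cohort16.flipped_to_left()),
                                      phantom16.brain_mask)
        brain = phantom16.brain_mask.data > 0
        assert np.all(atlas.data[brain] > 0)
        assert np.all(atlas.data[~brain] == 0)

    def test_matches_argmax_plus_nearest_fill_oracle(self, cohort16, phantom16):
        from arterial_atlas import average_prob_maps
        from arterial_atlas.assign import _priority_rank_for_label
        from arterial_atlas.core_io import TERRITORY_PRIORITY

        pm = average_prob_maps(cohort16.flipped_to_left())
        atlas = sharp_atlas_from_prob(pm, phantom16.brain_mask)
        brain = phantom16.brain_mask.data > 0
        # oracle: per-voxel argmax with priority ties, then nearest-label fill
        data = np.zeros(phantom16.grid.shape, dtype=int)
        for idx in np.argwhere(brain):
            vals = {t: pm.maps[t][tuple(idx)] for t in pm.maps}
            best = max(vals.values())
            if best > 0:
                winners = [t for t, v in vals.items() if v == best]
                win = min(winners, key=TERRITORY_PRIORITY.index)
                data[tuple(idx)] = TERRITORY_LABELS[win]
        oracle = brute_force_nearest_label(data, brain, phantom16.grid.voxel_size,
                                           _priority_rank_for_label)
        assert np.array_equal(atlas.data, oracle)


class TestSmoothLabels:
    def test_radius_zero_identity(self, phantom16):
        out = smooth_labels(phantom16.true_labels, radius=0)
        assert out is phantom16.true_labels

    def test_island_absorbed(self):
        grid = VolumeGrid((7, 7, 7))
        data = np.full(grid.shape, 2, dtype=int)
        data[3, 3, 3] = 3  # single PCA voxel inside MCA
        out = smooth_labels(LabelVolume(grid, data, territory_scheme()), radius=1)
        assert out.data[3, 3, 3] == 2

    def test_homogeneous_unchanged(self, grid16):
        data = np.full(grid16.shape, 4, dtype=int)
        out = smooth_labels(LabelVolume(grid16, data, territory_scheme()), radius=2)
        assert np.array_equal(out.data, data)

    def test_background_not_invaded_and_no_new_labels(self, phantom16):
        out = smooth_labels(phantom16.true_labels, radius=1)
        assert np.array_equal(out.data > 0, phantom16.true_labels.data > 0)
        assert set(np.unique(out.data)) <= set(np.unique(phantom16.true_labels.data))


SUB_SCHEME = LabelScheme([
    (1, "ACA", "anterior territory", 1),
    (2, "MCA", "middle territory", 2),
    (3, "PCA", "posterior territory", 3),
    (4, "VB", "vertebro-basilar territory", 4),
    (10, "MCAf", "MCA frontal", 2),
    (11, "MCAp", "MCA parietal", 2),
    (12, "latLS", "lateral lenticulostriate", 2),
])


class TestHierarchy:
    def test_subsegments_merge_to_major_territory(self, grid16):
        data = np.zeros(grid16.shape, dtype=int)
        data[0], data[1], data[2] = 10, 11, 12  # MCAf, MCAp, latLS
        merged = merge_to_level2(LabelVolume(grid16, data, SUB_SCHEME))
        assert set(np.unique(merged.data[:3])) == {2}

    def test_identity_mapping_unchanged(self, phantom16):
        merged = merge_to_level2(phantom16.true_labels)
        assert np.array_equal(merged.data, phantom16.true_labels.data)

    def test_volume_conservation(self, grid16):
        rng = np.random.default_rng(2)
        data = rng.choice([0, 2, 10, 11, 12], size=grid16.shape)
        vol = LabelVolume(grid16, data, SUB_SCHEME)
        merged = merge_to_level2(vol)
        level1_mca = int(np.isin(data, [2, 10, 11, 12]).sum())
        assert merged.counts().get(2, 0) == level1_mca

    def test_missing_mapping_errors(self, grid16):
        scheme = LabelScheme([(7, "X", "x", 7)])
        data = np.full(grid16.shape, 7, dtype=int)
        bad = LabelVolume(grid16, data, scheme)
        bad.scheme = LabelScheme([(8, "Y", "y", 8)])  # break the coverage
        bad.scheme.entries = [(8, "Y", "y", 8)]
        with pytest.raises(ValueError):
            merge_to_level2(bad)


class TestSubdivideByAnatomy:
    def test_mapped_intersection(self, grid16):
        terr = np.full(grid16.shape, 2, dtype=int)  # all MCA
        anat = np.zeros(grid16.shape, dtype=int)
        anat[:8] = 1  # "frontal"
        labels = LabelVolume(grid16, terr, SUB_SCHEME)
        anat_vol = LabelVolume(grid16, anat, LabelScheme([(1, "frontal", "frontal lobe", 1)]))
        out = subdivide_by_anatomy(labels, anat_vol, {(2, 1): 10}, SUB_SCHEME)
        assert np.all(out.data[:8] == 10)
        assert np.all(out.data[8:] == 2)  # unmapped keeps territory label

    def test_identity_mapping(self, phantom16):
        out = subdivide_by_anatomy(phantom16.true_labels, phantom16.true_labels,
                                   {}, territory_scheme())
        assert np.array_equal(out.data, phantom16.true_labels.data)

    def test_partition_preserved(self, grid16):
        terr = np.zeros(grid16.shape, dtype=int)
        terr[2:10] = 2
        anat = np.zeros(grid16.shape, dtype=int)
        anat[5:16] = 1
        labels = LabelVolume(grid16, terr, SUB_SCHEME)
        anat_vol = LabelVolume(grid16, anat, LabelScheme([(1, "frontal", "frontal", 1)]))
        out = subdivide_by_anatomy(labels, anat_vol, {(2, 1): 11}, SUB_SCHEME)
        assert np.array_equal(out.data > 0, terr > 0)
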