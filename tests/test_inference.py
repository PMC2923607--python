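"""Permutation null, p-values, BH-FDR and cluster extraction."""

from collections import deque

import numpy as np
import pytest

from jointale.errors import FociInputError
from jointale.grid import GridSpec, ellipsoid_mask
from jointale.inference import (
    NullDistribution,
    PermutationConfig,
    ThresholdConfig,
    extract_clusters,
    fdr_threshold,
    permutation_null,
    voxel_pvalues,
)
from jointale.kernel import KernelSpec, kernel_prob_at_distance
from jointale.maps import LikelihoodMap, MapKind
from .conftest import make_study


def pmap(grid, values):
    return LikelihoodMap(grid, np.asarray(values, dtype=float), MapKind.PVALUE)


def jmap(grid, values):
    return LikelihoodMap(grid, np.asarray(values, dtype=float), MapKind.JOINT)


class TestPValues:
    def grid1(self, n):
        return GridSpec(voxel_size=2.0, x_range=(0, max(2.0 * (n - 1), 0.1)),
                        y_range=(0, 0.1), z_range=(0, 0.1))

    def test_addone_extremes(self):
        grid = self.grid1(2)
        null = np.linspace(0.1, 0.5, 99)
        joint = jmap(grid, np.array([[[0.9]], [[0.0]]]))
        p = voxel_pvalues(joint, null)
        assert p.values[0, 0, 0] == pytest.approx(1.0 / 100.0)
        assert p.values[1, 0, 0] == pytest.approx(1.0)

    def test_observed_at_null_median(self):
        grid = self.grid1(1)
        null = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7])  # median 0.4
        joint = jmap(grid, np.array([[[0.4]]]))
        p = voxel_pvalues(joint, null)
        # direct count: 4 of 7 null values >= 0.4 -> (1+4)/(1+7)
        assert p.values[0, 0, 0] == pytest.approx(5.0 / 8.0)

    def test_monotone_in_observed(self):
        grid = self.grid1(50)
        rng = np.random.default_rng(0)
        null = rng.uniform(0, 1, 500)
        obs = np.sort(rng.uniform(0, 1, 50))[::-1]
        joint = jmap(grid, obs.reshape(-1, 1, 1))
        p = voxel_pvalues(joint, null).values.ravel()
        assert np.all(np.diff(p) >= 0)

    def test_histogram_path_agrees_with_exact(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 0.2, 5000)
        exact = NullDistribution()
        exact.add(vals)
        binned = NullDistribution(max_raw=10)  # force histogram fallback
        binned.add(vals)
        assert not binned.is_exact and exact.is_exact
        obs = rng.uniform(0, 0.2, 100)
        ce, cb = exact.count_ge(obs), binned.count_ge(obs)
        # histogram is conservative by at most one bin's occupancy
        assert np.all(cb >= ce)
        assert np.all(cb - ce <= 5)

    def test_empty_null_rejected(self):
        grid = self.grid1(1)
        with pytest.raises(FociInputError):
            voxel_pvalues(jmap(grid, np.zeros((1, 1, 1))), NullDistribution())


class TestFDR:
    def grid(self, n):
        return GridSpec(voxel_size=2.0, x_range=(0, 2.0 * (n - 1)),
                        y_range=(0, 0.1), z_range=(0, 0.1))

    def test_bh_by_hand(self):
        # p = {0.01, 0.02, 0.04, 0.9}, q = 0.05: k=2 is the largest k with
        # p_(k) <= k q / m (0.04 > 3 * 0.05 / 4 = 0.0375), so two survive.
        grid = self.grid(4)
        p = pmap(grid, np.array([0.01, 0.02, 0.04, 0.9]).reshape(-1, 1, 1))
        supra = fdr_threshold(p, 0.05)
        assert supra.ravel().tolist() == [True, True, False, False]

    def test_all_ones_nothing_survives(self):
        grid = self.grid(10)
        p = pmap(grid, np.ones((10, 1, 1)))
        assert not fdr_threshold(p, 0.05).any()

    def test_boundary_all_survive(self):
        m = 8
        grid = self.grid(m)
        p = pmap(grid, np.full((m, 1, 1), 0.05 / m))
        assert fdr_threshold(p, 0.05).all()


def flood_fill_components(supra, connectivity):
    """Brute-force BFS connected components oracle."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if (connectivity == 6 and order == 1) or \
                   (connectivity == 18 and order <= 2) or connectivity == 26:
                    offsets.append((dx, dy, dz))
    seen = np.zeros_like(supra, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(supra)):
        if seen[start]:
            continue
        comp = []
        q = deque([start])
        seen[start] = True
        while q:
            v = q.popleft()
            comp.append(v)
            for off in offsets:
                w = tuple(np.array(v) + off)
                if all(0 <= w[a] < supra.shape[a] for a in range(3)) \
                        and supra[w] and not seen[w]:
                    seen[w] = True
                    q.append(w)
        comps.append(frozenset(comp))
    return set(comps)


class TestClusters:
    def setup_method(self):
        self.grid = GridSpec(voxel_size=2.0, x_range=(-15, 15), y_range=(-15, 15),
                             z_range=(-15, 15))
        self.kernel = KernelSpec()
        # one study per condition with a focus at the centre: every nearby
        # cluster is supported by both
        self.studies = [
            make_study([(0, 0, 0)], study="sA", condition="A"),
            make_study([(0, 0, 0)], study="sB", condition="B"),
        ]
        self.joint = jmap(self.grid, np.ones(self.grid.shape))

    def extract(self, supra, **kw):
        tc = ThresholdConfig(**{"min_cluster_volume": 0.0, "min_study_support": 0, **kw})
        return extract_clusters(supra, tc, self.studies, self.grid, self.joint,
                                self.kernel)

    def test_face_adjacent_pair_is_one_component(self):
        supra = np.zeros(self.grid.shape, dtype=bool)
        supra[5, 5, 5] = supra[6, 5, 5] = True
        for conn in (6, 18, 26):
            assert len(self.extract(supra, connectivity=conn)) == 1

    def test_volume_filter_is_strict(self):
        supra = np.zeros(self.grid.shape, dtype=bool)
        supra[5, 5, 2:14] = True  # 12 voxels -> 96 mm^3 at 2 mm
        assert self.extract(supra, min_cluster_volume=100.0) == []
        supra[5, 5, 1] = True  # 13 voxels -> 104 mm^3
        out = self.extract(supra, min_cluster_volume=100.0)
        assert len(out) == 1 and out[0].volume_mm3 == pytest.approx(104.0)

    def test_diagonal_pair_connectivity(self):
        supra = np.zeros(self.grid.shape, dtype=bool)
        supra[5, 5, 5] = supra[6, 6, 6] = True
        assert len(self.extract(supra, connectivity=26)) == 1
        assert len(self.extract(supra, connectivity=6)) == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        grid = GridSpec(voxel_size=2.0, x_range=(0, 30), y_range=(0, 30),
                        z_range=(0, 30))
        joint = jmap(grid, np.ones(grid.shape))
        rng = np.random.default_rng(connectivity)
        for _ in range(5):
            supra = rng.random(grid.shape) < 0.2
            tc = ThresholdConfig(min_cluster_volume=0.0, min_study_support=0,
                                 connectivity=connectivity)
            ours = extract_clusters(supra, tc, self.studies, grid, joint,
                                    self.kernel)
            got = {frozenset(map(tuple, c.voxels)) for c in ours}
            assert got == flood_fill_components(supra, connectivity)

    def test_study_support_radius(self):
        supra = np.zeros(self.grid.shape, dtype=bool)
        supra[6:9, 6:9, 6:9] = True  # cluster near (0,0,0)..(2,2,2) mm
        studies = [
            make_study([(0, 0, 0)], study="near", condition="A"),
            make_study([(0, 0, 0)], study="near2", condition="B"),
            # focus 100 mm away in y: beyond any kernel reach on this grid
            make_study([(0, -100, 0)], study="far", condition="B"),
        ]
        tc = ThresholdConfig(min_cluster_volume=0.0, min_study_support=0)
        out = extract_clusters(supra, tc, studies, self.grid, self.joint,
                               self.kernel)
        support = out[0].supporting_studies
        assert support == {"A": ("near",), "B": ("near2",)}

    def test_single_study_clusters_dropped(self):
        supra = np.zeros(self.grid.shape, dtype=bool)
        supra[6:9, 6:9, 6:9] = True
        studies = [make_study([(0, 0, 0)], study="only", condition="A")]
        tc = ThresholdConfig(min_cluster_volume=0.0, min_study_support=2)
        assert extract_clusters(supra, tc, studies, self.grid, self.joint,
                                self.kernel) == []


class TestPermutationNull:
    def test_deterministic_under_seed(self, small_grid):
        mask = ellipsoid_mask(small_grid)
        studies = [
            make_study([(0, 0, 0), (5, 5, 0)], study="sA", condition="A"),
            make_study([(0, 0, 5)], study="sB", condition="B"),
        ]
        pc = PermutationConfig(n_permutations=100, seed=11)
        k = KernelSpec()
        a = permutation_null(studies, small_grid, k, mask, pc)
        b = permutation_null(studies, small_grid, k, mask, pc)
        obs = np.linspace(0, 0.2, 64)
        assert np.array_equal(a.count_ge(obs), b.count_ge(obs))
        assert a.n == b.n == 100 * mask.sum()

    def test_null_bounds_and_peak(self, small_grid):
        mask = ellipsoid_mask(small_grid)
        studies = [
            make_study([(0, 0, 0)], study="sA", condition="A"),
            make_study([(0, 0, 0)], study="sB", condition="B"),
        ]
        k = KernelSpec()
        pc = PermutationConfig(n_permutations=100, seed=1)
        null = permutation_null(studies, small_grid, k, mask, pc)
        # with one focus per condition the joint can never exceed twice the
        # kernel peak value
        peak = kernel_prob_at_distance(0.0, k, small_grid.voxel_volume)
        assert null.count_ge(np.array([2 * peak + 1e-12]))[0] == 0
        assert null.count_ge(np.array([0.0]))[0] == null.n

    def test_empty_mask_rejected(self, small_grid):
        studies = [make_study([(0, 0, 0)])]
        with pytest.raises(FociInputError):
            permutation_null(studies, small_grid, KernelSpec(),
                             np.zeros(small_grid.shape, dtype=bool),
                             PermutationConfig(n_permutations=100, seed=0))

    def test_too_few_permutations_rejected(self):
        with pytest.raises(FociInputError):
            PermutationConfig(n_permutations=50, seed=0)
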