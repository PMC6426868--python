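import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from infantdot.errors import ConfigError, EstimationError
from infantdot.stats import (
    CONDITIONS,
    GroupSample,
    RoiSet,
    adaptive_cluster,
    bonferroni,
    global_analysis,
    roi_analysis,
    tukey_kramer,
    voxelwise_pmap,
)

GRID = (12, 12, 12)


def _sample(rng, n=21, effect=None, grid=GRID, conditions=CONDITIONS):
    """Noise maps, optionally with a per-condition additive effect map."""
    mags = {}
    for c in conditions:
        maps = rng.standard_normal((n,) + grid)
        if effect and c in effect:
            maps += effect[c]
        mags[c] = maps
    return GroupSample(mags, voxel_size_mm=2.0, conditions=tuple(conditions))


class TestBonferroni:
    def test_worked_examples(self):
        assert bonferroni(3.3e-4, 120) == pytest.approx(0.04, abs=0.005)
        assert bonferroni(7.0e-6, 120) == pytest.approx(8.4e-4, rel=1e-9)

    def test_cap_at_one(self):
        assert bonferroni(0.5, 120) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ConfigError):
            bonferroni(-0.1, 10)
        with pytest.raises(ConfigError):
            bonferroni(1.5, 10)
        with pytest.raises(ConfigError):
            bonferroni(0.5, 0)

    @settings(max_examples=50, derandomize=True)
    @given(
        p1=st.floats(0, 1),
        p2=st.floats(0, 1),
        n1=st.integers(1, 500),
        n2=st.integers(1, 500),
    )
    def test_monotone_and_bounded(self, p1, p2, n1, n2):
        c = bonferroni(p1, n1)
        assert 0.0 <= c <= 1.0
        if p1 <= p2:
            assert c <= bonferroni(p2, n1)
        if n1 <= n2:
            assert c <= bonferroni(p1, n2)


class TestTukeyKramer:
    def test_identical_groups_p_near_one(self, rng):
        g = rng.standard_normal(15)
        pmat, _ = tukey_kramer([g, g.copy()])
        assert pmat[0, 1] > 0.999

    def test_two_group_equivalence_to_pooled_t(self, rng):
        """With two groups the studentized-range test reduces to the pooled
        two-sample t-test (q = sqrt(2)|t|)."""
        a = rng.standard_normal(12) + 0.8
        b = rng.standard_normal(9)
        pmat, _ = tukey_kramer([a, b])
        t_p = sstats.ttest_ind(a, b).pvalue
        assert pmat[0, 1] == pytest.approx(t_p, abs=1e-6)

    def test_shifted_group_flagged_exclusively(self):
        """One group shifted by 5 SD: exactly its three pairs are flagged in
        >= 95% of seeded replicates."""
        rng = np.random.default_rng(7)
        ok = 0
        n_rep = 400
        for _ in range(n_rep):
            groups = [rng.standard_normal(10) for _ in range(4)]
            groups[2] = groups[2] + 5.0
            pmat, _ = tukey_kramer(groups)
            sig = pmat < 0.05
            want = np.zeros((4, 4), bool)
            want[2, :] = want[:, 2] = True
            np.fill_diagonal(want, False)
            ok += np.array_equal(sig & ~np.eye(4, dtype=bool), want)
        assert ok / n_rep >= 0.95

    def test_small_group_rejected(self):
        with pytest.raises(EstimationError):
            tukey_kramer([np.array([1.0]), np.array([0.0, 1.0])])


class TestGlobalAnalysis:
    def test_null_type_one_error_rate(self):
        """Under identical condition distributions the ANOVA rejects at
        about the nominal 5% rate."""
        rng = np.random.default_rng(11)
        grid = (4, 4, 4)
        mask = np.ones(grid, bool)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            sample = _sample(rng, n=21, grid=grid)
            res = global_analysis(sample, mask, mask)
            rejections += res["anova"]["p"] < 0.05
        assert 0.03 <= rejections / n_rep <= 0.075

    def test_shifted_condition_detected(self):
        """A condition shifted by +3 pooled SD drives the ANOVA below 0.01
        and Tukey flags exactly its pairs in >= 95% of replicates."""
        rng = np.random.default_rng(13)
        grid = (4, 4, 4)
        mask = np.ones(grid, bool)
        ok = 0
        n_rep = 200
        for _ in range(n_rep):
            sample = _sample(rng, n=21, grid=grid, effect={"happy": 3.0})
            res = global_analysis(sample, mask, mask)
            if res["anova"]["p"] >= 0.01 or res["tukey"] is None:
                continue
            flagged = {k for k, v in res["tukey"].items() if v < 0.05}
            want = {"happy > neutral", "happy > angry", "happy > sad"}
            ok += flagged == want
        assert ok / n_rep >= 0.95

    def test_positive_mask_rule(self, rng):
        grid = (6, 6, 6)
        gm = np.ones(grid, bool)
        sample = _sample(rng, n=8, grid=grid, effect={c: 5.0 for c in CONDITIONS})
        res = global_analysis(sample, gm, gm)
        assert res["n_vox"] == gm.sum()  # all-positive means -> full mask

    def test_too_few_subjects(self, rng):
        sample = _sample(rng, n=2, grid=(4, 4, 4))
        with pytest.raises(EstimationError):
            global_analysis(sample, np.ones((4, 4, 4), bool), np.ones((4, 4, 4), bool))


class TestVoxelwisePmap:
    def test_null_pvalues_uniform(self, rng):
        sample = _sample(rng, n=21)
        p = voxelwise_pmap(sample, "avg_vs_zero").ravel()
        ks = sstats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_effect_low_p(self, rng):
        effect = np.zeros(GRID)
        effect[5:8, 5:8, 5:8] = 2.0
        sample = _sample(rng, n=21, effect={c: effect for c in CONDITIONS})
        p = voxelwise_pmap(sample, "avg_vs_zero")
        assert p[6, 6, 6] < 1e-3

    def test_single_condition_test_reduces_to_avg(self, rng):
        sample = _sample(rng, n=10, conditions=("happy",))
        p_avg = voxelwise_pmap(sample, "avg_vs_zero")
        p_cond = voxelwise_pmap(sample, ("condition", "happy"))
        assert np.allclose(p_avg, p_cond, atol=1e-14)

    def test_anova_vs_scipy(self, rng):
        sample = _sample(rng, n=9)
        p = voxelwise_pmap(sample, "anova").ravel()
        data = sample.stacked()
        ref = sstats.f_oneway(*[data[:, i] for i in range(4)], axis=0).pvalue
        assert np.allclose(p, ref, atol=1e-12)

    def test_zero_variance_voxel_p_one(self):
        mags = {c: np.zeros((5,) + GRID) for c in CONDITIONS}
        sample = GroupSample(mags, voxel_size_mm=2.0)
        with pytest.warns(UserWarning):
            p = voxelwise_pmap(sample, "avg_vs_zero")
        assert np.all(p == 1.0)


def _pmap_with(mask, regions):
    """p-value map equal to 0.5 except given (slice, value) regions."""
    p = np.full(mask.shape, 0.5)
    for sl, val in regions:
        p[sl] = val
    return p


class TestAdaptiveClustering:
    grid = (20, 20, 20)

    def _sample_for(self, effect_mask, rng, n=21, strength=3.0):
        eff = strength * effect_mask
        return _sample(rng, n=n, grid=self.grid, effect={c: eff for c in CONDITIONS})

    def test_single_blob_single_cluster(self, rng):
        mask = np.ones(self.grid, bool)
        blob = np.zeros(self.grid, bool)
        blob[4:12, 4:12, 4:12] = True  # 512 voxels > 200
        sample = self._sample_for(blob, rng)
        pmap = voxelwise_pmap(sample, "avg_vs_zero")
        clusters = adaptive_cluster(pmap, sample, mask, min_voxels=200)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.n_vox >= 200
        assert c.p_corrected <= 1.0
        # nesting: seed set inside level-2 inside level-3
        ths = sorted(c.voxel_sets)
        assert np.all(c.voxel_sets[ths[1]][c.voxel_sets[ths[0]]])
        assert np.all(c.voxel_sets[ths[2]][c.voxel_sets[ths[1]]])

    def test_seeds_merging_at_looser_level(self, rng):
        """Two seeds whose p < 0.01 regions connect are one cluster."""
        mask = np.ones(self.grid, bool)
        pmap = _pmap_with(
            mask,
            [
                ((slice(2, 5), slice(2, 5), slice(2, 5)), 1e-5),
                ((slice(8, 11), slice(2, 5), slice(2, 5)), 1e-5),
                ((slice(2, 11), slice(2, 5), slice(2, 5)), None),
            ][:2],
        )
        # bridge significant only at the loosest threshold
        pmap[5:8, 2:5, 2:5] = 0.005
        sample = _sample(rng, n=21, grid=self.grid)
        clusters = adaptive_cluster(pmap, sample, mask, min_voxels=1)
        assert len(clusters) == 1
        # without the bridge they stay separate
        pmap[5:8, 2:5, 2:5] = 0.5
        clusters2 = adaptive_cluster(pmap, sample, mask, min_voxels=1)
        assert len(clusters2) == 2

    def test_small_clusters_discarded(self, rng):
        mask = np.ones(self.grid, bool)
        pmap = _pmap_with(mask, [((slice(5, 8), slice(5, 8), slice(5, 8)), 1e-5)])
        sample = _sample(rng, n=21, grid=self.grid)
        assert adaptive_cluster(pmap, sample, mask, min_voxels=200) == []

    def test_empty_when_no_seeds(self, rng):
        mask = np.ones(self.grid, bool)
        pmap = np.full(self.grid, 0.5)
        sample = _sample(rng, n=21, grid=self.grid)
        assert adaptive_cluster(pmap, sample, mask) == []

    def test_shape_mismatch(self, rng):
        sample = _sample(rng, n=5, grid=self.grid)
        with pytest.raises(ConfigError):
            adaptive_cluster(np.zeros((3, 3, 3)), sample, np.ones(self.grid, bool))


class TestRoiAnalysis:
    def _rois(self, head):
        return RoiSet()

    def test_zero_images_no_significance(self, ctx):
        grid = ctx.head.grid_shape
        mags = {c: np.zeros((6,) + grid) for c in CONDITIONS}
        sample = GroupSample(mags, voxel_size_mm=2.0)
        table = roi_analysis(sample, RoiSet(), ctx.gm_mask)
        assert np.allclose(table.mean_hbt, 0.0)
        assert (table.p_vs_baseline == 1.0).all()
        assert (table.tukey == "").all()

    def test_planted_negative_angry_at_psts(self, ctx, rng):
        """A negative effect planted at the pSTS center for the angry
        condition is flagged angry < baseline in the pSTS row."""
        rois = RoiSet()
        centers = rois.centers_mm()
        grid = ctx.head.grid_shape
        vs = ctx.head.voxel_size_mm
        coords = np.stack(
            np.meshgrid(*[(np.arange(n) + 0.5) * vs for n in grid], indexing="ij"),
            axis=-1,
        )
        d2 = ((coords - centers["pSTS"]) ** 2).sum(axis=-1)
        effect = -3.0 * np.exp(-d2 / (2 * 36.0))
        mags = {
            c: 0.3 * rng.standard_normal((21,) + grid)
            + (effect if c == "angry" else 0.0)
            for c in CONDITIONS
        }
        sample = GroupSample(mags, voxel_size_mm=vs)
        table = roi_analysis(sample, rois, ctx.gm_mask, fov_mask=ctx.fov)
        row = table[(table.roi == "pSTS") & (table.condition == "angry")].iloc[0]
        assert row.mean_hbt < 0
        assert row.p_vs_baseline_corrected < 0.05
        anova_row = table[table.roi == "pSTS"].iloc[0]
        assert "neutral > angry" in anova_row.tukey or "happy > angry" in anova_row.tukey

    def test_radius_zero_single_voxel(self, ctx, rng):
        rois = RoiSet(radius_mm=ctx.head.voxel_size_mm / 2)
        sets = rois.voxel_sets(ctx.gm_mask, ctx.head.voxel_size_mm)
        for name, s in sets.items():
            assert s.sum() == 1

    def test_roi_outside_gm_raises(self, ctx):
        rois = RoiSet(centers_template={"bad": (0.0, -27.0, 40.0)})
        with pytest.raises(EstimationError):
            rois.voxel_sets(ctx.gm_mask, ctx.head.voxel_size_mm)


class TestGroupSample:
    def test_empty_mask_rejected(self, rng):
        sample = _sample(rng, n=4, grid=(4, 4, 4))
        with pytest.raises(EstimationError):
            sample.region_means(np.zeros((4, 4, 4), bool))

    def test_mismatched_shapes_rejected(self, rng):
        mags = {c: rng.standard_normal((4,) + GRID) for c in CONDITIONS}
        mags["happy"] = rng.standard_normal((5,) + GRID)
        with pytest.raises(ConfigError):
            GroupSample(mags, voxel_size_mm=2.0)
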