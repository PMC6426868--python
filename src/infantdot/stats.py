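"""Group-level statistics: global FOV analysis, adaptive voxel-based
clustering, ROI tables, and Bonferroni correction.

The group unit is the subject: each subject contributes one window-magnitude
HbT map per condition.  Three families of tests are used throughout:
(1) one-sample two-tailed t of the across-condition average against zero,
(2) one-way ANOVA across conditions (Tukey-Kramer post hoc when significant),
(3) one-sample two-tailed t of a single condition against (subtracted)
baseline.

Adaptive clustering seeds contiguous regions at voxelwise p < 0.001, grows
each seed inside the p < 0.0033 and p < 0.01 superlevel sets, merges seeds
whose grown regions join, re-tests the cluster-mean magnitude at every
level, takes the smallest level p as the cluster p, discards clusters below
200 voxels at the chosen level, and Bonferroni-corrects with N_MC = 120
(the number of practically separable regions the probe can image).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sstats

from .errors import ConfigError, EstimationError
from .hemodynamics import CONDITIONS

DEFAULT_THRESHOLDS = (0.001, 0.0033, 0.01)
DEFAULT_N_MC = 120
DEFAULT_MIN_VOXELS = 200

#: Approximate infant-template (MNI-like) ROI centers, left hemisphere, mm.
DEFAULT_ROI_CENTERS = {
    "aSTS": (-26.0, -4.0, 1.0),
    "STG": (-20.0, -6.0, -2.0),
    "IFG": (-21.0, -9.0, 6.0),
    "AI": (-24.0, 0.0, 8.0),
    "MI": (-26.0, -8.0, 4.0),
    "pSTS": (-20.0, -15.0, 1.0),
}

#: Default affine mapping template RAS mm coordinates onto the synthetic
#: slab phantom (80 mm cube, probe on the z = 0 face over the left temporal
#: field): template y (posterior-anterior) -> grid x, template z
#: (inferior-superior) -> grid y, template -x (lateral depth) -> grid z.
DEFAULT_TEMPLATE_AFFINE = {
    "matrix": [[0.0, 2.0, 0.0], [0.0, 0.0, 2.0], [-1.0, 0.0, 0.0]],
    "offset": [54.0, 34.0, -14.0],
}


@dataclass
class GroupSample:
    """Window-magnitude HbT maps per subject and condition."""

    magnitudes: dict[str, np.ndarray]  # cond -> (n_subjects,) + grid_shape
    voxel_size_mm: float
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self):
        shapes = {v.shape for v in self.magnitudes.values()}
        if len(shapes) != 1:
            raise ConfigError("all condition maps must share (n_subjects,) + grid shape")

    @property
    def n_subjects(self) -> int:
        return next(iter(self.magnitudes.values())).shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return next(iter(self.magnitudes.values())).shape[1:]

    def stacked(self) -> np.ndarray:
        """(n_subjects, n_conditions, n_voxels) array in condition order."""
        n = self.n_subjects
        return np.stack(
            [self.magnitudes[c].reshape(n, -1) for c in self.conditions], axis=1
        )

    def region_means(self, mask: np.ndarray) -> np.ndarray:
        """(n_subjects, n_conditions) means over a voxel mask."""
        flat = np.asarray(mask, bool).ravel()
        if not flat.any():
            raise EstimationError("empty analysis mask")
        return self.stacked()[:, :, flat].mean(axis=2)


def bonferroni(p: float, n: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * n)."""
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"p-value {p} outside [0, 1]")
    if n < 1:
        raise ConfigError("n must be >= 1")
    return min(1.0, p * n)


def tukey_kramer(groups: list[np.ndarray]):
    """Studentized-range pairwise comparisons honoring unequal group sizes.

    Returns the pairwise p-value matrix (k x k) and the mean differences.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ConfigError("Tukey-Kramer needs at least two groups")
    for g in groups:
        if g.size < 2:
            raise EstimationError("every group needs n >= 2")
    res = sstats.tukey_hsd(*groups)
    means = np.array([g.mean() for g in groups])
    return res.pvalue, means[:, None] - means[None, :]


def _ttest_1samp_vec(x: np.ndarray):
    """Two-tailed one-sample t vs 0 along axis 0; zero-variance -> p = 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = sstats.ttest_1samp(x, 0.0, axis=0)
    bad = ~np.isfinite(p)
    if np.any(bad):
        warnings.warn(f"{int(bad.sum())} zero-variance voxels set to p = 1", stacklevel=2)
        p = np.where(bad, 1.0, p)
        t = np.where(np.isfinite(t), t, 0.0)
    return t, p


def _anova_vec(data: np.ndarray, repeated: bool = False):
    """One-way ANOVA across conditions, vectorized over trailing axes.

    ``data`` has shape (n_subjects, n_conditions, ...).  The default treats
    subjects as independent replicates per condition; ``repeated=True`` uses
    the one-way repeated-measures decomposition with subject blocking.
    """
    n, k = data.shape[:2]
    grand = data.mean(axis=(0, 1))
    cond_mean = data.mean(axis=0)
    if not repeated:
        ss_between = n * ((cond_mean - grand) ** 2).sum(axis=0)
        ss_within = ((data - cond_mean[None]) ** 2).sum(axis=(0, 1))
        df1, df2 = k - 1, k * (n - 1)
        ms_err = ss_within / df2
    else:
        subj_mean = data.mean(axis=1)
        ss_between = n * ((cond_mean - grand) ** 2).sum(axis=0)
        ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=0)
        ss_total = ((data - grand) ** 2).sum(axis=(0, 1))
        ss_err = ss_total - ss_between - ss_subj
        df1, df2 = k - 1, (k - 1) * (n - 1)
        ms_err = ss_err / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / ms_err
        p = sstats.f.sf(F, df1, df2)
    bad = ~np.isfinite(p)
    if np.any(bad):
        p = np.where(bad, 1.0, p)
        F = np.where(np.isfinite(F), F, 0.0)
    return F, p


def _group_test(scalars: np.ndarray, test, conditions, repeated=False):
    """p-value for (n_subjects, n_conditions) cluster/region means."""
    if test == "avg_vs_zero":
        _, p = _ttest_1samp_vec(scalars.mean(axis=1))
    elif test == "anova":
        _, p = _anova_vec(scalars[..., None], repeated=repeated)
        p = float(np.asarray(p).ravel()[0])
    elif isinstance(test, tuple) and test[0] == "condition":
        ci = conditions.index(test[1])
        _, p = _ttest_1samp_vec(scalars[:, ci])
    else:
        raise ConfigError(f"unknown test {test!r}")
    return float(p)


def global_analysis(
    sample: GroupSample,
    fov: np.ndarray,
    gm: np.ndarray,
    alpha: float = 0.05,
    repeated: bool = False,
) -> dict:
    """FOV-wide statistics over GM voxels positive for >= 1 condition.

    The analysis mask keeps GM-within-FOV voxels whose group-mean magnitude
    is positive for at least one condition; subject scalars are magnitude
    means over that mask.  Reports the speech-average t-test vs zero,
    Bartlett's equal-variance check, one-way ANOVA across conditions with
    Tukey-Kramer pairs when significant, and per-condition t-tests vs zero.
    """
    if sample.n_subjects < 3:
        raise EstimationError("global analysis needs at least 3 subjects")
    mask = np.asarray(gm, bool) & np.asarray(fov, bool)
    group_means = {c: sample.magnitudes[c].mean(axis=0) for c in sample.conditions}
    positive_any = np.zeros(sample.grid_shape, bool)
    for c in sample.conditions:
        positive_any |= group_means[c] > 0
    mask &= positive_any
    if not mask.any():
        raise EstimationError("empty global-analysis mask (no positive GM/FOV voxels)")

    scalars = sample.region_means(mask)  # (n_subj, n_cond)
    avg = scalars.mean(axis=1)
    t_avg, p_avg = sstats.ttest_1samp(avg, 0.0)
    groups = [scalars[:, i] for i in range(len(sample.conditions))]
    bartlett_stat, bartlett_p = sstats.bartlett(*groups)
    F, p_anova = _anova_vec(scalars[..., None], repeated=repeated)
    p_anova = float(np.asarray(p_anova).ravel()[0])
    result = {
        "n_vox": int(mask.sum()),
        "mask": mask,
        "speech_average": {"mean": float(avg.mean()), "t": float(t_avg), "p": float(p_avg)},
        "bartlett_p": float(bartlett_p),
        "anova": {"F": float(np.asarray(F).ravel()[0]), "p": p_anova},
        "per_condition": {},
        "tukey": None,
    }
    for i, c in enumerate(sample.conditions):
        t, p = sstats.ttest_1samp(scalars[:, i], 0.0)
        result["per_condition"][c] = {
            "mean": float(scalars[:, i].mean()),
            "t": float(t),
            "p": float(p),
        }
    if p_anova < alpha:
        pmat, diffs = tukey_kramer(groups)
        pairs = {}
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                ci, cj = sample.conditions[i], sample.conditions[j]
                hi, lo = (ci, cj) if diffs[i, j] > 0 else (cj, ci)
                pairs[f"{hi} > {lo}"] = float(pmat[i, j])
        result["tukey"] = pairs
    return result


def voxelwise_pmap(
    sample: GroupSample, test="avg_vs_zero", repeated: bool = False
) -> np.ndarray:
    """Per-voxel p-value map for the selected group test (two-tailed t's)."""
    data = sample.stacked()  # (n_subj, n_cond, n_vox)
    if test == "avg_vs_zero":
        _, p = _ttest_1samp_vec(data.mean(axis=1))
    elif test == "anova":
        _, p = _anova_vec(data, repeated=repeated)
    elif isinstance(test, tuple) and test[0] == "condition":
        ci = sample.conditions.index(test[1])
        _, p = _ttest_1samp_vec(data[:, ci])
    else:
        raise ConfigError(f"unknown test {test!r}")
    return np.asarray(p).reshape(sample.grid_shape)


@dataclass
class ClusterResult:
    """One adaptive cluster with its per-level extents and p-values."""

    voxel_sets: dict[float, np.ndarray]  # threshold -> bool mask
    level_p: dict[float, float]
    chosen_threshold: float
    n_vox: int
    p_uncorrected: float
    p_corrected: float
    n_mc: int
    test: object
    condition_means: dict[str, float] = field(default_factory=dict)
    tukey: dict[str, float] | None = None  # ordered pairs, ANOVA clusters only

    @property
    def mask(self) -> np.ndarray:
        return self.voxel_sets[self.chosen_threshold]


def _connectivity(conn: int):
    if conn == 6:
        return ndimage.generate_binary_structure(3, 1)
    if conn == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ConfigError("connectivity must be 6 or 26")


def adaptive_cluster(
    pmap: np.ndarray,
    sample: GroupSample,
    mask: np.ndarray,
    test="avg_vs_zero",
    thresholds=DEFAULT_THRESHOLDS,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    n_mc: int = DEFAULT_N_MC,
    connectivity: int = 6,
    repeated: bool = False,
) -> list[ClusterResult]:
    """Adaptive multi-threshold clustering with cluster-mean re-testing.

    Seeds are connected components of ``pmap < thresholds[0]`` within
    ``mask``; each seed grows to its connected component of the looser
    superlevel sets, seeds sharing a grown component merge, the cluster-mean
    magnitude is re-tested with ``test`` at every level, and the smallest
    level p (Bonferroni-corrected by ``n_mc``) is reported.  Clusters with
    fewer than ``min_voxels`` voxels at the chosen level are discarded.
    An empty list is a valid result.
    """
    mask = np.asarray(mask, bool)
    if pmap.shape != mask.shape:
        raise ConfigError("pmap and mask shapes differ")
    structure = _connectivity(connectivity)
    thresholds = tuple(sorted(thresholds))
    seed_labels, n_seeds = ndimage.label((pmap < thresholds[0]) & mask, structure)
    if n_seeds == 0:
        return []

    # per-level component labels and each seed's component id at each level
    level_labels = {}
    seed_component = {}
    for th in thresholds:
        labels, _ = ndimage.label((pmap < th) & mask, structure)
        level_labels[th] = labels
        for s in range(1, n_seeds + 1):
            comp_ids = np.unique(labels[seed_labels == s])
            comp_ids = comp_ids[comp_ids > 0]
            # a seed lies inside exactly one component of every looser set
            seed_component[(s, th)] = int(comp_ids[0])

    # merge seeds sharing a component at the loosest level (nesting makes
    # this the complete merge relation)
    loosest = thresholds[-1]
    groups: dict[int, list[int]] = {}
    for s in range(1, n_seeds + 1):
        groups.setdefault(seed_component[(s, loosest)], []).append(s)

    results = []
    for seeds in groups.values():
        voxel_sets = {}
        for th in thresholds:
            comp_ids = {seed_component[(s, th)] for s in seeds}
            voxel_sets[th] = np.isin(level_labels[th], sorted(comp_ids))
        level_p = {}
        for th in thresholds:
            scalars = sample.region_means(voxel_sets[th])
            level_p[th] = _group_test(scalars, test, list(sample.conditions), repeated)
        chosen = min(level_p, key=level_p.get)
        n_vox = int(voxel_sets[chosen].sum())
        if n_vox < min_voxels:
            continue
        p_unc = level_p[chosen]
        scalars = sample.region_means(voxel_sets[chosen])
        cond_means = {
            c: float(scalars[:, i].mean()) for i, c in enumerate(sample.conditions)
        }
        tukey = None
        if test == "anova" and p_unc < 0.05:
            pmat, diffs = tukey_kramer([scalars[:, i] for i in range(scalars.shape[1])])
            tukey = {}
            for i in range(scalars.shape[1]):
                for j in range(i + 1, scalars.shape[1]):
                    ci, cj = sample.conditions[i], sample.conditions[j]
                    hi, lo = (ci, cj) if diffs[i, j] > 0 else (cj, ci)
                    tukey[f"{hi} > {lo}"] = float(pmat[i, j])
        results.append(
            ClusterResult(
                voxel_sets=voxel_sets,
                level_p=level_p,
                chosen_threshold=chosen,
                n_vox=n_vox,
                p_uncorrected=p_unc,
                p_corrected=bonferroni(p_unc, n_mc),
                n_mc=n_mc,
                test=test,
                condition_means=cond_means,
                tukey=tukey,
            )
        )
    results.sort(key=lambda r: r.p_uncorrected)
    return results


def null_cluster_fwe(
    analysis_mask: np.ndarray,
    brain_mask: np.ndarray,
    n_subjects: int = 21,
    n_replicates: int = 200,
    seed: int = 0,
    smoothing_sigma_vox: float = 1.5,
    test="avg_vs_zero",
    alpha: float = 0.05,
    conditions=CONDITIONS,
    voxel_size_mm: float = 2.0,
    **cluster_kw,
) -> float:
    """Familywise error rate of the adaptive clustering under the null.

    Each replicate draws iid standard-normal magnitude maps for every
    subject and condition on the brain mask, smooths them like the real
    pipeline, and runs the full voxelwise-test -> adaptive-cluster ->
    Bonferroni chain; returns the fraction of replicates reporting any
    corrected-significant cluster.
    """
    from .reconstruct import smooth_image  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    brain = np.asarray(brain_mask, bool)
    hits = 0
    for _ in range(n_replicates):
        mags = {}
        for c in conditions:
            vols = rng.standard_normal((n_subjects,) + brain.shape) * brain
            mags[c] = np.stack(
                [smooth_image(v, brain, smoothing_sigma_vox) for v in vols]
            )
        sample = GroupSample(mags, voxel_size_mm=voxel_size_mm, conditions=tuple(conditions))
        pmap = voxelwise_pmap(sample, test)
        clusters = adaptive_cluster(pmap, sample, analysis_mask, test=test, **cluster_kw)
        if any(c.p_corrected < alpha for c in clusters):
            hits += 1
    return hits / n_replicates


@dataclass
class RoiSet:
    """Spherical ROIs at template coordinates, mapped onto the grid."""

    centers_template: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_CENTERS)
    )
    radius_mm: float = 8.0
    affine_matrix: list = field(
        default_factory=lambda: [row[:] for row in DEFAULT_TEMPLATE_AFFINE["matrix"]]
    )
    affine_offset: list = field(
        default_factory=lambda: list(DEFAULT_TEMPLATE_AFFINE["offset"])
    )

    def centers_mm(self) -> dict[str, np.ndarray]:
        M = np.asarray(self.affine_matrix, float)
        t = np.asarray(self.affine_offset, float)
        return {
            name: M @ np.asarray(c, float) + t
            for name, c in self.centers_template.items()
        }

    def voxel_sets(
        self, gm_mask: np.ndarray, voxel_size_mm: float
    ) -> dict[str, np.ndarray]:
        """GM-restricted sphere masks; raises when an ROI captures no GM."""
        gm = np.asarray(gm_mask, bool)
        grids = np.stack(
            np.meshgrid(
                *[(np.arange(n) + 0.5) * voxel_size_mm for n in gm.shape], indexing="ij"
            ),
            axis=-1,
        )
        out = {}
        for name, c in self.centers_mm().items():
            d2 = ((grids - c) ** 2).sum(axis=-1)
            sphere = d2 <= self.radius_mm**2
            # the ROI always includes the voxel containing its center, so a
            # degenerate radius yields a single-voxel ROI
            center_vox = np.clip(
                np.floor(c / voxel_size_mm).astype(int), 0, np.asarray(gm.shape) - 1
            )
            sphere[tuple(center_vox)] = True
            roi = sphere & gm
            if not roi.any():
                raise EstimationError(f"ROI {name} at {tuple(c)} contains no GM voxels")
            out[name] = roi
        return out


def roi_analysis(
    sample: GroupSample,
    rois: RoiSet,
    gm_mask: np.ndarray,
    fov_mask: np.ndarray | None = None,
    alpha: float = 0.05,
    n_regions_correction: int | None = None,
    repeated: bool = False,
) -> pd.DataFrame:
    """Per-ROI condition means, t vs baseline, ANOVA and Tukey flags.

    Returns one row per (ROI, condition) plus the ROI-level ANOVA p-value,
    Tukey-significant ordered pairs, and Bonferroni flags across the ROI
    family (N defaults to the number of ROIs).
    """
    voxel_sets = rois.voxel_sets(gm_mask, sample.voxel_size_mm)
    n_corr = n_regions_correction or len(voxel_sets)
    rows = []
    for name, roi in voxel_sets.items():
        coverage = 1.0
        if fov_mask is not None:
            coverage = float((roi & fov_mask).sum() / roi.sum())
            if coverage < 1.0:
                warnings.warn(
                    f"ROI {name} only {coverage:.0%} inside the FOV", stacklevel=2
                )
        scalars = sample.region_means(roi)
        _, p_anova = _anova_vec(scalars[..., None], repeated=repeated)
        p_anova = float(np.asarray(p_anova).ravel()[0])
        tukey_pairs = {}
        if p_anova < alpha:
            pmat, diffs = tukey_kramer([scalars[:, i] for i in range(scalars.shape[1])])
            for i in range(scalars.shape[1]):
                for j in range(i + 1, scalars.shape[1]):
                    if pmat[i, j] < alpha:
                        ci, cj = sample.conditions[i], sample.conditions[j]
                        hi, lo = (ci, cj) if diffs[i, j] > 0 else (cj, ci)
                        tukey_pairs[f"{hi} > {lo}"] = float(pmat[i, j])
        for i, cond in enumerate(sample.conditions):
            t, p = sstats.ttest_1samp(scalars[:, i], 0.0)
            if not np.isfinite(p):
                t, p = 0.0, 1.0
            rows.append(
                {
                    "roi": name,
                    "condition": cond,
                    "mean_hbt": float(scalars[:, i].mean()),
                    "t": float(t),
                    "p_vs_baseline": float(p),
                    "p_vs_baseline_corrected": bonferroni(float(p), n_corr),
                    "anova_p": p_anova,
                    "tukey": "; ".join(f"{k} (p={v:.3g})" for k, v in tukey_pairs.items()),
                    "fov_coverage": coverage,
                    "n_vox": int(roi.sum()),
                }
            )
    return pd.DataFrame(rows)
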