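"""Nested pipeline configuration with lossless YAML round-tripping.

Every tunable used by the phantom, hemodynamics, generator, preprocessing,
reconstruction and statistics stages appears here exactly once; module-level
dataclasses (:class:`~infantdot.preprocess.PreprocessConfig`,
:class:`~infantdot.reconstruct.ReconstructionConfig`) are embedded directly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass

import yaml

from .preprocess import PreprocessConfig
from .reconstruct import ReconstructionConfig
from .stats import (
    DEFAULT_MIN_VOXELS,
    DEFAULT_N_MC,
    DEFAULT_ROI_CENTERS,
    DEFAULT_TEMPLATE_AFFINE,
    DEFAULT_THRESHOLDS,
)


@dataclass
class PhantomSection:
    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size_mm: float = 2.0
    layer_thicknesses_mm: dict = field(
        default_factory=lambda: {"scalp": 2.0, "skull": 2.0, "csf": 1.0, "gm": 10.0}
    )
    optical_props: dict | None = None  # None -> per-tissue defaults
    probe_layout: tuple[int, int] = (5, 6)
    probe_spacing_mm: float = 10.0
    max_sds_mm: float = 45.0
    wavelength_nm: float = 798.0
    jacobian_background: str = "mean"
    n_rel: float = 1.4
    fov_threshold: float = 0.001


@dataclass
class HemodynamicsSection:
    n_blocks_per_condition: int = 7
    block_duration_s: float = 11.0
    rest_bounds_s: tuple[float, float] = (20.0, 30.0)
    habituation_amplitudes: tuple[float, ...] = (1.0, 0.6, 0.3, 0.2)
    phrase_duration_s: float = 2.2
    phrase_gap_s: float = 0.7
    hrf_response_delay_s: float = 6.0
    hrf_undershoot_delay_s: float = 16.0
    hrf_response_dispersion: float = 1.0
    hrf_undershoot_dispersion: float = 1.0
    hrf_ratio: float = 6.0
    hbo2_shift_s: float = -1.0
    train_mode: str = "phrases"  # or "block"


@dataclass
class DatagenSection:
    frame_interval_s: float = 1.2
    frame_jitter_s: float = 0.04
    extinction_hbt_per_mm_mM: float = 0.1
    # planted effect: happy > neutral blobs in anterior/posterior temporal GM
    planted_condition: str = "happy"
    planted_rois: tuple[str, ...] = ("aSTS", "pSTS")
    planted_sigma_mm: float = 6.0
    effect_noise_ratio: float = 3.0  # planted effect over map-level noise SD
    subject_gain_sd: float = 0.2  # lognormal sigma of per-subject response gain
    global_amp: float = 0.01
    global_band_hz: tuple[float, float] = (0.01, 0.1)
    coupling_scale_mm: float = 20.0
    cardiac_amp: float = 0.002
    cardiac_freq_hz: float = 1.2
    drift_sd: float = 0.005
    shot_noise_sd: float = 0.002
    artifact_rate_per_min: float = 0.3
    artifact_amp_k: float = 8.0
    dialect: str = "tsv"


@dataclass
class StatsSection:
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    min_cluster_voxels: int = DEFAULT_MIN_VOXELS
    n_mc: int = DEFAULT_N_MC
    connectivity: int = 6
    roi_centers: dict = field(default_factory=lambda: dict(DEFAULT_ROI_CENTERS))
    roi_radius_mm: float = 8.0
    template_affine_matrix: list = field(
        default_factory=lambda: [row[:] for row in DEFAULT_TEMPLATE_AFFINE["matrix"]]
    )
    template_affine_offset: list = field(
        default_factory=lambda: list(DEFAULT_TEMPLATE_AFFINE["offset"])
    )
    repeated_measures: bool = False
    cluster_tests: tuple = ("avg_vs_zero", "anova", "conditions")

    def __post_init__(self):
        # normalize container types so YAML round trips compare equal
        self.roi_centers = {
            k: tuple(float(x) for x in v) for k, v in self.roi_centers.items()
        }
        self.template_affine_matrix = [
            [float(x) for x in row] for row in self.template_affine_matrix
        ]
        self.template_affine_offset = [float(x) for x in self.template_affine_offset]


@dataclass
class PipelineConfig:
    seed: int = 0
    n_subjects: int = 21
    out_dir: str = "results"
    phantom: PhantomSection = field(default_factory=PhantomSection)
    hemodynamics: HemodynamicsSection = field(default_factory=HemodynamicsSection)
    datagen: DatagenSection = field(default_factory=DatagenSection)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    reconstruct: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    stats: StatsSection = field(default_factory=StatsSection)

    def to_dict(self) -> dict:
        return _plain(asdict(self))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _build(cls, d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _plain(obj):
    """Recursively convert tuples to lists so YAML stays round-trippable."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _build(cls, d: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if is_dataclass(f.type) if isinstance(f.type, type) else False:
            kwargs[f.name] = _build(f.type, v)
        elif f.name in _SECTION_TYPES and isinstance(v, dict):
            kwargs[f.name] = _build(_SECTION_TYPES[f.name], v)
        elif isinstance(v, list) and _wants_tuple(cls, f.name):
            kwargs[f.name] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


_SECTION_TYPES = {
    "phantom": PhantomSection,
    "hemodynamics": HemodynamicsSection,
    "datagen": DatagenSection,
    "preprocess": PreprocessConfig,
    "reconstruct": ReconstructionConfig,
    "stats": StatsSection,
}

_TUPLE_FIELDS = {
    "grid_shape",
    "probe_layout",
    "rest_bounds_s",
    "habituation_amplitudes",
    "global_band_hz",
    "artifact_duration_s",
    "thresholds",
    "planted_rois",
    "cluster_tests",
    "epoch_span_s",
    "artifact_k_range",
}


def _wants_tuple(cls, name: str) -> bool:
    return name in _TUPLE_FIELDS
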