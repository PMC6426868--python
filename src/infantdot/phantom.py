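"""Voxelized layered head phantom, probe geometry and optical sensitivity.

The phantom is a slab model: tissue layers (scalp, skull, CSF, gray matter,
white matter) stacked along the depth axis z, with the probe resting on the
z = 0 surface.  Photon transport is modeled with the diffusion approximation
for a homogeneous semi-infinite medium with an extrapolated boundary; the
sensitivity (Jacobian) of each channel's log-amplitude to local absorption
changes is the normalized product of the source and detector Green's
functions (Rytov convention).

Coordinates are 0-based, axis order (x, y, z), z positive into the head,
all positions in mm from the grid origin corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import yaml

from .errors import ConfigError, DimensionError, PlacementError

# Integer tissue codes used in the label volume.
TISSUE_CODES = {
    "outside": 0,
    "scalp": 1,
    "skull": 2,
    "csf": 3,
    "gm": 4,
    "wm": 5,
}
LAYER_ORDER = ("scalp", "skull", "csf", "gm")  # wm fills the remainder

#: Placeholder per-tissue optical properties at ~798 nm.  The absorption
#: coefficient mu_a and reduced scattering mu_s' are in 1/mm.  These are
#: configuration defaults, not measured ground truth, and every entry can be
#: overridden when building a phantom.
DEFAULT_OPTICAL_PROPS = {
    "scalp": {"mu_a": 0.016, "mu_sp": 0.74},
    "skull": {"mu_a": 0.012, "mu_sp": 0.94},
    "csf": {"mu_a": 0.002, "mu_sp": 0.3},
    "gm": {"mu_a": 0.015, "mu_sp": 1.0},
    "wm": {"mu_a": 0.012, "mu_sp": 1.2},
}


@dataclass
class HeadModel:
    """Voxelized layered tissue model used as the reconstruction grid."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    tissue_labels: np.ndarray  # int array, grid_shape
    optical_props: dict[str, dict[str, float]]

    def mask(self, *tissues: str) -> np.ndarray:
        codes = [TISSUE_CODES[t] for t in tissues]
        return np.isin(self.tissue_labels, codes)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.mask("gm", "wm")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, float) * self.voxel_size_mm

    def tissue_volumes_mm3(self) -> dict[str, float]:
        vv = self.voxel_size_mm**3
        return {
            name: float(np.count_nonzero(self.tissue_labels == code) * vv)
            for name, code in TISSUE_CODES.items()
        }

    def save(self, nifti_path, yaml_path=None) -> None:
        """Persist labels as an integer NIfTI volume plus a YAML sidecar."""
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        img = nib.Nifti1Image(self.tissue_labels.astype(np.int16), affine)
        nib.save(img, str(nifti_path))
        if yaml_path is not None:
            with open(yaml_path, "w") as fh:
                yaml.safe_dump(
                    {
                        "voxel_size_mm": self.voxel_size_mm,
                        "optical_props": self.optical_props,
                        "tissue_codes": TISSUE_CODES,
                    },
                    fh,
                )


@dataclass
class ProbeGeometry:
    """Optode positions on the scalp surface and the usable channel list.

    ``channels`` holds one (source index, detector index, SDS mm) triple per
    retained source-detector pair, restricted at construction to separations
    not exceeding the configured maximum.
    """

    source_positions: np.ndarray  # (n_src, 3) mm
    detector_positions: np.ndarray  # (n_det, 3) mm
    channels: list[tuple[int, int, float]]
    wavelength_nm: float = 798.0

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def sds_mm(self) -> np.ndarray:
        return np.array([c[2] for c in self.channels])

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("optode_id\ttype\tx_mm\ty_mm\tz_mm\n")
            for i, p in enumerate(self.source_positions):
                fh.write(f"S{i}\tsource\t{p[0]:.3f}\t{p[1]:.3f}\t{p[2]:.3f}\n")
            for i, p in enumerate(self.detector_positions):
                fh.write(f"D{i}\tdetector\t{p[0]:.3f}\t{p[1]:.3f}\t{p[2]:.3f}\n")


@dataclass
class SensitivityMatrix:
    """Channel x voxel sensitivity of -dlog(amplitude) to d(mu_a), in mm.

    ``relative_sensitivity`` is the per-voxel maximum, over channels, of each
    channel's Jacobian normalized by that channel's maximum within brain
    tissue; it is supported on brain voxels and its maximum there is 1.
    """

    J: np.ndarray  # (n_channels, n_voxels) over the flattened grid
    channel_index: list[tuple[int, int, float]]
    relative_sensitivity: np.ndarray  # grid_shape
    grid_shape: tuple[int, int, int]
    brain_mask: np.ndarray  # grid_shape bool
    gm_mask: np.ndarray
    convention: str = "rytov"
    metadata: dict = field(default_factory=dict)

    def forward(self, delta_mua: np.ndarray) -> np.ndarray:
        """Project voxel absorption changes to channel -dlog(amplitude).

        ``delta_mua`` may be a grid volume or flattened; trailing time axes
        are supported on the flattened form (n_voxels, n_t).
        """
        x = np.asarray(delta_mua, float)
        if x.shape[: len(self.grid_shape)] == tuple(self.grid_shape):
            x = x.reshape(int(np.prod(self.grid_shape)), -1).squeeze()
        return self.J @ x


def build_layered_phantom(
    grid_shape=(40, 40, 40),
    layer_thicknesses_mm=None,
    voxel_size_mm: float = 2.0,
    optical_props=None,
) -> HeadModel:
    """Build a slab phantom with scalp/skull/CSF shells over GM over WM.

    ``layer_thicknesses_mm`` maps layer name to thickness in mm for
    ``scalp``, ``skull``, ``csf`` and ``gm``; white matter fills the rest of
    the grid depth.  Layer boundaries are placed at the voxel index nearest
    each cumulative depth, so a layer thinner than half a voxel may collapse
    to zero voxels (a zero-thickness layer is valid).  Deterministic.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if len(grid_shape) != 3 or any(n < 2 for n in grid_shape):
        raise DimensionError(f"grid_shape must be three axes of >=2 voxels, got {grid_shape}")
    if voxel_size_mm <= 0:
        raise ConfigError("voxel_size_mm must be positive")
    thick = {"scalp": 2.0, "skull": 2.0, "csf": 1.0, "gm": 10.0}
    if layer_thicknesses_mm:
        thick.update(layer_thicknesses_mm)
    if any(t < 0 for t in thick.values()):
        raise ConfigError("layer thicknesses must be non-negative")
    props = {k: dict(v) for k, v in DEFAULT_OPTICAL_PROPS.items()}
    if optical_props:
        for tissue, vals in optical_props.items():
            props.setdefault(tissue, {}).update(vals)
    for tissue, vals in props.items():
        if vals["mu_a"] <= 0 or vals["mu_sp"] <= 0:
            raise ConfigError(f"optical properties for {tissue} must be positive")

    depth_vox = grid_shape[2]
    cum = np.cumsum([thick[name] for name in LAYER_ORDER])
    bounds = np.rint(cum / voxel_size_mm).astype(int)
    if bounds[-1] >= depth_vox:
        raise DimensionError(
            f"layers need {bounds[-1]} voxels of depth but grid has only {depth_vox}"
        )
    labels = np.full(grid_shape, TISSUE_CODES["wm"], dtype=np.int16)
    start = 0
    for name, stop in zip(LAYER_ORDER, bounds):
        labels[:, :, start:stop] = TISSUE_CODES[name]
        start = stop
    return HeadModel(grid_shape, float(voxel_size_mm), labels, props)


def place_probe(
    head: HeadModel,
    layout=(5, 6),
    spacing_mm: float = 10.0,
    max_sds_mm: float = 45.0,
    wavelength_nm: float = 798.0,
) -> ProbeGeometry:
    """Place an interleaved (checkerboard) optode grid on the top surface.

    Rows x columns of optodes at ``spacing_mm`` pitch, centered on the scalp
    surface; optodes alternate source/detector so a 5x6 layout yields 15
    sources and 15 detectors.  Channels are all source-detector pairs with
    Euclidean separation <= ``max_sds_mm``.
    """
    rows, cols = layout
    extent = head.extent_mm
    span = np.array([(rows - 1) * spacing_mm, (cols - 1) * spacing_mm])
    origin = (extent[:2] - span) / 2.0
    if np.any(origin < 0) or np.any(origin + span > extent[:2]):
        raise PlacementError(
            f"{rows}x{cols} layout at {spacing_mm} mm pitch does not fit on the "
            f"{extent[0]:.0f}x{extent[1]:.0f} mm surface"
        )
    sources, detectors = [], []
    for i in range(rows):
        for j in range(cols):
            pos = np.array([origin[0] + i * spacing_mm, origin[1] + j * spacing_mm, 0.0])
            (sources if (i + j) % 2 == 0 else detectors).append(pos)
    src = np.array(sources).reshape(-1, 3)
    det = np.array(detectors).reshape(-1, 3)
    channels = []
    for si, s in enumerate(src):
        for di, d in enumerate(det):
            sds = float(np.linalg.norm(s - d))
            if sds <= max_sds_mm:
                channels.append((si, di, sds))
    return ProbeGeometry(src, det, channels, wavelength_nm=wavelength_nm)


def _effective_reflection(n_rel: float) -> float:
    """Groenhuis/Egan-Hilgeman effective reflection coefficient."""
    return -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel


def _semi_infinite_fluence(points, surface_xy, mu_a, mu_sp, n_rel):
    """Diffusion fluence at ``points`` from a source at ``surface_xy``.

    The pencil source is represented as an isotropic point source at depth
    z0 = 1/(mu_a + mu_s'); the extrapolated zero-fluence boundary at -z_b is
    satisfied by a negative image source.  Distances are clipped below to
    half the nearest-voxel scale to avoid the point-source singularity.
    """
    D = 1.0 / (3.0 * (mu_a + mu_sp))
    mu_eff = np.sqrt(mu_a / D)
    z0 = 1.0 / (mu_a + mu_sp)
    reff = _effective_reflection(n_rel)
    zb = 2.0 * D * (1.0 + reff) / (1.0 - reff)
    real_src = np.array([surface_xy[0], surface_xy[1], z0])
    image_src = np.array([surface_xy[0], surface_xy[1], -(z0 + 2.0 * zb)])
    r1 = np.linalg.norm(points - real_src, axis=-1)
    r2 = np.linalg.norm(points - image_src, axis=-1)
    eps = 0.5  # mm; regularizes voxels coincident with the source point
    r1 = np.maximum(r1, eps)
    r2 = np.maximum(r2, eps)
    phi = (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2) / (4.0 * np.pi * D)
    return np.maximum(phi, 0.0)


def _background_props(head: HeadModel, background) -> tuple[float, float]:
    if isinstance(background, tuple):
        mu_a, mu_sp = background
    elif background == "mean":
        labels = head.tissue_labels
        inside = labels > 0
        mu_a_vol = np.zeros(head.grid_shape)
        mu_sp_vol = np.zeros(head.grid_shape)
        for name, code in TISSUE_CODES.items():
            if name == "outside":
                continue
            sel = labels == code
            if name in head.optical_props:
                mu_a_vol[sel] = head.optical_props[name]["mu_a"]
                mu_sp_vol[sel] = head.optical_props[name]["mu_sp"]
        mu_a = float(mu_a_vol[inside].mean())
        mu_sp = float(mu_sp_vol[inside].mean())
    else:
        mu_a = head.optical_props[background]["mu_a"]
        mu_sp = head.optical_props[background]["mu_sp"]
    if mu_sp <= 0:
        raise ConfigError("diffusion approximation requires mu_s' > 0")
    if mu_a <= 0:
        raise ConfigError("mu_a must be positive")
    return mu_a, mu_sp


def compute_jacobian(
    head: HeadModel,
    probe: ProbeGeometry,
    background="mean",
    n_rel: float = 1.4,
) -> SensitivityMatrix:
    """Diffusion-approximation sensitivity matrix for every channel.

    Each row is J_v = phi_s(v) * phi_d(v) * V_vox / phi(s, d), the first-order
    Rytov sensitivity of -dlog(amplitude) to a local absorption increase in
    voxel v (units mm).  Entries are non-negative and zeroed outside tissue.
    """
    mu_a, mu_sp = _background_props(head, background)
    nx, ny, nz = head.grid_shape
    vs = head.voxel_size_mm
    # voxel centers in mm
    ax = (np.arange(nx) + 0.5) * vs
    ay = (np.arange(ny) + 0.5) * vs
    az = (np.arange(nz) + 0.5) * vs
    centers = np.stack(np.meshgrid(ax, ay, az, indexing="ij"), axis=-1).reshape(-1, 3)
    inside = (head.tissue_labels > 0).ravel()
    vox_vol = vs**3

    phi_src = {}
    phi_det = {}
    for si in {c[0] for c in probe.channels}:
        phi_src[si] = _semi_infinite_fluence(
            centers, probe.source_positions[si][:2], mu_a, mu_sp, n_rel
        )
    for di in {c[1] for c in probe.channels}:
        phi_det[di] = _semi_infinite_fluence(
            centers, probe.detector_positions[di][:2], mu_a, mu_sp, n_rel
        )

    z0 = 1.0 / (mu_a + mu_sp)
    J = np.empty((len(probe.channels), centers.shape[0]))
    for row, (si, di, _sds) in enumerate(probe.channels):
        det_pt = probe.detector_positions[di].copy()
        det_pt[2] = z0  # evaluate the unperturbed fluence at the buried detector point
        phi0 = _semi_infinite_fluence(
            det_pt[None, :], probe.source_positions[si][:2], mu_a, mu_sp, n_rel
        )[0]
        J[row] = phi_src[si] * phi_det[di] * vox_vol / phi0
        J[row, ~inside] = 0.0

    brain = head.brain_mask
    brain_flat = brain.ravel()
    row_max = J[:, brain_flat].max(axis=1)
    rel = (J[:, brain_flat] / row_max[:, None]).max(axis=0)
    relative_sensitivity = np.zeros(head.grid_shape)
    relative_sensitivity.ravel()[brain_flat] = np.minimum(rel, 1.0)

    return SensitivityMatrix(
        J=J,
        channel_index=list(probe.channels),
        relative_sensitivity=relative_sensitivity,
        grid_shape=head.grid_shape,
        brain_mask=brain,
        gm_mask=head.mask("gm"),
        convention="rytov",
        metadata={
            "background_mu_a": mu_a,
            "background_mu_sp": mu_sp,
            "n_rel": n_rel,
            "voxel_size_mm": vs,
            "wavelength_nm": probe.wavelength_nm,
        },
    )


def compute_fov(
    S,
    threshold: float = 0.001,
    gm_only: bool = False,
    min_subjects: int = 1,
) -> np.ndarray:
    """Field-of-view mask: brain voxels whose relative sensitivity exceeds
    ``threshold``.

    ``S`` may be a single :class:`SensitivityMatrix` or a sequence (one per
    subject), in which case a voxel enters the FOV when it passes the
    threshold in at least ``min_subjects`` of them.
    """
    if not 0 < threshold <= 1:
        raise ConfigError("threshold must be in (0, 1]")
    mats = [S] if isinstance(S, SensitivityMatrix) else list(S)
    counts = np.zeros(mats[0].grid_shape, dtype=int)
    for m in mats:
        counts += m.relative_sensitivity > threshold
    base = mats[0].gm_mask if gm_only else mats[0].brain_mask
    return (counts >= min_subjects) & base
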