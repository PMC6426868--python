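"""Small Monte Carlo photon random-walk oracle for the sensitivity tests.

Independent of the package's diffusion-approximation code: photons take
exponential steps at the reduced scattering rate with isotropic scattering,
weight decays with absorption along the path, and collision density is
tallied on a coarse voxel grid.  The channel sensitivity profile is the
product of the source and detector (reciprocal) fluence tallies.
"""

from __future__ import annotations

import numpy as np


def mc_fluence(
    origin_xy: tuple[float, float],
    mu_a: float,
    mu_sp: float,
    grid_shape: tuple[int, int, int],
    voxel_mm: float,
    n_photons: int = 60_000,
    max_steps: int = 400,
    seed: int = 0,
) -> np.ndarray:
    """Collision-density tally (~fluence) for a pencil beam at ``origin_xy``
    on the z=0 surface of a homogeneous semi-infinite medium."""
    rng = np.random.default_rng(seed)
    tally = np.zeros(grid_shape)
    pos = np.zeros((n_photons, 3))
    pos[:, 0] = origin_xy[0]
    pos[:, 1] = origin_xy[1]
    direc = np.zeros((n_photons, 3))
    direc[:, 2] = 1.0  # launch into the medium
    weight = np.ones(n_photons)
    alive = np.ones(n_photons, bool)
    extent = np.asarray(grid_shape) * voxel_mm
    for _ in range(max_steps):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        step = rng.exponential(1.0 / mu_sp, idx.size)
        pos[idx] += direc[idx] * step[:, None]
        weight[idx] *= np.exp(-mu_a * step)
        escaped = pos[idx, 2] < 0
        alive[idx[escaped]] = False
        idx = idx[~escaped]
        # tally collisions inside the grid
        vox = np.floor(pos[idx] / voxel_mm).astype(int)
        inside = np.all((vox >= 0) & (vox < np.asarray(grid_shape)), axis=1)
        np.add.at(
            tally,
            (vox[inside, 0], vox[inside, 1], vox[inside, 2]),
            weight[idx][inside],
        )
        # isotropic scattering (reduced-scattering random walk)
        u = rng.uniform(-1, 1, idx.size)
        phi = rng.uniform(0, 2 * np.pi, idx.size)
        s = np.sqrt(1 - u**2)
        direc[idx] = np.column_stack([s * np.cos(phi), s * np.sin(phi), u])
        alive[idx[weight[idx] < 1e-4]] = False
        # photons far outside the tally region cannot return with weight
        far = np.any(np.abs(pos[idx] - extent / 2) > 2.5 * extent, axis=1)
        alive[idx[far]] = False
    return tally


def mc_channel_sensitivity(
    source_xy,
    detector_xy,
    mu_a: float,
    mu_sp: float,
    grid_shape=(15, 15, 8),
    voxel_mm: float = 8.0,
    n_photons: int = 60_000,
    seed: int = 0,
) -> np.ndarray:
    """Product of source and detector fluence tallies (banana profile)."""
    phi_s = mc_fluence(source_xy, mu_a, mu_sp, grid_shape, voxel_mm, n_photons, seed=seed)
    phi_d = mc_fluence(
        detector_xy, mu_a, mu_sp, grid_shape, voxel_mm, n_photons, seed=seed + 1
    )
    return phi_s * phi_d
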