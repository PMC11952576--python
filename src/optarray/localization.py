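"""Point-activation localization study: HD vs sparse reconstruction error.

For a set of cortical seed points in the lateral field of view, a unit HbO
point activation is projected through each array's forward model and
reconstructed with the spatially regularized inverse; localization error is
the distance from the reconstructed center of mass to the seed, resolution
the intensity-weighted spread. Overlapping multi-distance channels give the
HD array a denser sampling of each cortical point, which is what this study
quantifies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .headmodel import HeadMesh
from .optics import extinction_matrix
from .recon import ReconConfig, build_regularized_system, localization_error, \
    reconstruct, resolution_metric, unmix_vertices


def lateral_seed_vertices(mesh: HeadMesh, n_seeds: int, seed=0) -> np.ndarray:
    """Sample brain vertices from the lateral (dlPFC) field of view."""
    rng = np.random.default_rng(seed)
    candidates = np.concatenate([mesh.region_vertices("dlPFC_left"),
                                 mesh.region_vertices("dlPFC_right")])
    if candidates.size < n_seeds:
        raise ValueError("not enough lateral vertices for the requested seeds")
    return rng.choice(candidates, size=n_seeds, replace=False)


def localization_study(sens_by_array: dict, mesh: HeadMesh,
                       recon_config: ReconConfig | None = None,
                       n_seeds: int = 20, seed: int = 0,
                       amplitude_uM: float = 1.0,
                       noise_od_sd: float = 0.0,
                       support_threshold: float = 0.5) -> pd.DataFrame:
    """Reconstruct point activations through every array; tabulate metrics.

    Returns one row per (array, seed vertex) with localization error and
    resolution in mm. ``noise_od_sd`` adds white channel noise to the
    projected optical density before inversion.

    Metrics are evaluated on the point-spread function's half-maximum
    support (``support_threshold`` x image maximum), the convention for
    summarizing a PSF core; sub-threshold vertices are masked the same way
    the reference sensitivity and activation maps mask sub-threshold
    values. The integrated sub-1% reconstruction ripple over the full
    surface carries no localization information but, summed over hundreds
    of vertices, would otherwise dominate the intensity weighting.
    """
    cfg = recon_config or ReconConfig()
    rng = np.random.default_rng(seed)
    seeds = lateral_seed_vertices(mesh, n_seeds, rng.integers(2 ** 31))
    wavelengths = tuple(s.wavelength_nm
                        for s in next(iter(sens_by_array.values())))
    E = extinction_matrix(wavelengths)

    rows = []
    for array, sens_pair in sorted(sens_by_array.items()):
        probe = sens_pair[0].probe
        ch_rows = probe.long_channels
        systems = tuple(build_regularized_system(s, cfg, channel_rows=ch_rows)
                        for s in sens_pair)
        for v in seeds:
            images = []
            for w, sens in enumerate(sens_pair):
                mua = E[w, 0] * amplitude_uM  # point HbO change at one vertex
                y = sens.values[ch_rows, v] * mua
                if noise_od_sd > 0:
                    y = y + noise_od_sd * rng.standard_normal(y.shape)
                images.append(reconstruct(y, systems[w]))
            hb = unmix_vertices(images, wavelengths)
            hbo_brain = hb[:mesh.n_brain, 0]
            core = np.abs(hbo_brain)
            hbo_brain = np.where(core >= support_threshold * core.max(),
                                 hbo_brain, 0.0)
            true_center = mesh.brain_vertices[v]
            rows.append({
                "array": array,
                "seed_vertex": int(v),
                "localization_error_mm": localization_error(
                    hbo_brain, mesh.brain_vertices, true_center),
                "resolution_mm": resolution_metric(hbo_brain,
                                                   mesh.brain_vertices),
            })
    return pd.DataFrame(rows)
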