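"""Spatially regularized Tikhonov image reconstruction and image metrics.

Channel optical density y is mapped to vertex absorption images x through
the underdetermined forward model y = A x. The inversion uses spatially
variant regularization to counteract the depth-dependent sensitivity
falloff — without it, the minimum-norm solution pins all contrast to the
scalp where sensitivity is largest:

    L_ii    = sqrt((A^T A)_ii + lambda_spatial),
    lambda_spatial = alpha_spatial * max_i (A^T A)_ii,
    A_hat   = A L^-1,
    x       = L^-1 A_hat^T (A_hat A_hat^T + lambda I)^-1 y,
    lambda  = alpha_meas * max(diag(A_hat A_hat^T)).

alpha_spatial controls reconstruction depth, alpha_meas smooths the image;
both default to 0.001. Reconstruction can include both brain and scalp
surfaces (so superficial physiology has somewhere to go) or the brain only.
Image localization is summarized by the intensity-weighted center of mass
and its mean spread (resolution).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .forward import SensitivityMatrix
from .optics import extinction_matrix, hb_to_od


@dataclass
class ReconConfig:
    alpha_spatial: float = 1e-3
    alpha_meas: float = 1e-3
    mode: str = "brain_and_scalp"   # or "brain_only"

    def __post_init__(self):
        if self.alpha_spatial <= 0 or self.alpha_meas <= 0:
            raise ValueError("regularization parameters must be positive")
        if self.mode not in ("brain_and_scalp", "brain_only"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class RegularizedSystem:
    """Pre-factored spatially regularized inverse operator."""

    L_diag: np.ndarray        # (n_vertices,) strictly positive
    A_hat: np.ndarray         # (n_channels, n_vertices)
    lambda_meas: float
    vertex_split: int         # brain/scalp column boundary (== n_cols if brain only)
    mode: str
    _chol: tuple = None

    @property
    def n_vertices(self) -> int:
        return self.A_hat.shape[1]


@dataclass
class VertexImage:
    """Vertex values (one column per chromophore or wavelength) on the mesh."""

    values: np.ndarray        # (n_vertices,) or (n_vertices, k)
    positions: np.ndarray     # (n_vertices, 3) mm
    vertex_split: int

    @property
    def brain(self) -> np.ndarray:
        return self.values[:self.vertex_split]

    @property
    def scalp(self) -> np.ndarray:
        return self.values[self.vertex_split:]


def build_regularized_system(A, config: ReconConfig | None = None,
                             channel_rows=None) -> RegularizedSystem:
    """Column-rescale A and pre-factor the regularized normal system.

    ``A`` may be a SensitivityMatrix or a plain array (then vertex_split
    defaults to all columns). ``channel_rows`` restricts to unpruned
    channels.
    """
    cfg = config or ReconConfig()
    if isinstance(A, SensitivityMatrix):
        values = A.values
        split = A.vertex_split
    else:
        values = np.asarray(A, dtype=float)
        split = values.shape[1]
    if channel_rows is not None:
        values = values[np.asarray(channel_rows, dtype=int)]
    if cfg.mode == "brain_only":
        values = values[:, :split]
        split = values.shape[1]

    col_energy = np.einsum("ij,ij->j", values, values)  # diag(A^T A)
    lam_spatial = cfg.alpha_spatial * col_energy.max()
    L = np.sqrt(col_energy + lam_spatial)
    if not np.all(L > 0):
        raise FloatingPointError("zero-sensitivity column not floored")
    A_hat = values / L[None, :]
    AAt = A_hat @ A_hat.T
    lam = cfg.alpha_meas * np.max(np.diag(AAt))
    chol = cho_factor(AAt + lam * np.eye(AAt.shape[0]), lower=True)
    return RegularizedSystem(L_diag=L, A_hat=A_hat, lambda_meas=float(lam),
                             vertex_split=split, mode=cfg.mode, _chol=chol)


def reconstruct(y: np.ndarray, system: RegularizedSystem) -> np.ndarray:
    """x = L^-1 A_hat^T (A_hat A_hat^T + lambda I)^-1 y.

    ``y`` may be (n_channels,) or (n_channels, m) for batched inversion.
    Returns vertex images with matching trailing shape.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != system.A_hat.shape[0]:
        raise ValueError("measurement length does not match system channels")
    z = cho_solve(system._chol, y)
    x = (system.A_hat.T @ z)
    if x.ndim == 1:
        return x / system.L_diag
    return x / system.L_diag[:, None]


def unmix_vertices(od_images, wavelengths=(760.0, 850.0)) -> np.ndarray:
    """Per-vertex 2x2 extinction solve: wavelength images -> (HbO, HbR).

    ``od_images`` is a sequence of per-wavelength vertex absorption images
    reconstructed on the same mesh. Returns (n_vertices, 2) in uM.
    """
    E = extinction_matrix(wavelengths)
    det = E[0, 0] * E[1, 1] - E[0, 1] * E[1, 0]
    if abs(det) < 1e-30:
        raise np.linalg.LinAlgError("singular extinction matrix")
    Einv = np.array([[E[1, 1], -E[0, 1]], [-E[1, 0], E[0, 0]]]) / det
    stacked = np.stack([np.asarray(im) for im in od_images], axis=-1)
    return stacked @ Einv.T


def reconstruct_hb(y_per_wavelength, systems, wavelengths=(760.0, 850.0)):
    """Reconstruct each wavelength with its own system, then unmix."""
    images = [reconstruct(y, s) for y, s in zip(y_per_wavelength, systems)]
    return unmix_vertices(images, wavelengths)


def hrf_to_od(hrf_conc: np.ndarray, probe, channel_rows=None,
              ppf: float = 1.0, wavelengths=(760.0, 850.0)) -> np.ndarray:
    """Convert estimated HRF concentrations back to channel optical density.

    Exact inverse of the Beer-Lambert concentration conversion; input is
    (..., n_channels, 2) with (HbO, HbR) in uM over the full channel list,
    optionally restricted to ``channel_rows``.
    """
    L = probe.nominal_separations() * ppf
    if channel_rows is not None:
        rows = np.asarray(channel_rows, dtype=int)
        hrf_conc = hrf_conc[..., rows, :]
        L = L[rows]
    return hb_to_od(hrf_conc, L, wavelengths)


def image_timecourse(hrf_conc_series: np.ndarray, time_s: np.ndarray,
                     systems, probe, channel_rows=None, step_s: float = 1.0,
                     roi_vertices=None, ppf: float = 1.0,
                     wavelengths=(760.0, 850.0)):
    """Reconstruct one image per time step of an HRF and track ROI means.

    hrf_conc_series: (n_times, n_channels, 2) concentration HRF. Returns
    (times, image stack (n_steps, n_vertices, 2), roi mean (n_steps, 2) or
    None).
    """
    if roi_vertices is not None and len(roi_vertices) == 0:
        raise ValueError("empty ROI vertex set")
    t0, t1 = time_s[0], time_s[-1]
    steps = np.arange(t0, t1 + 1e-9, step_s)
    idx = np.array([np.argmin(np.abs(time_s - s)) for s in steps])
    od = hrf_to_od(hrf_conc_series[idx], probe, channel_rows, ppf, wavelengths)
    # od: (n_steps, n_rows, 2); batch per wavelength
    images = [reconstruct(od[:, :, w].T, systems[w]).T
              for w in range(len(wavelengths))]
    stack = unmix_vertices(images, wavelengths)   # (n_steps, n_vertices, 2)
    roi_mean = None
    if roi_vertices is not None:
        roi_mean = stack[:, np.asarray(roi_vertices, int), :].mean(axis=1)
    return steps, stack, roi_mean


def _intensity(values: np.ndarray, intensity: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if intensity == "abs":
        return np.abs(v)
    if intensity == "positive":
        return np.maximum(v, 0.0)
    raise ValueError(f"unknown intensity rule {intensity!r}")


def center_of_mass(values: np.ndarray, positions: np.ndarray,
                   intensity: str = "abs") -> np.ndarray:
    """Intensity-weighted mean position r_cm = sum(I_i r_i) / sum(I_i)."""
    I = _intensity(values, intensity)
    total = I.sum()
    if total == 0:
        raise ValueError("all-zero image has no center of mass")
    return (I[:, None] * np.asarray(positions)).sum(axis=0) / total


def resolution_metric(values: np.ndarray, positions: np.ndarray,
                      intensity: str = "abs") -> float:
    """Intensity-weighted mean distance to the center of mass (R_cm)."""
    I = _intensity(values, intensity)
    total = I.sum()
    if total == 0:
        raise ValueError("all-zero image has no resolution metric")
    r_cm = center_of_mass(values, positions, intensity)
    d = np.linalg.norm(np.asarray(positions) - r_cm, axis=1)
    return float((I * d).sum() / total)


def localization_error(values: np.ndarray, positions: np.ndarray,
                       true_center: np.ndarray,
                       intensity: str = "abs") -> float:
    """Euclidean distance from the image center of mass to the true center."""
    r_cm = center_of_mass(values, positions, intensity)
    return float(np.linalg.norm(r_cm - np.asarray(true_center)))
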