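"""Channel sensitivity matrices from an analytic photon-diffusion model.

The forward model A maps vertex absorption changes to channel optical
density changes (y = A x). Rows are built from the Rytov adjoint product of
semi-infinite diffusion Green's functions,

    A[c, i]  ~  G(r_s, r_i) G(r_i, r_d) / G(r_s, r_d) * V_i,

which preserves the banana-shaped, depth-decaying, overlapping sensitivity
structure that the sparse-vs-HD comparison exercises. The curved scalp
boundary is handled by radial image-point reflection; sources and detectors
are placed one transport mean free path (1/mus') below the surface.

Rows of long channels are, by default, normalized so that the summed
brain-column sensitivity x volume equals the channel's Beer-Lambert
pathlength (separation x partial pathlength factor). This calibration makes
the generative forward projection and the channel-space Beer-Lambert
inversion quantitatively consistent: a spatially uniform cortical
concentration change is recovered exactly. Short-separation rows are
normalized over all tissue instead (they sense essentially no brain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .headmodel import HeadMesh
from .optics import OpticalProperties
from .probes import ProbeGeometry


@dataclass
class SensitivityMatrix:
    """Per-wavelength channel x vertex Jacobian.

    values columns are brain vertices then scalp vertices; ``vertex_split``
    is the index of the first scalp column. Units after pathlength
    normalization: mm of effective pathlength per vertex (OD change per unit
    absorption change).
    """

    values: np.ndarray        # (n_channels, n_brain + n_scalp)
    wavelength_nm: float
    vertex_split: int
    probe: ProbeGeometry
    normalized: bool = True

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def brain(self) -> np.ndarray:
        return self.values[:, :self.vertex_split]

    @property
    def scalp(self) -> np.ndarray:
        return self.values[:, self.vertex_split:]

    def rows(self, channel_idx) -> np.ndarray:
        return self.values[np.asarray(channel_idx, dtype=int)]

    def summed_map(self, channel_idx=None) -> np.ndarray:
        """Total probe sensitivity per vertex (sum over channels)."""
        v = self.values if channel_idx is None else self.rows(channel_idx)
        return v.sum(axis=0)


def _greens(r1: np.ndarray, r2: np.ndarray, props: OpticalProperties,
            boundary_radius: float) -> np.ndarray:
    """Semi-infinite diffusion Green's function between interior points.

    r1: (..., 3), r2: (..., 3). The planar image-source construction is
    adapted to the spherical boundary through the identity
    d_img^2 = d^2 + 4 h1 h2, with h the radial depth below the extrapolated
    boundary at ``boundary_radius + 2D`` — exact for a plane and symmetric
    in its arguments, so optical reciprocity (source-detector exchange)
    holds by construction.
    """
    D = props.diffusion_coeff
    mu = props.mu_eff
    rb = boundary_radius + 2.0 * D
    d = np.linalg.norm(r1 - r2, axis=-1)
    h1 = rb - np.linalg.norm(r1, axis=-1)
    h2 = rb - np.linalg.norm(r2, axis=-1)
    di = np.sqrt(d * d + 4.0 * h1 * h2)
    d = np.maximum(d, 1e-6)
    di = np.maximum(di, 1e-6)
    g = (np.exp(-mu * d) / d - np.exp(-mu * di) / di) / (4.0 * np.pi * D)
    return np.maximum(g, 0.0)


def compute_sensitivity(probe: ProbeGeometry, mesh: HeadMesh,
                        optical_properties: OpticalProperties | None = None,
                        wavelength_nm: float = 760.0,
                        slab_thickness_mm: float = 3.0,
                        normalize: str = "pathlength",
                        ppf: float = 1.0,
                        scalp_path_ratio: float = 1.5) -> SensitivityMatrix:
    """Compute the channel x vertex sensitivity matrix for one wavelength.

    Parameters
    ----------
    slab_thickness_mm : effective tissue thickness multiplying vertex areas
        to form the volume element V_i.
    normalize : "pathlength" applies the Beer-Lambert row calibration
        described in the module docstring; "none" returns the raw adjoint
        product (linear in the vertex volume elements).
    ppf : partial pathlength factor used in the row calibration; must match
        the value used by the concentration conversion for round-trip
        consistency.
    scalp_path_ratio : scalp partial pathlength of a long channel as a
        multiple of its brain partial pathlength (> 1: the scalp, being
        shallower, is the more sensitive compartment). The two compartments
        are calibrated separately so that the relative superficial
        contamination of a channel does not blow up with the (strongly
        separation-dependent) raw brain fraction.
    """
    props = optical_properties or OpticalProperties()
    if normalize not in ("pathlength", "none"):
        raise ValueError(f"unknown normalization {normalize!r}")

    R = probe.scalp_radius_mm
    verts = mesh.all_vertices()
    vols = mesh.all_areas() * slab_thickness_mm
    n_brain = mesh.n_brain

    # optodes one transport mean free path below the surface
    depth = 1.0 / props.musp
    src, det = probe.channel_positions()
    src = src * ((R - depth) / R)
    det = det * ((R - depth) / R)

    g_sv = _greens(src[:, None, :], verts[None, :, :], props, R)
    g_vd = _greens(verts[None, :, :], det[:, None, :], props, R)
    g_sd = _greens(src, det, props, R)
    if np.any(g_sd <= 0):
        raise FloatingPointError("vanishing source-detector Green's function")

    A = (g_sv * g_vd) / g_sd[:, None] * vols[None, :]

    if normalize == "pathlength":
        noms = probe.nominal_separations()
        brain_sum = A[:, :n_brain].sum(axis=1)
        scalp_sum = A[:, n_brain:].sum(axis=1)
        total_sum = brain_sum + scalp_sum
        for c, (_, _, cls) in enumerate(probe.channels):
            if cls == "short":
                # short channels barely sense brain: calibrate total path
                if total_sum[c] <= 0:
                    raise FloatingPointError(
                        f"channel {c} has no sensitivity to normalize against")
                A[c] *= noms[c] * ppf / total_sum[c]
            else:
                if brain_sum[c] <= 0 or scalp_sum[c] <= 0:
                    raise FloatingPointError(
                        f"channel {c} has no sensitivity to normalize against")
                A[c, :n_brain] *= noms[c] * ppf / brain_sum[c]
                A[c, n_brain:] *= noms[c] * ppf * scalp_path_ratio \
                    / scalp_sum[c]

    if np.any(A.sum(axis=1) <= 0):
        raise FloatingPointError("a channel row has no positive sensitivity")

    return SensitivityMatrix(values=A, wavelength_nm=float(wavelength_nm),
                             vertex_split=n_brain, probe=probe,
                             normalized=(normalize == "pathlength"))
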