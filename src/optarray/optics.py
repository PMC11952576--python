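"""Optical constants and modified Beer-Lambert conversions.

Channel-space conversions between two-wavelength optical density (natural
log) and oxy/deoxy-hemoglobin concentration changes. The extinction table is
a fixed, package-compiled compilation of the standard adult hemoglobin
spectra at the two laser-diode wavelengths used by the instrument class this
pipeline emulates (760 and 850 nm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Molar (decadic) extinction coefficients, cm^-1 / M, from the standard
#: compiled oxy/deoxy-hemoglobin absorption spectra.
MOLAR_EXTINCTION_CM_M = {
    760.0: {"HbO": 586.0, "HbR": 1548.52},
    850.0: {"HbO": 1058.0, "HbR": 691.32},
}

#: Conversion to natural-log absorption per mm per uM:
#: mu_a [mm^-1] = ln(10) * eps[cm^-1/M] * 1e-6 [M/uM] * 0.1 [cm/mm] * C[uM]
_LN10_SCALE = np.log(10.0) * 1e-7

DEFAULT_WAVELENGTHS_NM = (760.0, 850.0)


def extinction_matrix(wavelengths=DEFAULT_WAVELENGTHS_NM) -> np.ndarray:
    """Return E (n_wavelengths x 2) with columns (HbO, HbR).

    Units: natural-log optical density per mm pathlength per uM, i.e.
    mu_a(lambda) = E @ (C_HbO, C_HbR) for concentrations in uM.
    """
    rows = []
    for wl in wavelengths:
        try:
            eps = MOLAR_EXTINCTION_CM_M[float(wl)]
        except KeyError:
            raise KeyError(f"no extinction entry for wavelength {wl} nm")
        rows.append([eps["HbO"] * _LN10_SCALE, eps["HbR"] * _LN10_SCALE])
    return np.asarray(rows)


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk tissue optical properties for the diffusion forward model.

    mua: absorption coefficient, mm^-1.
    musp: reduced scattering coefficient, mm^-1.
    """

    mua: float = 0.01
    musp: float = 1.0

    def __post_init__(self):
        if self.mua <= 0 or self.musp <= 0:
            raise ValueError("optical properties must be positive")

    @property
    def diffusion_coeff(self) -> float:
        return 1.0 / (3.0 * (self.mua + self.musp))

    @property
    def mu_eff(self) -> float:
        return float(np.sqrt(3.0 * self.mua * (self.mua + self.musp)))


def od_to_hb(od_two_wl: np.ndarray, pathlengths_mm: np.ndarray,
             wavelengths=DEFAULT_WAVELENGTHS_NM) -> np.ndarray:
    """Solve the 2x2 Beer-Lambert system per channel.

    Parameters
    ----------
    od_two_wl : (..., n_channels, 2) optical density (natural log).
    pathlengths_mm : (n_channels,) effective pathlength per channel
        (separation x partial pathlength factor).

    Returns
    -------
    (..., n_channels, 2) array of (dHbO, dHbR) in uM.
    """
    E = extinction_matrix(wavelengths)  # (2, 2)
    det = E[0, 0] * E[1, 1] - E[0, 1] * E[1, 0]
    if abs(det) < 1e-30:
        raise np.linalg.LinAlgError("singular extinction matrix")
    Einv = np.array([[E[1, 1], -E[0, 1]], [-E[1, 0], E[0, 0]]]) / det
    od = np.asarray(od_two_wl, dtype=float)
    L = np.asarray(pathlengths_mm, dtype=float)
    if np.any(L <= 0):
        raise ValueError("pathlengths must be positive")
    mua = od / L[..., None]  # per-channel absorption change per mm
    return mua @ Einv.T


def hb_to_od(hb: np.ndarray, pathlengths_mm: np.ndarray,
             wavelengths=DEFAULT_WAVELENGTHS_NM) -> np.ndarray:
    """Inverse of :func:`od_to_hb`: (dHbO, dHbR) in uM -> two-wavelength OD."""
    E = extinction_matrix(wavelengths)
    hb = np.asarray(hb, dtype=float)
    L = np.asarray(pathlengths_mm, dtype=float)
    return (hb @ E.T) * L[..., None]
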