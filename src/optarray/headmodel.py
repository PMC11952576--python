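"""Two-surface head model: concentric brain and scalp hemispheres.

A geometric stand-in for an atlas head: localization and resolution metrics
only need vertex coordinates, areas and a brain/scalp split. Region labels
(dlPFC left/right, mPFC, other) are painted by angular sector over the
frontal band so that synthetic activation patches and ROI construction have
anatomy-like targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGION_LABELS = ("dlPFC_left", "dlPFC_right", "mPFC", "other")


@dataclass
class HeadMeshConfig:
    brain_radius_mm: float = 80.0
    scalp_gap_mm: float = 13.0      # optode standoff: scalp surface above brain
    scalp_inset_mm: float = 3.0     # scalp vertices sit mid-scalp, below the surface
    n_theta: int = 14               # latitude rings (pole excluded)
    n_phi: int = 56                 # vertices per ring
    theta_max_deg: float = 100.0    # polar extent; >90 covers cortex below the rim
    frontal_theta_deg: float = 40.0  # frontal band: polar angle >= this
    mpfc_half_width_deg: float = 18.0
    dlpfc_max_deg: float = 60.0


@dataclass
class HeadMesh:
    brain_vertices: np.ndarray   # (nb, 3) mm
    scalp_vertices: np.ndarray   # (ns, 3) mm
    brain_faces: np.ndarray      # (nf, 3) int
    scalp_faces: np.ndarray
    brain_areas: np.ndarray      # (nb,) mm^2, per-vertex Voronoi-style share
    scalp_areas: np.ndarray
    region_labels: np.ndarray    # (nb,) str, one of REGION_LABELS
    config: HeadMeshConfig

    @property
    def n_brain(self) -> int:
        return self.brain_vertices.shape[0]

    @property
    def n_scalp(self) -> int:
        return self.scalp_vertices.shape[0]

    @property
    def scalp_surface_radius(self) -> float:
        """Outer scalp surface radius where optodes sit."""
        return self.config.brain_radius_mm + self.config.scalp_gap_mm

    def all_vertices(self) -> np.ndarray:
        """Brain then scalp vertices, the column order of sensitivity matrices."""
        return np.vstack([self.brain_vertices, self.scalp_vertices])

    def all_areas(self) -> np.ndarray:
        return np.concatenate([self.brain_areas, self.scalp_areas])

    def region_vertices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.region_labels == label)

    def region_centroid(self, label: str) -> np.ndarray:
        idx = self.region_vertices(label)
        if idx.size == 0:
            raise ValueError(f"region {label!r} has no vertices")
        return self.brain_vertices[idx].mean(axis=0)


def _hemisphere(radius: float, n_theta: int, n_phi: int,
                theta_max_deg: float = 90.0):
    """UV-style triangulated hemispherical cap, mirror-symmetric about y-z."""
    verts = [np.array([0.0, 0.0, radius])]
    dphi = 2.0 * np.pi / n_phi
    theta_max = np.radians(theta_max_deg)
    for k in range(1, n_theta + 1):
        theta = theta_max * k / n_theta
        for j in range(n_phi):
            phi = np.pi / 2.0 + (j + 0.5) * dphi  # symmetric about +y
            verts.append(radius * np.array([
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                np.cos(theta)]))
    verts = np.asarray(verts)

    faces = []
    ring = lambda k, j: 1 + (k - 1) * n_phi + (j % n_phi)
    for j in range(n_phi):  # pole fan
        faces.append((0, ring(1, j), ring(1, j + 1)))
    for k in range(1, n_theta):
        for j in range(n_phi):
            a, b = ring(k, j), ring(k, j + 1)
            c, d = ring(k + 1, j), ring(k + 1, j + 1)
            faces.append((a, c, d))
            faces.append((a, d, b))
    return verts, np.asarray(faces, dtype=int)


def _vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    import trimesh

    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    areas = np.zeros(len(vertices))
    per_face = mesh.area_faces / 3.0
    for col in range(3):
        np.add.at(areas, faces[:, col], per_face)
    return areas


def _paint_regions(vertices: np.ndarray, cfg: HeadMeshConfig) -> np.ndarray:
    r = np.linalg.norm(vertices, axis=1)
    theta = np.degrees(np.arccos(np.clip(vertices[:, 2] / r, -1, 1)))
    beta = np.degrees(np.arctan2(vertices[:, 0], vertices[:, 1]))  # 0 = front
    labels = np.full(len(vertices), "other", dtype=object)
    frontal = theta >= cfg.frontal_theta_deg
    labels[frontal & (np.abs(beta) <= cfg.mpfc_half_width_deg)] = "mPFC"
    left = frontal & (beta < -cfg.mpfc_half_width_deg) & (beta >= -cfg.dlpfc_max_deg)
    right = frontal & (beta > cfg.mpfc_half_width_deg) & (beta <= cfg.dlpfc_max_deg)
    labels[left] = "dlPFC_left"
    labels[right] = "dlPFC_right"
    return labels.astype(str)


def build_head_mesh(config: HeadMeshConfig | None = None) -> HeadMesh:
    """Build the concentric brain/scalp hemisphere pair with region labels."""
    cfg = config or HeadMeshConfig()
    brain_v, brain_f = _hemisphere(cfg.brain_radius_mm, cfg.n_theta, cfg.n_phi,
                                   cfg.theta_max_deg)
    if brain_v.shape[0] < 200:
        raise ValueError(
            f"vertex density too low: {brain_v.shape[0]} brain vertices (< 200)")
    scalp_r = cfg.brain_radius_mm + cfg.scalp_gap_mm - cfg.scalp_inset_mm
    if scalp_r <= cfg.brain_radius_mm:
        raise ValueError("scalp vertices must lie outside the brain surface")
    scalp_v, scalp_f = _hemisphere(scalp_r, cfg.n_theta, cfg.n_phi,
                                   cfg.theta_max_deg)
    mesh = HeadMesh(
        brain_vertices=brain_v,
        scalp_vertices=scalp_v,
        brain_faces=brain_f,
        scalp_faces=scalp_f,
        brain_areas=_vertex_areas(brain_v, brain_f),
        scalp_areas=_vertex_areas(scalp_v, scalp_f),
        region_labels=_paint_regions(brain_v, cfg),
        config=cfg,
    )
    return mesh


def export_surfaces(mesh: HeadMesh, brain_path, scalp_path) -> None:
    """Write the two surfaces as OFF/PLY (format chosen by file extension)."""
    import trimesh

    trimesh.Trimesh(mesh.brain_vertices, mesh.brain_faces,
                    process=False).export(brain_path)
    trimesh.Trimesh(mesh.scalp_vertices, mesh.scalp_faces,
                    process=False).export(scalp_path)
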