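"""Probe geometries: sparse 30 mm grid and high-density hexagonal arrays.

Two optode layouts with a matched field of view over the prefrontal cortex:

* the *sparse* array: a 3 x 11 alternating source/detector grid with 30 mm
  channels (17 sources, 16 detectors, 52 long channels), the traditional
  commercial arrangement;
* the *high-density* (HD) array: a triangular lattice with 19 mm pitch and
  row-alternating roles, producing overlapping first (19 mm) and second
  (sqrt(3) x 19 ~ 33 mm) neighbor channels.

Both carry 8 dedicated short-separation (8 mm) detectors for superficial
physiology regression. Layouts are laid onto the scalp sphere row by row
with exact spherical circle-circle intersections — the way a flexible cap
drapes over a head — so that channel separations stay at their nominal
lengths despite the curvature; the residual distortion lands on
unconstrained diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SEPARATION_CLASSES = ("short", "second_nn", "third_nn", "grid30")

#: nominal source-detector distance per class, mm
NOMINAL_SEPARATION_MM = {
    "short": 8.0,
    "second_nn": 19.0,
    "third_nn": 33.0,
    "grid30": 30.0,
}

#: channel distances must match their class nominal within this tolerance
SEPARATION_TOL_MM = 1.5

MIN_OPTODE_DISTANCE_MM = 5.0


@dataclass
class ProbeGeometry:
    """An optode layout on the scalp sphere.

    channels are (source_index, detector_index, separation_class) triples;
    indices are 0-based into the respective position arrays.
    """

    name: str
    source_positions: np.ndarray  # (n_sources, 3) mm
    detector_positions: np.ndarray  # (n_detectors, 3) mm
    channels: list  # of (int, int, str)
    landmark_anchors: dict  # name -> (3,) mm
    scalp_radius_mm: float

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_positions(self):
        """(n_channels, 3) source and detector positions per channel."""
        src = self.source_positions[[c[0] for c in self.channels]]
        det = self.detector_positions[[c[1] for c in self.channels]]
        return src, det

    def channel_midpoints(self) -> np.ndarray:
        src, det = self.channel_positions()
        return 0.5 * (src + det)

    def separations(self) -> np.ndarray:
        src, det = self.channel_positions()
        return np.linalg.norm(src - det, axis=1)

    def nominal_separations(self) -> np.ndarray:
        return np.array([NOMINAL_SEPARATION_MM[c[2]] for c in self.channels])

    def channel_indices(self, separation_class: str) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.channels)
                         if c[2] == separation_class], dtype=int)

    @property
    def short_channels(self) -> np.ndarray:
        return self.channel_indices("short")

    @property
    def long_channels(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.channels)
                         if c[2] != "short"], dtype=int)

    def validate(self) -> None:
        """Raise AssertionError when a geometry invariant is violated."""
        seps = self.separations()
        noms = self.nominal_separations()
        worst = np.max(np.abs(seps - noms))
        assert worst <= SEPARATION_TOL_MM, (
            f"{self.name}: channel separation off nominal by {worst:.2f} mm")
        opt = np.vstack([self.source_positions, self.detector_positions])
        d = np.linalg.norm(opt[:, None] - opt[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= MIN_OPTODE_DISTANCE_MM, (
            f"{self.name}: optodes closer than {MIN_OPTODE_DISTANCE_MM} mm")
        assert len(set((c[0], c[1]) for c in self.channels)) == len(self.channels), \
            f"{self.name}: duplicate channels"


@dataclass
class SparseProbeConfig:
    grid_spacing_mm: float = 30.0
    ss_offset_mm: float = 8.0
    n_rows: int = 3
    n_cols: int = 11
    n_short: int = 8
    scalp_radius_mm: float = 93.0


@dataclass
class HDProbeConfig:
    pitch_mm: float = 19.0
    n_rows: int = 5
    n_cols: int = 17  # 16 x 19 mm = 304 mm span, matching the sparse 300 mm
    ss_offset_mm: float = 8.0
    n_short: int = 8
    scalp_radius_mm: float = 93.0


def _equator_point(u: float, radius: float) -> np.ndarray:
    """Point on the equatorial great circle at arc length u from the front."""
    a = u / radius  # azimuth from +y toward +x
    return radius * np.array([np.sin(a), np.cos(a), 0.0])


def _two_circle_point(a: np.ndarray, b: np.ndarray, da: float, db: float,
                      radius: float, up: bool = True) -> np.ndarray:
    """Point on the sphere at chord distance da from a and db from b.

    Of the two intersections (one on each side of the plane spanned by a, b
    and the origin), ``up`` selects the one with the larger z (toward the
    pole) and ``up=False`` the other.
    """
    ca = radius ** 2 - 0.5 * da ** 2   # x . a
    cb = radius ** 2 - 0.5 * db ** 2   # x . b
    G = np.array([[a @ a, a @ b], [a @ b, b @ b]])
    alpha, beta = np.linalg.solve(G, np.array([ca, cb]))
    m = alpha * a + beta * b
    n = np.cross(a, b)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise ValueError("degenerate circle intersection: collinear centers")
    n = n / nn
    gamma_sq = radius ** 2 - m @ m
    if gamma_sq < 0:
        raise ValueError("circles do not intersect on the sphere")
    gamma = np.sqrt(gamma_sq)
    x1, x2 = m + gamma * n, m - gamma * n
    hi, lo = (x1, x2) if x1[2] >= x2[2] else (x2, x1)
    return hi if up else lo


def _lay_grid_rows(n_rows: int, n_cols: int, spacing: float,
                   radius: float) -> np.ndarray:
    """Square grid on the sphere: bottom row on the equator, rows built up
    with exact horizontal and vertical edge lengths."""
    rows = [np.array([_equator_point((i - (n_cols - 1) / 2.0) * spacing, radius)
                      for i in range(n_cols)])]
    diag = np.sqrt(2.0) * spacing
    for _j in range(1, n_rows):
        prev = rows[-1]
        cur = [None] * n_cols
        # first point: vertical edge exact, diagonal to the next column holds
        # the residual curvature strain (it is not a channel)
        cur[0] = _two_circle_point(prev[0], prev[1], spacing, diag, radius)
        for i in range(1, n_cols):
            cur[i] = _two_circle_point(cur[i - 1], prev[i], spacing, spacing,
                                       radius)
        rows.append(np.asarray(cur))
    return np.asarray(rows)  # (n_rows, n_cols, 3)


def _next_triangular_row(prev: np.ndarray, n_cols: int, pitch: float,
                         radius: float, up: bool) -> np.ndarray:
    """One lattice row above (or below) the previous, distances exact."""
    d3 = np.sqrt(3.0) * pitch
    m = len(prev)
    if m == n_cols:      # next row is offset, one point fewer
        cur = [_two_circle_point(prev[i], prev[i + 1], pitch, pitch,
                                 radius, up) for i in range(m - 1)]
    else:                # next row realigned, one point more
        cur = [None] * (m + 1)
        cur[0] = _two_circle_point(prev[0], prev[1], pitch, d3, radius, up)
        for i in range(1, m):
            cur[i] = _two_circle_point(prev[i - 1], prev[i], pitch, pitch,
                                       radius, up)
        cur[m] = _two_circle_point(prev[m - 1], prev[m - 2], pitch, d3,
                                   radius, up)
    return np.asarray(cur)


def _lay_triangular_rows(n_rows: int, n_cols: int, pitch: float,
                         radius: float) -> list:
    """Triangular lattice on the sphere, nearest-neighbor distances exact.

    Built outward from a middle anchor row (halving accumulated curvature
    strain): the anchor row lies on the latitude circle at its nominal
    elevation with exact chord spacing; rows above and below are placed at
    exactly ``pitch`` from their two supporting neighbors. Rows alternate
    between n_cols and n_cols - 1 points (offset by half a pitch).
    """
    row_h = pitch * np.sqrt(3.0) / 2.0
    j_mid = n_rows // 2
    b = j_mid * row_h / radius       # elevation of the anchor row
    r_lat = radius * np.cos(b)       # latitude circle radius
    z_lat = radius * np.sin(b)
    dphi = 2.0 * np.arcsin(pitch / (2.0 * r_lat))  # exact chord spacing
    offset_mid = 0.5 * (j_mid % 2)
    mid = []
    for i in range(n_cols - (j_mid % 2)):
        a = (i - (n_cols - (j_mid % 2) - 1) / 2.0 + offset_mid * 0) * dphi
        mid.append(np.array([r_lat * np.sin(a), r_lat * np.cos(a), z_lat]))
    rows_up, rows_down = [np.asarray(mid)], []
    for _j in range(j_mid + 1, n_rows):
        rows_up.append(_next_triangular_row(rows_up[-1], n_cols, pitch,
                                            radius, up=True))
    for _j in range(j_mid - 1, -1, -1):
        prev = rows_down[-1] if rows_down else rows_up[0]
        rows_down.append(_next_triangular_row(prev, n_cols, pitch, radius,
                                              up=False))
    return list(reversed(rows_down)) + rows_up


def _tangent_frame(p: np.ndarray):
    """Orthonormal tangents at a scalp point: toward-pole and along-latitude."""
    r_hat = p / np.linalg.norm(p)
    z = np.array([0.0, 0.0, 1.0])
    t = z - np.dot(z, r_hat) * r_hat
    tn = np.linalg.norm(t)
    if tn < 1e-9:  # at the pole; any tangent will do
        t = np.array([1.0, 0.0, 0.0])
        tn = 1.0
    t = t / tn
    return t, np.cross(r_hat, t)


def _offset_along(p: np.ndarray, direction: np.ndarray, arc_mm: float,
                  radius: float) -> np.ndarray:
    """Move a scalp point by a given arc length along a tangent direction."""
    r_hat = p / np.linalg.norm(p)
    ang = arc_mm / radius
    return radius * (np.cos(ang) * r_hat + np.sin(ang) * direction)


def _landmarks(radius: float) -> dict:
    return {
        "FPz": np.array([0.0, radius, 0.0]),
        "T7": np.array([-radius, 0.0, 0.0]),
        "T8": np.array([radius, 0.0, 0.0]),
        "Cz": np.array([0.0, 0.0, radius]),
    }


def _pick_spread(candidates: np.ndarray, k: int) -> np.ndarray:
    """k indices spread evenly over a list sorted by position."""
    if len(candidates) < k:
        raise ValueError("fewer candidate sources than short channels requested")
    sel = np.linspace(0, len(candidates) - 1, k).round().astype(int)
    return candidates[sel]


def _attach_short_detectors(src_order_key, src_positions, channels,
                            det_positions, n_short, offset_mm, radius):
    """Place dedicated short-separation detectors next to spread-out sources.

    Each chosen source gets one detector at the short-separation arc offset,
    in whichever tangent direction has the most clearance from other optodes.
    """
    order = np.lexsort((src_order_key[:, 1], src_order_key[:, 0]))
    chosen = _pick_spread(order, n_short)
    det_positions = list(det_positions)
    others = np.vstack([src_positions,
                        np.asarray(det_positions).reshape(-1, 3)])
    for s_idx in chosen:
        s = src_positions[s_idx]
        t_pole, t_lat = _tangent_frame(s)
        best, best_clear = None, -np.inf
        for direction in (t_pole, -t_pole, t_lat, -t_lat):
            p = _offset_along(s, direction, offset_mm, radius)
            clear = np.min(np.linalg.norm(others - p, axis=1))
            if clear > best_clear:
                best, best_clear = p, clear
        det_positions.append(best)
        others = np.vstack([others, best])
        channels.append((int(s_idx), len(det_positions) - 1, "short"))
    return np.asarray(det_positions), channels


def build_sparse_probe(config: SparseProbeConfig | None = None) -> ProbeGeometry:
    """Construct the traditional 30 mm grid array.

    3 rows x 11 columns of alternating sources and detectors at the grid
    spacing, a channel for every orthogonally adjacent source-detector pair
    (52 at default), plus dedicated 8 mm short-separation detectors.
    """
    cfg = config or SparseProbeConfig()
    R = cfg.scalp_radius_mm
    grid = _lay_grid_rows(cfg.n_rows, cfg.n_cols, cfg.grid_spacing_mm, R)

    flat_key, points, roles = [], [], []
    index = {}
    for j in range(cfg.n_rows):
        for i in range(cfg.n_cols):
            index[(i, j)] = len(points)
            points.append(grid[j, i])
            roles.append("S" if (i + j) % 2 == 0 else "D")
            flat_key.append((i * cfg.grid_spacing_mm, j * cfg.grid_spacing_mm))
    points = np.asarray(points)
    flat_key = np.asarray(flat_key)

    src_ids = [k for k, r in enumerate(roles) if r == "S"]
    det_ids = [k for k, r in enumerate(roles) if r == "D"]
    src_of = {k: n for n, k in enumerate(src_ids)}
    det_of = {k: n for n, k in enumerate(det_ids)}

    channels = []
    for (i, j), k in index.items():
        for di, dj in ((1, 0), (0, 1)):
            nb = index.get((i + di, j + dj))
            if nb is None:
                continue
            a, b = (k, nb) if roles[k] == "S" else (nb, k)
            channels.append((src_of[a], det_of[b], "grid30"))

    src_pos = points[src_ids]
    det_pos = points[det_ids]
    det_pos, channels = _attach_short_detectors(
        flat_key[src_ids], src_pos, channels, det_pos,
        cfg.n_short, cfg.ss_offset_mm, R)

    probe = ProbeGeometry("sparse", src_pos, det_pos, channels,
                          _landmarks(R), R)
    probe.validate()
    return probe


def build_hd_probe(config: HDProbeConfig | None = None) -> ProbeGeometry:
    """Construct the high-density hexagonal array.

    Optodes on a triangular lattice (19 mm pitch) with row-alternating
    source/detector roles, so that both ~19 mm and ~33 mm source-detector
    pairs arise; channel classes are second_nn (19 mm) and third_nn (33 mm),
    plus dedicated 8 mm short-separation detectors.
    """
    cfg = config or HDProbeConfig()
    p = cfg.pitch_mm
    R = cfg.scalp_radius_mm
    if cfg.n_cols < 3 or cfg.n_rows < 2:
        raise ValueError("lattice too small to form third-nearest-neighbor "
                         "channels; need at least 3 columns and 2 rows")
    rows = _lay_triangular_rows(cfg.n_rows, cfg.n_cols, p, R)

    points, roles, flat_key = [], [], []
    row_h = p * np.sqrt(3.0) / 2.0
    for j, row in enumerate(rows):
        for i, pt in enumerate(row):
            points.append(pt)
            roles.append("S" if j % 2 == 0 else "D")
            flat_key.append((i * p + (j % 2) * p / 2.0, j * row_h))
    points = np.asarray(points)
    flat_key = np.asarray(flat_key)

    src_ids = [k for k, r in enumerate(roles) if r == "S"]
    det_ids = [k for k, r in enumerate(roles) if r == "D"]
    src_of = {k: n for n, k in enumerate(src_ids)}
    det_of = {k: n for n, k in enumerate(det_ids)}

    d2, d3 = p, np.sqrt(3.0) * p
    channels = []
    for k in src_ids:
        for m in det_ids:
            d = float(np.linalg.norm(points[k] - points[m]))
            if abs(d - d2) < SEPARATION_TOL_MM:
                channels.append((src_of[k], det_of[m], "second_nn"))
            elif abs(d - NOMINAL_SEPARATION_MM["third_nn"]) < SEPARATION_TOL_MM:
                channels.append((src_of[k], det_of[m], "third_nn"))

    if not any(c[2] == "third_nn" for c in channels):
        raise ValueError("HD role assignment produced no third-nearest-neighbor "
                         "channels; check lattice extent and row count")

    src_pos = points[src_ids]
    det_pos = points[det_ids]
    det_pos, channels = _attach_short_detectors(
        flat_key[src_ids], src_pos, channels, det_pos,
        cfg.n_short, cfg.ss_offset_mm, R)

    probe = ProbeGeometry("hd", src_pos, det_pos, channels, _landmarks(R), R)
    probe.validate()
    return probe
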