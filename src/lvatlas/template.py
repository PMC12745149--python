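"""Parametric LV template: truncated prolate-spheroid endo/epi surfaces.

The template is the synthetic stand-in for a population mean LV shape model:
an ellipsoidal endocardial cavity and a wall-offset epicardial surface, both
truncated by a basal plane and closed by basal cap fans, sampled on a shared
(ring x circumference) grid so that endocardial point ``i`` corresponds to
epicardial point ``i + p_per_surface``. The ES frame is a contracted copy
(radially and longitudinally scaled cavity, thickened wall), giving
physiological ejection fraction, longitudinal shortening and wall
thickening out of the box.

Default resolution is 781 points per surface (1562 total).
"""

from __future__ import annotations

import numpy as np

from .geometry import FRAMES, Landmarks, LVShape, Topology, mesh_volume


def _grid_factorisation(p_per_surface: int) -> tuple[int, int]:
    """Split ``p - 1`` grid points into n_rings x n_theta (plus the apex)."""
    n = p_per_surface - 1
    target = np.sqrt(1.2 * n)
    candidates = [d for d in range(8, n + 1)
                  if n % d == 0 and n // d >= 4]
    if not candidates:
        raise ValueError(
            f"p_per_surface={p_per_surface} admits no ring/sector grid "
            "(need p-1 = n_rings * n_theta with n_theta >= 8, n_rings >= 4)")
    n_theta = min(candidates, key=lambda d: abs(d - target))
    return n // n_theta, n_theta


def _surface_points(axes, phi_max, n_rings, n_theta):
    a, b, c = axes
    pts = [np.array([0.0, 0.0, -c])]                       # apex
    phis = phi_max * np.arange(1, n_rings + 1) / n_rings
    thetas = 2 * np.pi * np.arange(n_theta) / n_theta
    for phi in phis:
        sp, cp = np.sin(phi), np.cos(phi)
        ring = np.column_stack([a * sp * np.cos(thetas),
                                b * sp * np.sin(thetas),
                                -c * cp * np.ones(n_theta)])
        pts.append(ring)
    return np.vstack([pts[0][None, :], *pts[1:]])


def _surface_triangles(n_rings, n_theta, offset=0):
    tris = []
    ring0 = 1
    for j in range(n_theta):
        tris.append([0, ring0 + j, ring0 + (j + 1) % n_theta])
    for k in range(n_rings - 1):
        lo = 1 + k * n_theta
        hi = lo + n_theta
        for j in range(n_theta):
            jn = (j + 1) % n_theta
            tris.append([lo + j, hi + j, hi + jn])
            tris.append([lo + j, hi + jn, lo + jn])
    return np.asarray(tris, dtype=int) + offset


def _cap_fan(rim_indices):
    r = rim_indices
    return np.array([[r[0], r[i + 1], r[i]] for i in range(1, len(r) - 1)],
                    dtype=int)


def _signed_volume(points, triangles):
    a, b, c = (points[triangles[:, k]] for k in range(3))
    return np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0


def make_template(p_per_surface: int = 781,
                  wall_mm: float = 8.0,
                  cavity_axes: tuple[float, float, float] = (26.0, 26.0, 52.0),
                  base_fraction: float = 0.5,
                  es_radial_scale: float = 0.66,
                  es_long_scale: float = 0.87,
                  es_wall_scale: float = 1.35,
                  subject_id: str = "template") -> LVShape:
    """Build the two-frame LV template shape.

    Parameters
    ----------
    p_per_surface:
        Points per surface (endo and epi each); total points are twice this.
        Must factor as ``1 + n_rings * n_theta``. Default 781 (1562 total).
    wall_mm:
        ED wall offset between endo and epi ellipsoids (mm).
    cavity_axes:
        ED endocardial semi-axes (x, y, z) in mm; z is the long axis.
    base_fraction:
        Basal truncation plane height as a fraction of the long semi-axis.
    es_radial_scale, es_long_scale, es_wall_scale:
        ES cavity contraction factors and wall thickening factor; the
        defaults give an ejection fraction near 62% and longitudinal
        shortening near 13%.
    """
    if wall_mm <= 0:
        raise ValueError("wall_mm must be positive")
    if min(cavity_axes) <= 0:
        raise ValueError("cavity axes must be positive")
    if p_per_surface < 50:
        raise ValueError("p_per_surface must be at least 50")
    if not 0 < base_fraction < 1:
        raise ValueError("base_fraction must lie in (0, 1)")

    a, b, c = map(float, cavity_axes)
    w = float(wall_mm)
    f = float(base_fraction)
    n_rings, n_theta = _grid_factorisation(p_per_surface)
    p = p_per_surface

    def frame_points(sr, sl, wall):
        ax_endo = (a * sr, b * sr, c * sl)
        ax_epi = (a * sr + wall, b * sr + wall, c * sl + wall)
        z_base = f * c * sl
        phi_endo = np.arccos(-z_base / ax_endo[2])
        phi_epi = np.arccos(-z_base / ax_epi[2])
        endo = _surface_points(ax_endo, phi_endo, n_rings, n_theta)
        epi = _surface_points(ax_epi, phi_epi, n_rings, n_theta)
        return np.vstack([endo, epi])

    frames = {"ED": frame_points(1.0, 1.0, w),
              "ES": frame_points(es_radial_scale, es_long_scale,
                                 w * es_wall_scale)}

    endo_tris = _surface_triangles(n_rings, n_theta, offset=0)
    epi_tris = _surface_triangles(n_rings, n_theta, offset=p)
    rim = np.arange(1 + (n_rings - 1) * n_theta, 1 + n_rings * n_theta)
    cap = np.vstack([_cap_fan(rim), _cap_fan(rim + p)])

    # orient both closed surfaces consistently (positive signed volume)
    pts_ed = frames["ED"]
    endo_cap = cap[: len(rim) - 2]
    epi_cap = cap[len(rim) - 2:]
    if _signed_volume(pts_ed, np.vstack([endo_tris, endo_cap])) < 0:
        endo_tris = endo_tris[:, ::-1]
        endo_cap = endo_cap[:, ::-1]
    if _signed_volume(pts_ed, np.vstack([epi_tris, epi_cap])) < 0:
        epi_tris = epi_tris[:, ::-1]
        epi_cap = epi_cap[:, ::-1]

    topology = Topology(endo=endo_tris, epi=epi_tris,
                        cap=np.vstack([endo_cap, epi_cap]),
                        n_endo=p, n_points=2 * p)
    landmarks = Landmarks(apex_endo=0, mitral_ring=rim.copy())
    shape = LVShape(subject_id=subject_id, exam="baseline", protocol="GRE",
                    frames=frames, topology=topology, landmarks=landmarks)
    # construction sanity: closed surfaces must be watertight
    mesh_volume(frames["ED"], topology.closed_endo())
    mesh_volume(frames["ED"], topology.closed_epi())
    return shape
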