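"""Left-ventricular shape data model and derived clinical measures.

The unit object is an :class:`LVShape`: one exam's LV geometry, given as
``P`` template-corresponding 3D points (mm) for each of the two cardiac
frames (end-diastole ED, end-systole ES), plus a shared triangulation of
the endocardial and epicardial surfaces closed by basal caps, and two
anatomical landmarks (the endocardial apex point and the ordered
mitral-ring point set).

All algebra downstream (bias correction, trajectory atlas) operates on the
flattened *shape vector*: the ED point block concatenated with the ES block,
length ``2*P*3``.

Every geometric operation here is pose-invariant: volumes by the divergence
theorem, lengths and wall thicknesses by point distances, and the AHA-17
segmentation in a local frame built from the landmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

FRAMES = ("ED", "ES")

#: myocardial tissue density, g/mL (standard CMR convention)
MYOCARDIAL_DENSITY = 1.05

AHA17_NAMES = {
    1: "basal anterior", 2: "basal anteroseptal", 3: "basal inferoseptal",
    4: "basal inferior", 5: "basal inferolateral", 6: "basal anterolateral",
    7: "mid anterior", 8: "mid anteroseptal", 9: "mid inferoseptal",
    10: "mid inferior", 11: "mid inferolateral", 12: "mid anterolateral",
    13: "apical anterior", 14: "apical septal", 15: "apical inferior",
    16: "apical lateral", 17: "apex",
}


class MeshError(ValueError):
    """Raised for open, inconsistently oriented, or degenerate surfaces."""


@dataclass(frozen=True)
class Topology:
    """Shared triangulation of the LV template.

    Point indices ``0..n_endo-1`` are endocardial, ``n_endo..n_points-1``
    epicardial, with index ``i`` on the endocardium corresponding to index
    ``i + n_endo`` on the epicardium (same template parameter location, so
    per-point wall thickness is the distance between the pair).
    """

    endo: np.ndarray            # (T_endo, 3) int, endocardial surface
    epi: np.ndarray             # (T_epi, 3) int, epicardial surface
    cap: np.ndarray             # (T_cap, 3) int, basal closing fans
    n_endo: int
    n_points: int

    def closed_endo(self) -> np.ndarray:
        """Endocardial surface plus its basal cap fan (watertight)."""
        endo_cap = self.cap[(self.cap < self.n_endo).all(axis=1)]
        return np.vstack([self.endo, endo_cap])

    def closed_epi(self) -> np.ndarray:
        """Epicardial surface plus its basal cap fan (watertight)."""
        epi_cap = self.cap[(self.cap >= self.n_endo).all(axis=1)]
        return np.vstack([self.epi, epi_cap])


@dataclass(frozen=True)
class Landmarks:
    apex_endo: int                    # endocardial apex point index
    mitral_ring: np.ndarray           # ordered endocardial basal-ring indices


@dataclass
class LVShape:
    """One exam's LV geometry: corresponding ED and ES point clouds."""

    subject_id: str
    exam: str                         # "baseline" | "followup"
    protocol: str                     # "GRE" | "SSFP"
    frames: Dict[str, np.ndarray]     # frame -> (P, 3) float, mm
    topology: Topology
    landmarks: Landmarks
    bias_corrected: bool = False

    def __post_init__(self) -> None:
        for f in FRAMES:
            if f not in self.frames:
                raise ValueError(f"frame {f!r} missing from shape "
                                 f"{self.subject_id}/{self.exam}")
        shapes = {self.frames[f].shape for f in FRAMES}
        if len(shapes) != 1:
            raise ValueError("ED and ES frames must have identical point counts")
        p = self.frames["ED"].shape[0]
        if p != self.topology.n_points:
            raise ValueError(f"shape has {p} points but topology expects "
                             f"{self.topology.n_points}")

    @property
    def n_points(self) -> int:
        return self.frames["ED"].shape[0]

    def to_vector(self) -> np.ndarray:
        """Flatten to the shape vector: ED block then ES block, length 2*P*3."""
        return np.concatenate([self.frames["ED"].ravel(),
                               self.frames["ES"].ravel()])

    def with_vector(self, vec: np.ndarray, **updates) -> "LVShape":
        """New shape with the same metadata/topology and points from ``vec``."""
        p = self.n_points
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (2 * p * 3,):
            raise ValueError(f"expected vector of length {2 * p * 3}, "
                             f"got {vec.shape}")
        frames = {"ED": vec[: p * 3].reshape(p, 3).copy(),
                  "ES": vec[p * 3:].reshape(p, 3).copy()}
        return replace(self, frames=frames, **updates)


def shape_vector(shape: LVShape) -> np.ndarray:
    """Functional alias for :meth:`LVShape.to_vector`."""
    return shape.to_vector()


# ---------------------------------------------------------------------------
# mesh volume


def _check_watertight(triangles: np.ndarray) -> None:
    tri = np.asarray(triangles)
    edges = np.concatenate([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    directed = {}
    for a, b in edges:
        directed[(int(a), int(b))] = directed.get((int(a), int(b)), 0) + 1
    for (a, b), c in directed.items():
        if c > 1:
            raise MeshError(f"edge ({a}, {b}) used {c} times with the same "
                            "orientation: surface not consistently oriented")
        if directed.get((b, a), 0) != 1:
            raise MeshError(f"edge ({a}, {b}) has no opposite half-edge: "
                            "surface is open")


def mesh_volume(points: np.ndarray, triangles: np.ndarray,
                strict: bool = True) -> float:
    """Volume (mL) enclosed by a watertight oriented triangle surface.

    Signed sum of origin tetrahedra (divergence theorem); the absolute value
    is returned so the orientation convention does not matter. Points are in
    mm; 1 mL = 1000 mm^3.

    With ``strict`` (default), an open or inconsistently oriented surface
    raises :class:`MeshError` naming the offending edge, and a surface of
    (near-)zero area raises as degenerate; with ``strict=False`` a degenerate
    surface returns 0.0.
    """
    pts = np.asarray(points, dtype=float)
    tri = np.asarray(triangles, dtype=int)
    _check_watertight(tri)
    a, b, c = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
    area2 = np.linalg.norm(np.cross(b - a, c - a), axis=1).sum()
    if area2 < 1e-12:
        if strict:
            raise MeshError("degenerate surface: total area ~ 0")
        return 0.0
    vol_mm3 = abs(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)
    return vol_mm3 / 1000.0


# ---------------------------------------------------------------------------
# landmark frame and AHA-17 segmentation


def long_axis_frame(points: np.ndarray, landmarks: Landmarks):
    """Local anatomical frame from the landmarks.

    Returns ``(apex, u, L, e1, e2)`` with ``u`` the unit long axis (apex to
    mitral centroid), ``L`` its length (mm), and ``(e1, e2)`` orthonormal
    short-axis directions; ``e1`` points at mitral-ring point 0 (the
    template's septal reference) and the ``e2`` sign follows the ring's
    ordering so the frame is rigid-motion equivariant.
    """
    apex = points[landmarks.apex_endo]
    ring = points[landmarks.mitral_ring]
    base = ring.mean(axis=0)
    u = base - apex
    L = float(np.linalg.norm(u))
    if L <= 0:
        raise ValueError("degenerate long axis: apex coincides with mitral centroid")
    u = u / L

    def radial(p):
        v = p - apex
        return v - np.dot(v, u) * u

    e1 = radial(ring[0])
    n1 = np.linalg.norm(e1)
    if n1 <= 0:
        raise ValueError("mitral ring point 0 lies on the long axis")
    e1 = e1 / n1
    e2 = np.cross(u, e1)
    quarter = radial(ring[len(ring) // 4])
    if np.dot(quarter, e2) < 0:       # fix handedness from ring ordering
        e2 = -e2
    return apex, u, L, e1, e2


_BASAL = np.array([2, 1, 6, 5, 4, 3])
_MID = np.array([8, 7, 12, 11, 10, 9])
_APICAL = np.array([14, 13, 16, 15])


def aha17_segment_map(shape: LVShape, frame: str = "ED",
                      cap_fraction: float = 0.12) -> np.ndarray:
    """Assign every point (endo and epi) to one of the 17 AHA segments.

    The long axis is split into basal/mid/apical thirds (6/6/4 circumferential
    sectors) plus an apical cap (segment 17) covering the lowest
    ``cap_fraction`` of the axis. The circumferential zero is the template's
    septal reference (mitral-ring point 0), so sectors rotate rigidly with
    the shape: the assignment is invariant under rigid motion of points and
    landmarks together.
    """
    pts = shape.frames[frame]
    apex, u, L, e1, e2 = long_axis_frame(pts, shape.landmarks)
    v = pts - apex
    t = np.clip(v @ u / L, 0.0, 1.0)
    radial = v - np.outer(v @ u, u)
    theta = np.degrees(np.arctan2(radial @ e2, radial @ e1)) % 360.0
    # nudge off exact sector boundaries so template grid angles (which can
    # coincide with 60/90-degree boundaries) bin identically under rigid
    # motion despite roundoff
    theta = (theta + 1e-6) % 360.0
    theta[theta >= 360.0] = 0.0     # float wraparound: (-eps) % 360 == 360.0
    t = t + 1e-9

    seg = np.empty(len(pts), dtype=int)
    cap = t <= cap_fraction
    apical = (~cap) & (t <= 1 / 3)
    mid = (t > 1 / 3) & (t <= 2 / 3)
    basal = t > 2 / 3
    seg[cap] = 17
    seg[apical] = _APICAL[np.minimum(((theta[apical] + 45.0) % 360.0) // 90,
                                     3).astype(int)]
    seg[mid] = _MID[(theta[mid] // 60).astype(int)]
    seg[basal] = _BASAL[(theta[basal] // 60).astype(int)]
    return seg


# ---------------------------------------------------------------------------
# derived clinical measures


def wall_thickening(wt_ed, wt_es):
    """Percent systolic wall thickening: 100 * (WT_ES - WT_ED) / WT_ED."""
    wt_ed = np.asarray(wt_ed, dtype=float)
    wt_es = np.asarray(wt_es, dtype=float)
    if np.any(wt_ed <= 0):
        raise ValueError("wall thickening undefined for WT_ED <= 0")
    out = 100.0 * (wt_es - wt_ed) / wt_ed
    return float(out) if out.ndim == 0 else out


def percent_change(before: float, after: float) -> float:
    """Percent change 100 * (after - before) / before."""
    if before == 0:
        raise ValueError("percent change undefined for a zero reference")
    return 100.0 * (after - before) / before


def per_point_wall_thickness(shape: LVShape, frame: str) -> np.ndarray:
    """Endo-to-epi distance per corresponding template point (mm)."""
    pts = shape.frames[frame]
    n = shape.topology.n_endo
    return np.linalg.norm(pts[:n] - pts[n:2 * n], axis=1)


SEPTAL_SEGMENTS = (2, 3, 8, 9)
INFEROLATERAL_SEGMENTS = (5, 11)


@dataclass
class DerivedMeasures:
    """Conventional global and regional LV measures for one exam."""

    EDV: float                 # mL
    ESV: float                 # mL
    mass: float                # g, at ED
    EF: float                  # %
    MVR: float                 # g/mL
    SphVi_ED: float
    SphVi_ES: float
    LS: float                  # %
    RWT_ED: float
    septal_WT: float           # mm, ED
    inferolateral_WT: float    # mm, ED
    regional_WT_ED: np.ndarray     # (17,) mm
    regional_WT_ES: np.ndarray     # (17,) mm
    regional_thickening: np.ndarray  # (17,) %

    SCALAR_FIELDS = ("EDV", "ESV", "mass", "EF", "MVR", "SphVi_ED", "SphVi_ES",
                     "LS", "RWT_ED", "septal_WT", "inferolateral_WT")

    def to_row(self) -> Dict[str, float]:
        row = {k: getattr(self, k) for k in self.SCALAR_FIELDS}
        for s in range(17):
            row[f"WT_ED_seg{s + 1}"] = self.regional_WT_ED[s]
            row[f"WT_ES_seg{s + 1}"] = self.regional_WT_ES[s]
            row[f"thickening_seg{s + 1}"] = self.regional_thickening[s]
        return row


def _segment_means(values: np.ndarray, segments: np.ndarray) -> np.ndarray:
    out = np.full(17, np.nan)
    for s in range(1, 18):
        mask = segments == s
        if mask.any():
            out[s - 1] = values[mask].mean()
    return out


def derived_measures(shape: LVShape,
                     density: float = MYOCARDIAL_DENSITY) -> DerivedMeasures:
    """Compute all conventional measures from one exam's shape.

    Cavity volumes from the closed endocardial surface; mass from the
    ED myocardial shell (epi minus endo volume) times tissue density;
    EF = 100*(EDV-ESV)/EDV and MVR = mass/EDV hold exactly by construction.
    The long-axis length L (apex to mitral centroid) defines longitudinal
    shortening LS = 100*(L_ED-L_ES)/L_ED and the sphericity volume index
    SphVi = cavity volume / volume of the sphere of diameter L, per frame.
    RWT_ED = 2 * mean inferolateral wall thickness / mid-cavity internal
    diameter, at ED. Regional values average the per-point endo-epi wall
    thickness over AHA-17 segments of the endocardial points.
    """
    topo = shape.topology
    endo_closed = topo.closed_endo()
    epi_closed = topo.closed_epi()

    edv = mesh_volume(shape.frames["ED"], endo_closed)
    esv = mesh_volume(shape.frames["ES"], endo_closed)
    if edv <= 0:
        raise ValueError("zero end-diastolic volume")
    epi_ed = mesh_volume(shape.frames["ED"], epi_closed)
    mass = density * max(epi_ed - edv, 0.0)
    ef = 100.0 * (edv - esv) / edv
    mvr = mass / edv

    lengths = {}
    sph = {}
    for f, vol in (("ED", edv), ("ES", esv)):
        _, _, L, _, _ = long_axis_frame(shape.frames[f], shape.landmarks)
        if L <= 0:
            raise ValueError(f"zero long-axis length at {f}")
        lengths[f] = L
        sph[f] = vol / (np.pi / 6.0 * L ** 3 / 1000.0)
    ls = 100.0 * (lengths["ED"] - lengths["ES"]) / lengths["ED"]

    seg_ed = aha17_segment_map(shape, "ED")
    n = topo.n_endo
    seg_endo = seg_ed[:n]
    wt_ed = per_point_wall_thickness(shape, "ED")
    wt_es = per_point_wall_thickness(shape, "ES")
    reg_ed = _segment_means(wt_ed, seg_endo)
    reg_es = _segment_means(wt_es, seg_endo)
    with np.errstate(invalid="ignore", divide="ignore"):
        reg_thick = 100.0 * (reg_es - reg_ed) / reg_ed

    infero = np.isin(seg_endo, INFEROLATERAL_SEGMENTS)
    septal = np.isin(seg_endo, SEPTAL_SEGMENTS)
    pts_ed = shape.frames["ED"]
    apex, u, L_ed, _, _ = long_axis_frame(pts_ed, shape.landmarks)
    v = pts_ed[:n] - apex
    t = v @ u / L_ed
    radial = np.linalg.norm(v - np.outer(v @ u, u), axis=1)
    mid_mask = (t > 1 / 3) & (t <= 2 / 3)
    if not mid_mask.any():
        raise ValueError("no mid-cavity endocardial points for RWT")
    internal_diam = 2.0 * radial[mid_mask].mean()
    rwt = 2.0 * wt_ed[infero].mean() / internal_diam

    return DerivedMeasures(
        EDV=edv, ESV=esv, mass=mass, EF=ef, MVR=mvr,
        SphVi_ED=sph["ED"], SphVi_ES=sph["ES"], LS=ls, RWT_ED=rwt,
        septal_WT=float(wt_ed[septal].mean()),
        inferolateral_WT=float(wt_ed[infero].mean()),
        regional_WT_ED=reg_ed, regional_WT_ES=reg_es,
        regional_thickening=reg_thick,
    )


def measures_table(shapes: Iterable[LVShape],
                   density: float = MYOCARDIAL_DENSITY) -> pd.DataFrame:
    """One row of derived measures per subject-exam."""
    rows = []
    for s in shapes:
        row = {"subject_id": s.subject_id, "exam": s.exam,
               "protocol": s.protocol}
        row.update(derived_measures(s, density=density).to_row())
        rows.append(row)
    return pd.DataFrame(rows)
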