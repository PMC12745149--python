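"""Plain-text I/O for shapes, topology, landmarks and analysis outputs.

Shape file: long CSV with columns subject_id, exam, protocol, frame,
point_id, x_mm, y_mm, z_mm (point_id 0-based in template order). Companion
topology CSV (surface in {endo, epi, cap}, v0, v1, v2) and landmarks CSV
(role in {apex_endo, mitral_ring}, point_id; ring rows in ring order).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd

from .geometry import FRAMES, Landmarks, LVShape, Topology


def write_topology(topology: Topology, path) -> None:
    rows = []
    for name, tris in (("endo", topology.endo), ("epi", topology.epi),
                       ("cap", topology.cap)):
        for v0, v1, v2 in tris:
            rows.append({"surface": name, "v0": v0, "v1": v1, "v2": v2})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_topology(path) -> Topology:
    df = pd.read_csv(path)
    tri = {name: g[["v0", "v1", "v2"]].to_numpy(int)
           for name, g in df.groupby("surface")}
    n_endo = int(tri["endo"].max()) + 1
    n_points = int(df[["v0", "v1", "v2"]].to_numpy().max()) + 1
    return Topology(endo=tri["endo"], epi=tri["epi"], cap=tri["cap"],
                    n_endo=n_endo, n_points=n_points)


def write_landmarks(landmarks: Landmarks, path) -> None:
    rows = [{"role": "apex_endo", "point_id": int(landmarks.apex_endo)}]
    rows += [{"role": "mitral_ring", "point_id": int(i)}
             for i in landmarks.mitral_ring]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(path) -> Landmarks:
    df = pd.read_csv(path)
    apex = int(df.loc[df["role"] == "apex_endo", "point_id"].iloc[0])
    ring = df.loc[df["role"] == "mitral_ring", "point_id"].to_numpy(int)
    return Landmarks(apex_endo=apex, mitral_ring=ring)


def write_shapes(shapes: Iterable[LVShape], path) -> None:
    frames = []
    for s in shapes:
        for f in FRAMES:
            pts = s.frames[f]
            frames.append(pd.DataFrame({
                "subject_id": s.subject_id, "exam": s.exam,
                "protocol": s.protocol, "frame": f,
                "point_id": np.arange(len(pts)),
                "x_mm": pts[:, 0], "y_mm": pts[:, 1], "z_mm": pts[:, 2],
            }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.6f")


def read_shapes(path, topology: Topology,
                landmarks: Landmarks) -> List[LVShape]:
    df = pd.read_csv(path)
    shapes = []
    for (sid, exam, protocol), g in df.groupby(
            ["subject_id", "exam", "protocol"], sort=True):
        frames = {}
        for f, gf in g.groupby("frame"):
            gf = gf.sort_values("point_id")
            frames[f] = gf[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        shapes.append(LVShape(subject_id=str(sid), exam=exam,
                              protocol=protocol, frames=frames,
                              topology=topology, landmarks=landmarks))
    return shapes


def shapes_by_subject(shapes: Iterable[LVShape]) -> Dict[str, Dict[str, LVShape]]:
    out: Dict[str, Dict[str, LVShape]] = {}
    for s in shapes:
        out.setdefault(s.subject_id, {})[s.exam] = s
    return out


def write_vtk_polydata(points: np.ndarray, triangles: np.ndarray,
                       path, point_scalars: Dict[str, np.ndarray] = None) -> None:
    """Minimal legacy ASCII VTK PolyData export for mode visualization."""
    lines = ["# vtk DataFile Version 3.0", "lvatlas surface", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(points)} float"]
    lines += [" ".join(f"{c:.6f}" for c in p) for p in points]
    lines.append(f"POLYGONS {len(triangles)} {4 * len(triangles)}")
    lines += ["3 " + " ".join(str(v) for v in t) for t in triangles]
    if point_scalars:
        lines.append(f"POINT_DATA {len(points)}")
        for name, vals in point_scalars.items():
            lines += [f"SCALARS {name} float 1", "LOOKUP_TABLE default"]
            lines += [f"{v:.6f}" for v in vals]
    Path(path).write_text("\n".join(lines) + "\n")
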