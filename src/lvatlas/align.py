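"""Rigid/similarity Procrustes and generalized Procrustes analysis (GPA).

Alignment is always driven by the ED frame: the least-squares transform that
maps a shape's ED points onto the evolving mean is applied unchanged to the
ES frame, so contraction-related differences between the frames are retained
rather than being absorbed by per-frame pose fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Sequence, Tuple

import numpy as np

from .geometry import LVShape


@dataclass(frozen=True)
class RigidTransform:
    """y = scale * R @ x + t (scale fixed to 1 in rigid mode)."""

    rotation: np.ndarray      # (3, 3)
    translation: np.ndarray   # (3,)
    scale: float = 1.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        r_inv = self.rotation.T / self.scale
        return RigidTransform(rotation=self.rotation.T,
                              translation=-r_inv @ self.translation,
                              scale=1.0 / self.scale)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3), 1.0)


def fit_transform(moving: np.ndarray, target: np.ndarray,
                  mode: str = "rigid") -> RigidTransform:
    """Least-squares rigid or similarity transform mapping moving -> target."""
    if mode not in ("rigid", "similarity"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    x = np.asarray(moving, float)
    y = np.asarray(target, float)
    xm, ym = x.mean(0), y.mean(0)
    xc, yc = x - xm, y - ym
    sv = np.linalg.svd(xc, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate point set (rank < 3): cannot align")
    h = xc.T @ yc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    scale = 1.0
    if mode == "similarity":
        scale = float(np.trace(np.diag(s) @ corr) / (xc ** 2).sum())
    t = ym - scale * r @ xm
    return RigidTransform(rotation=r, translation=t, scale=scale)


def transform_shape(shape: LVShape, tf: RigidTransform) -> LVShape:
    """Apply one transform to both frames of a shape."""
    frames = {f: tf.apply(p) for f, p in shape.frames.items()}
    return replace(shape, frames=frames)


def procrustes_align(shapes: Sequence[LVShape], mode: str = "rigid",
                     tol: float = 1e-6, max_iter: int = 100,
                     ) -> Tuple[List[LVShape], LVShape, List[RigidTransform]]:
    """Generalized Procrustes alignment of a shape set.

    Iteratively aligns each shape's ED frame to the current mean ED shape
    (rigid by default; ``mode="similarity"`` adds isotropic scaling), applies
    the same transform to ES, and recomputes the mean, until the mean moves
    by less than ``tol`` mm RMS or ``max_iter`` iterations.

    Returns ``(aligned_shapes, mean_shape, transforms)`` where ``transforms``
    are the cumulative per-shape transforms from original to aligned pose and
    ``mean_shape`` carries the mean ED and ES point sets.
    """
    if len(shapes) < 2:
        raise ValueError("GPA requires at least 2 shapes")
    ps = {s.n_points for s in shapes}
    if len(ps) != 1:
        raise ValueError("all shapes must share the template point count")

    aligned = list(shapes)
    transforms = [RigidTransform.identity() for _ in shapes]
    mean_ed = aligned[0].frames["ED"].copy()
    mean_ed -= mean_ed.mean(0)

    for _ in range(max_iter):
        new_aligned, new_tfs = [], []
        for s, prev in zip(shapes, transforms):
            tf = fit_transform(s.frames["ED"], mean_ed, mode=mode)
            new_aligned.append(transform_shape(s, tf))
            new_tfs.append(tf)
        aligned, transforms = new_aligned, new_tfs
        new_mean = np.mean([s.frames["ED"] for s in aligned], axis=0)
        shift = np.sqrt(((new_mean - mean_ed) ** 2).mean())
        mean_ed = new_mean
        if shift < tol:
            break

    mean_es = np.mean([s.frames["ES"] for s in aligned], axis=0)
    mean_shape = replace(aligned[0], subject_id="mean", protocol=shapes[0].protocol,
                         frames={"ED": mean_ed, "ES": mean_es})
    return aligned, mean_shape, transforms


def gpa_objective(aligned: Sequence[LVShape]) -> float:
    """Sum of squared ED distances to the mean (the GPA objective)."""
    stack = np.stack([s.frames["ED"] for s in aligned])
    return float(((stack - stack.mean(0)) ** 2).sum())
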