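"""Template-to-target mesh correspondence: rigid ICP followed by non-rigid ICP.

The statistical shape model needs every shape on one shared topology.
Meshes produced by the in-package synthetic pipeline already share the
template's topology (correspondence is the identity); these routines are
the path for external meshes such as patient 3D photographs — a rigid
(optionally similarity) alignment, then an Amberg-style non-rigid ICP
where each template vertex carries its own affine transform, regularised
towards its neighbours' transforms with a decreasing stiffness schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from cranioplan.mesh import TriangleMesh, surface_distance

__all__ = ["RigidTransform", "Correspondence", "rigid_icp", "nricp"]

DEFAULT_STIFFNESS_SCHEDULE = (10.0, 2.0, 0.5, 0.1, 0.02)


@dataclass
class RigidTransform:
    """Rotation + translation (+ optional uniform scale), applied as s R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale * points @ self.rotation.T + self.translation

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.scale * self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class Correspondence:
    """Template deformed onto a target: template topology, target geometry."""

    deformed_template: TriangleMesh
    residuals: np.ndarray
    rigid_transform: RigidTransform

    @property
    def mean_residual(self) -> float:
        return float(self.residuals.mean())


def _kabsch(src: np.ndarray, dst: np.ndarray, with_scale: bool) -> RigidTransform:
    """Least-squares similarity transform between paired point sets (Umeyama)."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    s_c, d_c = src - mu_s, dst - mu_d
    H = s_c.T @ d_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    scale = (S @ np.diag([1, 1, d]).diagonal()).sum() / (s_c ** 2).sum() if with_scale else 1.0
    t = mu_d - scale * R @ mu_s
    return RigidTransform(rotation=R, translation=t, scale=scale)


def _point_to_plane(src: np.ndarray, dst: np.ndarray, normals: np.ndarray) -> RigidTransform:
    """Small-angle point-to-plane rigid step: minimise sum(((R p + t - q) . n)^2)."""
    b = ((dst - src) * normals).sum(axis=1)
    A = np.hstack([np.cross(src, normals), normals])
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    omega, t = x[:3], x[3:]
    angle = np.linalg.norm(omega)
    if angle < 1e-12:
        R = np.eye(3)
    else:
        k = omega / angle
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    return RigidTransform(rotation=R, translation=t)


def rigid_icp(template: TriangleMesh, target: TriangleMesh,
              max_iterations: int = 100, tol: float = 1e-6,
              with_scale: bool = False):
    """Iterative closest point with a least-squares rigid (or similarity) update.

    Returns ``(transform, residual_history, aligned_template)``.  The
    root-mean-square nearest-neighbour residual is non-increasing across
    iterations (each step minimises the squared error of the current
    matches); the loop stops when it improves by less than ``tol`` mm.
    """
    pts = target.vertices
    if np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("target is degenerate (collinear points)")
    tree = cKDTree(pts)
    normals = np.asarray(target.to_trimesh().vertex_normals)
    cur = template.vertices.copy()
    residuals = []

    def rms(x):
        d, _ = tree.query(x)
        return float(np.sqrt((d ** 2).mean()))

    for _ in range(max_iterations):
        dist, idx = tree.query(cur)
        residuals.append(float(np.sqrt((dist ** 2).mean())))
        # point-to-point (Kabsch/Umeyama) step: provably non-increasing RMS
        step_pp = _kabsch(cur, pts[idx], with_scale)
        cand_pp = step_pp.apply(cur)
        # point-to-plane step: escapes the tangential-sliding stalls of
        # point-to-point matching on smooth surfaces; accepted only if it
        # actually lowers the RMS, so the recorded residuals stay monotone
        cand = cand_pp
        if not with_scale:
            step_ppl = _point_to_plane(cur, pts[idx], normals[idx])
            cand_ppl = step_ppl.apply(cur)
            if rms(cand_ppl) < rms(cand_pp):
                cand = cand_ppl
        if rms(cand) <= residuals[-1]:
            cur = cand
        if len(residuals) >= 2 and residuals[-2] - residuals[-1] < tol:
            break
    # compose the total transform from original template to final position
    total = _kabsch(template.vertices, cur, with_scale)
    aligned = template.with_vertices(total.apply(template.vertices))
    dist, _ = tree.query(aligned.vertices)
    residuals.append(min(float(np.sqrt((dist ** 2).mean())), residuals[-1]))
    return total, np.array(residuals), aligned


def nricp(template: TriangleMesh, target: TriangleMesh,
          stiffness_schedule=DEFAULT_STIFFNESS_SCHEDULE,
          inner_iterations: int = 20, rigid_first: bool = True,
          with_scale: bool = False) -> Correspondence:
    """Non-rigid ICP: fit the template's vertices onto the target surface.

    Per-vertex affine transforms minimise a closest-point data term plus a
    stiffness term penalising differences between neighbouring vertex
    transforms, solved to convergence at each level of the decreasing
    ``stiffness_schedule``.  The result keeps the template's exact
    vertex/face count whatever the target's resolution.
    """
    sched = list(stiffness_schedule)
    if not sched:
        raise ValueError("stiffness schedule is empty")
    if any(s <= 0 for s in sched):
        raise ValueError("stiffness values must be positive")
    if any(b >= a for a, b in zip(sched, sched[1:])):
        raise ValueError("stiffness schedule must be strictly decreasing")

    if rigid_first:
        rigid, _, aligned = rigid_icp(template, target, with_scale=with_scale)
    else:
        rigid = RigidTransform(rotation=np.eye(3), translation=np.zeros(3))
        aligned = template

    src = aligned.to_trimesh()
    tgt = target.to_trimesh()
    # generous threshold: craniofacial meshes are mm-scale, reject nothing nearby
    threshold = float(np.ptp(target.vertices, axis=0).max())
    steps = [[ws, 0.0, 0.0, inner_iterations] for ws in sched]
    try:
        fitted = trimesh.registration.nricp_amberg(
            src, tgt, steps=steps, eps=1e-5, distance_threshold=threshold,
            use_faces=False)
    except Exception as exc:
        raise RuntimeError(f"non-rigid ICP solve failed: {exc}") from exc

    deformed = template.with_vertices(np.asarray(fitted))
    residuals = surface_distance(deformed, target).distances
    return Correspondence(deformed_template=deformed, residuals=residuals,
                          rigid_transform=rigid)
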