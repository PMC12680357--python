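"""Quasi-static spring-distraction simulator.

Maps an osteotomised skull and a surgical configuration to a deformed
post-operative mesh.  Cranioplasty springs are Hookean distractors that
push the two sides of the parietal osteotomy apart: each exerts an
outward force F = k (L0 - x) while compressed (x < L0) and no force once
fully expanded.

The tissue response is a linear quasi-static shell solve: minimise
    E(u) = 1/2 u^T (alpha * (L_w + bending * L_w^2) + beta * I) u - f^T u
over the free vertices, where L_w is the edge-weighted graph Laplacian of
the skull mesh (applied per coordinate; the three components decouple).
The Laplacian is the membrane term; its square is the plate-bending term
that spreads point loads into a smooth, plate-like response.  u = 0 is
clamped on the skull-base ring.  Edge weights soften the suture bands
(default 1/10 of bone) and the excised osteotomy strip (default 1/50),
and the global stiffness scales linearly with patient age (older bone is
stiffer).

Spring force and notch opening are coupled self-consistently by damped
fixed-point iteration: forces are evaluated at the current notch
separation, the linear system re-solved, and the separation updated until
it changes by less than the tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from cranioplan.anatomy import SkullModel
from cranioplan.mesh import TriangleMesh

__all__ = [
    "SpringSpec",
    "SPRING_CATALOGUE",
    "SurgicalConfig",
    "SolverOptions",
    "SimResult",
    "spring_force",
    "equilibrium_opening",
    "simulate",
    "condensed_tissue_stiffness",
    "solve_spring_balance",
]


@dataclass(frozen=True)
class SpringSpec:
    """A distractor spring: Hookean stiffness (N/mm) and free length (mm)."""

    stiffness: float
    free_length: float = 60.0
    model_name: str = "custom"

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("spring stiffness must be positive")
        if self.free_length <= 0:
            raise ValueError("spring free length must be positive")


#: Three-model spring catalogue.  All models share the 60 mm free opening of
#: the clinical distractors; the stiffness values are configurable
#: placeholders (the manufacturer's per-model constants are not published).
SPRING_CATALOGUE: tuple[SpringSpec, ...] = (
    SpringSpec(stiffness=0.5, free_length=60.0, model_name="model-1"),
    SpringSpec(stiffness=1.0, free_length=60.0, model_name="model-2"),
    SpringSpec(stiffness=1.5, free_length=60.0, model_name="model-3"),
)

# osteotomy parameter bounds (ratios of the reference skull length)
A_RANGE = (0.18, 0.30)
AP_RANGE = (0.47, 0.63)
LAT_RANGE = (0.10, 0.25)


@dataclass(frozen=True)
class SurgicalConfig:
    """Osteotomy ratios plus the anterior and posterior spring choices.

    A, AP are the distances from the coronal-suture reference point to
    the anterior and posterior notch pairs; LAT is the osteotomy width.
    All three are ratios of the reference skull length L.
    """

    A: float
    AP: float
    LAT: float
    anterior_spring: SpringSpec
    posterior_spring: SpringSpec

    def __post_init__(self) -> None:
        for name, val, (lo, hi) in (("A", self.A, A_RANGE), ("AP", self.AP, AP_RANGE),
                                    ("LAT", self.LAT, LAT_RANGE)):
            if not (lo <= val <= hi):
                raise ValueError(f"{name}={val} outside allowed range [{lo}, {hi}]")
        if self.AP <= self.A:
            raise ValueError("AP must exceed A")


@dataclass
class SolverOptions:
    alpha: float = 0.023         # membrane (Laplacian) weight at the reference age
    bending: float = 100.0       # plate term: bending * L^2 added to L (dimensionless)
    beta: float = 1e-3           # Tikhonov anchor keeping the free system non-singular
    suture_ratio: float = 0.1    # suture-band weight relative to bone
    cut_ratio: float = 0.02      # osteotomy cut-line weight relative to bone
    reference_age_days: float = 174.0
    age_scaling: bool = True     # alpha scales with age_days / reference_age
    tol: float = 1e-4            # fixed-point convergence on opening change (mm)
    max_iter: int = 100
    relaxation: float = 0.3      # damping of the fixed-point update
    clamp: bool = True           # springs push only (force floored at zero)
    linearised: bool = False     # single solve with forces at the initial openings


@dataclass
class SimResult:
    postop_mesh: TriangleMesh
    spring_openings: dict[str, float]
    displacement: np.ndarray
    n_iterations: int
    residual: float              # relative linear-solve residual ||K u - f|| / ||f||


def spring_force(spec: SpringSpec, opening: float, clamp: bool = True) -> float:
    """Hookean push-only force F = k (L0 - opening), zero beyond the free length."""
    if opening < 0:
        raise ValueError("opening must be non-negative")
    f = spec.stiffness * (spec.free_length - opening)
    if clamp:
        f = max(f, 0.0)
    return float(f)


def equilibrium_opening(spec: SpringSpec, tissue_stiffness: float) -> float:
    """Opening where the spring force balances a linear tissue resistance c*x.

    Closed form x* = k L0 / (k + c): the unopposed spring (c = 0) expands
    fully, a rigid tissue (c -> inf) keeps the osteotomy shut.
    """
    if tissue_stiffness < 0:
        raise ValueError("tissue stiffness must be non-negative")
    denom = spec.stiffness + tissue_stiffness
    if denom == 0:
        raise ValueError("spring and tissue stiffness cannot both be zero")
    return spec.stiffness * spec.free_length / denom


def solve_spring_balance(opening_fn, specs, initial, tol=1e-4, max_iter=100,
                         relaxation=0.5, clamp=True):
    """Damped fixed-point iteration coupling spring forces and openings.

    ``opening_fn(forces) -> openings`` evaluates the (linear) mechanical
    response to the per-spring force vector.  Returns (openings, forces,
    n_iterations).  Raises on non-convergence.
    """
    x = np.asarray(initial, dtype=float).copy()
    omega = np.full(len(x), relaxation)
    x_prev = d_prev = None
    for it in range(1, max_iter + 1):
        f = np.array([spring_force(s, xi, clamp=clamp) for s, xi in zip(specs, x)])
        d = np.asarray(opening_fn(f), dtype=float)
        step = d - x
        if np.max(np.abs(step)) < tol:
            return x, f, it
        # adaptive relaxation: estimate the local slope m of the opening map
        # from successive iterates; omega = 1/(1 - m) converges in one step
        # for an affine map, so stiff-spring/soft-tissue cases (slope far
        # below -1) stay stable where a fixed damping would oscillate
        if x_prev is not None:
            dx = x - x_prev
            ok = np.abs(dx) > 1e-9
            m = np.where(ok, (d - d_prev) / np.where(ok, dx, 1.0), 0.0)
            omega = np.where(ok & (m < 0.9), 1.0 / (1.0 - np.minimum(m, 0.9)), omega)
            omega = np.clip(omega, 0.02, 1.0)
        x_prev, d_prev = x.copy(), d
        x = x + omega * step
        x = np.maximum(x, 0.0)
    raise RuntimeError(
        f"spring balance did not converge in {max_iter} iterations "
        f"(last opening change {np.max(np.abs(step)):.3e} mm)")


def _edge_weights(skull: SkullModel, opts: SolverOptions):
    """Unique mesh edges with weights from the softer of the two adjacent faces."""
    faces = skull.mesh.faces
    fw = np.ones(len(faces))
    fw[skull.face_labels == "coronal_suture"] = opts.suture_ratio
    fw[skull.face_labels == "lambdoid_suture"] = opts.suture_ratio
    if skull.cut_faces is not None:
        fw[skull.cut_faces] = opts.cut_ratio

    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    w = np.repeat(fw, 3)
    # soft hinge dominates: an edge bordering a cut face is cut-soft
    order = np.lexsort((e[:, 1], e[:, 0]))
    e, w = e[order], w[order]
    uniq, inverse = np.unique(e, axis=0, return_inverse=True)
    wmin = np.full(len(uniq), np.inf)
    np.minimum.at(wmin, inverse, w)
    return uniq, wmin


def _assemble_system(skull: SkullModel, opts: SolverOptions):
    """Reduced stiffness matrix (free vertices) and the index bookkeeping."""
    n = skull.mesh.n_vertices
    edges, w = _edge_weights(skull, opts)
    i, j = edges[:, 0], edges[:, 1]
    W = sp.coo_matrix((np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
                      shape=(n, n)).tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = sp.diags(deg) - W

    alpha = opts.alpha
    if opts.age_scaling:
        alpha = alpha * (skull.params.age_days / opts.reference_age_days)
    # membrane + bending shell: the pure graph Laplacian has a log-singular
    # point-load response that would pile all displacement onto the loaded
    # vertex; the squared-Laplacian term restores plate-like smoothness
    K = (alpha * (L + opts.bending * (L @ L)) + opts.beta * sp.identity(n)).tocsr()

    free = np.setdiff1d(np.arange(n), skull.base_ring)
    return K[free][:, free].tocsc(), free


class _MeshResponse:
    """Linear response of the skull to notch-pair forces, with a cached factorisation."""

    def __init__(self, skull: SkullModel, opts: SolverOptions):
        if skull.notch_vertices is None:
            raise ValueError("skull has no osteotomy: call apply_osteotomy first")
        K_ff, free = _assemble_system(skull, opts)
        self.skull = skull
        self.free = free
        self.pos_in_free = -np.ones(skull.mesh.n_vertices, dtype=int)
        self.pos_in_free[free] = np.arange(len(free))
        self.lu = splu(K_ff)
        self.K_ff = K_ff
        # notch pairs: (right, left) vertex indices; order anterior, posterior
        nv = skull.notch_vertices
        self.pairs = [(nv[0], nv[1]), (nv[2], nv[3])]
        verts = skull.mesh.vertices
        self.dirs = []
        for r, l in self.pairs:
            d = verts[r] - verts[l]
            self.dirs.append(d / np.linalg.norm(d))
        self.initial = np.array([np.linalg.norm(verts[r] - verts[l]) for r, l in self.pairs])

    def displacement(self, forces: np.ndarray) -> np.ndarray:
        n = self.skull.mesh.n_vertices
        rhs = np.zeros((len(self.free), 3))
        for (r, l), dvec, F in zip(self.pairs, self.dirs, forces):
            for vidx, sign in ((r, +1.0), (l, -1.0)):
                p = self.pos_in_free[vidx]
                if p >= 0:
                    rhs[p] += sign * F * dvec
        u_free = self.lu.solve(rhs)
        u = np.zeros((n, 3))
        u[self.free] = u_free
        return u

    def openings(self, forces: np.ndarray) -> np.ndarray:
        u = self.displacement(forces)
        verts = self.skull.mesh.vertices + u
        return np.array([np.linalg.norm(verts[r] - verts[l]) for r, l in self.pairs])

    def residual(self, forces: np.ndarray, u: np.ndarray) -> float:
        rhs = np.zeros((len(self.free), 3))
        for (r, l), dvec, F in zip(self.pairs, self.dirs, forces):
            for vidx, sign in ((r, +1.0), (l, -1.0)):
                p = self.pos_in_free[vidx]
                if p >= 0:
                    rhs[p] += sign * F * dvec
        num = np.linalg.norm(self.K_ff @ u[self.free] - rhs)
        den = np.linalg.norm(rhs)
        return float(num / den) if den > 0 else 0.0


def condensed_tissue_stiffness(skull: SkullModel, opts: SolverOptions | None = None,
                               pair: int = 0) -> float:
    """Tissue stiffness (N/mm) seen by one spring pair, by static condensation.

    Probes the assembled system with a unit equal-and-opposite force pair
    and returns the reciprocal of the separation change — the scalar
    stiffness a spring at that notch pair works against.
    """
    opts = opts or SolverOptions()
    resp = _MeshResponse(skull, opts)
    f = np.zeros(2)
    f[pair] = 1.0
    d = resp.openings(f)
    delta = d[pair] - resp.initial[pair]
    return float(1.0 / delta)


def simulate(skull: SkullModel, config: SurgicalConfig,
             opts: SolverOptions | None = None) -> SimResult:
    """Run the quasi-static spring solve; fully deterministic.

    Forces act as equal-and-opposite pairs at the anterior and posterior
    notch vertices, directed along the initial lateral separation; spring
    force and notch opening are iterated to self-consistency.
    """
    opts = opts or SolverOptions()
    resp = _MeshResponse(skull, opts)
    specs = (config.anterior_spring, config.posterior_spring)

    if opts.linearised:
        forces = np.array([spring_force(s, x0, clamp=opts.clamp)
                           for s, x0 in zip(specs, resp.initial)])
        n_iter = 1
    else:
        openings, forces, n_iter = solve_spring_balance(
            resp.openings, specs, resp.initial,
            tol=opts.tol, max_iter=opts.max_iter,
            relaxation=opts.relaxation, clamp=opts.clamp)

    u = resp.displacement(forces)
    verts = skull.mesh.vertices + u
    final = np.array([np.linalg.norm(verts[r] - verts[l]) for r, l in resp.pairs])
    res = resp.residual(forces, u)
    return SimResult(
        postop_mesh=skull.mesh.with_vertices(verts),
        spring_openings={"anterior": float(final[0]), "posterior": float(final[1])},
        displacement=u,
        n_iterations=n_iter,
        residual=res,
    )
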