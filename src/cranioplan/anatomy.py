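"""Synthetic scaphocephalic skull population.

Real cohorts for spring-assisted cranioplasty come from CT scans and 3D
photographs; none are deposited publicly.  This module generates a
parametric stand-in population: the neurocranium is the upper half of an
ellipsoid in the anatomical frame (x lateral, y anteroposterior with
posterior negative, z superior, base cut at z = 0), with scaphocephaly
severity modelled as a volume-preserving anteroposterior elongation.

Every skull at a given mesh resolution shares one template topology, so
point correspondence across the population holds by construction — the
property the statistical shape model needs.

Population parameter defaults reproduce the published cohort statistics:
skull thickness 2.02 ± 0.33 mm, soft-tissue thickness 3.42 ± 0.51 mm,
age 174 ± 35 days (5.8 ± 1.15 months).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from cranioplan.mesh import TriangleMesh

__all__ = [
    "PatientParams",
    "PopulationSpec",
    "SkullModel",
    "sample_population",
    "build_skull",
    "apply_osteotomy",
    "REGION_LABELS",
]

REGION_LABELS = ("frontal", "parietal", "occipital", "coronal_suture", "lambdoid_suture")

#: notch marks replicate the 5 mm surgical insertion holes
NOTCH_DIAMETER_MM = 5.0


@dataclass(frozen=True)
class PatientParams:
    """Anatomical parameters of one synthetic patient.

    ``semi_axes`` are the (lateral, anteroposterior, vertical) half-widths
    in mm of the base ellipsoid *before* the severity transform;
    ``elongation`` >= 1 stretches y by e and shrinks x and z by 1/sqrt(e),
    which leaves the cranial volume unchanged and divides the cranial
    index by e**1.5.
    """

    age_days: int
    t_skull: float
    t_skin: float
    semi_axes: tuple[float, float, float]
    elongation: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not (90 <= self.age_days <= 300):
            raise ValueError(f"age_days {self.age_days} outside cohort range [90, 300]")
        if self.t_skull <= 0 or self.t_skin <= 0:
            raise ValueError("thicknesses must be positive")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling distributions for :func:`sample_population` (means, SDs, truncations)."""

    t_skull_mean: float = 2.02
    t_skull_sd: float = 0.33
    t_skull_min: float = 0.5
    t_skin_mean: float = 3.42
    t_skin_sd: float = 0.51
    t_skin_min: float = 1.0
    age_mean: float = 174.0
    age_sd: float = 35.0
    age_range: tuple[int, int] = (90, 300)
    # base ellipsoid semi-axes (mm): lateral, anteroposterior, vertical.
    # Patients share one overall size factor (the dominant mode of real
    # cranial variation, removed later by volume normalisation) times
    # small independent per-axis shape residuals.
    ax_mean: float = 60.0
    ay_mean: float = 80.0
    az_mean: float = 60.0
    size_sd: float = 0.05        # relative SD of the common size factor
    shape_sd: float = 0.025      # relative SD of each per-axis residual
    elongation_mean: float = 1.15
    elongation_sd: float = 0.02  # severity spread (~1.7 cranial-index points)
    # template construction
    suture_fractions: tuple[float, float] = (0.30, 0.85)
    suture_width: float = 2.0
    resolution: tuple[int, int] = (50, 40)
    # parietal-eminence bulge: heads are widest a little above the skull
    # base, so the widest section must not lie on the fixed base ring
    bulge: float = 0.015
    bulge_height: float = 0.35   # peak elevation as a fraction of skull height

    def to_json(self, path: str | Path) -> None:
        d = {k: list(v) if isinstance(v, tuple) else v for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PopulationSpec":
        d = json.loads(Path(path).read_text())
        for k in ("age_range", "suture_fractions", "resolution", "semi_axes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -np.inf, hi: float = np.inf, size: int = 1) -> np.ndarray:
    """Rejection-sampled truncated normal; cheap at these mild truncations."""
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = (draw > lo) & (draw < hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def sample_population(n: int, seed: int, spec: PopulationSpec | None = None) -> list[PatientParams]:
    """Draw ``n`` patients from the population distributions, deterministically in ``seed``."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    spec = spec or PopulationSpec()
    rng = np.random.default_rng(seed)
    t_skull = _truncated_normal(rng, spec.t_skull_mean, spec.t_skull_sd, lo=spec.t_skull_min, size=n)
    t_skin = _truncated_normal(rng, spec.t_skin_mean, spec.t_skin_sd, lo=spec.t_skin_min, size=n)
    age = np.rint(_truncated_normal(rng, spec.age_mean, spec.age_sd,
                                    lo=spec.age_range[0] - 0.5, hi=spec.age_range[1] + 0.5, size=n))
    age = np.clip(age, spec.age_range[0], spec.age_range[1]).astype(int)
    size = _truncated_normal(rng, 1.0, spec.size_sd, lo=0.7, size=n)
    ax = spec.ax_mean * size * _truncated_normal(rng, 1.0, spec.shape_sd, lo=0.85, size=n)
    ay = spec.ay_mean * size * _truncated_normal(rng, 1.0, spec.shape_sd, lo=0.85, size=n)
    az = spec.az_mean * size * _truncated_normal(rng, 1.0, spec.shape_sd, lo=0.85, size=n)
    elong = _truncated_normal(rng, spec.elongation_mean, spec.elongation_sd, lo=1.0, size=n)
    return [
        PatientParams(
            age_days=int(age[i]),
            t_skull=float(t_skull[i]),
            t_skin=float(t_skin[i]),
            semi_axes=(float(ax[i]), float(ay[i]), float(az[i])),
            elongation=float(elong[i]),
            seed=seed + i,
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# template hemisphere and arc-length machinery


def _hemisphere_template(n_u: int, n_v: int):
    """Structured triangulation of the unit upper-half sphere.

    Parameterisation: u in (0, pi) is the polar angle from the anterior
    pole (+y) to the posterior pole (-y); v in [0, pi] sweeps from the
    right base (x > 0, z = 0) over the vertex of the skull to the left
    base.  Unit coordinates: y = cos u, x = sin u cos v, z = sin u sin v.
    The midsagittal midline is the v = pi/2 parameter curve, which makes
    arc-length measurements for suture and osteotomy placement direct.

    Returns (unit_vertices, faces, u_param, v_param, base_ring_indices).
    """
    us = np.linspace(0.0, np.pi, n_u + 1)[1:-1]          # interior rows
    vs = np.linspace(0.0, np.pi, n_v + 1)
    uu, vv = np.meshgrid(us, vs, indexing="ij")
    grid_y = np.cos(uu)
    grid_x = np.sin(uu) * np.cos(vv)
    grid_z = np.sin(uu) * np.sin(vv)

    n_rows, n_cols = uu.shape
    verts = [np.array([0.0, 1.0, 0.0]), np.array([0.0, -1.0, 0.0])]  # poles
    u_par = [0.0, np.pi]
    v_par = [np.pi / 2, np.pi / 2]
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols) + 2
    verts.extend(np.column_stack([grid_x.ravel(), grid_y.ravel(), grid_z.ravel()]))
    u_par.extend(uu.ravel())
    v_par.extend(vv.ravel())

    faces = []
    # anterior pole fan
    for j in range(n_cols - 1):
        faces.append([0, idx[0, j], idx[0, j + 1]])
    # interior quads
    for i in range(n_rows - 1):
        for j in range(n_cols - 1):
            a, b = idx[i, j], idx[i, j + 1]
            c, d = idx[i + 1, j], idx[i + 1, j + 1]
            faces.append([a, c, b])
            faces.append([b, c, d])
    # posterior pole fan
    for j in range(n_cols - 1):
        faces.append([1, idx[-1, j + 1], idx[-1, j]])

    base = np.concatenate([[0, 1], idx[:, 0], idx[:, -1]])
    return (np.array(verts), np.array(faces, dtype=np.int64),
            np.array(u_par), np.array(v_par), np.sort(base))


def _midline_arc_table(B: float, C: float, n: int = 2048):
    """Cumulative arc length of the midsagittal curve (y = B cos u, z = C sin u)."""
    u = np.linspace(0.0, np.pi, n)
    integrand = np.sqrt((B * np.sin(u)) ** 2 + (C * np.cos(u)) ** 2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(u))])
    return u, s


def _bulge_factor(zeta: np.ndarray, bulge: float, height: float) -> np.ndarray:
    """Lateral widening profile g(z/C): 1 at the base, 1 + bulge at the peak."""
    t = np.asarray(zeta) / height
    return 1.0 + bulge * t * np.exp(1.0 - t)


def _lateral_arc_rows(A: float, C: float, u_rows: np.ndarray,
                      bulge: float, height: float, n: int = 720):
    """Signed lateral arc length from the midline (v = pi/2) for each grid row.

    The cross-section at polar angle u is
    (x, z) = sin(u) * (A g(z/C) cos v, C sin v); with the bulge the arc
    no longer scales simply with sin(u), so each row is integrated
    numerically.  Positive toward x > 0 (v < pi/2).
    """
    v = np.linspace(0.0, np.pi, n)
    su = np.sin(u_rows)[:, None]
    zeta = su * np.sin(v)[None, :]
    x = A * _bulge_factor(zeta, bulge, height) * su * np.cos(v)[None, :]
    z = C * zeta
    seg = np.sqrt(np.diff(x, axis=1) ** 2 + np.diff(z, axis=1) ** 2)
    cum = np.concatenate([np.zeros((len(u_rows), 1)), np.cumsum(seg, axis=1)], axis=1)
    mid = np.array([np.interp(np.pi / 2, v, c) for c in cum])
    return v, mid[:, None] - cum  # positive for v < pi/2


@dataclass
class SkullModel:
    """A synthetic skull mesh with anatomical annotations.

    ``face_labels`` assigns each face one of :data:`REGION_LABELS`.  The
    osteotomy (applied by :func:`apply_osteotomy`) is carried as boolean
    face masks — the cut line is softened, not removed, by the simulator —
    plus the four spring-notch sites.
    """

    mesh: TriangleMesh
    face_labels: np.ndarray
    reference_point: np.ndarray          # centre of the coronal suture
    base_ring: np.ndarray                # vertex indices fixed in the simulator
    params: PatientParams
    # parameter-space bookkeeping (shared-topology construction)
    vertex_u: np.ndarray = field(repr=False, default=None)
    vertex_v: np.ndarray = field(repr=False, default=None)
    arc_length_L: float = 0.0            # reference point -> lambdoid suture, along midline
    bulge: float = 0.0
    bulge_height: float = 0.35
    # osteotomy annotations (set by apply_osteotomy)
    osteotomy_faces: np.ndarray | None = field(repr=False, default=None)
    cut_faces: np.ndarray | None = field(repr=False, default=None)
    notch_sites: np.ndarray | None = None        # (4, 3) corner points, order: ant-R, ant-L, post-R, post-L
    notch_vertices: np.ndarray | None = None     # nearest mesh vertex per notch
    notch_faces: np.ndarray | None = field(repr=False, default=None)

    def labels_to_csv(self, path: str | Path) -> None:
        """Export region labels as ``face_index,label`` rows."""
        with open(path, "w") as fh:
            fh.write("face_index,label\n")
            for i, lab in enumerate(self.face_labels):
                fh.write(f"{i},{lab}\n")

    def _scaled_axes(self) -> tuple[float, float, float]:
        ax, ay, az = self.params.semi_axes
        e = self.params.elongation
        return ax / np.sqrt(e), ay * e, az / np.sqrt(e)


def build_skull(params: PatientParams, spec: PopulationSpec | None = None) -> SkullModel:
    """Construct the annotated half-ellipsoid skull for one patient.

    The mesh topology depends only on the resolution in ``spec``, so all
    patients built at one resolution are in exact point correspondence.
    Suture bands are placed at the configured fractions of the
    anteroposterior extent (measured from the anterior pole) and are
    ``suture_width`` mm wide along the midline arc.
    """
    spec = spec or PopulationSpec()
    n_u, n_v = spec.resolution
    unit_verts, faces, u_par, v_par, base = _hemisphere_template(n_u, n_v)

    A, B, C = (params.semi_axes[0] / np.sqrt(params.elongation),
               params.semi_axes[1] * params.elongation,
               params.semi_axes[2] / np.sqrt(params.elongation))
    verts = unit_verts * np.array([A, B, C])
    # parietal-eminence widening, x only: the widest section sits above the
    # (later Dirichlet-fixed) base ring
    verts[:, 0] *= _bulge_factor(unit_verts[:, 2], spec.bulge, spec.bulge_height)
    mesh = TriangleMesh(verts, faces)

    u_tab, s_tab = _midline_arc_table(B, C)

    def u_at_y_fraction(frac: float) -> float:
        # fraction of the anteroposterior extent from the anterior pole
        y = B * (1.0 - 2.0 * frac)
        return float(np.arccos(np.clip(y / B, -1.0, 1.0)))

    u_cor = u_at_y_fraction(spec.suture_fractions[0])
    u_lam = u_at_y_fraction(spec.suture_fractions[1])
    s_of = lambda u: np.interp(u, u_tab, s_tab)
    half_w = spec.suture_width / 2.0

    # label faces by the midline-arc interval they span (so bands at least
    # one face-row wide survive coarse meshes)
    face_u = u_par[faces]
    s_min = s_of(face_u.min(axis=1))
    s_max = s_of(face_u.max(axis=1))
    s_cor, s_lam = s_of(u_cor), s_of(u_lam)

    labels = np.full(len(faces), "parietal", dtype="<U16")
    labels[s_max <= s_cor - half_w] = "frontal"
    labels[s_min >= s_lam + half_w] = "occipital"
    in_cor = (s_max >= s_cor - half_w) & (s_min <= s_cor + half_w)
    in_lam = (s_max >= s_lam - half_w) & (s_min <= s_lam + half_w)
    labels[in_cor] = "coronal_suture"
    labels[in_lam] = "lambdoid_suture"

    ref = np.array([0.0, B * np.cos(u_cor), C * np.sin(u_cor)])
    L = float(s_of(u_lam) - s_of(u_cor))

    return SkullModel(
        mesh=mesh,
        face_labels=labels,
        reference_point=ref,
        base_ring=base,
        params=params,
        vertex_u=u_par,
        vertex_v=v_par,
        arc_length_L=L,
        bulge=spec.bulge,
        bulge_height=spec.bulge_height,
    )


def _surface_coords(skull: SkullModel):
    """Per-vertex (s, l): midline arc from the reference point, signed lateral arc."""
    A, B, C = skull._scaled_axes()
    u_tab, s_tab = _midline_arc_table(B, C)
    u_cor = float(np.arccos(np.clip(skull.reference_point[1] / B, -1.0, 1.0)))
    s = np.interp(skull.vertex_u, u_tab, s_tab) - np.interp(u_cor, u_tab, s_tab)

    u_rows = np.unique(skull.vertex_u)
    v_grid, l_rows = _lateral_arc_rows(A, C, u_rows, skull.bulge, skull.bulge_height)
    lat = np.empty(len(skull.vertex_u))
    for i, u in enumerate(u_rows):
        sel = skull.vertex_u == u
        lat[sel] = np.interp(skull.vertex_v[sel], v_grid, l_rows[i])
    return s, lat


def apply_osteotomy(skull: SkullModel, config) -> SkullModel:
    """Mark the parietal osteotomy and its four spring notches on a skull.

    The rectangle is laid out in surface coordinates measured from the
    coronal-suture reference point: anterior edge at A*L, posterior edge
    at AP*L along the midline arc, half-width LAT*L/2 to each side, where
    L is the midline arc length from the reference point to the lambdoid
    suture.  The faces inside the rectangle are the excised bone strip the
    simulator softens; corner marks of 5 mm diameter are the spring
    insertion notches.
    """
    if config.AP <= config.A:
        raise ValueError(f"AP ({config.AP}) must exceed A ({config.A}): posterior "
                         "notches cannot sit anterior to the anterior ones")
    out = replace(skull, mesh=skull.mesh.copy(), face_labels=skull.face_labels.copy())
    L = skull.arc_length_L
    s, lat = _surface_coords(skull)
    faces = skull.mesh.faces
    fs = s[faces].mean(axis=1)
    flat = lat[faces].mean(axis=1)

    s_ant, s_post = config.A * L, config.AP * L
    half_w = config.LAT * L / 2.0

    inside = (fs >= s_ant) & (fs <= s_post) & (np.abs(flat) <= half_w)

    corners = np.array([
        [s_ant, +half_w], [s_ant, -half_w],
        [s_post, +half_w], [s_post, -half_w],
    ])
    d2 = (fs[:, None] - corners[:, 0]) ** 2 + (flat[:, None] - corners[:, 1]) ** 2
    notch_faces = (d2 <= (NOTCH_DIAMETER_MM / 2.0) ** 2).any(axis=1)

    # Notch sites sit at the rectangle corners.  The spring force must act
    # on solid bone beside the cut (the bone strip inside the rectangle is
    # excised and carries no load), so the force-bearing vertex for each
    # notch is the nearest vertex laterally outside the softened band.
    edge = np.median(np.linalg.norm(
        skull.mesh.vertices[faces[:, 0]] - skull.mesh.vertices[faces[:, 1]], axis=1))
    outside = np.abs(lat) >= half_w + 0.5 * edge
    vd2 = (s[:, None] - corners[:, 0]) ** 2 + (lat[:, None] - corners[:, 1]) ** 2
    notch_sites_v = np.argmin(vd2, axis=0)
    vd2_out = np.where(outside[:, None], vd2, np.inf)
    notch_vertices = np.argmin(vd2_out, axis=0)
    notch_sites = skull.mesh.vertices[notch_sites_v]

    bad = set(skull.face_labels[inside]) - {"parietal"}
    if bad:
        # tolerate edge faces straddling a suture, but a rectangle escaping
        # the parietal bone is a configuration error
        frac = np.mean(skull.face_labels[inside] == "parietal")
        if frac < 0.8:
            raise ValueError(f"osteotomy rectangle leaves the parietal bone (labels: {bad})")

    out.osteotomy_faces = inside
    out.cut_faces = inside.copy()   # whole excised strip is softened
    out.notch_faces = notch_faces
    out.notch_sites = notch_sites
    out.notch_vertices = notch_vertices
    return out
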