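"""Template construction and bending-energy sliding of semi-landmarks.

The core workflow: a template surface carries a small set of fixed anatomical
landmarks plus a dense cloud of semi-landmarks seeded from a prominent point
(by default the pronasale, the nose tip).  For each target scan the template
landmarks are transferred by a TPS fitted on the fixed points, projected to
the target surface, and then slid along local tangent structures — a tangent
plane for surface semi-landmarks, the curve tangent for curve semi-landmarks
— so as to minimize the TPS bending energy between the template configuration
and the target configuration.  Because sliding is restricted to tangents the
minimization is a linear least-squares problem at each iteration; the default
schedule runs six cycles with step scales decaying geometrically from 100%
to 5%, re-projecting onto the surface after every cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial import cKDTree

from .errors import CapacityError, GeometryError
from .mesh import (
    TriangleMesh,
    closest_point,
    curve_tangent,
    project_points,
    project_positions,
    surface_tangent_basis,
)
from .tps import EnergyTrace, bending_energy_matrix, fit_tps, warp_points

logger = logging.getLogger(__name__)

#: Table-standard 3D notation codes for the 16 fixed facial landmarks.
DEFAULT_FIXED_NAMES = [
    "enl", "exl", "exr", "enr",  # endo/exocanthions
    "se", "pr", "su",            # sellion, pronasale, subnasale
    "all", "alr",                # alares
    "chl", "chr", "ls", "li",    # mouth corners + lips
    "gn",                        # gnathion
    "obl", "obr",                # obelions
]

FIXED = "fixed"
SURFACE = "surface"
CURVE = "curve"

#: accepted aliases for the prominent (seeding) landmark
_PROMINENT_ALIASES = {"pronasale": "pr", "nose tip": "pr"}

# hexagonal packing density of equal disks in the plane
_HEX_DENSITY = np.pi / (2.0 * np.sqrt(3.0))


@dataclass
class TemplateScheme:
    """The reference object: template mesh, named landmarks, per-point kind.

    Landmarks are ordered fixed-first; curve semi-landmarks carry a curve id
    and an ordering along their curve.
    """

    mesh: TriangleMesh
    landmark_names: List[str]
    kinds: List[str]  # per landmark: fixed | surface | curve
    coords: np.ndarray  # (k, 3) template positions, mm
    curves: Dict[str, List[int]] = field(default_factory=dict)
    prominent_name: str = "pr"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.prominent_name = _PROMINENT_ALIASES.get(
            self.prominent_name, self.prominent_name
        )
        if len(self.landmark_names) != len(self.coords) or len(self.kinds) != len(
            self.coords
        ):
            raise ValueError("names, kinds, and coords must have equal length")
        fixed = self.fixed_names
        if len(set(fixed)) != len(fixed):
            raise ValueError("fixed landmark names must be unique")

    # ------------------------------------------------------------------ #
    @property
    def n_landmarks(self) -> int:
        return len(self.coords)

    @property
    def fixed_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == FIXED], dtype=int)

    @property
    def semi_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k != FIXED], dtype=int)

    @property
    def fixed_names(self) -> List[str]:
        return [self.landmark_names[i] for i in self.fixed_indices]

    @property
    def fixed_coords(self) -> np.ndarray:
        return self.coords[self.fixed_indices]

    @property
    def semi_coords(self) -> np.ndarray:
        return self.coords[self.semi_indices]

    @property
    def prominent_coord(self) -> np.ndarray:
        i = self.landmark_names.index(self.prominent_name)
        return self.coords[i]

    def validate(self, tol: float = 1e-6) -> None:
        """All landmarks must lie on the template surface (within tol, mm)."""
        proj = project_positions(self.mesh, self.coords)
        d = np.linalg.norm(proj - self.coords, axis=1)
        if d.max() > tol:
            bad = int(np.argmax(d))
            raise GeometryError(
                f"landmark {self.landmark_names[bad]!r} is {d.max():.3g} mm off the "
                f"template surface (tolerance {tol} mm)"
            )


@dataclass
class LandmarkConfiguration:
    """One specimen's landmark coordinates, ordered as the scheme."""

    specimen_id: str
    coords: np.ndarray  # (k, 3) mm
    provenance: List[str]  # digitized | warped | slid | projected

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for specimen {self.specimen_id}")
        if len(self.provenance) != len(self.coords):
            raise ValueError("provenance must have one entry per landmark")


# ---------------------------------------------------------------------- #
# Semi-landmark seeding
# ---------------------------------------------------------------------- #

def equilibrium_spacing(area: float, n: int) -> float:
    """Hexagonal-packing spacing for n points on an area (mm)."""
    return float(np.sqrt(2.0 * area / (np.sqrt(3.0) * n)))


def _random_surface_points(mesh: TriangleMesh, m: int, rng) -> np.ndarray:
    """Area-weighted uniform random points on the surface."""
    w = mesh.face_areas / mesh.face_areas.sum()
    fi = rng.choice(len(mesh.faces), size=m, p=w)
    r1 = np.sqrt(rng.random(m))
    r2 = rng.random(m)
    b = np.stack([1 - r1, r1 * (1 - r2), r1 * r2], axis=1)
    return np.einsum("mk,mkj->mj", b, mesh.triangles[fi])


def seed_semilandmarks(
    mesh: TriangleMesh,
    prominent_point: np.ndarray,
    n: int,
    spacing_radius: float = 1.5,
    region_faces: Optional[Sequence[int]] = None,
    seed: int = 0,
    n_relax: int = 60,
) -> np.ndarray:
    """Place n semi-landmarks quasi-uniformly on the mesh (or a face region).

    Points are first placed at random (seeded) on the surface, then spread by
    farthest-point propagation starting from the prominent point followed by
    iterative tangential repulsion with surface re-projection, approximating
    the hexagonal equilibrium spacing for (n, region area).  Raises
    :class:`CapacityError` when n disks of ``spacing_radius`` cannot fit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    surf = mesh if region_faces is None else mesh.submesh(region_faces)
    prominent = np.asarray(prominent_point, dtype=np.float64).reshape(3)
    area = surf.area
    max_n = int(np.floor(_HEX_DENSITY * area / (np.pi * spacing_radius**2)))
    if n > max_n:
        raise CapacityError(
            f"region area {area:.1f} mm^2 fits at most {max_n} points of radius "
            f"{spacing_radius} mm, requested {n}",
            max_feasible=max_n,
        )
    if n == 1:
        return prominent[None, :].copy()

    rng = np.random.default_rng(seed)
    m = max(4000, 40 * n)
    cand = _random_surface_points(surf, m, rng)

    # farthest-point propagation seeded at the prominent point (which is the
    # anchor, not itself a returned semi-landmark)
    dist = np.linalg.norm(cand - prominent, axis=1)
    chosen = np.empty(n, dtype=int)
    for j in range(n):
        chosen[j] = int(np.argmax(dist))
        d_new = np.linalg.norm(cand - cand[chosen[j]], axis=1)
        np.minimum(dist, d_new, out=dist)
    pts = cand[chosen].copy()

    # tangential repulsion toward the equilibrium spacing
    s_eq = equilibrium_spacing(area, n)
    sps = project_points(surf, pts)
    pts = np.array([sp.position for sp in sps])
    for it in range(n_relax):
        tree = cKDTree(pts)
        pairs = tree.query_pairs(1.4 * s_eq, output_type="ndarray")
        if len(pairs) == 0:
            break
        move = np.zeros_like(pts)
        delta = pts[pairs[:, 0]] - pts[pairs[:, 1]]
        d = np.linalg.norm(delta, axis=1)
        d = np.where(d == 0, 1e-9, d)
        overlap = np.clip(s_eq - d, 0.0, None)
        push = (0.4 * overlap / d)[:, None] * delta
        np.add.at(move, pairs[:, 0], push)
        np.add.at(move, pairs[:, 1], -push)
        # keep the motion tangential, then re-project onto the surface
        from .mesh import surface_normal

        normals = np.array([surface_normal(surf, sp) for sp in sps])
        move -= np.einsum("ij,ij->i", move, normals)[:, None] * normals
        scale = 1.0 - 0.5 * it / max(n_relax - 1, 1)
        sps = project_points(surf, pts + scale * move)
        pts = np.array([sp.position for sp in sps])
    return pts


def build_scheme(
    mesh: TriangleMesh,
    fixed_landmarks: Dict[str, np.ndarray],
    n_semis: int = 484,
    spacing_radius: float = 1.5,
    seed: int = 0,
    prominent_name: str = "pr",
) -> TemplateScheme:
    """Assemble a surface-semi-landmark scheme: fixed points + seeded semis.

    The default configuration — 16 fixed anatomical landmarks plus 484
    surface semi-landmarks at 1.5 mm radius — gives the standard 500-landmark
    facial scheme.
    """
    prominent_name = _PROMINENT_ALIASES.get(prominent_name, prominent_name)
    names = list(fixed_landmarks.keys())
    fixed = np.array([fixed_landmarks[k] for k in names], dtype=np.float64)
    prominent = fixed[names.index(prominent_name)]
    semis = seed_semilandmarks(
        mesh, prominent, n_semis, spacing_radius=spacing_radius, seed=seed
    )
    width = max(3, len(str(n_semis)))
    semi_names = [f"s{i + 1:0{width}d}" for i in range(n_semis)]
    scheme = TemplateScheme(
        mesh=mesh,
        landmark_names=names + semi_names,
        kinds=[FIXED] * len(names) + [SURFACE] * n_semis,
        coords=np.vstack([fixed, semis]),
        prominent_name=prominent_name,
    )
    return scheme


# ---------------------------------------------------------------------- #
# Template transfer
# ---------------------------------------------------------------------- #

def transfer_template(
    scheme: TemplateScheme,
    target_mesh: TriangleMesh,
    target_fixed: np.ndarray,
    beta: float = 0.0,
) -> LandmarkConfiguration:
    """Warp the template landmarks to a target scan.

    Fits a TPS from the template fixed landmarks to the digitized target
    fixed landmarks, warps every semi-landmark through it, and projects each
    warped semi-landmark onto the closest point of the target surface.  Fixed
    points are copied verbatim (provenance ``digitized``).
    """
    target_fixed = np.asarray(target_fixed, dtype=np.float64).reshape(-1, 3)
    if len(target_fixed) != len(scheme.fixed_indices):
        raise ValueError("target fixed landmarks do not match the scheme")
    model = fit_tps(scheme.fixed_coords, target_fixed, beta=beta)
    warped = warp_points(model, scheme.semi_coords)
    projected = project_positions(target_mesh, warped)
    coords = np.empty_like(scheme.coords)
    provenance = [""] * scheme.n_landmarks
    coords[scheme.fixed_indices] = target_fixed
    for i in scheme.fixed_indices:
        provenance[i] = "digitized"
    coords[scheme.semi_indices] = projected
    for i in scheme.semi_indices:
        provenance[i] = "projected"
    return LandmarkConfiguration("target", coords, provenance)


# ---------------------------------------------------------------------- #
# Sliding
# ---------------------------------------------------------------------- #

def configuration_energy(B: np.ndarray, coords: np.ndarray) -> float:
    """Bending energy of a configuration relative to the template whose
    bending-energy matrix is B: sum over x,y,z of y_c^T B y_c."""
    return float(np.einsum("ic,ij,jc->", coords, B, coords))


def _tangent_directions(scheme: TemplateScheme, coords: np.ndarray, target_mesh):
    """Allowed sliding directions at the current configuration.

    Returns (point_index_per_parameter, direction_per_parameter (T, 3)).
    """
    idx: List[int] = []
    dirs: List[np.ndarray] = []
    curve_polylines = {
        cid: coords[members] for cid, members in scheme.curves.items()
    }
    curve_pos = {
        (cid, i): j
        for cid, members in scheme.curves.items()
        for j, i in enumerate(members)
    }
    member_curve = {
        i: cid for cid, members in scheme.curves.items() for i in members
    }
    for i in scheme.semi_indices:
        if scheme.kinds[i] == CURVE:
            cid = member_curve[i]
            t = curve_tangent(curve_polylines[cid], curve_pos[(cid, i)])
            idx.append(i)
            dirs.append(t)
        else:
            sp = closest_point(target_mesh, coords[i])
            u, v = surface_tangent_basis(target_mesh, sp)
            idx.extend([i, i])
            dirs.extend([u, v])
    return np.array(idx, dtype=int), np.array(dirs, dtype=np.float64)


def slide_iteration(
    scheme: TemplateScheme,
    config: LandmarkConfiguration,
    target_mesh: TriangleMesh,
    step_scale: float = 1.0,
    B: Optional[np.ndarray] = None,
):
    """One linearized sliding cycle; returns (updated config, energy after).

    Minimizes sum_c (y_c + D_c tau)^T B (y_c + D_c tau) over tangential
    amplitudes tau (surface semis: 2 directions; curve semis: 1), applies
    ``step_scale`` times the optimal displacement, and re-projects every
    moved point onto the target surface.  Fixed landmarks never move.
    """
    if not 0 < step_scale <= 1:
        raise ValueError("step_scale must be in (0, 1]")
    if B is None:
        B = bending_energy_matrix(scheme.coords)
    y = config.coords
    semis = scheme.semi_indices
    if len(semis) == 0:
        return config, configuration_energy(B, y)
    idx, dirs = _tangent_directions(scheme, y, target_mesh)
    # normal matrix A[a,b] = (d_a . d_b) * B[i_a, i_b];  rhs b = -(B y)[i_a] . d_a
    A = B[np.ix_(idx, idx)] * (dirs @ dirs.T)
    rhs = -np.einsum("ac,ac->a", (B @ y)[idx], dirs)
    try:
        tau = cho_solve(cho_factor(A), rhs)
    except np.linalg.LinAlgError:
        logger.warning("singular sliding system; using a ridge-regularized solve")
        ridge = 1e-10 * max(np.trace(A) / len(A), 1e-12)
        tau = np.linalg.solve(A + ridge * np.eye(len(A)), rhs)
    disp = np.zeros_like(y)
    np.add.at(disp, idx, tau[:, None] * dirs)
    e_now = configuration_energy(B, y)
    # monotone safeguard: the linearized move descends, but re-projection onto
    # a curved surface can cost more than a near-converged step gains; halve
    # the applied step until the energy does not increase
    scale = step_scale
    best = None
    for _ in range(8):
        new = y.copy()
        moved = y[semis] + scale * disp[semis]
        new[semis] = project_positions(target_mesh, moved)
        e_new = configuration_energy(B, new)
        if e_new <= e_now + 1e-12 * max(abs(e_now), 1.0):
            best = (new, e_new)
            break
        scale *= 0.5
    if best is None:
        logger.debug("sliding step rejected (re-projection raised the energy)")
        return config, e_now
    new, e_new = best
    provenance = list(config.provenance)
    for i in semis:
        provenance[i] = "slid"
    out = LandmarkConfiguration(config.specimen_id, new, provenance)
    return out, e_new


def step_schedule(n_iter: int = 6, step_start: float = 1.0, step_end: float = 0.05):
    """Geometric decay of the sliding step scale over the cycles."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if n_iter == 1:
        return np.array([step_start])
    j = np.arange(n_iter)
    return step_start * (step_end / step_start) ** (j / (n_iter - 1))


def slide(
    scheme: TemplateScheme,
    config: LandmarkConfiguration,
    target_mesh: TriangleMesh,
    n_iter: int = 6,
    step_start: float = 1.0,
    step_end: float = 0.05,
    B: Optional[np.ndarray] = None,
):
    """Run the full sliding schedule; returns (final config, EnergyTrace).

    Default: six cycles with step scales decaying geometrically from 100% to
    5%.  The trace records the pre-sliding energy and the energy after every
    cycle; semi-landmarks end re-projected on the target surface.
    """
    if B is None:
        B = bending_energy_matrix(scheme.coords)
    scales = step_schedule(n_iter, step_start, step_end)
    trace = EnergyTrace()
    trace.energies.append(configuration_energy(B, config.coords))
    current = config
    for s in scales:
        current, e = slide_iteration(scheme, current, target_mesh, float(s), B=B)
        trace.energies.append(e)
        trace.step_scales.append(float(s))
    provenance = list(current.provenance)
    for i in scheme.semi_indices:
        provenance[i] = "projected"
    current = replace(current, provenance=provenance)
    final_model = fit_tps(scheme.coords, current.coords)
    trace.final_coefficients = final_model.coefficients
    trace.final_affine = final_model.affine_homogeneous
    return current, trace
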