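"""Synthetic face-like meshes and multi-population datasets with known truth.

Real facial-scan collections are licensed; this module emulates their
statistical structure so that every pipeline stage can be exercised and
scored offline.  A parametric half-dome "face" (nose protrusion, eye
depressions, lip ridge) carries the 16 standard fixed anatomical landmarks
at grid nodes (hence exactly on-surface).  Populations and individuals are
smooth TPS deformation fields with energy-bounded, seeded random
coefficients — so true homologous positions of every landmark are carried
through the known deformation — plus an isotropic per-individual scale, an
optional size-coupled (allometric) shape field, and iid digitization noise
on the fixed landmarks of each replicate (the manual step is the error
source; semi-landmark error enters only through the pipeline itself).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .errors import AmplitudeError
from .mesh import TriangleMesh, project_positions
from .sliding import DEFAULT_FIXED_NAMES
from .stats import centroid_size
from .tps import TPSModel, bending_energy, fit_tps, warp_points

# (u, v) parametric positions of the 16 fixed landmarks on the face sheet
_LANDMARK_UV = {
    "enl": (-0.16, 0.34),
    "exl": (-0.46, 0.36),
    "exr": (0.46, 0.36),
    "enr": (0.16, 0.34),
    "se": (0.0, 0.28),
    "pr": (0.0, 0.0),
    "su": (0.0, -0.20),
    "all": (-0.14, -0.10),
    "alr": (0.14, -0.10),
    "chl": (-0.28, -0.44),
    "chr": (0.28, -0.44),
    "ls": (0.0, -0.36),
    "li": (0.0, -0.50),
    "gn": (0.0, -0.72),
    "obl": (-0.22, 0.80),
    "obr": (0.22, 0.80),
}

_HALF_WIDTH_MM = 62.0
_HALF_HEIGHT_MM = 85.0


def _face_height(u: np.ndarray, v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Height field (mm) of the synthetic face over the parametric sheet."""
    z = 32.0 * np.exp(-0.9 * (u**2 + v**2))  # facial dome
    z += 14.0 * np.exp(-((u / 0.11) ** 2 + (v / 0.20) ** 2))  # nose, apex at (0,0)
    for s in (-1.0, 1.0):  # eye sockets
        z -= 3.5 * np.exp(-(((u - s * 0.32) / 0.13) ** 2 + ((v - 0.35) / 0.10) ** 2))
    z += 2.5 * np.exp(-((u / 0.28) ** 2 + ((v + 0.42) / 0.10) ** 2))  # lips
    z += 1.5 * np.exp(-((u / 0.16) ** 2 + ((v + 0.70) / 0.14) ** 2))  # chin
    # seeded large-scale idiosyncrasy (small: the nose tip must stay extremal)
    for _ in range(3):
        amp = rng.uniform(-0.8, 0.8)
        cu, cv = rng.uniform(-0.6, 0.6, size=2)
        z += amp * np.exp(-(((u - cu) / 0.35) ** 2 + ((v - cv) / 0.35) ** 2))
    return z


def make_face_mesh(resolution: int = 32, seed: int = 0):
    """Build a smooth synthetic face mesh and its 16 named anatomical points.

    ``resolution`` is the number of grid intervals per side (>= 16); the grid
    is made odd-noded so the pronasale sits exactly on a vertex.  Returns
    (mesh, dict of landmark name -> (3,) position); all named points are mesh
    vertices, hence exactly on the surface.  The pronasale is the point of
    maximal protrusion along the face (z) axis by construction.
    """
    if resolution < 16:
        raise ValueError("resolution must be >= 16")
    N = resolution + 1
    if N % 2 == 0:
        N += 1
    rng = np.random.default_rng(seed)
    lin = np.linspace(-1.0, 1.0, N)
    u, v = np.meshgrid(lin, lin, indexing="ij")
    z = _face_height(u, v, rng)
    verts = np.stack(
        [_HALF_WIDTH_MM * u.ravel(), _HALF_HEIGHT_MM * v.ravel(), z.ravel()], axis=1
    )
    faces = []
    for i in range(N - 1):
        for j in range(N - 1):
            a = i * N + j
            b = (i + 1) * N + j
            c = (i + 1) * N + j + 1
            d = i * N + j + 1
            faces.append([a, b, c])
            faces.append([a, c, d])
    mesh = TriangleMesh(verts, np.array(faces))
    points: Dict[str, np.ndarray] = {}
    for name in DEFAULT_FIXED_NAMES:
        pu, pv = _LANDMARK_UV[name]
        i = int(round((pu + 1.0) / 2.0 * (N - 1)))
        j = int(round((pv + 1.0) / 2.0 * (N - 1)))
        points[name] = verts[i * N + j].copy()
    return mesh, points


# ---------------------------------------------------------------------- #
# Random smooth deformation fields
# ---------------------------------------------------------------------- #

def _control_points(base_points: Dict[str, np.ndarray]) -> np.ndarray:
    """TPS control points of the deformation fields: the fixed anatomical
    landmarks themselves.

    Anchoring the fields at the anatomical landmarks keeps the simulated
    shape variation concentrated where real facial variation is expressed,
    and makes the true correspondence recoverable in principle from the
    fixed-landmark inputs the pipeline receives — digitization noise is then
    the error source, as in a real study.
    """
    return np.array([base_points[k] for k in base_points])


def random_deformation_field(
    controls: np.ndarray,
    amplitude_mm: float,
    rng: np.random.Generator,
    energy_cap_factor: float = 20.0,
) -> Optional[TPSModel]:
    """A smooth random TPS displacement field with bounded bending energy.

    Control displacements are drawn iid normal, rescaled to RMS amplitude,
    and shrunk if the resulting bending energy exceeds
    ``energy_cap_factor * amplitude^2``.  Returns None for zero amplitude.
    """
    if amplitude_mm <= 0:
        return None
    d = rng.normal(size=controls.shape)
    d *= amplitude_mm / np.sqrt(np.mean(np.sum(d**2, axis=1)))
    model = fit_tps(controls, controls + d)
    cap = energy_cap_factor * amplitude_mm**2
    E = bending_energy(model)
    if E > cap:
        d *= np.sqrt(cap / E)
        model = fit_tps(controls, controls + d)
    return model


def _apply(model: Optional[TPSModel], X: np.ndarray) -> np.ndarray:
    return X if model is None else warp_points(model, X)


# ---------------------------------------------------------------------- #
# Populations
# ---------------------------------------------------------------------- #

@dataclass
class SimulationSpec:
    """Conditions of a simulated multi-population study.

    Defaults mirror a three-population error-assessment design: five subjects
    per population digitized three times each, millimetre-scale smooth
    population and individual deformations, and half-millimetre digitization
    noise on the fixed landmarks.
    """

    seed: int = 0
    resolution: int = 32
    n_populations: int = 3
    subjects_per_population: int = 5
    replicate_count: int = 3
    population_effect_mm: float = 2.5
    individual_sd_mm: float = 1.2
    digitization_sd_mm: float = 0.5
    scale_sd: float = 0.06
    allometric_coeff: float = 0.03  # mm shape displacement per mm of size

    def __post_init__(self) -> None:
        for name in (
            "population_effect_mm",
            "individual_sd_mm",
            "digitization_sd_mm",
            "scale_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


@dataclass
class SyntheticSpecimen:
    """One simulated individual with its ground truth."""

    specimen_id: str
    population: str
    mesh: TriangleMesh
    true_fixed: np.ndarray  # (16, 3)
    digitized_fixed: List[np.ndarray]  # replicate_count noisy copies
    true_semis: Optional[np.ndarray]  # (S, 3) homologues, on the surface
    centroid_size: float
    scale: float


def simulate_population(
    base_mesh: TriangleMesh,
    base_points: Dict[str, np.ndarray],
    spec: SimulationSpec,
    population_index: int,
    semi_coords: Optional[np.ndarray] = None,
) -> List[SyntheticSpecimen]:
    """Simulate one population of individuals derived from the base face.

    Each individual is the base mesh pushed through a population-level smooth
    TPS field, an individual smooth TPS field, an isotropic scale, and an
    allometric displacement coupled to the size change; replicate
    digitizations add iid noise to the fixed landmarks only.  Raises
    :class:`AmplitudeError` if a deformation folds the mesh.
    """
    fixed = np.array([base_points[k] for k in base_points])
    controls = _control_points(base_points)
    cs_base = centroid_size(
        np.vstack([fixed, semi_coords]) if semi_coords is not None else fixed
    )
    rng_pop = np.random.default_rng([spec.seed, 7001, population_index])
    pop_field = random_deformation_field(controls, spec.population_effect_mm, rng_pop)
    allo_rng = np.random.default_rng([spec.seed, 9999])
    allo_field = random_deformation_field(controls, 1.0, allo_rng)  # unit RMS

    specimens = []
    for j in range(spec.subjects_per_population):
        rng = np.random.default_rng([spec.seed, 7002, population_index, j])
        ind_field = random_deformation_field(controls, spec.individual_sd_mm, rng)
        s = float(np.clip(1.0 + rng.normal(0.0, spec.scale_sd), 0.5, 2.0))

        def deform(X):
            X1 = _apply(pop_field, X)
            X2 = _apply(ind_field, X1)
            c = X2.mean(axis=0)
            X3 = c + s * (X2 - c)
            if spec.allometric_coeff > 0 and allo_field is not None:
                delta = spec.allometric_coeff * (s - 1.0) * cs_base
                X3 = X3 + delta * (_apply(allo_field, X3) - X3)
            return X3

        verts = deform(base_mesh.vertices)
        mesh = TriangleMesh(verts, base_mesh.faces.copy())
        dots = np.einsum("ij,ij->i", mesh.face_normals, base_mesh.face_normals)
        if (dots < 0).any():
            raise AmplitudeError(
                "deformation folded the mesh; reduce population_effect_mm / "
                "individual_sd_mm"
            )
        true_fixed = deform(fixed)
        true_semis = None
        if semi_coords is not None:
            true_semis = project_positions(mesh, deform(semi_coords))
        cs = centroid_size(
            np.vstack([true_fixed, true_semis]) if true_semis is not None else true_fixed
        )
        digitized = []
        for r in range(spec.replicate_count):
            rng_rep = np.random.default_rng([spec.seed, 7003, population_index, j, r])
            noise = rng_rep.normal(0.0, spec.digitization_sd_mm, size=true_fixed.shape)
            digitized.append(true_fixed + noise)
        specimens.append(
            SyntheticSpecimen(
                specimen_id=f"pop{population_index}_ind{j}",
                population=f"pop{population_index}",
                mesh=mesh,
                true_fixed=true_fixed,
                digitized_fixed=digitized,
                true_semis=true_semis,
                centroid_size=cs,
                scale=s,
            )
        )
    return specimens


def simulate_study(
    spec: SimulationSpec, semi_coords: Optional[np.ndarray] = None
) -> List[SyntheticSpecimen]:
    """All populations of a study, concatenated."""
    base_mesh, base_points = make_face_mesh(spec.resolution, seed=spec.seed)
    out: List[SyntheticSpecimen] = []
    for p in range(spec.n_populations):
        out.extend(
            simulate_population(base_mesh, base_points, spec, p, semi_coords=semi_coords)
        )
    return out


# ---------------------------------------------------------------------- #
# Pure landmark-level simulation (no meshes) for calibrating statistics
# ---------------------------------------------------------------------- #

def simulate_nested_landmarks(
    n_populations: int,
    n_individuals: int,
    n_replicates: int,
    k: int = 10,
    sigma_pop: float = 2.0,
    sigma_ind: float = 1.0,
    sigma_err: float = 0.5,
    seed: int = 0,
    base_scale: float = 50.0,
):
    """Nested Gaussian landmark data with known variance components.

    Returns (configs (n, k, 3), population, individual, replicate labels).
    Deviations are iid normal per coordinate at each stratum, so the
    variance-component ordering fed in is the ordering a Procrustes ANOVA
    should recover.
    """
    rng = np.random.default_rng(seed)
    base = rng.uniform(-base_scale, base_scale, size=(k, 3))
    configs, pops, inds, reps = [], [], [], []
    for p in range(n_populations):
        dp = rng.normal(0.0, sigma_pop, size=(k, 3))
        for i in range(n_individuals):
            di = rng.normal(0.0, sigma_ind, size=(k, 3))
            for r in range(n_replicates):
                de = rng.normal(0.0, sigma_err, size=(k, 3))
                configs.append(base + dp + di + de)
                pops.append(f"p{p}")
                inds.append(f"i{i}")
                reps.append(f"r{r}")
    return np.array(configs), np.array(pops), np.array(inds), np.array(reps)
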