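r"""3D thin-plate-spline fitting, warping, and bending energy.

The interpolant h : R^3 -> R^3 minimizing the integrated squared second
derivatives subject to h(source_i) = target_i decomposes into a non-affine
part driven by the fundamental kernel U(r) = r (the 3D TPS kernel, the plain
inter-point distance) and an affine part:

    h(q) = Psi(q) K + q A + t

with Psi(q)_w = ||q - source_w||.  K (M x 3) and the affine (A, t) come from
the bordered linear system

    [ Psi + beta I   Q ] [ K     ]   [ target ]
    [ Q^T            0 ] [ Gamma ] = [ 0      ]       Q = [1 | source]

beta = 0 gives exact interpolation; beta > 0 trades fidelity for smoothness.
The side condition Q^T K = 0 makes the bending energy a quadratic form: with
B = -(upper-left M x M block of the inverse system matrix) — the sign makes B
positive semi-definite, since the distance kernel is conditionally *negative*
definite — the energy is

    E = sum_c  target[:, c]^T  B  target[:, c]  =  -tr(K^T Psi K) >= 0

and vanishes exactly on affine maps (the null space of B is spanned by the
constant vector and the three source coordinate columns).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.distance import cdist

from .errors import DegenerateConfigurationError

_COPLANAR_RTOL = 1e-10


@dataclass
class TPSModel:
    """A fitted 3D thin-plate-spline map."""

    source: np.ndarray  # (M, 3)
    target: np.ndarray  # (M, 3)
    kernel: np.ndarray  # (M, M) Psi, entries ||source_w - source_l||
    coefficients: np.ndarray  # (M, 3) non-affine K, Q^T K = 0
    affine: np.ndarray  # (3, 3) linear part A (row-vector convention q @ A)
    translation: np.ndarray  # (3,)
    beta: float
    energy: float

    @property
    def affine_homogeneous(self) -> np.ndarray:
        """The affine part as a 4x4 homogeneous matrix ([q 1] @ G)."""
        G = np.zeros((4, 4))
        G[:3, :3] = self.affine
        G[3, :3] = self.translation
        G[3, 3] = 1.0
        return G

    def to_json(self, path) -> None:
        """Serialize the model (source, target, K, affine, beta, E) for audit."""
        obj = {
            "source": self.source.tolist(),
            "target": self.target.tolist(),
            "coefficients": self.coefficients.tolist(),
            "affine": self.affine.tolist(),
            "translation": self.translation.tolist(),
            "beta": self.beta,
            "energy": self.energy,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "TPSModel":
        with open(path) as fh:
            obj = json.load(fh)
        source = np.array(obj["source"])
        return cls(
            source=source,
            target=np.array(obj["target"]),
            kernel=cdist(source, source),
            coefficients=np.array(obj["coefficients"]),
            affine=np.array(obj["affine"]),
            translation=np.array(obj["translation"]),
            beta=float(obj["beta"]),
            energy=float(obj["energy"]),
        )


@dataclass
class EnergyTrace:
    """Per-iteration bending energies of a sliding run.

    ``energies[0]`` is the pre-sliding (initial) energy E_i and
    ``energies[-1]`` the final energy E_f; one entry is appended per completed
    iteration.  The final non-affine coefficients and affine part of the
    template -> final-configuration map are kept for reporting, together with
    the energy change E_f - E_i (recorded, never applied as a transformation).
    """

    energies: list = field(default_factory=list)
    step_scales: list = field(default_factory=list)
    final_coefficients: Optional[np.ndarray] = None
    final_affine: Optional[np.ndarray] = None

    @property
    def initial_energy(self) -> float:
        return self.energies[0]

    @property
    def final_energy(self) -> float:
        return self.energies[-1]

    @property
    def energy_change(self) -> float:
        """E_f - E_i after the full schedule."""
        return self.final_energy - self.initial_energy

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "iteration": np.arange(len(self.energies)),
                "step_scale": [float("nan")] + list(self.step_scales),
                "energy": self.energies,
            }
        ).to_csv(path, index=False)


# ---------------------------------------------------------------------- #

def _check_source(source: np.ndarray) -> None:
    M = len(source)
    if M < 4:
        raise DegenerateConfigurationError(f"need at least 4 source points, got {M}")
    D = cdist(source, source)
    np.fill_diagonal(D, np.inf)
    diam = float(np.max(np.where(np.isfinite(D), D, 0.0)))
    imin = np.unravel_index(np.argmin(D), D.shape)
    if D[imin] <= 1e-12 * max(diam, 1.0):
        raise DegenerateConfigurationError(
            f"duplicate source points {imin[0]} and {imin[1]}"
        )
    s = np.linalg.svd(source - source.mean(axis=0), compute_uv=False)
    if s[2] <= _COPLANAR_RTOL * s[0]:
        raise DegenerateConfigurationError(
            "source points are (near-)coplanar; the affine part is not identifiable"
        )


def _system_matrix(source: np.ndarray, beta: float) -> np.ndarray:
    # The smoothing term adds beta*I to the kernel block *in the sign
    # convention where the bending-energy quadratic form is PSD*.  The raw
    # 3D distance kernel is conditionally negative definite, so on the raw
    # block the regularizer enters with a minus sign; adding +beta*I to the
    # raw distances would anti-smooth (bending energy would grow with beta).
    M = len(source)
    Psi = cdist(source, source)
    Q = np.hstack([np.ones((M, 1)), source])
    L = np.zeros((M + 4, M + 4))
    L[:M, :M] = Psi - beta * np.eye(M)
    L[:M, M:] = Q
    L[M:, :M] = Q.T
    return L


def fit_tps(source, target, beta: float = 0.0) -> TPSModel:
    """Fit the 3D TPS map source -> target by a dense pivoted direct solve.

    ``beta > 0`` adds beta*I to the kernel block (smoothing); beta = 0 gives
    exact interpolation.  Raises :class:`DegenerateConfigurationError` for
    coplanar or duplicated source points.
    """
    source = np.asarray(source, dtype=np.float64).reshape(-1, 3)
    target = np.asarray(target, dtype=np.float64).reshape(-1, 3)
    if source.shape != target.shape:
        raise ValueError("source and target must have the same shape")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    _check_source(source)
    M = len(source)
    L = _system_matrix(source, beta)
    rhs = np.vstack([target, np.zeros((4, 3))])
    sol = lu_solve(lu_factor(L), rhs)
    K = sol[:M]
    Gamma = sol[M:]
    model = TPSModel(
        source=source,
        target=target,
        kernel=cdist(source, source),
        coefficients=K,
        affine=Gamma[1:4],
        translation=Gamma[0],
        beta=float(beta),
        energy=0.0,
    )
    model.energy = bending_energy(model)
    return model


def warp_points(model: TPSModel, query) -> np.ndarray:
    """Evaluate the fitted map at arbitrary query points (N, 3)."""
    query = np.asarray(query, dtype=np.float64).reshape(-1, 3)
    Psi = cdist(query, model.source)
    return Psi @ model.coefficients + query @ model.affine + model.translation


def bending_energy_matrix(source) -> np.ndarray:
    """The PSD quadratic form B over landmark coordinates giving the TPS
    bending energy: E = sum_c y_c^T B y_c for a target configuration y.

    B is minus the upper-left M x M block of the inverse bordered system (the
    distance kernel is conditionally negative definite, so the raw block is
    NSD); its null space is spanned by {1, x, y, z} of the source.
    """
    source = np.asarray(source, dtype=np.float64).reshape(-1, 3)
    _check_source(source)
    M = len(source)
    L = _system_matrix(source, 0.0)
    Linv = np.linalg.inv(L)
    B = -Linv[:M, :M]
    return 0.5 * (B + B.T)


def bending_energy(model: TPSModel) -> float:
    """Bending energy of a fitted model: -tr(K^T Psi K) >= 0.

    For beta = 0 this equals sum_c target_c^T B target_c with B from
    :func:`bending_energy_matrix`; with smoothing, K comes from the
    regularized solve but the energy is still evaluated through the
    unregularized kernel.
    """
    K = model.coefficients
    return float(-np.einsum("ic,ij,jc->", K, model.kernel, K))
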