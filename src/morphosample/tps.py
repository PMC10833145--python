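"""Thin-plate-spline machinery.

The 2D thin-plate spline with fundamental solution U(r) = r^2 log r gives
(i) a bending-energy quadratic form on landmark displacements, used as the
criterion for sliding semilandmarks, and (ii) exact landmark interpolants
used to draw deformation grids.  Bending energy vanishes exactly on affine
deformations; sliding therefore removes only the arbitrary along-curve
component of semilandmark placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_landmarks import SliderTable

__all__ = [
    "BendingEnergyMatrix",
    "TPSWarp",
    "bending_energy_matrix",
    "bending_energy",
    "tps_warp_from_landmarks",
    "slide_semilandmarks",
    "slide_pass",
]


def _kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r = 0.5 r^2 log r^2, with U(0) = 0
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = 0.5 * r2[nz] * np.log(r2[nz])
    return out


def _build_L(reference: np.ndarray) -> np.ndarray:
    k = reference.shape[0]
    d2 = ((reference[:, None, :] - reference[None, :, :]) ** 2).sum(-1)
    kmat = _kernel(d2)
    q = np.column_stack([np.ones(k), reference])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = kmat
    L[:k, k:] = q
    L[k:, :k] = q.T
    return L


@dataclass
class BendingEnergyMatrix:
    """The k x k bending-energy quadratic form of a reference configuration.

    For a displacement field given per coordinate axis as a k-vector d, the
    bending energy contribution of that axis is d^T B d.  B is symmetric
    positive semidefinite and annihilates affine displacement fields.
    """

    matrix: np.ndarray
    reference: np.ndarray


def bending_energy_matrix(reference: np.ndarray) -> BendingEnergyMatrix:
    """Bending-energy matrix of a reference configuration.

    Computed as the upper-left k x k block of the inverse of the bordered
    TPS system matrix L.  Raises on collinear references (singular system).
    """
    ref = np.asarray(reference, float)
    k = ref.shape[0]
    if k < 4:
        raise ValueError("bending energy needs at least 4 landmarks")
    L = _build_L(ref)
    try:
        linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system: reference landmarks are collinear") from exc
    if not np.all(np.isfinite(linv)):
        raise ValueError("singular TPS system: reference landmarks are collinear")
    b = linv[:k, :k]
    b = 0.5 * (b + b.T)  # enforce exact symmetry
    return BendingEnergyMatrix(matrix=b, reference=ref)


def bending_energy(be: BendingEnergyMatrix, target: np.ndarray) -> float:
    """Bending energy of the deformation taking the reference to ``target``.

    Sum over the x and y displacement fields of the quadratic form.  (The
    form annihilates affine terms, so the target can be passed either as
    absolute coordinates or as a displacement from the reference.)
    """
    t = np.asarray(target, float)
    return float(np.einsum("ki,kl,li->", t, be.matrix, t))


@dataclass
class TPSWarp:
    """Exact TPS interpolant mapping a reference configuration onto a target."""

    reference: np.ndarray
    target: np.ndarray
    affine: np.ndarray  # 3 x 2: rows constant, x, y
    weights: np.ndarray  # k x 2

    def __call__(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, float))
        d2 = ((p[:, None, :] - self.reference[None, :, :]) ** 2).sum(-1)
        u = _kernel(d2)
        q = np.column_stack([np.ones(len(p)), p])
        return q @ self.affine + u @ self.weights

    def grid(self, n: int = 20, pad: float = 0.15) -> tuple[np.ndarray, np.ndarray]:
        """An n x n grid covering the reference (flattened to (n*n, 2)) and its image."""
        lo = self.reference.min(axis=0)
        hi = self.reference.max(axis=0)
        span = hi - lo
        lo = lo - pad * span
        hi = hi + pad * span
        gx, gy = np.meshgrid(np.linspace(lo[0], hi[0], n), np.linspace(lo[1], hi[1], n))
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        return pts, self(pts)


def tps_warp_from_landmarks(reference: np.ndarray, target: np.ndarray) -> TPSWarp:
    """Solve the TPS interpolation problem reference -> target."""
    ref = np.asarray(reference, float)
    tgt = np.asarray(target, float)
    if ref.shape != tgt.shape:
        raise ValueError("reference/target shape mismatch")
    k = ref.shape[0]
    L = _build_L(ref)
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system: reference landmarks are collinear") from exc
    return TPSWarp(reference=ref, target=tgt, affine=sol[k:], weights=sol[:k])


# ---------------------------------------------------------------------------
# Semilandmark sliding
# ---------------------------------------------------------------------------

def _tangents(config: np.ndarray, sliders: SliderTable, specimen_label: str = "") -> np.ndarray:
    """Unit chord directions (before -> after) at each sliding point."""
    b = config[sliders.rows[:, 0]]
    a = config[sliders.rows[:, 2]]
    t = a - b
    norms = np.sqrt((t**2).sum(axis=1))
    bad = np.nonzero(norms == 0)[0]
    if bad.size:
        row = sliders.rows[bad[0]]
        raise ValueError(
            f"zero-length tangent{(' for ' + specimen_label) if specimen_label else ''}:"
            f" slider row (before={row[0]}, slide={row[1]}, after={row[2]}) has coincident neighbours"
        )
    return t / norms[:, None]


def slide_pass(
    aligned: np.ndarray,
    consensus: np.ndarray,
    be: BendingEnergyMatrix,
    sliders: SliderTable,
) -> np.ndarray:
    """One joint sliding step for every specimen against a fixed consensus.

    Each sliding semilandmark moves along its tangent (the unit chord
    between its neighbours in the specimen itself) by the displacement that
    minimises the bending energy of the specimen-to-consensus deformation;
    all sliders of a specimen are solved jointly as one linear system.
    Fixed landmarks never move.  The step never increases bending energy,
    since the quadratic objective is minimised exactly.
    """
    x = np.asarray(aligned, float).copy()
    idx = sliders.sliding_indices
    bmat = be.matrix
    bsub = bmat[np.ix_(idx, idx)]
    for i in range(x.shape[0]):
        u = _tangents(x[i], sliders, specimen_label=f"specimen {i}")
        g = bmat @ (x[i] - consensus)  # k x 2 gradient-like term
        h = bsub * (u @ u.T)
        rhs = -(u * g[idx]).sum(axis=1)
        t, *_ = np.linalg.lstsq(h, rhs, rcond=None)
        x[i, idx] += t[:, None] * u
    return x


def slide_semilandmarks(
    aligned: np.ndarray,
    consensus: np.ndarray,
    sliders: SliderTable,
    iterations: int = 5,
    return_consensus: bool = False,
):
    """Iterative bending-energy sliding with re-superimposition.

    Each pass slides every specimen against the current consensus (whose
    bending-energy matrix is recomputed between passes), then re-centres,
    re-scales, re-rotates, and updates the consensus.
    """
    from .procrustes import optimal_rotations  # local import to avoid cycle

    x = np.asarray(aligned, float).copy()
    cons = np.asarray(consensus, float).copy()
    if len(sliders) == 0:
        return (x, cons) if return_consensus else x
    for _ in range(iterations):
        be = bending_energy_matrix(cons)
        x = slide_pass(x, cons, be, sliders)
        x -= x.mean(axis=1, keepdims=True)
        x /= np.sqrt((x**2).sum(axis=(1, 2)))[:, None, None]
        x = optimal_rotations(x, cons)
        cons = x.mean(axis=0)
        cons /= np.sqrt((cons**2).sum())
    return (x, cons) if return_consensus else x
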