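"""Procrustes superimposition primitives.

Partial Procrustes superimposition in 2D: every configuration is centred and
scaled to unit centroid size, then rotated; no per-specimen rescaling is
applied during rotation and reflections are disallowed by default, so the
alignment removes exactly the similarity transforms (translation, scale,
rotation).  Shape statistics downstream operate on the superimposed
coordinates directly, without projection to a tangent space — at the small
shape variation typical of intraspecific cranial data the difference is
negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_landmarks import LandmarkDataset, SliderTable

__all__ = [
    "GPAResult",
    "GPAConvergenceError",
    "DegenerateShapeError",
    "centroid_size",
    "center",
    "to_preshape",
    "opa_align",
    "optimal_rotations",
    "gpa",
    "mean_shape",
    "procrustes_distance",
]


class DegenerateShapeError(ValueError):
    """All landmarks coincident (zero centroid size) where shape is required."""


class GPAConvergenceError(RuntimeError):
    def __init__(self, iterations: int, last_change: float):
        self.iterations = iterations
        self.last_change = last_change
        super().__init__(f"GPA did not converge in {iterations} iterations (last change {last_change:.3e})")


@dataclass
class GPAResult:
    """Superimposed coordinates and bookkeeping from a GPA run.

    ``aligned`` holds the n x k x 2 consensus-registered configurations at
    unit centroid size; ``centroid_sizes`` are the pre-scaling sizes in the
    original coordinate units; ``consensus`` is the unit-size mean shape.
    """

    aligned: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    iterations: int
    final_change: float
    slid: bool
    ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared distances of landmarks from their centroid."""
    c = np.asarray(config, float)
    centred = c - c.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def center(config: np.ndarray) -> np.ndarray:
    c = np.asarray(config, float)
    return c - c.mean(axis=0)


def to_preshape(config: np.ndarray) -> np.ndarray:
    """Centre and scale to unit centroid size."""
    c = center(config)
    size = np.sqrt((c**2).sum())
    if size == 0.0:
        raise DegenerateShapeError("cannot scale a configuration with zero centroid size")
    return c / size


def _rotation_from_cross(m: np.ndarray, allow_reflection: bool) -> np.ndarray:
    u, s, vt = np.linalg.svd(m)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def opa_align(
    target: np.ndarray, reference: np.ndarray, allow_reflection: bool = False
) -> tuple[np.ndarray, np.ndarray, float]:
    """Ordinary Procrustes alignment of ``target`` onto ``reference``.

    Both inputs must already be centred with unit centroid size.  Returns the
    rotated target, the 2x2 rotation matrix R (applied as ``target @ R``) and
    the partial Procrustes distance (root of the minimised sum of squares).
    The optimal rotation comes from the SVD of the cross-product matrix with
    the usual determinant sign correction when reflections are disallowed.
    """
    t = np.asarray(target, float)
    ref = np.asarray(reference, float)
    if t.shape != ref.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {ref.shape}")
    m = t.T @ ref
    if np.allclose(m, 0):
        raise DegenerateShapeError("rank-0 cross-product matrix")
    r = _rotation_from_cross(m, allow_reflection)
    rotated = t @ r
    dist = float(np.sqrt(((rotated - ref) ** 2).sum()))
    return rotated, r, dist


def optimal_rotations(configs: np.ndarray, reference: np.ndarray, allow_reflection: bool = False) -> np.ndarray:
    """Rotate a stack of centred unit-size configs onto one reference (batched)."""
    x = np.asarray(configs, float)
    m = np.einsum("nki,kj->nij", x, reference)
    u, s, vt = np.linalg.svd(m)
    r = u @ vt
    if not allow_reflection:
        neg = np.linalg.det(r) < 0
        if neg.any():
            u = u.copy()
            u[neg, :, -1] *= -1
            r[neg] = u[neg] @ vt[neg]
    return np.einsum("nki,nij->nkj", x, r)


def gpa(
    data: LandmarkDataset | np.ndarray,
    slide: bool = False,
    sliders: SliderTable | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    slide_passes: int = 5,
    allow_reflection: bool = False,
) -> GPAResult:
    """Generalized Procrustes Analysis, optionally with semilandmark sliding.

    All configurations are centred and scaled to unit centroid size; the
    consensus is initialised as the first specimen and the rotate/average
    cycle repeats until the summed squared change in the consensus falls
    below ``tol``.  With ``slide=True``, bending-energy sliding passes are
    interleaved with re-superimposition until joint convergence.

    Raises :class:`GPAConvergenceError` when ``max_iter`` is exhausted.
    """
    import warnings as _warnings

    ids = None
    if isinstance(data, LandmarkDataset):
        coords = data.coords_array()
        ids = data.ids
        if sliders is None:
            sliders = data.sliders
    else:
        coords = np.asarray(data, float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 specimens")

    sizes = np.empty(n)
    x = np.empty_like(coords, dtype=float)
    for i in range(n):
        c = center(coords[i])
        sizes[i] = np.sqrt((c**2).sum())
        if sizes[i] == 0.0:
            raise DegenerateShapeError(f"specimen {i} has zero centroid size")
        x[i] = c / sizes[i]

    if slide and (sliders is None or len(sliders) == 0):
        _warnings.warn("slide=True but no sliders defined; proceeding without sliding")
        slide = False

    consensus = x[0].copy()
    iterations = 0
    change = np.inf
    for iterations in range(1, max_iter + 1):
        x = optimal_rotations(x, consensus, allow_reflection)
        new = x.mean(axis=0)
        new = new / np.sqrt((new**2).sum())
        change = float(((new - consensus) ** 2).sum())
        consensus = new
        if change < tol:
            break
    else:
        raise GPAConvergenceError(max_iter, change)

    slid = False
    if slide:
        from .tps import slide_semilandmarks  # local import to avoid cycle

        x, consensus = slide_semilandmarks(
            x, consensus, sliders, iterations=slide_passes, return_consensus=True
        )
        # final re-registration so GPAResult invariants hold exactly
        for _ in range(max_iter):
            x = optimal_rotations(x, consensus, allow_reflection)
            new = x.mean(axis=0)
            new = new / np.sqrt((new**2).sum())
            change = float(((new - consensus) ** 2).sum())
            consensus = new
            if change < tol:
                break
        slid = True

    return GPAResult(
        aligned=x,
        centroid_sizes=sizes,
        consensus=consensus,
        iterations=iterations,
        final_change=change,
        slid=slid,
        ids=ids,
    )


def mean_shape(aligned: np.ndarray) -> np.ndarray:
    """Coordinate-wise mean of superimposed configurations."""
    a = np.asarray(aligned, float)
    if a.ndim != 3 or a.shape[0] == 0:
        raise ValueError("need a non-empty n x k x 2 array")
    return a.mean(axis=0)


def procrustes_distance(a: np.ndarray, b: np.ndarray, allow_reflection: bool = False) -> float:
    """Partial Procrustes distance between two configurations.

    Both are centred and scaled to unit centroid size, optimally rotated,
    and the root-sum-of-squares of the remaining coordinate differences is
    returned.  Symmetric in its arguments.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"landmark count mismatch: {a.shape} vs {b.shape}")
    _, _, d = opa_align(to_preshape(a), to_preshape(b), allow_reflection)
    return d
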