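"""Sample-size rarefaction of mean shape, shape variance, and centroid size.

Specimens are repeatedly subsampled without replacement into fraction bins
(by default 100/75/50/25/10% of the sample); every subsample gets its own
self-contained superimposition (GPA, with semilandmark sliding when sliders
exist), and its mean shape and mean log10 centroid size are compared against
the full-sample ("true") values.  The 100% bin is the reference: all its
draws are the complete sample, so its distance to the true mean is exactly
zero in every iteration.

Each (fraction, iteration) draw has its own recorded seed derived from the
base seed, so any single record can be reproduced in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_landmarks import LandmarkDataset
from .procrustes import GPAResult, gpa, opa_align, procrustes_distance, to_preshape
from .stats import PermTestResult, ShapePCA, anova_tukey, dispersion_test, pca_shape
from .tps import tps_warp_from_landmarks

__all__ = [
    "SubsampleRecord",
    "RarefactionSummary",
    "subsample_seed",
    "run_rarefaction",
    "records_to_dataframe",
    "summarize_rarefaction",
    "pc1_grids_for_iterations",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = (1.0, 0.75, 0.5, 0.25, 0.1)


@dataclass
class SubsampleRecord:
    """One rarefaction draw: a (fraction, iteration) subsample and its summaries."""

    fraction: float
    iteration: int
    seed: int
    member_ids: list[str]
    mean_shape: np.ndarray
    mean_log_cs: float
    dist_to_true: float


@dataclass
class RarefactionSummary:
    """The full comparison battery over rarefaction bins."""

    cs_anova: pd.DataFrame
    cs_tukey: pd.DataFrame
    dist_anova: pd.DataFrame | None
    dist_tukey: pd.DataFrame | None
    dispersion_table: pd.DataFrame
    dispersion_results: dict[tuple, PermTestResult]
    pca: ShapePCA
    bin_scores: dict[float, np.ndarray]  # fraction -> (T, 2) PC1/PC2 scores of bin means
    hulls: dict[float, np.ndarray]  # fraction -> hull vertex coordinates in (PC1, PC2)
    hull_areas: dict[float, float]


def subsample_seed(base_seed: int, bin_index: int, iteration: int) -> int:
    """Deterministic audit-able seed for one draw: base*1e6 + bin*1e4 + iteration."""
    return base_seed * 10**6 + bin_index * 10**4 + iteration


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def run_rarefaction(
    dataset: LandmarkDataset,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    T: int = 1000,
    base_seed: int = 1,
    slide: bool = True,
    compute_shapes: bool = True,
    full_gpa: GPAResult | None = None,
) -> tuple[list[SubsampleRecord], GPAResult]:
    """Run the seeded subsampling experiment.

    For every fraction bin and iteration, draws ``round(fraction * n)``
    specimens without replacement (seeded per draw), runs GPA on the
    subsample alone, and records its mean shape, mean log10 centroid size,
    and partial Procrustes distance to the full-sample consensus.  Bins at
    fraction 1.0 reuse the full-sample result (distance exactly 0).

    ``compute_shapes=False`` skips the per-subsample GPA and records only
    centroid-size summaries (mean shapes set to the full consensus and
    distances to NaN) — useful when only the size battery is needed.

    Returns the records plus the full-sample GPA result.
    """
    n = dataset.n
    if n < 10:
        raise ValueError("rarefaction needs at least 10 specimens")
    if T < 1:
        raise ValueError("T must be >= 1")
    for f in fractions:
        if not (0 < f <= 1):
            raise ValueError(f"fraction {f} outside (0, 1]")
        if _round_half_up(f * n) < 3:
            raise ValueError(f"fraction {f} yields fewer than 3 specimens (n={n})")

    do_slide = slide and len(dataset.sliders) > 0
    if full_gpa is None:
        full_gpa = gpa(dataset, slide=do_slide)
    true_consensus = full_gpa.consensus
    log_cs = np.log10(full_gpa.centroid_sizes)
    ids = np.asarray(dataset.ids)

    records: list[SubsampleRecord] = []
    for bin_index, frac in enumerate(fractions):
        m = _round_half_up(frac * n)
        for it in range(1, T + 1):
            seed = subsample_seed(base_seed, bin_index, it)
            if m == n:
                members = np.arange(n)
                mean = true_consensus
                dist = 0.0
            else:
                rng = np.random.default_rng(seed)
                members = np.sort(rng.choice(n, size=m, replace=False))
                if compute_shapes:
                    sub = dataset.subset(members)
                    res = gpa(sub, slide=do_slide)
                    mean = res.consensus
                    dist = procrustes_distance(mean, true_consensus)
                else:
                    mean = true_consensus
                    dist = float("nan")
            records.append(
                SubsampleRecord(
                    fraction=frac,
                    iteration=it,
                    seed=seed,
                    member_ids=ids[members].tolist(),
                    mean_shape=mean,
                    mean_log_cs=float(log_cs[members].mean()),
                    dist_to_true=dist,
                )
            )
    return records, full_gpa


def records_to_dataframe(records: list[SubsampleRecord]) -> pd.DataFrame:
    """Tidy table: one row per subsample draw."""
    return pd.DataFrame(
        {
            "fraction": [r.fraction for r in records],
            "iteration": [r.iteration for r in records],
            "seed": [r.seed for r in records],
            "n_members": [len(r.member_ids) for r in records],
            "mean_log_cs": [r.mean_log_cs for r in records],
            "dist_to_true": [r.dist_to_true for r in records],
            "member_ids": [";".join(r.member_ids) for r in records],
        }
    )


def _hull_vertices(points: np.ndarray) -> tuple[np.ndarray, float]:
    from shapely import MultiPoint

    hull = MultiPoint(points).convex_hull
    if hull.geom_type == "Polygon":
        verts = np.asarray(hull.exterior.coords)[:-1]
        return verts, float(hull.area)
    return np.atleast_2d(np.asarray(hull.coords)), 0.0


def summarize_rarefaction(
    records: list[SubsampleRecord],
    full_gpa: GPAResult,
    n_perm: int = 1000,
    seed: int = 0,
) -> RarefactionSummary:
    """The full comparison battery across rarefaction bins.

    (a) one-way ANOVA + Tukey on mean log10 centroid size by bin; (b) the
    same on distance-to-true (bins whose records are all at zero distance —
    the 100% bin — are excluded from this ANOVA as degenerate); (c) pairwise
    permutation tests on the dispersion of bin mean shapes; (d) projection
    of every subsample mean into the full-sample PCA space (after aligning
    each mean to the full consensus) with 2D convex hulls per bin.
    """
    fractions = sorted({r.fraction for r in records}, reverse=True)
    if len(fractions) < 2:
        raise ValueError("need records from at least 2 bins")
    frac_of = np.asarray([r.fraction for r in records])
    labels = np.asarray([f"{int(round(r.fraction * 100))}%" for r in records])

    mean_log_cs = np.asarray([r.mean_log_cs for r in records])
    cs_anova, cs_tukey = anova_tukey(mean_log_cs, labels)

    dist = np.asarray([r.dist_to_true for r in records])
    keep = np.ones(len(records), bool)
    for f in fractions:
        sel = frac_of == f
        if np.allclose(dist[sel], 0.0):
            keep[sel] = False
    dist_anova = dist_tukey = None
    if len(np.unique(labels[keep])) >= 2:
        dist_anova, dist_tukey = anova_tukey(dist[keep], labels[keep])

    # align every subsample mean to the full consensus so bin means share a frame
    consensus = full_gpa.consensus
    aligned_means = np.stack(
        [opa_align(to_preshape(r.mean_shape), consensus)[0] for r in records]
    )
    disp_table, disp_results = dispersion_test(aligned_means, labels, n_perm=n_perm, seed=seed)

    pca = pca_shape(full_gpa.aligned)
    scores = pca.transform(aligned_means)[:, :2]
    bin_scores: dict[float, np.ndarray] = {}
    hulls: dict[float, np.ndarray] = {}
    areas: dict[float, float] = {}
    for f in fractions:
        pts = scores[frac_of == f]
        bin_scores[f] = pts
        uniq = np.unique(pts.round(15), axis=0)
        if len(uniq) >= 3:
            hulls[f], areas[f] = _hull_vertices(pts)
        else:
            hulls[f], areas[f] = uniq, 0.0

    return RarefactionSummary(
        cs_anova=cs_anova,
        cs_tukey=cs_tukey,
        dist_anova=dist_anova,
        dist_tukey=dist_tukey,
        dispersion_table=disp_table,
        dispersion_results=disp_results,
        pca=pca,
        bin_scores=bin_scores,
        hulls=hulls,
        hull_areas=areas,
    )


@dataclass
class PC1Grid:
    """Deformation grids from a (sub)sample consensus to its PC1 extremes."""

    fraction: float
    iteration: int
    n: int
    grid: np.ndarray  # (g, 2) undeformed grid points
    warped_neg: np.ndarray
    warped_pos: np.ndarray

    @property
    def displacement(self) -> np.ndarray:
        """Concatenated displacement fields toward both PC1 extremes."""
        return np.concatenate(
            [(self.warped_neg - self.grid).ravel(), (self.warped_pos - self.grid).ravel()]
        )


def pc1_grids_for_iterations(
    records: list[SubsampleRecord],
    dataset: LandmarkDataset,
    full_gpa: GPAResult,
    which: list[tuple[float, int]],
    slide: bool = True,
    grid_n: int = 20,
) -> dict[tuple[float, int] | str, PC1Grid]:
    """Thin-plate-spline grids along PC1 for selected subsample draws.

    For every requested (fraction, iteration), re-assembles the recorded
    subsample, runs its own GPA + PCA, and warps the subsample consensus to
    the shapes at the observed PC1 extremes; the full sample gets the same
    treatment under the key ``'full'``.  Grids of different draws share the
    same displacement-field layout, so fields can be correlated directly.
    """
    by_key = {(r.fraction, r.iteration): r for r in records}
    id_pos = {sid: i for i, sid in enumerate(dataset.ids)}
    do_slide = slide and len(dataset.sliders) > 0

    ref_axis: dict[str, np.ndarray] = {}

    def grids_from(aligned: np.ndarray, consensus: np.ndarray, fraction: float, iteration: int) -> PC1Grid:
        # rotate into the full-sample frame: each subsample GPA has its own
        # arbitrary orientation, and displacement fields only compare in a
        # common frame
        _, rot, _ = opa_align(consensus, full_gpa.consensus)
        aligned = aligned @ rot
        consensus = consensus @ rot
        pca = pca_shape(aligned)
        pc1 = pca.scores[:, 0]
        axis = pca.components[0]
        if "full" not in ref_axis:
            ref_axis["full"] = axis
        elif float(axis @ ref_axis["full"]) < 0:
            # PC sign is arbitrary; orient like the full-sample PC1
            axis = -axis
            pc1 = -pc1
            pca.components[0] = axis
            pca.scores[:, 0] = pc1
        lo = pca.shape_at([pc1.min()])
        hi = pca.shape_at([pc1.max()])
        warp_lo = tps_warp_from_landmarks(consensus, lo)
        warp_hi = tps_warp_from_landmarks(consensus, hi)
        # evaluate both warps on the same grid (over the full consensus) so
        # displacement fields from different draws are comparable
        ref = full_gpa.consensus
        span = ref.max(axis=0) - ref.min(axis=0)
        lo_c = ref.min(axis=0) - 0.15 * span
        hi_c = ref.max(axis=0) + 0.15 * span
        gx, gy = np.meshgrid(np.linspace(lo_c[0], hi_c[0], grid_n), np.linspace(lo_c[1], hi_c[1], grid_n))
        grid = np.column_stack([gx.ravel(), gy.ravel()])
        return PC1Grid(
            fraction=fraction,
            iteration=iteration,
            n=aligned.shape[0],
            grid=grid,
            warped_neg=warp_lo(grid),
            warped_pos=warp_hi(grid),
        )

    out: dict[tuple[float, int] | str, PC1Grid] = {
        "full": grids_from(full_gpa.aligned, full_gpa.consensus, 1.0, 0)
    }
    for key in which:
        if key not in by_key:
            raise KeyError(f"no record for (fraction, iteration) = {key}")
        rec = by_key[key]
        if len(rec.member_ids) < 3:
            raise ValueError(f"subsample {key} has fewer than 3 specimens")
        sub = dataset.subset([id_pos[s] for s in rec.member_ids])
        res = gpa(sub, slide=do_slide)
        out[key] = grids_from(res.aligned, res.consensus, rec.fraction, rec.iteration)
    return out
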