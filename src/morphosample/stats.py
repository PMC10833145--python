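"""Statistical layer for shape data.

Shape PCA, Procrustes ANOVA with significance by residual randomization
(RRPP), permutation tests on group dispersion (Procrustes variance),
two-block partial least squares, and classical one-way ANOVA with Tukey HSD.

All permutation tests are seeded and reproducible bit-for-bit for a given
``(seed, n_perm)``; permutation p-values include the observed arrangement,
so p >= 1/n_perm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ShapePCA",
    "PermTestResult",
    "AnovaResult",
    "pca_shape",
    "proc_anova_rrpp",
    "dispersion_test",
    "two_block_pls",
    "PLSResult",
    "anova_tukey",
    "sexual_dimorphism_suite",
]


def _flatten_shapes(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    if x.ndim == 3:
        return x.reshape(x.shape[0], -1)
    if x.ndim == 2:
        return x
    raise ValueError("expected an (n, k, 2) or (n, p) array")


@dataclass
class PermTestResult:
    """Outcome of one permutation test, with enough metadata to audit it."""

    statistic_name: str
    observed: float
    p_value: float
    n_perm: int
    effect_size_z: float
    seed: int
    r_squared: float | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "effect_size_z": self.effect_size_z,
            "r_squared": self.r_squared,
            "seed": self.seed,
        }


def _perm_p_and_z(observed: float, permuted: np.ndarray) -> tuple[float, float]:
    """p as the proportion of the full distribution (observed included) >= observed."""
    all_stats = np.concatenate([[observed], permuted])
    p = float(np.mean(all_stats >= observed - 1e-12))
    sd = all_stats.std()
    z = float((observed - all_stats.mean()) / sd) if sd > 0 else 0.0
    return p, z


# ---------------------------------------------------------------------------
# Shape PCA
# ---------------------------------------------------------------------------

@dataclass
class ShapePCA:
    """Principal components of superimposed shape coordinates.

    ``components`` rows are orthonormal directions in flattened (2k)
    coordinate space; ``scores`` are centred projections of the specimens.
    """

    scores: np.ndarray
    components: np.ndarray
    explained_fraction: np.ndarray
    center: np.ndarray

    def transform(self, shapes: np.ndarray) -> np.ndarray:
        """Project configurations (m x k x 2, k x 2, or m x 2k) into score space."""
        x = np.asarray(shapes, float)
        if x.ndim == 2 and x.shape[1] == 2:
            x = x.reshape(1, -1)
        else:
            x = _flatten_shapes(x)
        return (x - self.center) @ self.components.T

    def shape_at(self, scores: np.ndarray) -> np.ndarray:
        """Reconstruct a k x 2 configuration from a (partial) score vector."""
        s = np.zeros(self.components.shape[0])
        s[: len(scores)] = scores
        flat = self.center + s @ self.components
        return flat.reshape(-1, 2)

    @property
    def n_above(self) -> int:
        """Number of PCs individually explaining more than 10% of variance
        (the usual reporting filter; not a truncation of any analysis)."""
        return int(np.sum(self.explained_fraction > 0.10))


def pca_shape(aligned: np.ndarray) -> ShapePCA:
    """PCA of flattened superimposed coordinates via SVD."""
    x = _flatten_shapes(aligned)
    n = x.shape[0]
    if n < 3:
        raise ValueError("shape PCA needs at least 3 specimens")
    center = x.mean(axis=0)
    xc = x - center
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = (s**2).sum()
    if total == 0:
        raise ValueError("no shape variation")
    q = min(n - 1, vt.shape[0])
    return ShapePCA(
        scores=(u[:, :q] * s[:q]),
        components=vt[:q],
        explained_fraction=s[:q] ** 2 / total,
        center=center,
    )


# ---------------------------------------------------------------------------
# Procrustes ANOVA with RRPP
# ---------------------------------------------------------------------------

def _encode_term(values: np.ndarray) -> np.ndarray:
    """Covariate columns for one model term: numeric as-is, categorical dummy-coded."""
    v = np.asarray(values)
    if v.ndim == 2:
        return v.astype(float)
    if v.dtype.kind in "fiub" and v.dtype.kind != "b":
        return v.astype(float).reshape(-1, 1)
    levels = np.unique(v)
    if len(levels) < 2:
        raise ValueError("categorical term with a single level")
    return np.column_stack([(v == lev).astype(float) for lev in levels[1:]])


def _hat(x: np.ndarray) -> np.ndarray:
    return x @ np.linalg.pinv(x)


@dataclass
class AnovaResult:
    """Sequential (type I) ANOVA table with per-term permutation results."""

    table: pd.DataFrame
    perm_results: dict[str, PermTestResult] = field(default_factory=dict)

    def p(self, term: str) -> float:
        return self.perm_results[term].p_value

    def r_squared(self, term: str) -> float:
        return self.perm_results[term].r_squared


def proc_anova_rrpp(
    shape: np.ndarray,
    terms: list[tuple[str, np.ndarray]],
    n_perm: int = 1000,
    seed: int = 0,
) -> AnovaResult:
    """Procrustes ANOVA: sequential sums of squares with RRPP significance.

    ``terms`` is an ordered list of (name, values) covariates — order
    matters, as sums of squares are sequential (each term adjusted for the
    ones before it).  Significance of each term comes from randomizing the
    residuals of its reduced model: the reduced-model residuals are permuted
    across specimens, added back to the reduced fit, and the term's F ratio
    recomputed, ``n_perm`` total arrangements including the observed one.
    Effect size is the z-score of the observed F in the permutation
    distribution; R^2 is SS_term / SS_total.
    """
    y = _flatten_shapes(shape)
    n, p = y.shape
    if n_perm < 2:
        raise ValueError("n_perm must be at least 2")
    yc = y - y.mean(axis=0)
    ss_total = float((yc**2).sum())
    if ss_total <= 0:
        raise ValueError("constant shape data: no variation to decompose")

    # nested design matrices
    designs = [np.ones((n, 1))]
    for name, vals in terms:
        vals = np.asarray(vals)
        if vals.shape[0] != n:
            raise ValueError(f"term {name!r}: length {vals.shape[0]} != n={n}")
        designs.append(np.column_stack([designs[-1], _encode_term(vals)]))
    ranks = [np.linalg.matrix_rank(x) for x in designs]
    for (name, _), r0, r1 in zip(terms, ranks[:-1], ranks[1:]):
        if r1 == r0:
            raise ValueError(f"term {name!r} is collinear with earlier terms")
    hats = [_hat(x) for x in designs]
    h_full = hats[-1]
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")
    resid_full = y - h_full @ y
    ss_res = float((resid_full**2).sum())
    ms_res = ss_res / df_res

    rng = np.random.default_rng(seed)
    rows = []
    perm_results: dict[str, PermTestResult] = {}
    for i, (name, _) in enumerate(terms):
        d = hats[i + 1] - hats[i]
        df_t = ranks[i + 1] - ranks[i]
        e_red = y - hats[i] @ y
        ss_obs = float(np.einsum("np,nm,mp->", e_red, d, e_red))
        f_obs = (ss_obs / df_t) / ms_res
        # permute reduced-model residual rows; fitted part projects to zero
        # under both D and the full-model residual maker, so only E matters
        perms = np.stack([rng.permutation(n) for _ in range(n_perm - 1)])
        ep = e_red[perms]  # (B, n, p)
        ss_perm = np.einsum("bnp,nm,bmp->b", ep, d, ep)
        r_full = np.eye(n) - h_full
        ssres_perm = np.einsum("bnp,nm,bmp->b", ep, r_full, ep)
        f_perm = (ss_perm / df_t) / (ssres_perm / df_res)
        p_val, z = _perm_p_and_z(f_obs, f_perm)
        r2 = ss_obs / ss_total
        rows.append((name, df_t, ss_obs, ss_obs / df_t, f_obs, r2, z, p_val))
        perm_results[name] = PermTestResult(
            statistic_name=f"F[{name}]",
            observed=f_obs,
            p_value=p_val,
            n_perm=n_perm,
            effect_size_z=z,
            seed=seed,
            r_squared=r2,
        )

    rows.append(("Residuals", df_res, ss_res, ms_res, np.nan, ss_res / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, np.nan, np.nan, 1.0, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["term", "df", "SS", "MS", "F", "R2", "Z", "p"])
    return AnovaResult(table=table, perm_results=perm_results)


# ---------------------------------------------------------------------------
# Dispersion (Procrustes variance) permutation test
# ---------------------------------------------------------------------------

def _group_variances(y: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    v = np.empty(n_groups)
    for g in range(n_groups):
        m = y[codes == g]
        v[g] = ((m - m.mean(axis=0)) ** 2).sum(axis=1).mean()
    return v


def dispersion_test(
    shapes: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple, PermTestResult]]:
    """Pairwise permutation tests on group dispersion.

    Dispersion of a group is its Procrustes variance: the mean squared
    (flattened-coordinate) distance of members to the group mean.  The
    pairwise statistic is the absolute variance difference; the null is
    built by permuting group labels across all specimens.
    """
    y = _flatten_shapes(shapes)
    g = np.asarray(groups)
    levels, codes = np.unique(g, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        bad = levels[counts.argmin()]
        raise ValueError(f"group {bad!r} has fewer than 2 members")

    ng = len(levels)
    v_obs = _group_variances(y, codes, ng)
    rng = np.random.default_rng(seed)
    v_perm = np.empty((n_perm - 1, ng))
    for b in range(n_perm - 1):
        v_perm[b] = _group_variances(y, codes[rng.permutation(len(codes))], ng)

    rows = []
    results: dict[tuple, PermTestResult] = {}
    for i in range(ng):
        for j in range(i + 1, ng):
            obs = abs(v_obs[i] - v_obs[j])
            perm = np.abs(v_perm[:, i] - v_perm[:, j])
            p, z = _perm_p_and_z(obs, perm)
            rows.append((levels[i], levels[j], v_obs[i], v_obs[j], obs, z, p))
            results[(levels[i], levels[j])] = PermTestResult(
                statistic_name="|var_i - var_j|",
                observed=obs,
                p_value=p,
                n_perm=n_perm,
                effect_size_z=z,
                seed=seed,
            )
    table = pd.DataFrame(
        rows, columns=["group_i", "group_j", "var_i", "var_j", "abs_diff", "Z", "p"]
    )
    return table, results


# ---------------------------------------------------------------------------
# Two-block partial least squares
# ---------------------------------------------------------------------------

@dataclass
class PLSResult:
    """First-axis two-block PLS association between two data blocks."""

    test: PermTestResult
    scores1: np.ndarray
    scores2: np.ndarray
    axis1: np.ndarray
    axis2: np.ndarray

    @property
    def r_pls(self) -> float:
        return self.test.observed


def _first_axis_corr(x1: np.ndarray, x2: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    c = x1.T @ x2 / (x1.shape[0] - 1)
    u, s, vt = np.linalg.svd(c, full_matrices=False)
    a1, a2 = u[:, 0], vt[0]
    s1, s2 = x1 @ a1, x2 @ a2
    denom = s1.std() * s2.std()
    if denom == 0:
        return 0.0, a1, a2
    r = float(np.corrcoef(s1, s2)[0, 1])
    if r < 0:  # sign of the singular vectors is arbitrary
        a2, s2, r = -a2, -s2, -r
    return r, a1, a2


def two_block_pls(
    block1: np.ndarray,
    block2: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> PLSResult:
    """Two-block PLS: rPLS and its permutation test.

    Both blocks are column-centred; the first pair of singular axes of the
    cross-block covariance matrix is extracted and rPLS is the correlation
    of the paired axis scores.  The null distribution comes from shuffling
    the rows of block 2 relative to block 1.
    """
    x1 = _flatten_shapes(block1)
    x2 = _flatten_shapes(block2)
    if x1.shape[0] != x2.shape[0]:
        raise ValueError(f"row-count mismatch: {x1.shape[0]} vs {x2.shape[0]}")
    n = x1.shape[0]
    if n < 4:
        raise ValueError("two-block PLS needs at least 4 specimens")
    x1 = x1 - x1.mean(axis=0)
    x2 = x2 - x2.mean(axis=0)
    if not (x1.any() and x2.any()):
        raise ValueError("zero-variance block")

    r_obs, a1, a2 = _first_axis_corr(x1, x2)
    rng = np.random.default_rng(seed)
    r_perm = np.empty(n_perm - 1)
    for b in range(n_perm - 1):
        r_perm[b], _, _ = _first_axis_corr(x1, x2[rng.permutation(n)])
    p, z = _perm_p_and_z(r_obs, r_perm)
    test = PermTestResult(
        statistic_name="rPLS",
        observed=r_obs,
        p_value=p,
        n_perm=n_perm,
        effect_size_z=z,
        seed=seed,
    )
    return PLSResult(test=test, scores1=x1 @ a1, scores2=x2 @ a2, axis1=a1, axis2=a2)


# ---------------------------------------------------------------------------
# One-way ANOVA with Tukey HSD
# ---------------------------------------------------------------------------

def anova_tukey(values: np.ndarray, groups: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA with a Tukey HSD post-hoc.

    Returns the ANOVA table and a pairwise table of mean differences with
    adjusted p-values from the studentized-range distribution.  Unbalanced
    designs use the harmonic mean of each pair's sample sizes (the
    Tukey-Kramer standard error).
    """
    v = np.asarray(values, float)
    g = np.asarray(groups)
    levels, codes = np.unique(g, return_inverse=True)
    ngroups = len(levels)
    if ngroups < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError(f"group {levels[counts.argmin()]!r} has fewer than 2 members")

    grand = v.mean()
    means = np.array([v[codes == i].mean() for i in range(ngroups)])
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(sum(((v[codes == i] - means[i]) ** 2).sum() for i in range(ngroups)))
    df_b, df_w = ngroups - 1, len(v) - ngroups
    ms_b = ss_between / df_b
    degenerate = ss_within == 0.0
    if degenerate:
        if np.allclose(means, means[0]):
            warnings.warn("zero variance everywhere: ANOVA undefined, reporting p = 1")
            f_stat, p_val = np.nan, 1.0
        else:
            warnings.warn("zero residual variance with unequal means: reporting p = 0")
            f_stat, p_val = np.inf, 0.0
        ms_w = 0.0
    else:
        ms_w = ss_within / df_w
        f_stat = ms_b / ms_w
        p_val = float(sps.f.sf(f_stat, df_b, df_w))

    ss_tot = ss_between + ss_within
    table = pd.DataFrame(
        [
            ("group", df_b, ss_between, ms_b, f_stat, ss_between / ss_tot if ss_tot else np.nan, p_val),
            ("Residuals", df_w, ss_within, ms_w, np.nan, ss_within / ss_tot if ss_tot else np.nan, np.nan),
        ],
        columns=["term", "df", "SS", "MS", "F", "R2", "p"],
    )

    rows = []
    for i in range(ngroups):
        for j in range(i + 1, ngroups):
            diff = means[j] - means[i]
            if degenerate:
                p_adj = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(ms_w * 0.5 * (1 / counts[i] + 1 / counts[j]))
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, ngroups, df_w))
            rows.append((levels[i], levels[j], diff, p_adj))
    pairwise = pd.DataFrame(rows, columns=["group_i", "group_j", "difference", "p_adj"])
    return table, pairwise


# ---------------------------------------------------------------------------
# Sexual dimorphism battery
# ---------------------------------------------------------------------------

def sexual_dimorphism_suite(
    aligned: np.ndarray,
    centroid_sizes: np.ndarray,
    sex: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    balanced_T: int = 0,
    balanced_n_perm: int = 200,
    alpha: float = 0.05,
) -> dict:
    """Sexual shape (SShD) and size (SSD) dimorphism tests.

    SShD: Procrustes ANOVA of shape on log10 centroid size then sex, so the
    sex effect is assessed after allometry.  SSD: one-way ANOVA of log10
    centroid size on sex.  With ``balanced_T > 0`` and unequal sex counts,
    the larger sex is repeatedly subsampled to match the smaller and the
    SShD sex term re-tested, reporting how many of the T balanced resamples
    reach significance at ``alpha``.
    """
    sex = np.asarray(sex)
    levels = np.unique(sex)
    if len(levels) < 2:
        raise ValueError("both sexes must be present")
    log_cs = np.log10(np.asarray(centroid_sizes, float))
    sshd = proc_anova_rrpp(aligned, [("size", log_cs), ("sex", sex)], n_perm=n_perm, seed=seed)
    ssd_table, ssd_pairs = anova_tukey(log_cs, sex)
    out = {"SShD": sshd, "SSD": (ssd_table, ssd_pairs)}

    if balanced_T > 0:
        counts = {lev: int((sex == lev).sum()) for lev in levels}
        small = min(counts, key=counts.get)
        n_small = counts[small]
        rng = np.random.default_rng(seed)
        y = _flatten_shapes(aligned)
        hits = 0
        for t in range(balanced_T):
            keep = []
            for lev in levels:
                idx = np.flatnonzero(sex == lev)
                if len(idx) > n_small:
                    idx = rng.choice(idx, size=n_small, replace=False)
                keep.append(idx)
            keep = np.concatenate(keep)
            sub = proc_anova_rrpp(
                y[keep],
                [("size", log_cs[keep]), ("sex", sex[keep])],
                n_perm=balanced_n_perm,
                seed=int(rng.integers(2**31 - 1)),
            )
            if sub.p("sex") <= alpha:
                hits += 1
        out["balanced"] = {
            "significant": hits,
            "T": balanced_T,
            "alpha": alpha,
            "n_per_sex": n_small,
        }
    return out
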