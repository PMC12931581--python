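"""Composition-level statistics from first principles.

Bray-Curtis dissimilarities, one-way PERMANOVA with free or
stratum-restricted permutations, the homogeneity-of-multivariate-dispersion
test (principal-coordinate embedding with negative-eigenvalue axes kept on
an imaginary subspace, distances to group spatial medians), and Mantel
correlograms for distance decay of community similarity.

Permutation p-values use the (b + 1) / (m + 1) convention with b the number
of permuted statistics at least as extreme as the observed one.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "bray_curtis",
    "permanova",
    "dispersion_homogeneity",
    "mantel_correlogram",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metric: str = "bray_curtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.nan_to_num(np.diag(v)), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def bray_curtis(rows, labels: Sequence[str] | None = None) -> DistanceMatrix:
    """Pairwise Bray-Curtis: d(x, y) = sum|x - y| / sum(x + y).

    A pair of all-zero rows has no defined dissimilarity; the cell is NaN.
    """
    if isinstance(rows, pd.DataFrame):
        labels = list(rows.index) if labels is None else list(labels)
        mat = rows.values.astype(float)
    else:
        mat = np.asarray(rows, dtype=float)
        if labels is None:
            labels = [f"s{i}" for i in range(mat.shape[0])]
    if mat.shape[0] < 2:
        raise ValueError("need at least two rows")
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    n = mat.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(mat[i] - mat[i + 1:]).sum(axis=1)
        tot = (mat[i] + mat[i + 1:]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(tot > 0, diff / np.where(tot > 0, tot, 1), np.nan)
        d[i, i + 1:] = vals
        d[i + 1:, i] = vals
    return DistanceMatrix(labels=list(labels), values=d)


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int
    df_between: int
    df_within: int

    def summary(self) -> str:
        return (
            f"PERMANOVA F({self.df_between},{self.df_within}) = "
            f"{self.pseudo_F:.3g}, R2 = {self.R2:.3g}, p = {self.p:.4g} "
            f"({self.n_permutations} permutations)"
        )


def _groups_to_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(groups))
    return codes, len(uniques)


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, a: int) -> tuple[float, float]:
    """(SS_within, SS_between) for one labelling (Anderson's partition)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(a):
        idx = np.flatnonzero(codes == g)
        if idx.size > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    return ss_within, ss_total - ss_within


def permanova(
    D: DistanceMatrix | np.ndarray,
    groups,
    strata=None,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "monte_carlo",
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    pseudo-F = (SS_between / (a - 1)) / (SS_within / (N - a)) on squared
    distances; p by permuting group labels (within ``strata`` levels when
    given).  ``method='exhaustive'`` enumerates every relabelling (small N
    only).  Degenerate SS_within = 0 reports an infinite F.
    """
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    codes, a = _groups_to_codes(groups)
    n = d.shape[0]
    if a < 2 or np.bincount(codes).min() < 1:
        raise ValueError("need >= 2 groups, each non-empty")
    d2 = d * d
    ss_w, ss_b = _permanova_stats(d2, codes, a)
    df_b, df_w = a - 1, n - a
    if ss_w <= 1e-12:
        f_obs = math.inf
    else:
        f_obs = (ss_b / df_b) / (ss_w / df_w)
    ss_total = ss_w + ss_b
    r2 = ss_b / ss_total if ss_total > 0 else 0.0

    def stat(perm_codes: np.ndarray) -> float:
        w, b = _permanova_stats(d2, perm_codes, a)
        return math.inf if w <= 1e-12 else (b / df_b) / (w / df_w)

    if method == "exhaustive":
        if n > 9:
            raise ValueError("exhaustive enumeration is limited to n <= 9")
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        vals = np.array([stat(codes[list(p)]) for p in perms])
        p_val = float(np.mean(vals >= f_obs - 1e-12))
        m = len(perms)
    else:
        rng = substream(seed, "permanova")
        if strata is None:
            strata_codes = np.zeros(n, dtype=int)
        else:
            strata_codes, _ = _groups_to_codes(strata)
        idx_by_stratum = [np.flatnonzero(strata_codes == s)
                          for s in np.unique(strata_codes)]
        b_count = 0
        for _ in range(n_permutations):
            perm = np.arange(n)
            for idx in idx_by_stratum:
                perm[idx] = idx[rng.permutation(idx.size)]
            if stat(codes[perm]) >= f_obs - 1e-12:
                b_count += 1
        p_val = (b_count + 1) / (n_permutations + 1)
        m = n_permutations
    return PermanovaResult(
        pseudo_F=f_obs, R2=r2, p=p_val, n_permutations=m,
        df_between=df_b, df_within=df_w,
    )


# ---------------------------------------------------------------------------
# multivariate dispersion


def _pcoa_axes(d: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates: (real axes, imaginary axes) column stacks."""
    n = d.shape[0]
    a = -0.5 * d * d
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    evals, evecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > tol
    neg = evals < -tol
    real = evecs[:, pos] * np.sqrt(evals[pos])
    imag = evecs[:, neg] * np.sqrt(-evals[neg])
    return real, imag


def _geometric_median(x: np.ndarray, iters: int = 100, eps: float = 1e-9) -> np.ndarray:
    """Weiszfeld iteration; x is (n, k)."""
    if x.shape[0] == 1:
        return x[0].copy()
    m = x.mean(axis=0)
    for _ in range(iters):
        dist = np.linalg.norm(x - m, axis=1)
        dist = np.maximum(dist, eps)
        w = 1.0 / dist
        new = (x * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - m) < 1e-12:
            m = new
            break
        m = new
    return m


def _dispersion_distances(
    real: np.ndarray, imag: np.ndarray, codes: np.ndarray, a: int,
    use_median: bool,
) -> np.ndarray:
    z = np.empty(codes.size)
    for g in range(a):
        idx = np.flatnonzero(codes == g)
        xr = real[idx]
        xi = imag[idx] if imag.size else np.zeros((idx.size, 0))
        if use_median:
            cr = _geometric_median(xr) if xr.size else np.zeros(0)
            ci = _geometric_median(xi) if xi.size else np.zeros(0)
        else:
            cr = xr.mean(axis=0) if xr.size else np.zeros(0)
            ci = xi.mean(axis=0) if xi.size else np.zeros(0)
        d2 = ((xr - cr) ** 2).sum(axis=1)
        if xi.size:
            d2 = d2 - ((xi - ci) ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.maximum(d2, 0.0))
    return z


def _anova_f(z: np.ndarray, codes: np.ndarray, a: int) -> float:
    n = z.size
    grand = z.mean()
    ss_b = ss_w = 0.0
    for g in range(a):
        zg = z[codes == g]
        ss_b += zg.size * (zg.mean() - grand) ** 2
        ss_w += ((zg - zg.mean()) ** 2).sum()
    if ss_w <= 1e-15:
        return math.inf
    return (ss_b / (a - 1)) / (ss_w / (n - a))


def dispersion_homogeneity(
    D: DistanceMatrix | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    centre: str = "median",
) -> dict:
    """Homogeneity test of multivariate dispersion (betadisper analogue).

    Samples are embedded by principal coordinates (negative-eigenvalue axes
    kept imaginary); each sample's dispersion is its distance to the group
    spatial median (``centre='centroid'`` uses means), with imaginary-axis
    contributions subtracted under the square root.  The group effect is an
    ANOVA F on those distances, with a permutation p-value (group labels
    permuted, centres recomputed).  Singleton groups get dispersion 0 and
    are flagged.
    """
    d = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    codes, a = _groups_to_codes(groups)
    if a < 2:
        raise ValueError("need >= 2 groups")
    use_median = centre == "median"
    real, imag = _pcoa_axes(d)
    z = _dispersion_distances(real, imag, codes, a, use_median)
    f_obs = _anova_f(z, codes, a)
    rng = substream(seed, "betadisper")
    b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes.size)
        pc = codes[perm]
        zp = _dispersion_distances(real, imag, pc, a, use_median)
        if _anova_f(zp, pc, a) >= f_obs - 1e-12:
            b += 1
    sizes = np.bincount(codes, minlength=a)
    means = np.array([z[codes == g].mean() for g in range(a)])
    return dict(
        group_dispersion=means,
        group_sizes=sizes,
        F=f_obs,
        p=(b + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
        singleton_groups=bool((sizes == 1).any()),
        distances=z,
    )


# ---------------------------------------------------------------------------
# Mantel correlogram


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(running, 1.0)
    return adj


def mantel_correlogram(
    D_community: DistanceMatrix | np.ndarray,
    coordinates: np.ndarray,
    distance_classes: int | Sequence[float] = 6,
    n_permutations: int = 499,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel correlogram: spatial autocorrelation of community composition.

    Per geographic distance class (edges half-open [lo, hi)), the statistic
    is the negated Pearson correlation between community dissimilarity and
    the within-class pair indicator over all pairs, so r > 0 means pairs in
    that class are more similar than average.  Two-sided permutation p per
    class, Holm-corrected across classes.  Empty classes are skipped.
    """
    d = (D_community.values if isinstance(D_community, DistanceMatrix)
         else np.asarray(D_community, float))
    coords = np.asarray(coordinates, float)
    n = d.shape[0]
    if coords.shape[0] != n:
        raise ValueError("coordinates must cover every sample")
    iu = np.triu_indices(n, 1)
    geo = np.sqrt(
        ((coords[iu[0]] - coords[iu[1]]) ** 2).sum(axis=1)
    )
    if np.isscalar(distance_classes):
        edges = np.linspace(0.0, geo.max() + 1e-9, int(distance_classes) + 1)
    else:
        edges = np.asarray(distance_classes, float)
    if edges.size < 3:
        raise ValueError("need >= 2 distance classes")
    dvec = d[iu]
    valid = ~np.isnan(dvec)
    rng = substream(seed, "correlog")
    perms = [rng.permutation(n) for _ in range(n_permutations)]

    recs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        ind = (geo >= lo) & (geo < hi)
        n_pairs = int(ind[valid].sum())
        if n_pairs == 0 or n_pairs == valid.sum():
            continue

        def stat(vec):
            x = vec[valid]
            y = ind[valid].astype(float)
            if x.std() == 0 or y.std() == 0:
                return 0.0
            return float(-np.corrcoef(x, y)[0, 1])

        r_obs = stat(dvec)
        b = 0
        for perm in perms:
            dp = d[np.ix_(perm, perm)][iu]
            if abs(stat(dp)) >= abs(r_obs) - 1e-12:
                b += 1
        recs.append(dict(class_lo=lo, class_hi=hi, n_pairs=n_pairs,
                         r=r_obs, p=(b + 1) / (n_permutations + 1)))
    out = pd.DataFrame(recs)
    if len(out):
        out["p_holm"] = _holm(out["p"].values)
    return out
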