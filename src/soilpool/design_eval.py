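"""Design-comparison analytics.

Summaries of each (site, design) stratum on depth-standardised data, ratios
of site-level diversity between designs, site-ranking concordance, the
pooling-effect statistic, and the rectangular area-subsampling test.

The pooling effect (PE) of a design at one site is the ratio of a diversity
estimate from the pooled sample — rarefied to a fraction of the design's
summary sequencing depth (the total reads across the same design's unpooled
samples) — to the estimate from the unpooled samples.  PE < 1 means pooling
lost diversity relative to processing every subsample separately; PE > 1
means the pooled sample, given the same sequencing budget, recovered more.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from ._rng import substream
from .divmetrics import (  # noqa: F401

    AbundanceVector,
    hill_diversity,
    rarefy_mc,
    substream_seed,
)
from .labsim import ReadTable

__all__ = [
    "DesignSummary",
    "PEResult",
    "summarise_design",
    "design_ratios",
    "rank_sites",
    "pooling_effect",
    "area_subsampling_test",
]

log = logging.getLogger(__name__)

MIN_READS = 100  # samples below this are dropped from summaries


@dataclass
class DesignSummary:
    site_id: str
    design_name: str
    n_samples: int
    rarefaction_depth: int
    iterations: int
    mean_richness: float
    mean_shannon: float
    mean_hill1: float
    site_richness: float
    site_shannon: float
    site_hill1: float
    summary_depth: int


@dataclass
class PEResult:
    site_id: str
    design_name: str
    strategy: str
    q: int
    depth_fraction: float
    pe: float
    pooled_value: float
    unpooled_value: float
    depth: int
    flag: str = ""


def _stratum(table: ReadTable, site: str, design: str, strategy: str) -> pd.DataFrame:
    meta = table.sample_meta
    mask = (
        (meta["site"] == site)
        & (meta["design"] == design)
        & (meta["strategy"] == strategy)
    )
    return table.counts.loc[mask.values]


def summarise_design(
    table: ReadTable,
    site: str,
    design: str,
    rarefy_to: int | str = "near_min",
    iterations: int = 100,
    seed: int = 0,
    strategy: str = "unpooled",
) -> DesignSummary:
    """Depth-standardised per-sample and site-level diversity of one stratum.

    Samples below ``MIN_READS`` reads are dropped with a logged warning.
    Per-sample metrics are Monte-Carlo rarefied to the policy depth (the
    minimum depth across retained samples by default).  Site-level totals
    are computed per iteration on the union of the rarefied samples and
    averaged, so totals and per-sample means share one depth standard.
    """
    rows = _stratum(table, site, design, strategy)
    if rows.shape[0] == 0:
        raise ValueError(f"no {strategy} samples for {design} at {site}")
    depths = rows.sum(axis=1)
    keep = depths >= MIN_READS
    if not keep.all():
        log.warning(
            "dropping %d/%d samples with < %d reads (%s, %s)",
            (~keep).sum(), len(keep), MIN_READS, site, design,
        )
    rows = rows.loc[keep]
    if rows.shape[0] == 0:
        raise ValueError("all samples below the read floor")
    depths = rows.sum(axis=1)
    depth = int(depths.min()) if rarefy_to == "near_min" else int(rarefy_to)

    mat = rows.values
    per_sample = []
    for i, sid in enumerate(rows.index):
        res = rarefy_mc(mat[i], min(depth, int(mat[i].sum())),
                        iterations, substream_seed(seed, sid))
        per_sample.append((res.richness, res.shannon, res.hill1))
    per_sample = np.array(per_sample)

    # site totals: per-iteration union of rarefied samples
    rng_seeds = [substream_seed(seed, f"union_{i}") for i in range(len(rows))]
    rich_tot = np.zeros(iterations)
    shan_tot = np.zeros(iterations)
    hill_tot = np.zeros(iterations)
    gens = [substream(s, "rarefy") for s in rng_seeds]
    compact = [r[r > 0].astype(np.int64) for r in mat]
    cols = [np.flatnonzero(r > 0) for r in mat]
    n_otus = mat.shape[1]
    for it in range(iterations):
        union = np.zeros(n_otus, dtype=np.int64)
        for j, (vec, idx) in enumerate(zip(compact, cols)):
            d = min(depth, int(vec.sum()))
            sub = gens[j].multivariate_hypergeometric(vec, d)
            union[idx] += sub
        v = union[union > 0]
        p = v / v.sum()
        h = -np.sum(p * np.log(p))
        rich_tot[it] = v.size
        shan_tot[it] = h
        hill_tot[it] = np.exp(h)
    return DesignSummary(
        site_id=site,
        design_name=design,
        n_samples=rows.shape[0],
        rarefaction_depth=depth,
        iterations=iterations,
        mean_richness=float(per_sample[:, 0].mean()),
        mean_shannon=float(per_sample[:, 1].mean()),
        mean_hill1=float(per_sample[:, 2].mean()),
        site_richness=float(rich_tot.mean()),
        site_shannon=float(shan_tot.mean()),
        site_hill1=float(hill_tot.mean()),
        summary_depth=int(depths.sum()),
    )


def design_ratios(
    summaries: Sequence[DesignSummary],
    reference: str,
    exclusions: Sequence[str] = (),
    q: int = 0,
) -> pd.DataFrame:
    """Per-site ratio of the reference design's site-level diversity to each
    other design's (q=0 richness, q=1 effective OTU number).

    Zero denominators yield NaN cells, never exceptions; excluded designs
    are dropped.
    """
    attr = "site_richness" if q == 0 else "site_hill1"
    frame = pd.DataFrame(
        [
            dict(site=s.site_id, design=s.design_name, value=getattr(s, attr))
            for s in summaries
            if s.design_name not in exclusions
        ]
    ).pivot(index="design", columns="site", values="value")
    if reference not in frame.index:
        raise ValueError(f"reference design {reference!r} absent")
    ref = frame.loc[reference]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = frame.rdiv(ref, axis=1)
    return ratios.replace([np.inf, -np.inf], np.nan)


def rank_sites(summaries: Sequence[DesignSummary]) -> dict:
    """Per-design site ranking by site-level richness plus pairwise
    Kendall-tau concordance between designs (ties broken by site id)."""
    frame = pd.DataFrame(
        [
            dict(site=s.site_id, design=s.design_name, value=s.site_richness)
            for s in summaries
        ]
    ).pivot(index="site", columns="design", values="value")
    if frame.shape[0] < 2:
        raise ValueError("need >= 2 sites to rank")
    rankings = {}
    for d in frame.columns:
        order = sorted(frame.index, key=lambda s: (-frame.loc[s, d], s))
        rankings[d] = order
        if frame[d].duplicated().any():
            log.info("ties in site richness for %s broken by site id", d)
    designs = list(frame.columns)
    tau = pd.DataFrame(np.eye(len(designs)), index=designs, columns=designs)
    for i, a in enumerate(designs):
        for b in designs[i + 1:]:
            t = kendalltau(frame[a], frame[b]).statistic
            tau.loc[a, b] = tau.loc[b, a] = t
    return dict(rankings=rankings, concordance=tau)


def pooling_effect(
    table: ReadTable,
    site: str,
    design: str,
    strategy: str,
    q: int = 0,
    depth_fractions: Sequence[float] = (0.25, 0.5, 0.75, 1.0),
    iterations: int = 100,
    seed: int = 0,
) -> list[PEResult]:
    """Pooling effect of one (site, design, strategy) cell across fractions
    of the summary sequencing depth.

    The unpooled reference is the observed site-level value over the
    design's unpooled samples at full depth; the pooled value is the
    Monte-Carlo rarefaction of the pooled sample (composites summed) at
    floor(fraction x summary depth).  Requests exceeding the pooled read
    count are flagged, never extrapolated.
    """
    if q not in (0, 1):
        raise ValueError("q must be 0 or 1")
    unpooled = _stratum(table, site, design, "unpooled")
    pooled = _stratum(table, site, design, strategy)
    if unpooled.shape[0] == 0 or pooled.shape[0] == 0:
        raise ValueError(
            f"missing unpooled or {strategy} rows for {design} at {site}"
        )
    unpooled = unpooled.loc[unpooled.sum(axis=1) > 0]
    summary_depth = int(unpooled.values.sum())
    union = unpooled.values.sum(axis=0)
    ref = float((union > 0).sum()) if q == 0 else hill_diversity(
        AbundanceVector(union), 1
    )
    pooled_vec = pooled.values.sum(axis=0)
    pooled_total = int(pooled_vec.sum())
    out: list[PEResult] = []
    for f in depth_fractions:
        if not 0 < f <= 1:
            raise ValueError("depth fractions must be in (0, 1]")
        d = math.floor(f * summary_depth)
        if d > pooled_total:
            out.append(
                PEResult(site, design, strategy, q, f, float("nan"),
                         float("nan"), ref, d,
                         flag="pooled depth insufficient")
            )
            continue
        res = rarefy_mc(pooled_vec, d, iterations, substream_seed(seed, f))
        val = res.richness if q == 0 else res.hill1
        out.append(
            PEResult(site, design, strategy, q, f, val / ref, val, ref, d)
        )
    return out


def pe_frame(results: Sequence[PEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(site=r.site_id, design=r.design_name, strategy=r.strategy,
                 q=r.q, fraction=r.depth_fraction, pe=r.pe,
                 pooled_value=r.pooled_value, unpooled_value=r.unpooled_value,
                 depth=r.depth, flag=r.flag)
            for r in results
        ]
    )


def area_subsampling_test(
    table: ReadTable,
    k: int = 8,
    area_min: float = 327.0,
    area_max: float = 2000.0,
    aspect_tolerance: float = 5.0,
    n_combinations: int = 40,
    n_permutations: int = 999,
    seed: int = 0,
    n_area_bins: int = 5,
    max_attempts_per_combination: int = 2000,
) -> dict:
    """Does sampled area change recovered richness at fixed subsample count?

    Draws ``n_combinations`` subsets of ``k`` unpooled samples per site whose
    axis-aligned bounding rectangle is near-square (|width - length| <=
    ``aspect_tolerance``) with area inside [area_min, area_max], stratified
    over ``n_area_bins`` equal area bins so the range is covered evenly.
    Union OTU richness is regressed on area (OLS with site fixed effects);
    the slope's p-value comes from permuting richness within sites.
    """
    meta = table.sample_meta
    mask = (meta["strategy"] == "unpooled") & meta["x"].notna()
    if mask.sum() < k:
        raise ValueError("not enough unpooled samples with coordinates")
    counts = table.counts.loc[mask.values].values > 0
    meta = meta.loc[mask.values]
    sites = meta["site"].values
    xy = meta[["x", "y"]].values
    rng = substream(seed, "area_test")
    edges = np.linspace(area_min, area_max, n_area_bins + 1)

    recs = []
    for site in pd.unique(sites):
        idx_site = np.flatnonzero(sites == site)
        if idx_site.size < k:
            continue
        fills = np.zeros(n_area_bins, dtype=int)
        target = math.ceil(n_combinations / n_area_bins)
        attempts = 0
        budget = max_attempts_per_combination * n_combinations
        while fills.sum() < n_combinations and attempts < budget:
            attempts += 1
            pick = idx_site[rng.choice(idx_site.size, k, replace=False)]
            pts = xy[pick]
            w = pts[:, 0].max() - pts[:, 0].min()
            l = pts[:, 1].max() - pts[:, 1].min()
            area = w * l
            if abs(w - l) > aspect_tolerance:
                continue
            if not (area_min <= area <= area_max):
                continue
            b = min(np.searchsorted(edges, area, side="right") - 1,
                    n_area_bins - 1)
            if fills[b] >= target:
                continue
            fills[b] += 1
            richness = int(counts[pick].any(axis=0).sum())
            recs.append(dict(site=site, area=area, width=w, length=l,
                             richness=richness, _members=pick))
        if fills.sum() == 0:
            raise ValueError(
                f"no feasible {k}-sample combination at {site} within "
                f"[{area_min}, {area_max}] m^2 after {attempts} attempts"
            )
    combos = pd.DataFrame(recs)
    if combos.empty:
        raise ValueError("no feasible combinations at any site")

    members = [r["_members"] for r in recs]
    combos = combos.drop(columns="_members")

    # OLS richness ~ area + site fixed effects.  The permutation null
    # shuffles which community sits at which core position (within site)
    # and recomputes every subset's union richness, so the overlap between
    # subsets is preserved under the null and the test keeps its size.
    site_codes, site_levels = pd.factorize(combos["site"])
    n = len(combos)
    X = np.column_stack(
        [np.ones(n), combos["area"].values]
        + [
            (site_codes == s).astype(float)
            for s in range(1, len(site_levels))
        ]
    )

    def slope_of(yv: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
        return float(beta[1])

    y = combos["richness"].values.astype(float)
    obs = slope_of(y)
    sample_sites = sites
    site_idx = {s: np.flatnonzero(sample_sites == s)
                for s in pd.unique(sample_sites)}
    b = 0
    for _ in range(n_permutations):
        perm = np.arange(counts.shape[0])
        for idx in site_idx.values():
            perm[idx] = idx[rng.permutation(idx.size)]
        yp = np.array(
            [counts[perm[m]].any(axis=0).sum() for m in members], dtype=float
        )
        if abs(slope_of(yp)) >= abs(obs) - 1e-12:
            b += 1
    return dict(
        combinations=combos,
        slope=obs,
        p=(b + 1) / (n_permutations + 1),
        n_permutations=n_permutations,
    )
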