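"""Diversity estimation kernels.

Coverage, Hill diversities of order 0 and 1, analytic (hypergeometric) and
Monte-Carlo rarefaction, bias-corrected Chao1, sample-based accumulation
curves, read-based richness extrapolation and cumulative abundance curves.
All combinatorial terms are evaluated in log space via log-gamma so read
depths up to ~1e6 are safe.  Rarefaction is without replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._rng import substream

__all__ = [
    "AbundanceVector",
    "DiversityResult",
    "goods_coverage",
    "hill_diversity",
    "rarefy_expect",
    "rarefy_mc",
    "chao1",
    "accumulation_curve",
    "extrapolate_richness",
    "cumulative_abundance_curve",
    "diversity_table",
]


class AbundanceVector:
    """Non-negative integer read counts of one sample's OTUs.

    ``n`` is the total read count, ``f1``/``f2`` the numbers of singleton
    and doubleton OTUs, always recomputed from the counts.
    """

    def __init__(self, counts: Iterable[int] | np.ndarray | pd.Series | dict):
        if isinstance(counts, dict):
            counts = list(counts.values())
        if isinstance(counts, pd.Series):
            counts = counts.values
        arr = np.asarray(counts)
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            arr = np.round(arr).astype(np.int64)
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = arr.astype(np.int64)[arr > 0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def s_obs(self) -> int:
        return int(self.counts.size)

    @property
    def f1(self) -> int:
        return int((self.counts == 1).sum())

    @property
    def f2(self) -> int:
        return int((self.counts == 2).sum())


def _as_vector(v) -> AbundanceVector:
    return v if isinstance(v, AbundanceVector) else AbundanceVector(v)


@dataclass
class DiversityResult:
    """Per-sample diversity summary (Hill q=0 and q=1, coverage)."""

    richness: float
    shannon: float
    hill1: float
    coverage: float
    depth: int | None = None
    iterations: int = 1

    def as_dict(self) -> dict:
        return dict(
            richness=self.richness, shannon=self.shannon, hill1=self.hill1,
            coverage=self.coverage, depth=self.depth, iterations=self.iterations,
        )


def goods_coverage(v) -> float:
    """Good's coverage 1 - f1/n: estimated non-singleton read fraction."""
    v = _as_vector(v)
    if v.n < 1:
        raise ValueError("empty abundance vector")
    return 1.0 - v.f1 / v.n


def _shannon(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def hill_diversity(v, q: int) -> float:
    """Hill number: q=0 observed richness, q=1 exp(Shannon)."""
    v = _as_vector(v)
    if v.n < 1:
        raise ValueError("empty abundance vector")
    if q == 0:
        return float(v.s_obs)
    if q == 1:
        return float(np.exp(_shannon(v.counts)))
    raise ValueError(f"unsupported Hill order q={q}")


def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy_expect(v, d: int) -> float:
    """Expected richness of a without-replacement subsample of d reads.

    E[S_d] = sum_s [1 - C(n - n_s, d) / C(n, d)], evaluated in log space.
    """
    v = _as_vector(v)
    d = int(d)
    if d < 0 or d > v.n:
        raise ValueError(f"depth {d} outside [0, {v.n}]")
    if d == 0:
        return 0.0
    n = v.n
    counts = v.counts
    keep = (n - counts) >= d
    miss = np.zeros(counts.size)
    if keep.any():
        miss[keep] = np.exp(
            _log_choose(n - counts[keep], d) - _log_choose(n, d)
        )
    return float(np.sum(1.0 - miss))


def rarefy_mc(v, d: int, iterations: int = 1000, seed: int = 0) -> DiversityResult:
    """Average diversity over repeated without-replacement subsampling.

    Returns the mean richness, Shannon, exp(Shannon) and Good's coverage
    across ``iterations`` subsamples of ``d`` reads; deterministic given
    ``seed``.
    """
    v = _as_vector(v)
    d = int(d)
    if d > v.n:
        raise ValueError(f"depth {d} exceeds sample total {v.n}")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if d == v.n:
        return DiversityResult(
            richness=float(v.s_obs), shannon=_shannon(v.counts),
            hill1=float(np.exp(_shannon(v.counts))),
            coverage=goods_coverage(v), depth=d, iterations=iterations,
        )
    rng = substream(seed, "rarefy")
    rich = np.empty(iterations)
    shan = np.empty(iterations)
    cov = np.empty(iterations)
    for i in range(iterations):
        sub = rng.multivariate_hypergeometric(v.counts, d)
        sub = sub[sub > 0]
        rich[i] = sub.size
        shan[i] = _shannon(sub) if sub.size else 0.0
        cov[i] = 1.0 - (sub == 1).sum() / d if d else 0.0
    return DiversityResult(
        richness=float(rich.mean()), shannon=float(shan.mean()),
        hill1=float(np.exp(shan).mean()), coverage=float(cov.mean()),
        depth=d, iterations=iterations,
    )


def chao1(v, bias_corrected: bool = True) -> float:
    """Chao1 asymptotic richness from singletons and doubletons."""
    v = _as_vector(v)
    if v.n < 1:
        raise ValueError("empty abundance vector")
    s, f1, f2 = v.s_obs, v.f1, v.f2
    if bias_corrected:
        return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        return s + f1 * (f1 - 1) / 2.0
    return s + f1 * f1 / (2.0 * f2)


def accumulation_curve(
    rows: Sequence, mode: str = "exact", permutations: int = 999, seed: int = 0
) -> np.ndarray:
    """Expected OTU richness after k = 1..K samples (sample-based curve).

    ``exact`` uses the hypergeometric incidence formula
    E[S_k] = sum_sp [1 - C(K - m_sp, k) / C(K, k)] with m_sp the number of
    samples containing sp; ``permuted`` averages over random sample orders.
    """
    mat = np.asarray([np.asarray(r) for r in rows])
    if mat.size == 0 or mat.shape[0] < 1:
        raise ValueError("empty input")
    inc = mat > 0
    K = inc.shape[0]
    m = inc.sum(axis=0)
    m = m[m > 0]
    if mode == "exact":
        ks = np.arange(1, K + 1)
        out = np.empty(K)
        for i, k in enumerate(ks):
            keep = (K - m) >= k
            miss = np.zeros(m.size)
            if keep.any():
                miss[keep] = np.exp(
                    _log_choose(K - m[keep], k) - _log_choose(K, k)
                )
            out[i] = np.sum(1.0 - miss)
        return out
    if mode == "permuted":
        rng = substream(seed, "accum")
        acc = np.zeros(K)
        for _ in range(permutations):
            order = rng.permutation(K)
            seen = np.cumsum(inc[order], axis=0) > 0
            acc += seen.sum(axis=1)
        return acc / permutations
    raise ValueError(f"unknown mode {mode!r}")


def extrapolate_richness(v, m: int) -> float:
    """Expected richness after m additional reads (size-based, order q=0).

    S(n+m) = S_obs + f0_hat * [1 - (1 - f1 / (n * f0_hat + f1))^m] with
    f0_hat = Chao1 - S_obs; monotone, S_obs at m=0, bounded by Chao1.
    """
    v = _as_vector(v)
    if m < 0:
        raise ValueError("m must be non-negative")
    s = v.s_obs
    f0 = chao1(v) - s
    if m == 0 or f0 <= 0 or v.f1 == 0:
        return float(s)
    ratio = v.f1 / (v.n * f0 + v.f1)
    return float(s + f0 * (1.0 - (1.0 - ratio) ** m))


def cumulative_abundance_curve(v) -> np.ndarray:
    """Cumulative read share by descending OTU rank (ends exactly at 1)."""
    v = _as_vector(v)
    if v.n < 1:
        raise ValueError("empty abundance vector")
    sorted_counts = np.sort(v.counts)[::-1]
    cum = np.cumsum(sorted_counts) / v.n
    cum[-1] = 1.0
    return cum


def diversity_table(
    counts: pd.DataFrame, depth: int | None = None,
    iterations: int = 1000, seed: int = 0,
) -> pd.DataFrame:
    """Per-sample diversity TSV payload (optionally depth-standardised)."""
    recs = []
    for i, (sid, row) in enumerate(counts.iterrows()):
        v = AbundanceVector(row)
        if v.n == 0:
            continue
        if depth is None or depth >= v.n:
            res = rarefy_mc(v, v.n, 1, seed)
        else:
            res = rarefy_mc(v, depth, iterations, substream_seed(seed, sid))
        recs.append(dict(sample_id=sid, n_reads=v.n, **res.as_dict()))
    return pd.DataFrame(recs).set_index("sample_id")


def substream_seed(seed: int, token) -> int:
    from ._rng import key_of

    return (int(seed) * 1_000_003 + key_of(token)) % (2**31 - 1)
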