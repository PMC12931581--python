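"""Synthetic soil communities: species pools and spatially explicit sites.

The generator realises, for each species, a Thomas cluster process inside a
square plot: Poisson-distributed "parent" cluster centres, each scattering a
Poisson number of propagules with an isotropic Gaussian displacement.  This
is the standard minimal model of the patchy horizontal distributions soil
organisms show.  Vertical structure is an exponential decline of propagule
density with depth, except for a small fraction of subsoil specialists whose
density peaks in the 30-40 cm layer.  Per-species PCR amplification bias
factors are carried on the pool so the lab simulator can apply them.

Three organism-group presets (animal-, bacteria-, fungus-like) order total
richness as bacteria > fungi > animals and carry the subsoil-unique
fractions and aggregation scales the downstream analyses assume.  The
presets are calibrated to reproduce qualitative patterns (patchiness,
distance decay, vertical stratification, dilution-sensitivity of rare
species), not the magnitudes of any particular field survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "GROUPS",
    "GROUP_PRESETS",
    "SpeciesParams",
    "SpeciesPool",
    "VirtualSite",
    "make_species_pool",
    "realise_site",
    "pool_to_frame",
    "pool_from_frame",
    "site_points_to_frame",
]

GROUPS = ("animal_like", "bacteria_like", "fungus_like")

#: Documented preset parameters per organism group.  All rates are per-species
#: distribution parameters: ``kappa`` (parents per m^2) ~ Gamma(kappa_shape,
#: mean=kappa_mean); ``sigma`` (cluster spread, m) ~ LogNormal around
#: sigma_mean; ``mu`` (propagules per parent) ~ LogNormal around mu_mean with
#: log-sd mu_lsd (the heavy right tail makes most species locally rare);
#: ``depth_decay`` (per cm) ~ Gamma around depth_decay_mean; ``bias_factor``
#: ~ LogNormal(0, bias_lsd).  ``density_scale`` multiplies every kappa and is
#: the single knob for overall propagule density.
GROUP_PRESETS: dict[str, dict[str, float]] = {
    "animal_like": dict(
        richness_total=120,
        subsoil_unique_fraction=0.006,
        kappa_mean=0.02,
        kappa_shape=1.0,
        sigma_mean=1.0,
        sigma_lsd=0.6,
        mu_mean=120.0,
        mu_lsd=1.2,
        depth_decay_mean=0.12,
        depth_decay_shape=2.0,
        bias_lsd=0.6,
        density_scale=1.0,
    ),
    "bacteria_like": dict(
        richness_total=400,
        subsoil_unique_fraction=0.049,
        kappa_mean=0.10,
        kappa_shape=1.5,
        sigma_mean=0.5,
        sigma_lsd=0.5,
        mu_mean=30.0,
        mu_lsd=0.8,
        depth_decay_mean=0.06,
        depth_decay_shape=2.0,
        bias_lsd=0.4,
        density_scale=1.0,
    ),
    "fungus_like": dict(
        richness_total=250,
        subsoil_unique_fraction=0.015,
        kappa_mean=0.05,
        kappa_shape=1.2,
        sigma_mean=0.7,
        sigma_lsd=0.6,
        mu_mean=40.0,
        mu_lsd=1.0,
        depth_decay_mean=0.10,
        depth_decay_shape=2.0,
        bias_lsd=0.5,
        density_scale=1.0,
    ),
}


@dataclass(frozen=True)
class SpeciesParams:
    """Generative parameters of one species.

    kappa
        Parent-cluster intensity (clusters per m^2).
    sigma
        Gaussian cluster spread (m).
    mu
        Mean propagules per cluster.
    depth_decay
        Exponential decay rate of propagule density with depth (per cm).
    subsoil_specialist
        If True the depth profile peaks in the 30-40 cm layer instead.
    bias_factor
        Per-species PCR amplification multiplier (> 0).
    """

    species_id: str
    group: str
    kappa: float
    sigma: float
    mu: float
    depth_decay: float
    subsoil_specialist: bool
    bias_factor: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.kappa <= 0 or self.sigma <= 0 or self.mu <= 0:
            raise ValueError("kappa, sigma and mu must be positive")
        if self.depth_decay < 0:
            raise ValueError("depth_decay must be non-negative")
        if self.bias_factor <= 0:
            raise ValueError("bias_factor must be positive")


@dataclass(frozen=True)
class SpeciesPool:
    group: str
    species: tuple[SpeciesParams, ...]

    @property
    def richness_total(self) -> int:
        return len(self.species)

    @property
    def subsoil_unique_fraction(self) -> float:
        if not self.species:
            return 0.0
        return sum(s.subsoil_specialist for s in self.species) / len(self.species)

    @property
    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.species]

    @property
    def bias_factors(self) -> np.ndarray:
        return np.array([s.bias_factor for s in self.species])


@dataclass
class VirtualSite:
    """One realised propagule point pattern: the "truth" community.

    Coordinates: x, y in metres within [0, extent]^2; z is depth in cm,
    positive downward, within [0, 40].  ``species_index`` maps each point to
    a row of ``pool.species``.
    """

    site_id: str
    extent: float
    pool: SpeciesPool
    seed: int
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    species_index: np.ndarray
    _order: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_points(self) -> int:
        return self.x.size

    def points_of(self, species_id: str) -> np.ndarray:
        idx = self.pool.species_ids.index(species_id)
        mask = self.species_index == idx
        return np.column_stack([self.x[mask], self.y[mask], self.z[mask]])

    def x_sorted_order(self) -> np.ndarray:
        """Indices sorting points by x, cached; used for fast core queries."""
        if self._order is None:
            self._order = np.argsort(self.x, kind="stable")
        return self._order


_OVERRIDABLE = frozenset(
    [
        "richness_total",
        "subsoil_unique_fraction",
        "kappa_mean",
        "kappa_shape",
        "sigma_mean",
        "sigma_lsd",
        "mu_mean",
        "mu_lsd",
        "depth_decay_mean",
        "depth_decay_shape",
        "bias_lsd",
        "density_scale",
    ]
)


def make_species_pool(
    group: str,
    richness_total: int | None = None,
    preset_overrides: Mapping[str, float] | None = None,
    seed: int = 0,
) -> SpeciesPool:
    """Draw a species pool from the group preset distributions.

    Deterministic given ``seed``.  ``preset_overrides`` may only name
    parameters documented in :data:`GROUP_PRESETS`.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    params = dict(GROUP_PRESETS[group])
    if preset_overrides:
        unknown = set(preset_overrides) - _OVERRIDABLE
        if unknown:
            raise ValueError(f"unknown preset overrides: {sorted(unknown)}")
        params.update(preset_overrides)
    if richness_total is None:
        richness_total = int(params["richness_total"])
    if richness_total < 1:
        raise ValueError("richness_total must be >= 1")

    rng = substream(seed, "pool", group)
    n = richness_total
    kappa = rng.gamma(
        params["kappa_shape"], params["kappa_mean"] / params["kappa_shape"], n
    )
    kappa = np.maximum(kappa, 1e-9) * params["density_scale"]
    sigma = params["sigma_mean"] * rng.lognormal(
        -0.5 * params["sigma_lsd"] ** 2, params["sigma_lsd"], n
    )
    mu = params["mu_mean"] * rng.lognormal(
        -0.5 * params["mu_lsd"] ** 2, params["mu_lsd"], n
    )
    mu = np.maximum(mu, 0.1)
    decay = rng.gamma(
        params["depth_decay_shape"],
        max(params["depth_decay_mean"], 1e-12) / params["depth_decay_shape"],
        n,
    )
    bias = rng.lognormal(0.0, params["bias_lsd"], n)
    specialist = rng.random(n) < params["subsoil_unique_fraction"]

    width = len(str(n))
    species = tuple(
        SpeciesParams(
            species_id=f"{group[:3]}_{i:0{width}d}",
            group=group,
            kappa=float(kappa[i]),
            sigma=float(max(sigma[i], 1e-3)),
            mu=float(mu[i]),
            depth_decay=float(decay[i]),
            subsoil_specialist=bool(specialist[i]),
            bias_factor=float(bias[i]),
        )
        for i in range(n)
    )
    return SpeciesPool(group=group, species=species)


def _reflect(v: np.ndarray, extent: float) -> np.ndarray:
    """Reflect coordinates into [0, extent] (mirror at both boundaries)."""
    period = 2.0 * extent
    m = np.mod(v, period)
    return np.where(m > extent, period - m, m)


def _draw_depths(sp: SpeciesParams, size: int, rng: np.random.Generator) -> np.ndarray:
    if sp.subsoil_specialist:
        return rng.triangular(30.0, 35.0, 40.0, size)
    r = sp.depth_decay
    u = rng.random(size)
    if r <= 1e-12:
        return 40.0 * u
    # inverse CDF of the exponential truncated to [0, 40] cm
    return -np.log1p(-u * (1.0 - np.exp(-40.0 * r))) / r


def realise_site(
    pool: SpeciesPool, extent: float, seed: int, site_id: str = "site"
) -> VirtualSite:
    """Realise the propagule point pattern of one plot.

    Per species: parents ~ Poisson(kappa * extent^2) uniform on the square,
    propagules per parent ~ Poisson(mu), displaced by an isotropic Gaussian
    of sd sigma and reflected back inside the plot; depth drawn from the
    species' vertical profile.  Bit-reproducible from (pool, extent, seed).
    """
    if extent <= 0:
        raise ValueError("extent must be positive")
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    zs: list[np.ndarray] = []
    idxs: list[np.ndarray] = []
    for i, sp in enumerate(pool.species):
        rng = substream(seed, "site", site_id, pool.group, i)
        n_parents = rng.poisson(sp.kappa * extent * extent)
        if n_parents == 0:
            continue
        px = rng.uniform(0.0, extent, n_parents)
        py = rng.uniform(0.0, extent, n_parents)
        counts = rng.poisson(sp.mu, n_parents)
        total = int(counts.sum())
        if total == 0:
            continue
        cx = np.repeat(px, counts) + rng.normal(0.0, sp.sigma, total)
        cy = np.repeat(py, counts) + rng.normal(0.0, sp.sigma, total)
        xs.append(_reflect(cx, extent))
        ys.append(_reflect(cy, extent))
        zs.append(_draw_depths(sp, total, rng))
        idxs.append(np.full(total, i, dtype=np.int32))
    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        z = np.concatenate(zs)
        si = np.concatenate(idxs)
    else:
        x = y = z = np.empty(0)
        si = np.empty(0, dtype=np.int32)
    return VirtualSite(
        site_id=site_id, extent=float(extent), pool=pool, seed=int(seed),
        x=x, y=y, z=z, species_index=si,
    )


# ---------------------------------------------------------------------------
# serialisation

def pool_to_frame(pool: SpeciesPool) -> pd.DataFrame:
    """One row per species with every generative parameter (TSV-ready)."""
    return pd.DataFrame(
        dict(
            species_id=[s.species_id for s in pool.species],
            group=[s.group for s in pool.species],
            kappa=[s.kappa for s in pool.species],
            sigma=[s.sigma for s in pool.species],
            mu=[s.mu for s in pool.species],
            depth_decay=[s.depth_decay for s in pool.species],
            subsoil_specialist=[s.subsoil_specialist for s in pool.species],
            bias_factor=[s.bias_factor for s in pool.species],
        )
    )


def pool_from_frame(frame: pd.DataFrame) -> SpeciesPool:
    species = tuple(
        SpeciesParams(
            species_id=str(r.species_id),
            group=str(r.group),
            kappa=float(r.kappa),
            sigma=float(r.sigma),
            mu=float(r.mu),
            depth_decay=float(r.depth_decay),
            subsoil_specialist=bool(r.subsoil_specialist),
            bias_factor=float(r.bias_factor),
        )
        for r in frame.itertuples(index=False)
    )
    if not species:
        raise ValueError("empty species table")
    return SpeciesPool(group=species[0].group, species=species)


def site_points_to_frame(site: VirtualSite) -> pd.DataFrame:
    ids = np.asarray(site.pool.species_ids, dtype=object)
    return pd.DataFrame(
        dict(
            species_id=ids[site.species_index],
            x=site.x,
            y=site.y,
            z=site.z,
        )
    )
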