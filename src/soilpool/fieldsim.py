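"""Sampling designs and virtual coring.

A :class:`DesignSpec` encodes one published soil-sampling design: how many
subsamples, over what area, at which depth intervals, with what core
diameter, and — for composite protocols — the nested grouping tree that
says which physical cores are merged into which composite sample.
:func:`builtin_designs` returns twelve such designs spanning widely used
continental and global soil biodiversity monitoring protocols, from 5
cores over 16 m^2 to 75 hierarchically composited cores over 2500 m^2.

Design areas are modelled as concentric squares (side = sqrt(area)) around
the plot centre.  Core positions use continuous metre coordinates with the
origin at the plot centre; depth is positive downward in cm and depth
intervals are half-open [top, bottom) so stacked intervals never double
count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._rng import substream
from .synthcomm import VirtualSite

__all__ = [
    "DesignSpec",
    "CoreSample",
    "builtin_designs",
    "get_design",
    "place_cores",
    "take_core",
    "collect_cores",
    "subset_positions",
]


@dataclass(frozen=True)
class DesignSpec:
    """One sampling design.

    ``composite_tree`` is a tuple of branching factors, top-down: (3, 5, 5)
    means 3 top-level composites, each merging 5 composites of 5 physical
    cores.  ``None`` means a flat design (pooling merges all cores into a
    single composite).  Designs with a composite tree are field protocols
    that only exist in pooled form.
    """

    name: str
    n_subsamples: int
    area: float
    depth_intervals: tuple[tuple[float, float], ...]
    core_diameter: float
    composite_tree: tuple[int, ...] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")
        if self.area <= 0:
            raise ValueError("area must be positive")
        ivs = sorted(self.depth_intervals)
        for top, bottom in ivs:
            if not top < bottom:
                raise ValueError(f"degenerate depth interval ({top}, {bottom})")
        for (_, b1), (t2, _) in zip(ivs, ivs[1:]):
            if t2 < b1:
                raise ValueError("depth intervals overlap")
        if self.composite_tree is not None:
            if self.n_leaves != self.n_subsamples * len(self.depth_intervals):
                raise ValueError(
                    "composite tree leaves must equal n_subsamples x depth intervals"
                )

    @property
    def n_leaves(self) -> int:
        """Physical cores per plot (tree leaves, or N x depth intervals)."""
        if self.composite_tree is None:
            return self.n_subsamples * len(self.depth_intervals)
        return int(np.prod(self.composite_tree))

    @property
    def n_top_composites(self) -> int:
        """Pooled samples produced per plot (1 for flat designs)."""
        if self.composite_tree is None:
            return 1
        return self.composite_tree[0]

    @property
    def pooled_only(self) -> bool:
        return self.composite_tree is not None

    @property
    def side(self) -> float:
        return math.sqrt(self.area)


@dataclass
class CoreSample:
    """One physical soil core and its per-species propagule (template) counts."""

    sample_id: str
    site_id: str
    design_name: str
    x: float
    y: float
    depth_top: float
    depth_bottom: float
    diameter: float
    templates: np.ndarray

    @property
    def total(self) -> int:
        return int(self.templates.sum())


def builtin_designs() -> list[DesignSpec]:
    """The twelve compared designs (N = subsamples, D = depth range in cm)."""
    d = [
        DesignSpec("N62D0-5", 62, 2500, ((0, 5),), 5, None, "global topsoil survey protocol"),
        DesignSpec("N40D0-5A", 40, 2500, ((0, 5),), 5, None, "global topsoil survey protocol"),
        DesignSpec("N40D0-5B", 40, 1400, ((0, 5),), 5, None, "global topsoil survey protocol"),
        DesignSpec("N9D0-1", 9, 900, ((0, 1),), 5, None, "global AM fungal survey protocol"),
        DesignSpec("N8D0-10", 8, 100, ((0, 10),), 5, None, "grassland dark-diversity protocol"),
        DesignSpec("N5D0-20", 5, 16, ((0, 20),), 5, None, "continental LUCAS-soil protocol"),
        DesignSpec("N9D0-10", 9, 900, ((0, 10),), 5, None, "Soil BON monitoring protocol"),
        DesignSpec("N9D30-40", 9, 900, ((30, 40),), 5, None, "Soil BON monitoring protocol"),
        DesignSpec("N9D0-40", 9, 900, ((0, 10), (30, 40)), 5, None, "Soil BON monitoring protocol"),
        DesignSpec("N25D0-7.5", 25, 2500, ((0, 7.5),), 2.5, (5, 5),
                   "global drylands composite protocol"),
        DesignSpec("N75D0-7.5", 75, 2500, ((0, 7.5),), 2.5, (3, 5, 5),
                   "global drylands composite protocol"),
        DesignSpec("N50D0-7.5", 50, 900, ((0, 7.5),), 2.5, (10, 5),
                   "global drylands composite protocol"),
    ]
    return d


def get_design(name: str) -> DesignSpec:
    for spec in builtin_designs():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown design {name!r}")


def place_cores(
    design: DesignSpec,
    site: VirtualSite,
    seed: int,
    max_tries_per_core: int = 2000,
) -> np.ndarray:
    """Core-centre positions, uniform in the design's central square.

    Returns an (n_subsamples, 2) array in plot-centred coordinates.  A
    minimum pairwise spacing of twice the core diameter is enforced by
    rejection sampling; deterministic given ``seed``.
    """
    side = design.side
    if side > site.extent + 1e-9:
        raise ValueError(
            f"design area {design.area} m^2 does not fit in the "
            f"{site.extent} m site"
        )
    rng = substream(seed, "place", design.name, site.site_id)
    half = side / 2.0
    min_d2 = (2.0 * design.core_diameter / 100.0) ** 2
    pos = np.empty((design.n_subsamples, 2))
    for i in range(design.n_subsamples):
        for _ in range(max_tries_per_core):
            p = rng.uniform(-half, half, 2)
            if i == 0 or np.min(np.sum((pos[:i] - p) ** 2, axis=1)) >= min_d2:
                pos[i] = p
                break
        else:
            raise RuntimeError(
                f"could not place core {i + 1}/{design.n_subsamples} of "
                f"{design.name} with the required spacing"
            )
    return pos


def subset_positions(positions: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Pick k of an existing layout (e.g., nest N40D0-5A inside N62D0-5)."""
    if k > len(positions):
        raise ValueError("subset larger than layout")
    rng = substream(seed, "subset", len(positions), k)
    idx = rng.choice(len(positions), size=k, replace=False)
    return positions[np.sort(idx)]


def take_core(
    site: VirtualSite,
    x: float,
    y: float,
    depth: tuple[float, float],
    diameter: float,
    sample_id: str = "core",
    design_name: str = "",
) -> CoreSample:
    """Count propagules inside one core cylinder.

    ``x, y`` are plot-centred metres; the cylinder has horizontal radius
    ``diameter / 200`` m and spans depth [top, bottom) in cm.
    """
    top, bottom = depth
    if not top < bottom:
        raise ValueError(f"degenerate depth interval ({top}, {bottom})")
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    cx = x + site.extent / 2.0
    cy = y + site.extent / 2.0
    r = diameter / 200.0
    order = site.x_sorted_order()
    xs = site.x[order]
    lo = np.searchsorted(xs, cx - r, side="left")
    hi = np.searchsorted(xs, cx + r, side="right")
    band = order[lo:hi]
    dy = site.y[band] - cy
    dx = site.x[band] - cx
    zin = (site.z[band] >= top) & (site.z[band] < bottom)
    inside = band[(dx * dx + dy * dy <= r * r) & zin]
    counts = np.bincount(
        site.species_index[inside], minlength=site.pool.richness_total
    ).astype(np.int64)
    return CoreSample(
        sample_id=sample_id,
        site_id=site.site_id,
        design_name=design_name,
        x=float(x),
        y=float(y),
        depth_top=float(top),
        depth_bottom=float(bottom),
        diameter=float(diameter),
        templates=counts,
    )


def collect_cores(
    design: DesignSpec, site: VirtualSite, seed: int
) -> list[CoreSample]:
    """Place and extract every physical core of a design on a site.

    For multi-interval designs each position yields one core per depth
    interval (leaf order: position-major, then interval).
    """
    positions = place_cores(design, site, seed)
    cores: list[CoreSample] = []
    for i, (px, py) in enumerate(positions):
        for j, iv in enumerate(design.depth_intervals):
            suffix = f"_d{j}" if len(design.depth_intervals) > 1 else ""
            cores.append(
                take_core(
                    site,
                    float(px),
                    float(py),
                    iv,
                    design.core_diameter,
                    sample_id=f"{site.site_id}_{design.name}_c{i:02d}{suffix}",
                    design_name=design.name,
                )
            )
    return cores
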