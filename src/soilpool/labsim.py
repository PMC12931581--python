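"""Wet-lab simulator: pooling, DNA extraction, biased PCR and sequencing.

The chain mirrors the physical workflow.  Soil pooling mixes equal masses of
crushed soil, i.e. averages the cores' relative template compositions
(optionally with mass jitter).  DNA pooling mixes equal volumes of the
per-core extracts, i.e. averages the extracts' compositions.  A DNA
extraction recovers a Poisson number of template molecules per species from
a fixed 0.2 g aliquot — the root of the dilution effect: a species confined
to one of N pooled cores enters the extraction at 1/N of its within-core
proportion and is lost with probability exp(-T q / N).  PCR amplifies
templates with per-species bias factors (plus per-run log-normal jitter) and
spawns artefact OTUs — per-PCR chimeras and other spurious sequences — at a
rate that grows with read depth and with the effective diversity of the
template mixture.  Sequencing allocates a negative-binomially distributed
read depth multinomially across amplicons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .fieldsim import CoreSample, DesignSpec, collect_cores
from .synthcomm import SpeciesPool, VirtualSite

__all__ = [
    "LabConfig",
    "ReadTable",
    "OtuRegistry",
    "STRATEGIES",
    "pool_soil",
    "pool_dna",
    "extract_dna",
    "pcr_and_sequence",
    "run_survey",
]

log = logging.getLogger(__name__)

STRATEGIES = ("unpooled", "soil_pool", "dna_pool")

#: tolerance for composition-normalisation checks
NORM_TOL = 1e-9


@dataclass(frozen=True)
class LabConfig:
    """Rates and sizes of the simulated wet lab.

    templates_per_extraction
        Expected template molecules recovered from one 0.2 g extraction.
    pcr_template_aliquot
        Expected templates entering one PCR; defaults to
        ``templates_per_extraction`` when None.
    bias_sd
        SD of the per-PCR log-normal amplification jitter applied on top of
        the species-level bias factors.
    artefact_rate
        Expected new artefact OTUs per 1000 reads per PCR (baseline).
    chimera_coeff
        Adds ``chimera_coeff * Hill1(template proportions)`` to the artefact
        rate: chimera formation escalates with template diversity.
    artefact_read_share
        Read-weight of each artefact OTU relative to the total biological
        amplicon mass (low-abundance by construction).
    reads_mean, reads_dispersion
        Negative-binomial per-sample sequencing depth (mean, shape).
    reads_mean_pooled
        Depth mean for pooled samples (pools are typically sequenced
        deeper); falls back to ``reads_mean`` when None.
    mass_jitter_sd, concentration_jitter_sd
        Optional log-normal jitter of per-core soil masses / extract
        concentrations during pooling (0 = exactly equal, the default).
    """

    templates_per_extraction: float = 6000.0
    pcr_template_aliquot: float | None = None
    bias_sd: float = 0.3
    artefact_rate: float = 0.05
    chimera_coeff: float = 1e-4
    artefact_read_share: float = 2e-4
    reads_mean: float = 800.0
    reads_dispersion: float = 0.8
    reads_mean_pooled: float | None = None
    reads_dispersion_pooled: float | None = None
    mass_jitter_sd: float = 0.0
    concentration_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.templates_per_extraction < 1:
            raise ValueError("templates_per_extraction must be >= 1")
        for name in ("bias_sd", "artefact_rate", "chimera_coeff",
                     "artefact_read_share", "reads_mean", "reads_dispersion",
                     "mass_jitter_sd", "concentration_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def aliquot(self) -> float:
        return (self.pcr_template_aliquot
                if self.pcr_template_aliquot is not None
                else self.templates_per_extraction)


class OtuRegistry:
    """Maps every OTU to its origin: a biological species or a generating PCR."""

    def __init__(self) -> None:
        self._records: dict[str, tuple[str, str]] = {}
        self._n_artefacts = 0

    def register_biological(self, otu_id: str, species_id: str) -> None:
        self._records.setdefault(otu_id, ("biological", species_id))

    def new_artefact(self, pcr_id: str) -> str:
        self._n_artefacts += 1
        otu_id = f"art{self._n_artefacts:05d}_{pcr_id}"
        self._records[otu_id] = ("artefact", pcr_id)
        return otu_id

    def origin(self, otu_id: str) -> str:
        return self._records[otu_id][0]

    def parent(self, otu_id: str) -> str:
        return self._records[otu_id][1]

    def to_frame(self) -> pd.DataFrame:
        if not self._records:
            return pd.DataFrame(columns=["origin", "parent"])
        return pd.DataFrame.from_dict(
            self._records, orient="index", columns=["origin", "parent"]
        ).rename_axis("otu_id")

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self._records

    def __len__(self) -> int:
        return len(self._records)


@dataclass
class ReadTable:
    """Samples x OTU count matrix plus sample metadata and the OTU registry.

    ``counts`` rows are samples (index sample_id) and columns OTU ids; every
    column has at least one read; row sums equal ``sample_meta.total_reads``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    otu_registry: pd.DataFrame

    def validate(self) -> None:
        if not self.counts.index.equals(self.sample_meta.index):
            raise ValueError("counts and sample_meta indices differ")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        sums = self.counts.sum(axis=1)
        if not (sums == self.sample_meta["total_reads"]).all():
            raise ValueError("row sums do not match recorded total reads")
        nonempty = (self.counts.sum(axis=0) > 0).all() if self.counts.shape[1] else True
        if not nonempty:
            raise ValueError("empty OTU column")
        missing = set(self.counts.columns) - set(self.otu_registry.index)
        if missing:
            raise ValueError(f"OTUs missing from registry: {sorted(missing)[:5]}")

    def subset(self, mask: pd.Series) -> "ReadTable":
        counts = self.counts.loc[mask.values]
        counts = counts.loc[:, counts.sum(axis=0) > 0]
        return ReadTable(
            counts=counts,
            sample_meta=self.sample_meta.loc[mask.values],
            otu_registry=self.otu_registry,
        )

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]


# ---------------------------------------------------------------------------
# mixing operations


def _as_composition(templates: np.ndarray) -> np.ndarray:
    templates = np.asarray(templates, dtype=float)
    total = templates.sum()
    if total <= 0:
        return np.zeros_like(templates)
    return templates / total


def pool_soil(
    cores: Sequence[CoreSample | np.ndarray],
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Equal-mass soil compositing: mean of per-core relative abundances.

    Cores with no templates contribute a zero vector but still count in the
    mean (their soil mass carries no DNA).  ``weights`` (optional, positive)
    model unequal aliquot masses.
    """
    if len(cores) == 0:
        raise ValueError("empty core list")
    comps = [
        _as_composition(c.templates if isinstance(c, CoreSample) else c)
        for c in cores
    ]
    if all(c.sum() == 0 for c in comps):
        raise ValueError("all cores are empty")
    if weights is None:
        mix = np.mean(comps, axis=0)
    else:
        w = np.asarray(weights, dtype=float)
        mix = np.average(comps, axis=0, weights=w)
    return mix / mix.sum()


def pool_dna(extracts: Sequence[np.ndarray], weights: np.ndarray | None = None) -> np.ndarray:
    """Equal-volume, equal-concentration DNA mixing: unweighted mean of
    extract compositions (zero extracts count as zero vectors)."""
    if len(extracts) == 0:
        raise ValueError("empty extract list")
    comps = [_as_composition(e) for e in extracts]
    if weights is None:
        mix = np.mean(comps, axis=0)
    else:
        w = np.asarray(weights, dtype=float)
        mix = np.average(comps, axis=0, weights=w)
    total = mix.sum()
    if total <= 0:
        return mix
    return mix / total


def extract_dna(
    composition: np.ndarray,
    config: LabConfig,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw per-species template counts ~ Poisson(T * p_s) from one aliquot.

    Species drawing zero templates are lost for every downstream step — the
    dilution effect in action.
    """
    if isinstance(rng, (int, np.integer)):
        rng = substream(int(rng), "extract")
    p = np.asarray(composition, dtype=float)
    if (p < 0).any():
        raise ValueError("negative proportions")
    if abs(p.sum() - 1.0) > 1e-6 and p.sum() > 0:
        raise ValueError("composition must sum to 1")
    return rng.poisson(config.templates_per_extraction * p)


def _hill1(p: np.ndarray) -> float:
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    p = p / p.sum()
    return float(np.exp(-np.sum(p * np.log(p))))


def pcr_and_sequence(
    templates: np.ndarray,
    registry: OtuRegistry,
    config: LabConfig,
    depth: int,
    rng: np.random.Generator,
    bias_factors: np.ndarray,
    species_ids: Sequence[str],
    pcr_id: str,
) -> dict[str, int]:
    """Amplify and sequence one PCR; returns {otu_id: reads}.

    Biological read weights are templates * bias * per-PCR jitter.  The PCR
    also spawns ``Poisson(depth/1000 * (artefact_rate + chimera_coeff *
    Hill1(template proportions)))`` brand-new artefact OTUs, each with a
    small fixed share of the amplicon mass; reads are multinomial at the
    given depth.  Artefact OTUs are unique to their generating PCR.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if depth == 0:
        return {}
    templates = np.asarray(templates, dtype=float)
    if templates.sum() <= 0:
        raise ValueError("empty template vector with positive depth")

    weights = templates * np.asarray(bias_factors, dtype=float)
    if config.bias_sd > 0:
        weights = weights * rng.lognormal(0.0, config.bias_sd, weights.size)

    rate = config.artefact_rate + config.chimera_coeff * _hill1(templates)
    n_art = rng.poisson(depth / 1000.0 * rate)
    total_bio = weights.sum()
    art_w = np.full(n_art, config.artefact_read_share * total_bio)
    allw = np.concatenate([weights, art_w])
    reads = rng.multinomial(depth, allw / allw.sum())

    row: dict[str, int] = {}
    for i, c in enumerate(reads[: weights.size]):
        if c > 0:
            sid = species_ids[i]
            registry.register_biological(sid, sid)
            row[sid] = int(c)
    for c in reads[weights.size:]:
        if c > 0:
            row[registry.new_artefact(pcr_id)] = int(c)
    return row


# ---------------------------------------------------------------------------
# survey orchestration


def _draw_depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _tree_groups(tree: Sequence[int] | None, n_leaves: int) -> list[list[int]]:
    """Leaf indices of each top-level composite (single group when flat)."""
    if tree is None:
        return [list(range(n_leaves))]
    per_top = int(np.prod(tree[1:])) if len(tree) > 1 else 1
    return [
        list(range(g * per_top, (g + 1) * per_top)) for g in range(tree[0])
    ]


def _nested_pool(
    comps: list[np.ndarray], tree: Sequence[int] | None, rng: np.random.Generator,
    jitter_sd: float,
) -> np.ndarray:
    """Pool compositions bottom-up along the (sub)tree below one top node."""
    def weights(k: int) -> np.ndarray | None:
        if jitter_sd <= 0:
            return None
        return rng.lognormal(0.0, jitter_sd, k)

    if tree is None or len(tree) <= 1:
        return pool_soil(comps, weights(len(comps)))
    branch = tree[1]
    size = len(comps) // branch
    subs = [
        _nested_pool(comps[i * size:(i + 1) * size], tree[1:], rng, jitter_sd)
        for i in range(branch)
    ]
    return pool_soil(subs, weights(branch))


def run_survey(
    sites: Sequence[VirtualSite],
    designs: Sequence[DesignSpec],
    strategies: Sequence[str],
    config: LabConfig,
    seed: int,
    share_layouts: bool = True,
) -> ReadTable:
    """Run the full virtual campaign and return one ReadTable.

    Unpooled processing yields one row per physical core; soil and DNA
    pooling yield one row per top-level composite (one for flat designs).
    Unpooled is skipped with a warning for composite-only designs.  With
    ``share_layouts`` the three strategies of a (site, design) cell reuse the
    same physical cores, as in a real revisit of the same holes.
    """
    for s in strategies:
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}")
    registry = OtuRegistry()
    rows: dict[str, dict[str, int]] = {}
    meta: list[dict] = []

    for site in sites:
        species_ids = site.pool.species_ids
        bias = site.pool.bias_factors
        for design in designs:
            cores = collect_cores(design, site, seed)
            comps = [_as_composition(c.templates) for c in cores]
            groups = _tree_groups(design.composite_tree, len(cores))

            def seq_row(sample_id, templates, depth_mean, meta_extra, rng,
                        dispersion=None):
                if dispersion is None:
                    dispersion = config.reads_dispersion
                depth = _draw_depth(rng, depth_mean, dispersion)
                if templates.sum() <= 0:
                    depth = 0
                row = (
                    pcr_and_sequence(
                        templates, registry, config, depth, rng, bias,
                        species_ids, pcr_id=sample_id,
                    )
                    if depth > 0
                    else {}
                )
                rows[sample_id] = row
                meta.append(
                    dict(
                        sample_id=sample_id, site=site.site_id,
                        design=design.name, total_reads=sum(row.values()),
                        **meta_extra,
                    )
                )

            pooled_mean = (
                config.reads_mean_pooled
                if config.reads_mean_pooled is not None
                else config.reads_mean
            )
            pooled_disp = (
                config.reads_dispersion_pooled
                if config.reads_dispersion_pooled is not None
                else config.reads_dispersion
            )

            for strategy in strategies:
                if strategy == "unpooled":
                    if design.pooled_only:
                        warnings.warn(
                            f"{design.name} exists only in pooled form; "
                            "skipping unpooled", stacklevel=2,
                        )
                        continue
                    for core in cores:
                        rng = substream(seed, "lab", site.site_id, design.name,
                                        "unpooled", core.sample_id)
                        extract = extract_dna(_as_composition(core.templates),
                                              config, rng) if core.total else np.zeros(len(species_ids))
                        aliquot = rng.poisson(
                            config.aliquot * _as_composition(extract))
                        seq_row(
                            f"{core.sample_id}_U", aliquot, config.reads_mean,
                            dict(strategy="unpooled", x=core.x, y=core.y,
                                 depth_top=core.depth_top,
                                 depth_bottom=core.depth_bottom, composite=""),
                            rng,
                        )
                elif strategy == "soil_pool":
                    for g, leaf_idx in enumerate(groups):
                        rng = substream(seed, "lab", site.site_id, design.name,
                                        "soil_pool", g)
                        sub = [comps[i] for i in leaf_idx]
                        if all(c.sum() == 0 for c in sub):
                            mix = np.zeros(len(species_ids))
                        else:
                            mix = _nested_pool(
                                sub,
                                (design.composite_tree[1:]
                                 if design.composite_tree and len(design.composite_tree) > 1
                                 else None),
                                rng, config.mass_jitter_sd,
                            )
                        extract = (extract_dna(mix, config, rng)
                                   if mix.sum() > 0 else mix)
                        aliquot = rng.poisson(
                            config.aliquot * _as_composition(extract))
                        label = f"p{g}" if len(groups) > 1 else "pool"
                        seq_row(
                            f"{site.site_id}_{design.name}_S_{label}", aliquot,
                            pooled_mean,
                            dict(strategy="soil_pool", x=np.nan, y=np.nan,
                                 depth_top=design.depth_intervals[0][0],
                                 depth_bottom=design.depth_intervals[-1][1],
                                 composite=label),
                            rng, pooled_disp,
                        )
                elif strategy == "dna_pool":
                    for g, leaf_idx in enumerate(groups):
                        rng = substream(seed, "lab", site.site_id, design.name,
                                        "dna_pool", g)
                        extracts = []
                        for i in leaf_idx:
                            extracts.append(
                                extract_dna(comps[i], config, rng)
                                if comps[i].sum() > 0
                                else np.zeros(len(species_ids))
                            )
                        w = (rng.lognormal(0.0, config.concentration_jitter_sd,
                                           len(extracts))
                             if config.concentration_jitter_sd > 0 else None)
                        mix = pool_dna(extracts, w)
                        aliquot = rng.poisson(config.aliquot * mix)
                        label = f"p{g}" if len(groups) > 1 else "pool"
                        seq_row(
                            f"{site.site_id}_{design.name}_D_{label}", aliquot,
                            pooled_mean,
                            dict(strategy="dna_pool", x=np.nan, y=np.nan,
                                 depth_top=design.depth_intervals[0][0],
                                 depth_bottom=design.depth_intervals[-1][1],
                                 composite=label),
                            rng, pooled_disp,
                        )

    counts = (
        pd.DataFrame.from_dict(rows, orient="index")
        .fillna(0)
        .astype(np.int64)
    )
    counts = counts.loc[:, counts.sum(axis=0) > 0] if counts.shape[1] else counts
    counts = counts.reindex(index=[m["sample_id"] for m in meta], fill_value=0)
    counts.index.name = "sample_id"
    meta_df = pd.DataFrame(meta).set_index("sample_id")
    table = ReadTable(counts=counts, sample_meta=meta_df,
                      otu_registry=registry.to_frame())
    table.validate()
    return table
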