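"""Configuration, table I/O and the end-to-end experiment runner.

`run_experiment` strings a complete virtual campaign together on
synthetic data: realise virtual plots per organism group, run the virtual field and
lab campaign under every requested pooling strategy, then produce the
standard analysis artefacts — per-sample diversity tables, design
summaries, ratio matrices, site rankings, pooling-effect curves with
break-even depths, community statistics, the artefact screening report and
the cost reports — plus a JSON manifest recording every seed.

All tables are TSV for diff-ability; sequences are FASTA.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import key_of
from .commstats import bray_curtis, dispersion_homogeneity, permanova
from .costcalc import CostModel, break_even_depth, compute_costs
from .design_eval import (
    DesignSummary,
    design_ratios,
    pe_frame,
    pooling_effect,
    rank_sites,
    summarise_design,
)
from .divmetrics import diversity_table
from .fieldsim import DesignSpec, builtin_designs
from .labsim import LabConfig, ReadTable, run_survey
from .screenfx import (
    align_global,
    classify_rare,
    classify_unique,
    make_synthetic_alignment,
    screen_artefacts,
    write_fasta,
)
from .synthcomm import GROUPS, make_species_pool, pool_to_frame, realise_site

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_experiment", "read_otu_table", "write_otu_table",
           "scale_design"]


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; YAML round-trippable."""

    seed: int = 1
    n_sites: int = 3
    extent: float = 6.0
    groups: list = field(default_factory=lambda: list(GROUPS))
    designs: list = field(default_factory=lambda: [d.name for d in builtin_designs()])
    strategies: list = field(default_factory=lambda: ["unpooled", "soil_pool", "dna_pool"])
    density_scale: float = 50.0
    geometry_fill: float = 0.9  # largest design area as a fraction of the plot
    lab: dict = field(default_factory=dict)
    rarefaction_iterations: int = 100
    depth_fractions: list = field(default_factory=lambda: [0.25, 0.5, 0.75, 1.0])
    rare_threshold: float = 0.0005
    n_permutations: int = 199
    reference_design: str = "N62D0-5"
    ratio_exclusions: list = field(default_factory=lambda: ["N9D30-40"])
    screen_max_otus: int = 80
    cost_plots: int = 100

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def lab_config(self) -> LabConfig:
        return LabConfig(**self.lab)


def scale_design(design: DesignSpec, area_factor: float) -> DesignSpec:
    """Shrink a design's area (geometry only; N, depths, pooling unchanged)."""
    return dataclasses.replace(design, area=design.area * area_factor)


# ---------------------------------------------------------------------------
# OTU table I/O


def write_otu_table(table: ReadTable, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = dict(
        counts=outdir / "otu_table.tsv",
        meta=outdir / "sample_metadata.tsv",
        registry=outdir / "otu_registry.tsv",
    )
    table.counts.to_csv(paths["counts"], sep="\t")
    table.sample_meta.to_csv(paths["meta"], sep="\t")
    table.otu_registry.to_csv(paths["registry"], sep="\t")
    return paths


def read_otu_table(counts_path, meta_path, registry_path=None) -> ReadTable:
    """Strict TSV reader: integer cells, unique sample ids, matching metadata.

    Errors carry the offending row/column so malformed uploads are easy to
    fix.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {counts_path}")
    for col in counts.columns:
        vals = counts[col]
        if not np.issubdtype(vals.dtype, np.number) or (vals % 1 != 0).any():
            bad = vals.index[(pd.to_numeric(vals, errors="coerce") % 1 != 0)
                             | pd.to_numeric(vals, errors="coerce").isna()]
            raise ValueError(
                f"non-integer count at sample {bad[0]!r}, OTU {col!r}"
            )
        if (vals < 0).any():
            bad = vals.index[vals < 0][0]
            raise ValueError(f"negative count at sample {bad!r}, OTU {col!r}")
    counts = counts.astype(np.int64)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    missing = set(counts.index) - set(meta.index)
    if missing:
        raise ValueError(f"samples missing metadata: {sorted(missing)[:5]}")
    meta = meta.loc[counts.index]
    if "total_reads" not in meta.columns:
        meta = meta.assign(total_reads=counts.sum(axis=1))
    if registry_path is not None:
        registry = pd.read_csv(registry_path, sep="\t", index_col=0)
    else:
        registry = pd.DataFrame(
            dict(origin="biological", parent=list(counts.columns)),
            index=counts.columns,
        ).rename_axis("otu_id")
    table = ReadTable(counts=counts, sample_meta=meta, otu_registry=registry)
    table.validate()
    return table


# ---------------------------------------------------------------------------
# end-to-end runner


def run_experiment(config: RunConfig, outdir) -> dict:
    """Run simulate -> survey -> analyse -> report; returns the manifest.

    Output files land under ``outdir/<group>/``; a failure in any stage
    raises with the stage name while earlier outputs stay on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lab = config.lab_config()
    designs = {d.name: d for d in builtin_designs()}
    unknown = set(config.designs) - set(designs)
    if unknown:
        raise ValueError(f"unknown designs: {sorted(unknown)}")
    chosen = [designs[n] for n in config.designs]
    max_area = max(d.area for d in chosen)
    factor = min(1.0, config.geometry_fill * config.extent**2 / max_area)
    scaled = [scale_design(d, factor) for d in chosen]
    manifest: dict = dict(
        package_version=__version__,
        config=asdict(config),
        area_scale_factor=factor,
        stage_seeds={},
        groups={},
    )

    for group in config.groups:
        stage = f"simulate[{group}]"
        gdir = outdir / group
        gdir.mkdir(exist_ok=True)
        try:
            pool_seed = key_of((config.seed, group, "pool")) % (2**31 - 1)
            pool = make_species_pool(
                group, preset_overrides=dict(density_scale=config.density_scale),
                seed=pool_seed,
            )
            pool_to_frame(pool).to_csv(gdir / "species_pool.tsv", sep="\t",
                                       index=False)
            sites = []
            for s in range(config.n_sites):
                site_seed = key_of((config.seed, group, "site", s)) % (2**31 - 1)
                sites.append(
                    realise_site(pool, config.extent, site_seed,
                                 site_id=f"site{s + 1}")
                )
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

        stage = f"survey[{group}]"
        try:
            survey_seed = key_of((config.seed, group, "survey")) % (2**31 - 1)
            table = run_survey(sites, scaled, config.strategies, lab,
                               survey_seed)
            write_otu_table(table, gdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

        stage = f"analyse[{group}]"
        try:
            ana_seed = key_of((config.seed, group, "analysis")) % (2**31 - 1)
            results = _analyse_group(table, config, ana_seed, gdir)
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

        manifest["stage_seeds"][group] = dict(
            pool=pool_seed, survey=survey_seed, analysis=ana_seed,
            sites={s.site_id: s.seed for s in sites},
        )
        manifest["groups"][group] = results

    stage = "costs"
    try:
        cost_rows = []
        for d in chosen:
            for strat in ("soil_pool", "dna_pool"):
                r = compute_costs(designs[d.name], strat, config.cost_plots)
                cost_rows.append(dataclasses.asdict(r))
        pd.DataFrame(cost_rows).to_csv(outdir / "cost_reports.tsv", sep="\t",
                                       index=False)
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return manifest


def _analyse_group(table: ReadTable, config: RunConfig, seed: int,
                   gdir: Path) -> dict:
    meta = table.sample_meta
    results: dict = {}

    # per-sample diversity
    div = diversity_table(table.counts, depth=None, seed=seed)
    div = div.join(meta[["site", "design", "strategy"]])
    div.to_csv(gdir / "diversity_per_sample.tsv", sep="\t")

    # design summaries on unpooled strata
    summaries: list[DesignSummary] = []
    unpooled = meta[meta["strategy"] == "unpooled"]
    for (site, design), sub in unpooled.groupby(["site", "design"]):
        if (table.counts.loc[sub.index].sum(axis=1) >= 100).sum() == 0:
            continue
        try:
            summaries.append(
                summarise_design(table, site, design,
                                 iterations=config.rarefaction_iterations,
                                 seed=seed)
            )
        except ValueError:
            continue
    if summaries:
        pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
            gdir / "design_summaries.tsv", sep="\t", index=False
        )
        ref = config.reference_design
        if any(s.design_name == ref for s in summaries):
            for q in (0, 1):
                ratios = design_ratios(summaries, ref,
                                       config.ratio_exclusions, q=q)
                ratios.to_csv(gdir / f"design_ratios_q{q}.tsv", sep="\t")
                results[f"max_ratio_q{q}"] = float(np.nanmax(ratios.values))
        sites_present = {s.site_id for s in summaries}
        if len(sites_present) >= 2:
            rk = rank_sites(summaries)
            rk["concordance"].to_csv(gdir / "site_rank_concordance.tsv",
                                     sep="\t")
            results["min_rank_concordance"] = float(
                np.nanmin(rk["concordance"].values)
            )

    # pooling effect for designs with both arms
    pe_rows = []
    breakevens = []
    for (site, design), sub in meta.groupby(["site", "design"]):
        strategies = set(sub["strategy"])
        if "unpooled" not in strategies:
            continue
        for strat in ("soil_pool", "dna_pool"):
            if strat not in strategies:
                continue
            for q in (0, 1):
                try:
                    res = pooling_effect(
                        table, site, design, strat, q=q,
                        depth_fractions=config.depth_fractions,
                        iterations=config.rarefaction_iterations, seed=seed,
                    )
                except ValueError:
                    continue
                pe_rows.extend(res)
                finite = [r for r in res if np.isfinite(r.pe)]
                if q == 0 and len(finite) >= 2:
                    be = break_even_depth(finite)
                    breakevens.append(
                        dict(site=site, design=design, strategy=strat, **be)
                    )
    if pe_rows:
        pe_frame(pe_rows).to_csv(gdir / "pooling_effect.tsv", sep="\t",
                                 index=False)
        pd.DataFrame(breakevens).to_csv(gdir / "break_even.tsv", sep="\t",
                                        index=False)
        finite = [r.pe for r in pe_rows if np.isfinite(r.pe)]
        if finite:
            results["median_pe"] = float(np.median(finite))

    # community statistics on unpooled samples across designs
    up_idx = meta.index[(meta["strategy"] == "unpooled")
                        & (meta["total_reads"] >= 100)]
    if len(up_idx) >= 6 and meta.loc[up_idx, "design"].nunique() >= 2:
        d = bray_curtis(table.counts.loc[up_idx])
        perm = permanova(
            d, meta.loc[up_idx, "design"].values,
            strata=meta.loc[up_idx, "site"].values,
            n_permutations=config.n_permutations, seed=seed,
        )
        results["permanova"] = dict(F=perm.pseudo_F, R2=perm.R2, p=perm.p)
        disp_rows = []
        for site in meta.loc[up_idx, "site"].unique():
            site_idx = up_idx[meta.loc[up_idx, "site"] == site]
            if meta.loc[site_idx, "design"].nunique() < 2 or len(site_idx) < 6:
                continue
            ds = bray_curtis(table.counts.loc[site_idx])
            disp = dispersion_homogeneity(
                ds, meta.loc[site_idx, "design"].values,
                n_permutations=config.n_permutations, seed=seed,
            )
            disp_rows.append(dict(site=site, F=disp["F"], p=disp["p"]))
        if disp_rows:
            pd.DataFrame(disp_rows).to_csv(gdir / "dispersion_tests.tsv",
                                           sep="\t", index=False)

    # rare / unique classification + artefact screening on a subset
    rare = classify_rare(table, config.rare_threshold, stratum="site")
    registry = table.otu_registry
    subset = registry.iloc[: config.screen_max_otus]
    fx = make_synthetic_alignment(subset, seed)
    write_fasta(fx["otus"], gdir / "otus_synthetic.fasta",
                window=(fx["window_start"], fx["window_length"]))
    write_fasta(fx["references"], gdir / "references_synthetic.fasta")
    rows = []
    for otu_id, seq in fx["otus"].items():
        ref = fx["references"][fx["best_reference"][otu_id]]
        pair = align_global(seq, ref, query_id=otu_id)
        flags = screen_artefacts(pair, fx["window_start"], fx["window_length"])
        rows.append(
            dict(
                otu_id=otu_id,
                rare=bool(rare.loc[otu_id].any()) if otu_id in rare.index else False,
                flags=";".join(sorted(flags)),
                flagged_artefact=bool(flags),
                truth_origin=registry.loc[otu_id, "origin"],
            )
        )
    screen = pd.DataFrame(rows)
    screen.to_csv(gdir / "otu_screening.tsv", sep="\t", index=False)
    truly = (subset["origin"] == "artefact").values
    flagged = screen["flagged_artefact"].values
    if truly.any():
        results["screen_sensitivity"] = float(flagged[truly].mean())
    if (~truly).any():
        results["screen_specificity"] = float((~flagged[~truly]).mean())
    results["n_samples"] = int(table.n_samples)
    results["n_otus"] = int(table.n_otus)
    return results
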