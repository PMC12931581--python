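"""Canned simulation experiments probing the pooling phenomenology.

Each function runs one self-contained experiment at a reduced problem size
chosen so the full battery completes in minutes on one CPU while keeping
the mechanisms it probes (template dilution, uneven sequencing depth,
per-PCR artefact accumulation, spatial homogeneity) in their informative
regimes.  The geometries are scaled-down analogues of the built-in
designs: the subsample numbers and pooling structure are kept, the plot
is shrunk, and the core diameter is widened to 10 cm so that single cores
capture a few hundred propagules.

Frozen experiment conditions (documented in docs/methods.md):

* Pooling-effect experiment: a 300-species fungus-like pool with tight,
  heavy-tailed clusters and ~300-400 propagules per core; a 62- and a 5-subsample
  design on the same virtual plot; soil pooling; pooled samples sequenced
  deep enough to be rarefied to 100% of the unpooled summary depth.
* Area experiment: a spatially homogeneous community (dense, wide
  clusters), 62 cores, 8-sample subsets over a near-square bounding
  rectangle; the true area effect is zero by construction.
* Artefact experiment: equal sequencing depth for pooled and unpooled
  samples and an elevated artefact rate so per-PCR artefact counts are
  informative at small read depths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import substream
from .commstats import bray_curtis, permanova
from .design_eval import area_subsampling_test, pooling_effect
from .divmetrics import AbundanceVector, rarefy_expect, rarefy_mc
from .fieldsim import DesignSpec
from .labsim import LabConfig, run_survey
from .screenfx import (
    align_global,
    make_synthetic_alignment,
    screen_artefacts,
)
from .synthcomm import make_species_pool, realise_site

__all__ = [
    "pe_direction_experiment",
    "pe_direction_trials",
    "area_null_experiment",
    "area_null_trials",
    "artefact_direction_experiment",
    "artefact_direction_trials",
    "rarefaction_agreement",
    "permanova_type_i",
    "screening_performance",
]

# -- frozen experiment geometry ---------------------------------------------

PE_EXTENT = 3.6
PE_DESIGN_LARGE = DesignSpec("N62pe", 62, 9.0, ((0, 5),), 10.0)
PE_DESIGN_SMALL = DesignSpec("N5pe", 5, 4.0, ((0, 5),), 10.0)
PE_POOL_KW = dict(
    richness_total=300,
    preset_overrides=dict(
        kappa_mean=0.5, kappa_shape=1.5, sigma_mean=0.15, sigma_lsd=0.4,
        mu_mean=600.0, mu_lsd=1.5, density_scale=1.0,
    ),
)
PE_LAB = LabConfig(
    reads_mean_pooled=130_000,
    reads_dispersion_pooled=50.0,
)

AREA_DESIGN = DesignSpec("N62area", 62, 9.0, ((0, 5),), 10.0)
AREA_POOL_KW = dict(
    richness_total=240,
    preset_overrides=dict(
        kappa_mean=5.0, kappa_shape=4.0, sigma_mean=2.0, sigma_lsd=0.2,
        mu_mean=10.0, mu_lsd=0.6, density_scale=1.0,
    ),
)
AREA_LAB = LabConfig(reads_mean=800, reads_dispersion=3.0)

ART_DESIGN = DesignSpec("N9art", 9, 4.0, ((0, 5),), 10.0)
ART_POOL_KW = dict(
    richness_total=120,
    preset_overrides=dict(density_scale=60.0),
)
ART_LAB = LabConfig(
    templates_per_extraction=20_000,
    artefact_rate=2.0,
    chimera_coeff=0.001,
    reads_mean=2000,
    reads_dispersion=4.0,
)


# -- pooling effect ----------------------------------------------------------


def pe_direction_experiment(seed: int) -> dict:
    """PE(q=0, 100% summary depth, soil pooling) for a 62- and a 5-subsample
    design sampled from the same virtual plot."""
    pool = make_species_pool("fungus_like", seed=seed, **PE_POOL_KW)
    site = realise_site(pool, PE_EXTENT, seed, site_id=f"pe{seed}")
    table = run_survey(
        [site], [PE_DESIGN_LARGE, PE_DESIGN_SMALL],
        ["unpooled", "soil_pool"], PE_LAB, seed,
    )
    out = {}
    for design in (PE_DESIGN_LARGE, PE_DESIGN_SMALL):
        res = pooling_effect(
            table, site.site_id, design.name, "soil_pool", q=0,
            depth_fractions=(1.0,), iterations=60, seed=seed,
        )[0]
        out[design.name] = res.pe
    return dict(pe_large_n=out[PE_DESIGN_LARGE.name],
                pe_small_n=out[PE_DESIGN_SMALL.name])


def pe_direction_trials(seed: int, n_trials: int = 20) -> dict:
    """Fraction of seeds with PE < 1 at N=62 and PE > 1 at N=5."""
    large = np.empty(n_trials)
    small = np.empty(n_trials)
    for i in range(n_trials):
        r = pe_direction_experiment(seed * 1000 + i)
        large[i] = r["pe_large_n"]
        small[i] = r["pe_small_n"]
    return dict(
        pe_large_n=large,
        pe_small_n=small,
        frac_large_below_1=float(np.mean(large < 1.0)),
        frac_small_above_1=float(np.mean(small > 1.0)),
        n=n_trials,
    )


# -- area null ---------------------------------------------------------------


def area_null_experiment(seed: int) -> dict:
    """Richness-vs-area slope test on a homogeneous community (true slope 0)."""
    pool = make_species_pool("fungus_like", seed=seed, **AREA_POOL_KW)
    site = realise_site(pool, PE_EXTENT, seed, site_id=f"area{seed}")
    table = run_survey([site], [AREA_DESIGN], ["unpooled"], AREA_LAB, seed)
    res = area_subsampling_test(
        table, k=8, area_min=1.0, area_max=8.0, aspect_tolerance=0.6,
        n_combinations=30, n_permutations=499, seed=seed,
    )
    return dict(slope=res["slope"], p=res["p"],
                n_combinations=len(res["combinations"]))


def area_null_trials(seed: int, n_trials: int = 50) -> dict:
    ps = np.array([area_null_experiment(seed * 1000 + i)["p"]
                   for i in range(n_trials)])
    return dict(p_values=ps,
                frac_nonsignificant=float(np.mean(ps > 0.05)),
                n=n_trials)


# -- artefact uniqueness -----------------------------------------------------


def artefact_direction_experiment(seed: int) -> dict:
    """Unique artefact OTUs in summed unpooled PCRs vs one DNA pool at equal
    per-sample sequencing depth."""
    pool = make_species_pool("fungus_like", seed=seed, **ART_POOL_KW)
    site = realise_site(pool, 2.5, seed, site_id=f"art{seed}")
    table = run_survey([site], [ART_DESIGN], ["unpooled", "dna_pool"],
                       ART_LAB, seed)
    art = table.otu_registry["origin"] == "artefact"
    meta = table.sample_meta

    def artefact_count(strategy: str) -> int:
        rows = table.counts.loc[(meta["strategy"] == strategy).values]
        detected = rows.sum(axis=0) > 0
        return int((detected & art.reindex(detected.index,
                                           fill_value=False)).sum())

    return dict(unpooled=artefact_count("unpooled"),
                dna_pool=artefact_count("dna_pool"))


def artefact_direction_trials(seed: int, n_trials: int = 20) -> dict:
    res = [artefact_direction_experiment(seed * 1000 + i)
           for i in range(n_trials)]
    more = np.array([r["unpooled"] > r["dna_pool"] for r in res])
    return dict(
        unpooled=np.array([r["unpooled"] for r in res]),
        dna_pool=np.array([r["dna_pool"] for r in res]),
        frac_unpooled_more=float(more.mean()),
        n=n_trials,
    )


# -- oracle batteries --------------------------------------------------------


def rarefaction_agreement(seed: int, n_vectors: int = 50,
                          iterations: int = 1000) -> dict:
    """Monte-Carlo vs analytic rarefaction on random abundance vectors.

    Returns per-vector |MC mean - analytic| in Monte-Carlo SD units and the
    worst case (the MC mean of S_d has SD <= sqrt(Var(S_d)/iterations),
    bounded via the per-iteration richness variance estimate).
    """
    rng = substream(seed, "raroracle")
    devs = []
    for _ in range(n_vectors):
        s = int(rng.integers(5, 60))
        counts = rng.geometric(rng.uniform(0.05, 0.5), s)
        v = AbundanceVector(counts)
        d = int(rng.integers(1, v.n))
        expect = rarefy_expect(v, d)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        gen = substream(sub_seed, "rarefy")
        rich = np.empty(iterations)
        for i in range(iterations):
            sub = gen.multivariate_hypergeometric(v.counts, d)
            rich[i] = (sub > 0).sum()
        mc_mean = rarefy_mc(v, d, iterations, sub_seed).richness
        sd = max(rich.std(ddof=1) / np.sqrt(iterations), 1e-9)
        devs.append(abs(mc_mean - expect) / sd)
    devs = np.array(devs)
    return dict(deviations_sd=devs, max_deviation_sd=float(devs.max()),
                n=n_vectors)


def permanova_type_i(seed: int, n_sims: int = 1000,
                     n_permutations: int = 199) -> dict:
    """Rejection rate at alpha = 0.05 under the null (labels uninformative)."""
    rng = substream(seed, "permnull")
    rejections = 0
    groups = np.repeat([0, 1], 6)
    for i in range(n_sims):
        rows = rng.gamma(1.0, 1.0, size=(12, 20))
        d = bray_curtis(rows)
        res = permanova(d, groups, n_permutations=n_permutations,
                        seed=int(rng.integers(0, 2**31 - 1)))
        if res.p <= 0.05:
            rejections += 1
    return dict(rejection_rate=rejections / n_sims, n=n_sims)


def screening_performance(seed: int, n_biological: int = 30,
                          n_artefacts: int = 30) -> dict:
    """Sensitivity and specificity of artefact screening on planted fixtures."""
    registry = pd.DataFrame(
        dict(
            origin=["biological"] * n_biological + ["artefact"] * n_artefacts,
            parent=[f"sp{i % 10}" for i in range(n_biological)]
            + [f"pcr{i}" for i in range(n_artefacts)],
        ),
        index=[f"otu{i:03d}" for i in range(n_biological + n_artefacts)],
    )
    fx = make_synthetic_alignment(registry, seed)
    tp = fp = tn = fn = 0
    for otu_id, seq in fx["otus"].items():
        ref = fx["references"][fx["best_reference"][otu_id]]
        pair = align_global(seq, ref, query_id=otu_id)
        flagged = bool(screen_artefacts(pair, fx["window_start"],
                                        fx["window_length"]))
        truly = fx["truth"][otu_id] != "biological"
        tp += flagged and truly
        fp += flagged and not truly
        tn += (not flagged) and (not truly)
        fn += (not flagged) and truly
    return dict(
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        n=n_biological + n_artefacts,
    )
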