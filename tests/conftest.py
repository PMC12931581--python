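import numpy as np
import pandas as pd
import pytest

from soilpool.fieldsim import DesignSpec
from soilpool.labsim import LabConfig, ReadTable, run_survey
from soilpool.synthcomm import make_species_pool, realise_site


@pytest.fixture(scope="session")
def small_pool():
    return make_species_pool(
        "fungus_like",
        richness_total=60,
        preset_overrides=dict(
            kappa_mean=0.5, sigma_mean=0.2, mu_mean=300.0, mu_lsd=1.0,
            density_scale=1.0,
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_site(small_pool):
    return realise_site(small_pool, 3.0, seed=11, site_id="siteA")


@pytest.fixture(scope="session")
def small_design():
    return DesignSpec("N9t", 9, 4.0, ((0, 5),), 10.0)


@pytest.fixture(scope="session")
def small_survey(small_site, small_design):
    """One site, one 9-core design, all three strategies."""
    config = LabConfig(reads_mean=600, reads_mean_pooled=8000,
                       reads_dispersion_pooled=20.0)
    return run_survey([small_site], [small_design],
                      ["unpooled", "soil_pool", "dna_pool"], config, seed=5)


def toy_read_table(counts: dict, sites=None, designs=None, strategies=None):
    """Hand-built ReadTable for arithmetic oracles."""
    frame = pd.DataFrame(counts).T.fillna(0).astype(np.int64)
    frame.index.name = "sample_id"
    n = len(frame)
    meta = pd.DataFrame(
        dict(
            site=sites or ["siteA"] * n,
            design=designs or ["D1"] * n,
            strategy=strategies or ["unpooled"] * n,
            x=np.zeros(n),
            y=np.zeros(n),
            depth_top=0.0,
            depth_bottom=5.0,
            composite="",
            total_reads=frame.sum(axis=1).values,
        ),
        index=frame.index,
    )
    registry = pd.DataFrame(
        dict(origin="biological", parent=list(frame.columns)),
        index=frame.columns,
    ).rename_axis("otu_id")
    table = ReadTable(counts=frame, sample_meta=meta, otu_registry=registry)
    table.validate()
    return table
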