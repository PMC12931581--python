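"""Pooling arithmetic, extraction dilution, PCR artefacts, survey assembly."""

import numpy as np
import pytest

from soilpool._rng import substream
from soilpool.fieldsim import CoreSample, DesignSpec
from soilpool.labsim import (
    LabConfig,
    OtuRegistry,
    extract_dna,
    pcr_and_sequence,
    pool_dna,
    pool_soil,
    run_survey,
)


def core(counts):
    return CoreSample("c", "s", "d", 0, 0, 0, 5, 5, np.asarray(counts))


class TestPoolSoil:
    def test_single_core_identity(self):
        mix = pool_soil([core([10, 0, 30])])
        assert np.allclose(mix, [0.25, 0, 0.75])

    def test_two_core_symmetry(self):
        mix = pool_soil([core([10, 0]), core([0, 10])])
        assert np.allclose(mix, [0.5, 0.5])

    def test_mean_of_proportions(self):
        rng = np.random.default_rng(1)
        cores = [core(rng.integers(0, 50, 6) + 1) for _ in range(3)]
        mix = pool_soil(cores)
        direct = np.mean(
            [c.templates / c.templates.sum() for c in cores], axis=0
        )
        assert np.allclose(mix, direct / direct.sum())

    def test_zero_core_counts_in_mean(self):
        mix = pool_soil([core([4, 4]), core([0, 0])])
        assert np.allclose(mix, [0.5, 0.5])  # renormalised after dilution

    def test_errors(self):
        with pytest.raises(ValueError):
            pool_soil([])
        with pytest.raises(ValueError):
            pool_soil([core([0, 0])])


class TestPoolDna:
    def test_idempotent_on_identical_extracts(self):
        e = np.array([0.2, 0.8])
        assert np.allclose(pool_dna([e, e, e]), e)

    def test_uniform_mixing_of_private_species(self):
        n = 62
        extracts = [np.eye(n)[i] for i in range(n)]
        mix = pool_dna(extracts)
        assert np.allclose(mix, np.full(n, 1 / n))

    def test_mix_then_normalise_commutes(self):
        rng = np.random.default_rng(2)
        extracts = [rng.dirichlet(np.ones(5)) for _ in range(4)]
        a = pool_dna(extracts)
        b = np.mean(extracts, axis=0)
        assert np.allclose(a, b / b.sum())


class TestExtractDna:
    def test_zero_mass_never_detected(self):
        comp = np.array([0.0, 1.0])
        config = LabConfig()
        for s in range(50):
            assert extract_dna(comp, config, s)[0] == 0

    def test_poisson_detection_probability(self):
        # p = 0.001 at T = 1000 -> detection 1 - exp(-1)
        config = LabConfig(templates_per_extraction=1000)
        comp = np.array([0.001, 0.999])
        rng = substream(0, "det")
        n_rep = 10_000
        hits = sum(extract_dna(comp, config, rng)[0] > 0 for _ in range(n_rep))
        p = 1 - np.exp(-1)
        sd = np.sqrt(p * (1 - p) / n_rep)
        assert abs(hits / n_rep - p) <= 3 * sd

    def test_dilution_monotone_in_pool_size(self):
        # a species private to one core is lost more often as N grows
        config = LabConfig(templates_per_extraction=2000)
        q = 0.005
        detect = []
        for n_cores in (1, 5, 25, 60):
            comps = [np.array([q, 1 - q])] + [
                np.array([0.0, 1.0]) for _ in range(n_cores - 1)
            ]
            mix = pool_soil([core((c * 1000).astype(int)) for c in comps])
            rng = substream(n_cores, "dil")
            hits = sum(extract_dna(mix, config, rng)[0] > 0
                       for _ in range(3000))
            detect.append(hits / 3000)
        assert detect[0] > detect[1] > detect[2] > detect[3]
        # closed form 1 - exp(-T q / N)
        for d, n_cores in zip(detect, (1, 5, 25, 60)):
            expect = 1 - np.exp(-2000 * q / n_cores)
            assert abs(d - expect) < 0.05

    def test_negative_proportions_rejected(self):
        with pytest.raises(ValueError):
            extract_dna(np.array([-0.1, 1.1]), LabConfig(), 0)


class TestPcrAndSequence:
    def test_zero_depth_empty_row(self):
        row = pcr_and_sequence(np.array([5, 5]), OtuRegistry(), LabConfig(),
                               0, substream(0), np.ones(2), ["a", "b"], "p1")
        assert row == {}

    def test_unbiased_limit_recovers_template_proportions(self):
        config = LabConfig(bias_sd=0.0, artefact_rate=0.0, chimera_coeff=0.0)
        templates = np.array([300, 100])
        rng = substream(3, "pcr")
        totals = np.zeros(2)
        reps, depth = 300, 1000
        for i in range(reps):
            row = pcr_and_sequence(templates, OtuRegistry(), config, depth,
                                   rng, np.ones(2), ["a", "b"], f"p{i}")
            totals += [row.get("a", 0), row.get("b", 0)]
        props = totals / totals.sum()
        assert abs(props[0] - 0.75) < 0.01

    def test_artefacts_unique_per_pcr_and_poisson_additive(self):
        config = LabConfig(bias_sd=0.0, artefact_rate=2.0, chimera_coeff=0.0,
                           artefact_read_share=0.005)
        templates = np.array([100, 100])
        registry = OtuRegistry()
        rng = substream(4, "pcr")
        depth, n_pcr = 2000, 40
        counts = []
        for i in range(n_pcr):
            row = pcr_and_sequence(templates, registry, config, depth, rng,
                                   np.ones(2), ["a", "b"], f"p{i}")
            arts = [o for o in row if o.startswith("art")]
            counts.append(len(arts))
            for o in arts:
                assert registry.parent(o) == f"p{i}"
        expect = depth / 1000 * 2.0  # per-PCR expectation (reads drawn > 0)
        assert abs(np.mean(counts) - expect) < 3 * np.sqrt(expect / n_pcr) + 0.5

    def test_empty_templates_with_depth_rejected(self):
        with pytest.raises(ValueError):
            pcr_and_sequence(np.zeros(2), OtuRegistry(), LabConfig(), 10,
                             substream(0), np.ones(2), ["a", "b"], "p")


class TestRunSurvey:
    def test_row_bookkeeping(self, small_site, small_design):
        table = run_survey([small_site], [small_design], ["unpooled"],
                           LabConfig(reads_mean=500), seed=1)
        assert table.n_samples == 9
        assert (table.sample_meta["strategy"] == "unpooled").all()

    def test_composite_design_rows_per_top_level(self, small_site):
        design = DesignSpec("N12t", 12, 4.0, ((0, 5),), 5,
                            composite_tree=(3, 4))
        table = run_survey([small_site], [design], ["soil_pool"],
                           LabConfig(reads_mean=500), seed=1)
        assert table.n_samples == 3

    def test_unpooled_skipped_for_composite_designs(self, small_site):
        design = DesignSpec("N12t", 12, 4.0, ((0, 5),), 5,
                            composite_tree=(3, 4))
        with pytest.warns(UserWarning):
            table = run_survey([small_site], [design],
                               ["unpooled", "soil_pool"],
                               LabConfig(reads_mean=500), seed=1)
        assert table.n_samples == 3

    def test_determinism_and_conservation(self, small_survey, small_site,
                                          small_design):
        config = LabConfig(reads_mean=600, reads_mean_pooled=8000,
                           reads_dispersion_pooled=20.0)
        again = run_survey([small_site], [small_design],
                           ["unpooled", "soil_pool", "dna_pool"], config,
                           seed=5)
        assert small_survey.counts.equals(again.counts)
        assert (small_survey.counts.sum(axis=1)
                == small_survey.sample_meta["total_reads"]).all()

    def test_registry_covers_all_otus(self, small_survey):
        reg = small_survey.otu_registry
        assert set(small_survey.counts.columns) <= set(reg.index)
        bio = reg.loc[reg["origin"] == "biological"]
        assert (bio.index == bio["parent"]).all()
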