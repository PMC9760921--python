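import dataclasses

import numpy as np
import pandas as pd
import pytest

from genecov.calibration import fit_calibration, pair_for_calibration
from genecov.detection import CANONICAL_RULES, detect
from genecov.errors import ValidationError
from genecov.simulate import (
    HUMAN_PROTEIN_CODING_COUNTS,
    PlatformModel,
    SimulationConfig,
    catalog_from_truth,
    preset,
    simulate_platform_tables,
    simulate_study,
    simulate_truth,
)

SMALL = preset("liver", size_factor=0.05, seed=5)  # ~1000 genes


def test_default_universe_matches_published_gene_counts():
    cfg = preset("liver")
    assert sum(cfg.n_genes_per_chromosome.values()) == 19593
    assert cfg.n_genes_per_chromosome == HUMAN_PROTEIN_CODING_COUNTS


class TestTruth:
    def test_seed_determinism(self):
        a, b = simulate_truth(SMALL), simulate_truth(SMALL)
        pd.testing.assert_frame_equal(a, b)
        other = simulate_truth(dataclasses.replace(SMALL, seed=6))
        assert not a["copies_per_cell"].equals(other["copies_per_cell"])

    def test_zero_donor_effect_makes_donors_identical(self):
        cfg = dataclasses.replace(SMALL, donor_effect_sd=0.0)
        truth = simulate_truth(cfg)
        for donor in cfg.donors:
            assert truth[f"copies_{donor}"].equals(truth["copies_per_cell"])

    def test_bimodal_mixture_structure(self):
        """Component draws match the weights binomially and the two
        components sit at their configured log10 means."""
        counts = {"1": 5000}
        cfg = SimulationConfig(
            n_genes_per_chromosome=counts, profile="bimodal",
            mixture_weights=(0.4, 0.6), mixture_means=(0.5, 2.5),
            mixture_sigmas=(0.6, 0.6), seed=2,
        )
        truth = simulate_truth(cfg)
        n1 = int((truth["component"] == 1).sum())
        # 3-sigma binomial band around 0.6 * 5000
        assert abs(n1 - 3000) < 3 * np.sqrt(5000 * 0.6 * 0.4)
        log_copies = np.log10(truth["copies_per_cell"])
        assert log_copies[truth["component"] == 0].mean() == pytest.approx(0.5, abs=0.1)
        assert log_copies[truth["component"] == 1].mean() == pytest.approx(2.5, abs=0.1)

    def test_chromosome_layout_matches_config(self):
        truth = simulate_truth(SMALL)
        catalog = catalog_from_truth(truth)
        assert catalog.per_chromosome_counts == dict(SMALL.n_genes_per_chromosome)
        assert truth["gene_id"].is_unique


class TestConfigValidation:
    def test_presets(self):
        assert preset("liver").profile == "unimodal"
        assert preset("hepg2").profile == "bimodal"
        with pytest.raises(ValidationError):
            preset("kidney")

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mixture_weights": (0.5, 0.6)},
            {"n_donors": 0},
            {"unimodal_sigma": 0.0},
            {"n_genes_per_chromosome": {"25": 10}},
            {"n_genes_per_chromosome": {}},
            {"profile": "trimodal"},
            {"donor_effect_sd": -0.1},
            {"platform": PlatformModel(ont_depth=-1.0)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            dataclasses.replace(SMALL, **kwargs).validate()


class TestPlatformTables:
    def test_all_genes_present_in_every_table(self):
        catalog, truth, tables = simulate_study(SMALL)
        assert set(tables) == {(d, p) for d in SMALL.donors for p in ("illumina", "ont", "qpcr")}
        for (donor, platform), table in tables.items():
            assert set(table.df["gene_id"]) == set(truth["gene_id"])
        assert tables[("donor1", "qpcr")].df["ct"].notna().all()

    def test_zero_ont_depth_detects_nothing(self):
        cfg = dataclasses.replace(SMALL, platform=PlatformModel(ont_depth=0.0))
        catalog, truth, tables = simulate_study(cfg)
        s = detect(tables[("donor1", "ont")], CANONICAL_RULES["ont"], catalog)
        assert len(s) == 0

    def test_detection_non_decreasing_in_true_copies(self):
        """Tertiles of true copy number show non-decreasing detection on
        every platform (the expected-detection monotonicity invariant)."""
        catalog, truth, tables = simulate_study(preset("liver", size_factor=0.3, seed=9))
        tert = pd.qcut(truth["copies_per_cell"], 3, labels=False)
        for platform in ("illumina", "ont", "qpcr"):
            detected = detect(tables[("donor1", platform)], CANONICAL_RULES[platform], catalog).genes
            hit = truth["gene_id"].isin(detected)
            rates = [hit[tert == k].mean() for k in range(3)]
            assert rates[0] <= rates[1] <= rates[2]

    def test_short_transcripts_depress_ont_detection(self):
        """Below the ONT length floor, detection drops relative to
        longer genes of comparable abundance (the chrY-style effect)."""
        cfg = preset("liver", size_factor=0.3, seed=4)
        catalog, truth, tables = simulate_study(cfg)
        detected = detect(tables[("donor1", "ont")], CANONICAL_RULES["ont"], catalog).genes
        hit = truth["gene_id"].isin(detected)
        mid = truth["copies_per_cell"].between(
            truth["copies_per_cell"].quantile(0.3), truth["copies_per_cell"].quantile(0.9)
        )
        short = truth["length_nt"] < cfg.platform.ont_min_length
        assert hit[mid & short].mean() < hit[mid & ~short].mean()

    def test_chry_preset_lengths_are_short(self):
        truth = simulate_truth(preset("liver", size_factor=0.5, seed=1))
        med_y = truth.loc[truth["chromosome"] == "Y", "length_nt"].median()
        med_rest = truth.loc[truth["chromosome"] != "Y", "length_nt"].median()
        assert med_y < med_rest / 2


def test_calibration_recovers_configured_loglog_slope():
    """Pairs built from simulated FPKM and simulated qPCR copies recover the
    unit log-log slope of the generative model.  The tolerance (+-0.15)
    allows for the attenuation from measurement noise on the FPKM axis and
    from selecting detected genes only."""
    catalog, truth, tables = simulate_study(preset("liver", size_factor=0.5, seed=12))
    pairs = pair_for_calibration(tables[("donor1", "illumina")], tables[("donor1", "qpcr")])
    model = fit_calibration(pairs, platform="illumina")
    assert model.slope == pytest.approx(1.0, abs=0.15)
    assert model.r_squared > 0.5
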