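"""Synthetic-data generator: planted overlaps, correlations and modules."""

import numpy as np
import pandas as pd
import pytest

from cernet import (
    SimulationScenario,
    simulate_catalog,
    simulate_dataset,
    simulate_expression,
)
from cernet.containers import NORMAL, TUMOR
from cernet.coexpr import pearson
from cernet.errors import ScenarioError


def scenario(**kw):
    defaults = dict(n_mirna=100, n_lnc=10, n_mrna=10, n_samples_per_group=10, seed=0)
    defaults.update(kw)
    return SimulationScenario(**defaults)


class TestSimulateCatalog:
    def test_planted_pair_shares_exact_count(self):
        scn = scenario(planted_pairs=((("LNC0001"), "MRNA0001", 5, 0.5, 0.0),))
        cat = simulate_catalog(scn)
        assert len(cat.lnc_to_mir["LNC0001"] & cat.mrna_to_mir["MRNA0001"]) == 5

    def test_null_overlap_matches_hypergeometric_expectation(self):
        """Mean pairwise overlap approximates M*N/K over 200 seeds."""
        total, expected = 0.0, 0.0
        n_pairs = 0
        for seed in range(200):
            scn = SimulationScenario(n_mirna=50, n_lnc=5, n_mrna=5,
                                     background_set_size=(5, 5), seed=seed)
            cat = simulate_catalog(scn)
            for lset in cat.lnc_to_mir.values():
                for mset in cat.mrna_to_mir.values():
                    total += len(lset & mset)
                    expected += len(lset) * len(mset) / 50
                    n_pairs += 1
        assert total / n_pairs == pytest.approx(expected / n_pairs, rel=0.05)

    def test_same_seed_is_bit_stable(self):
        scn = scenario(planted_pairs=(("LNC0002", "MRNA0003", 4, 0.8, 0.0),))
        c1, c2 = simulate_catalog(scn), simulate_catalog(scn)
        assert c1.lnc_to_mir == c2.lnc_to_mir
        assert c1.mrna_to_mir == c2.mrna_to_mir

    def test_infeasible_overlap_names_pair(self):
        scn = scenario(n_mirna=8, background_set_size=(8, 8),
                       planted_pairs=(("LNC0001", "MRNA0001", 2, 0.5, 0.0),))
        with pytest.raises(ScenarioError, match="LNC0001"):
            simulate_catalog(scn)

    def test_overlap_larger_than_set_size_rejected(self):
        with pytest.raises(ScenarioError):
            scenario(background_set_size=(5, 10),
                     planted_pairs=(("LNC0001", "MRNA0001", 11, 0.5, 0.0),))

    def test_gene_in_two_planted_pairs_rejected(self):
        with pytest.raises(ScenarioError, match="LNC0001"):
            scenario(planted_pairs=(
                ("LNC0001", "MRNA0001", 3, 0.5, 0.0),
                ("LNC0001", "MRNA0002", 3, 0.5, 0.0)))


class TestSimulateExpression:
    def test_planted_correlations_converge_at_large_n(self):
        """rho_tumor=0.95, rho_normal=0 at 500 samples/group: sample PCCs
        within +-0.05 (Fisher-z sampling tolerance)."""
        scn = scenario(n_samples_per_group=500,
                       planted_pairs=(("LNC0001", "MRNA0001", 5, 0.95, 0.0),))
        cat = simulate_catalog(scn)
        expr = simulate_expression(scn, cat)
        pcc_t = pearson(expr.vector("LNC0001", TUMOR), expr.vector("MRNA0001", TUMOR))
        pcc_n = pearson(expr.vector("LNC0001", NORMAL), expr.vector("MRNA0001", NORMAL))
        assert pcc_t == pytest.approx(0.95, abs=0.05)
        assert pcc_n == pytest.approx(0.0, abs=0.1)

    def test_null_pairs_rarely_exceed_weight_cutoff(self):
        """|PCC| of unplanted pairs at n=20/group stays below 0.8 in >=99%
        of 1000 pairs (null-distribution check)."""
        scn = SimulationScenario(n_mirna=200, n_lnc=1000, n_mrna=1000,
                                 n_samples_per_group=20, seed=5)
        cat = simulate_catalog(scn)
        expr = simulate_expression(scn, cat)
        tumor = expr.values[expr.samples(TUMOR)].to_numpy()
        lncs = tumor[:1000]
        mrnas = tumor[1000:]
        a = (lncs - lncs.mean(1, keepdims=True)) / lncs.std(1, keepdims=True)
        b = (mrnas - mrnas.mean(1, keepdims=True)) / mrnas.std(1, keepdims=True)
        pccs = (a * b).mean(axis=1)
        assert np.mean(np.abs(pccs) < 0.8) >= 0.99

    def test_determinism_and_sample_layout(self):
        scn = scenario()
        cat = simulate_catalog(scn)
        e1 = simulate_expression(scn, cat)
        e2 = simulate_expression(scn, cat)
        pd.testing.assert_frame_equal(e1.values, e2.values)
        assert e1.samples(NORMAL) == [f"Normal_{i:03d}" for i in range(1, 11)]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ScenarioError, match="samples"):
            scn = scenario(n_samples_per_group=2)
            simulate_expression(scn, simulate_catalog(scn))


class TestPlantModules:
    def test_small_module_truth_table(self):
        scn = scenario(planted_modules=((("LNC0001", "LNC0002"),
                                         ("MRNA0001", "MRNA0002", "MRNA0003")),))
        cat, mat, truth = simulate_dataset(scn)
        assert len(truth) == 6
        assert set(truth["source"]) == {"module1"}
        # every cross pair shares exactly the module core
        core = cat.lnc_to_mir["LNC0001"] & cat.mrna_to_mir["MRNA0001"]
        assert len(core) == scn.module_shared_mirnas
        for l in ("LNC0001", "LNC0002"):
            for m in ("MRNA0001", "MRNA0002", "MRNA0003"):
                assert cat.lnc_to_mir[l] & cat.mrna_to_mir[m] == core

    def test_disjoint_modules_are_additive(self):
        scn = scenario(planted_modules=(
            (("LNC0001", "LNC0002"), ("MRNA0001", "MRNA0002", "MRNA0003")),
            (("LNC0003", "LNC0004", "LNC0005"), ("MRNA0004", "MRNA0005"))))
        _, _, truth = simulate_dataset(scn)
        assert len(truth) == 12
        edges = set(zip(truth["lnc"], truth["partner"]))
        assert len(edges) == 12

    def test_overlapping_modules_rejected(self):
        with pytest.raises(ScenarioError, match="shared"):
            scenario(planted_modules=(
                (("LNC0001",), ("MRNA0001", "MRNA0002")),
                (("LNC0001",), ("MRNA0003", "MRNA0004"))))

    def test_module_expression_is_correlated_in_tumor_group(self):
        scn = scenario(n_samples_per_group=500,
                       planted_modules=((("LNC0001", "LNC0002"),
                                         ("MRNA0001", "MRNA0002")),))
        _, mat, _ = simulate_dataset(scn)
        pcc = pearson(mat.vector("LNC0001", TUMOR), mat.vector("MRNA0002", TUMOR))
        assert pcc == pytest.approx(scn.module_rho_tumor, abs=0.05)

    def test_whole_generator_seed_stability(self):
        scn = scenario(planted_pairs=(("LNC0009", "MRNA0009", 4, 0.9, -0.3),),
                       planted_modules=((("LNC0001", "LNC0002"),
                                         ("MRNA0001", "MRNA0002")),))
        c1, m1, t1 = simulate_dataset(scn)
        c2, m2, t2 = simulate_dataset(scn)
        assert c1.lnc_to_mir == c2.lnc_to_mir
        pd.testing.assert_frame_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1, t2)


class TestScenarioSerialization:
    def test_yaml_round_trip(self, tmp_path):
        scn = scenario(planted_pairs=(("LNC0001", "MRNA0001", 5, 0.9, -0.3),),
                       planted_modules=((("LNC0002",), ("MRNA0002", "MRNA0003")),))
        p = tmp_path / "scn.yaml"
        scn.to_yaml(p)
        assert SimulationScenario.from_yaml(p) == scn
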