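"""Synthetic cohort generator and closed-form population ICC."""

import numpy as np
import pytest
from scipy import stats

import pairdissect as pdx

PARAMS = dict(var_host=0.1, var_genetic=0.5, var_time=0.3, var_noise=0.2)


class TestPopulationICC:
    def test_sharing_structures(self):
        p = pdx.GeneClassParams(name="bg", **PARAMS)
        assert pdx.population_icc(p, True, False) == pytest.approx(0.6 / 1.1)
        assert pdx.population_icc(p, False, True) == pytest.approx(0.4 / 1.1)
        assert pdx.population_icc(p, False, False) == pytest.approx(0.1 / 1.1)
        assert pdx.population_icc_group(p, "LRC") == pytest.approx(0.6 / 1.1)

    def test_all_variance_shared_gives_one(self):
        p = pdx.GeneClassParams(
            name="host-only",
            var_host=1.0,
            var_genetic=0.0,
            var_time=0.0,
            var_noise=1e-300,
        )
        for gs in (True, False):
            for ts in (True, False):
                assert pdx.population_icc(p, gs, ts) == pytest.approx(1.0)

    def test_group_ordering_when_genetic_exceeds_time(self):
        """var_genetic > var_time > 0 implies LRC > SBC > MBC."""
        p = pdx.GeneClassParams(name="bg", **PARAMS)
        lrc = pdx.population_icc_group(p, "LRC")
        sbc = pdx.population_icc_group(p, "SBC")
        mbc = pdx.population_icc_group(p, "MBC")
        assert lrc > sbc > mbc

    def test_unknown_group_rejected(self):
        p = pdx.GeneClassParams(name="bg", **PARAMS)
        with pytest.raises(ValueError):
            pdx.population_icc_group(p, "XYZ")


class TestConfigValidation:
    def test_variances_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            pdx.GeneClassParams(name="bad", var_host=-0.1)

    def test_noise_strictly_positive(self):
        with pytest.raises(ValueError):
            pdx.GeneClassParams(name="bad", var_noise=0.0)

    def test_pairs_minimum(self):
        with pytest.raises(ValueError, match="n_pairs"):
            pdx.SimulationConfig(
                gene_classes=[pdx.GeneClassParams(name="bg")],
                n_pairs={"SBC": 1, "MBC": 4, "LRC": 4},
            )

    def test_unknown_group_key(self):
        with pytest.raises(ValueError, match="unknown group"):
            pdx.SimulationConfig(
                gene_classes=[pdx.GeneClassParams(name="bg")],
                n_pairs={"ABC": 5},
            )


class TestSimulateCohort:
    def test_structure_and_truth_labels(self, default_cohort):
        cfg = default_cohort.config
        n_samples = 2 * sum(cfg.n_pairs.values())
        assert default_cohort.matrix.n_samples == n_samples
        n_genes = sum(c.n_genes for c in cfg.gene_classes)
        assert default_cohort.matrix.n_probes == n_genes
        class_names = {c.name for c in cfg.gene_classes}
        assert set(default_cohort.truth["gene_class"]) == class_names
        # each sample appears in exactly one pair
        default_cohort.design.validate_against(default_cohort.matrix)

    def test_seed_reproducibility_bitwise(self):
        cfg = lambda: pdx.SimulationConfig(  # noqa: E731
            gene_classes=[pdx.GeneClassParams(name="bg", n_genes=25)], seed=123
        )
        a = pdx.simulate_cohort(cfg())
        b = pdx.simulate_cohort(cfg())
        assert a.matrix.values.equals(b.matrix.values)

    def test_per_gene_substreams_stable_under_gene_count(self):
        """Gene i's values do not depend on how many genes follow it."""
        small = pdx.simulate_cohort(
            pdx.SimulationConfig(
                gene_classes=[pdx.GeneClassParams(name="bg", n_genes=5)], seed=3
            )
        )
        big = pdx.simulate_cohort(
            pdx.SimulationConfig(
                gene_classes=[pdx.GeneClassParams(name="bg", n_genes=20)], seed=3
            )
        )
        np.testing.assert_array_equal(
            small.matrix.values.to_numpy(), big.matrix.values.to_numpy()[:5]
        )

    def test_no_shared_components_gives_zero_population_icc(self):
        p = pdx.GeneClassParams(
            name="noise",
            var_host=0.0,
            var_genetic=0.0,
            var_time=0.0,
            var_noise=1.0,
            n_genes=3,
        )
        cohort = pdx.simulate_cohort(
            pdx.SimulationConfig(gene_classes=[p], seed=1)
        )
        for g in pdx.GROUPS:
            assert (cohort.truth[f"pop_icc_{g}"] == 0).all()

    def test_sharing_realized_in_draws(self):
        """With only shared terms, LRC pair members are identical."""
        p = pdx.GeneClassParams(
            name="clean",
            var_host=0.3,
            var_genetic=1.0,
            var_time=0.0,
            var_noise=1e-300,
            n_genes=4,
        )
        cohort = pdx.simulate_cohort(
            pdx.SimulationConfig(gene_classes=[p], seed=2)
        )
        pairs = cohort.design.pairs_for_group("LRC")
        v = cohort.matrix.values
        np.testing.assert_allclose(
            v[pairs["member1_sample"].tolist()].to_numpy(),
            v[pairs["member2_sample"].tolist()].to_numpy(),
            atol=1e-7,
        )
        # SBC members differ (independent genetic term)
        pairs = cohort.design.pairs_for_group("SBC")
        assert not np.allclose(
            v[pairs["member1_sample"].tolist()].to_numpy(),
            v[pairs["member2_sample"].tolist()].to_numpy(),
        )

    def test_median_icc_recovers_population_icc(self):
        """Monte-Carlo check against the closed form at study pair counts."""
        cfg = pdx.SimulationConfig(
            gene_classes=[pdx.GeneClassParams(name="bg", n_genes=2000, **PARAMS)],
            seed=7,
        )
        cohort = pdx.simulate_cohort(cfg)
        for g, pop in [("LRC", 0.6 / 1.1), ("SBC", 0.4 / 1.1), ("MBC", 0.1 / 1.1)]:
            table = pdx.icc_per_gene(cohort.matrix, cohort.design, g)
            med = float(np.nanmedian(table["icc"]))
            assert med == pytest.approx(pop, abs=0.05)

    def test_empirical_group_ordering(self):
        """Median estimated ICC over >=1000 genes ranks LRC > SBC > MBC."""
        cfg = pdx.SimulationConfig(
            gene_classes=[pdx.GeneClassParams(name="bg", n_genes=1200, **PARAMS)],
            seed=21,
        )
        cohort = pdx.simulate_cohort(cfg)
        med = {
            g: float(
                np.nanmedian(pdx.icc_per_gene(cohort.matrix, cohort.design, g)["icc"])
            )
            for g in pdx.GROUPS
        }
        assert med["LRC"] > med["SBC"] > med["MBC"]

    def test_intrinsic_like_recovery_sbc_mbc_overlap(self):
        """With no time variance, SBC and MBC ICC distributions coincide.

        Population ICCs are equal, so a two-sample t-test between the
        estimated per-gene ICCs should be non-significant at alpha=0.01
        in at least 95% of seeded replicates.
        """
        replicates, nonsig = 40, 0
        for r in range(replicates):
            cfg = pdx.SimulationConfig(
                gene_classes=[
                    pdx.GeneClassParams(
                        name="intrinsic-like", var_time=0.0, n_genes=400
                    )
                ],
                seed=5000 + r,
            )
            cohort = pdx.simulate_cohort(cfg)
            sbc = pdx.icc_per_gene(cohort.matrix, cohort.design, "SBC")["icc"]
            mbc = pdx.icc_per_gene(cohort.matrix, cohort.design, "MBC")["icc"]
            p = stats.ttest_ind(sbc, mbc, equal_var=False).pvalue
            nonsig += p >= 0.01
        assert nonsig / replicates >= 0.95

    def test_stromal_like_recovery(self):
        """With no genetic variance: MBC < SBC and LRC equals MBC in truth."""
        p = pdx.GeneClassParams(name="stromal-like", var_genetic=0.0, n_genes=800)
        assert pdx.population_icc_group(p, "LRC") == pytest.approx(
            pdx.population_icc_group(p, "MBC")
        )
        cohort = pdx.simulate_cohort(
            pdx.SimulationConfig(gene_classes=[p], seed=33)
        )
        med = {
            g: float(
                np.nanmedian(pdx.icc_per_gene(cohort.matrix, cohort.design, g)["icc"])
            )
            for g in ("SBC", "MBC")
        }
        assert med["MBC"] < med["SBC"]

    def test_undetected_flag_sets_detection_p(self):
        classes = [
            pdx.GeneClassParams(name="seen", n_genes=3),
            pdx.GeneClassParams(name="unseen", n_genes=2, undetected=True),
        ]
        cohort = pdx.simulate_cohort(
            pdx.SimulationConfig(gene_classes=classes, seed=0)
        )
        dp = cohort.matrix.detection_p.to_numpy()
        assert (dp[:3] == 0.0).all() and (dp[3:] == 0.5).all()

    def test_noise_sampler_hook(self):
        heavy = pdx.GeneClassParams(
            name="heavy",
            n_genes=2,
            noise_sampler=lambda rng, size: rng.standard_t(3, size=size)
            / np.sqrt(3.0),
        )
        cohort = pdx.simulate_cohort(
            pdx.SimulationConfig(gene_classes=[heavy], seed=4)
        )
        assert np.isfinite(cohort.matrix.values.to_numpy()).all()


def test_config_yaml_roundtrip(tmp_path):
    cfg_file = tmp_path / "sim.yaml"
    cfg_file.write_text(
        """
seed: 12
n_pairs: {SBC: 4, MBC: 3, LRC: 2}
gene_classes:
  - {name: bg, var_host: 0.1, var_genetic: 0.5, var_time: 0.3, var_noise: 0.2, n_genes: 10}
  - {name: silent, var_genetic: 0.0, n_genes: 5, undetected: true}
"""
    )
    from pairdissect.simulate import load_config

    cfg = load_config(cfg_file)
    assert cfg.seed == 12
    assert cfg.n_pairs == {"SBC": 4, "MBC": 3, "LRC": 2}
    assert [c.name for c in cfg.gene_classes] == ["bg", "silent"]
    assert cfg.gene_classes[1].undetected


def test_save_cohort_roundtrip(tmp_path):
    from pairdissect.simulate import save_cohort

    cfg = pdx.SimulationConfig(
        gene_classes=[pdx.GeneClassParams(name="bg", n_genes=6)],
        n_pairs={"SBC": 3, "MBC": 2, "LRC": 2},
        seed=8,
    )
    cohort = pdx.simulate_cohort(cfg)
    paths = save_cohort(cohort, tmp_path / "cohort")
    matrix = pdx.read_expression(paths["expression"])
    np.testing.assert_allclose(
        matrix.values.to_numpy(), cohort.matrix.values.to_numpy(), atol=1e-9
    )
    design = pdx.read_design(paths["design"])
    assert design.table.shape == cohort.design.table.shape
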