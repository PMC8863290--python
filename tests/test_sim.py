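"""Synthetic-data generator: determinism, LD regimes, Hardy–Weinberg,
expression effect convention, ASE calibration and catalog integrity."""

import json

import numpy as np
import pytest
from scipy import stats

from locuslens.ld import ld_matrix, r2_phased
from locuslens.sim import (
    AseSpec,
    SimulationConfig,
    simulate_ase,
    simulate_expression,
    simulate_haplotypes,
    simulate_locus_catalog,
)
from locuslens.sim.ase import biased_ref_probability
from locuslens.sim.config import CausalGene
from locuslens.sim.haplotypes import MafConstraintError


class TestConfigValidation:
    def test_bad_maf_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.1, 0.6))

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            CausalGene("G", (("v", -0.1),))

    def test_ase_spec_bounds(self):
        with pytest.raises(ValueError):
            AseSpec(ref_bias=1.0)
        with pytest.raises(ValueError):
            AseSpec(fold_change=0.0)


class TestHaplotypes:
    def test_single_founder_forces_perfect_ld(self):
        cfg = SimulationConfig(seed=1, n_samples=300, block_spec=((6, 1),))
        panel = simulate_haplotypes(cfg)
        for i in range(6):
            for j in range(i + 1, 6):
                assert r2_phased(panel, i, j) == pytest.approx(1.0)

    def test_cross_block_ld_near_zero(self):
        cfg = SimulationConfig(seed=2, n_samples=2000, block_spec=((6, 3), (6, 3)))
        panel = simulate_haplotypes(cfg)
        cross = [
            r2_phased(panel, i, j) for i in range(6) for j in range(6, 12)
        ]
        assert np.median(cross) < 0.01

    def test_determinism(self):
        cfg = SimulationConfig(seed=7, n_samples=100, block_spec=((5, 2), (4, 1)))
        a = simulate_haplotypes(cfg)
        b = simulate_haplotypes(cfg)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        assert a.variant_ids == b.variant_ids

    def test_maf_within_range(self):
        cfg = SimulationConfig(
            seed=3, n_samples=1000, block_spec=((8, 4), (8, 4)),
            maf_range=(0.1, 0.5),
        )
        panel = simulate_haplotypes(cfg)
        freqs = panel.haplotypes.mean(axis=0)
        maf = np.minimum(freqs, 1 - freqs)
        assert (maf >= 0.1).all() and (maf <= 0.5).all()

    def test_impossible_maf_errors_naming_variant(self):
        # k=2 founders + background: achievable frequencies cluster near
        # 1/3 and 2/3, so a tight low-MAF band cannot be satisfied
        cfg = SimulationConfig(
            seed=4, n_samples=500, block_spec=((3, 2),), maf_range=(0.01, 0.05)
        )
        with pytest.raises(MafConstraintError, match="variant"):
            simulate_haplotypes(cfg)

    def test_even_chromosome_count_and_alleles(self):
        cfg = SimulationConfig(seed=5, n_samples=11, block_spec=((4, 2),))
        panel = simulate_haplotypes(cfg)
        assert panel.haplotypes.shape[0] == 22
        assert set(np.unique(panel.haplotypes)) <= {0, 1}

    def test_hardy_weinberg(self):
        """Genotype frequencies at n = 5000 are consistent with HWE by
        chi-square at alpha = 0.001."""
        cfg = SimulationConfig(seed=6, n_samples=5000, block_spec=((6, 3),))
        panel = simulate_haplotypes(cfg)
        dosages = panel.dosages()
        for j in range(panel.n_variants):
            p = panel.haplotypes[:, j].mean()
            expected = 5000 * np.array(
                [(1 - p) ** 2, 2 * p * (1 - p), p * p]
            )
            observed = np.bincount(dosages[:, j], minlength=3)
            chi2 = ((observed - expected) ** 2 / expected).sum()
            assert stats.chi2.sf(chi2, df=2) > 0.001


class TestExpression:
    def test_null_delta_gives_flat_means(self):
        cfg = SimulationConfig(seed=8, n_samples=2000, block_spec=((3, 1),))
        panel = simulate_haplotypes(cfg)
        dosages = panel.dosages()
        expr = simulate_expression(
            dosages, panel.variant_ids,
            (CausalGene("G", ((panel.variant_ids[0], 0.0),)),), 1.0, 9,
        )
        slope = stats.linregress(dosages[:, 0], expr["G"]).slope
        assert abs(slope) < 0.1

    def test_twenty_percent_effect_convention(self):
        """delta = 0.2 at mu = 10 puts genotype-class means at (8, 10, 12)
        within two standard errors at n = 2000."""
        cfg = SimulationConfig(seed=10, n_samples=2000, block_spec=((3, 1),))
        panel = simulate_haplotypes(cfg)
        dosages = panel.dosages()
        expr = simulate_expression(
            dosages, panel.variant_ids,
            (CausalGene("G", ((panel.variant_ids[0], 0.2),), mu=10.0),), 1.0, 11,
        )
        for g, want in ((0, 8.0), (1, 10.0), (2, 12.0)):
            vals = expr["G"][dosages[:, 0] == g]
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert vals.mean() == pytest.approx(want, abs=2 * se + 1e-9)

    def test_two_unlinked_causals_recovered_jointly(self):
        """A two-predictor least-squares fit on the emitted data recovers
        both planted slopes."""
        cfg = SimulationConfig(seed=12, n_samples=2000, block_spec=((3, 1), (3, 1)))
        panel = simulate_haplotypes(cfg)
        dosages = panel.dosages().astype(float)
        v1, v2 = panel.variant_ids[0], panel.variant_ids[3]
        expr = simulate_expression(
            dosages, panel.variant_ids,
            (CausalGene("G", ((v1, 0.2), (v2, 0.1)), mu=10.0),), 1.0, 13,
        )
        x = np.column_stack([np.ones(2000), dosages[:, 0], dosages[:, 3]])
        beta, *_ = np.linalg.lstsq(x, expr["G"].to_numpy(), rcond=None)
        assert beta[1] == pytest.approx(2.0, abs=0.3)  # mu * delta
        assert beta[2] == pytest.approx(1.0, abs=0.3)

    def test_absent_causal_variant_errors(self):
        cfg = SimulationConfig(seed=14, n_samples=50, block_spec=((2, 1),))
        panel = simulate_haplotypes(cfg)
        with pytest.raises(KeyError, match="nope"):
            simulate_expression(
                panel.dosages(), panel.variant_ids,
                (CausalGene("G", (("nope", 0.2),)),), 1.0, 15,
            )

    def test_null_genes_are_noise_only(self):
        cfg = SimulationConfig(seed=16, n_samples=3000, block_spec=((2, 1),))
        panel = simulate_haplotypes(cfg)
        dosages = panel.dosages()
        expr = simulate_expression(
            dosages, panel.variant_ids, (), 1.0, 17, n_null_genes=2
        )
        for col in expr.columns:
            slope = stats.linregress(dosages[:, 0], expr[col]).slope
            assert abs(slope) < 0.12


class TestAse:
    def test_balanced_null_expectation(self):
        obs = simulate_ase(
            [f"s{i}" for i in range(2000)], "v", "T",
            AseSpec(fold_change=1.0, ref_bias=0.5), 18,
        )
        ratios = [o.ref_ratio for o in obs if o.total > 0]
        assert np.mean(ratios) == pytest.approx(0.5, abs=0.01)
        assert obs[0].null_ratio == 0.5

    def test_bias_absorbed_by_null(self):
        obs = simulate_ase(
            [f"s{i}" for i in range(2000)], "v", "T",
            AseSpec(fold_change=1.0, ref_bias=0.55), 19,
        )
        devs = [o.ref_ratio - o.null_ratio for o in obs if o.total > 0]
        assert np.mean(devs) == pytest.approx(0.0, abs=0.01)

    def test_fold_change_two_mean_deviation(self):
        """AFC = 2 with no bias: E[REF_RATIO] = 2/3, mean deviation about
        +0.1667 over 1000 simulated samples at depth 100."""
        assert biased_ref_probability(2.0, 0.5) == pytest.approx(2 / 3)
        obs = simulate_ase(
            [f"s{i}" for i in range(1000)], "v", "T",
            AseSpec(depth_mean=100, depth_dispersion=1e6, fold_change=2.0), 20,
        )
        devs = [o.ref_ratio - o.null_ratio for o in obs if o.total > 0]
        assert np.mean(devs) == pytest.approx(1 / 6, abs=0.01)

    def test_zero_depth_rows_emitted(self):
        obs = simulate_ase(
            [f"s{i}" for i in range(300)], "v", "T",
            AseSpec(depth_mean=0.5, depth_dispersion=0.3), 21,
        )
        assert len(obs) == 300
        assert any(o.total == 0 for o in obs)


class TestCatalog:
    def test_files_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(seed=22, n_samples=60)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = simulate_locus_catalog(cfg).write(d1)
        p2 = simulate_locus_catalog(cfg).write(d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_empty_plan_yields_valid_empty_catalog(self, tmp_path):
        cat = simulate_locus_catalog(
            SimulationConfig(seed=23, n_samples=30), tier_plan=()
        )
        assert cat.loci == [] and cat.truth == []
        paths = cat.write(tmp_path)
        assert paths["gwas"].exists() and paths["truth"].exists()
        assert json.loads(paths["truth"].read_text()) == []

    def test_truth_covers_every_tier_once(self):
        cat = simulate_locus_catalog(SimulationConfig(seed=24, n_samples=40))
        assert sorted(t.tier for t in cat.truth) == ["1", "2A", "2B", "2C", "3"]
        assert len({t.locus_id for t in cat.truth}) == 5

    def test_multi_snp_locus_planted(self):
        cat = simulate_locus_catalog(SimulationConfig(seed=25, n_samples=40))
        tier1 = [l for l in cat.loci if l.locus_label == cat.truth[0].locus_id][0]
        assert len(tier1.variants) == 2

    def test_tier3_locus_has_no_qtl_and_no_overlap(self):
        cat = simulate_locus_catalog(SimulationConfig(seed=26, n_samples=40))
        tier3 = next(t for t in cat.truth if t.tier == "3")
        locus = next(l for l in cat.loci if l.locus_label == tier3.locus_id)
        rs = {v.rs_id for v in locus.variants}
        assert not set(cat.qtls.rs_id) & rs
        for v in locus.variants:
            assert cat.positional[v.key] == set()

    def test_ase_truth_round_trip(self):
        """The planted allelic fold-change is recoverable from the emitted
        counts: mean REF_RATIO approximates a/(1+a)."""
        cat = simulate_locus_catalog(SimulationConfig(seed=27, n_samples=400))
        truth = cat.truth[0]
        (variant, afc), = truth.allelic_fold_change.items()
        obs = [o for o in cat.ase if o.variant_id == variant and o.total > 0]
        assert len(obs) > 50
        mean_ratio = np.mean([o.ref_ratio for o in obs])
        assert mean_ratio == pytest.approx(afc / (1 + afc), abs=0.03)
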