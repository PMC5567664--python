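"""Synthetic-data generator: determinism, structure and statistical targets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tetraqtl as tq
from tetraqtl.exceptions import ConfigurationError, SizingError


class TestSimulateGenome:
    def test_two_genes_fit_one_chromosome(self):
        genome = tq.GenomeSpec((("chr1", 1_000_000),))
        genes, _ = tq.simulate_genome(genome, gene_count=2, snp_count=10, seed=1)
        assert len(genes) == 2
        a, b = sorted(genes, key=lambda g: g.start)
        assert 1 <= a.start <= a.end < b.start <= b.end <= 1_000_000

    def test_same_seed_is_bit_identical(self, small_genome):
        g1, s1 = tq.simulate_genome(small_genome, 50, 500, seed=7)
        g2, s2 = tq.simulate_genome(small_genome, 50, 500, seed=7)
        assert g1 == g2 and s1 == s2
        g3, s3 = tq.simulate_genome(small_genome, 50, 500, seed=8)
        assert s3 != s1

    def test_missense_sites_lie_inside_genes(self):
        """Brute-force interval scan: every missense SNP is inside its gene."""
        genome = tq.GenomeSpec.default_potato()
        genes, sites = tq.simulate_genome(genome, 500, 5000, seed=3)
        by_id = {g.gene_id: g for g in genes}
        n_missense = 0
        for s in sites:
            if s.coding_effect == "missense":
                n_missense += 1
                g = by_id[s.gene_id]
                assert g.chrom == s.chrom and g.start <= s.pos <= g.end
        assert n_missense > 0

    def test_genes_never_overlap_within_chromosome(self, small_annotation):
        genes, _ = small_annotation
        by_chrom: dict[str, list] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom_genes in by_chrom.values():
            chrom_genes.sort(key=lambda g: g.start)
            for a, b in zip(chrom_genes, chrom_genes[1:]):
                assert a.end < b.start

    def test_infeasible_gene_count_raises(self):
        genome = tq.GenomeSpec((("chr1", 10_000),))
        with pytest.raises(SizingError):
            tq.simulate_genome(genome, gene_count=10, snp_count=5, seed=1,
                               gene_length_range=(5_000, 6_000))


class TestSimulatePopulation:
    def test_dosages_bounded_and_tsy_exact(self, planted_study):
        s = planted_study
        assert s.dosages.min() >= 0 and s.dosages.max() <= 4
        np.testing.assert_allclose(
            s.phenotypes["TSY"], s.phenotypes["TY"] * s.phenotypes["TSC"] / 100.0
        )

    def test_same_seed_reproduces_population(self, small_genome, small_annotation):
        genes, sites = small_annotation
        cfg = tq.SimConfig(seed=11, n_individuals=30)
        a = tq.simulate_population(small_genome, sites, [], cfg, genes=genes)
        b = tq.simulate_population(small_genome, sites, [], cfg, genes=genes)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.phenotypes.equals(b.phenotypes)
        c = tq.simulate_population(small_genome, sites, [],
                                   tq.SimConfig(seed=12, n_individuals=30), genes=genes)
        assert not np.array_equal(a.dosages, c.dosages)

    def test_null_model_has_no_genotype_phenotype_correlation(self, null_study):
        s = null_study
        tsc = s.phenotypes["TSC"].to_numpy()
        rng = np.random.default_rng(0)
        for j in rng.choice(s.dosages.shape[1], size=25, replace=False):
            d = s.dosages[:, j].astype(float)
            if d.std() == 0:
                continue
            r = np.corrcoef(tsc, d)[0, 1]
            assert abs(r) < 0.2

    def test_antagonistic_qtl_forces_negative_trait_correlation(
        self, small_genome, small_annotation
    ):
        genes, sites = small_annotation
        missense = [s for s in sites if s.coding_effect == "missense"]
        qtls = [tq.QTLSpec(missense[i].snp_id, 2.0, -50.0, "antagonistic") for i in range(2)]
        cfg = tq.SimConfig(seed=21, n_individuals=150, h2_tsc=0.99, h2_ty=0.99)
        study = tq.simulate_population(small_genome, sites, qtls, cfg, genes=genes)
        r = np.corrcoef(study.phenotypes["TSC"], study.phenotypes["TY"])[0, 1]
        assert r < 0

    def test_realized_heritability_matches_target(self, small_genome, small_annotation):
        """Variance decomposition recomputed from the simulated components."""
        genes, sites = small_annotation
        missense = [s for s in sites if s.coding_effect == "missense"]
        qtls = [tq.QTLSpec(missense[i].snp_id, 1.0, 20.0, "synergistic") for i in range(4)]
        cfg = tq.SimConfig(seed=31, n_individuals=200, h2_tsc=0.7, h2_ty=0.4)
        study = tq.simulate_population(small_genome, sites, qtls, cfg, genes=genes)
        ix = study.qtl_site_indices
        g_tsc = study.dosages[:, ix].astype(float) @ np.array([q.effect_tsc for q in study.qtls])
        g_ty = study.dosages[:, ix].astype(float) @ np.array([q.effect_ty for q in study.qtls])
        for g, trait, h2 in ((g_tsc, "TSC", 0.7), (g_ty, "TY", 0.4)):
            total = study.phenotypes[trait].to_numpy()
            noise = total - total.mean() - (g - g.mean())
            realized = np.var(g) / (np.var(g) + np.var(noise))
            assert abs(realized - h2) < 0.1

    def test_planted_effects_with_degenerate_config_raise(self, small_genome, small_annotation):
        genes, sites = small_annotation
        qtl = tq.QTLSpec(sites[0].snp_id, 1.0, 20.0, "synergistic")
        with pytest.raises(ConfigurationError):
            # nonzero genetic effects cannot coexist with zero heritability
            tq.simulate_population(
                small_genome, sites, [qtl],
                tq.SimConfig(seed=41, n_individuals=20, h2_tsc=0.0), genes=genes,
            )
        with pytest.raises(ConfigurationError):
            tq.simulate_population(
                small_genome, sites,
                [tq.QTLSpec("NOT_A_SNP", 1.0, 20.0, "synergistic")],
                tq.SimConfig(seed=41, n_individuals=20), genes=genes,
            )

    def test_within_block_ld_exceeds_cross_chromosome(self, small_genome):
        """Sites close on one chromosome correlate more than cross-chromosome
        pairs, averaged over 50 replicate populations."""
        genes, sites = tq.simulate_genome(small_genome, 20, 120, seed=55)
        pos = np.array([s.pos for s in sites])
        chrom = np.array([s.chrom for s in sites])
        near, far = [], []
        for rep in range(50):
            cfg = tq.SimConfig(seed=600 + rep, n_individuals=60)
            study = tq.simulate_population(small_genome, sites, [], cfg, genes=genes)
            d = study.dosages.astype(float)
            keep = d.std(axis=0) > 0
            c = np.corrcoef(d[:, keep].T)
            p = pos[keep]
            ch = chrom[keep]
            same = (ch[:, None] == ch[None, :]) & (np.abs(p[:, None] - p[None, :]) < 300_000)
            cross = ch[:, None] != ch[None, :]
            iu = np.triu_indices(len(p), 1)
            near.append(np.abs(c[iu][same[iu]]).mean())
            far.append(np.abs(c[iu][cross[iu]]).mean())
        assert np.mean(near) > np.mean(far)


class TestPoolReads:
    def test_fixed_alt_pool_has_no_ref_reads(self):
        dosages = np.full((10, 50), 4, dtype=np.int8)
        alt, ref = tq.sample_pool_reads(dosages, mean_depth=30, seed=1)
        assert (ref == 0).all() and (alt >= 0).all()

    def test_zero_depth_gives_zero_counts(self):
        dosages = np.random.default_rng(0).integers(0, 5, size=(10, 50)).astype(np.int8)
        alt, ref = tq.sample_pool_reads(dosages, mean_depth=0, seed=1)
        assert (alt == 0).all() and (ref == 0).all()

    def test_mean_alt_fraction_matches_pool_frequency(self):
        """Law of large numbers at frequency 1/2, depth 100, 10k SNPs."""
        dosages = np.full((10, 10_000), 2, dtype=np.int8)  # pooled freq exactly 0.5
        alt, ref = tq.sample_pool_reads(dosages, mean_depth=100, seed=2)
        depth = alt + ref
        frac = alt[depth > 0] / depth[depth > 0]
        assert 0.49 < frac.mean() < 0.51


class TestObserveDosages:
    def test_zero_rate_is_identity(self):
        d = np.random.default_rng(1).integers(0, 5, size=(40, 40)).astype(np.int8)
        assert np.array_equal(tq.observe_dosages(d, 0.0, seed=3), d)

    def test_full_rate_shifts_every_call_by_one_unless_clamped(self):
        d = np.random.default_rng(2).integers(0, 5, size=(50, 50)).astype(np.int8)
        obs = tq.observe_dosages(d, 1.0, seed=4)
        diff = obs.astype(int) - d.astype(int)
        assert set(np.unique(np.abs(diff))) <= {0, 1}
        # unchanged entries can only come from clamping at the boundaries
        assert np.isin(d[diff == 0], [0, 4]).all()

    def test_error_rate_realized_within_binomial_bounds(self):
        d = np.ones((250, 400), dtype=np.int8) * 2  # interior: no clamping
        obs = tq.observe_dosages(d, 0.05, seed=5)
        frac = (obs != d).mean()
        assert 0.04 < frac < 0.06


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    rate=st.floats(min_value=0, max_value=1),
    seed=st.integers(min_value=0, max_value=2**20),
)
def test_observed_dosages_always_valid(rate, seed):
    d = np.random.default_rng(9).integers(0, 5, size=(12, 30)).astype(np.int8)
    obs = tq.observe_dosages(d, rate, seed=seed)
    assert obs.min() >= 0 and obs.max() <= 4
    assert (np.abs(obs.astype(int) - d.astype(int)) <= 1).all()
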