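"""Shared fixtures: small synthetic studies reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import tetraqtl as tq


@pytest.fixture(scope="session")
def small_genome() -> tq.GenomeSpec:
    """Four 10-Mbp chromosomes: enough structure, fast to simulate."""
    return tq.GenomeSpec(tuple((f"chr{i + 1:02d}", 10_000_000) for i in range(4)))


@pytest.fixture(scope="session")
def small_annotation(small_genome):
    genes, sites = tq.simulate_genome(small_genome, gene_count=120, snp_count=1200, seed=101)
    return genes, sites


@pytest.fixture(scope="session")
def planted_study(small_genome, small_annotation):
    """A population with three strong antagonistic QTL on missense SNPs."""
    genes, sites = small_annotation
    missense = [s for s in sites if s.coding_effect == "missense"]
    qtls = [
        tq.QTLSpec(missense[i * 7].snp_id, 1.5, -30.0, "antagonistic") for i in range(3)
    ]
    config = tq.SimConfig(seed=202, n_individuals=600, h2_tsc=0.9, h2_ty=0.9)
    return tq.simulate_population(small_genome, sites, qtls, config, genes=genes)


@pytest.fixture(scope="session")
def null_study(small_genome, small_annotation):
    """A population with no QTL at all (pure-noise phenotypes)."""
    genes, sites = small_annotation
    config = tq.SimConfig(seed=303, n_individuals=200)
    return tq.simulate_population(small_genome, sites, [], config, genes=genes)


def pool_indices(study: tq.SimulatedStudy, pair: tq.PoolPair) -> tuple[list[int], list[int]]:
    index = {g: i for i, g in enumerate(study.genotype_ids)}
    return [index[g] for g in pair.case_ids], [index[g] for g in pair.control_ids]


@pytest.fixture(scope="session")
def reads_scan_by_trait(planted_study):
    """Pooled-read Fisher scans for all three traits on the planted study."""
    study = planted_study
    pheno = tq.PhenotypeTable(study.phenotypes)
    out = {}
    for k, trait in enumerate(tq.TRAITS):
        pair = tq.select_pools(pheno, trait, 24, 24)
        case_ix, ctrl_ix = pool_indices(study, pair)
        alt_c, ref_c = tq.sample_pool_reads(study.dosages[case_ix], 40, seed=900 + k)
        alt_k, ref_k = tq.sample_pool_reads(study.dosages[ctrl_ix], 40, seed=950 + k)
        counts = tq.AlleleCounts(alt_c, ref_c, alt_k, ref_k)
        out[trait] = tq.PooledReadScan(counts, study.sites, trait=trait).fit()
    return out
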