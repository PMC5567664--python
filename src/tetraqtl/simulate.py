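"""Synthetic autotetraploid study generator.

Generates the inputs a pooled case-control QTL study consumes: a
multi-chromosome genome with annotated genes, biallelic SNPs (noncoding /
synonymous / missense), an autotetraploid population whose genotypes are
mosaics of founder haplotypes (block-wise recombination produces linkage
disequilibrium on the 0.6-2.5 Mbp scale typical of euchromatic regions of
tetraploid potato), quantitative phenotypes for tuber starch content (TSC,
% fresh weight), tuber yield (TY) and tuber starch yield
(TSY = TY * TSC / 100), pooled sequencing read counts, and noisy five-class
dosage calls (AAAA..BBBB, i.e. 0-4 copies of the alternate allele).

All randomness flows through :class:`numpy.random.Generator` instances
seeded explicitly; equal seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, SizingError

__all__ = [
    "TRAITS",
    "PLOIDY",
    "GenomeSpec",
    "GeneModel",
    "VariantSite",
    "QTLSpec",
    "SimConfig",
    "SimulatedStudy",
    "simulate_genome",
    "simulate_population",
    "simulate_family_population",
    "sample_pool_reads",
    "observe_dosages",
]

TRAITS = ("TSC", "TY", "TSY")
PLOIDY = 4

# Trait baselines: starch content in % fresh weight, yield in dt/ha. The
# residual SDs apply when a trait carries no genetic variance at all.
MEAN_TSC = 17.0
MEAN_TY = 450.0
BASE_SD_TSC = 2.0
BASE_SD_TY = 60.0


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosomes with physical lengths in bp."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ConfigurationError(f"chromosome {name} has non-positive length")

    @classmethod
    def default_potato(cls) -> "GenomeSpec":
        """Twelve chromosomes of 60-90 Mbp (~849 Mbp total)."""
        mbp = (90, 84, 78, 74, 72, 70, 68, 66, 64, 62, 61, 60)
        return cls(tuple((f"chr{i + 1:02d}", m * 1_000_000) for i, m in enumerate(mbp)))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)


@dataclass(frozen=True)
class GeneModel:
    """A gene locus, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DataError(f"gene {self.gene_id}: invalid span [{self.start}, {self.end}]")
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: strand must be + or -")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


CODING_EFFECTS = ("noncoding", "synonymous", "missense")


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP with optional gene assignment and coding effect."""

    snp_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None = None
    coding_effect: str = "noncoding"

    def __post_init__(self) -> None:
        if self.coding_effect not in CODING_EFFECTS:
            raise DataError(f"unknown coding effect {self.coding_effect!r}")
        if self.coding_effect == "missense" and self.gene_id is None:
            raise DataError(f"SNP {self.snp_id}: missense requires a gene assignment")
        if self.ref == self.alt or len(self.ref) != 1 or len(self.alt) != 1:
            raise DataError(f"SNP {self.snp_id}: ref/alt must be distinct single nucleotides")


QTL_MODES = ("antagonistic", "synergistic", "tsc_only", "ty_only")


@dataclass(frozen=True)
class QTLSpec:
    """Additive per-alt-copy effects of one SNP on TSC and TY.

    ``mode`` declares the intended pleiotropy pattern and is validated
    against the effect signs: an antagonistic QTL increases one trait and
    decreases the other, a synergistic QTL moves both in the same
    direction.
    """

    snp_id: str
    effect_tsc: float
    effect_ty: float
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in QTL_MODES:
            raise ConfigurationError(f"unknown QTL mode {self.mode!r}")
        s_tsc, s_ty = np.sign(self.effect_tsc), np.sign(self.effect_ty)
        if self.mode == "antagonistic" and not (s_tsc != 0 and s_ty == -s_tsc):
            raise ConfigurationError("antagonistic QTL needs nonzero, opposite-sign effects")
        if self.mode == "synergistic" and not (s_tsc != 0 and s_ty == s_tsc):
            raise ConfigurationError("synergistic QTL needs nonzero, same-sign effects")
        if self.mode == "tsc_only" and not (s_tsc != 0 and s_ty == 0):
            raise ConfigurationError("tsc_only QTL must have zero TY effect")
        if self.mode == "ty_only" and not (s_ty != 0 and s_tsc == 0):
            raise ConfigurationError("ty_only QTL must have zero TSC effect")


@dataclass(frozen=True)
class SimConfig:
    """Population-level simulation parameters.

    ``ld_block_length_range`` is the support of the uniform block-length
    distribution of the founder-haplotype mosaic; the default matches the
    0.6-2.5 Mbp LD decay reported for euchromatic regions of tetraploid
    potato panels. ``h2_tsc > h2_ty`` by default, reflecting the lower
    heritability of tuber yield compared with starch content.

    ``mean_depth`` (pooled reads per SNP per pool) is not dictated by any
    study design and is freely configurable; 40x is a realistic pooled
    RADseq depth.
    """

    seed: int
    n_individuals: int = 90
    n_founder_haplotypes: int = 24
    ld_block_length_range: tuple[int, int] = (600_000, 2_500_000)
    snp_density: float = 1 / 40_000  # SNPs per bp retained after filtering
    h2_tsc: float = 0.7
    h2_ty: float = 0.4
    mean_depth: float = 40.0
    dosage_error_rate: float = 0.02
    founder_freq_range: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        for name in ("h2_tsc", "h2_ty", "dosage_error_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        if self.mean_depth < 0:
            raise ConfigurationError("mean_depth must be >= 0")
        if self.n_founder_haplotypes < 2:
            raise ConfigurationError("need at least 2 founder haplotypes")
        lo, hi = self.ld_block_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid LD block length range")
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")


@dataclass
class SimulatedStudy:
    """A complete simulated study: genome, annotation, genotypes, phenotypes."""

    genome: GenomeSpec
    genes: list[GeneModel]
    sites: list[VariantSite]
    qtls: list[QTLSpec]
    dosages: np.ndarray  # (n_individuals, n_sites) int8, alt-allele copies 0..4
    phenotypes: pd.DataFrame  # index genotype_id, columns TSC, TY, TSY

    def __post_init__(self) -> None:
        if self.dosages.min() < 0 or self.dosages.max() > PLOIDY:
            raise DataError("dosages must lie in {0..4}")
        tsy = self.phenotypes["TY"] * self.phenotypes["TSC"] / 100.0
        if not np.allclose(self.phenotypes["TSY"], tsy):
            raise DataError("TSY must equal TY * TSC / 100 for every individual")

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.phenotypes.index)

    @property
    def qtl_site_indices(self) -> np.ndarray:
        lookup = {s.snp_id: i for i, s in enumerate(self.sites)}
        return np.array([lookup[q.snp_id] for q in self.qtls], dtype=int)


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def _place_genes_on_chrom(
    chrom: str,
    length: int,
    count: int,
    lengths: np.ndarray,
    rng: np.random.Generator,
    density: str,
) -> list[tuple[int, int]]:
    """Place ``count`` non-overlapping gene spans on one chromosome."""
    total = int(lengths.sum())
    free = length - total
    if free < count:  # need at least 1 bp of gap around each gene
        raise SizingError(
            f"{count} genes of total length {total} bp do not fit on {chrom} ({length} bp)"
        )
    if density == "uniform":
        # split the free space into count+1 gaps via sorted uniforms
        cuts = np.sort(rng.random(count))
        gaps = np.diff(np.concatenate(([0.0], cuts, [1.0]))) * free
    elif density == "u_shaped":
        # gene-poor pericentromeric middle: pile gap mass into the centre
        cuts = np.sort(rng.beta(0.5, 0.5, size=count))
        gaps = np.diff(np.concatenate(([0.0], cuts, [1.0]))) * free
        # beta(0.5,0.5) concentrates *genes* at the ends; gaps follow suit
    else:
        raise ConfigurationError(f"unknown gene density mode {density!r}")
    spans: list[tuple[int, int]] = []
    cursor = 1
    for i in range(count):
        start = cursor + int(gaps[i])
        end = start + int(lengths[i]) - 1
        spans.append((start, end))
        cursor = end + 1
    if spans and spans[-1][1] > length:
        raise SizingError(f"gene placement overflowed chromosome {chrom}")
    return spans


def simulate_genome(
    spec: GenomeSpec,
    gene_count: int,
    snp_count: int,
    seed: int,
    gene_length_range: tuple[int, int] = (2_000, 8_000),
    genic_snp_fraction: float = 0.3,
    coding_snp_fraction: float = 0.4,
    missense_fraction: float = 0.5,
    gene_density: str = "uniform",
) -> tuple[list[GeneModel], list[VariantSite]]:
    """Generate non-overlapping gene models and biallelic SNPs.

    Genes are distributed across chromosomes proportionally to physical
    length and placed without overlap. A fraction ``genic_snp_fraction``
    of SNPs is placed inside gene spans (sequenced SNP panels are strongly
    enriched in genic space), the rest uniformly along the chromosome. A
    SNP inside a gene is exonic with probability ``coding_snp_fraction``
    and then missense with probability ``missense_fraction``, else
    synonymous; intronic/UTR and intergenic SNPs are noncoding.
    Deterministic given ``seed``.
    """
    if gene_count < 1:
        raise SizingError("gene_count must be >= 1")
    if snp_count < 1:
        raise SizingError("snp_count must be >= 1")
    rng = np.random.default_rng(seed)

    lengths = np.array([L for _, L in spec.chromosomes], dtype=float)
    gene_alloc = _proportional_allocation(gene_count, lengths)
    snp_alloc = _proportional_allocation(snp_count, lengths)

    genes: list[GeneModel] = []
    sites: list[VariantSite] = []
    nucleotides = np.array(list("ACGT"))
    gene_no = 0
    snp_no = 0
    for (chrom, length), n_genes, n_snps in zip(spec.chromosomes, gene_alloc, snp_alloc):
        glen = rng.integers(gene_length_range[0], gene_length_range[1] + 1, size=n_genes)
        spans = _place_genes_on_chrom(chrom, length, n_genes, glen, rng, gene_density)
        chrom_genes = []
        for start, end in spans:
            gene_no += 1
            g = GeneModel(f"GENE{gene_no:05d}", chrom, start, end)
            chrom_genes.append(g)
            genes.append(g)

        starts = np.array([g.start for g in chrom_genes], dtype=int)
        ends = np.array([g.end for g in chrom_genes], dtype=int)
        positions = _site_positions(length, n_snps, starts, ends, genic_snp_fraction, rng)
        # gene containment by interval scan over sorted, disjoint spans
        idx = np.searchsorted(starts, positions, side="right") - 1
        ref_idx = rng.integers(0, 4, size=n_snps)
        alt_shift = rng.integers(1, 4, size=n_snps)
        in_gene_u = rng.random(n_snps)
        missense_u = rng.random(n_snps)
        for j, pos in enumerate(positions):
            snp_no += 1
            gene_id = None
            effect = "noncoding"
            k = idx[j]
            if k >= 0 and positions[j] <= ends[k]:
                gene_id = chrom_genes[k].gene_id
                if in_gene_u[j] < coding_snp_fraction:
                    effect = "missense" if missense_u[j] < missense_fraction else "synonymous"
            ref = nucleotides[ref_idx[j]]
            alt = nucleotides[(ref_idx[j] + alt_shift[j]) % 4]
            sites.append(
                VariantSite(f"SNP{snp_no:06d}", chrom, int(pos), str(ref), str(alt), gene_id, effect)
            )
    return genes, sites


def _site_positions(
    length: int,
    n_snps: int,
    gene_starts: np.ndarray,
    gene_ends: np.ndarray,
    genic_fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Distinct sorted SNP positions, a share of them inside gene spans."""
    n_genic = int(round(genic_fraction * n_snps)) if gene_starts.size else 0
    genic = np.array([], dtype=np.int64)
    if n_genic:
        gene_of = rng.integers(0, gene_starts.size, size=n_genic)
        u = rng.random(n_genic)
        span = gene_ends[gene_of] - gene_starts[gene_of] + 1
        genic = (gene_starts[gene_of] + np.floor(u * span)).astype(np.int64)
    uniform = rng.integers(1, length + 1, size=n_snps - n_genic)
    positions = np.unique(np.concatenate([genic, uniform]))
    while positions.size < n_snps:  # top up collisions
        extra = rng.integers(1, length + 1, size=n_snps - positions.size)
        positions = np.unique(np.concatenate([positions, extra]))
    return positions[:n_snps] if positions.size == n_snps else np.sort(
        rng.permutation(positions)[:n_snps]
    )


def _proportional_allocation(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` items by ``weights``."""
    quota = total * weights / weights.sum()
    alloc = np.floor(quota).astype(int)
    remainder = total - alloc.sum()
    order = np.argsort(-(quota - alloc), kind="stable")
    alloc[order[:remainder]] += 1
    return alloc


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _sites_by_chrom(sites: Sequence[VariantSite], genome: GenomeSpec):
    by_chrom: dict[str, list[int]] = {name: [] for name in genome.names}
    for i, s in enumerate(sites):
        if s.chrom not in by_chrom:
            raise DataError(f"SNP {s.snp_id} on unknown chromosome {s.chrom}")
        if not 1 <= s.pos <= genome.length_of(s.chrom):
            raise DataError(f"SNP {s.snp_id} position {s.pos} outside {s.chrom}")
        by_chrom[s.chrom].append(i)
    return {c: np.asarray(ix, dtype=int) for c, ix in by_chrom.items()}


def _mosaic_haplotypes(
    genome: GenomeSpec,
    sites: Sequence[VariantSite],
    founders: np.ndarray,
    n_haplotypes: int,
    block_range: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Build haplotypes as block mosaics of founder haplotypes.

    Each haplotype walks every chromosome left to right; block lengths are
    uniform on ``block_range`` and each block copies one founder drawn
    uniformly at random. Returns (n_haplotypes, n_sites) int8.
    """
    n_sites = len(sites)
    n_founders = founders.shape[0]
    out = np.empty((n_haplotypes, n_sites), dtype=np.int8)
    by_chrom = _sites_by_chrom(sites, genome)
    lo, hi = block_range
    for chrom, length in genome.chromosomes:
        ix = by_chrom[chrom]
        if ix.size == 0:
            continue
        pos = np.array([sites[i].pos for i in ix], dtype=np.int64)
        fndr_c = founders[:, ix]
        # draw enough blocks to cover the chromosome for every haplotype
        max_blocks = int(length // lo) + 2
        for h in range(n_haplotypes):
            blens = rng.integers(lo, hi + 1, size=max_blocks)
            bounds = np.cumsum(blens)
            n_blocks = int(np.searchsorted(bounds, length)) + 1
            donor = rng.integers(0, n_founders, size=n_blocks)
            block_of_site = np.searchsorted(bounds[:n_blocks], pos, side="left")
            out[h, ix] = fndr_c[donor[block_of_site], np.arange(ix.size)]
    return out


def _balanced_column(n: int, rng: np.random.Generator) -> np.ndarray:
    col = np.zeros(n, dtype=np.int8)
    col[: n // 2] = 1
    return rng.permutation(col)


def simulate_population(
    genome: GenomeSpec,
    sites: Sequence[VariantSite],
    qtls: Sequence[QTLSpec],
    config: SimConfig,
    genes: Sequence[GeneModel] = (),
) -> SimulatedStudy:
    """Simulate an autotetraploid population with block-LD and phenotypes.

    Each individual carries four haplotypes drawn block-wise from a panel of
    founder haplotypes. Founder allele frequencies are uniform on
    ``config.founder_freq_range``; QTL sites are forced to be balanced
    (frequency 1/2) among founders so planted effects always segregate.

    Phenotypes follow an additive model, e.g. for starch content
    ``TSC_i = mu + sum_q a_q d_iq + e_i`` with Gaussian noise rescaled
    against the realized genetic variance so that the realized narrow-sense
    heritability approximates ``h2_tsc`` (likewise TY). TSY is derived as
    ``TY * TSC / 100`` exactly.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    m = len(sites)
    n_f = config.n_founder_haplotypes
    site_index = {s.snp_id: i for i, s in enumerate(sites)}
    for q in qtls:
        if q.snp_id not in site_index:
            raise ConfigurationError(f"QTL {q.snp_id} is not among the simulated sites")

    freqs = rng.uniform(*config.founder_freq_range, size=m)
    founders = (rng.random((n_f, m)) < freqs).astype(np.int8)
    for q in qtls:
        founders[:, site_index[q.snp_id]] = _balanced_column(n_f, rng)

    haplotypes = _mosaic_haplotypes(
        genome, sites, founders, PLOIDY * n, config.ld_block_length_range, rng
    )
    dosages = haplotypes.reshape(n, PLOIDY, m).sum(axis=1).astype(np.int8)

    qtl_ix = np.array([site_index[q.snp_id] for q in qtls], dtype=int)
    eff_tsc = np.array([q.effect_tsc for q in qtls], dtype=float)
    eff_ty = np.array([q.effect_ty for q in qtls], dtype=float)
    d_q = dosages[:, qtl_ix].astype(float) if len(qtls) else np.zeros((n, 0))

    tsc = MEAN_TSC + _trait_with_noise(d_q, eff_tsc, config.h2_tsc, BASE_SD_TSC, rng, "TSC")
    ty = MEAN_TY + _trait_with_noise(d_q, eff_ty, config.h2_ty, BASE_SD_TY, rng, "TY")
    tsy = ty * tsc / 100.0

    ids = [f"G{i + 1:04d}" for i in range(n)]
    pheno = pd.DataFrame({"TSC": tsc, "TY": ty, "TSY": tsy}, index=pd.Index(ids, name="genotype_id"))
    return SimulatedStudy(genome, list(genes), list(sites), list(qtls), dosages, pheno)


def _trait_with_noise(
    d_q: np.ndarray,
    effects: np.ndarray,
    h2: float,
    base_sd: float,
    rng: np.random.Generator,
    trait: str,
) -> np.ndarray:
    """Genetic values plus Gaussian noise scaled to the target heritability."""
    g = d_q @ effects if effects.size else np.zeros(d_q.shape[0])
    var_g = float(np.var(g))
    has_effects = bool(effects.size) and bool(np.any(effects != 0))
    if var_g == 0.0:
        if has_effects and h2 > 0:
            raise ConfigurationError(
                f"{trait}: QTL effects are planted but realized genetic variance is zero"
            )
        return g + rng.normal(0.0, base_sd, size=d_q.shape[0])
    if h2 >= 1.0:
        return g
    if h2 <= 0.0:
        raise ConfigurationError(f"{trait}: h2 must be positive when QTL effects are planted")
    var_e = var_g * (1.0 - h2) / h2
    return g + rng.normal(0.0, np.sqrt(var_e), size=d_q.shape[0])


def simulate_family_population(
    genome: GenomeSpec,
    sites: Sequence[VariantSite],
    config: SimConfig,
    n_families: int,
    founders_per_family: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Structured population: disjoint founder sets per family.

    Individuals within a family draw their haplotype blocks from that
    family's private founders only, creating strong relatedness structure
    (for mixed-model calibration studies). Returns ``(dosages, family)``
    where ``family`` is the family index per individual.
    """
    if n_families < 2:
        raise ConfigurationError("need at least 2 families")
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    m = len(sites)
    n_f = n_families * founders_per_family
    freqs = rng.uniform(*config.founder_freq_range, size=m)
    founders = (rng.random((n_f, m)) < freqs).astype(np.int8)

    fam = np.repeat(np.arange(n_families), int(np.ceil(n / n_families)))[:n]
    dosages = np.empty((n, m), dtype=np.int8)
    for f in range(n_families):
        members = np.flatnonzero(fam == f)
        if members.size == 0:
            continue
        fam_founders = founders[f * founders_per_family : (f + 1) * founders_per_family]
        haps = _mosaic_haplotypes(
            genome, sites, fam_founders, PLOIDY * members.size,
            config.ld_block_length_range, rng,
        )
        dosages[members] = haps.reshape(members.size, PLOIDY, m).sum(axis=1)
    return dosages, fam


# ---------------------------------------------------------------------------
# observation layers: pooled reads and array dosage calls
# ---------------------------------------------------------------------------

def sample_pool_reads(
    pool_dosages: np.ndarray,
    mean_depth: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample pooled sequencing read counts for one pool.

    The pooled alternate allele frequency at each SNP is the total alt
    dosage over ``4 * pool size`` chromosomes; per-SNP depth is
    Poisson(``mean_depth``) and alt reads are Binomial(depth, frequency).
    Returns ``(alt_reads, ref_reads)``.
    """
    pool_dosages = np.asarray(pool_dosages)
    if pool_dosages.ndim != 2 or pool_dosages.shape[0] == 0:
        raise DataError("pool_dosages must be a non-empty (individuals x SNPs) matrix")
    rng = np.random.default_rng(seed)
    freq = pool_dosages.sum(axis=0) / (PLOIDY * pool_dosages.shape[0])
    depth = rng.poisson(mean_depth, size=freq.size)
    alt = rng.binomial(depth, freq)
    return alt, depth - alt


def observe_dosages(dosages: np.ndarray, dosage_error_rate: float, seed: int) -> np.ndarray:
    """Perturb true dosages into observed five-class calls.

    With probability ``dosage_error_rate`` a call is shifted by one class
    (+/-1 with equal probability) and clamped to [0, 4]; otherwise it is
    returned unchanged.
    """
    if not 0.0 <= dosage_error_rate <= 1.0:
        raise ConfigurationError("dosage_error_rate must lie in [0, 1]")
    dosages = np.asarray(dosages, dtype=np.int8)
    rng = np.random.default_rng(seed)
    hit = rng.random(dosages.shape) < dosage_error_rate
    step = rng.choice(np.array([-1, 1], dtype=np.int8), size=dosages.shape)
    observed = dosages + hit * step
    return np.clip(observed, 0, PLOIDY).astype(np.int8)
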