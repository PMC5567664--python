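"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 1-based inclusive everywhere (the VCF/GFF3
convention); conversion to BED's 0-based half-open happens only at the BED
boundary. All writers are atomic (write to a temp file in the target
directory, then rename); all VCF access goes through :mod:`pysam` and GFF3
parsing through :mod:`gffutils`.
"""

from __future__ import annotations

import contextlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

from .exceptions import DataError, FormatError
from .simulate import (
    PLOIDY,
    TRAITS,
    GeneModel,
    GenomeSpec,
    SimulatedStudy,
    VariantSite,
)

__all__ = [
    "PhenotypeTable",
    "AnnotationIndex",
    "VariantData",
    "read_phenotypes",
    "write_phenotypes",
    "read_variants",
    "write_pool_vcf",
    "write_dosage_vcf",
    "annotate_sites",
    "read_gff3_genes",
    "write_gff3",
    "read_bed",
    "write_bed",
    "write_genome_table",
    "read_genome_table",
    "write_study",
]

logger = logging.getLogger(__name__)


@contextlib.contextmanager
def _atomic_path(path: str | Path):
    """Yield a temp path in the same directory; rename onto ``path`` on success."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        yield tmp
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

class PhenotypeTable:
    """Adjusted entry means per genotype for TSC, TY and TSY.

    Missing values are permitted per trait; genotype identifiers must be
    unique. Backed by a DataFrame indexed by ``genotype_id``.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate genotype_id {dup!r}")
        present = [t for t in TRAITS if t in df.columns]
        if not present:
            raise FormatError(f"no recognized trait column among {TRAITS}")
        data = {}
        for t in TRAITS:
            if t in df.columns:
                data[t] = pd.to_numeric(df[t], errors="coerce")
            else:
                data[t] = pd.Series(np.nan, index=df.index)
        self.df = pd.DataFrame(data, index=df.index)
        self.df.index.name = "genotype_id"

    def __len__(self) -> int:
        return len(self.df)

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.df.index)

    def trait_values(self, trait: str, ids: Sequence[str] | None = None) -> pd.Series:
        """Non-missing values of one trait, optionally restricted to ``ids``."""
        if trait not in TRAITS:
            raise KeyError(f"unknown trait {trait!r}")
        s = self.df[trait]
        if ids is not None:
            s = s.loc[list(ids)]
        return s.dropna()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={0: str})
        if "genotype_id" not in df.columns:
            raise FormatError("phenotype table must have a genotype_id column")
        return cls(df.set_index("genotype_id"))

    def to_tsv(self, path: str | Path) -> None:
        with _atomic_path(path) as tmp:
            self.df.to_csv(tmp, sep="\t", float_format="%.10g")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    return PhenotypeTable.from_tsv(path)


def write_phenotypes(pheno: PhenotypeTable | pd.DataFrame, path: str | Path) -> None:
    if isinstance(pheno, pd.DataFrame):
        pheno = PhenotypeTable(pheno)
    pheno.to_tsv(path)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass
class VariantData:
    """Parsed biallelic SNPs plus per-sample counts or dosages.

    ``reads`` mode: ``counts[sample] = (alt_reads, ref_reads)`` arrays.
    ``dosages`` mode: ``dosages`` is (n_samples, n_sites) with -1 = missing.
    """

    sites: list[VariantSite]
    samples: list[str]
    mode: str
    counts: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    dosages: np.ndarray | None = None
    n_skipped: int = 0


def _vcf_header(
    sites: Sequence[VariantSite],
    samples: Sequence[str],
    genome: GenomeSpec | None,
    fmt: str,
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if genome is not None:
        contigs = genome.chromosomes
    else:
        seen: dict[str, int] = {}
        for s in sites:
            seen[s.chrom] = max(seen.get(s.chrom, 0), s.pos)
        contigs = tuple(seen.items())
    for name, length in contigs:
        header.contigs.add(name, length=length)
    header.info.add("GENE", 1, "String", "Gene containing the SNP")
    header.info.add("EFFECT", 1, "String", "Coding effect: noncoding, synonymous or missense")
    if fmt == "AD":
        header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    else:
        header.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        header.add_sample(s)
    return header


def _new_record(vcf: pysam.VariantFile, site: VariantSite) -> pysam.VariantRecord:
    rec = vcf.new_record(
        contig=site.chrom,
        start=site.pos - 1,  # pysam is 0-based internally
        alleles=(site.ref, site.alt),
        id=site.snp_id,
    )
    if site.gene_id is not None:
        rec.info["GENE"] = site.gene_id
    rec.info["EFFECT"] = site.coding_effect
    return rec


def write_pool_vcf(
    sites: Sequence[VariantSite],
    pool_counts: Mapping[str, tuple[np.ndarray, np.ndarray]],
    path: str | Path,
    genome: GenomeSpec | None = None,
) -> None:
    """Write a pooled-reads VCF: one sample per pool, AD = (ref, alt) depths.

    ``pool_counts`` maps sample name to ``(alt_reads, ref_reads)`` arrays in
    site order (the package's internal alt-first convention; AD follows the
    VCF standard ref-first order on disk).
    """
    samples = list(pool_counts)
    header = _vcf_header(sites, samples, genome, "AD")
    with _atomic_path(path) as tmp:
        with pysam.VariantFile(tmp, "w", header=header) as vcf:
            for i, site in enumerate(sites):
                rec = _new_record(vcf, site)
                for s in samples:
                    alt, ref = pool_counts[s]
                    rec.samples[s]["AD"] = (int(ref[i]), int(alt[i]))
                vcf.write(rec)


def write_dosage_vcf(
    sites: Sequence[VariantSite],
    dosages: np.ndarray,
    sample_ids: Sequence[str],
    path: str | Path,
    genome: GenomeSpec | None = None,
) -> None:
    """Write per-individual tetraploid genotypes, GT-encoded (e.g. 0/0/1/1)."""
    dosages = np.asarray(dosages)
    if dosages.shape != (len(sample_ids), len(sites)):
        raise DataError("dosage matrix shape must be (n_samples, n_sites)")
    header = _vcf_header(sites, sample_ids, genome, "GT")
    gt_by_dosage = {d: (0,) * (PLOIDY - d) + (1,) * d for d in range(PLOIDY + 1)}
    with _atomic_path(path) as tmp:
        with pysam.VariantFile(tmp, "w", header=header) as vcf:
            for j, site in enumerate(sites):
                rec = _new_record(vcf, site)
                for i, s in enumerate(sample_ids):
                    d = int(dosages[i, j])
                    if not 0 <= d <= PLOIDY:
                        raise DataError(f"dosage {d} out of range at {site.snp_id}")
                    rec.samples[s]["GT"] = gt_by_dosage[d]
                vcf.write(rec)


def read_variants(path: str | Path, mode: str) -> VariantData:
    """Read biallelic SNPs plus AD counts (``reads``) or GT dosages (``dosages``).

    Multi-allelic and indel records are skipped with a logged warning and
    counted in ``n_skipped``. Positions stay 1-based as in the VCF.
    """
    if mode not in ("reads", "dosages"):
        raise ValueError(f"mode must be 'reads' or 'dosages', got {mode!r}")
    sites: list[VariantSite] = []
    rows: list[list] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        fmt_key = "AD" if mode == "reads" else "GT"
        if fmt_key not in vcf.header.formats:
            raise FormatError(f"VCF lacks required FORMAT field {fmt_key}")
        has_gene = "GENE" in vcf.header.info
        has_effect = "EFFECT" in vcf.header.info
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                n_skipped += 1
                logger.warning("skipping non-biallelic-SNP record at %s:%s", rec.chrom, rec.pos)
                continue
            gene = rec.info.get("GENE") if has_gene else None
            effect = rec.info.get("EFFECT", "noncoding") if has_effect else "noncoding"
            sites.append(
                VariantSite(
                    rec.id or f"{rec.chrom}:{rec.pos}",
                    rec.chrom,
                    rec.pos,
                    rec.ref,
                    rec.alts[0],
                    gene,
                    effect,
                )
            )
            row = []
            for s in samples:
                value = rec.samples[s].get(fmt_key)
                if mode == "reads":
                    if value is None or value[0] is None:
                        raise FormatError(f"missing AD for sample {s} at {rec.chrom}:{rec.pos}")
                    row.append((value[1], value[0]))  # internal order: (alt, ref)
                else:
                    if value is None or any(a is None for a in value):
                        row.append(-1)
                    else:
                        row.append(int(sum(value)))
            rows.append(row)

    data = VariantData(sites=sites, samples=samples, mode=mode, n_skipped=n_skipped)
    if mode == "reads":
        for k, s in enumerate(samples):
            alt = np.array([r[k][0] for r in rows], dtype=np.int64)
            ref = np.array([r[k][1] for r in rows], dtype=np.int64)
            data.counts[s] = (alt, ref)
    else:
        data.dosages = np.array(rows, dtype=np.int16).T if rows else np.zeros((len(samples), 0), np.int16)
    return data


# ---------------------------------------------------------------------------
# GFF3 and the annotation index
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with _atomic_path(path) as tmp:
        with open(tmp, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genes:
                fh.write(
                    f"{g.chrom}\ttetraqtl\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
                )


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene features from a GFF3 file via gffutils (in-memory DB)."""
    import gffutils

    _validate_gff_lines(path)
    try:
        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - gffutils raises various types
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneModel(gene_id, feat.seqid, feat.start, feat.end, feat.strand or "+"))
    return genes


def _validate_gff_lines(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise FormatError(f"{path}: malformed GFF line {lineno}: expected 9 columns")


class AnnotationIndex:
    """Interval index over gene models; lookup returns containing genes."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._trees: dict[str, IntervalTree] = {}
        self.genes = list(genes)
        for g in self.genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)

    @classmethod
    def from_gff3(cls, path: str | Path) -> "AnnotationIndex":
        return cls(read_gff3_genes(path))

    def lookup(self, chrom: str, pos: int) -> list[str]:
        """Gene IDs whose [start, end] span contains ``pos`` (sorted)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))


def annotate_sites(
    sites: Sequence[VariantSite],
    annotation: AnnotationIndex | str | Path,
) -> list[VariantSite]:
    """Fill ``gene_id`` from gene spans; ties go to the smallest gene_id.

    Coding effects are carried along unchanged for sites that land in a
    gene (they come from upstream effect annotation); a site outside every
    gene is reset to noncoding with no gene assignment.
    """
    if not isinstance(annotation, AnnotationIndex):
        annotation = AnnotationIndex.from_gff3(annotation)
    out = []
    for s in sites:
        hits = annotation.lookup(s.chrom, s.pos)
        if hits:
            out.append(VariantSite(s.snp_id, s.chrom, s.pos, s.ref, s.alt, hits[0], s.coding_effect))
        else:
            out.append(VariantSite(s.snp_id, s.chrom, s.pos, s.ref, s.alt, None, "noncoding"))
    return out


# ---------------------------------------------------------------------------
# BED and genome tables
# ---------------------------------------------------------------------------

def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write internal 1-based inclusive intervals as 0-based half-open BED.

    ``intervals`` needs columns chrom/start/end; extra columns (name, score)
    are carried through in order.
    """
    df = intervals.copy()
    required = ("chrom", "start", "end")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"intervals need a {col!r} column")
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    if ((df["end"] - df["start"]) <= 0).any():
        raise DataError("interval with end <= start after BED conversion")
    cols = ["chrom", "start", "end"] + [c for c in df.columns if c not in required]
    with _atomic_path(path) as tmp:
        with open(tmp, "w") as fh:
            fh.write("#" + "\t".join(cols) + "\n")
            df[cols].to_csv(fh, sep="\t", header=False, index=False, float_format="%.10g")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file back into internal 1-based inclusive coordinates."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.startswith("#"):
            names = header[1:].split("\t")
            df = pd.read_csv(fh, sep="\t", names=names)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", header=None)
            df.columns = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    if df.empty:
        return df
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df


def write_genome_table(genome: GenomeSpec, path: str | Path) -> None:
    df = pd.DataFrame(genome.chromosomes, columns=["chrom", "length"])
    with _atomic_path(path) as tmp:
        df.to_csv(tmp, sep="\t", index=False)


def read_genome_table(path: str | Path) -> GenomeSpec:
    df = pd.read_csv(path, sep="\t")
    return GenomeSpec(tuple(zip(df["chrom"].astype(str), df["length"].astype(int))))


# ---------------------------------------------------------------------------
# bundled study output
# ---------------------------------------------------------------------------

def write_study(study: SimulatedStudy, out_dir: str | Path, dosage_error_rate: float = 0.0,
                seed: int = 0) -> dict[str, Path]:
    """Write a simulated study to a directory (GFF3 + VCF + TSV + truth table)."""
    from .simulate import observe_dosages

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.tsv",
        "genes": out / "genes.gff3",
        "dosages": out / "dosages.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "qtls": out / "qtls.tsv",
    }
    write_genome_table(study.genome, paths["genome"])
    write_gff3(study.genes, paths["genes"])
    observed = observe_dosages(study.dosages, dosage_error_rate, seed) if dosage_error_rate else study.dosages
    write_dosage_vcf(study.sites, observed, study.genotype_ids, paths["dosages"], study.genome)
    write_phenotypes(study.phenotypes.reset_index().set_index("genotype_id"), paths["phenotypes"])
    qtl_rows = []
    site_by_id = {s.snp_id: s for s in study.sites}
    for q in study.qtls:
        s = site_by_id[q.snp_id]
        qtl_rows.append((q.snp_id, s.chrom, s.pos, q.effect_tsc, q.effect_ty, q.mode))
    qtl_df = pd.DataFrame(qtl_rows, columns=["snp_id", "chrom", "pos", "effect_tsc", "effect_ty", "mode"])
    with _atomic_path(paths["qtls"]) as tmp:
        qtl_df.to_csv(tmp, sep="\t", index=False, float_format="%.10g")
    return paths
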