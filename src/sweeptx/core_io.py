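"""Data model and file I/O for the genome + transcriptome pipeline.

All population-genetic statistics run on a :class:`GenotypeMatrix` of
alternate-allele dosages; expression analysis runs on a
:class:`CountsTable`; annotation is a list of :class:`GeneModel`.

Coordinate conventions
----------------------
Internally everything is 0-based half-open.  VCF positions stay 1-based at
the I/O boundary (the ``pos`` array mirrors the file); GFF/GTF 1-based
closed intervals are converted on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    LabeledSampleError,
    OrderingError,
    ValidationError,
)

#: Sentinel for a missing genotype call.  Never 0: dosage 0 is a valid
#: homozygous-reference call.
MISSING = -1


@dataclass
class GenotypeMatrix:
    """Samples x biallelic SNPs with per-site metadata.

    ``dosage`` holds alternate-allele counts in {0, 1, 2} or :data:`MISSING`,
    shape ``(n_samples, n_variants)``.  ``pos`` is 1-based (VCF convention).
    """

    chrom: np.ndarray            # str per variant
    pos: np.ndarray              # int, 1-based
    ref: np.ndarray              # str
    alt: np.ndarray              # str
    qual: np.ndarray             # float, Phred site quality
    site_depth: np.ndarray       # int, summed depth across samples
    dosage: np.ndarray           # int8 (n_samples, n_variants)
    sample_ids: list[str]
    pop_labels: dict[str, str]   # sample -> population
    depth_source: str = "INFO/DP"
    n_skipped: int = 0           # non-SNP / multi-allelic records dropped on read

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n_s, n_v = self.dosage.shape
        if n_s != len(self.sample_ids):
            raise ValidationError("dosage rows != number of samples")
        for arr_name in ("chrom", "pos", "ref", "alt", "qual", "site_depth"):
            if len(getattr(self, arr_name)) != n_v:
                raise ValidationError(f"{arr_name} length != number of variants")
        missing = [s for s in self.sample_ids if s not in self.pop_labels]
        if missing:
            raise LabeledSampleError(f"samples without population label: {missing}")
        vals = np.unique(self.dosage)
        bad = vals[~np.isin(vals, [MISSING, 0, 1, 2])]
        if bad.size:
            raise ValidationError(f"invalid dosage values {bad.tolist()}")
        if n_v and self.pos.min() < 1:
            raise ValidationError("VCF positions must be >= 1")
        # strictly increasing positions within each chromosome
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise OrderingError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.pop_labels[s], None)
        return list(seen)

    def sample_indices(self, pop: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.pop_labels[s] == pop]
        if not idx:
            raise LabeledSampleError(f"no samples in population {pop!r}")
        return np.asarray(idx)

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given site mask/index."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return dataclasses.replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            qual=self.qual[idx],
            site_depth=self.site_depth[idx],
            dosage=self.dosage[:, idx],
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene interval with its merged-exon length.

    ``start``/``end`` are 0-based half-open; ``exons`` are merged
    non-overlapping half-open intervals within ``[start, end)``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"{self.gene_id}: start must be < end")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(f"{self.gene_id}: exon [{s},{e}) outside gene")

    @property
    def exon_union_length_bp(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exon_union_length_kb(self) -> float:
        return self.exon_union_length_bp / 1000.0


@dataclass
class CountsTable:
    """Gene x sample integer count matrix with group labels and library sizes."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray           # (n_genes, n_samples) non-negative ints
    group_labels: dict[str, str]
    mapped_reads: np.ndarray     # per-sample total mapped fragments

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("counts shape does not match gene/sample ids")
        if np.any(self.counts < 0):
            raise ValidationError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValidationError("non-integer counts")
            self.counts = self.counts.astype(np.int64)
        unlabeled = [s for s in self.sample_ids if s not in self.group_labels]
        if unlabeled:
            raise LabeledSampleError(f"samples without group label: {unlabeled}")
        if len(self.mapped_reads) != len(self.sample_ids):
            raise ValidationError("mapped_reads length != number of samples")
        if np.any(self.mapped_reads < self.counts.sum(axis=0)):
            raise ValidationError("mapped_reads below column count sums")

    def group_indices(self, group: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.sample_ids) if self.group_labels[s] == group]
        if not idx:
            raise LabeledSampleError(f"no samples in group {group!r}")
        return np.asarray(idx)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.group_labels[s], None)
        return list(seen)


# ---------------------------------------------------------------------------
# sample / group maps
# ---------------------------------------------------------------------------

def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample<TAB>label`` TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns")
    first = df.iloc[0]
    if first[0].lower() in {"sample", "sample_id"}:
        df = df.iloc[1:]
    return dict(zip(df[0], df[1]))


def write_sample_map(mapping: dict[str, str], path: str | Path,
                     header: tuple[str, str] = ("sample", "population")) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{header[0]}\t{header[1]}\n")
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNP_ALLELES = frozenset("ACGT")


def read_vcf(path: str | Path, sample_map: str | Path | dict[str, str]) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF 4.x file into a :class:`GenotypeMatrix`.

    Non-SNP and multi-allelic records are skipped and counted in
    ``n_skipped`` (splitting multi-allelics would silently change site
    counts, so they are dropped whole).  Site depth comes from INFO/DP when
    present, otherwise the sum of per-sample FORMAT/DP.
    """
    from cyvcf2 import VCF

    pop_labels = sample_map if isinstance(sample_map, dict) else read_sample_map(sample_map)

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in pop_labels]
    if unmapped:
        raise LabeledSampleError(f"VCF samples missing from sample map: {unmapped}")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    quals: list[float] = []
    depths: list[int] = []
    dosages: list[np.ndarray] = []
    n_skipped = 0
    depth_source = "INFO/DP"
    for rec in vcf:
        if len(rec.ALT) != 1 or rec.REF not in _SNP_ALLELES or rec.ALT[0] not in _SNP_ALLELES:
            n_skipped += 1
            continue
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        quals.append(rec.QUAL if rec.QUAL is not None else float("nan"))
        dp = rec.INFO.get("DP")
        if dp is None:
            depth_source = "sum(FORMAT/DP)"
            fmt_dp = rec.format("DP")
            dp = int(np.nansum(fmt_dp)) if fmt_dp is not None else 0
        depths.append(int(dp))
        # gts012: 0/1/2 = dosage, 3 = unknown
        gt = rec.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        dosages.append(gt)
    if not dosages:
        raise EmptyInputError(f"{path}: no biallelic SNP records")

    return GenotypeMatrix(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        qual=np.asarray(quals, dtype=float),
        site_depth=np.asarray(depths, dtype=np.int64),
        dosage=np.column_stack(dosages).astype(np.int8),
        sample_ids=samples,
        pop_labels={s: pop_labels[s] for s in samples},
        depth_source=depth_source,
        n_skipped=n_skipped,
    )


_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as a minimal, deterministic VCF 4.2 file."""
    if contig_lengths is None:
        contig_lengths = {}
        for c, p in zip(gm.chrom, gm.pos):
            contig_lengths[c] = max(contig_lengths.get(c, 0), int(p))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c, ln in contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j in range(gm.n_variants):
            gts = "\t".join(_DOSAGE_TO_GT[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}\t"
                f"{gm.qual[j]:.2f}\t.\tDP={int(gm.site_depth[j])}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# GFF3 / GTF
# ---------------------------------------------------------------------------

def read_gff(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GFF3 or GTF file.

    Exon intervals are merged per gene; coordinates convert from 1-based
    closed to 0-based half-open on read.
    """
    import gffutils

    path = str(path)
    is_gtf = path.endswith((".gtf", ".gtf.gz"))
    try:
        db = gffutils.create_db(
            path, ":memory:",
            force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
            gtf_transcript_key="transcript_id" if is_gtf else None,
        )
    except Exception as exc:
        if not any(line.strip() and not line.startswith("#")
                   for line in open(path, encoding="utf-8")):
            raise EmptyInputError(f"{path}: no gene features") from exc
        raise FormatError(f"{path}: cannot parse annotation: {exc}") from exc

    exons_by_gene: dict[str, list[tuple[int, int]]] = {}
    genes: dict[str, tuple[str, int, int, str]] = {}
    for feat in db.features_of_type("gene"):
        gid = _gene_id_of(feat)
        genes[gid] = (feat.seqid, feat.start - 1, feat.end, feat.strand or ".")
    for feat in db.features_of_type("exon"):
        gid = _exon_gene_id(feat, db)
        if gid not in genes:
            raise FormatError(f"exon at {feat.seqid}:{feat.start} has no parent gene {gid!r}")
        exons_by_gene.setdefault(gid, []).append((feat.start - 1, feat.end))
    if not genes:
        raise EmptyInputError(f"{path}: no gene features")

    models = []
    for gid, (chrom, start, end, strand) in genes.items():
        exons = merge_intervals(exons_by_gene.get(gid, [(start, end)]))
        models.append(GeneModel(gid, chrom, start, end, strand, tuple(exons)))
    models.sort(key=lambda g: (g.chrom, g.start))
    return models


def _gene_id_of(feat) -> str:
    for key in ("gene_id", "ID", "Name"):
        if key in feat.attributes:
            return feat.attributes[key][0]
    raise FormatError(f"gene feature at {feat.seqid}:{feat.start} lacks a gene id")


def _exon_gene_id(feat, db) -> str:
    if "gene_id" in feat.attributes:
        return feat.attributes["gene_id"][0]
    # GFF3: walk Parent chain (exon -> mRNA -> gene)
    parent = feat
    for _ in range(3):
        pids = parent.attributes.get("Parent")
        if not pids:
            break
        parent = db[pids[0]]
        if parent.featuretype == "gene":
            return _gene_id_of(parent)
    raise FormatError(f"exon at {feat.seqid}:{feat.start} has no resolvable gene parent")


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def write_gff(models: Sequence[GeneModel], path: str | Path,
              chrom_lengths: dict[str, int] | None = None) -> None:
    """Write gene models as GFF3 (gene + mRNA + exon features)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for c, ln in chrom_lengths.items():
                fh.write(f"##sequence-region {c} 1 {ln}\n")
        for g in models:
            fh.write(f"{g.chrom}\tsweeptx\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\tsweeptx\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                     f"ID={mrna};Parent={g.gene_id}\n")
            for k, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.chrom}\tsweeptx\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mrna}.exon{k};Parent={mrna}\n")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, group_map: str | Path | dict[str, str],
                mapped_reads: str | Path | dict[str, int]) -> CountsTable:
    """Read a gene x sample counts TSV plus group map and library sizes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    groups = group_map if isinstance(group_map, dict) else read_sample_map(group_map)
    if not isinstance(mapped_reads, dict):
        mapped_reads = {k: int(v) for k, v in read_sample_map(mapped_reads).items()}
    samples = list(df.columns)
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or np.any(vals != np.floor(vals)):
        raise ValidationError(f"{path}: counts must be integers")
    if np.any(vals < 0):
        raise ValidationError(f"{path}: negative counts")
    missing_mr = [s for s in samples if s not in mapped_reads]
    if missing_mr:
        raise LabeledSampleError(f"samples without mapped-read totals: {missing_mr}")
    missing_grp = [s for s in samples if s not in groups]
    if missing_grp:
        raise LabeledSampleError(f"samples without group label: {missing_grp}")
    return CountsTable(
        gene_ids=list(df.index.astype(str)),
        sample_ids=samples,
        counts=vals.astype(np.int64),
        group_labels={s: groups[s] for s in samples},
        mapped_reads=np.asarray([mapped_reads[s] for s in samples], dtype=np.int64),
    )


def write_counts(ct: CountsTable, path: str | Path) -> None:
    df = pd.DataFrame(ct.counts, index=pd.Index(ct.gene_ids, name="gene_id"),
                      columns=ct.sample_ids)
    df.to_csv(path, sep="\t")
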