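"""Domain types and readers/writers for the formats the pipeline touches.

The pipeline consumes a multi-sample VCF with per-sample genotypes (GT) and
per-allele read depths (AD), a tab-delimited library-composition table, and
optional contig lengths (TSV or FASTA). All reports are tab-delimited with a
header row and a fixed column order.
"""
from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

FASTA_SUFFIXES = {".fa", ".fasta", ".fna", ".ffn"}

LIBRARY_COLUMNS = ["individual_id", "total_mapped", "rrna", "mito", "chloro", "te"]


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


@dataclass(frozen=True)
class Individual:
    """One sequenced individual of known sex.

    run_batch groups individuals by sequencing run; the synthetic generator
    uses it to vary rRNA content between runs, mirroring real batch effects.
    """

    id: str
    sex: Sex
    run_batch: str = "run1"


@dataclass(frozen=True)
class LibraryComposition:
    """Read-number breakdown of one individual's mapped library.

    The nuclear-mRNA component (total minus rRNA, mitochondrial, chloroplast
    and transposable-element reads) defines the normalized library size used
    for cross-individual expression comparison.
    """

    individual_id: str
    total_mapped: int
    rrna: int
    mito: int
    chloro: int
    te: int

    def __post_init__(self) -> None:
        counts = (self.total_mapped, self.rrna, self.mito, self.chloro, self.te)
        if any(c < 0 for c in counts):
            raise ValueError(f"negative read count in library composition for {self.individual_id}")
        if self.rrna + self.mito + self.chloro + self.te > self.total_mapped:
            raise ValueError(
                f"component reads exceed total mapped reads for {self.individual_id}"
            )

    @property
    def nuclear(self) -> int:
        return self.total_mapped - self.rrna - self.mito - self.chloro - self.te


@dataclass(frozen=True)
class SampleCall:
    """Genotype call plus ref/alt read depths for one individual at one site."""

    genotype: Genotype
    depth_ref: int
    depth_alt: int

    def __post_init__(self) -> None:
        if self.depth_ref < 0 or self.depth_alt < 0:
            raise ValueError("negative allele depth")

    @property
    def total_depth(self) -> int:
        return self.depth_ref + self.depth_alt


@dataclass
class SnpSite:
    """One biallelic SNV with calls for every individual in the dataset."""

    contig_id: str
    position: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    calls: dict[str, SampleCall]

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")


@dataclass(frozen=True)
class ContigInfo:
    contig_id: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"non-positive contig length for {self.contig_id}")
        if self.length_bp < 200:
            logger.warning(
                "contig %s is shorter than the 200 bp assembly floor (%d bp)",
                self.contig_id,
                self.length_bp,
            )


def read_individuals(path: str | Path) -> list[Individual]:
    """Read a sample sheet (individual_id, sex, run_batch) from TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual_id", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        batch = getattr(row, "run_batch", "run1") or "run1"
        out.append(Individual(id=row.individual_id, sex=Sex(row.sex), run_batch=batch))
    if len({ind.id for ind in out}) != len(out):
        raise ValueError("duplicate individual ids in sample sheet")
    return out


def read_library_composition(path: str | Path) -> list[LibraryComposition]:
    """Read the per-individual library-composition table (TSV).

    Raises on negative counts or component sums exceeding the total, which
    would make the normalized library size meaningless.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"library composition table missing columns: {sorted(missing)}")
    return [
        LibraryComposition(
            individual_id=str(row.individual_id),
            total_mapped=int(row.total_mapped),
            rrna=int(row.rrna),
            mito=int(row.mito),
            chloro=int(row.chloro),
            te=int(row.te),
        )
        for row in df.itertuples(index=False)
    ]


def read_contig_lengths(path: str | Path) -> list[ContigInfo]:
    """Contig lengths from a two-column TSV or from FASTA sequence lengths."""
    path = Path(path)
    if path.suffix.lower() in FASTA_SUFFIXES:
        from Bio import SeqIO

        return [
            ContigInfo(contig_id=rec.id, length_bp=len(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    df = pd.read_csv(path, sep="\t")
    if not {"contig_id", "length_bp"}.issubset(df.columns):
        raise ValueError("contig length table must have columns contig_id, length_bp")
    return [
        ContigInfo(contig_id=str(r.contig_id), length_bp=int(r.length_bp))
        for r in df.itertuples(index=False)
    ]


def _decode_genotype(alleles: tuple[int, int], alt_index: int) -> Genotype:
    """Map a VCF genotype (allele indices) onto hom/het for one ref/alt pair.

    Genotypes that involve a different alternate allele are treated as missing
    for this decomposed record.
    """
    a, b = alleles
    if a < 0 or b < 0:
        return Genotype.MISSING
    pair = {a, b}
    if pair == {0}:
        return Genotype.HOM_REF
    if pair == {alt_index}:
        return Genotype.HOM_ALT
    if pair == {0, alt_index}:
        return Genotype.HET
    return Genotype.MISSING


def read_snp_table(
    path: str | Path, individuals: list[Individual]
) -> Iterator[SnpSite]:
    """Stream biallelic SnpSite records from a VCF with GT and AD.

    Multi-allelic rows are decomposed into one record per alternate allele,
    dropping alternate alleles with zero read support across all samples.
    Indel rows are skipped: the segregation filter is defined on SNVs.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_index: dict[str, int] = {}
    for ind in individuals:
        if ind.id not in vcf.samples:
            raise ValueError(f"sample {ind.id!r} not found in VCF {path}")
        sample_index[ind.id] = vcf.samples.index(ind.id)

    n_skipped_indels = 0
    for variant in vcf:
        alts = variant.ALT
        if not alts:
            continue
        if len(variant.REF) != 1 or any(len(a) != 1 for a in alts):
            n_skipped_indels += 1
            continue
        try:
            ad = variant.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(f"VCF record {variant.CHROM}:{variant.POS} has no AD field")
        genotypes = variant.genotypes  # [a0, a1, phased] per sample
        for alt_index, alt in enumerate(alts, start=1):
            if len(alts) > 1:
                # drop decomposed alleles unsupported by any read
                if sum(max(int(ad[i][alt_index]), 0) for i in sample_index.values()) == 0:
                    logger.warning(
                        "dropping unsupported allele %s at %s:%d",
                        alt,
                        variant.CHROM,
                        variant.POS,
                    )
                    continue
            calls: dict[str, SampleCall] = {}
            for ind in individuals:
                i = sample_index[ind.id]
                g = genotypes[i]
                calls[ind.id] = SampleCall(
                    genotype=_decode_genotype((int(g[0]), int(g[1])), alt_index),
                    depth_ref=max(int(ad[i][0]), 0),
                    depth_alt=max(int(ad[i][alt_index]), 0),
                )
            yield SnpSite(
                contig_id=variant.CHROM,
                position=variant.POS,
                ref_allele=variant.REF,
                alt_allele=alt,
                calls=calls,
            )
    if n_skipped_indels:
        logger.warning("skipped %d non-SNV records", n_skipped_indels)


def write_report(records: Iterable, path: str | Path) -> None:
    """Write a list of dataclass records as a TSV with a stable column order.

    Columns follow the dataclass field order; an empty record list still
    produces a header-only file when a record type is known, otherwise an
    empty file.
    """
    records = list(records)
    if records:
        columns = [f.name for f in dataclasses.fields(records[0])]
        df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=columns)
    else:
        df = pd.DataFrame()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_frame(df: pd.DataFrame, path: str | Path) -> None:
    """TSV writer used for all tabular reports (bit-stable formatting)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
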