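"""Normalized allele-class expression from sex-linked SNP read counts.

Reads are counted at sex-linked SNP positions only, never over whole contigs,
so X-derived and Y-derived reads stay cleanly separated. For one contig,
individual and allele class the normalized expression is

    E = r / (n * l)

with r the summed read count of that allele class over the contig's
sex-linked SNPs, n the number of sex-linked SNPs and l the normalized library
size in millions of nuclear-mRNA mapped reads (total mapped minus rRNA,
mitochondrial, chloroplast and TE reads). A per-contig RPKM variant divides
by contig length instead of SNP count:

    RPKM = r / ((length_bp / 1000) * l)
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ContigInfo, Individual, LibraryComposition, Sex
from .sexlink_detection import SexLinkedCall

ALLELE_CLASSES = ("X_male", "Y_male", "X_female_both")


@dataclass(frozen=True)
class NormalizedLibrarySize:
    individual_id: str
    l: float  # millions of nuclear-mRNA mapped reads

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError(f"non-positive normalized library size for {self.individual_id}")


@dataclass(frozen=True)
class AlleleExpression:
    contig_id: str
    individual_id: str
    allele_class: str
    r: int
    n: int
    E: float
    rpkm: float | None = None


def normalized_library_size(comp: LibraryComposition) -> NormalizedLibrarySize:
    """l = (total mapped - rRNA - mito - chloro - TE) / 1e6.

    Subtracting the non-nuclear-mRNA categories removes the between-sex and
    between-run differences in organellar, TE and rRNA content before any
    cross-individual expression comparison.
    """
    corrected = comp.nuclear
    if corrected <= 0:
        raise ValueError(f"corrected library size is non-positive for {comp.individual_id}")
    return NormalizedLibrarySize(individual_id=comp.individual_id, l=corrected / 1e6)


def contig_rpkm(r: int, length_bp: int, total_mapped: int | float) -> float:
    """Reads per kilobase of contig per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("contig length must be positive")
    if total_mapped <= 0:
        raise ValueError("library size must be positive")
    return r / ((length_bp / 1000.0) * (total_mapped / 1e6))


def allele_expression(
    calls: list[SexLinkedCall],
    individual: Individual,
    allele_class: str,
    l: float,
    length_bp: int | None = None,
) -> AlleleExpression:
    """E (and optionally RPKM) for one allele class of one contig/individual.

    ``allele_class`` must match the individual's sex: X_male / Y_male for
    males, X_female_both (both X copies) for females.
    """
    if not calls:
        raise ValueError("contig has no sex-linked SNPs")
    n = len(calls)
    contig_id = calls[0].site.contig_id
    if allele_class == "X_male":
        depths = [c.x_depths for c in calls]
    elif allele_class == "Y_male":
        depths = [c.y_depths for c in calls]
    elif allele_class == "X_female_both":
        depths = [c.female_x_totals for c in calls]
    else:
        raise ValueError(f"unknown allele class {allele_class!r}")
    try:
        r = int(sum(d[individual.id] for d in depths))
    except KeyError:
        raise ValueError(f"individual {individual.id!r} absent from call set") from None
    rpkm = contig_rpkm(r, length_bp, l * 1e6) if length_bp else None
    return AlleleExpression(
        contig_id=contig_id,
        individual_id=individual.id,
        allele_class=allele_class,
        r=r,
        n=n,
        E=r / (n * l),
        rpkm=rpkm,
    )


def expression_table(
    calls_by_contig: dict[str, list[SexLinkedCall]],
    individuals: list[Individual],
    lib_sizes: dict[str, NormalizedLibrarySize],
    contig_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Long-format expression matrix: contig x individual x allele class."""
    rows = []
    for contig_id, calls in calls_by_contig.items():
        length = contig_lengths.get(contig_id) if contig_lengths else None
        for ind in individuals:
            classes = ("X_male", "Y_male") if ind.sex is Sex.MALE else ("X_female_both",)
            for cls in classes:
                expr = allele_expression(calls, ind, cls, lib_sizes[ind.id].l, length)
                rows.append(
                    {
                        "contig_id": contig_id,
                        "individual_id": ind.id,
                        "sex": ind.sex.value,
                        "allele_class": cls,
                        "r": expr.r,
                        "n": expr.n,
                        "E": expr.E,
                        "rpkm": np.nan if expr.rpkm is None else expr.rpkm,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "individual_id",
            "sex",
            "allele_class",
            "r",
            "n",
            "E",
            "rpkm",
        ],
    )


def per_sex_summary(
    expr: pd.DataFrame, stat: str = "mean", value: str = "E"
) -> pd.DataFrame:
    """Summarize each allele class across same-sex individuals per contig.

    Aggregation happens before any ratio is formed (ratio-of-summaries, not
    summary-of-ratios). ``stat`` is mean or median.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    if expr.empty:
        raise ValueError("empty expression table")
    out = (
        expr.groupby(["contig_id", "allele_class"], sort=True)[value]
        .agg(stat)
        .rename("summary")
        .reset_index()
    )
    return out
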