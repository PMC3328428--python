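"""Sex-linked SNP detection by family segregation.

In an XY family every male carries one X and one Y allele at a gametolog SNP,
so the diagnostic pattern is: all males heterozygous, all females homozygous
for the same (X) allele. Female genotypes are taken from the upstream caller's
GT field as-is; male genotypes are re-inferred from allele read depths,
because a diploid caller assumes balanced allelic expression and misses
heterozygotes whose Y allele is weakly expressed. The default male rule is
maximally permissive (any read support on both alleles), with a binomial-test
alternative that rejects homozygosity when the minor-allele depth is
improbable under the base-call error rate.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from scipy import stats

from .data_model import Genotype, Individual, SampleCall, Sex, SnpSite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds for male re-genotyping and female checking.

    Defaults keep both thresholds at their most permissive values so that
    weakly expressed Y alleles, supported by a single read, still yield a male
    heterozygote — raising ``min_y_reads`` strictly shrinks the detected set.
    """

    min_y_reads: int = 1
    min_minor_fraction: float = 0.0
    min_depth: int = 1
    male_caller: str = "support"  # support | binomial
    error_rate: float = 0.005  # used by the binomial caller
    alpha: float = 0.05
    strict_females: bool = False
    female_max_minor_fraction: float = 0.05


@dataclass
class SexLinkedCall:
    """A SNP classified sex-linked, with X/Y allele assignment and depths."""

    site: SnpSite
    x_allele: str
    y_allele: str
    x_depths: dict[str, int]  # per male
    y_depths: dict[str, int]  # per male
    female_x_totals: dict[str, int]  # per female, both X copies


@dataclass
class ContigClassification:
    contig_id: str
    n_sexlinked_snps: int
    is_sex_linked: bool
    passes_strict: bool
    x_polymorphic: bool


def infer_male_genotype(call: SampleCall, params: DetectionParams = DetectionParams()) -> Genotype:
    """Re-genotype a male from its ref/alt read depths.

    support rule: heterozygous iff both alleles have >= min_y_reads supporting
    reads and the minor-allele fraction is >= min_minor_fraction; equal depths
    still count as heterozygous (the rule is support-based, not ratio-based).
    binomial rule: heterozygous iff the minor-allele depth is significantly
    higher than expected from base-call error alone.
    """
    total = call.total_depth
    if total < params.min_depth:
        return Genotype.MISSING
    minor = min(call.depth_ref, call.depth_alt)
    if params.male_caller == "support":
        het = (
            min(call.depth_ref, call.depth_alt) >= params.min_y_reads
            and call.depth_alt >= params.min_y_reads
            and call.depth_ref >= params.min_y_reads
            and (total == 0 or minor / total >= params.min_minor_fraction)
        )
    elif params.male_caller == "binomial":
        # P(minor reads >= observed | homozygous, error rate e) < alpha
        het = minor >= 1 and stats.binom.sf(minor - 1, total, params.error_rate) < params.alpha
    else:
        raise ValueError(f"unknown male_caller {params.male_caller!r}")
    if het:
        return Genotype.HET
    return Genotype.HOM_REF if call.depth_ref >= call.depth_alt else Genotype.HOM_ALT


def _female_genotype(call: SampleCall, params: DetectionParams) -> Genotype:
    """Female genotype: the upstream GT verbatim, optionally depth-checked."""
    gt = call.genotype
    if params.strict_females and gt in (Genotype.HOM_REF, Genotype.HOM_ALT):
        total = call.total_depth
        minor = min(call.depth_ref, call.depth_alt)
        if total == 0 or minor / total > params.female_max_minor_fraction:
            return Genotype.MISSING
    return gt


def classify_site(
    site: SnpSite,
    individuals: list[Individual],
    params: DetectionParams = DetectionParams(),
) -> SexLinkedCall | None:
    """Apply the segregation filter to one site.

    Returns a SexLinkedCall when every male is heterozygous (re-inferred from
    depths) and every female is homozygous for the same allele; None
    otherwise. Any individual with a missing call disqualifies the site.
    """
    males = [ind for ind in individuals if ind.sex is Sex.MALE]
    females = [ind for ind in individuals if ind.sex is Sex.FEMALE]
    if not males or not females:
        raise ValueError("classification requires at least one individual of each sex")

    female_gts = []
    for ind in females:
        call = site.calls.get(ind.id)
        if call is None:
            return None
        gt = _female_genotype(call, params)
        if gt in (Genotype.MISSING,):
            return None
        female_gts.append(gt)
    if any(gt is Genotype.HET for gt in female_gts):
        return None
    if len(set(female_gts)) != 1:
        return None  # homozygous, but not all for the same allele

    for ind in males:
        call = site.calls.get(ind.id)
        if call is None:
            return None
        gt = infer_male_genotype(call, params)
        if gt is Genotype.MISSING:
            return None
        if gt is not Genotype.HET:
            return None

    x_is_ref = female_gts[0] is Genotype.HOM_REF
    x_allele = site.ref_allele if x_is_ref else site.alt_allele
    y_allele = site.alt_allele if x_is_ref else site.ref_allele
    x_depths: dict[str, int] = {}
    y_depths: dict[str, int] = {}
    female_x_totals: dict[str, int] = {}
    for ind in males:
        call = site.calls[ind.id]
        x_depths[ind.id] = call.depth_ref if x_is_ref else call.depth_alt
        y_depths[ind.id] = call.depth_alt if x_is_ref else call.depth_ref
    for ind in females:
        call = site.calls[ind.id]
        female_x_totals[ind.id] = call.depth_ref if x_is_ref else call.depth_alt
    return SexLinkedCall(
        site=site,
        x_allele=x_allele,
        y_allele=y_allele,
        x_depths=x_depths,
        y_depths=y_depths,
        female_x_totals=female_x_totals,
    )


def detect_x_polymorphism(
    sites: Iterable[SnpSite], individuals: list[Individual]
) -> bool:
    """X-chromosome polymorphism on a sex-linked contig.

    True iff any remaining (non-sex-linked) site shows: at least one
    individual heterozygous, or all individuals homozygous but not all for the
    same allele. Uses the upstream GT calls for every individual; sites with
    any missing call are skipped.
    """
    for site in sites:
        gts = []
        missing = False
        for ind in individuals:
            call = site.calls.get(ind.id)
            if call is None or call.genotype is Genotype.MISSING:
                missing = True
                break
            gts.append(call.genotype)
        if missing:
            continue
        if any(g is Genotype.HET for g in gts):
            return True
        if len({g for g in gts}) > 1:
            return True  # all homozygous but for different alleles
    return False


def classify_contig(
    contig_id: str,
    site_results: list[SexLinkedCall | None],
    x_polymorphic: bool = False,
) -> ContigClassification:
    """Aggregate per-site calls: sex-linked with >= 1 diagnostic SNP, strict
    with >= 2 (the threshold at which false contigs become vanishingly rare)."""
    n = sum(1 for r in site_results if r is not None)
    return ContigClassification(
        contig_id=contig_id,
        n_sexlinked_snps=n,
        is_sex_linked=n >= 1,
        passes_strict=n >= 2,
        x_polymorphic=x_polymorphic,
    )


@dataclass
class DetectionResult:
    classifications: list[ContigClassification]
    calls_by_contig: dict[str, list[SexLinkedCall]]

    @property
    def sex_linked_contigs(self) -> list[str]:
        return [c.contig_id for c in self.classifications if c.is_sex_linked]


def detect_sex_linked(
    sites: Iterable[SnpSite],
    individuals: list[Individual],
    params: DetectionParams = DetectionParams(),
) -> DetectionResult:
    """Run the segregation filter over a site stream grouped by contig."""
    classifications: list[ContigClassification] = []
    calls_by_contig: dict[str, list[SexLinkedCall]] = {}
    for contig_id, contig_sites in itertools.groupby(sites, key=lambda s: s.contig_id):
        contig_sites = list(contig_sites)
        results = [classify_site(s, individuals, params) for s in contig_sites]
        calls = [r for r in results if r is not None]
        x_poly = False
        if calls:
            remaining = [s for s, r in zip(contig_sites, results) if r is None]
            x_poly = detect_x_polymorphism(remaining, individuals)
            calls_by_contig[contig_id] = calls
        classifications.append(classify_contig(contig_id, results, x_poly))
    return DetectionResult(classifications=classifications, calls_by_contig=calls_by_contig)


def detect_from_vcf(
    vcf_path: str | Path,
    individuals: list[Individual],
    params: DetectionParams = DetectionParams(),
) -> DetectionResult:
    from .data_model import read_snp_table

    return detect_sex_linked(read_snp_table(vcf_path, individuals), individuals, params)
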