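"""Synthetic RNA-seq genotype datasets with full ground truth.

Emulates the data structure of an allele-specific expression experiment on an
inbred XY family: a handful of males and females from a sib-mated line,
transcriptome contigs that either carry an X/Y gametolog pair (with per-contig
Y-expression degeneration and optional X dosage compensation) or are autosomal
with residual heterozygosity, negative-binomially overdispersed site depths,
and base-call error. The generator emits the same VCF/TSV dialects the
pipeline reads, plus a truth table labelling every contig and SNP, so each
downstream stage can be tested against known ground truth.

Expression model for a sex-linked site with per-allele baseline b (half the
configured mean site depth):

* female (XX): homozygous for the X allele, total depth ~ NB(2b)
* male X:      depth ~ NB(cx * b) where cx depends on the compensation mode
* male Y:      depth ~ NB(d * cx * b), d the per-contig degeneration factor

Compensation modes set cx as: ``none`` -> 1 (no compensation, expected
Xmale/2Xfemale = 0.5); ``proportional`` -> 2/(1+d) (total male output equals
total female output exactly); ``full`` -> 2 (the single male X is upregulated
to the output of both female copies, expected Xmale/2Xfemale = 1). Because Y
scales with the compensated X, the male Y/X depth ratio estimates d under
every mode.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Individual, LibraryComposition, Sex

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class DistSpec:
    """Flat description of a 1-d sampler: (kind, a, b).

    kinds: ``constant`` (value a), ``uniform`` (low a, high b, half-open),
    ``lognormal`` (median a, sigma b of log). Used for the per-contig
    degeneration factor d; support must be positive.
    """

    kind: str = "constant"
    a: float = 1.0
    b: float = 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(size, float(self.a))
        if self.kind == "uniform":
            return rng.uniform(self.a, self.b, size=size)
        if self.kind == "lognormal":
            return self.a * np.exp(rng.normal(0.0, self.b, size=size))
        raise ValueError(f"unknown distribution kind {self.kind!r}")


@dataclass
class SimulationConfig:
    """All knobs of the generator; ``seed`` fixes the full output stream.

    ``depth_mean`` is the expected total read depth at a site in an individual
    expressing two allele copies at baseline (an XX female); the per-allele
    baseline is depth_mean/2. ``depth_dispersion`` is the negative-binomial
    size parameter (variance = m + m^2/dispersion).
    """

    n_males: int = 3
    n_females: int = 3
    n_sexlinked_contigs: int = 500
    n_autosomal_contigs: int = 500
    snps_per_contig_mean: float = 3.0  # Poisson, clipped to >= 1
    contig_length_median: int = 800
    contig_length_sigma: float = 0.5  # lognormal sigma; floored at 200 bp
    depth_mean: float = 50.0
    depth_dispersion: float = 10.0
    degeneration_d: DistSpec = field(default_factory=lambda: DistSpec("lognormal", 0.77, 0.5))
    compensation_mode: str = "none"  # none | proportional | full
    residual_heterozygosity_h: float = 0.05
    base_error_rate_e: float = 0.001
    x_polymorphism_rate: float = 0.1
    # library composition
    base_nuclear_reads: int = 10_000_000
    lib_size_sigma: float = 0.15
    rrna_frac_run1: float = 0.12
    rrna_frac_run2: float = 0.05
    mito_frac_male: float = 0.02
    mito_frac_female: float = 0.03
    chloro_frac_male: float = 0.02
    chloro_frac_female: float = 0.05
    te_frac_male: float = 0.04
    te_frac_female: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "residual_heterozygosity_h",
            "base_error_rate_e",
            "x_polymorphism_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.compensation_mode not in ("none", "proportional", "full"):
            raise ValueError(f"unknown compensation_mode {self.compensation_mode!r}")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth model parameters must be positive")

    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, DistSpec):
                v = f"{v.kind},{v.a},{v.b}"
            lines.append(f"{f.name}={v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key == "degeneration_d":
                kind, a, b = raw.split(",")
                kwargs[key] = DistSpec(kind, float(a), float(b))
            elif key in ("compensation_mode",):
                kwargs[key] = raw
            elif types.get(key) == "int" or key in (
                "n_males",
                "n_females",
                "n_sexlinked_contigs",
                "n_autosomal_contigs",
                "contig_length_median",
                "base_nuclear_reads",
                "seed",
            ):
                kwargs[key] = int(raw)
            else:
                kwargs[key] = float(raw)
        return cls(**kwargs)


@dataclass
class SimulatedDataset:
    """File paths plus in-memory copies of everything a test needs."""

    vcf: Path
    samples: Path
    library: Path
    contig_lengths: Path
    truth_contigs_path: Path
    truth_snps_path: Path
    config_path: Path
    individuals: list[Individual]
    library_composition: list[LibraryComposition]
    truth_contigs: pd.DataFrame
    truth_snps: pd.DataFrame


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws with given mean vector and size `dispersion`."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def _apply_error(
    rng: np.random.Generator, d_ref: np.ndarray, d_alt: np.ndarray, e: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mis-assign each read to the other allele with probability e."""
    if e <= 0:
        return d_ref, d_alt
    flip_r = rng.binomial(d_ref, e)
    flip_a = rng.binomial(d_alt, e)
    return d_ref - flip_r + flip_a, d_alt - flip_a + flip_r


def _naive_gt(d_ref: np.ndarray, d_alt: np.ndarray) -> np.ndarray:
    """Emulate an upstream diploid genotype caller from allele depths.

    Heterozygous when the minor allele has >= 2 reads and >= 10% of the depth;
    homozygous for the majority allele otherwise; missing at zero depth.
    Returns codes 0=0/0, 1=0/1, 2=1/1, 3=./.
    """
    total = d_ref + d_alt
    minor = np.minimum(d_ref, d_alt)
    gt = np.where(d_ref >= d_alt, 0, 2)
    het = (minor >= 2) & (minor >= 0.1 * total)
    gt = np.where(het, 1, gt)
    return np.where(total == 0, 3, gt)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", 3: "./."}
_GT_TRUTH = {0: "hom_ref", 1: "het", 2: "hom_alt", 3: "missing"}


def _make_individuals(config: SimulationConfig) -> list[Individual]:
    inds = []
    for i in range(config.n_males):
        inds.append(Individual(f"M{i + 1:02d}", Sex.MALE, f"run{i % 2 + 1}"))
    for i in range(config.n_females):
        inds.append(Individual(f"F{i + 1:02d}", Sex.FEMALE, f"run{i % 2 + 1}"))
    return inds


def _library_composition(
    config: SimulationConfig,
    individuals: list[Individual],
    scale: np.ndarray,
) -> list[LibraryComposition]:
    comps = []
    for ind, s in zip(individuals, scale):
        nuclear = int(round(config.base_nuclear_reads * s))
        if ind.sex is Sex.MALE:
            fracs = (config.mito_frac_male, config.chloro_frac_male, config.te_frac_male)
        else:
            fracs = (config.mito_frac_female, config.chloro_frac_female, config.te_frac_female)
        rrna_frac = config.rrna_frac_run1 if ind.run_batch == "run1" else config.rrna_frac_run2
        denom = 1.0 - rrna_frac - sum(fracs)
        provisional_total = nuclear / denom
        rrna = int(round(rrna_frac * provisional_total))
        mito = int(round(fracs[0] * provisional_total))
        chloro = int(round(fracs[1] * provisional_total))
        te = int(round(fracs[2] * provisional_total))
        comps.append(
            LibraryComposition(
                individual_id=ind.id,
                total_mapped=nuclear + rrna + mito + chloro + te,
                rrna=rrna,
                mito=mito,
                chloro=chloro,
                te=te,
            )
        )
    return comps


def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> SimulatedDataset:
    """Generate a full dataset (VCF + tables + truth) under `config`.

    Deterministic: identical config (including seed) produces byte-identical
    files. See the module docstring for the expression model.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    individuals = _make_individuals(config)
    n_ind = len(individuals)
    male_idx = [i for i, ind in enumerate(individuals) if ind.sex is Sex.MALE]
    female_idx = [i for i, ind in enumerate(individuals) if ind.sex is Sex.FEMALE]
    b = config.depth_mean / 2.0
    disp = config.depth_dispersion
    e = config.base_error_rate_e

    # --- contigs ---------------------------------------------------------
    n_sl = config.n_sexlinked_contigs
    n_au = config.n_autosomal_contigs
    n_contigs = n_sl + n_au
    contig_ids = [f"sl{i + 1:05d}" for i in range(n_sl)] + [
        f"au{i + 1:05d}" for i in range(n_au)
    ]
    lengths = np.maximum(
        200,
        np.round(
            config.contig_length_median
            * np.exp(rng.normal(0.0, config.contig_length_sigma, size=n_contigs))
        ).astype(int),
    )
    n_snps = np.maximum(1, rng.poisson(config.snps_per_contig_mean, size=n_contigs))
    d = np.zeros(n_contigs)
    d[:n_sl] = config.degeneration_d.sample(rng, n_sl)
    if np.any(d[:n_sl] <= 0):
        raise ValueError("degeneration_d sampler produced non-positive values")
    if config.compensation_mode == "none":
        cx = np.ones(n_contigs)
    elif config.compensation_mode == "full":
        cx = np.full(n_contigs, 2.0)
    else:  # proportional: male total output = cx*(1+d) = 2
        cx = np.where(d > 0, 2.0 / (1.0 + d), 1.0)
    has_xpoly = np.zeros(n_contigs, dtype=bool)
    has_xpoly[:n_sl] = rng.random(n_sl) < config.x_polymorphism_rate

    # per-individual sequencing scale; the normalized library size is
    # proportional to it, so E = r/(n*l) cancels it exactly in expectation
    scale = np.exp(rng.normal(0.0, config.lib_size_sigma, size=n_ind))
    comps = _library_composition(config, individuals, scale)
    l_eff = np.array([c.nuclear / config.base_nuclear_reads for c in comps])
    # depths track the realized nuclear library size, not the latent scale
    depth_scale = l_eff

    # --- site layout -----------------------------------------------------
    site_contig: list[int] = []
    site_pos: list[np.ndarray] = []
    site_kind: list[np.ndarray] = []  # 0 sex-linked, 1 x-poly extra, 2 autosomal
    for c in range(n_contigs):
        k = int(n_snps[c])
        extra = 1 if has_xpoly[c] else 0
        total_sites = k + extra
        pos = np.sort(rng.choice(lengths[c], size=min(total_sites, lengths[c]), replace=False)) + 1
        kinds = np.full(pos.size, 2 if c >= n_sl else 0)
        if c < n_sl and extra and pos.size == total_sites:
            kinds[rng.integers(pos.size)] = 1
        site_contig.extend([c] * pos.size)
        site_pos.append(pos)
        site_kind.append(kinds)
    contig_of_site = np.array(site_contig)
    pos_of_site = np.concatenate(site_pos) if site_pos else np.array([], dtype=int)
    kind_of_site = np.concatenate(site_kind) if site_kind else np.array([], dtype=int)
    n_sites = pos_of_site.size

    ref_base_i = rng.integers(0, 4, size=n_sites)
    alt_base_i = (ref_base_i + rng.integers(1, 4, size=n_sites)) % 4
    x_is_ref = rng.random(n_sites) < 0.5  # sex-linked sites: which allele is X

    is_sl_site = kind_of_site == 0
    is_xp_site = kind_of_site == 1
    is_au_site = kind_of_site == 2
    d_site = d[contig_of_site]
    cx_site = cx[contig_of_site]

    # x-poly extra sites: one carrier female heterozygous, everyone else hom
    carrier = np.full(n_sites, -1)
    if np.any(is_xp_site) and female_idx:
        carrier[is_xp_site] = rng.choice(female_idx, size=int(is_xp_site.sum()))

    # autosomal genotypes: per individual, het w.p. h, else hom ref/alt at 1/2
    h = config.residual_heterozygosity_h
    au_gt = np.full((n_sites, n_ind), -1, dtype=np.int8)  # 0 hom_ref 1 het 2 hom_alt
    if np.any(is_au_site):
        u = rng.random((int(is_au_site.sum()), n_ind))
        hom_alt = rng.random((int(is_au_site.sum()), n_ind)) < 0.5
        g = np.where(u < h, 1, np.where(hom_alt, 2, 0)).astype(np.int8)
        au_gt[is_au_site] = g

    # --- depths ----------------------------------------------------------
    depth_ref = np.zeros((n_sites, n_ind), dtype=np.int64)
    depth_alt = np.zeros((n_sites, n_ind), dtype=np.int64)
    truth_gt = np.full((n_sites, n_ind), 0, dtype=np.int8)

    for i, ind in enumerate(individuals):
        s = depth_scale[i]
        d_x = np.zeros(n_sites, dtype=np.int64)  # depth on the X (female) allele
        d_y = np.zeros(n_sites, dtype=np.int64)
        if ind.sex is Sex.MALE:
            d_x[is_sl_site] = _nb(rng, cx_site[is_sl_site] * b * s, disp)
            d_y[is_sl_site] = _nb(rng, d_site[is_sl_site] * cx_site[is_sl_site] * b * s, disp)
            truth_gt[is_sl_site, i] = 1  # het X/Y
            # at X-polymorphism sites males carry a single X, hom for the major allele
            d_x[is_xp_site] = _nb(
                rng, np.full(int(is_xp_site.sum()), 2 * b * s), disp
            )
        else:
            d_x[is_sl_site] = _nb(rng, np.full(int(is_sl_site.sum()), 2 * b * s), disp)
            is_carrier = is_xp_site & (carrier == i)
            plain = is_xp_site & ~is_carrier
            d_x[plain] = _nb(rng, np.full(int(plain.sum()), 2 * b * s), disp)
            d_x[is_carrier] = _nb(rng, np.full(int(is_carrier.sum()), b * s), disp)
            d_y[is_carrier] = _nb(rng, np.full(int(is_carrier.sum()), b * s), disp)
            truth_gt[is_carrier, i] = 1
        # autosomal
        if np.any(is_au_site):
            g = au_gt[:, i]
            het = is_au_site & (g == 1)
            hom_r = is_au_site & (g == 0)
            hom_a = is_au_site & (g == 2)
            d_x[het] = _nb(rng, np.full(int(het.sum()), b * s), disp)
            d_y[het] = _nb(rng, np.full(int(het.sum()), b * s), disp)
            d_x[hom_r] = _nb(rng, np.full(int(hom_r.sum()), 2 * b * s), disp)
            d_y[hom_a] = _nb(rng, np.full(int(hom_a.sum()), 2 * b * s), disp)
            truth_gt[is_au_site, i] = g[is_au_site]

        # map allele-space (X/Y for sex-linked, ref/alt for autosomal) to ref/alt
        to_ref = np.where(is_au_site, True, x_is_ref)  # d_x lands on ref where True
        dr = np.where(to_ref, d_x, d_y)
        da = np.where(to_ref, d_y, d_x)
        dr, da = _apply_error(rng, dr, da, e)
        depth_ref[:, i] = dr
        depth_alt[:, i] = da

    # flip truth genotype codes where the X allele is the alt allele
    flip = ~is_au_site & ~x_is_ref
    # sex-linked truth: female hom-X, male het; autosomal codes are ref/alt already
    for i, ind in enumerate(individuals):
        col = truth_gt[:, i].astype(int)
        sl_mask = ~is_au_site
        if ind.sex is Sex.FEMALE:
            # hom for X allele unless carrier-het
            hom_code = np.where(flip, 2, 0)
            col[sl_mask] = np.where(truth_gt[sl_mask, i] == 1, 1, hom_code[sl_mask])
        else:
            hom_code = np.where(flip, 2, 0)
            col[is_xp_site] = hom_code[is_xp_site]  # males hom for major X allele
            col[is_sl_site] = 1
        truth_gt[:, i] = col

    called_gt = _naive_gt(depth_ref, depth_alt)

    # --- write VCF -------------------------------------------------------
    vcf_path = outdir / "dataset.vcf"
    sample_ids = [ind.id for ind in individuals]
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=xydosage-simulate\n")
        for c in range(n_contigs):
            fh.write(f"##contig=<ID={contig_ids[c]},length={lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(sample_ids) + "\n")
        for sidx in range(n_sites):
            c = contig_of_site[sidx]
            cols = [
                contig_ids[c],
                str(pos_of_site[sidx]),
                ".",
                _BASES[ref_base_i[sidx]],
                _BASES[alt_base_i[sidx]],
                ".",
                ".",
                ".",
                "GT:AD:DP",
            ]
            for i in range(n_ind):
                dr = depth_ref[sidx, i]
                da = depth_alt[sidx, i]
                cols.append(f"{_GT_STR[int(called_gt[sidx, i])]}:{dr},{da}:{dr + da}")
            fh.write("\t".join(cols) + "\n")

    # --- companion tables ------------------------------------------------
    samples_path = outdir / "samples.tsv"
    pd.DataFrame(
        {
            "individual_id": sample_ids,
            "sex": [ind.sex.value for ind in individuals],
            "run_batch": [ind.run_batch for ind in individuals],
        }
    ).to_csv(samples_path, sep="\t", index=False)

    library_path = outdir / "library_composition.tsv"
    pd.DataFrame(
        [
            {
                "individual_id": c.individual_id,
                "total_mapped": c.total_mapped,
                "rrna": c.rrna,
                "mito": c.mito,
                "chloro": c.chloro,
                "te": c.te,
            }
            for c in comps
        ]
    ).to_csv(library_path, sep="\t", index=False)

    lengths_path = outdir / "contig_lengths.tsv"
    pd.DataFrame({"contig_id": contig_ids, "length_bp": lengths}).to_csv(
        lengths_path, sep="\t", index=False
    )

    truth_contigs = pd.DataFrame(
        {
            "contig_id": contig_ids,
            "contig_class": ["sex_linked"] * n_sl + ["autosomal"] * n_au,
            "length_bp": lengths,
            "n_snps": n_snps,
            "true_d": np.where(np.arange(n_contigs) < n_sl, d, np.nan),
            "true_cx": np.where(np.arange(n_contigs) < n_sl, cx, np.nan),
            "compensation_mode": config.compensation_mode,
            "x_polymorphic_truth": has_xpoly,
        }
    )
    truth_contigs_path = outdir / "truth_contigs.tsv"
    truth_contigs.to_csv(truth_contigs_path, sep="\t", index=False, float_format="%.10g")

    kind_names = np.array(["sex_linked", "x_polymorphism", "autosomal"])
    truth_snps = pd.DataFrame(
        {
            "contig_id": [contig_ids[c] for c in contig_of_site],
            "position": pos_of_site,
            "ref_allele": _BASES[ref_base_i],
            "alt_allele": _BASES[alt_base_i],
            "site_class": kind_names[kind_of_site],
            "x_allele": np.where(
                kind_of_site == 0,
                np.where(x_is_ref, _BASES[ref_base_i], _BASES[alt_base_i]),
                "NA",
            ),
            "y_allele": np.where(
                kind_of_site == 0,
                np.where(x_is_ref, _BASES[alt_base_i], _BASES[ref_base_i]),
                "NA",
            ),
        }
    )
    for i, ind in enumerate(individuals):
        truth_snps[f"gt_{ind.id}"] = [
            _GT_TRUTH[int(g)] for g in np.where(truth_gt[:, i] < 0, 3, truth_gt[:, i])
        ]
    truth_snps_path = outdir / "truth_snps.tsv"
    truth_snps.to_csv(truth_snps_path, sep="\t", index=False)

    config_path = outdir / "sim_config.txt"
    config.to_file(config_path)

    return SimulatedDataset(
        vcf=vcf_path,
        samples=samples_path,
        library=library_path,
        contig_lengths=lengths_path,
        truth_contigs_path=truth_contigs_path,
        truth_snps_path=truth_snps_path,
        config_path=config_path,
        individuals=individuals,
        library_composition=comps,
        truth_contigs=truth_contigs,
        truth_snps=truth_snps,
    )


def simulate_autosomal_null(config: SimulationConfig, outdir: str | Path) -> SimulatedDataset:
    """Autosomal-only dataset: every contig is a true negative for sex linkage."""
    null_config = dataclasses.replace(config, n_sexlinked_contigs=0)
    return simulate_dataset(null_config, outdir)
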