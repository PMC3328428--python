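import numpy as np
import pytest

from xydosage.data_model import Genotype, Individual, SampleCall, Sex, SnpSite

# depths used to realize a genotype as error-free read counts
GT_DEPTHS = {"AA": (30, 0), "AB": (18, 12), "BB": (0, 30)}
GT_CALL = {"AA": Genotype.HOM_REF, "AB": Genotype.HET, "BB": Genotype.HOM_ALT}


def make_individuals(n_males: int = 3, n_females: int = 3) -> list[Individual]:
    males = [Individual(f"M{i+1:02d}", Sex.MALE) for i in range(n_males)]
    females = [Individual(f"F{i+1:02d}", Sex.FEMALE) for i in range(n_females)]
    return males + females


def make_site(
    genotypes: dict[str, str],
    contig_id: str = "contig1",
    position: int = 100,
    depths: dict[str, tuple[int, int]] | None = None,
) -> SnpSite:
    """Build a biallelic site from genotype strings (AA/AB/BB/missing)."""
    calls = {}
    for ind_id, gt in genotypes.items():
        if gt == "missing":
            calls[ind_id] = SampleCall(Genotype.MISSING, 0, 0)
            continue
        dr, da = (depths or {}).get(ind_id, GT_DEPTHS[gt])
        calls[ind_id] = SampleCall(GT_CALL[gt], dr, da)
    return SnpSite(
        contig_id=contig_id, position=position, ref_allele="A", alt_allele="G", calls=calls
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 50+50-contig simulated dataset shared across read-only tests."""
    from xydosage.synthetic_data import DistSpec, SimulationConfig, simulate_dataset

    config = SimulationConfig(
        n_sexlinked_contigs=50,
        n_autosomal_contigs=50,
        degeneration_d=DistSpec("lognormal", 0.77, 0.5),
        seed=123,
    )
    return simulate_dataset(config, tmp_path_factory.mktemp("small_ds"))
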