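import pytest

from kdrkit.datatypes import GenotypeCounts, PhenoGenoTable
from kdrkit.io import bundled_path, load_genotype_counts, load_pheno_geno_tables, load_two_locus_counts
from kdrkit.rflp import Amplicon, get_enzyme, load_enzymes
from kdrkit.simulate import make_amplicon_fixtures


@pytest.fixture(scope="session")
def table1():
    return load_genotype_counts(bundled_path("table1_genotype_counts.csv"))


@pytest.fixture(scope="session")
def table2():
    tables = load_pheno_geno_tables(bundled_path("table2_pheno_geno.csv"))
    return {pg.insecticide: pg for pg in tables}


@pytest.fixture(scope="session")
def table3():
    return load_two_locus_counts(bundled_path("table3_two_locus.csv"))


@pytest.fixture(scope="session")
def ddt_table(table2) -> PhenoGenoTable:
    return table2["DDT"]


@pytest.fixture(scope="session")
def amplicons():
    fx = make_amplicon_fixtures(seed=0)
    return {k: Amplicon(v, 1, len(v)) for k, v in fx.items()}


@pytest.fixture(scope="session")
def enzymes():
    return load_enzymes()


@pytest.fixture(scope="session")
def bsabi():
    return get_enzyme("BsaBI")


@pytest.fixture(scope="session")
def ssii():
    return get_enzyme("SsiI")


@pytest.fixture()
def sdii_counts() -> GenotypeCounts:
    """South Delhi II F1534 genotype counts — the one survey site in HWE."""
    return GenotypeCounts("F1534", 35, 128, 158, population="South Delhi II")
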