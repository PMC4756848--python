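import pytest

from mirimpact.fixtures import HairpinDesign, make_fixture
from mirimpact.fold import ViennaRNAFold
from mirimpact.mirna_db import Mature, MiRNAGene, RegionModel


@pytest.fixture(scope="session")
def vienna():
    return ViennaRNAFold()


@pytest.fixture(scope="session")
def mir125_like():
    """A gene shaped like hsa-mir-125a: 86 nt hairpin, two 22-24 nt matures.

    Gene-relative layout: mature5p [15,39), loop [41,52), mature3p [52,74).
    """
    base = 52196500
    gene = MiRNAGene(
        "hsa-mir-125a", "chr19", "+", base, base + 86,
        Mature("hsa-miR-125a-5p", base + 15, base + 39),
        Mature("hsa-miR-125a-3p", base + 52, base + 74),
        base + 41, base + 52,
    )
    return gene


@pytest.fixture(scope="session")
def mir125_model(mir125_like):
    model = RegionModel(mir125_like, 100, 100)
    model.validate_tiling()
    return model


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """Full synthetic fixture: 2 genes (one per strand), all variant classes."""
    out = tmp_path_factory.mktemp("fixture")
    paths, genome, db, variants, expected = make_fixture(out, seed=0)
    return {
        "paths": paths, "genome": genome, "db": db,
        "variants": variants, "expected": expected,
        "design": HairpinDesign(seed=0),
    }
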