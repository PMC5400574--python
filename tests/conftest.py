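import pytest

from snpmeta import load_fixture
from snpmeta.contingency import FourfoldTable, GeneticModel
from snpmeta.study_io import StudyRecord, StudyTable


@pytest.fixture(scope="session")
def fixture_table():
    """The packaged 16-cohort glaucoma rs1063192 genotype table."""
    return load_fixture()


@pytest.fixture
def toy_record():
    """A small balanced cohort: 10 of each genotype in each arm."""
    return StudyRecord(
        study_id="S1",
        year=2000,
        ethnicity="Asian",
        soc="PB",
        case_tt=10,
        case_tc=10,
        case_cc=10,
        ctrl_tt=10,
        ctrl_tc=10,
        ctrl_cc=10,
    )


@pytest.fixture
def toy_table(toy_record):
    return StudyTable((toy_record,), provenance="toy")


def make_fourfold(a, b, c, d, model=GeneticModel.ALLELE, **kwargs):
    return FourfoldTable(
        a=float(a), b=float(b), c=float(c), d=float(d), model=model, **kwargs
    )
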