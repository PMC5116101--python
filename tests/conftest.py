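import pytest

from snaq.composition import (
    default_composition,
    default_nrv,
    default_supplements,
    default_targets,
)


@pytest.fixture(scope="session")
def composition():
    return default_composition()


@pytest.fixture(scope="session")
def supplements():
    return default_supplements()


@pytest.fixture(scope="session")
def nrv():
    return default_nrv()


@pytest.fixture(scope="session")
def targets():
    return default_targets()


@pytest.fixture
def records_csv(tmp_path):
    """Two-participant, long-format records file with a supplement companion."""
    records = tmp_path / "records.csv"
    records.write_text(
        "participant_id,day,occasion,group,servings\n"
        "P1,1,breakfast,grains,2\n"
        "P1,1,lunch,vegetables,1.5\n"
        "P1,2,dinner,Fruit,1\n"
        "P1,3,dinner,meat,2\n"
        "P2,1,breakfast,dairy,1\n"
        "P2,2,snack,discretionary,3\n"
    )
    uses = tmp_path / "uses.csv"
    uses.write_text(
        "participant_id,day,product_id,doses\n"
        "P1,1,prenatal_multivitamin,1\n"
        "P1,2,prenatal_multivitamin,1\n"
        "P1,3,prenatal_multivitamin,1\n"
    )
    return records, uses
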