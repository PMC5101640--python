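import io

import pytest

from bruiseage.datamodel import (
    BruiseHistology,
    LeukocyteLocalization,
    PigRecord,
    write_bruise_table,
)


def make_bruise(pig_id="P1", bruise_label="a", **overrides):
    """A valid bruise record with overridable fields."""
    fields = dict(
        pig_id=pig_id,
        bruise_label=bruise_label,
        dermis_hemorrhage=True,
        dermis_hyperleukocytosis=False,
        dermis_leukocytes=True,
        subcutis_hemorrhage=True,
        subcutis_hyperleukocytosis=True,
        subcutis_neutrophils=2,
        subcutis_macrophages=1,
        muscle_hemorrhage=True,
        muscle_hyperleukocytosis=False,
        muscle_necrosis=1,
        muscle_neutrophils=1,
        muscle_macrophages=2,
        muscle_leukocyte_localization=LeukocyteLocalization.INTERSTITIAL,
        gross_pattern="tramline",
    )
    fields.update(overrides)
    return BruiseHistology(**fields)


@pytest.fixture
def bruise_factory():
    return make_bruise


@pytest.fixture
def two_bruise_pig():
    return PigRecord(
        pig_id="P1",
        bruises=[make_bruise(bruise_label="a"), make_bruise(bruise_label="b")],
    )


def records_to_csv_text(records) -> str:
    buf = io.StringIO()
    write_bruise_table(records, buf)
    return buf.getvalue()


@pytest.fixture
def csv_text():
    return records_to_csv_text
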