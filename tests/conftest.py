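import numpy as np
import pandas as pd
import pytest

from readzipf import EncounterCorpus, Section, SectionSpec, generate_terminology


def make_corpus(codes, practices=None, patients=None):
    """Build a corpus from bare code strings (valid by construction)."""
    n = len(codes)
    practices = practices or ["P001"] * n
    patients = patients or [f"S{i:06d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "patient_id": patients,
            "practice_id": practices,
            "date": pd.Timestamp("2005-06-01"),
            "code": list(codes),
        }
    )
    return EncounterCorpus(df)


@pytest.fixture(scope="session")
def diagnosis_terminology():
    """A mid-sized diagnosis terminology shared by the slower tests."""
    return generate_terminology(5, {Section.DIAGNOSIS: SectionSpec(8000, 5)})


@pytest.fixture(scope="session")
def medication_terminology():
    """Medication section with the depth-4 ceiling."""
    return generate_terminology(7, {Section.MEDICATION: SectionSpec(5500, 4)})


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
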