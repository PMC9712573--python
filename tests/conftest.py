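import pytest

from tikd.cohort import CohortConfig, generate_cohort
from tikd.filtering import IndividualRecord
from tikd.io import load_table1_fixture


@pytest.fixture(scope="session")
def table1():
    """The packaged diagnostic-variant table (36 variants, 34 individuals)."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic registry, seed 1."""
    return generate_cohort(CohortConfig(), seed=1)


@pytest.fixture()
def funnel_cohort():
    """Deterministic 303-member cohort with exactly 16 DNA-quality failures
    and 16 identity mismatches planted, reproducing a 303 -> 287 -> 271
    selection funnel."""
    records = []
    for i in range(303):
        dna_ok = i >= 16
        fingerprint = not (16 <= i < 24)  # 8 fingerprint mismatches
        sex = "male" if i % 2 == 0 else "female"
        inferred = sex
        if 24 <= i < 32:  # 8 inferred-sex mismatches
            inferred = "female" if sex == "male" else "male"
        records.append(
            IndividualRecord(
                id=f"F_{i:03d}",
                age=45.0,
                sex_declared=sex,
                sex_inferred=inferred,
                categories=("nephrosclerosis",),
                dna_quality_ok=dna_ok,
                fingerprint_match=fingerprint,
            )
        )
    return records
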