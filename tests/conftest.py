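import numpy as np
import pytest

from cdsite import (
    Cohort,
    SubjectRecord,
    load_packaged_panel,
    load_printed_table,
)


@pytest.fixture(scope="session")
def panel():
    return load_packaged_panel()


@pytest.fixture(scope="session")
def table1():
    return load_printed_table("table1")


@pytest.fixture(scope="session")
def table2():
    return load_printed_table("table2")


@pytest.fixture(scope="session")
def table3():
    return load_printed_table("table3")


def make_cohort(panel, dosage, groups_sites):
    """Cohort from a dosage matrix and (group, site) labels."""
    subjects = [
        SubjectRecord(f"S{i:04d}", group, site)
        for i, (group, site) in enumerate(groups_sites)
    ]
    return Cohort(subjects, panel, np.asarray(dosage, dtype=float))


@pytest.fixture()
def small_cohort(panel):
    """6 controls + 6 CD (2 per site), deterministic dosages."""
    rng = np.random.default_rng(7)
    labels = [("control", "none")] * 6 + [
        ("CD", "L1"), ("CD", "L1"), ("CD", "L2"), ("CD", "L2"), ("CD", "L3"), ("CD", "L3"),
    ]
    dosage = rng.integers(0, 3, size=(12, len(panel))).astype(float)
    return make_cohort(panel, dosage, labels)
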