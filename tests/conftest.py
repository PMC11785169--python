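import pytest

from ringstate import enumerate_classes, load_fixture


@pytest.fixture(scope="session")
def classes4():
    return enumerate_classes(4)


@pytest.fixture(scope="session")
def class_by_name(classes4):
    return {c.name: c for c in classes4}


@pytest.fixture(scope="session")
def fixture_spectra():
    return {
        key: load_fixture(key)
        for key in ("cim_18C", "apo_18C", "apo_37C", "primidone_18C")
    }
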