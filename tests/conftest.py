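import random

import pytest

from depot import Store
from depot.context import ContextTreeRule


@pytest.fixture
def store(tmp_path):
    s = Store(tmp_path / "proj")
    yield s
    s.close()


@pytest.fixture
def unit_factory(store, tmp_path):
    """Create (and optionally assign) a unit from an in-memory file dict."""
    counter = {"n": 0}

    def make(files: dict[str, bytes], attrs: dict | None = None):
        counter["n"] += 1
        scratch = tmp_path / f"incoming{counter['n']}"
        scratch.mkdir()
        paths, names = [], []
        for name, data in files.items():
            p = scratch / name.replace("/", "__")
            p.write_bytes(data)
            paths.append(p)
            names.append(name)
        unit = store.ingest_unit(paths, names=names)
        if attrs:
            store.assign_metadata(unit.unit_id, attrs)
        return unit

    return make


@pytest.fixture
def rng():
    return random.Random(20240612)


@pytest.fixture
def alpha_rule():
    """Morphology view: SWC files grouped state/region/animal/parameters."""
    return ContextTreeRule.make(
        "morphology", filter={"FORMAT": "SWC"},
        grouping=["LABOR_STATE", "REGION", "HONEYBEE_ID", "SIGEN_PARAMETERS"],
        leaf_template="morphology.swc")


@pytest.fixture
def beta_rule():
    """Imaging view: TIFF stacks grouped animal/region, leaves per member."""
    return ContextTreeRule.make(
        "imaging", filter={"FORMAT": "TIFF_STACK"},
        grouping=["HONEYBEE_ID", "REGION"],
        leaf_template="{MEMBER_NAME}")
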