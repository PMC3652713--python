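import json
from importlib import resources as importlib_resources

import pytest

from mcckit.registry import load_default_registry


@pytest.fixture(scope="session")
def registry():
    return load_default_registry()


@pytest.fixture(scope="session")
def raw_resource():
    """The packaged registry JSON as a plain dict (for independent oracles)."""
    ref = importlib_resources.files("mcckit.resources") / "oash20_registry.json"
    return json.loads(ref.read_bytes())


@pytest.fixture()
def registry_payload(raw_resource):
    """Deep copy of the resource for mutation in validation tests."""
    return json.loads(json.dumps(raw_resource))
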