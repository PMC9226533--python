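import pathlib

import pytest

from gsmkit.fixtures import load_manifest, make_toy_world


@pytest.fixture(scope="session")
def toy_world(tmp_path_factory) -> pathlib.Path:
    """One shared synthetic fixture world (seed 1, defaults)."""
    directory = tmp_path_factory.mktemp("world") / "w"
    make_toy_world(1, directory)
    return directory


@pytest.fixture(scope="session")
def manifest(toy_world) -> dict:
    return load_manifest(toy_world)
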