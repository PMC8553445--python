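import warnings

import pytest

from cimlc import BeamlineGeometry, load_material_table


@pytest.fixture(scope="session")
def geom():
    return BeamlineGeometry()


@pytest.fixture(scope="session")
def materials():
    return {m.name: m for m in load_material_table()}


@pytest.fixture(scope="session")
def tungsten(materials):
    return materials["W100"]


@pytest.fixture(autouse=True)
def _quiet_large_field_warning():
    # tables and examples routinely extrapolate past the 6 cm physical
    # half-field; the warning itself is tested explicitly once
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*exceeds the maximum physical half-field.*"
        )
        yield
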