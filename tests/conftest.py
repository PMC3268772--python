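import pytest

from labtrace import DemoSpec, generate_demo, init_schema
from labtrace.schema import add_code


@pytest.fixture()
def db(tmp_path):
    """Fresh empty schema."""
    handle = init_schema(tmp_path / "lims.db")
    yield handle
    handle.close()


@pytest.fixture()
def seeded(db):
    """Empty schema plus a minimal vocabulary for registry/workflow tests."""
    for cls, names in {
        "SPECIES": ["BOS", "OVIS"],
        "BREED": ["HOLSTEIN", "MERINO"],
        "SEX": ["F", "M"],
        "MATERIAL_TYPE": ["BLOOD", "TISSUE"],
        "VESSEL_TYPE": ["VIAL", "TUBE"],
        "PURPOSE": ["sequencing", "genotyping"],
        "PRIMER": ["DLOOP", "BM1824", "ETH10"],
        "MARKER_TYPE": ["SEQUENCE", "MICROSATELLITE"],
        "METHOD": ["CAPILLARY", "GEL"],
        "SOFTWARE": ["SEQANALYZER"],
        "PROTOCOL_TYPE": ["EXTRACTION"],
        "MIMETYPE": ["PNG"],
    }.items():
        for name in names:
            add_code(db, cls, name)
    return db


@pytest.fixture(scope="session")
def demo_db(tmp_path_factory):
    """Shared read-mostly demo dataset (seed 1, defaults)."""
    path = tmp_path_factory.mktemp("demo") / "demo.db"
    handle, manifest = generate_demo(DemoSpec(seed=1), path)
    handle.manifest = manifest
    yield handle
    handle.close()
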