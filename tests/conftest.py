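import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from polprofiler import fixtures as fx
from polprofiler.domain_model import load_domain_map
from polprofiler.structure_io import read_structure


@pytest.fixture
def roundtrip(tmp_path):
    """Write a fixture Structure as PDB and re-read it through the parser,
    so tests exercise the real I/O path."""
    def _roundtrip(structure, name="fixture"):
        path = tmp_path / f"{name}.pdb"
        fx.write_fixture(structure, {}, tmp_path, name)
        return read_structure(path)
    return _roundtrip


@pytest.fixture
def helix_domain_map():
    """Domain map for the rotation-pair pseudo-protein (mobile = 'finger',
    residues 31..60)."""
    body = {"finger": [["A", 31, 60]], "core": [["A", 1, 30]]}
    return load_domain_map({"domains": {
        "helix": body, "helix_closed": body}})


@pytest.fixture(scope="session")
def duplex_with_contacts():
    plan = [
        {"strand": "template", "position": -7, "atom": "OP1",
         "distance": 2.9, "role": "both"},
        {"strand": "template", "position": -3, "atom": "OP1",
         "distance": 3.5, "role": "both"},
        {"strand": "primer", "position": 0, "atom": "OP1",
         "distance": 2.9, "role": "donor"},
        {"strand": "template", "position": -2, "atom": "OP1",
         "distance": 2.9, "role": "both", "water_legs": (2.8, 2.9)},
    ]
    return fx.make_duplex_complex(contact_plan=plan)


DEPOSITED_DIR = Path(__file__).resolve().parent.parent / "data" / "pdb"


def deposited(entry: str) -> Path:
    """Path of a locally cached deposited entry; fails the calling test
    with instructions when the file is absent."""
    for suffix in (".cif", ".pdb"):
        path = DEPOSITED_DIR / f"{entry.lower()}{suffix}"
        if path.exists():
            return path
    pytest.fail(
        f"deposited entry {entry} not available at {DEPOSITED_DIR}; "
        f"run scripts/fetch_pdb.py on a machine with network access and "
        f"place the files there", pytrace=False)
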