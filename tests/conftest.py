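"""Shared fixtures: session-scoped synthetic corpora and helper builders."""
from __future__ import annotations

import numpy as np
import pytest

from bsite.structure_io import Atom, ChainRecord, Residue, parse_structure
from bsite.synthetic_fixtures import generate_corpus
from bsite.template_db import build_database, load_mapping

# one defect per entry, spread over two families; the clean entries make the
# families alignable while the defective ones exercise each filter stage
DEFECT_TABLE = {
    "S001": ["nmr"],
    "S002": ["high_resolution"],
    "S003": ["small_ligand"],
    "S101": ["unstable_ligand"],
    "S102": ["modres_mask"],
    "S103": ["short_chain"],
}


@pytest.fixture(scope="session")
def corpus(tmp_path_factory):
    """Clean 3-family x 4-member corpus with mapping and truth table."""
    out = tmp_path_factory.mktemp("corpus")
    truth = generate_corpus(3, 4, seed=7, out_dir=out)
    return {"dir": out, "truth": truth,
            "paths": sorted(out.glob("*.pdb")),
            "mapping": load_mapping(out / "mapping.tsv")}


@pytest.fixture(scope="session")
def corpus_db(corpus):
    return build_database(corpus["paths"], corpus["mapping"])


@pytest.fixture(scope="session")
def defect_corpus(tmp_path_factory):
    """2-family x 5-member corpus with one engineered defect per entry."""
    out = tmp_path_factory.mktemp("defect_corpus")
    truth = generate_corpus(2, 5, seed=13, out_dir=out,
                            defect_table=DEFECT_TABLE)
    return {"dir": out, "truth": truth,
            "paths": sorted(out.glob("*.pdb")),
            "mapping": load_mapping(out / "mapping.tsv")}


@pytest.fixture(scope="session")
def first_structure(corpus):
    return parse_structure(corpus["paths"][0])


def make_chain(coords, chain_id="A", name="ALA"):
    """A bare CA-only chain from an (n, 3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    residues = tuple(
        Residue(name, str(i + 1), (Atom("CA", "C", coords[i]),))
        for i in range(len(coords))
    )
    return ChainRecord(chain_id, residues)


@pytest.fixture
def chain_factory():
    return make_chain
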