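import pytest

from genealias.fixture_gen import canonical_human_fixture, write_gene_info
from genealias.gene_db import build_index, parse_gene_info

# The ten inflammation-related search terms of the worked example, with the
# official symbols and Entrez IDs they should resolve to when every pending
# suggestion is resolved to its top-ranked candidate.
INFLAMMATION_TERMS = [
    "TGF-β", "IL-8", "MCP-1", "CRP", "TNF-α",
    "CXCR1", "CXCR2", "CCR2", "MYPT1", "TGF-β1",
]
EXPECTED_SYMBOLS = [
    "TGFB1", "CXCL8", "CCL2", "CRP", "TNF",
    "CXCR1", "CXCR2", "CCR2", "PPP1R12A", "TGFB1",
]
EXPECTED_ENTREZ = [7040, 3576, 6347, 1401, 7124, 3577, 3579, 729230, 4659, 7040]


@pytest.fixture(scope="session")
def canonical_spec():
    return canonical_human_fixture()


@pytest.fixture(scope="session")
def canonical_records(canonical_spec):
    return canonical_spec.to_records()


@pytest.fixture(scope="session")
def canonical_index(canonical_records):
    return build_index(canonical_records)


@pytest.fixture()
def canonical_db_path(tmp_path, canonical_spec):
    path = tmp_path / "human.gene_info.tsv"
    write_gene_info(canonical_spec, path)
    return path


@pytest.fixture(scope="session")
def reparse_canonical(canonical_spec, tmp_path_factory):
    """Records obtained by writing the canonical fixture to disk and parsing
    it back — the path every CLI run exercises."""
    path = tmp_path_factory.mktemp("db") / "human.gene_info.tsv"
    write_gene_info(canonical_spec, path)
    return parse_gene_info(path)
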