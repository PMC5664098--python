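import pytest

from hgtscan import fixtures, taxonomy


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    """Toy taxdump + mapping files written once per session."""
    outdir = tmp_path_factory.mktemp("toy_taxonomy")
    spec = fixtures.default_toy_taxonomy()
    paths = fixtures.make_toy_taxdump(spec, outdir)
    return outdir, paths, spec


@pytest.fixture(scope="session")
def db(toy_dir):
    _, paths, _ = toy_dir
    db = taxonomy.load_taxdump(paths["nodes"], paths["names"], paths["merged"])
    db.protein_to_taxid = taxonomy.load_protein_mapping(paths["gi_mapping"], "gi")
    return db


@pytest.fixture(scope="session")
def config():
    return fixtures.default_config()
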