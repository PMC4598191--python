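import pytest

from varmend.pipeline import run_trio
from varmend.simulate import TrioSimSpec, make_annotation_fixture, simulate_trio


@pytest.fixture(scope="session")
def trio_fixture():
    """One simulated trio with planted segments and candidate events."""
    return simulate_trio(TrioSimSpec(seed=1))


@pytest.fixture(scope="session")
def trio_paths(trio_fixture, tmp_path_factory):
    out = tmp_path_factory.mktemp("trio_fixture")
    return trio_fixture.write(out)


@pytest.fixture(scope="session")
def trio_run(trio_fixture, trio_paths, tmp_path_factory):
    out = tmp_path_factory.mktemp("trio_run")
    return run_trio(trio_paths["vcf"], "F", "M", "C", out,
                    freq_tsv=trio_paths["freq"],
                    genes_bed=trio_paths["genes"],
                    deletions_bed=trio_paths["deletions"],
                    disease_genes_path=trio_paths["disease_genes"])


@pytest.fixture(scope="session")
def annotation_fixture():
    return make_annotation_fixture(seed=0)
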