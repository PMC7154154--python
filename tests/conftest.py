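import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from varepi.candidate_report import run_pipeline
from varepi.core_io import GeneModel
from varepi.synthetic_data import SimConfig, generate_bundle


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_models():
    """Two genes on chr1: a plus-strand coding gene and a minus-strand ncRNA."""
    coding = GeneModel(
        gene_id="geneA", gene_name="GENEA", chrom="chr1", strand="+",
        tss=1000, tes=4000,
        exons=((1000, 1400), (2000, 2400), (3500, 4000)),
        utr5=((1000, 1099),), utr3=((3900, 4000),), biotype="coding",
        transcript_id="geneA.1")
    ncrna = GeneModel(
        gene_id="geneB", gene_name="GENEB", chrom="chr1", strand="-",
        tss=9000, tes=7000,
        exons=((7000, 7300), (8800, 9000)),
        biotype="noncoding", transcript_id="geneB.1")
    return [coding, ncrna]


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """Default synthetic bundle, written once per session."""
    out = tmp_path_factory.mktemp("bundle") / "default"
    generate_bundle(SimConfig(), seed=17, out_dir=out)
    return out


@pytest.fixture(scope="session")
def bundle(bundle_dir):
    return generate_bundle(SimConfig(), seed=17)


@pytest.fixture(scope="session")
def pipeline_result(bundle_dir):
    return run_pipeline(bundle_dir)
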