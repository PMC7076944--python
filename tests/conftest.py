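import pytest
from hypothesis import settings

import itrseq as iq

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")

PCSK9 = "TGGACCTCTTTGCCCCAGGGGA"


@pytest.fixture(scope="session")
def fixture_err0():
    """The default planted dataset, error-free."""
    return iq.default_fixture(seed=0, err_rate=0.0)


@pytest.fixture(scope="session")
def fixture_paths(fixture_err0, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    return iq.write_fixture(fixture_err0, outdir)


@pytest.fixture(scope="session")
def pipeline_result(fixture_err0, fixture_paths):
    """Full pipeline output on the default fixture (computed once)."""
    fx = fixture_err0
    p = fixture_paths
    return iq.run_pipeline(iq.PipelineConfig(), iq.PipelineInputs(
        r1=p["r1"], r2=p["r2"], samples=p["samples"], genome=p["genome"],
        itr=p["itr"], primer=fx.primer, motif=fx.motif,
    ))
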