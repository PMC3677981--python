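import pytest

from vestrt.pipeline import RunConfig, run_simulation_study


@pytest.fixture(scope="session")
def recovery_df(tmp_path_factory):
    """20-seed simulate-then-refit recovery study over the rotation set,
    with the reference per-condition trial noise."""
    out = tmp_path_factory.mktemp("recovery")
    cfg = RunConfig(seeds=tuple(range(20)), output_dir=str(out))
    return run_simulation_study(cfg)
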