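import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from sidscreen.pipeline import demo_pipeline_config, run_pipeline


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """The bundled planted demonstration pipeline, run once at seed 0."""
    out = tmp_path_factory.mktemp("demo_pipeline")
    manifest = run_pipeline(demo_pipeline_config(out, seed=0))
    return manifest, out
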