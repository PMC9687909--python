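import numpy as np
import pytest

from angioflow import pipeline as pl


@pytest.fixture(scope="session")
def mini_pipeline():
    """Miniature four-case pipeline through the dataset stage (~5 s)."""
    config, sequences, images, fields, table = pl.make_fixtures(seed=7)
    return {"config": config, "sequences": sequences, "images": images,
            "fields": fields, "table": table}


@pytest.fixture(scope="session")
def full_run():
    """The default desk-scale pipeline run used by the acceptance checks.

    This is the same computation `scripts/acceptance.py` performs; it is
    session-scoped because the four-case simulation plus the repeated
    cross-validation of all models takes several minutes.
    """
    return pl.run_pipeline(pl.default_config(seed=1))
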