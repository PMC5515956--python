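from pathlib import Path

import pytest

from triowes.fixture import gene_flag_table, load_study_fixture
from triowes.model import FilterConfig
from triowes.prioritize import run_cohort

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def study():
    """The packaged 19-trio study fixture: (trios, variants_by_trio, annotations)."""
    return load_study_fixture()


@pytest.fixture(scope="session")
def study_results(study):
    """Full pipeline run over the study fixture with default config."""
    trios, variants, annotations = study
    return run_cohort(trios, variants, annotations, FilterConfig(), gene_flag_table())


@pytest.fixture()
def default_cfg():
    return FilterConfig()
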