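import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from isomirqtl import simulate_cohort, standard_cohort_config
from isomirqtl.pipeline import analyze_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort: 12 subjects, 6 precursors."""
    cfg = standard_cohort_config(
        seed=7, n_subjects=12, n_precursors=6, reads_per_subject_per_mirna=60
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_analysis(small_cohort):
    """Full in-memory analysis of the small cohort (min_subjects relaxed to 3)."""
    return analyze_cohort(small_cohort, min_subjects=3, min_informative_subjects=5)
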