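import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import seropanel as sp

settings.register_profile(
    "ci", derandomize=True, max_examples=60, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study with a strong 4h spike and a treated-only 1d spike."""
    config = sp.StudyConfig(
        n_proteins=120,
        mean_total_scans_per_sample=3000.0,
        abundance_dispersion=0.8,
        seed=42,
        spike_set=(sp.Spike(0, "4h", 16.0), sp.Spike(1, "1d", 8.0, treated_only=True)),
    )
    return config, sp.generate_study(config)


@pytest.fixture(scope="session")
def small_matrix(small_study):
    config, psms = small_study
    thresholds = sp.FilterThresholds()
    retained = sp.filter_psms(psms, thresholds)
    hits = sp.assemble_protein_hits(retained, thresholds)
    return sp.build_count_matrix(hits, sp.design_from_psms(psms))


def make_psms(rows):
    """PSM table from (sample, animal, group, tp, fraction, protein, peptide, sp, pp)."""
    return pd.DataFrame(rows, columns=sp.simulate.PSM_COLUMNS)
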