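"""Generator contracts: determinism, design coverage, count-model calibration."""

import numpy as np
import pandas as pd
import pytest

import seropanel as sp
from seropanel.simulate import PSM_COLUMNS


def test_zero_proteins_gives_empty_table():
    psms = sp.generate_study(sp.StudyConfig(n_proteins=0))
    assert list(psms.columns) == PSM_COLUMNS
    assert psms.empty


def test_fixed_seed_is_byte_identical(tmp_path):
    config = sp.StudyConfig(n_proteins=40, mean_total_scans_per_sample=500.0, seed=7)
    a, b = sp.generate_study(config), sp.generate_study(config)
    pd.testing.assert_frame_equal(a, b)
    pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
    sp.simulate.write_psm_table(pa, a)
    sp.simulate.write_psm_table(pb, b)
    assert pa.read_bytes() == pb.read_bytes()


@pytest.mark.parametrize(
    "kwargs, message",
    [
        ({"n_animals": 0}, "n_animals"),
        ({"n_fractions": 0}, "n_fractions"),
        ({"n_proteins": -1}, "n_proteins"),
        ({"mean_total_scans_per_sample": 0.0}, "mean_total_scans_per_sample"),
        ({"abundance_dispersion": 0.0}, "abundance_dispersion"),
        ({"decoy_fraction": 1.0}, "decoy_fraction"),
        ({"spike_set": (sp.Spike(99, "4h", 2.0),)}, "protein_index"),
        ({"spike_set": (sp.Spike(0, "3d", 2.0),), "n_timepoints": 1}, "timepoint"),
        ({"spike_set": (sp.Spike(0, "4h", 0.5),)}, "fold"),
    ],
)
def test_invalid_config_reported_by_field_name(kwargs, message):
    base = dict(n_proteins=10)
    base.update(kwargs)
    with pytest.raises(ValueError, match=message):
        sp.generate_study(sp.StudyConfig(**base))


def test_design_coverage_and_record_invariants(small_study):
    config, psms = small_study
    expected_samples = {
        sp.simulate.sample_id(a, g, t)
        for a in config.animal_ids
        for g in sp.simulate.GROUPS
        for t in config.timepoints
    }
    assert set(psms["sample_id"]) == expected_samples
    assert psms["fraction"].between(1, config.n_fractions).all()
    for col in ("spectrum_probability", "protein_probability"):
        assert psms[col].between(0, 1).all()
    # sample_id <-> (animal, group, timepoint) bijection under the paired design
    keys = psms[["sample_id", "animal_id", "group", "timepoint"]].drop_duplicates()
    assert len(keys) == len(expected_samples)


def test_peptides_unique_per_protein(small_study):
    _, psms = small_study
    owners = psms.groupby("peptide_sequence")["protein_accession"].nunique()
    assert (owners == 1).all()


def test_grand_total_matches_closed_form_expectation():
    """Per-sample totals are Poisson sums: mean over replicates must sit
    within 3 standard errors of mean_total_scans_per_sample."""
    mean_total = 300.0
    totals = []
    for rep in range(200):
        config = sp.StudyConfig(
            n_proteins=500,
            n_animals=2,
            n_timepoints=1,
            mean_total_scans_per_sample=mean_total,
            seed=rep,
        )
        psms = sp.generate_study(config)
        totals.extend(psms.groupby("sample_id").size().tolist())
    totals = np.asarray(totals, dtype=float)
    se = np.sqrt(mean_total / totals.size)  # Var = mean for a Poisson sum
    assert abs(totals.mean() - mean_total) < 3 * se


def test_spike_check_errors_and_edge_cases(small_study):
    _, psms = small_study
    with pytest.raises(ValueError, match="P99999"):
        sp.empirical_spike_check(psms, [sp.Spike(99999, "4h", 2.0)])
    assert sp.empirical_spike_check(psms, []).empty


def test_unit_fold_spikes_center_on_one():
    """fold=1 spikes are null: observed pooled ratios scatter around 1."""
    spikes = tuple(sp.Spike(i, "4h", 1.0) for i in range(5))
    ratios = []
    for rep in range(50):
        config = sp.StudyConfig(
            n_proteins=30,
            n_timepoints=1,
            mean_total_scans_per_sample=2000.0,
            abundance_dispersion=0.4,
            spike_set=spikes,
            seed=300 + rep,
        )
        psms = sp.generate_study(config)
        ratios.extend(sp.empirical_spike_check(psms, spikes)["observed_ratio"])
    mean = np.nanmean(ratios)
    assert abs(mean - 1.0) < 0.05


def test_fold16_spike_ratio_concentrates_on_nominal():
    """Monte-Carlo mean of the observed pooled ratio approaches the nominal
    fold change (small positive ratio-estimator bias of order 1/E[x_c])."""
    spikes = (sp.Spike(4, "4h", 16.0),)
    ratios = []
    for rep in range(200):
        config = sp.StudyConfig(
            n_proteins=20,
            n_timepoints=1,
            mean_total_scans_per_sample=1500.0,
            abundance_dispersion=0.4,
            spike_set=spikes,
            seed=10_000 + rep,
        )
        psms = sp.generate_study(config)
        ratios.append(
            sp.empirical_spike_check(psms, spikes)["observed_ratio"].iloc[0]
        )
    ratios = np.asarray(ratios)
    se = ratios.std(ddof=1) / np.sqrt(ratios.size)
    assert abs(ratios.mean() - 16.0) < 4 * se + 0.1


def test_marginal_conservation(small_study):
    """Each sample's grand total equals the sum of its per-protein counts."""
    _, psms = small_study
    per_sample = psms.groupby("sample_id").size()
    per_protein = psms.groupby(["sample_id", "protein_accession"]).size()
    assert per_protein.groupby("sample_id").sum().equals(per_sample)


def test_treated_only_spike_absent_from_controls(small_study):
    config, psms = small_study
    acc = sp.simulate.protein_accession(1)  # treated-only spike at 1d
    sub = psms[(psms["timepoint"] == "1d") & (psms["protein_accession"] == acc)]
    assert (sub["group"] == "treated").all()
    assert len(sub) > 0
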