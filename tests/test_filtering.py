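"""Probability thresholds, the two-peptide rule, and fraction merging."""

import numpy as np
import pandas as pd
import pytest

import seropanel as sp
from conftest import make_psms

THR = sp.FilterThresholds()


def _row(sample="s1", fraction=1, protein="P1", peptide="AAAK", spec=0.95, prot=0.9):
    return ("%s" % sample, "A01", "control", "4h", fraction, protein, peptide, spec, prot)


def test_probability_boundaries_are_inclusive():
    psms = make_psms(
        [
            _row(peptide="AAK", spec=0.85, prot=0.60),  # exactly at both thresholds
            _row(peptide="CCK", spec=0.84, prot=0.99),
            _row(peptide="DDK", spec=0.99, prot=0.59),
        ]
    )
    kept = sp.filter_psms(psms, THR)
    assert kept["peptide_sequence"].tolist() == ["AAK"]


def test_filter_preserves_order_and_handles_empty():
    psms = make_psms([_row(peptide=p) for p in ("AK", "CK", "DK")])
    kept = sp.filter_psms(psms, THR)
    assert kept["peptide_sequence"].tolist() == ["AK", "CK", "DK"]
    empty = sp.filter_psms(psms.iloc[0:0], THR)
    assert empty.empty


def test_missing_probability_is_an_error():
    psms = make_psms([_row(), _row(peptide="CCK", spec=np.nan)])
    with pytest.raises(ValueError, match="record 1.*spectrum_probability"):
        sp.filter_psms(psms, THR)


def test_filtering_is_idempotent(small_study):
    _, psms = small_study
    once = sp.filter_psms(psms, THR)
    twice = sp.filter_psms(once, THR)
    pd.testing.assert_frame_equal(once, twice)


def test_raising_thresholds_never_retains_more_proteins(small_study):
    """Monotonicity of the identification cascade in every threshold."""
    _, psms = small_study
    levels = [
        sp.FilterThresholds(0.50, 0.30, 1),
        sp.FilterThresholds(0.85, 0.60, 2),
        sp.FilterThresholds(0.95, 0.80, 3),
    ]
    n_proteins = []
    for thr in levels:
        hits = sp.assemble_protein_hits(sp.filter_psms(psms, thr), thr)
        n_proteins.append(hits["protein_accession"].nunique())
    assert n_proteins == sorted(n_proteins, reverse=True)


def test_two_peptide_rule_pools_fractions_first():
    """One peptide in fraction 2 plus a different one in fraction 7 of the
    same sample satisfies the rule; five spectra of a single peptide do not."""
    psms = make_psms(
        [
            _row(fraction=2, protein="P1", peptide="AAK"),
            _row(fraction=7, protein="P1", peptide="CCK"),
        ]
        + [_row(fraction=1, protein="P2", peptide="DDK")] * 5
    )
    hits = sp.assemble_protein_hits(psms, THR)
    assert hits["protein_accession"].tolist() == ["P1"]
    assert hits.loc[0, "unique_peptide_count"] == 2
    assert hits.loc[0, "spectral_count"] == 2
    assert sp.assemble_protein_hits(psms.iloc[0:0], THR).empty


def test_two_peptide_rule_is_per_sample():
    psms = make_psms(
        [
            _row(sample="s1", protein="P1", peptide="AAK"),
            _row(sample="s1", protein="P1", peptide="CCK"),
            _row(sample="s2", protein="P1", peptide="AAK"),
        ]
    )
    hits = sp.assemble_protein_hits(psms, THR)
    assert hits["sample_id"].tolist() == ["s1"]


def _design(samples):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "animal_id": ["A01"] * len(samples),
            "group": ["control"] * len(samples),
            "timepoint": ["4h"] * len(samples),
        }
    )


def test_count_matrix_zero_fill_and_totals():
    hits = pd.DataFrame(
        [{"sample_id": "s1", "protein_accession": "P1",
          "unique_peptide_count": 2, "spectral_count": 7}]
    )
    matrix = sp.build_count_matrix(hits, _design(["s1", "s2"]))
    assert matrix.counts.loc["P1"].tolist() == [7, 0]
    assert matrix.totals.tolist() == [7, 0]


def test_count_matrix_rejects_unknown_sample_and_duplicates():
    hits = pd.DataFrame(
        [{"sample_id": "sX", "protein_accession": "P1",
          "unique_peptide_count": 2, "spectral_count": 3}]
    )
    with pytest.raises(ValueError, match="sX"):
        sp.build_count_matrix(hits, _design(["s1"]))
    dup = pd.DataFrame(
        [
            {"sample_id": "s1", "protein_accession": "P1",
             "unique_peptide_count": 2, "spectral_count": 3},
            {"sample_id": "s1", "protein_accession": "P1",
             "unique_peptide_count": 2, "spectral_count": 4},
        ]
    )
    with pytest.raises(ValueError, match="duplicate"):
        sp.build_count_matrix(dup, _design(["s1"]))


def test_fraction_merge_conserves_sample_totals(small_study):
    """Column sums of the count matrix equal the per-sample retained PSM
    counts (restricted to proteins passing the two-peptide rule)."""
    _, psms = small_study
    retained = sp.filter_psms(psms, THR)
    hits = sp.assemble_protein_hits(retained, THR)
    matrix = sp.build_count_matrix(hits, sp.design_from_psms(psms))

    kept_proteins = {
        sample: set(h["protein_accession"])
        for sample, h in hits.groupby("sample_id")
    }
    for sample in matrix.design.index:
        direct = retained[
            (retained["sample_id"] == sample)
            & retained["protein_accession"].isin(kept_proteins.get(sample, set()))
        ]
        assert matrix.totals[sample] == len(direct)
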