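"""Synthetic PSM-level data for a paired-control serum proteomics study.

The generator emulates the structure of a paired ocular-injury study: six
animals, each serving as its own control (mock procedure vs. treatment),
sampled at three time points, with each serum sample pre-fractionated into
ten isoelectric-focusing (IEF) fractions before LC-MS/MS.

The count model is deliberately simple and matches the premise of spectral
counting — that the number of MS/MS spectra matched to a protein tracks its
abundance:

* protein abundances are log-normal (wide dynamic range, as in serum);
* per-sample spectral counts per protein are Poisson with rate proportional
  to abundance x number of tryptic peptides, scaled so the expected grand
  total per sample equals ``mean_total_scans_per_sample``;
* each protein has a latent isoelectric point and its PSMs spread over
  adjacent IEF fractions by a discretised bell, so fraction merging is a
  real operation downstream;
* identification probabilities come from two Beta modes (high for true
  matches, low for decoys), so the probability thresholds downstream have
  genuine work to do;
* spiked proteins have their treated-group Poisson rate multiplied by the
  fold change at the spiked time point; a treated-only spike sets the
  control rate to zero (giving the undefined "-" abundance ratio).

Spiked rates are not renormalised, so a strong spike slightly inflates the
treated grand total — exactly as a genuinely elevated protein would in a
real run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TIMEPOINTS = ("4h", "1d", "3d")
GROUPS = ("control", "treated")

#: Column order of the on-disk PSM table (tab-separated, one header line).
PSM_COLUMNS = [
    "sample_id",
    "animal_id",
    "group",
    "timepoint",
    "fraction",
    "protein_accession",
    "peptide_sequence",
    "spectrum_probability",
    "protein_probability",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def protein_accession(index: int) -> str:
    """Accession string used by the generator for protein ``index``."""
    return f"P{index:05d}"


def sample_id(animal_id: str, group: str, timepoint: str) -> str:
    return f"{animal_id}_{group}_{timepoint}"


@dataclass(frozen=True)
class Spike:
    """A treatment-elevated protein: rate x ``fold`` in treated samples at
    one time point; ``treated_only`` zeroes the control rate instead."""

    protein_index: int
    timepoint: str
    fold: float
    treated_only: bool = False


@dataclass(frozen=True)
class ProbabilityModel:
    """Beta(a, b) modes for identification probabilities.

    True matches draw from the high modes, decoy matches from the low ones.
    Defaults put ~95% of true spectra above the 0.85 spectrum threshold and
    essentially all decoys below it.
    """

    true_spectrum: tuple[float, float] = (38.0, 2.0)
    decoy_spectrum: tuple[float, float] = (2.0, 8.0)
    true_protein: tuple[float, float] = (20.0, 2.0)
    decoy_protein: tuple[float, float] = (2.0, 4.0)


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one simulated paired-control study.

    Defaults mirror the study design (6 animals, paired mock/treated, 3 time
    points, 10 IEF fractions) and a serum-like proteome: ~900 detectable
    proteins with log-normal abundances spanning several orders of magnitude.
    """

    n_animals: int = 6
    n_timepoints: int = 3
    n_fractions: int = 10
    n_proteins: int = 900
    mean_total_scans_per_sample: float = 25000.0
    abundance_dispersion: float = 2.0
    peptides_per_protein_mean: float = 7.0
    probability_noise: ProbabilityModel = field(default_factory=ProbabilityModel)
    decoy_fraction: float = 0.10
    spike_set: tuple[Spike, ...] = ()
    seed: int = 0

    @property
    def timepoints(self) -> tuple[str, ...]:
        return TIMEPOINTS[: self.n_timepoints]

    @property
    def animal_ids(self) -> tuple[str, ...]:
        return tuple(f"A{i + 1:02d}" for i in range(self.n_animals))

    def validate(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if not 1 <= self.n_timepoints <= len(TIMEPOINTS):
            raise ValueError(f"n_timepoints must be in [1, {len(TIMEPOINTS)}]")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        if self.mean_total_scans_per_sample <= 0:
            raise ValueError("mean_total_scans_per_sample must be > 0")
        if self.abundance_dispersion <= 0:
            raise ValueError("abundance_dispersion must be > 0")
        if self.peptides_per_protein_mean < 1:
            raise ValueError("peptides_per_protein_mean must be >= 1")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must be in [0, 1)")
        for spike in self.spike_set:
            if not 0 <= spike.protein_index < self.n_proteins:
                raise ValueError(
                    f"spike_set: protein_index {spike.protein_index} outside "
                    f"[0, {self.n_proteins})"
                )
            if spike.timepoint not in self.timepoints:
                raise ValueError(
                    f"spike_set: timepoint {spike.timepoint!r} not among "
                    f"{self.timepoints}"
                )
            if spike.fold < 1:
                raise ValueError("spike_set: fold must be >= 1")


def _unique_peptides(rng: np.random.Generator, total: int) -> np.ndarray:
    """``total`` distinct synthetic tryptic-peptide strings (8-20 residues)."""
    lengths = rng.integers(8, 21, size=total)
    flat = rng.integers(0, len(_AMINO_ACIDS), size=int(lengths.sum()))
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    out = np.empty(total, dtype=object)
    seen: set[str] = set()
    for i in range(total):
        seq = "".join(_AMINO_ACIDS[j] for j in flat[offsets[i] : offsets[i + 1]])
        while seq in seen:  # vanishingly rare at these lengths
            seq = "".join(
                _AMINO_ACIDS[j]
                for j in rng.integers(0, len(_AMINO_ACIDS), size=lengths[i])
            )
        seen.add(seq)
        out[i] = seq
    return out


def _empty_psm_table() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in PSM_COLUMNS})
    df["fraction"] = df["fraction"].astype(np.int64)
    for c in ("spectrum_probability", "protein_probability"):
        df[c] = df[c].astype(float)
    return df


def generate_study(config: StudyConfig) -> pd.DataFrame:
    """Simulate one full study and return its PSM table.

    The table covers every animal x group x time point x fraction; identical
    configs (same seed) give identical tables.
    """
    config.validate()
    if config.n_proteins == 0:
        return _empty_psm_table()

    rng = np.random.default_rng(config.seed)
    n = config.n_proteins

    abundance = rng.lognormal(mean=0.0, sigma=config.abundance_dispersion, size=n)
    n_peptides = 1 + rng.poisson(config.peptides_per_protein_mean - 1.0, size=n)
    pep_sequences = _unique_peptides(rng, int(n_peptides.sum()))
    pep_start = np.concatenate(([0], np.cumsum(n_peptides)))[:-1]

    # Latent pI -> discretised bell over fractions (pH 3-10 gradient).
    pi = rng.uniform(3.0, 10.0, size=n)
    centres = 3.0 + (np.arange(config.n_fractions) + 0.5) * (7.0 / config.n_fractions)
    bell = np.exp(-0.5 * ((centres[None, :] - pi[:, None]) / 0.8) ** 2)
    frac_cum = np.cumsum(bell / bell.sum(axis=1, keepdims=True), axis=1)

    weight = abundance * n_peptides
    base_rate = config.mean_total_scans_per_sample * weight / weight.sum()

    spikes_at: dict[str, list[Spike]] = {}
    for spike in config.spike_set:
        spikes_at.setdefault(spike.timepoint, []).append(spike)

    pm = config.probability_noise
    accessions = np.array([protein_accession(i) for i in range(n)], dtype=object)

    chunks: list[dict[str, np.ndarray]] = []
    for tp in config.timepoints:
        for group in GROUPS:
            rate = base_rate.copy()
            for spike in spikes_at.get(tp, ()):
                if group == "treated":
                    rate[spike.protein_index] *= spike.fold
                elif spike.treated_only:
                    rate[spike.protein_index] = 0.0
            for animal in config.animal_ids:
                counts = rng.poisson(rate)
                m = int(counts.sum())
                prot = np.repeat(np.arange(n), counts)
                pep_local = (rng.random(m) * n_peptides[prot]).astype(np.int64)
                fraction = (
                    (rng.random(m)[:, None] > frac_cum[prot]).sum(axis=1) + 1
                ).astype(np.int64)
                decoy = rng.random(m) < config.decoy_fraction
                spec_p = np.where(
                    decoy,
                    rng.beta(*pm.decoy_spectrum, size=m),
                    rng.beta(*pm.true_spectrum, size=m),
                )
                prot_p = np.where(
                    decoy,
                    rng.beta(*pm.decoy_protein, size=m),
                    rng.beta(*pm.true_protein, size=m),
                )
                sid = sample_id(animal, group, tp)
                chunks.append(
                    {
                        "sample_id": np.full(m, sid, dtype=object),
                        "animal_id": np.full(m, animal, dtype=object),
                        "group": np.full(m, group, dtype=object),
                        "timepoint": np.full(m, tp, dtype=object),
                        "fraction": fraction,
                        "protein_accession": accessions[prot],
                        "peptide_sequence": pep_sequences[pep_start[prot] + pep_local],
                        "spectrum_probability": spec_p,
                        "protein_probability": prot_p,
                    }
                )

    data = {
        col: np.concatenate([chunk[col] for chunk in chunks]) for col in PSM_COLUMNS
    }
    return pd.DataFrame(data, columns=PSM_COLUMNS)


def empirical_spike_check(
    psms: pd.DataFrame, spike_set: Sequence[Spike]
) -> pd.DataFrame:
    """Observed pooled treated/control count ratio for each spiked protein.

    Calibration harness for the generator: group totals are taken over the
    NON-spiked proteins only, so the spike's own contribution does not
    deflate the normalisation and the observed ratio is a consistent
    estimator of the nominal fold change. (The analysis-facing statistics in
    :mod:`seropanel.stats` normalise by full grand totals, as the published
    method does.)
    """
    rows = []
    known = set(psms["protein_accession"].unique()) if len(psms) else set()
    spiked_acc = {protein_accession(s.protein_index) for s in spike_set}
    for spike in spike_set:
        acc = protein_accession(spike.protein_index)
        if acc not in known:
            raise ValueError(f"spike references unknown protein {acc}")
        sub = psms[psms["timepoint"] == spike.timepoint]
        ref = sub[~sub["protein_accession"].isin(spiked_acc)]
        t_treated = int((ref["group"] == "treated").sum())
        t_control = int((ref["group"] == "control").sum())
        hit = sub[sub["protein_accession"] == acc]
        x_treated = int((hit["group"] == "treated").sum())
        x_control = int((hit["group"] == "control").sum())
        if x_control == 0 or t_treated == 0 or t_control == 0:
            ratio = np.nan
        else:
            ratio = (x_treated / t_treated) / (x_control / t_control)
        rows.append(
            {
                "protein_accession": acc,
                "timepoint": spike.timepoint,
                "observed_ratio": ratio,
            }
        )
    return pd.DataFrame(
        rows, columns=["protein_accession", "timepoint", "observed_ratio"]
    )


def write_psm_table(path: str | Path, psms: pd.DataFrame, *, seed: int | None = None) -> None:
    """Write a PSM table as TSV; if ``seed`` is given, record it in a JSON
    sidecar (``<path>.meta.json``) for reproducibility."""
    path = Path(path)
    psms.to_csv(path, sep="\t", index=False)
    if seed is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps({"seed": seed}, indent=2) + "\n")


def read_psm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"fraction": np.int64})
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} missing columns: {missing}")
    return df[PSM_COLUMNS]


def with_seed(config: StudyConfig, seed: int) -> StudyConfig:
    """A copy of ``config`` with a different RNG seed."""
    return replace(config, seed=seed)
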