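# Demonstration study: paired design (6 animals x mock/treated x 3 time
# points x 10 IEF fractions) with a proteome small enough to inspect by eye.
# Spiked proteins emulate injury-elevated biomarkers: two strong early
# responders (one at each of 4h and 1d) and one treated-only protein.
study:
  n_animals: 6
  n_timepoints: 3
  n_fractions: 10
  n_proteins: 250
  mean_total_scans_per_sample: 6000.0
  abundance_dispersion: 1.0
  seed: 2026
spikes:
  - {protein_index: 5, timepoint: "4h", fold: 16.0}
  - {protein_index: 5, timepoint: "1d", fold: 20.0}
  - {protein_index: 11, timepoint: "1d", fold: 8.0}
  - {protein_index: 17, timepoint: "4h", fold: 6.0, treated_only: true}
thresholds:
  spectrum_probability_min: 0.85
  protein_probability_min: 0.60
  min_unique_peptides: 2
cascade:
  alpha_prefilter: 0.05
  alpha_adjusted: 0.05
  min_fold: 2.0
  min_detection_fraction: 0.5
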