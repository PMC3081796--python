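# Methods

## Study design and quantification model

The pipeline targets a paired-control design: n = 6 animals, each sampled
under a mock (control) procedure and again after treatment, at three time
points (4 h, 1 day, 3 days). Each serum sample is split into 10 IEF
fractions analysed separately by LC-MS/MS; the fractions are merged back per
sample before any statistics, so the unit of analysis is the (animal, group,
time point) sample.

Quantification is spectral counting: a protein's relative abundance in a
sample is proxied by the number of MS/MS spectra (PSMs) matched to it. All
inference is on pooled counts — per protein and time point the six control
samples and six treated samples are summed. Per-animal variance is
deliberately not modelled: one p-value per protein per time point is
computed from the pooled 2×2 comparison, which is the documented analysis
convention here. Pooling (rather than averaging per-animal statistics) is a
choice the upstream description leaves open; it is the simpler and more
powerful reading and is applied uniformly.

## Identification filtering

* Probability thresholds: spectrum ≥ 0.85, protein ≥ 0.60. Comparisons are
  inclusive (≥) so that the stated thresholds are themselves attainable
  values.
* Two-peptide rule: within one sample, after merging its fractions, a
  protein needs ≥ 2 distinct peptide sequences. Applying the rule per sample
  (not per fraction, not study-wide) keeps the later "detected in ≥ 50% of
  treated samples" count well defined; "detection" everywhere means presence
  after all identification filters.
* A unique peptide is a distinct sequence string; modified forms are out of
  scope, and synthetic peptides are unique to one protein so no inference or
  grouping of shared peptides is needed.

## Statistics

For pooled counts x_c, x_t with group grand totals T_c, T_t (totals over all
proteins in the group's samples at that time point):

* Normalized scan count ratio R = (x_t/T_t)/(x_c/T_c); undefined when
  x_c = 0 (rendered "-"). Ratios are reported to 4 decimals.
* G statistic (likelihood-ratio test of a common detection rate):
  G = 2[x_c ln(x_c/ê_c) + x_t ln(x_t/ê_t)], ê_g = T_g(x_c+x_t)/(T_c+T_t),
  referred to the χ² distribution with 1 df. The expected counts ê are
  total-scan-normalized, which is the reading adopted for a "normalized
  p-value"; no further normalization is applied.
* Zero-count rule: when exactly one group's count is zero, 0.5 is added to
  both counts and both totals for the G computation only; the ratio column
  still reports the undefined marker. A protein absent from both groups has
  no test.
* p-values are floored at 1e-300: underflow is never rendered as an exact
  zero for finite G (reference tables that print 0.00E+00 are read as
  underflow).

Known property: the χ²(1) reference is anticonservative for small pooled
counts (a generic feature of likelihood-ratio tests on sparse counts); in
simulation the rejection rate under the null is ~0.15 for pooled counts of
20–50 and within Monte-Carlo error of 0.05 once pooled counts reach ~100.
The calibration checks therefore run in the large-count regime; conclusions
about rare proteins rest on the filter cascade's stringency, not on exact
small-sample calibration.

## Filter cascade

Per time point: (1) keep raw p < 0.05 and elevated in treated (R > 1, or
treated-only with x_t > 0); (2) Holm-Sidak step-down adjustment over exactly
this subset — the family size m is the elevated, pre-filtered subset, which
changes every adjusted p and is therefore fixed as the documented choice;
(3) keep adjusted p < 0.05; (4) keep R ≥ 2, with treated-only proteins
(undefined R) bypassing the fold rule; (5) keep proteins detected in ≥ 50%
of treated samples, boundary inclusive (3 of 6 passes). The detection rule
constrains treated samples only. Output rows are ordered by descending
ratio, undefined-ratio rows last, ties by ascending adjusted p — an output
convention only.

Holm-Sidak: sort ascending, candidate_i = 1 − (1 − p_(i))^(m−i+1), running
maxima enforce monotonicity, cap at 1, return in input order. Implemented
with expm1/log1p so small inputs do not underflow prematurely; tests verify
equality with an independent step-down implementation.

Note on error control: because the family adjusted is a subset pre-selected
at raw p < 0.05, the procedure does not control the family-wise error rate
over the full protein list; it reproduces the published cascade as stated.
In simulation the per-null-protein probability of entering the final panel
is ~1e-3, well below the adjusted alpha.

## GO summary

Each candidate carries one biological-process and one cellular-component
term from a supplied mapping keyed by protein accession (a transcription of
the study's published classification ships with the package). Counting is
flat — no ontology graph, no ancestor propagation, no enrichment statistic —
over distinct proteins; the defining term per category is the maximal-count
term, with all ties returned. Unmapped panel proteins are carried through
flagged, with a warning.

## Synthetic data generator

The generator emulates what the downstream stages need from real data:

* abundances log-normal (σ = `abundance_dispersion`, default 2.0, giving the
  several-orders-of-magnitude dynamic range typical of serum);
* per-sample per-protein counts Poisson with rate ∝ abundance × peptide
  count, normalized so the expected grand total per sample equals
  `mean_total_scans_per_sample` (default 25 000 — a plausible per-sample
  MS/MS yield for 10 fractions on an ion-trap instrument; the source study
  does not state its totals, so this is a calibration choice, as is the
  dispersion);
* ~900 proteins by default, matching the reported identification depth;
* each protein has a latent pI uniform on pH 3–10; its PSMs spread over
  adjacent fractions by a discretised Gaussian bell (σ = 0.8 fractions) —
  enough structure to make fraction merging a real operation without
  modelling IEF chemistry;
* peptide counts per protein are 1 + Poisson(mean−1) (default mean 7);
  sequences are random amino-acid strings, globally unique, so the
  two-peptide rule is unambiguous;
* identification probabilities draw from Beta modes — true matches
  Beta(38,2)/Beta(20,2) for spectrum/protein, decoys Beta(2,8)/Beta(2,4) —
  with a decoy fraction of 0.10, so the probability filters remove a
  realistic ~11% of PSMs;
* spikes multiply the treated-group rate by the fold change at one time
  point; treated-only spikes zero the control rate. Spiked rates are not
  renormalised, so a strong spike slightly inflates the treated total, as a
  genuinely elevated protein would.

What the generator does **not** emulate: raw spectra (no m/z, retention
time, or search-engine scoring), shared peptides between proteins,
between-animal biological variance beyond Poisson noise, and correlated
missingness. Passing tests therefore demonstrate the correctness of the
pipeline's logic and its statistical behaviour under the stated count model,
not robustness to overdispersed real serum data.

`empirical_spike_check`, the generator's calibration harness, normalizes by
group totals over the non-spiked proteins only; otherwise the spike's own
contribution to the treated total would bias the observed ratio below the
nominal fold. The analysis-facing ratio uses full totals, as the published
method does.

## Problem sizes in tests and the acceptance script

Replicated simulations use reduced sizes chosen as this package's standard
verification conditions: null-calibration replicates use 300 proteins, one
time point, mean total 9 000 and dispersion 0.25 (placing pooled counts in
the χ² asymptotic regime the check is about); spike-recovery replicates use
300 proteins, mean total 6 000, dispersion 0.5, three fold-16 spikes.
Tolerances on Monte-Carlo estimates are multiples of the replicate-level
standard error, not fixed constants.

## Degenerate inputs and tie-breaks

Empty protein sets yield empty tables (not errors) in the generator and GO
annotation; an empty time point, a protein absent from both groups, an empty
p-value family, and fewer than two identification totals are errors. GO
frequency ties order by GO identifier; candidate ordering ties break by
adjusted p. Matrix columns with no retained hits are explicit zero columns,
and totals are always column sums by construction.
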