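"""Candidate biomarker panel: filter cascade and cross-time-point overlap.

Applies the elevation pre-filter, Holm-Sidak adjustment, twofold rule and
50%-detection rule per time point, then reports which candidates the time
points share. The spiked proteins (P00005, P00011, P00017) should be
recovered; everything else in the panel is a false positive.
"""

from pathlib import Path

from seropanel import CascadeConfig, apply_cascade, compare_groups, cross_timepoint_overlap
from seropanel.filtering import read_count_matrix
from seropanel.io import write_candidates
from seropanel.pipeline import load_config

HERE = Path(__file__).parent
RESULTS = HERE.parent / "results" / "demo"


def main() -> None:
    config = load_config(HERE / "config.yaml")
    cascade_cfg = CascadeConfig(**config["cascade"])
    matrix = read_count_matrix(RESULTS / "counts.tsv", RESULTS / "design.tsv")
    panels = {}
    for tp in dict.fromkeys(matrix.design["timepoint"]):
        comparisons = compare_groups(matrix, tp)
        n_treated = len(matrix.samples(tp, "treated"))
        panel = apply_cascade(comparisons, cascade_cfg, n_treated)
        panels[tp] = panel
        write_candidates(panel, RESULTS / f"candidates_{tp}.tsv")
        print(f"\ncandidates at {tp} ({len(panel)}):")
        if len(panel):
            print(panel.to_string(index=False))
    report = cross_timepoint_overlap(panels)
    report.to_frame().to_csv(RESULTS / "overlap.tsv", sep="\t", index=False)
    print("\n" + report.summary())


if __name__ == "__main__":
    main()
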