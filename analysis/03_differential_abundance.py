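"""Pooled G-test differential abundance per time point.

For each protein, counts are pooled over the six animals per group and the
normalized scan-count ratio and G-test p-value are computed against the
group grand totals. Writes one comparison table per time point and prints
the most significant proteins.
"""

from pathlib import Path

from seropanel import compare_groups
from seropanel.filtering import read_count_matrix
from seropanel.io import write_comparisons

HERE = Path(__file__).parent
RESULTS = HERE.parent / "results" / "demo"


def main() -> None:
    matrix = read_count_matrix(RESULTS / "counts.tsv", RESULTS / "design.tsv")
    for tp in dict.fromkeys(matrix.design["timepoint"]):
        comparisons = compare_groups(matrix, tp)
        write_comparisons(comparisons, RESULTS / f"comparisons_{tp}.tsv")
        top = comparisons.nsmallest(3, "p_raw")
        print(f"\n{tp}: {len(comparisons)} proteins tested; most significant:")
        print(
            top[["protein_accession", "x_c", "x_t", "ratio", "G", "p_raw"]]
            .to_string(index=False)
        )


if __name__ == "__main__":
    main()
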