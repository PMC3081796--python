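"""GO-term summary of the published candidate panel.

Tallies one cellular-component and one biological-process term per protein
over the packaged reference panel (19 distinct proteins) and selects the
defining terms — the ones shared by the greatest number of proteins.
"""

from pathlib import Path

from seropanel import annotate, defining_terms, term_frequencies
from seropanel.datasets import load_candidate_table, load_go_annotations

RESULTS = Path(__file__).parent.parent / "results" / "published_panel"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    annotated = annotate(load_candidate_table(), load_go_annotations())
    annotated.to_csv(RESULTS / "go_annotated.tsv", sep="\t", index=False)
    for category in ("component", "process"):
        freq = term_frequencies(annotated, category)
        freq.to_csv(RESULTS / f"go_{category}_frequencies.tsv", sep="\t", index=False)
        print(f"\n{category} term tallies over {int(annotated['mapped'].sum())} proteins:")
        print(freq.to_string(index=False))
    defining = defining_terms(annotated)
    print("\ndefining terms:")
    for category, terms in defining.items():
        for gid, label in terms:
            print(f"  {category}: {gid} ({label})")


if __name__ == "__main__":
    main()
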