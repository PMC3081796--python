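"""Flat gene-ontology tallies over a candidate biomarker panel.

Each panel protein carries one biological-process and one cellular-component
GO term via a user-supplied mapping (accession, human homolog gene id, one
term per category). Terms are counted over distinct proteins and the
defining term of each category is the one shared by the greatest number of
proteins (all ties returned). No ontology graph, ancestor propagation or
enrichment statistic is involved — this is transparent counting.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import pandas as pd

GO_MAP_COLUMNS = [
    "protein_accession",
    "gene_id",
    "process_go_id",
    "process_label",
    "component_go_id",
    "component_label",
]

CATEGORIES = ("component", "process")

_GO_PATTERN = re.compile(r"^GO:\d{7}$")


def read_go_map(path: str | Path) -> pd.DataFrame:
    go_map = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GO_MAP_COLUMNS if c not in go_map.columns]
    if missing:
        raise ValueError(f"GO map {path} missing columns: {missing}")
    for col in ("process_go_id", "component_go_id"):
        bad = go_map.loc[~go_map[col].fillna("").str.match(_GO_PATTERN), col]
        if len(bad):
            raise ValueError(f"malformed GO identifier in {col}: {bad.iloc[0]!r}")
    return go_map[GO_MAP_COLUMNS]


def annotate(panel: pd.DataFrame, go_map: pd.DataFrame) -> pd.DataFrame:
    """One annotated row per distinct panel protein.

    Proteins absent from the mapping are carried through with empty terms,
    flagged ``mapped = False``, and reported in a warning. Duplicate mapping
    rows for one protein are an error.
    """
    dup = go_map["protein_accession"].duplicated()
    if dup.any():
        acc = go_map.loc[dup, "protein_accession"].iloc[0]
        raise ValueError(f"duplicate GO mapping rows for protein {acc}")
    proteins = panel[["protein_accession"]].drop_duplicates()
    annotated = proteins.merge(go_map, on="protein_accession", how="left")
    annotated["mapped"] = annotated["process_go_id"].notna()
    unmapped = annotated.loc[~annotated["mapped"], "protein_accession"].tolist()
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} panel protein(s) lack GO annotation: "
            + ", ".join(unmapped),
            stacklevel=2,
        )
    for col in GO_MAP_COLUMNS[1:]:
        annotated[col] = annotated[col].fillna("")
    return annotated.reset_index(drop=True)


def term_frequencies(annotated: pd.DataFrame, category: str) -> pd.DataFrame:
    """Counts of each GO term over distinct mapped proteins, descending.

    Ties are ordered by GO identifier.
    """
    if category not in CATEGORIES:
        raise ValueError(f"category must be one of {CATEGORIES}, got {category!r}")
    if annotated.empty:
        return pd.DataFrame(columns=["go_id", "label", "count"])
    mapped = annotated[annotated["mapped"]]
    freq = (
        mapped.groupby([f"{category}_go_id", f"{category}_label"])
        .size()
        .reset_index(name="count")
        .rename(
            columns={f"{category}_go_id": "go_id", f"{category}_label": "label"}
        )
    )
    return freq.sort_values(
        ["count", "go_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def defining_terms(annotated: pd.DataFrame) -> dict[str, list[tuple[str, str]]]:
    """Per category, the term(s) shared by the greatest number of proteins."""
    out: dict[str, list[tuple[str, str]]] = {}
    for category in CATEGORIES:
        freq = term_frequencies(annotated, category)
        if freq.empty:
            out[category] = []
            continue
        top = freq["count"].max()
        winners = freq[freq["count"] == top]
        out[category] = list(zip(winners["go_id"], winners["label"]))
    return out
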