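"""End-to-end pipeline: simulate -> filter -> compare -> cascade -> GO.

Configuration is a YAML/JSON-compatible mapping with four blocks (all
optional; defaults are the study's stated thresholds):

.. code-block:: yaml

    study:                # StudyConfig fields (simulate-first mode)
      n_animals: 6
      n_timepoints: 3
      ...
    spikes:               # list of {protein_index, timepoint, fold, treated_only}
      - {protein_index: 3, timepoint: "4h", fold: 16}
    psm_table: null       # path to an existing PSM TSV (skips simulation)
    thresholds:
      spectrum_probability_min: 0.85
      protein_probability_min: 0.60
      min_unique_peptides: 2
    cascade:
      alpha_prefilter: 0.05
      alpha_adjusted: 0.05
      min_fold: 2.0
      min_detection_fraction: 0.5
    go_map: null          # path to a GO mapping TSV (null -> packaged table)

Every stage writes a standalone TSV under the output directory and the run
manifest records per-stage row counts, so each stage is independently
checkable. Identical (config, seed) pairs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from statistics import mean, stdev
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import cascade as cascade_mod
from . import datasets, go, io, stats
from .filtering import (
    FilterThresholds,
    build_count_matrix,
    design_from_psms,
    assemble_protein_hits,
    filter_psms,
    write_count_matrix,
)
from .simulate import Spike, StudyConfig, generate_study, read_psm_table, write_psm_table

logger = logging.getLogger("seropanel")


class StageError(RuntimeError):
    """Failure attributed to a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    proteins_detected: dict[str, int] = field(default_factory=dict)
    prefilter_family_size: dict[str, int] = field(default_factory=dict)
    candidates: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"


def load_config(source: str | Path | Mapping[str, Any] | None) -> dict:
    if source is None:
        raw: dict = {}
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        raw = yaml.safe_load(Path(source).read_text()) or {}
    raw.setdefault("study", {})
    raw.setdefault("spikes", [])
    raw.setdefault("psm_table", None)
    raw.setdefault("thresholds", {})
    raw.setdefault("cascade", {})
    raw.setdefault("go_map", None)
    return raw


def study_config_from(config: Mapping[str, Any], seed: int | None) -> StudyConfig:
    spikes = tuple(Spike(**s) for s in config.get("spikes", []))
    kwargs = dict(config.get("study", {}))
    if seed is not None:
        kwargs["seed"] = seed
    return StudyConfig(spike_set=spikes, **kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


def run_pipeline(
    config_source: str | Path | Mapping[str, Any] | None,
    out_dir: str | Path,
    *,
    seed: int | None = None,
    timepoint: str = "all",
) -> RunManifest:
    """Run every stage and write all outputs plus ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = load_config(config_source)
    manifest = RunManifest(config=config, seed=-1)

    # --- simulate (or load) ------------------------------------------------
    try:
        t0 = _stage("simulate")
        if config["psm_table"]:
            psm_path = Path(config["psm_table"])
            if not psm_path.exists():
                raise FileNotFoundError(f"PSM table not found: {psm_path}")
            psms = read_psm_table(psm_path)
            manifest.input_digests[psm_path.name] = _sha256(psm_path)
            manifest.seed = seed if seed is not None else -1
        else:
            study = study_config_from(config, seed)
            manifest.seed = study.seed
            psms = generate_study(study)
            write_psm_table(out / "psms.tsv", psms, seed=study.seed)
            manifest.outputs["psms"] = "psms.tsv"
        logger.info("simulate: %d PSMs (%.2fs)", len(psms), time.perf_counter() - t0)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError("simulate", exc) from exc

    # --- identification filtering -----------------------------------------
    try:
        t0 = _stage("filter")
        thresholds = FilterThresholds(**config["thresholds"])
        retained = filter_psms(psms, thresholds)
        hits = assemble_protein_hits(retained, thresholds)
        design = design_from_psms(psms)
        matrix = build_count_matrix(hits, design)
        write_count_matrix(matrix, out / "counts.tsv", out / "design.tsv")
        manifest.outputs["counts"] = "counts.tsv"
        manifest.outputs["design"] = "design.tsv"
        logger.info(
            "filter: %d/%d PSMs retained, %d proteins (%.2fs)",
            len(retained), len(psms), matrix.counts.shape[0], time.perf_counter() - t0,
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("filter", exc) from exc

    timepoints = (
        list(dict.fromkeys(design["timepoint"])) if timepoint == "all" else [timepoint]
    )

    # --- compare + cascade per time point ----------------------------------
    cascade_cfg = cascade_mod.CascadeConfig(**config["cascade"])
    candidate_tables: dict[str, pd.DataFrame] = {}
    for tp in timepoints:
        try:
            t0 = _stage(f"compare[{tp}]")
            comparisons = stats.compare_groups(matrix, tp)
            io.write_comparisons(comparisons, out / f"comparisons_{tp}.tsv")
            manifest.outputs[f"comparisons_{tp}"] = f"comparisons_{tp}.tsv"
            manifest.proteins_detected[tp] = len(comparisons)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"compare[{tp}]", exc) from exc
        try:
            _stage(f"cascade[{tp}]")
            n_treated = len(matrix.samples(tp, "treated"))
            elevated = cascade_mod.prefilter_elevated(comparisons, cascade_cfg)
            manifest.prefilter_family_size[tp] = len(elevated)
            panel = cascade_mod.apply_cascade(comparisons, cascade_cfg, n_treated)
            io.write_candidates(panel, out / f"candidates_{tp}.tsv")
            manifest.outputs[f"candidates_{tp}"] = f"candidates_{tp}.tsv"
            manifest.candidates[tp] = len(panel)
            candidate_tables[tp] = panel
            logger.info(
                "cascade[%s]: %d detected -> m=%d -> %d candidates (%.2fs)",
                tp, len(comparisons), len(elevated), len(panel),
                time.perf_counter() - t0,
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"cascade[{tp}]", exc) from exc

    # --- overlap ------------------------------------------------------------
    try:
        _stage("overlap")
        report = cascade_mod.cross_timepoint_overlap(candidate_tables)
        report.to_frame().to_csv(out / "overlap.tsv", sep="\t", index=False)
        (out / "overlap_summary.txt").write_text(report.summary() + "\n")
        manifest.outputs["overlap"] = "overlap.tsv"
    except Exception as exc:  # noqa: BLE001
        raise StageError("overlap", exc) from exc

    # --- GO summary ----------------------------------------------------------
    try:
        _stage("go")
        if config["go_map"]:
            go_path = Path(config["go_map"])
            if not go_path.exists():
                raise FileNotFoundError(f"GO map not found: {go_path}")
            go_map = go.read_go_map(go_path)
            manifest.input_digests[go_path.name] = _sha256(go_path)
        else:
            go_map = datasets.load_go_annotations()
        union = pd.concat(candidate_tables.values(), ignore_index=True) if candidate_tables else pd.DataFrame(columns=["protein_accession"])
        if len(union):
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                annotated = go.annotate(union, go_map)
            annotated.to_csv(out / "go_annotated.tsv", sep="\t", index=False)
            for category in go.CATEGORIES:
                go.term_frequencies(annotated, category).to_csv(
                    out / f"go_{category}_frequencies.tsv", sep="\t", index=False
                )
                manifest.outputs[f"go_{category}_frequencies"] = (
                    f"go_{category}_frequencies.tsv"
                )
            manifest.outputs["go_annotated"] = "go_annotated.tsv"
    except Exception as exc:  # noqa: BLE001
        raise StageError("go", exc) from exc

    (out / "manifest.json").write_text(manifest.to_json())
    manifest.outputs["manifest"] = "manifest.json"
    return manifest


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def summarize_totals(totals: Sequence[int]) -> tuple[int, int]:
    """Mean and sample (n-1) standard deviation of per-time-point protein
    totals, each rounded half-up to an integer."""
    if len(totals) < 2:
        raise ValueError("need at least two totals (sd undefined otherwise)")
    return _round_half_up(mean(totals)), _round_half_up(stdev(totals))


def configure_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(asctime)s] %(message)s", "%H:%M:%S"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
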